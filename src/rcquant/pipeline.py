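"""End-to-end orchestration of the phantom study and batch quantification.

``run_synthetic_study`` mirrors the full two-stage workflow at phantom
scale: generate a cohort → simulate raters → STAPLE references → augment →
cross-validate one network per muscle per fold → postprocess raw
predictions → quantify degeneration → evaluate automatic-vs-reference and
inter-rater agreement plus ratio regressions.  Every artifact is
reproducible from the config snapshot + seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentParams
from .io import read_mask, read_section, write_mask, write_phantom_case
from .metrics import (AgreementRecord, agreement_frame, dice, hausdorff,
                      inter_rater_report, paired_t_test, regression_eval)
from .phantom import CohortSampler, generate_cohort
from .postprocess import finalize_mask
from .quantify import QuantConfig, quantify_degeneration
from .staple import binarize_reference, staple_em
from .train import TrainConfig, crossvalidate
from .types import MUSCLE_LABELS
from .unet import NetworkConfig


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable snapshot of an entire study configuration."""

    n_cases: int = 40
    n_raters: int = 3
    rater_boundary_sd_mm: float = 0.5
    sampler: CohortSampler = field(default_factory=lambda: CohortSampler(image_size=128))
    network: NetworkConfig = field(default_factory=lambda: NetworkConfig(64, 4, 8))
    training: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            n_folds=5, learning_rate=5e-3, max_epochs=8, patience=8
        )
    )
    augment: AugmentParams = field(
        default_factory=lambda: AugmentParams(
            scale_range=(-0.10, 0.10), rotation_range_deg=(-15.0, 15.0),
            expansion_factor=2,
        )
    )
    quant: QuantConfig = field(default_factory=QuantConfig)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def desk_study_config(seed: int = 0) -> PipelineConfig:
    """The reduced-scale study profile: 40 cases of 128×128 sections, a
    base-8 depth-4 network fed at 64×64 (predictions upscaled back to the
    native resolution for quantification), 3 simulated raters, twofold
    augmentation."""
    return PipelineConfig(seed=seed)


@dataclass
class StudyResult:
    config: PipelineConfig
    agreement: pd.DataFrame     # auto-vs-STAPLE and rater-vs-rater records
    quant: pd.DataFrame         # per case/muscle ratios (auto, staple, truth)
    regressions: pd.DataFrame   # slope/R² per ratio and comparison
    t_tests: pd.DataFrame       # auto-vs-inter-rater Dice, per muscle
    summary: dict


def run_synthetic_study(config: PipelineConfig | None = None,
                        out_dir: str | Path | None = None,
                        save_models: bool = False,
                        save_images: bool = False) -> StudyResult:
    """Run the full phantom study; optionally write all artifacts."""
    config = config or desk_study_config()
    muscles = MUSCLE_LABELS
    ss = np.random.SeedSequence(config.seed)
    cohort_seed, rater_seed, cv_seed = (int(s % (2 ** 31))
                                        for s in ss.generate_state(3))

    cases = generate_cohort(config.n_cases, config.sampler, seed=cohort_seed,
                            n_raters=config.n_raters,
                            boundary_sd_mm=config.rater_boundary_sd_mm)
    spacing = cases[0].section.pixel_size_mm

    # STAPLE reference per case and muscle
    references = {}
    for case in cases:
        for mi, muscle in enumerate(muscles):
            masks = [case.rater_masks[r][mi] for r in range(config.n_raters)]
            result = staple_em(masks)
            references[(case.case_id, muscle)] = binarize_reference(
                result, 0.5, muscle_label=muscle
            )

    # cross-validated premorbid prediction + postprocessing
    training = dataclasses.replace(config.training, seed=cv_seed)
    cv = crossvalidate(cases, n_folds=config.training.n_folds,
                       muscles=muscles, net_config=config.network,
                       train_config=training,
                       augment_params=config.augment, use_raters=True)
    # predictions come back at network resolution; upscale to the sections'
    # native resolution, keep the largest component and fill holes
    predicted = {
        key: finalize_mask(raw, config.sampler.image_size)
        for key, raw in cv.predictions.items()
    }

    # quantification with automatic, reference and ground-truth masks
    quant_rows = []
    agreement_records: list[AgreementRecord] = []
    for case in cases:
        for mi, muscle in enumerate(muscles):
            key = (case.case_id, muscle)
            auto = predicted[key]
            ref = references[key]
            truth = case.premorbid_masks[mi]
            row = {"case_id": case.case_id, "muscle": muscle,
                   "empty_auto_mask": auto.area_px == 0}
            for tag, mask in (("auto", auto), ("staple", ref), ("truth", truth)):
                if mask.area_px == 0:
                    for r in ("Ra", "Ri", "Ro", "Rd"):
                        row[f"{tag}_{r}"] = np.nan
                    continue
                meas = quantify_degeneration(case.section, mask, config.quant)
                row.update({f"{tag}_Ra": meas.ra, f"{tag}_Ri": meas.ri,
                            f"{tag}_Ro": meas.ro, f"{tag}_Rd": meas.rd})
            true_meas = case.true_measures[mi]
            row.update({f"true_{r}": getattr(true_meas, r.lower())
                        for r in ("Ra", "Ri", "Ro", "Rd")})
            quant_rows.append(row)
            if auto.area_px > 0:
                agreement_records.append(AgreementRecord(
                    case_id=case.case_id, muscle_label=muscle,
                    dice=dice(auto, ref),
                    hausdorff_mm=hausdorff(auto, ref, spacing),
                    comparison_kind="auto_vs_staple",
                ))
                agreement_records.append(AgreementRecord(
                    case_id=case.case_id, muscle_label=muscle,
                    dice=dice(auto, truth),
                    hausdorff_mm=hausdorff(auto, truth, spacing),
                    comparison_kind="auto_vs_truth",
                ))

    inter = inter_rater_report(
        {c.case_id: c.rater_masks for c in cases}, spacing
    )
    agreement = agreement_frame(agreement_records + inter)
    quant = pd.DataFrame(quant_rows)

    # regressions: automatic vs STAPLE-reference ratios, pooled over muscles
    reg_rows = []
    for param in ("Ra", "Ri", "Ro", "Rd"):
        for pred_tag, ref_tag, kind in (("auto", "staple", "auto_vs_staple"),
                                        ("auto", "true", "auto_vs_truth"),
                                        ("truth", "true", "truth_vs_true")):
            sub = quant[[f"{pred_tag}_{param}", f"{ref_tag}_{param}"]].dropna()
            if len(sub) < 3 or np.ptp(sub[f"{ref_tag}_{param}"]) == 0:
                continue
            rec = regression_eval(sub[f"{pred_tag}_{param}"],
                                  sub[f"{ref_tag}_{param}"], parameter=param)
            reg_rows.append({"parameter": param, "comparison": kind,
                             **dataclasses.asdict(rec)})
    regressions = pd.DataFrame(reg_rows)

    # paired t-test per muscle: auto-vs-STAPLE Dice against per-case mean
    # inter-rater Dice
    t_rows = []
    auto_df = agreement[agreement.comparison_kind == "auto_vs_staple"]
    inter_df = agreement[agreement.comparison_kind == "rater_vs_rater"]
    for muscle in muscles:
        a = auto_df[auto_df.muscle_label == muscle].set_index("case_id").dice
        b = inter_df[inter_df.muscle_label == muscle].groupby("case_id").dice.mean()
        common = a.index.intersection(b.index)
        if len(common) >= 3:
            res = paired_t_test(a.loc[common].values, b.loc[common].values)
            t_rows.append({"muscle": muscle, "t": res.t, "p_value": res.p_value,
                           "n": res.n, "degenerate": res.degenerate})
    t_tests = pd.DataFrame(t_rows)

    truth_df = agreement[agreement.comparison_kind == "auto_vs_truth"]
    summary = {
        "n_cases": config.n_cases,
        "n_networks": len(cv.models),
        "mean_dice_auto_vs_staple": float(auto_df.dice.mean()),
        "mean_dice_auto_vs_truth": float(truth_df.dice.mean()),
        "mean_dice_inter_rater": float(inter_df.dice.mean()),
        "mean_hausdorff_auto_vs_staple_mm": float(auto_df.hausdorff_mm.mean()),
        "n_empty_auto_masks": int(quant.empty_auto_mask.sum()),
    }
    for _, row in regressions[regressions.comparison == "auto_vs_truth"].iterrows():
        summary[f"slope_{row.parameter}_auto_vs_truth"] = row.slope
        summary[f"r2_{row.parameter}_auto_vs_truth"] = row.r_squared

    result = StudyResult(config=config, agreement=agreement, quant=quant,
                         regressions=regressions, t_tests=t_tests,
                         summary=summary)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(config.to_json())
        agreement.to_csv(out_dir / "agreement.csv", index=False)
        quant.to_csv(out_dir / "quantification.csv", index=False)
        regressions.to_csv(out_dir / "regressions.csv", index=False)
        t_tests.to_csv(out_dir / "t_tests.csv", index=False)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        if save_images:
            for case in cases:
                write_phantom_case(case, out_dir / "cases")
            for (case_id, muscle), mask in predicted.items():
                write_mask(mask, out_dir / "cases" / f"{case_id}_{muscle}_auto.nii.gz",
                           spacing)
        if save_models:
            mdir = out_dir / "models"
            mdir.mkdir(exist_ok=True)
            for (muscle, fold), model in cv.models.items():
                model.save(mdir / f"net_{muscle}_fold{fold}.npz")
    return result


def run_quantify_batch(image_dir: str | Path, mask_dir: str | Path,
                       config: QuantConfig = QuantConfig()
                       ) -> tuple[pd.DataFrame, list[dict]]:
    """Quantify every ``{case}_image.*`` / ``{case}_{muscle}_*.nii|png`` pair.

    Returns (rows, errors).  Missing or unreadable pairs are listed in
    ``errors``, never silently skipped.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    rows, errors = [], []
    images = sorted(p for p in image_dir.iterdir()
                    if p.name.endswith(("_image.nii.gz", "_image.nii",
                                        "_image.dcm", "_image.png")))
    for img_path in images:
        case_id = img_path.name.split("_image")[0]
        try:
            section = read_section(img_path)
        except Exception as exc:  # noqa: BLE001 — reported, not swallowed
            errors.append({"case_id": case_id, "file": str(img_path),
                           "error": str(exc)})
            continue
        for muscle in MUSCLE_LABELS:
            matches = sorted(mask_dir.glob(f"{case_id}_{muscle}_*.nii*")) or \
                sorted(mask_dir.glob(f"{case_id}_{muscle}_*.png"))
            if not matches:
                errors.append({"case_id": case_id, "file": "",
                               "error": f"no mask for muscle {muscle}"})
                continue
            try:
                mask = read_mask(matches[0], muscle)
                meas = quantify_degeneration(section, mask, config)
            except Exception as exc:  # noqa: BLE001
                errors.append({"case_id": case_id, "file": str(matches[0]),
                               "error": str(exc)})
                continue
            rows.append({"case_id": case_id, **meas.as_dict()})
    return pd.DataFrame(rows), errors
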