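"""Training and fivefold cross-validation of the premorbid network.

One independent binary network is trained per muscle per fold (the full
protocol is 4 muscles × 5 folds = 20 networks).  Fold assignment is by
case id, and every augmented copy of a case — and every rater's
delineation of it — stays in the same fold as its source, so no network
is ever evaluated on a case it saw in any form.  Within each fold a small
validation split (default 1% of cases, at least one case) is carved from
the training cases to select the best checkpoint by validation Dice.

Loss is soft Dice (suited to class-imbalanced binary segmentation),
optimized with Adam.  Training is deterministic given the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentedItem, AugmentParams, SegItem, augment_dataset
from .types import MUSCLE_LABELS, CTSection, PremorbidMask
from .unet import NetworkConfig, UNet, normalize_hu, predict_mask


@dataclass(frozen=True)
class TrainConfig:
    n_folds: int = 5
    val_split: float = 0.01
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 30
    patience: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.val_split < 1:
            raise ValueError("val_split must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be ≥ 2")


def assign_folds(case_ids: list[str], n_folds: int, seed: int = 0
                 ) -> dict[str, int]:
    """Disjoint, exhaustive fold assignment of case ids (seeded shuffle)."""
    ids = list(dict.fromkeys(case_ids))
    if n_folds > len(ids):
        raise ValueError(f"n_folds={n_folds} exceeds number of cases {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = {}
    for pos, idx in enumerate(perm):
        folds[ids[idx]] = pos % n_folds
    return folds


def _to_arrays(items: list[AugmentedItem], muscle_label: str
               ) -> tuple[np.ndarray, np.ndarray]:
    xs, ts = [], []
    for item in items:
        section, masks = item.materialize()
        mask = next(m for m in masks if m.muscle_label == muscle_label)
        xs.append(normalize_hu(section.pixels))
        ts.append(mask.pixels.astype(np.float32))
    return np.stack(xs)[:, None], np.stack(ts)[:, None]


def _mean_dice(model: UNet, x: np.ndarray, t: np.ndarray,
               batch: int = 8) -> float:
    scores = []
    for i in range(0, len(x), batch):
        proba = model.predict_proba(x[i:i + batch])
        pred = proba >= 0.5
        truth = t[i:i + batch] > 0.5
        for pm, tm in zip(pred, truth):
            denom = pm.sum() + tm.sum()
            scores.append(1.0 if denom == 0 else 2.0 * (pm & tm).sum() / denom)
    return float(np.mean(scores))


def train_fold(train_items: list[AugmentedItem], muscle_label: str,
               net_config: NetworkConfig,
               config: TrainConfig = TrainConfig()) -> tuple[UNet, pd.DataFrame]:
    """Train one network; return the best-validation-Dice checkpoint + log."""
    if not train_items:
        raise ValueError("empty training set")
    if muscle_label not in MUSCLE_LABELS:
        raise ValueError(f"unknown muscle {muscle_label!r}")
    rng = np.random.default_rng(config.seed)

    case_ids = list(dict.fromkeys(item.case_id for item in train_items))
    n_val = max(1, int(round(config.val_split * len(case_ids))))
    val_cases = set(
        np.array(case_ids)[rng.choice(len(case_ids), n_val, replace=False)]
    )
    tr = [it for it in train_items if it.case_id not in val_cases]
    va = [it for it in train_items if it.case_id in val_cases and it.is_identity]
    if not tr or not va:
        raise ValueError("validation split left train or val empty")

    x_tr, t_tr = _to_arrays(tr, muscle_label)
    x_va, t_va = _to_arrays(va, muscle_label)

    model = UNet(net_config, np.random.default_rng(config.seed))
    opt = nn.Adam(model.layers(), lr=config.learning_rate)
    best_state, best_dice, best_epoch = None, -1.0, -1
    rows = []
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            z = model.forward(x_tr[sel], train=True)
            p = nn.sigmoid(z)
            loss, dp = nn.soft_dice_loss(p, t_tr[sel])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            model.backward((dp * p * (1.0 - p)).astype(np.float32))
            opt.step()
            losses.append(loss)
        val_dice = _mean_dice(model, x_va, t_va)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_dice": val_dice})
        if val_dice > best_dice:
            best_dice, best_epoch = val_dice, epoch
            best_state = nn.get_state(model.layers())
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    nn.set_state(model.layers(), best_state)
    log = pd.DataFrame(rows)
    log.attrs["best_epoch"] = best_epoch
    log.attrs["best_val_dice"] = best_dice
    return model, log


@dataclass
class CVResult:
    """Out-of-fold predictions: every case predicted exactly once per
    muscle, by a network that never saw it or any augmented copy."""

    folds: dict[str, int]
    predictions: dict[tuple[str, str], PremorbidMask]  # (case_id, muscle) → raw mask
    models: dict[tuple[str, int], UNet]                # (muscle, fold) → network
    logs: dict[tuple[str, int], pd.DataFrame] = field(default_factory=dict)


def crossvalidate(cases, n_folds: int = 5,
                  muscles: tuple[str, ...] = MUSCLE_LABELS,
                  net_config: NetworkConfig = NetworkConfig(64, 4, 8),
                  train_config: TrainConfig = TrainConfig(),
                  augment_params: AugmentParams | None = None,
                  use_raters: bool = True) -> CVResult:
    """Fivefold (by default) cross-validated prediction of phantom cases.

    ``cases`` are phantom cases; training examples come from their rater
    delineations when present (and ``use_raters``), else the ground-truth
    masks.  Sections and masks are resampled to the network input size on
    the fly; raw predictions are returned at network resolution (upscale
    and cleanup happen downstream).
    """
    from .io import resample_to_network

    if n_folds > len(cases):
        raise ValueError("n_folds exceeds number of cases")
    folds = assign_folds([c.case_id for c in cases], n_folds,
                         seed=train_config.seed)

    size = net_config.input_size

    def fit(obj):
        return obj if obj.shape[0] == size else resample_to_network(obj, size)

    prepared: dict[str, tuple[CTSection, list[list[PremorbidMask]]]] = {}
    for case in cases:
        sec = fit(case.section)
        if use_raters and case.rater_masks:
            mask_sets = [[fit(m) for m in masks] for masks in case.rater_masks]
        else:
            mask_sets = [[fit(m) for m in case.premorbid_masks]]
        prepared[case.case_id] = (sec, mask_sets)

    def seg_items(case) -> list[SegItem]:
        sec, mask_sets = prepared[case.case_id]
        if use_raters and case.rater_masks:
            return [SegItem(case.case_id, r, sec, masks)
                    for r, masks in enumerate(mask_sets)]
        return [SegItem(case.case_id, -1, sec, mask_sets[0])]

    predictions: dict[tuple[str, str], PremorbidMask] = {}
    models: dict[tuple[str, int], UNet] = {}
    logs: dict[tuple[str, int], pd.DataFrame] = {}
    for muscle in muscles:
        for fold in range(n_folds):
            train_cases = [c for c in cases if folds[c.case_id] != fold]
            test_cases = [c for c in cases if folds[c.case_id] == fold]
            if not test_cases:
                raise ValueError(f"fold {fold} is empty")
            items = [si for c in train_cases for si in seg_items(c)]
            if augment_params is not None:
                items = augment_dataset(items, augment_params)
            else:
                items = [AugmentedItem(si, 0.0, 0.0, True) for si in items]
            model, log = train_fold(items, muscle, net_config, train_config)
            models[(muscle, fold)] = model
            logs[(muscle, fold)] = log
            for c in test_cases:
                predictions[(c.case_id, muscle)] = predict_mask(
                    model, prepared[c.case_id][0], muscle_label=muscle
                )
    return CVResult(folds=folds, predictions=predictions, models=models,
                    logs=logs)
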