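"""Segmentation-agreement metrics and statistical comparisons.

Dice coefficient, symmetric Hausdorff distance over boundary pixels (in
mm), paired Student t tests, and ordinary-least-squares regression of
predicted against reference degeneration ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .types import PremorbidMask


@dataclass(frozen=True)
class AgreementRecord:
    case_id: str
    muscle_label: str
    dice: float
    hausdorff_mm: float
    comparison_kind: str  # "auto_vs_staple" | "auto_vs_truth" | "rater_vs_rater"


@dataclass(frozen=True)
class RegressionRecord:
    parameter: str  # Ra / Ri / Ro / Rd
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    n: int


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p_value: float
    n: int
    degenerate: bool  # zero-variance differences


def dice(a: PremorbidMask, b: PremorbidMask) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks agree on absence → 1.0."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    am, bm = a.as_bool(), b.as_bool()
    denom = am.sum() + bm.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(am & bm) / denom


def boundary_pixels(mask: PremorbidMask) -> np.ndarray:
    """(K, 2) coordinates of foreground pixels with a 4-neighbor background."""
    m = mask.as_bool()
    eroded = ndimage.binary_erosion(m, ndimage.generate_binary_structure(2, 1),
                                    border_value=0)
    return np.argwhere(m & ~eroded)


def hausdorff(a: PremorbidMask, b: PremorbidMask,
              pixel_size_mm: tuple[float, float] = (1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in mm.

    Max over both directed maxima of nearest-boundary-point Euclidean
    distances, with coordinates scaled per-axis by the pixel size.
    Empty masks have no boundary and are rejected.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.area_px == 0 or b.area_px == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    scale = np.asarray(pixel_size_mm, dtype=float)
    pa = boundary_pixels(a) * scale
    pb = boundary_pixels(b) * scale
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def paired_t_test(x, y) -> PairedTResult:
    """Paired Student t test on per-case metric differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return PairedTResult(0.0, 1.0, x.size, degenerate=True)
        t = np.inf if diff[0] > 0 else -np.inf
        return PairedTResult(t, 0.0, x.size, degenerate=True)
    res = stats.ttest_rel(x, y)
    return PairedTResult(float(res.statistic), float(res.pvalue), x.size,
                         degenerate=False)


def regression_eval(pred, ref, parameter: str = "") -> RegressionRecord:
    """OLS of predicted on reference values; slope, R² and Pearson r."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("pred and ref must be equal-length 1D sequences")
    if pred.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(pred).all() and np.isfinite(ref).all()):
        raise ValueError("non-finite values in regression input")
    if np.ptp(ref) == 0:
        raise ValueError("reference values have zero variance")
    res = stats.linregress(ref, pred)
    return RegressionRecord(
        parameter=parameter,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        pearson_r=float(res.rvalue),
        n=pred.size,
    )


def inter_rater_report(cases_rater_masks: dict[str, list[list[PremorbidMask]]],
                       pixel_size_mm: tuple[float, float] = (1.0, 1.0)
                       ) -> list[AgreementRecord]:
    """Pairwise agreement between raters, one record per unordered pair
    per case per muscle (3 raters → 3 pairs per case)."""
    records: list[AgreementRecord] = []
    for case_id, rater_masks in cases_rater_masks.items():
        n_raters = len(rater_masks)
        if n_raters < 2:
            raise ValueError(f"case {case_id}: need ≥ 2 raters")
        n_muscles = len(rater_masks[0])
        for mi in range(n_muscles):
            for i, j in combinations(range(n_raters), 2):
                a, b = rater_masks[i][mi], rater_masks[j][mi]
                records.append(AgreementRecord(
                    case_id=case_id,
                    muscle_label=a.muscle_label,
                    dice=dice(a, b),
                    hausdorff_mm=hausdorff(a, b, pixel_size_mm),
                    comparison_kind="rater_vs_rater",
                ))
    return records


def agreement_frame(records: list[AgreementRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
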