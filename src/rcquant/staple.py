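"""STAPLE: simultaneous truth and performance level estimation.

Expectation-maximization fusion of multiple binary delineations into a
probabilistic estimate of the true segmentation, with per-rater
sensitivity p and specificity q (Warfield et al.'s formulation).

E-step: given (p, q) and the foreground prior π, the posterior foreground
probability at pixel i with rater decisions d_ij is

    W_i = a_i / (a_i + b_i),
    a_i = π       Π_j p_j^d_ij (1 − p_j)^(1 − d_ij)
    b_i = (1 − π) Π_j q_j^(1 − d_ij) (1 − q_j)^d_ij

M-step: p_j = Σ_i W_i d_ij / Σ_i W_i and
        q_j = Σ_i (1 − W_i)(1 − d_ij) / Σ_i (1 − W_i).

Defaults follow the reference conventions: p = q = 0.99999 initially, a
scalar prior equal to the mean foreground fraction across raters, and
convergence when max |ΔW| < 1e−6 (cap 100 iterations).  The computation
is restricted to a bounding box around the union of the rater masks (plus
margin); pixels outside are fixed background, so specificity is not
dominated by vast empty background.  The EM data log-likelihood
Σ_i log(a_i + b_i) is tracked per iteration and is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import PremorbidMask


@dataclass
class StapleResult:
    """Probabilistic reference and per-rater performance."""

    W: np.ndarray                 # per-pixel foreground probability
    p: np.ndarray                 # per-rater sensitivity
    q: np.ndarray                 # per-rater specificity
    n_iterations: int
    converged: bool
    log_likelihood: list[float] = field(default_factory=list)

    @property
    def reference_mask(self) -> PremorbidMask:
        return binarize_reference(self, 0.5)


def binarize_reference(result: StapleResult, threshold: float = 0.5,
                       muscle_label: str = "SS") -> PremorbidMask:
    """W ≥ threshold → foreground (ties go to foreground)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return PremorbidMask((result.W >= threshold).astype(np.uint8), muscle_label)


def staple_em(rater_masks: list[PremorbidMask],
              prior: float | np.ndarray | None = None,
              tol: float = 1e-6, max_iter: int = 100,
              init_pq: float = 0.99999,
              bbox_margin: int = 8) -> StapleResult:
    """Run STAPLE EM on ≥ 2 same-shape binary delineations.

    ``prior`` may be a scalar foreground probability, a per-pixel map, or
    None (mean foreground fraction across raters).  Deterministic: no
    randomness anywhere.
    """
    if len(rater_masks) < 2:
        raise ValueError("STAPLE needs at least 2 raters")
    shape = rater_masks[0].shape
    for m in rater_masks:
        if m.shape != shape:
            raise ValueError("rater masks must share one shape")
    d_full = np.stack([m.as_bool() for m in rater_masks])  # (R, H, W)
    union = d_full.any(axis=0)
    if not union.any():
        raise ValueError("all rater masks empty; sensitivity undefined")

    rows = np.nonzero(union.any(axis=1))[0]
    cols = np.nonzero(union.any(axis=0))[0]
    r0 = max(rows[0] - bbox_margin, 0)
    r1 = min(rows[-1] + bbox_margin + 1, shape[0])
    c0 = max(cols[0] - bbox_margin, 0)
    c1 = min(cols[-1] + bbox_margin + 1, shape[1])
    d = d_full[:, r0:r1, c0:c1].reshape(len(rater_masks), -1)  # (R, N)

    if prior is None:
        pi = float(d_full.mean(axis=(1, 2)).mean())
    elif np.isscalar(prior):
        pi = np.full(d.shape[1], float(prior))
    else:
        pi = np.asarray(prior)[r0:r1, c0:c1].ravel().astype(float)
    pi = np.clip(pi, 1e-8, 1 - 1e-8)

    p = np.full(len(rater_masks), init_pq)
    q = np.full(len(rater_masks), init_pq)
    w = None
    loglik: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for numerical safety
        log_a = np.log(pi) + (
            d * np.log(p)[:, None] + (~d) * np.log1p(-p)[:, None]
        ).sum(axis=0)
        log_b = np.log1p(-pi) + (
            (~d) * np.log(q)[:, None] + d * np.log1p(-q)[:, None]
        ).sum(axis=0)
        m = np.maximum(log_a, log_b)
        denom = m + np.log(np.exp(log_a - m) + np.exp(log_b - m))
        loglik.append(float(denom.sum()))
        w_new = np.exp(log_a - denom)
        if w is not None and np.max(np.abs(w_new - w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
        # M-step
        sw = w.sum()
        swc = (1.0 - w).sum()
        p = (d * w).sum(axis=1) / max(sw, 1e-12)
        q = ((~d) * (1.0 - w)).sum(axis=1) / max(swc, 1e-12)
        p = np.clip(p, 1e-8, 1 - 1e-8)
        q = np.clip(q, 1e-8, 1 - 1e-8)

    W = np.zeros(shape, dtype=float)
    W[r0:r1, c0:c1] = w.reshape(r1 - r0, c1 - c0)
    return StapleResult(W=W, p=p, q=q, n_iterations=it,
                        converged=converged, log_likelihood=loglik)
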