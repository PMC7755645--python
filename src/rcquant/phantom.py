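"""Synthetic sagittal-oblique CT phantoms with known ground truth.

Each phantom emulates the context of a shoulder section: four muscle
regions (SS, SC, IS, TM) drawn as smooth star-convex blobs arranged around
a central high-HU bone structure standing in for the scapula.  Muscle
degeneration is rendered with exact pixel bookkeeping:

* atrophy — the outermost pixels of the premorbid region are removed by a
  uniform radial shrink of the boundary and re-rendered at fat HU,
  emulating a shrunken residual muscle surrounded by fat;
* fatty infiltration — a compact fat pocket (HU below −29) carved inside
  the residual muscle, by default fully enclosed so hole filling must
  recover it;
* secondary bone formation — a compact high-HU island (HU above 166)
  inside the residual muscle.

Because degeneration is rendered pixel-exactly, the generator's recorded
:class:`~rcquant.quantify.DegenerationMeasures` are reproduced *exactly*
by :func:`~rcquant.quantify.quantify_degeneration` on the noise-free
image with the true premorbid mask.  Additive noise is clipped per tissue
class so it never crosses a classification threshold.

Simulated raters perturb each true boundary with a smooth random radial
displacement field, emulating independent human delineations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .quantify import DegenerationMeasures, measures_from_counts
from .types import MUSCLE_LABELS, CTSection, PremorbidMask

# geometry as fractions of image size
_BONE_RADIUS = 0.10
_MUSCLE_DIST = 0.30
_MUSCLE_RADIUS = 0.13
_MUSCLE_ANGLES_DEG = (45.0, 135.0, 225.0, 315.0)
# margin (HU) kept between noisy values and the classification thresholds
_NOISE_MARGIN = 4.0
_FAT_THRESH = -29.0
_BONE_THRESH = 166.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic section.

    Degeneration fractions are per muscle, each in [0, 1] with
    ``atrophy + fat + bone ≤ 1``; HU means must satisfy
    ``hu_fat < −29 < hu_muscle < 166 < hu_bone`` so tissue classes stay
    separable by the quantification thresholds.
    """

    image_size: int = 128
    pixel_size_mm: float = 0.5
    n_muscles: int = 4
    atrophy_fraction: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    fat_fraction: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    bone_fraction: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    hu_muscle: float = 50.0
    hu_fat: float = -100.0
    hu_bone: float = 300.0
    hu_background: float = -1000.0
    hu_noise_sd: float = 5.0
    enclosed_pockets: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be ≥ 64")
        if not 1 <= self.n_muscles <= len(MUSCLE_LABELS):
            raise ValueError(f"n_muscles must be in [1, {len(MUSCLE_LABELS)}]")
        for name in ("atrophy_fraction", "fat_fraction", "bone_fraction"):
            v = getattr(self, name)
            if np.isscalar(v):
                object.__setattr__(self, name, (float(v),) * self.n_muscles)
            elif len(v) != self.n_muscles:
                raise ValueError(f"{name} must have one entry per muscle")
        for a, f, b in zip(self.atrophy_fraction, self.fat_fraction,
                           self.bone_fraction):
            if min(a, f, b) < 0 or a + f + b > 1 + 1e-12:
                raise ValueError(
                    f"infeasible fractions: atrophy={a}, fat={f}, bone={b} "
                    "(each ≥ 0, sum ≤ 1)"
                )
        if not (self.hu_fat < _FAT_THRESH < self.hu_muscle
                < _BONE_THRESH < self.hu_bone):
            raise ValueError(
                "HU means must satisfy hu_fat < −29 < hu_muscle < 166 < hu_bone"
            )
        if self.hu_noise_sd < 0:
            raise ValueError("hu_noise_sd must be ≥ 0")

    @property
    def muscle_labels(self) -> tuple[str, ...]:
        return MUSCLE_LABELS[: self.n_muscles]


@dataclass
class _RadialBlob:
    """Star-convex region: r ≤ R(θ) about a center, R a low-order
    Fourier series.  Kept so rater simulation can displace the same
    analytic boundary that generated the mask."""

    center: tuple[float, float]  # (row, col)
    r0: float
    amps: np.ndarray    # harmonic amplitudes (relative)
    orders: np.ndarray  # harmonic orders
    phases: np.ndarray

    def radius(self, theta: np.ndarray) -> np.ndarray:
        r = np.ones_like(theta)
        for a, k, p in zip(self.amps, self.orders, self.phases):
            r = r + a * np.cos(k * theta + p)
        return self.r0 * r

    def rasterize(self, image_size: int,
                  displacement=None) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(image_size), np.arange(image_size),
                             indexing="ij")
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        theta = np.arctan2(dc, dr)
        radius = self.radius(theta)
        if displacement is not None:
            radius = radius + displacement(theta)
        return (dr * dr + dc * dc) <= radius * radius


@dataclass
class PhantomCase:
    """One rendered phantom with full ground truth."""

    case_id: str
    spec: PhantomSpec
    section: CTSection
    premorbid_masks: list[PremorbidMask]
    true_measures: list[DegenerationMeasures]
    rater_masks: list[list[PremorbidMask]] = field(default_factory=list)
    blobs: list[_RadialBlob] = field(default_factory=list)

    @property
    def n_raters(self) -> int:
        return len(self.rater_masks)


def _random_blob(rng: np.random.Generator, center, r0: float) -> _RadialBlob:
    orders = np.array([2, 3, 4, 5])
    amps = rng.uniform(0.01, 0.05, size=4) * rng.choice([-1, 1], size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    return _RadialBlob(center=center, r0=r0, amps=amps, orders=orders,
                       phases=phases)


def _radial_shrink(mask: np.ndarray, blob: "_RadialBlob", n_remove: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Remove exactly ``n_remove`` outermost pixels of a star-convex blob.

    Pixels are ranked by their relative radius r/R(θ), so removal is a
    uniform radial shrink of the boundary; the residual stays star-convex
    and therefore a single connected component.  A tiny seeded jitter
    breaks rank ties deterministically.
    """
    if n_remove == 0:
        return mask.copy()
    rows, cols = np.nonzero(mask)
    dr = rows - blob.center[0]
    dc = cols - blob.center[1]
    theta = np.arctan2(dc, dr)
    rho = np.hypot(dr, dc) / blob.radius(theta)
    order = np.argsort(-(rho + rng.uniform(0, 1e-6, rho.size)))
    out = mask.copy()
    out[rows[order[:n_remove]], cols[order[:n_remove]]] = False
    return out


def _compact_region(candidates: np.ndarray, seed_pt: tuple[int, int],
                    n_pixels: int) -> np.ndarray:
    """Pick the ``n_pixels`` candidate pixels nearest to ``seed_pt``."""
    rows, cols = np.nonzero(candidates)
    d2 = (rows - seed_pt[0]) ** 2 + (cols - seed_pt[1]) ** 2
    order = np.argsort(d2, kind="stable")[:n_pixels]
    out = np.zeros_like(candidates)
    out[rows[order], cols[order]] = True
    return out


def generate_phantom(spec: PhantomSpec, case_id: str = "phantom") -> PhantomCase:
    """Render one phantom section with exact degeneration bookkeeping."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    center = ((n - 1) / 2.0, (n - 1) / 2.0)

    bone_blob = _random_blob(rng, center, _BONE_RADIUS * n)
    bone_struct = bone_blob.rasterize(n)

    blobs: list[_RadialBlob] = []
    premorbid: list[np.ndarray] = []
    for i in range(spec.n_muscles):
        ang = np.deg2rad(_MUSCLE_ANGLES_DEG[i])
        r0 = _MUSCLE_RADIUS * n * rng.uniform(0.9, 1.1)
        c = (center[0] + _MUSCLE_DIST * n * np.cos(ang),
             center[1] + _MUSCLE_DIST * n * np.sin(ang))
        blob = _random_blob(rng, c, r0)
        m = blob.rasterize(n)
        blobs.append(blob)
        premorbid.append(m)

    occupied = bone_struct.copy()
    for m in premorbid:
        if (m & occupied).any():
            raise RuntimeError("phantom geometry overlap; reduce blob wobble")
        occupied |= m

    hu = np.full((n, n), spec.hu_background, dtype=np.float64)
    hu[bone_struct] = spec.hu_bone

    measures: list[DegenerationMeasures] = []
    fat_class = ~occupied  # pixels rendered at fat-or-lower HU (background too)
    muscle_class = np.zeros((n, n), dtype=bool)
    bone_class = bone_struct.copy()

    for i, (label, m) in enumerate(zip(spec.muscle_labels, premorbid)):
        s = int(m.sum())
        n_a = int(round(spec.atrophy_fraction[i] * s))
        n_i = int(round(spec.fat_fraction[i] * s))
        n_o = int(round(spec.bone_fraction[i] * s))
        if n_a + n_i + n_o > s:
            n_a = s - n_i - n_o  # rounding pushed the sum past S

        residual = _radial_shrink(m, blobs[i], n_a, rng)
        n_cc = ndimage.label(residual)[1] if residual.any() else 0
        if residual.any() and n_cc != 1:
            raise RuntimeError("residual muscle fragmented during atrophy peel")

        if n_i or n_o:
            if spec.enclosed_pockets:
                # EDT ≥ 2 leaves a ≥ 1 px residual-muscle wall around any
                # pocket, which the 4-connected background flood cannot cross
                interior = residual & (
                    ndimage.distance_transform_edt(residual) >= 2.0
                )
            else:
                interior = residual.copy()
            if n_i + n_o > int(interior.sum()):
                raise ValueError(
                    f"muscle {label}: fat+bone fractions infeasible for "
                    f"{'enclosed' if spec.enclosed_pockets else 'open'} "
                    f"rendering (need {n_i + n_o} px, capacity {int(interior.sum())})"
                )
            edt_int = ndimage.distance_transform_edt(residual)
            edt_int[~interior] = -1
            seed_fat = np.unravel_index(np.argmax(edt_int), edt_int.shape)
            fat = _compact_region(interior, seed_fat, n_i)
            if n_o:
                cand = interior & ~fat
                rows, cols = np.nonzero(cand)
                d2 = (rows - seed_fat[0]) ** 2 + (cols - seed_fat[1]) ** 2
                seed_bone = (rows[np.argmax(d2)], cols[np.argmax(d2)])
                bone_isl = _compact_region(cand, seed_bone, n_o)
            else:
                bone_isl = np.zeros_like(m)
        else:
            fat = np.zeros_like(m)
            bone_isl = np.zeros_like(m)

        atrophy_band = m & ~residual
        hu[residual] = spec.hu_muscle
        hu[atrophy_band] = spec.hu_fat
        hu[fat] = spec.hu_fat
        hu[bone_isl] = spec.hu_bone

        fat_class |= atrophy_band | fat
        bone_class |= bone_isl
        muscle_class |= residual & ~fat & ~bone_isl

        measures.append(measures_from_counts(
            label, s, s - n_a, n_i, n_o,
            spec.pixel_size_mm ** 2,
        ))

    if spec.hu_noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.hu_noise_sd, hu.shape)
        # clip per tissue class so noise never crosses a threshold
        hu[fat_class] = np.minimum(hu[fat_class], _FAT_THRESH - _NOISE_MARGIN)
        hu[muscle_class] = np.clip(hu[muscle_class],
                                   _FAT_THRESH + _NOISE_MARGIN,
                                   _BONE_THRESH - _NOISE_MARGIN)
        hu[bone_class] = np.maximum(hu[bone_class], _BONE_THRESH + _NOISE_MARGIN)
    hu = np.clip(hu, -1024, 3071)

    section = CTSection(hu, (spec.pixel_size_mm, spec.pixel_size_mm),
                        origin_id=case_id)
    masks = [PremorbidMask(m.astype(np.uint8), lab)
             for m, lab in zip(premorbid, spec.muscle_labels)]
    return PhantomCase(case_id=case_id, spec=spec, section=section,
                       premorbid_masks=masks, true_measures=measures,
                       blobs=blobs)


def simulate_raters(case: PhantomCase, n_raters: int = 3,
                    boundary_sd_mm: float = 0.5,
                    seed: int = 0) -> PhantomCase:
    """Add simulated human delineations to a phantom case.

    Each rater's mask is produced by displacing the true boundary radius
    R(θ) with a smooth zero-mean random field whose standard deviation
    over θ equals ``boundary_sd_mm``.  Star-convexity of the blobs keeps
    every perturbed mask a single connected component.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be ≥ 1")
    if boundary_sd_mm < 0:
        raise ValueError("boundary_sd_mm must be ≥ 0")
    rng = np.random.default_rng(seed)
    sd_px = boundary_sd_mm / case.spec.pixel_size_mm
    n = case.spec.image_size
    theta_grid = np.linspace(-np.pi, np.pi, 720, endpoint=False)

    rater_masks: list[list[PremorbidMask]] = []
    for _ in range(n_raters):
        per_muscle: list[PremorbidMask] = []
        for blob, true_mask in zip(case.blobs, case.premorbid_masks):
            if sd_px == 0:
                per_muscle.append(PremorbidMask(true_mask.pixels.copy(),
                                                true_mask.muscle_label))
                continue
            bcos = rng.standard_normal(4)
            bsin = rng.standard_normal(4)
            ks = np.arange(1, 5)

            def raw(theta):
                t = theta[..., None]
                return (bcos * np.cos(ks * t) + bsin * np.sin(ks * t)).sum(-1)

            scale = sd_px / max(raw(theta_grid).std(), 1e-9)
            disp = lambda theta: scale * raw(theta)
            arr = blob.rasterize(n, displacement=disp)
            per_muscle.append(PremorbidMask(arr.astype(np.uint8),
                                            true_mask.muscle_label))
        rater_masks.append(per_muscle)

    out = copy.copy(case)
    out.rater_masks = rater_masks
    return out


@dataclass(frozen=True)
class CohortSampler:
    """Distribution over PhantomSpec for cohort generation.

    Defaults emulate a mostly mildly degenerated arthroplasty cohort:
    atrophy and fatty-infiltration fractions uniform on [0, 0.3], and a
    small minority (12%) of cases carrying secondary bone formation of up
    to 5% of the premorbid surface.
    """

    atrophy_range: tuple[float, float] = (0.0, 0.3)
    fat_range: tuple[float, float] = (0.0, 0.3)
    bone_prob: float = 0.12
    bone_range: tuple[float, float] = (0.01, 0.05)
    image_size: int = 128
    pixel_size_mm: float = 0.5
    hu_noise_sd: float = 5.0

    def sample(self, rng: np.random.Generator, seed: int) -> PhantomSpec:
        nm = 4
        return PhantomSpec(
            image_size=self.image_size,
            pixel_size_mm=self.pixel_size_mm,
            n_muscles=nm,
            atrophy_fraction=tuple(rng.uniform(*self.atrophy_range, nm)),
            fat_fraction=tuple(rng.uniform(*self.fat_range, nm)),
            bone_fraction=tuple(
                rng.uniform(*self.bone_range) if rng.random() < self.bone_prob
                else 0.0
                for _ in range(nm)
            ),
            hu_noise_sd=self.hu_noise_sd,
            seed=seed,
        )


def generate_cohort(n_cases: int, sampler: CohortSampler | None = None,
                    seed: int = 0, n_raters: int = 0,
                    boundary_sd_mm: float = 0.5) -> list[PhantomCase]:
    """Generate a reproducible cohort of phantom cases.

    With ``n_raters > 0``, simulated delineations are attached to each
    case.  Per-case seeds derive from ``seed`` via ``SeedSequence``, so
    the cohort is byte-identical across runs.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be ≥ 1")
    sampler = sampler or CohortSampler()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_cases)
    cases = []
    for i, child in enumerate(children):
        sub = child.generate_state(3)
        rng = np.random.default_rng(int(sub[0]))
        spec = sampler.sample(rng, seed=int(sub[1] % (2 ** 31)))
        case = generate_phantom(spec, case_id=f"case{i:04d}")
        if n_raters:
            case = simulate_raters(case, n_raters=n_raters,
                                   boundary_sd_mm=boundary_sd_mm,
                                   seed=int(sub[2] % (2 ** 31)))
        cases.append(case)
    return cases
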