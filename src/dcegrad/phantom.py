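"""Synthetic 4D breast DCE-MRI phantom with known ground truth.

The phantom emulates the statistical structure the analysis pipeline
relies on, not anatomy: a static chest band across the posterior rows of
every slice, two half-elliptical breasts of fatty tissue in front of it,
a concentric fibroglandular core, an optional configurable fraction of
enhancing glandular voxels (background parenchymal enhancement, BPE)
following a mild persistent kinetic curve, and an optional lesion —
a sphere or anisotropic ellipsoid of voxels following a prescribed
kinetic curve (persistent/plateau/washout). Acquisition indices stand in
for the scanner's dynamic times; only their order matters downstream.

All randomness (BPE voxel subset, noise field) derives from the spec's
seed, so equal specs give bit-identical series. Voxel intensities are
arbitrary scanner units: air 0, fat at ``baseline_intensity``, glandular
tissue 10% above it, chest 30% above it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import DceSeries
from .synthesis_classify import postinitial_class_of

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "BPE_CATEGORIES",
    "bpe_category_of",
    "kinetic_curve",
    "breast_mask_2d",
    "glandular_mask_2d",
    "generate_phantom",
    "generate_cohort",
    "DEFAULT_BPE_DISTRIBUTION",
]

BPE_CATEGORIES = ("minimal", "mild", "moderate", "marked")

#: Cohort frequencies of the BPE categories (matching a screening
#: population in which marked enhancement is rare enough to be absent).
DEFAULT_BPE_DISTRIBUTION = {
    "minimal": 20 / 46,
    "mild": 18 / 46,
    "moderate": 8 / 46,
    "marked": 0.0,
}

#: bpe_fraction sampling band per category (half-open [lo, hi)).
_BPE_FRACTION_BANDS = {
    "minimal": (0.05, 0.24),
    "mild": (0.25, 0.49),
    "moderate": (0.50, 0.74),
    "marked": (0.75, 0.95),
}

_POSTINITIAL_CLASSES = ("continuous", "plateau", "washout")


def bpe_category_of(bpe_fraction: float) -> str:
    """BPE category from the enhancing-glandular fraction.

    minimal < 0.25 <= mild < 0.50 <= moderate < 0.75 <= marked.
    """
    if bpe_fraction < 0.25:
        return "minimal"
    if bpe_fraction < 0.50:
        return "mild"
    if bpe_fraction < 0.75:
        return "moderate"
    return "marked"


def kinetic_curve(
    baseline: float,
    initial_enhancement_pct: float,
    postinitial_class: str,
    postinitial_change_pct: float,
    n_acquisitions: int = 6,
    peak_index: int = 2,
) -> np.ndarray:
    """One signal value per acquisition for a two-phase kinetic curve.

    The signal rises linearly from ``baseline`` at acquisition 0 to
    ``baseline * (1 + initial_enhancement_pct/100)`` at ``peak_index``
    (0-based; the initial phase), then changes linearly to
    ``peak * (1 + postinitial_change_pct/100)`` at the last acquisition
    (the postinitial phase). The stated class must be consistent with
    the change: continuous > +10%, plateau within ±10%, washout < -10%.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if n_acquisitions < 2:
        raise ValueError("need at least 2 acquisitions")
    if not 1 <= peak_index < n_acquisitions:
        raise ValueError(
            f"peak_index must lie in [1, {n_acquisitions - 1}], got {peak_index}"
        )
    if initial_enhancement_pct < 0:
        raise ValueError("initial enhancement must be nonnegative")
    if postinitial_class not in _POSTINITIAL_CLASSES:
        raise ValueError(f"unknown postinitial class {postinitial_class!r}")
    if postinitial_class_of(postinitial_change_pct) != postinitial_class:
        raise ValueError(
            f"postinitial class {postinitial_class!r} inconsistent with "
            f"change {postinitial_change_pct:+.1f}% (continuous > +10, "
            "plateau within ±10, washout < -10)"
        )
    if peak_index == n_acquisitions - 1 and postinitial_change_pct != 0:
        raise ValueError("a peak at the last acquisition leaves no postinitial phase")
    peak_value = baseline * (1.0 + initial_enhancement_pct / 100.0)
    final_value = peak_value * (1.0 + postinitial_change_pct / 100.0)
    curve = np.empty(n_acquisitions)
    curve[: peak_index + 1] = np.linspace(baseline, peak_value, peak_index + 1)
    curve[peak_index:] = np.linspace(peak_value, final_value, n_acquisitions - peak_index)
    return curve


@dataclass
class LesionSpec:
    """Parameters of one simulated enhancing lesion.

    ``radius_voxels`` may be a scalar (spherical mass) or a per-axis
    ``(rz, ry, rx)`` triple (anisotropic non-mass-like blob). The peak of
    the kinetic curve sits at 0-based acquisition ``peak_index``.
    """

    center: tuple[int, int, int]
    radius_voxels: float | tuple[float, float, float] = 2.0
    initial_enhancement_pct: float = 150.0
    postinitial_class: str = "washout"
    postinitial_change_pct: float = -20.0
    peak_index: int = 2

    def __post_init__(self) -> None:
        if len(self.center) != 3:
            raise ValueError("lesion center must be a (slice, row, col) triple")
        self.center = tuple(int(c) for c in self.center)
        radii = self.radii
        if any(r <= 0 for r in radii):
            raise ValueError("lesion radii must be positive")
        if self.initial_enhancement_pct <= 0:
            raise ValueError("lesion initial enhancement must be positive")
        if postinitial_class_of(self.postinitial_change_pct) != self.postinitial_class:
            raise ValueError(
                f"postinitial class {self.postinitial_class!r} inconsistent with "
                f"change {self.postinitial_change_pct:+.1f}%"
            )

    @property
    def radii(self) -> tuple[float, float, float]:
        if np.isscalar(self.radius_voxels):
            r = float(self.radius_voxels)
            return (r, r, r)
        rz, ry, rx = self.radius_voxels
        return (float(rz), float(ry), float(rx))

    def curve(self, baseline: float, n_acquisitions: int) -> np.ndarray:
        return kinetic_curve(
            baseline,
            self.initial_enhancement_pct,
            self.postinitial_class,
            self.postinitial_change_pct,
            n_acquisitions,
            self.peak_index,
        )


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic dynamic series.

    Defaults describe a desk-scale study: 6 acquisitions (1 precontrast +
    5 postcontrast) of 40 axial slices of 64x64 pixels (use 150 slices
    for full-scale geometry), baseline 100 scanner units and Gaussian
    noise of sigma 2 (signal-to-noise about 50). ``bpe_fraction`` is the
    fraction of glandular voxels that enhance; ``bpe_amplitude`` their
    total relative signal rise (0.4 = 40% above baseline by the end of
    the examination). The first ``breast_start_slice`` slices contain
    chest only, mimicking stack positions beyond the breast.
    """

    n_acquisitions: int = 6
    n_slices: int = 40
    slice_shape: tuple[int, int] = (64, 64)
    chest_depth: int = 12
    glandular_fraction: float = 0.25
    bpe_fraction: float = 0.15
    bpe_amplitude: float = 0.4
    lesion: LesionSpec | None = None
    noise_sigma: float = 2.0
    noise_model: str = "gaussian"
    baseline_intensity: float = 100.0
    breast_start_slice: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_acquisitions < 2:
            raise ValueError("n_acquisitions must be >= 2")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        y, x = self.slice_shape
        if y < 4 or x < 4:
            raise ValueError("slice_shape too small")
        if not 0 <= self.chest_depth < y:
            raise ValueError("chest_depth must satisfy 0 <= chest_depth < Y")
        for name in ("glandular_fraction", "bpe_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bpe_amplitude < 0:
            raise ValueError("bpe_amplitude must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        if not 0 <= self.breast_start_slice < self.n_slices:
            raise ValueError("breast_start_slice out of range")

    @property
    def bpe_category(self) -> str:
        return bpe_category_of(self.bpe_fraction)


@dataclass
class PhantomTruth:
    """Ground truth of one generated series."""

    has_lesion: bool
    lesion_center: tuple[int, int, int] | None
    bpe_category: str
    bpe_fraction: float
    enhancing_mask: np.ndarray  # (Z, Y, X) bool: BPE and lesion voxels
    chest_mask: np.ndarray  # (Y, X) bool
    seed: int

    def __post_init__(self) -> None:
        if self.has_lesion != (self.lesion_center is not None):
            raise ValueError("has_lesion must match presence of lesion_center")

    def to_json_dict(self) -> dict:
        return {
            "has_lesion": self.has_lesion,
            "lesion_center": list(self.lesion_center) if self.lesion_center else None,
            "bpe_category": self.bpe_category,
            "bpe_fraction": self.bpe_fraction,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Geometry


def _half_ellipse(shape: tuple[int, int], base_row: int, ry: float, rx: float) -> np.ndarray:
    """Union of two half-ellipses resting on ``base_row``, opening anteriorly."""
    y_len, x_len = shape
    yy, xx = np.mgrid[0:y_len, 0:x_len]
    mask = np.zeros(shape, dtype=bool)
    for cx in (0.27 * x_len, 0.73 * x_len):
        inside = ((yy - base_row) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        mask |= inside & (yy < base_row)
    return mask


def breast_mask_2d(spec: PhantomSpec) -> np.ndarray:
    """In-plane breast mask: two half-ellipses anterior to the chest band."""
    y_len, x_len = spec.slice_shape
    base_row = y_len - spec.chest_depth
    return _half_ellipse(spec.slice_shape, base_row, 0.78 * base_row, 0.21 * x_len)


def glandular_mask_2d(spec: PhantomSpec) -> np.ndarray:
    """Fibroglandular core: the breast ellipses shrunk so the core holds
    ``glandular_fraction`` of the breast area."""
    if spec.glandular_fraction == 0:
        return np.zeros(spec.slice_shape, dtype=bool)
    y_len, x_len = spec.slice_shape
    base_row = y_len - spec.chest_depth
    scale = float(np.sqrt(spec.glandular_fraction))
    inner = _half_ellipse(spec.slice_shape, base_row, 0.78 * base_row * scale,
                          0.21 * x_len * scale)
    return inner & breast_mask_2d(spec)


def chest_mask_2d(spec: PhantomSpec) -> np.ndarray:
    """Posterior chest band: the last ``chest_depth`` image rows."""
    y_len, x_len = spec.slice_shape
    mask = np.zeros((y_len, x_len), dtype=bool)
    if spec.chest_depth:
        mask[y_len - spec.chest_depth :, :] = True
    return mask


def _bpe_multiplier(spec: PhantomSpec) -> np.ndarray:
    """Per-acquisition signal multiplier of an enhancing parenchymal voxel.

    A mild persistent curve: 60% of the total amplitude is reached at the
    second postcontrast acquisition and the remainder by the end, so
    normal tissue keeps rising slowly while typical lesions peak early.
    """
    amp = spec.bpe_amplitude
    if amp == 0:
        return np.ones(spec.n_acquisitions)
    peak_gain = 1.0 + 0.6 * amp
    change_pct = 100.0 * ((1.0 + amp) / peak_gain - 1.0)
    peak_index = min(2, spec.n_acquisitions - 1)
    if peak_index == spec.n_acquisitions - 1:
        change_pct = 0.0
    return kinetic_curve(
        1.0,
        100.0 * 0.6 * amp,
        postinitial_class_of(change_pct),
        change_pct,
        spec.n_acquisitions,
        peak_index,
    )


def _lesion_mask_3d(spec: PhantomSpec, lesion: LesionSpec) -> np.ndarray:
    rz, ry, rx = lesion.radii
    cz, cy, cx = lesion.center
    z_len = spec.n_slices
    y_len, x_len = spec.slice_shape
    zz, yy, xx = np.ogrid[0:z_len, 0:y_len, 0:x_len]
    mask = (
        ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    ) <= 1.0
    mask[: spec.breast_start_slice] = False
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[DceSeries, PhantomTruth]:
    """Render a :class:`PhantomSpec` into a dynamic series plus ground truth.

    The chest band is static over time; non-enhancing breast tissue sits
    at its baseline; a seeded random subset of glandular voxels of exact
    size ``round(bpe_fraction * n_glandular)`` follows the mild
    persistent BPE curve; lesion voxels (which take precedence over BPE)
    follow the lesion's kinetic curve. Zero-mean noise of scale
    ``noise_sigma`` is then added independently per voxel and time point
    and the result clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    t_len = spec.n_acquisitions
    z_len = spec.n_slices
    y_len, x_len = spec.slice_shape

    breast2d = breast_mask_2d(spec)
    gland2d = glandular_mask_2d(spec)
    chest2d = chest_mask_2d(spec)

    base = np.zeros((z_len, y_len, x_len))
    base[:, chest2d] = 1.3 * spec.baseline_intensity
    base[spec.breast_start_slice :, breast2d] = spec.baseline_intensity
    base[spec.breast_start_slice :, gland2d] = 1.1 * spec.baseline_intensity

    gland3d = np.zeros((z_len, y_len, x_len), dtype=bool)
    gland3d[spec.breast_start_slice :] = gland2d

    # Exact-count BPE subset keeps |enhancing| / |glandular| within
    # 1 / |glandular| of the requested fraction.
    gland_idx = np.flatnonzero(gland3d.ravel())
    n_bpe = int(round(spec.bpe_fraction * gland_idx.size))
    bpe3d = np.zeros(z_len * y_len * x_len, dtype=bool)
    if n_bpe:
        chosen = rng.choice(gland_idx, size=n_bpe, replace=False)
        bpe3d[chosen] = True
    bpe3d = bpe3d.reshape(z_len, y_len, x_len)

    lesion3d = np.zeros((z_len, y_len, x_len), dtype=bool)
    if spec.lesion is not None:
        cz, cy, cx = spec.lesion.center
        if not (0 <= cz < z_len and 0 <= cy < y_len and 0 <= cx < x_len):
            raise ValueError(f"lesion center {spec.lesion.center} outside the volume")
        if cz < spec.breast_start_slice or not breast2d[cy, cx]:
            raise ValueError(
                f"lesion center {spec.lesion.center} lies outside the breast region"
            )
        lesion3d = _lesion_mask_3d(spec, spec.lesion)
        bpe3d &= ~lesion3d  # lesion kinetics take precedence

    bpe_curve = _bpe_multiplier(spec)
    data = np.empty((t_len, z_len, y_len, x_len))
    data[:] = base[None]
    if bpe3d.any():
        for t in range(t_len):
            data[t][bpe3d] = base[bpe3d] * bpe_curve[t]
    if lesion3d.any():
        lesion_curves = np.stack(
            [spec.lesion.curve(float(b), t_len) for b in np.atleast_1d(base[lesion3d])],
            axis=1,
        )
        for t in range(t_len):
            data[t][lesion3d] = lesion_curves[t]

    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            data = data + rng.normal(0.0, spec.noise_sigma, data.shape)
        else:  # rician: magnitude of a complex signal with Gaussian channels
            re = data + rng.normal(0.0, spec.noise_sigma, data.shape)
            im = rng.normal(0.0, spec.noise_sigma, data.shape)
            data = np.hypot(re, im)
    data = np.clip(data, 0.0, None)

    truth = PhantomTruth(
        has_lesion=spec.lesion is not None,
        lesion_center=spec.lesion.center if spec.lesion is not None else None,
        bpe_category=spec.bpe_category,
        bpe_fraction=spec.bpe_fraction,
        enhancing_mask=bpe3d | lesion3d,
        chest_mask=chest2d,
        seed=spec.seed,
    )
    series = DceSeries(data=data, voxel_spacing=(1.5, 1.5, 1.5), patient_id=f"phantom-{spec.seed}")
    return series, truth


# ---------------------------------------------------------------------------
# Cohorts


def _sample_lesion(spec: PhantomSpec, rng: np.random.Generator) -> LesionSpec:
    """Draw lesion parameters from the documented cohort ranges.

    Location: any glandular in-plane pixel, interior slice. Size: radius
    2-3 voxels (small masses, the hard detection case). Kinetics: initial
    enhancement 100-200% ("strong" enhancing lesions), postinitial class
    uniform over continuous/plateau/washout with a consistent change.
    Curves with a nonnegative postinitial drift peak at the last
    initial-window acquisition (0-based index 3) so that re-classifying
    the generated curve recovers the generating classes exactly;
    decaying curves peak at the second postcontrast acquisition.
    """
    gland = glandular_mask_2d(spec)
    ys, xs = np.nonzero(gland)
    if ys.size == 0:
        raise ValueError("cannot place a lesion: phantom has no glandular tissue")
    i = int(rng.integers(ys.size))
    z_lo = spec.breast_start_slice + 3
    z_hi = spec.n_slices - 4
    if z_hi < z_lo:
        raise ValueError("too few slices to place an interior lesion")
    cz = int(rng.integers(z_lo, z_hi + 1))
    post_class = _POSTINITIAL_CLASSES[int(rng.integers(3))]
    if post_class == "continuous":
        change = float(rng.uniform(15.0, 40.0))
    elif post_class == "plateau":
        change = float(rng.uniform(-8.0, 8.0))
    else:
        change = float(rng.uniform(-40.0, -15.0))
    peak_index = 3 if change >= 0 else 2
    return LesionSpec(
        center=(cz, int(ys[i]), int(xs[i])),
        radius_voxels=float(rng.uniform(2.0, 3.0)),
        initial_enhancement_pct=float(rng.uniform(100.0, 200.0)),
        postinitial_class=post_class,
        postinitial_change_pct=change,
        peak_index=peak_index,
    )


def _sample_bpe(rng: np.random.Generator, distribution: dict[str, float]) -> float:
    cats = list(distribution)
    probs = np.array([distribution[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    cat = cats[int(rng.choice(len(cats), p=probs))]
    lo, hi = _BPE_FRACTION_BANDS[cat]
    return float(rng.uniform(lo, hi))


def generate_cohort(
    n_normal: int,
    n_abnormal: int,
    spec_template: PhantomSpec,
    seed: int,
    bpe_distribution: dict[str, float] | None = None,
) -> list[tuple[DceSeries, PhantomTruth]]:
    """Generate a cohort of phantoms: normals first, then lesioned cases.

    Each case gets its own sub-seed derived from ``seed``; BPE categories
    are sampled per ``bpe_distribution`` (default
    :data:`DEFAULT_BPE_DISTRIBUTION`) with the enhancing fraction drawn
    uniformly inside the category band, and lesion parameters per the
    ranges documented in the sampler. Deterministic for a given seed.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("case counts must be nonnegative")
    distribution = dict(bpe_distribution or DEFAULT_BPE_DISTRIBUTION)
    rng = np.random.default_rng(seed)
    cases = []
    for k in range(n_normal + n_abnormal):
        case_seed = int(rng.integers(2**31 - 1))
        lesion = _sample_lesion(spec_template, rng) if k >= n_normal else None
        spec = dataclasses.replace(
            spec_template,
            bpe_fraction=_sample_bpe(rng, distribution),
            lesion=lesion,
            seed=case_seed,
        )
        cases.append(generate_phantom(spec))
    return cases
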