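"""Synthetic mean/std images, peak detection, kinetic-curve and lesion scoring.

Once the most informative acquisition has been chosen, the gradient
volume at that acquisition is collapsed into two 2D summaries: the
per-pixel mean and (population) standard deviation across slices. A
patient is called *abnormal* when **both** summaries show a peak — a
maximum standing more than ``tau`` image standard deviations above the
image mean.

The module also houses the kinetic-curve classifier (initial /
postinitial enhancement classes) and the 0-8 point multimodal lesion
score with its five diagnostic groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SyntheticImagePair",
    "PeakStat",
    "CurveFeatures",
    "LesionDescriptors",
    "ScoreResult",
    "synthetic_images",
    "peak_stat",
    "classify_case",
    "classify_curve",
    "multimodal_score",
    "initial_class_of",
    "postinitial_class_of",
    "SCORE_POINTS",
    "SCORE_GROUPS",
]

#: Default peak threshold. Calibrated above the null envelope of the
#: maximum z-score of an independent-Gaussian image at desk-scale sizes:
#: for n pixels that maximum concentrates near sqrt(2 ln n) (about 4.1
#: for 64x64), so a threshold of 4 flags "peaks" on structureless images
#: about half the time. 5.0 sits roughly three Gumbel scale units above
#: that mean; scale it with sqrt(2 ln n) for much larger images.
DEFAULT_TAU = 5.0

INITIAL_CLASSES = ("lt50", "50to100", "gt100")
POSTINITIAL_CLASSES = ("continuous", "plateau", "washout")

#: Points per criterion of the multimodal lesion score.
SCORE_POINTS = {
    "shape": {"round": 0, "oval": 0, "dendritic": 1, "irregular": 1},
    "border": {"well_defined": 0, "ill_defined": 1},
    "cm_pattern": {"homogeneous": 0, "heterogeneous": 1, "rim": 2},
    "initial": {"lt50": 0, "50to100": 1, "gt100": 2},
    "postinitial": {"continuous": 0, "plateau": 1, "washout": 2},
}

#: Diagnostic groups by total points.
SCORE_GROUPS = (
    ("I", range(0, 2), "Benign"),
    ("II", range(2, 3), "Probably benign"),
    ("III", range(3, 4), "Probably benign"),
    ("IV", range(4, 6), "Suspicious abnormality"),
    ("V", range(6, 9), "Highly suggestive of malignancy"),
)


def initial_class_of(pct: float) -> str:
    """Initial-enhancement class: <50% / 50-100% (inclusive) / >100% (strict)."""
    if pct < 50.0:
        return "lt50"
    if pct <= 100.0:
        return "50to100"
    return "gt100"


def postinitial_class_of(pct: float) -> str:
    """Postinitial class: rise > +10% continuous, within ±10% plateau, drop > 10% washout."""
    if pct > 10.0:
        return "continuous"
    if pct < -10.0:
        return "washout"
    return "plateau"


@dataclass
class SyntheticImagePair:
    """The mean and population-std summary images of a gradient volume.

    ``axis_collapsed`` records whether slices were collapsed at a fixed
    acquisition (``slice_axis``, the default) or acquisitions at a fixed
    slice (``time_axis``); ``source_index`` is the fixed 0-based index.
    """

    mean_image: np.ndarray
    std_image: np.ndarray
    axis_collapsed: str = "slice_axis"
    source_index: int = 0

    def __post_init__(self) -> None:
        self.mean_image = np.asarray(self.mean_image, dtype=np.float64)
        self.std_image = np.asarray(self.std_image, dtype=np.float64)
        if self.mean_image.shape != self.std_image.shape:
            raise ValueError("mean and std images must share one shape")
        if self.std_image.size and self.std_image.min() < 0:
            raise ValueError("standard-deviation image must be nonnegative")


@dataclass
class PeakStat:
    """Peak statistic of one image: location and z-score of its maximum."""

    location: tuple[int, int]
    value: float
    z_score: float
    is_peak: bool

    def to_dict(self) -> dict:
        return {
            "location": [int(self.location[0]), int(self.location[1])],
            "value": float(self.value),
            "z_score": float(self.z_score),
            "is_peak": bool(self.is_peak),
        }


@dataclass
class CurveFeatures:
    """Initial/postinitial enhancement features of a time-signal curve."""

    initial_enhancement_pct: float
    initial_class: str
    postinitial_change_pct: float
    postinitial_class: str
    peak_index: int

    def __post_init__(self) -> None:
        if self.initial_class != initial_class_of(self.initial_enhancement_pct):
            raise ValueError("initial class inconsistent with percentage")
        if self.postinitial_class != postinitial_class_of(self.postinitial_change_pct):
            raise ValueError("postinitial class inconsistent with percentage")


@dataclass
class LesionDescriptors:
    """Radiologist-provided morphology plus kinetic classes for scoring."""

    shape: str
    border: str
    cm_pattern: str
    initial_class: str
    postinitial_class: str

    def __post_init__(self) -> None:
        for crit, value in (
            ("shape", self.shape),
            ("border", self.border),
            ("cm_pattern", self.cm_pattern),
            ("initial", self.initial_class),
            ("postinitial", self.postinitial_class),
        ):
            if value not in SCORE_POINTS[crit]:
                raise ValueError(
                    f"{crit} must be one of {sorted(SCORE_POINTS[crit])}, got {value!r}"
                )


@dataclass
class ScoreResult:
    """Multimodal score: per-criterion points, 0-8 total and diagnostic group."""

    points_per_criterion: dict[str, int]
    total: int
    group: str
    diagnostic_value: str


def synthetic_images(grad, selection, mode: str = "slice_axis") -> SyntheticImagePair:
    """Collapse a gradient volume into mean and std summary images.

    In ``slice_axis`` mode (default) the per-pixel mean and population
    standard deviation of ``grad.data[t_star, z, y, x]`` are taken over
    all slices ``z``; in ``time_axis`` mode over all acquisitions ``t``
    at the selected slice ``z_star``. ``selection`` is any object with
    0-based ``t_star`` and ``z_star`` attributes.
    """
    data = grad.data
    if mode == "slice_axis":
        t_star = int(selection.t_star)
        if not 0 <= t_star < data.shape[0]:
            raise ValueError(f"t_star {t_star} out of range")
        stack = data[t_star]
        source = t_star
    elif mode == "time_axis":
        z_star = int(selection.z_star)
        if not 0 <= z_star < data.shape[1]:
            raise ValueError(f"z_star {z_star} out of range")
        stack = data[:, z_star]
        source = z_star
    else:
        raise ValueError(f"unknown synthetic-image mode {mode!r}")
    mean_image = stack.mean(axis=0)
    if stack.shape[0] < 2:
        warnings.warn("single plane: standard-deviation image is identically zero",
                      stacklevel=2)
        std_image = np.zeros_like(mean_image)
    else:
        std_image = stack.std(axis=0, ddof=0)
    return SyntheticImagePair(mean_image=mean_image, std_image=std_image,
                              axis_collapsed=mode, source_index=source)


def peak_stat(image: np.ndarray, tau: float = DEFAULT_TAU) -> PeakStat:
    """Peak statistic of an image at threshold ``tau``.

    The peak is the global maximum (row-major first on ties); its
    z-score is ``(max - mean) / std`` over the whole image, and
    ``is_peak`` holds when the z-score exceeds ``tau``. A constant image
    has z-score 0 and no peak.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("peak statistic undefined for non-finite images")
    flat_idx = int(np.argmax(image))
    location = np.unravel_index(flat_idx, image.shape)
    value = float(image[location])
    sd = float(image.std())
    z = 0.0 if sd == 0.0 else (value - float(image.mean())) / sd
    return PeakStat(location=(int(location[0]), int(location[1])), value=value,
                    z_score=z, is_peak=z > tau)


def classify_case(pair: SyntheticImagePair, tau: float = DEFAULT_TAU) -> str:
    """Normal/abnormal decision: abnormal iff *both* summary images peak."""
    both = peak_stat(pair.mean_image, tau).is_peak and peak_stat(pair.std_image, tau).is_peak
    return "abnormal" if both else "normal"


def classify_curve(signal: Sequence[float], initial_window: int = 3) -> CurveFeatures:
    """Kinetic features of a time-signal curve.

    ``signal[0]`` is the precontrast value; the peak is sought among the
    first ``initial_window`` postcontrast acquisitions (the initial
    phase). Initial enhancement is the percent rise from baseline to
    that peak; postinitial change is the percent change from the peak to
    the final acquisition, classified as continuous (> +10%), plateau
    (within ±10%) or washout (< -10%).
    """
    s = np.asarray(signal, dtype=np.float64)
    if s.ndim != 1 or s.size < 3:
        raise ValueError("signal must be a 1D sequence of length >= 3")
    if s[0] <= 0:
        raise ValueError("precontrast (baseline) signal must be positive")
    if initial_window < 1:
        raise ValueError("initial_window must be >= 1")
    window_end = min(initial_window, s.size - 1)
    peak_index = 1 + int(np.argmax(s[1 : window_end + 1]))
    initial_pct = 100.0 * (s[peak_index] - s[0]) / s[0]
    post_pct = 100.0 * (s[-1] - s[peak_index]) / s[peak_index]
    return CurveFeatures(
        initial_enhancement_pct=float(initial_pct),
        initial_class=initial_class_of(initial_pct),
        postinitial_change_pct=float(post_pct),
        postinitial_class=postinitial_class_of(post_pct),
        peak_index=peak_index,
    )


def multimodal_score(desc: LesionDescriptors) -> ScoreResult:
    """The 0-8 point multimodal lesion score and its diagnostic group.

    Points: shape round/oval 0, dendritic/irregular 1; border
    well-defined 0, ill-defined 1; contrast-medium pattern homogeneous 0,
    heterogeneous 1, rim 2; initial enhancement <50% 0, 50-100% 1,
    >100% 2; postinitial continuous 0, plateau 1, washout 2. Groups:
    I 0-1 benign, II 2 / III 3 probably benign, IV 4-5 suspicious,
    V 6-8 highly suggestive of malignancy.
    """
    points = {
        "shape": SCORE_POINTS["shape"][desc.shape],
        "border": SCORE_POINTS["border"][desc.border],
        "cm_pattern": SCORE_POINTS["cm_pattern"][desc.cm_pattern],
        "initial": SCORE_POINTS["initial"][desc.initial_class],
        "postinitial": SCORE_POINTS["postinitial"][desc.postinitial_class],
    }
    total = sum(points.values())
    for group, span, label in SCORE_GROUPS:
        if total in span:
            return ScoreResult(points_per_criterion=points, total=total,
                               group=group, diagnostic_value=label)
    raise AssertionError(f"total {total} outside 0-8")  # unreachable: closed enums
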