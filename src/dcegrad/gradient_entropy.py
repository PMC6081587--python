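"""Temporal Sobel gradient and per-slice entropy.

The central operation of the pipeline: each axial slice of a dynamic
series is differentiated *along the acquisition-time axis* with a
Sobel-type operator — a central difference in time combined with a
3x3 triangle smoothing in the image plane — and the information content
of each resulting gradient slice is summarised by its Shannon entropy
over 256 quantised gray levels.

The 3x3x3 Sobel kernel is separable into the 1D triangle filter
``h = (1, 2, 1)`` applied along each in-plane axis and the 1D central
difference ``h' = (1, 0, -1)`` applied along time; both routes are
provided and agree exactly on integer data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import DceSeries

__all__ = [
    "SMOOTHING_FILTER",
    "DERIVATIVE_FILTER",
    "sobel_temporal_kernel",
    "GradientVolume",
    "EntropyTable",
    "temporal_gradient",
    "slice_entropy",
    "entropy_table",
    "entropy_table_to_csv",
]

#: Triangle smoothing filter h(-1), h(0), h(1).
SMOOTHING_FILTER = np.array([1.0, 2.0, 1.0])
#: Central-difference derivative filter h'(-1), h'(0), h'(1).
DERIVATIVE_FILTER = np.array([1.0, 0.0, -1.0])

_BOUNDARY_TO_SCIPY = {"replicate": "nearest", "reflect": "reflect", "zero": "constant"}


def sobel_temporal_kernel() -> np.ndarray:
    """The full 3x3x3 temporal Sobel kernel, indexed ``[dy, dx, dt]``.

    ``kernel[i, j, k] = h[i] * h[j] * h'[k]`` for offsets i, j, k in
    {-1, 0, +1} (array index = offset + 1): the dt = -1 plane is the
    16-sum triangle ``[[1,2,1],[2,4,2],[1,2,1]]``, the dt = 0 plane is
    zero, and the dt = +1 plane is its negation. Entries sum to zero, so
    the operator annihilates signals constant in time.
    """
    return (
        SMOOTHING_FILTER[:, None, None]
        * SMOOTHING_FILTER[None, :, None]
        * DERIVATIVE_FILTER[None, None, :]
    )


@dataclass
class GradientVolume:
    """Magnitudes of the temporal directional gradient of a series.

    Same ``(t, z, y, x)`` shape as the source series; entries are the
    absolute value of the signed Sobel response, hence nonnegative.
    """

    data: np.ndarray
    boundary_mode: str = "replicate"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("GradientVolume data must be 4D (t, z, y, x)")
        if self.data.size and self.data.min() < 0:
            raise ValueError("gradient magnitudes must be nonnegative")


@dataclass
class EntropyTable:
    """Per-slice entropies of the gradient images: ``values[t, z]`` in bits."""

    values: np.ndarray
    n_levels: int = 256

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("EntropyTable values must be a (T, Z) matrix")
        upper = np.log2(self.n_levels)
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > upper + 1e-12):
            raise ValueError(f"entropies must lie in [0, {upper}]")


def temporal_gradient(
    series: DceSeries,
    boundary_mode: str = "replicate",
    method: str = "separable",
) -> GradientVolume:
    """Sobel gradient of every slice along the temporal dimension.

    Parameters
    ----------
    series
        The dynamic series; the derivative is taken along axis ``t``.
        Slices are treated independently: no smoothing crosses ``z``.
    boundary_mode
        Temporal/spatial padding: ``replicate`` (default), ``reflect``
        or ``zero``. With ``replicate`` the first and last acquisitions
        receive an attenuated one-sided response instead of a spurious
        edge from zero padding.
    method
        ``separable`` (1D triangle along y then x, central difference
        along t) or ``full`` (correlation with the full 3x3x3 kernel).
        The two agree exactly on integer-valued input.

    Returns
    -------
    GradientVolume
        Absolute Sobel responses, same shape as ``series.data``.
    """
    if boundary_mode not in _BOUNDARY_TO_SCIPY:
        raise ValueError(f"unknown boundary mode {boundary_mode!r}")
    if series.n_acquisitions < 2:
        raise ValueError("temporal gradient needs at least 2 acquisitions")
    mode = _BOUNDARY_TO_SCIPY[boundary_mode]
    data = series.data
    if method == "separable":
        out = ndimage.correlate1d(data, SMOOTHING_FILTER, axis=2, mode=mode, cval=0.0)
        out = ndimage.correlate1d(out, SMOOTHING_FILTER, axis=3, mode=mode, cval=0.0)
        out = ndimage.correlate1d(out, DERIVATIVE_FILTER, axis=0, mode=mode, cval=0.0)
    elif method == "full":
        # 4D kernel spanning (t, z, y, x) with a singleton z axis.
        kernel = np.transpose(sobel_temporal_kernel(), (2, 0, 1))[:, None, :, :]
        out = ndimage.correlate(data, kernel, mode=mode, cval=0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GradientVolume(data=np.abs(out), boundary_mode=boundary_mode)


def _quantize(image: np.ndarray, n_levels: int, vmin: float, vmax: float) -> np.ndarray:
    if vmax <= vmin:
        return np.zeros(image.shape, dtype=np.intp)
    levels = np.floor((image - vmin) / (vmax - vmin) * n_levels).astype(np.intp)
    return np.clip(levels, 0, n_levels - 1)


def slice_entropy(
    image: np.ndarray,
    n_levels: int = 256,
    value_range: tuple[float, float] | None = None,
) -> float:
    """Shannon entropy of an image over ``n_levels`` quantised gray levels.

    The image is linearly mapped to integer levels ``0 .. n_levels-1``
    over ``value_range`` (its own min/max when omitted), and the entropy
    ``-sum p_k log2 p_k`` of the level frequencies is returned, with
    ``0 log 0 = 0``. The result lies in ``[0, log2(n_levels)]``; a
    constant image has entropy 0.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("entropy undefined for non-finite pixel values")
    if value_range is None:
        vmin, vmax = float(image.min()), float(image.max())
    else:
        vmin, vmax = float(value_range[0]), float(value_range[1])
    levels = _quantize(image, n_levels, vmin, vmax)
    counts = np.bincount(levels.ravel(), minlength=n_levels)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 avoids returning -0.0


def entropy_table(
    grad: GradientVolume,
    normalization: str = "global_minmax",
    n_levels: int = 256,
    fixed_range: tuple[float, float] | None = None,
) -> EntropyTable:
    """Entropy of every gradient slice at every acquisition.

    With ``global_minmax`` (default) one min/max over the whole gradient
    volume defines the gray-level mapping for every slice, so entropies
    are comparable across slices and acquisitions — the property the
    selection step relies on. ``per_slice_minmax`` rescales each slice
    independently (documented as breaking that comparability);
    ``fixed_range`` uses the supplied ``(lo, hi)``.
    """
    data = grad.data
    t_total, z_total = data.shape[0], data.shape[1]
    if normalization == "global_minmax":
        vmin, vmax = float(data.min()), float(data.max())
        if vmax <= vmin:
            warnings.warn(
                "degenerate gradient volume (constant values); all entropies are 0",
                stacklevel=2,
            )
        ranges = [(vmin, vmax)] * (t_total * z_total)
    elif normalization == "per_slice_minmax":
        ranges = None
    elif normalization == "fixed_range":
        if fixed_range is None:
            raise ValueError("fixed_range normalization requires an explicit (lo, hi)")
        ranges = [tuple(map(float, fixed_range))] * (t_total * z_total)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    values = np.empty((t_total, z_total))
    k = 0
    for t in range(t_total):
        for z in range(z_total):
            vr = None if ranges is None else ranges[k]
            values[t, z] = slice_entropy(data[t, z], n_levels=n_levels, value_range=vr)
            k += 1
    return EntropyTable(values=values, n_levels=n_levels)


def entropy_table_to_csv(table: EntropyTable, path) -> None:
    """Export an entropy table as CSV (rows = acquisitions, columns = slices)."""
    header = ",".join(f"slice_{z + 1}" for z in range(table.values.shape[1]))
    np.savetxt(path, table.values, delimiter=",", header=header, comments="")
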