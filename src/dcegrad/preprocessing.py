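"""Chest/breast separation.

Before any temporal measurement, the chest is removed from every slice.
The mask is derived from the first slice of the sequence — taken here as
slice ``z = 0`` of the precontrast acquisition, which in a stack that
starts beyond the breast contains chest only — binarised (Otsu by
default) and optionally dilated, then applied to every slice of every
acquisition by zeroing the masked voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

from .io_formats import DceSeries

__all__ = ["ChestMask", "build_chest_mask", "extract_breast"]


@dataclass
class ChestMask:
    """Binary chest mask (True = chest/background to remove)."""

    mask: np.ndarray
    source_threshold: float
    coverage_fraction: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("chest mask must be 2D")
        if abs(self.coverage_fraction - float(self.mask.mean())) > 1e-12:
            raise ValueError("coverage_fraction must equal the mask mean")


def build_chest_mask(
    series: DceSeries,
    threshold_mode: str = "otsu",
    fixed_threshold: float | None = None,
    dilation_radius: int = 0,
    source: tuple[int, int] = (0, 0),
) -> ChestMask:
    """Binarise the first slice of the sequence into a chest mask.

    Parameters
    ----------
    series
        The dynamic series; the mask source is ``series.data[source]``.
    threshold_mode
        ``otsu`` (parameter-free, default) or ``fixed`` (requires
        ``fixed_threshold``). Pixels strictly above the threshold are
        masked. A constant source slice yields an empty mask when zero
        and a full mask otherwise.
    dilation_radius
        Radius of a disk-shaped morphological dilation applied to the
        binarised mask; 0 disables it.
    source
        ``(t, z)`` of the mask source slice; default the first slice of
        the precontrast acquisition.
    """
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    t, z = source
    image = series.data[t, z]
    if threshold_mode == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed threshold mode requires fixed_threshold")
        thr = float(fixed_threshold)
        mask = image > thr
    elif threshold_mode == "otsu":
        if float(image.min()) == float(image.max()):
            thr = 0.0
            mask = image > 0.0
        else:
            thr = float(threshold_otsu(image))
            mask = image > thr
    else:
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    if dilation_radius > 0:
        mask = dilation(mask, disk(dilation_radius)).astype(bool)
    return ChestMask(mask=mask, source_threshold=thr, coverage_fraction=float(mask.mean()))


def extract_breast(series: DceSeries, mask: ChestMask) -> DceSeries:
    """Zero every masked voxel in every slice of every acquisition.

    Returns a new series; the input is not mutated.
    """
    if mask.mask.shape != series.slice_shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match slice shape {series.slice_shape}"
        )
    data = series.data.copy()
    data[:, :, mask.mask] = 0.0
    return series.with_data(data)
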