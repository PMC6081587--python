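"""Selection of the most informative acquisition and slice.

The acquisition whose gradient slices carry the most information (the
entropy values aggregated over slices, maximised over acquisitions) is
chosen first; within it, the most informative slice is the one holding
the maximum gradient magnitude. Ties break toward the lowest index and
are flagged. Indices are 0-based here; reports add 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradient_entropy import EntropyTable, GradientVolume, entropy_table

__all__ = ["SelectionResult", "select_acquisition", "select_slice", "select"]


@dataclass
class SelectionResult:
    """Outcome of acquisition + slice selection (0-based indices)."""

    t_star: int
    z_star: int
    acquisition_scores: np.ndarray
    slice_scores: np.ndarray
    aggregation: str
    tie_broken: bool

    @property
    def t_star_reported(self) -> int:
        """1-based acquisition index, as surfaced in reports."""
        return self.t_star + 1

    @property
    def z_star_reported(self) -> int:
        return self.z_star + 1


def _argmax_lowest(scores: np.ndarray, eligible: np.ndarray) -> tuple[int, bool]:
    masked = np.where(eligible, scores, -np.inf)
    best = float(masked.max())
    winners = np.flatnonzero(masked == best)
    return int(winners[0]), winners.size > 1


def select_acquisition(
    table: EntropyTable,
    aggregation: str = "max",
    exclude_precontrast: bool = False,
) -> tuple[int, np.ndarray, bool]:
    """Acquisition maximising the aggregated per-slice entropies.

    ``aggregation`` is ``max`` (default: the acquisition containing the
    single most informative slice), ``mean`` or ``sum`` over slices.
    With ``exclude_precontrast`` the precontrast acquisition is scored
    but ineligible. Returns ``(t_star, acquisition_scores, tie_broken)``.
    """
    values = table.values
    if values.size == 0:
        raise ValueError("empty entropy table")
    if aggregation == "max":
        scores = values.max(axis=1)
    elif aggregation == "mean":
        scores = values.mean(axis=1)
    elif aggregation == "sum":
        scores = values.sum(axis=1)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    eligible = np.ones(scores.size, dtype=bool)
    if exclude_precontrast:
        if scores.size < 2:
            raise ValueError("cannot exclude precontrast from a single-acquisition table")
        eligible[0] = False
    t_star, tie = _argmax_lowest(scores, eligible)
    return t_star, scores, tie


def select_slice(
    grad: GradientVolume,
    t_star: int,
    score: str = "max_gradient",
    whole_sequence: bool = False,
) -> tuple[int, np.ndarray, bool]:
    """Slice maximising the chosen score at acquisition ``t_star``.

    ``max_gradient`` (default) scores each slice by its maximum gradient
    magnitude at ``t_star`` (or across every acquisition when
    ``whole_sequence``); ``entropy`` scores slices by their entropy at
    ``t_star`` under the volume-wide gray-level mapping. Returns
    ``(z_star, slice_scores, tie_broken)``.
    """
    t_total = grad.data.shape[0]
    if not 0 <= t_star < t_total:
        raise ValueError(f"t_star {t_star} out of range [0, {t_total})")
    if score == "max_gradient":
        source = grad.data if whole_sequence else grad.data[t_star : t_star + 1]
        scores = source.max(axis=(0, 2, 3))
    elif score == "entropy":
        vmin, vmax = float(grad.data.min()), float(grad.data.max())
        table = entropy_table(
            GradientVolume(grad.data[t_star : t_star + 1], grad.boundary_mode),
            normalization="fixed_range",
            fixed_range=(vmin, vmax),
        )
        scores = table.values[0]
    else:
        raise ValueError(f"unknown slice score {score!r}")
    z_star, tie = _argmax_lowest(scores, np.ones(scores.size, dtype=bool))
    return z_star, scores, tie


def select(
    table: EntropyTable,
    grad: GradientVolume,
    aggregation: str = "max",
    exclude_precontrast: bool = False,
    slice_score: str = "max_gradient",
    whole_sequence: bool = False,
) -> SelectionResult:
    """Full selection: acquisition by entropy, then slice by gradient."""
    t_star, acq_scores, tie_t = select_acquisition(table, aggregation, exclude_precontrast)
    z_star, slice_scores, tie_z = select_slice(grad, t_star, slice_score, whole_sequence)
    return SelectionResult(
        t_star=t_star,
        z_star=z_star,
        acquisition_scores=acq_scores,
        slice_scores=slice_scores,
        aggregation=aggregation,
        tie_broken=tie_t or tie_z,
    )
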