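"""A-posteriori homogenization of minute-level mode predictions.

Random-forest predictions of contiguous trips contain sporadic
single-minute misclassifications. The moving-majority output filter
replaces each minute's predicted mode by the mode predicted most often
in a window of b minutes before and after it (bandwidth b), which
erases isolated discrepancies: with b = 1, a lone A between two Bs
becomes B.

The filter reads raw predictions only (non-recursive), so its output is
independent of processing direction. Windows are truncated at the edges
of contiguity blocks — maximal runs of consecutive minutes — and never
span wear gaps or participant boundaries. A tie in the window majority
keeps the raw label of the central minute; b = 0 is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import RatesReport, prediction_rates


@dataclass
class PredictionSeries:
    """One participant's ordered minute-level predictions.

    ``minutes`` must be strictly increasing; a gap of more than one
    minute starts a new contiguity block.
    """

    participant_id: str
    minutes: np.ndarray
    raw: np.ndarray
    truth: np.ndarray | None = None
    smoothed: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.minutes = np.asarray(self.minutes, dtype=np.int64)
        self.raw = np.asarray(self.raw, dtype=object)
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=object)
        if self.minutes.size != self.raw.size:
            raise ValueError("minutes and raw predictions differ in length")
        if np.any(np.diff(self.minutes) <= 0):
            raise ValueError("minutes must be strictly increasing")

    @property
    def block_ids(self) -> np.ndarray:
        return contiguity_blocks(self.minutes)


def contiguity_blocks(minutes: np.ndarray) -> np.ndarray:
    """Block id per minute; a gap > 1 minute starts a new block."""
    minutes = np.asarray(minutes, dtype=np.int64)
    if minutes.size == 0:
        return np.empty(0, dtype=np.int64)
    return np.concatenate([[0], np.cumsum(np.diff(minutes) > 1)])


def _filter_block(labels: np.ndarray, b: int) -> np.ndarray:
    codes, inv = np.unique(labels, return_inverse=True)
    n = inv.size
    out = inv.copy()
    for t in range(n):
        lo, hi = max(t - b, 0), min(t + b + 1, n)
        counts = np.bincount(inv[lo:hi], minlength=codes.size)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if winners.size == 1:
            out[t] = winners[0]
        # tie: keep the raw central label
    return codes[out]


def mode_filter(series: PredictionSeries, bandwidth: int) -> np.ndarray:
    """Moving-majority smoothing at the given bandwidth.

    Output for minute t is the modal raw label within
    [t - b, t + b] intersected with t's contiguity block (truncated
    windows at block edges, no padding). Ties keep the raw label at t.
    The result is also stored in ``series.smoothed[bandwidth]``.
    """
    if bandwidth < 0 or int(bandwidth) != bandwidth:
        raise ValueError("bandwidth must be a non-negative integer")
    b = int(bandwidth)
    if b == 0 or series.raw.size == 0:
        out = series.raw.copy()
    else:
        out = np.empty_like(series.raw)
        blocks = series.block_ids
        for blk in np.unique(blocks):
            mask = blocks == blk
            out[mask] = _filter_block(series.raw[mask], b)
    series.smoothed[b] = out
    return out


def bandwidth_sweep(series_list: list[PredictionSeries],
                    bandwidths=(0, 1, 2, 3, 4, 5),
                    ) -> dict[int, list[RatesReport]]:
    """Rates per bandwidth per series (series must carry truth labels).

    Bandwidth 0 reproduces the pre-homogenization rates; smoothing
    changes predictions only, never denominators.
    """
    out: dict[int, list[RatesReport]] = {int(b): [] for b in bandwidths}
    for series in series_list:
        if series.truth is None:
            raise ValueError("bandwidth_sweep needs truth labels")
        for b in bandwidths:
            smoothed = mode_filter(series, int(b))
            out[int(b)].append(prediction_rates(series.truth, smoothed))
    return out
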