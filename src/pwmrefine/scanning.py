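"""Promoter scanning, positional z-score profiles and functional windows.

A scoring model <W, c> slides along the TSS-aligned promoters; at each start
position p the number of promoters with a hit (score >= c) is O(p).  The
z-score profile standardizes O against its own positional mean and
population standard deviation:

    z(p) = (O(p) - E) / sigma ,  E = mean_p O(p),  sigma = std_p O(p).

Start positions with z >= 3 mark over-represented motif locations; nearby
peaks (closer than the motif length L) are fused into a single "functional
window", the candidate location of functional binding sites.  Because the
z-profile depends on the unknown cut-off, a grid of cut-offs is scanned and
signals that persist across the grid are the trusted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import HitTable, PromoterSet
from .pwm_model import DiPWM, MonoPWM, ScoringModel

__all__ = [
    "PositionalProfile",
    "FunctionalWindow",
    "CutoffGrid",
    "score_all_windows",
    "scan",
    "z_profile",
    "cutoff_z_grid",
    "default_cutoff_grid",
    "detect_functional_windows",
]


@dataclass
class PositionalProfile:
    """Per-start-position hit counts and z-scores for one <W, c>."""

    O: np.ndarray  # observed promoter counts per start position
    E: float
    sigma: float
    z: np.ndarray
    cutoff: float
    matrix_id: str = ""


@dataclass
class FunctionalWindow:
    """Interval of promoter coordinates (0-based, half-open) with
    over-represented hits.  ``cutoff_range`` is the (most stringent, most
    permissive) pair of grid cut-offs at which the peak persists."""

    start: int
    end: int
    peak_z: float
    cutoff_range: tuple[float, float] = (0.0, 0.0)
    peak_positions: tuple[int, ...] = field(default_factory=tuple)
    # above-threshold z summed over the cut-off grid at the window's best
    # position: how sustained the signal is, the basis of window ranking
    strength: float = 0.0

    @property
    def span(self) -> int:
        return self.end - self.start

    def n_starts(self, L: int) -> int:
        """Number of motif start positions fully inside the window."""
        return max(0, self.span - L + 1)


@dataclass
class CutoffGrid:
    """z-scores on a (cutoff x start-position) grid for one matrix."""

    cutoffs: np.ndarray  # descending, all <= 0
    z: np.ndarray  # (n_cutoffs, n_positions)
    O: np.ndarray  # (n_cutoffs, n_positions) hit counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.cutoffs,
                            columns=np.arange(self.z.shape[1]))


def score_all_windows(matrix: MonoPWM | DiPWM, promoters: PromoterSet) -> np.ndarray:
    """(n_promoters, n_positions) matching scores of every length-L window."""
    L = matrix.L
    if promoters.length < L:
        raise ValueError("promoters shorter than the motif")
    rows = matrix.encode_for_scoring(promoters.encoded())
    k = matrix.weights.shape[1]  # columns: L for mono, L-1 for di
    win = np.lib.stride_tricks.sliding_window_view(rows, k, axis=1)
    return matrix.weights[win, np.arange(k)].sum(axis=-1)


def _window_start_bounds(
    window: FunctionalWindow | None, L: int, promoter_length: int
) -> tuple[int, int]:
    if window is None:
        return 0, promoter_length - L + 1
    if window.span < L:
        raise ValueError(f"window span {window.span} shorter than motif length {L}")
    lo = max(0, window.start)
    hi = min(window.end - L, promoter_length - L) + 1
    return lo, hi


def scan(
    model: ScoringModel,
    promoters: PromoterSet,
    window: FunctionalWindow | None = None,
    scores: np.ndarray | None = None,
) -> HitTable:
    """All (promoter, start) pairs with score >= cutoff, restricted to starts
    whose full motif lies inside ``window`` when one is given.

    ``scores`` may carry a precomputed :func:`score_all_windows` matrix.
    """
    if scores is None:
        scores = score_all_windows(model.matrix, promoters)
    lo, hi = _window_start_bounds(window, model.matrix.L, promoters.length)
    sub = scores[:, lo:hi]
    prom_idx, pos_idx = np.nonzero(sub >= model.cutoff)
    records = [
        (promoters.identifiers[p], int(lo + q), float(sub[p, q]), "+")
        for p, q in zip(prom_idx, pos_idx)
    ]
    if not records:
        return HitTable.empty()
    return HitTable.from_records(records)


def _profile_from_counts(O: np.ndarray, cutoff: float, matrix_id: str = "") -> PositionalProfile:
    E = float(O.mean())
    sigma = float(O.std())  # population SD over positions
    if sigma == 0:
        z = np.zeros_like(O, dtype=float)
    else:
        z = (O - E) / sigma
    return PositionalProfile(O=O, E=E, sigma=sigma, z=z, cutoff=cutoff,
                             matrix_id=matrix_id)


def z_profile(
    model: ScoringModel,
    promoters: PromoterSet,
    scores: np.ndarray | None = None,
) -> PositionalProfile:
    """Positional hit-count profile and z-scores at the model's cut-off.

    O(p) counts promoters with at least one hit starting at p (capped at one
    per promoter)."""
    if scores is None:
        scores = score_all_windows(model.matrix, promoters)
    O = (scores >= model.cutoff).sum(axis=0).astype(float)
    return _profile_from_counts(O, model.cutoff)


def default_cutoff_grid(matrix: MonoPWM | DiPWM, step: float = 0.5) -> np.ndarray:
    """Descending cut-off grid from 0 down to the minimum achievable score."""
    lo = matrix.min_score()
    n = int(np.ceil(-lo / step)) + 1
    return -step * np.arange(n)


def cutoff_z_grid(
    matrix: MonoPWM | DiPWM,
    promoters: PromoterSet,
    cutoffs: np.ndarray | None = None,
) -> CutoffGrid:
    """z-profiles over a descending grid of cut-offs (rows) and start
    positions (columns); the raw material for the signal-detection heat map."""
    if cutoffs is None:
        cutoffs = default_cutoff_grid(matrix)
    cutoffs = np.asarray(cutoffs, dtype=float)
    if cutoffs.size == 0:
        raise ValueError("empty cut-off grid")
    if (cutoffs > 0).any():
        raise ValueError("cut-offs must be <= 0")
    scores = score_all_windows(matrix, promoters)
    O = np.stack([(scores >= c).sum(axis=0).astype(float) for c in cutoffs])
    z = np.zeros_like(O)
    for i in range(O.shape[0]):
        prof = _profile_from_counts(O[i], cutoffs[i])
        z[i] = prof.z
    return CutoffGrid(cutoffs=cutoffs, z=z, O=O)


def detect_functional_windows(
    grid: CutoffGrid, L: int, z_threshold: float = 3.0
) -> list[FunctionalWindow]:
    """Fuse over-represented start positions into functional windows.

    The anchor is the start position with the largest *sustained*
    over-representation signal on the detection heat map: the above-
    threshold z excess summed over the cut-off grid, counted only for
    positions that qualify at two or more cut-offs.  (A bare per-row
    maximum is unreliable: at very stringent cut-offs the positional
    counts are tiny and a couple of chance hits produce enormous one-row z
    spikes, whereas a genuine signal stays above threshold across a band
    of cut-offs.)  Qualifying positions (z >= ``z_threshold``) are then
    collected at the anchor's strongest row; peaks closer than L are
    merged into one window spanning both (a single peak yields a window of
    span exactly L).  Each window reports the contiguous band of grid
    cut-offs, around its own peak row, over which the signal is sustained;
    the permissive end of that band is the natural initial matching
    cut-off for refinement.  Windows are returned most sustained (highest
    ``strength``, the robust excess mass summed over the window's peak
    positions) first.
    """
    if not (grid.z >= z_threshold).any():
        return []
    excess_mass = np.maximum(grid.z - z_threshold, 0.0).sum(axis=0)
    n_qualifying_rows = (grid.z >= z_threshold).sum(axis=0)
    robust = np.where(n_qualifying_rows >= 2, excess_mass, 0.0)
    if not robust.any():
        robust = excess_mass  # single-row grids: no persistence to demand
    anchor = int(robust.argmax())
    row = int(grid.z[:, anchor].argmax())
    positions = np.nonzero(grid.z[row] >= z_threshold)[0]
    clusters: list[list[int]] = [[int(positions[0])]]
    for p in positions[1:]:
        if p - clusters[-1][-1] < L:
            clusters[-1].append(int(p))
        else:
            clusters.append([int(p)])
    windows = []
    for cluster in clusters:
        start, last = cluster[0], cluster[-1]
        peak_z = float(grid.z[row, cluster].max())
        # sustained cut-off band: the contiguous run of qualifying rows
        # containing the reference row
        qualifies = (grid.z[:, cluster] >= z_threshold).any(axis=1)
        top = row
        while top > 0 and qualifies[top - 1]:
            top -= 1
        bottom = row
        while bottom < len(grid.cutoffs) - 1 and qualifies[bottom + 1]:
            bottom += 1
        cutoff_range = (float(grid.cutoffs[top]), float(grid.cutoffs[bottom]))
        windows.append(
            FunctionalWindow(
                start=start,
                end=last + L,
                peak_z=peak_z,
                cutoff_range=cutoff_range,
                peak_positions=tuple(cluster),
                strength=float(robust[cluster].sum()),
            )
        )
    windows.sort(key=lambda w: -w.strength)
    return windows
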