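"""Iterative PWM optimization driven by the Matthews correlation.

Starting from an initial matrix/cut-off suite <W0, c0> and a functional
window, each cycle (1) collects the hits of the current suite inside the
window, (2) unions the hit sites with the training sites and rebuilds the
matrix, (3) grid-searches the cut-off maximizing the Matthews correlation
Cor between the new suite's hits and the current ("old", taken as true)
hits, (4) evaluates four one-nucleotide length variants of the motif —
clipped left/right (cl/cr) and extended left/right (el/er) — each rebuilt
from the current hit sites and grid-searched the same way, and (5) accepts
the best candidate and repeats until Cor reaches 1 or stops improving
(hard cap ``max_cycles``).  The accepted-trajectory Cor is non-decreasing
by construction.

The confusion counts of a cycle treat the old suite's hits as truth:
TP = |new ∩ old| (exact promoter+start identity), FP = |new| - TP,
FN = |old| - TP, and TN complements to N_total = n_promoters *
max(1, window_span - L + 1), the number of possible hits in the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import mcc_from_counts
from .formats_io import HitTable, PromoterSet, SiteSet
from .pwm_model import (
    Background,
    MonoPWM,
    ScoringModel,
    build_di_pwm,
    build_mono_pwm,
    estimate_background,
)
from .scanning import (
    FunctionalWindow,
    cutoff_z_grid,
    detect_functional_windows,
    score_all_windows,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RefineConfig",
    "IterationConfusion",
    "RefinementResult",
    "iteration_confusion",
    "length_variants",
    "refine",
]

_VARIANTS = ("cl", "cr", "el", "er")


@dataclass
class RefineConfig:
    """Tunable parameters of the refinement loop."""

    matrix_type: str = "mono"  # "mono" | "di"
    cutoff_step: float = 0.5
    c1: float | None = None  # most permissive cut-off; default: min achievable score
    c2: float = 0.0  # most stringent cut-off
    z_threshold: float = 3.0
    min_length: int = 5
    max_cycles: int = 20
    rewindow: bool = False
    window: FunctionalWindow | None = None
    # windows whose sustained z signal falls below this fraction of the
    # strongest window's are not considered "equally strong" and are skipped
    window_strength: float = 0.8
    seed: int | None = None


@dataclass
class IterationConfusion:
    """TP/FP/FN/TN of one refinement cycle (old hits taken as true)."""

    TP: int
    FP: int
    FN: int
    TN: int
    convention: str = "iteration"

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class RefinementResult:
    """Final optimized suite plus the discovered sites and the Cor trajectory."""

    model: ScoringModel
    sites: SiteSet
    hits: HitTable
    window: FunctionalWindow
    cor: float
    trajectory: list[dict] = field(default_factory=list)
    converged: bool = True
    improved: bool = True

    @property
    def n_cycles(self) -> int:
        return len(self.trajectory)


def iteration_confusion(
    old_hits: HitTable,
    new_hits: HitTable,
    window: FunctionalWindow,
    n_promoters: int,
    L: int,
) -> IterationConfusion:
    """Confusion counts of new vs. old hits inside one functional window."""
    old = old_hits.pairs()
    new = new_hits.pairs()
    tp = len(new & old)
    fp = len(new) - tp
    fn = len(old) - tp
    n_total = n_promoters * max(1, window.span - L + 1)
    tn = n_total - (tp + fp + fn)
    if tn < 0:
        raise RuntimeError(
            f"window capacity {n_total} smaller than TP+FP+FN={tp + fp + fn}"
        )
    return IterationConfusion(TP=tp, FP=fp, FN=fn, TN=tn)


def _sites_from_hits(hits: HitTable, promoters: PromoterSet, L: int) -> list[str]:
    seq_by_id = dict(zip(promoters.identifiers, promoters.sequences))
    out = []
    for pid, start in sorted(hits.pairs()):
        out.append(seq_by_id[pid][start:start + L])
    return out


def length_variants(
    model: ScoringModel,
    hits: HitTable,
    promoters: PromoterSet,
    min_length: int = 5,
) -> dict[str, SiteSet | None]:
    """The four one-nucleotide length variants of the current hit sites.

    cl/cr clip the left/right flanking column (length L-1); el/er extend
    the site by the adjacent promoter nucleotide (length L+1).  Hits whose
    extension would cross a promoter boundary are dropped from that
    variant.  A variant is None when it is infeasible (below ``min_length``,
    or fewer than 2 usable sites).
    """
    if len(hits) == 0:
        raise ValueError("no hits to derive length variants from")
    L = model.matrix.L
    seq_by_id = dict(zip(promoters.identifiers, promoters.sequences))
    prom_len = promoters.length
    spans = {
        "cl": (1, 0),  # (left trim, right delta) applied to (start, start+L)
        "cr": (0, -1),
        "el": (-1, 0),
        "er": (0, 1),
    }
    out: dict[str, SiteSet | None] = {}
    for name, (dl, dr) in spans.items():
        new_len = L - dl + dr
        if new_len < min_length:
            out[name] = None
            continue
        seqs = []
        for pid, start in sorted(hits.pairs()):
            lo, hi = start + dl, start + L + dr
            if lo < 0 or hi > prom_len:
                continue  # boundary-crossing hit dropped from this variant
            seqs.append(seq_by_id[pid][lo:hi])
        out[name] = SiteSet(seqs) if len(seqs) >= 2 else None
    return out


def _build(matrix_type: str, sites: SiteSet, background: Background):
    if matrix_type == "mono":
        return build_mono_pwm(sites, background)
    if matrix_type == "di":
        return build_di_pwm(sites, background)
    raise ValueError(f"unknown matrix type {matrix_type!r}")


class _Scorer:
    """Caches encoded promoters and computes window-restricted score blocks."""

    def __init__(self, promoters: PromoterSet):
        self.promoters = promoters
        self.enc = promoters.encoded()
        self.di = 4 * self.enc[:, :-1] + self.enc[:, 1:]

    def scores(self, matrix, window: FunctionalWindow) -> tuple[np.ndarray, int]:
        """(scores, lo): scores[:, j] is the score at start position lo+j."""
        L = matrix.span
        if window.span < L:
            return np.empty((len(self.promoters), 0)), window.start
        lo = max(0, window.start)
        hi = min(window.end - L, self.promoters.length - L) + 1
        rows = self.enc if isinstance(matrix, MonoPWM) else self.di
        k = matrix.weights.shape[1]
        win = np.lib.stride_tricks.sliding_window_view(rows, k, axis=1)[:, lo:hi]
        return matrix.weights[win, np.arange(k)].sum(axis=-1), lo

    def hits(self, matrix, cutoff: float, window: FunctionalWindow,
             block: tuple[np.ndarray, int] | None = None) -> HitTable:
        scores, lo = block if block is not None else self.scores(matrix, window)
        prom_idx, pos_idx = np.nonzero(scores >= cutoff)
        if prom_idx.size == 0:
            return HitTable.empty()
        ids = self.promoters.identifiers
        return HitTable.from_records(
            [(ids[p], int(lo + q), float(scores[p, q]), "+")
             for p, q in zip(prom_idx, pos_idx)]
        )


def _cutoff_grid(matrix, config: RefineConfig) -> np.ndarray:
    c1 = matrix.min_score() if config.c1 is None else config.c1
    c2 = config.c2
    n = int(np.ceil((c2 - c1) / config.cutoff_step)) + 1
    grid = c2 - config.cutoff_step * np.arange(n)  # stringent -> permissive
    return grid[grid >= c1 - 1e-9]


def _grid_search(
    scorer: _Scorer,
    matrix,
    window: FunctionalWindow,
    old_hits: HitTable,
    config: RefineConfig,
    offset: int = 0,
):
    """Best (cutoff, cor, hits) of ``matrix`` against ``old_hits``.

    ``offset`` maps this matrix's hit starts back to the coordinate frame
    of ``old_hits`` (a left-clip shifts starts by +1, a left-extension by
    -1), so a site and its one-nucleotide length variant count as the same
    hit.  The grid is walked from stringent to permissive, so among
    equal-Cor cut-offs the most stringent wins.  Returns None when Cor is
    undefined at every cut-off.
    """
    block = scorer.scores(matrix, window)
    scores, lo = block
    if scores.shape[1] == 0:
        return None
    old = old_hits.pairs()
    n_total = len(scorer.promoters) * max(1, window.span - matrix.span + 1)
    best = None
    for c in _cutoff_grid(matrix, config):
        prom_idx, pos_idx = np.nonzero(scores >= c)
        new = {
            (scorer.promoters.identifiers[p], int(lo + q + offset))
            for p, q in zip(prom_idx, pos_idx)
        }
        tp = len(new & old)
        fp = len(new) - tp
        fn = len(old) - tp
        tn = n_total - (tp + fp + fn)
        if tn < 0:
            continue
        if tp > 0 and fp == 0 and fn == 0:
            # exact agreement with the old suite: perfect correlation even
            # when the window is saturated and no true negatives remain
            cor = 1.0
        else:
            cor = mcc_from_counts(tp, fp, fn, tn)
        if cor is None:
            continue
        if best is None or cor > best[1] + 1e-12:
            best = (float(c), cor)
    if best is None:
        return None
    c, cor = best
    return c, cor, scorer.hits(matrix, c, window, block)


def _initial_cutoff(
    scorer: _Scorer, matrix, window: FunctionalWindow, config: RefineConfig
) -> float:
    """Initial matching cut-off c0 from the sustained z-signal band.

    Walking the grid from stringent to permissive, c0 is the permissive end
    of the first contiguous run of cut-offs at which some window start
    position reaches the z threshold — the cut-off the signal is sustained
    up to on the detection heat map.  A permissive c0 is what lets the
    first cycle collect degenerate variant sites rather than only exact
    consensus copies.  Falls back to the most stringent cut-off producing
    any hit in the window.
    """
    scores, lo = scorer.scores(matrix, window)
    full = score_all_windows(matrix, scorer.promoters)
    band_last = None
    fallback = None
    for c in _cutoff_grid(matrix, config):
        O = (full >= c).sum(axis=0).astype(float)
        sigma = O.std()
        qualified = False
        if sigma > 0:
            z = (O - O.mean()) / sigma
            qualified = bool((z[lo:lo + scores.shape[1]] >= config.z_threshold).any())
        if qualified:
            band_last = float(c)
        elif band_last is not None:
            return band_last  # sustained band just ended
        if fallback is None and (scores >= c).any():
            fallback = float(c)
    if band_last is not None:
        return band_last
    if fallback is None:
        raise RuntimeError(
            "no cut-off yields hits in the functional window; relax the grid"
        )
    return fallback


def _redetect_window(
    promoters: PromoterSet, matrix, window: FunctionalWindow,
    config: RefineConfig,
) -> FunctionalWindow:
    """Re-run window detection with the current matrix and keep the detected
    window that overlaps the working one (used only when rewindow is on)."""
    grid = cutoff_z_grid(matrix, promoters)
    detected = detect_functional_windows(grid, L=matrix.L,
                                         z_threshold=config.z_threshold)
    overlap = lambda w: min(w.end, window.end) - max(w.start, window.start)
    candidates = [w for w in detected if overlap(w) > 0]
    if not candidates:
        return window
    return max(candidates, key=overlap)


def _adjust_window(window: FunctionalWindow, variant: str,
                   promoter_length: int) -> FunctionalWindow:
    """Let the window track the motif footprint of an accepted length variant."""
    start, end = window.start, window.end
    if variant == "cl":
        start += 1
    elif variant == "cr":
        end -= 1
    elif variant == "el":
        start = max(0, start - 1)
    elif variant == "er":
        end = min(promoter_length, end + 1)
    return replace(window, start=start, end=end)


def refine(
    initial_sites: SiteSet,
    promoters: PromoterSet,
    matrix_type: str = "mono",
    config: RefineConfig | None = None,
) -> RefinementResult:
    """Run the full iterative refinement from an initial aligned site set.

    When no window is supplied in ``config``, functional windows are
    detected with the initial *mononucleotide* matrix (the signal-detection
    stage always uses the mono model); every detected window is refined and
    the one with the maximal optimized Cor is returned.
    """
    if config is None:
        config = RefineConfig(matrix_type=matrix_type)
    background = estimate_background(promoters)
    scorer = _Scorer(promoters)

    if config.window is not None:
        windows = [config.window]
    else:
        mono0 = build_mono_pwm(initial_sites, background)
        grid = cutoff_z_grid(mono0, promoters)
        windows = detect_functional_windows(grid, L=mono0.L,
                                            z_threshold=config.z_threshold)
        if not windows:
            raise RuntimeError(
                "no functional window detected (no position sustains the z "
                "threshold); supply one in config or lower z_threshold"
            )
        # only windows with "equally strong" sustained signals compete on Cor
        strongest = windows[0].strength
        windows = [w for w in windows
                   if w.strength >= config.window_strength * strongest]

    best: RefinementResult | None = None
    best_key: tuple[float, float] = (-np.inf, -np.inf)
    for window in windows:
        result = _refine_window(initial_sites, promoters, matrix_type, config,
                                background, scorer, window)
        key = (result.cor, window.strength)  # Cor first, sustained signal breaks ties
        if np.isnan(key[0]):
            key = (-np.inf, window.strength)
        if key > best_key:
            best, best_key = result, key
    assert best is not None
    return best


def _refine_window(
    initial_sites: SiteSet,
    promoters: PromoterSet,
    matrix_type: str,
    config: RefineConfig,
    background: Background,
    scorer: _Scorer,
    window: FunctionalWindow,
) -> RefinementResult:
    W = _build(matrix_type, initial_sites, background)
    c = _initial_cutoff(scorer, W, window, config)

    cur_cor = -np.inf
    trajectory: list[dict] = []
    converged = False
    n_sites = len(initial_sites)

    for cycle in range(1, config.max_cycles + 1):
        if config.rewindow and cycle > 1:
            window = _redetect_window(scorer.promoters, W, window, config)

        # step 1: hits of the current suite in the window
        old_hits = scorer.hits(W, c, window)
        if len(old_hits) == 0:
            if cycle == 1:
                raise RuntimeError(
                    "initial suite finds no hits in the functional window; "
                    "relax the cut-off grid"
                )
            break

        # step 2: union training + discovered sites, rebuild
        discovered = _sites_from_hits(old_hits, promoters, W.L)
        seqs = list(discovered)
        if initial_sites.length == W.L:
            seqs = list(initial_sites.sequences) + seqs
        union = SiteSet(seqs)
        Wi = _build(matrix_type, union, background)

        # step 3: cut-off grid search against the old suite's hits
        same = _grid_search(scorer, Wi, window, old_hits, config)
        candidates: list[tuple] = []
        if same is not None:
            ci, cor_i, hits_i = same
            candidates.append((cor_i, 1, -Wi.L, ci, Wi, hits_i, None, union))

            # step 4: the four length variants, rebuilt from current hits
            variants = length_variants(
                ScoringModel(Wi, ci), hits_i, promoters, config.min_length
            )
            for name in _VARIANTS:
                sites_v = variants[name]
                if sites_v is None:
                    continue
                if matrix_type == "di" and sites_v.length < 5:
                    continue
                Wv = _build(matrix_type, sites_v, background)
                win_v = _adjust_window(window, name, promoters.length)
                # map variant hit starts back to the unmodified frame
                offset = {"cl": -1, "cr": 0, "el": 1, "er": 0}[name]
                res_v = _grid_search(scorer, Wv, win_v, hits_i, config,
                                     offset=offset)
                if res_v is None:
                    continue
                cv, cor_v, hits_v = res_v
                candidates.append(
                    (cor_v, 0, -Wv.L, cv, Wv, hits_v, name, sites_v)
                )

        if not candidates:
            break
        # lexicographic preference: Cor, then unmodified length, then
        # shorter L, then more stringent (larger) cut-off
        cor_b, _, _, c_b, W_b, hits_b, variant_b, sites_b = max(
            candidates, key=lambda t: t[:4]
        )

        if cor_b <= cur_cor + 1e-12:
            converged = True
            break

        W, c, cur_cor = W_b, c_b, cor_b
        if variant_b is not None:
            window = _adjust_window(window, variant_b, promoters.length)
        n_sites = len(sites_b)
        trajectory.append(
            {
                "cycle": cycle,
                "cor": cur_cor,
                "L": W.L,
                "cutoff": c,
                "n_sites": n_sites,
                "variant": variant_b or "same",
            }
        )
        logger.info(
            "cycle %d: Cor=%.4f L=%d cutoff=%.2f sites=%d variant=%s",
            cycle, cur_cor, W.L, c, n_sites, variant_b or "same",
        )
        if cur_cor >= 1.0 - 1e-12:
            converged = True
            break

    final_hits = scorer.hits(W, c, window)
    final_sites = SiteSet(_sites_from_hits(final_hits, promoters, W.L)) \
        if len(final_hits) else initial_sites
    improved = bool(trajectory)
    return RefinementResult(
        model=ScoringModel(W, c),
        sites=final_sites,
        hits=final_hits,
        window=window,
        cor=float(cur_cor) if np.isfinite(cur_cor) else float("nan"),
        trajectory=trajectory,
        converged=converged,
        improved=improved,
    )
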