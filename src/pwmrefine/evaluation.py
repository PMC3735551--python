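"""Prediction scoring on synthetic tests.

A hit is credited to an embedded motif when its start lies within
floor(L/2)+1 nt of the nearer motif edge (the tolerance used for the
method-comparison tables; an alternative looser mode accepts anything
within one motif length).  Each embedded motif yields at most one true
positive; surplus matching hits count as false positives.  True negatives
complement TP+FP+FN to the total number of possible hits in the test,
N_total = test_size * (seq_len - L + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import HitTable

__all__ = [
    "TestConfusion",
    "MetricReport",
    "match_hits",
    "precision",
    "recall",
    "mcc",
    "mcc_from_counts",
    "percent_change",
    "frequency_recovery",
    "evaluate_model",
    "format_metric",
]


@dataclass
class TestConfusion:
    """TP/FP/FN/TN under the synthetic-test convention."""

    TP: int
    FP: int
    FN: int
    TN: int
    test_size: int
    N_total: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.FP + self.FN + self.TN != self.N_total:
            raise ValueError("confusion counts do not reconcile to N_total")


@dataclass
class MetricReport:
    """Precision/recall/MCC; None encodes the undefined ('n/a') case."""

    precision: float | None
    recall: float | None
    mcc: float | None


def _tolerance(L: int, tolerance) -> int:
    if tolerance == "paper":
        return L // 2 + 1
    return int(tolerance)


def match_hits(
    hits: HitTable,
    truth: pd.DataFrame,
    L: int,
    seq_len: int,
    tolerance="paper",
) -> TestConfusion:
    """Tolerance-based matching of predicted hits against embedded motifs.

    ``truth`` has one row per test sequence with columns ``sequence_id``,
    ``insert_start`` and ``motif_length``.  A motif (edges ``insert_start``
    and ``insert_start + motif_length - 1``) is recovered if at least one
    hit start lies within the tolerance of the nearer edge; the closest
    such hit is credited and every other hit is a false positive.
    """
    required = {"sequence_id", "insert_start", "motif_length"}
    if not required <= set(truth.columns):
        raise ValueError(f"truth table must have columns {sorted(required)}")
    known = set(truth["sequence_id"])
    if len(hits) and not set(hits.frame["promoter_id"]) <= known:
        unknown = sorted(set(hits.frame["promoter_id"]) - known)
        raise ValueError(f"hits reference unknown sequences: {unknown[:5]}")

    test_size = len(truth)
    n_total = test_size * (seq_len - L + 1)
    tol = _tolerance(L, tolerance)

    by_seq: dict[str, list[int]] = {}
    for pid, start in zip(hits.frame["promoter_id"], hits.frame["start"].astype(int)):
        by_seq.setdefault(pid, []).append(start)

    tp = 0
    for row in truth.itertuples(index=False):
        starts = by_seq.get(row.sequence_id, [])
        if not starts:
            continue
        left = int(row.insert_start)
        right = left + int(row.motif_length) - 1
        dists = [min(abs(s - left), abs(s - right)) for s in starts]
        if min(dists) <= tol:
            tp += 1
    fp = len(hits) - tp
    fn = test_size - tp
    tn = n_total - (tp + fp + fn)
    return TestConfusion(TP=tp, FP=fp, FN=fn, TN=tn, test_size=test_size,
                         N_total=n_total)


def precision(cc) -> float | None:
    """TP/(TP+FP); None when no positive calls were made."""
    denom = cc.TP + cc.FP
    return cc.TP / denom if denom else None


def recall(cc) -> float | None:
    """Sensitivity TP/(TP+FN); None when there are no actual positives."""
    denom = cc.TP + cc.FN
    return cc.TP / denom if denom else None


def mcc_from_counts(tp: int, fp: int, fn: int, tn: int) -> float | None:
    """Matthews correlation coefficient; None when any marginal is zero."""
    factors = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(f == 0 for f in factors):
        return None
    return (tp * tn - fp * fn) / math.sqrt(math.prod(float(f) for f in factors))


def mcc(cc) -> float | None:
    """Matthews correlation of any confusion object with TP/FP/FN/TN fields."""
    return mcc_from_counts(cc.TP, cc.FP, cc.FN, cc.TN)


def percent_change(old_count: float, new_count: float) -> float:
    """Signed percentage change 100*(new-old)/old of a hit count."""
    if old_count == 0:
        raise ValueError("percent change undefined for old_count = 0")
    return 100.0 * (new_count - old_count) / old_count


def format_metric(value: float | None, digits: int = 3) -> str:
    """Render a metric the way the comparison tables print it ('n/a' when
    undefined)."""
    return "n/a" if value is None else f"{value:.{digits}f}"


def frequency_recovery(
    recovered: np.ndarray, generating: np.ndarray, min_overlap: int = 4
) -> tuple[int, float]:
    """Mean per-column Pearson correlation between a recovered and a
    generating 4 x L base-frequency matrix, maximized over column offsets.

    Refinement may return a motif one or two columns longer or shorter than
    the generator's, so the two matrices are slid against each other and
    the offset with the best mean per-column correlation over the overlap
    (at least ``min_overlap`` columns) is reported as ``(offset, mean_r)``.
    ``offset`` is the recovered column aligned with the generator's first.
    """
    rec = np.asarray(recovered, dtype=float)
    gen = np.asarray(generating, dtype=float)
    if rec.shape[0] != 4 or gen.shape[0] != 4:
        raise ValueError("frequency matrices must have 4 rows")
    n_rec, n_gen = rec.shape[1], gen.shape[1]
    best = (0, -np.inf)
    for offset in range(-(n_gen - min_overlap), n_rec - min_overlap + 1):
        cols = [
            (offset + j, j)
            for j in range(n_gen)
            if 0 <= offset + j < n_rec
        ]
        if len(cols) < min_overlap:
            continue
        rs = []
        for jr, jg in cols:
            a, b = rec[:, jr], gen[:, jg]
            if a.std() == 0 or b.std() == 0:
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(a, b)[0, 1]))
        mean_r = float(np.mean(rs))
        if mean_r > best[1]:
            best = (offset, mean_r)
    return best


def evaluate_model(model, tests, tolerance="paper") -> tuple[MetricReport, pd.DataFrame]:
    """Scan each replicate with the model's cut-off, match hits against the
    truth and report per-replicate and replicate-mean metrics.

    ``tests`` is a list of :class:`~pwmrefine.synthetic.SyntheticTest`
    replicates.  Means are taken over replicates where the metric is
    defined; an all-undefined column yields None.
    """
    from .formats_io import PromoterSet
    from .scanning import scan

    L = model.matrix.L
    rows = []
    for test in tests:
        promoters = PromoterSet(
            list(test.sequences), tss_offset=0, identifiers=list(test.identifiers)
        )
        hits = scan(model, promoters)
        cc = match_hits(hits, test.truth, L=L, seq_len=promoters.length,
                        tolerance=tolerance)
        rows.append(
            {
                "replicate": test.replicate_id,
                "TP": cc.TP,
                "FP": cc.FP,
                "FN": cc.FN,
                "TN": cc.TN,
                "precision": precision(cc),
                "recall": recall(cc),
                "mcc": mcc(cc),
            }
        )
    table = pd.DataFrame(rows)

    def _mean(col: str) -> float | None:
        vals = [v for v in table[col] if v is not None and not pd.isna(v)]
        return float(np.mean(vals)) if vals else None

    report = MetricReport(
        precision=_mean("precision"), recall=_mean("recall"), mcc=_mean("mcc")
    )
    return report, table
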