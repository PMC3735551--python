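"""Background-corrected mono- and dinucleotide position weight matrices.

A matrix is built from an aligned, gap-free site set against a pooled
promoter background.  Per column i and base b the weight is the corrected
log-odds

    w_bi = ln( p_bi / e_b ) - c_i ,   p_bi = (n_bi + s_i) / (n_m + A * s_i)

where ``n_bi`` are the observed counts among the ``n_m`` training sites,
``e_b`` is the background fraction of base b (position-independent, pooled
over the promoter region), ``A`` is the alphabet size (4 bases or 16
dinucleotides), ``s_i`` is a Laplace pseudocount applied only to columns
that contain a zero count, and ``c_i`` shifts each column so that its
maximum weight is exactly 0.  Consequently every matching score is <= 0 and
the consensus scores 0.

The dinucleotide matrix applies the same construction to the 16 overlapping
base pairs of each site, so a length-L motif yields a 16 x (L-1) matrix.
Matching scores are plain sums of the selected per-column weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .alphabet import ALPHABET, DINUCLEOTIDES, encode
from .formats_io import PromoterSet, SiteSet

logger = logging.getLogger(__name__)

__all__ = [
    "Background",
    "MonoPWM",
    "DiPWM",
    "ScoringModel",
    "estimate_background",
    "build_mono_pwm",
    "build_di_pwm",
    "dinucleotide_sequence",
    "score",
    "column_frequencies",
    "information_content",
]


@dataclass
class Background:
    """Pooled base and dinucleotide fractions of a promoter region.

    ``e_b`` follows the (A,T,G,C) order; ``e_d`` the fixed 16-dinucleotide
    order.  Fractions are position-independent.
    """

    e_b: np.ndarray
    e_d: np.ndarray
    n_p: int
    region: tuple[int, int]

    def __post_init__(self) -> None:
        self.e_b = np.asarray(self.e_b, dtype=float)
        self.e_d = np.asarray(self.e_d, dtype=float)
        for name, v, k in (("e_b", self.e_b, 4), ("e_d", self.e_d, 16)):
            if v.shape != (k,):
                raise ValueError(f"{name} must have shape ({k},)")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {v.sum()}, not 1")

    @classmethod
    def uniform(cls, n_p: int = 0, region: tuple[int, int] = (0, 0)) -> "Background":
        return cls(np.full(4, 0.25), np.full(16, 1 / 16), n_p, region)


def _floored_fractions(counts: np.ndarray, what: str) -> np.ndarray:
    """Counts -> fractions, flooring zeros at 1/(total+k) and renormalizing."""
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no {what} counts in region")
    frac = counts / total
    if (frac == 0).any():
        floor = 1.0 / (total + len(counts))
        warnings.warn(
            f"zero {what} background frequency floored at {floor:.3g}",
            stacklevel=3,
        )
        frac = np.maximum(frac, floor)
        frac = frac / frac.sum()
    return frac


def estimate_background(
    promoters: PromoterSet, region: tuple[int, int] | None = None
) -> Background:
    """Pooled base and overlapping-dinucleotide fractions over ``region``
    (0-based, half-open promoter indices; default: the full promoter span).
    """
    if region is None:
        region = (0, promoters.length)
    start, end = region
    if not (0 <= start < end <= promoters.length):
        raise ValueError(f"region {region} outside promoter bounds")
    enc = promoters.encoded()[:, start:end]
    base_counts = np.bincount(enc.ravel(), minlength=4).astype(float)
    di = 4 * enc[:, :-1] + enc[:, 1:]
    di_counts = np.bincount(di.ravel(), minlength=16).astype(float)
    return Background(
        _floored_fractions(base_counts, "base"),
        _floored_fractions(di_counts, "dinucleotide"),
        n_p=len(promoters),
        region=region,
    )


@dataclass
class MonoPWM:
    """4 x L background-corrected log-odds matrix, max-shifted to 0 per column."""

    weights: np.ndarray  # (4, L)
    counts: np.ndarray  # (4, L)
    pseudo: np.ndarray  # (L,) s_i actually applied
    shift: np.ndarray  # (L,) c_i subtracted per column
    background: Background
    n_m: int

    @property
    def L(self) -> int:
        return self.weights.shape[1]

    @property
    def alphabet_size(self) -> int:
        return 4

    @property
    def row_labels(self) -> tuple[str, ...]:
        return tuple(ALPHABET)

    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    def encode_for_scoring(self, encoded_seq: np.ndarray) -> np.ndarray:
        """Map an encoded base sequence to this matrix's row indices."""
        return encoded_seq

    @property
    def span(self) -> int:
        """Nucleotide footprint of one match (equals L)."""
        return self.L


@dataclass
class DiPWM:
    """16 x (L-1) dinucleotide matrix over overlapping pairs of a length-L motif."""

    weights: np.ndarray  # (16, L-1)
    counts: np.ndarray
    pseudo: np.ndarray
    shift: np.ndarray
    background: Background
    n_m: int

    @property
    def L(self) -> int:
        """Length of the nucleotide motif (columns + 1)."""
        return self.weights.shape[1] + 1

    @property
    def alphabet_size(self) -> int:
        return 16

    @property
    def row_labels(self) -> tuple[str, ...]:
        return DINUCLEOTIDES

    def min_score(self) -> float:
        return float(self.weights.min(axis=0).sum())

    def encode_for_scoring(self, encoded_seq: np.ndarray) -> np.ndarray:
        if encoded_seq.shape[-1] < 2:
            raise ValueError("need at least 2 nucleotides for dinucleotides")
        return 4 * encoded_seq[..., :-1] + encoded_seq[..., 1:]

    @property
    def span(self) -> int:
        return self.L


@dataclass
class ScoringModel:
    """A matrix plus its matching cut-off c; a window is a hit iff S >= c."""

    matrix: MonoPWM | DiPWM
    cutoff: float

    def __post_init__(self) -> None:
        if self.cutoff > 0:
            raise ValueError("cut-off must be <= 0 for max-shifted matrices")


def _build_weights(
    counts: np.ndarray, expected: np.ndarray, n_m: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared log-odds construction for 4- and 16-letter alphabets."""
    k = counts.shape[0]
    pseudo = (counts == 0).any(axis=0).astype(float)  # s_i per column
    p = (counts + pseudo) / (n_m + k * pseudo)
    raw = np.log(p / expected[:, None])
    shift = raw.max(axis=0)
    return raw - shift, pseudo, shift


def build_mono_pwm(sites: SiteSet, background: Background) -> MonoPWM:
    """Build the 4 x L mononucleotide PWM from aligned sites."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to build a matrix")
    if sites.length < 4:
        raise ValueError("motif length must be >= 4")
    enc = sites.encoded()
    counts = np.stack([(enc == b).sum(axis=0) for b in range(4)]).astype(float)
    weights, pseudo, shift = _build_weights(counts, background.e_b, len(sites))
    return MonoPWM(weights, counts, pseudo, shift, background, n_m=len(sites))


def build_di_pwm(sites: SiteSet, background: Background) -> DiPWM:
    """Build the 16 x (L-1) dinucleotide PWM from aligned sites."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites to build a matrix")
    if sites.length < 5:
        raise ValueError("dinucleotide model needs motif length >= 5")
    enc = sites.encoded()
    di = 4 * enc[:, :-1] + enc[:, 1:]
    counts = np.stack([(di == d).sum(axis=0) for d in range(16)]).astype(float)
    weights, pseudo, shift = _build_weights(counts, background.e_d, len(sites))
    return DiPWM(weights, counts, pseudo, shift, background, n_m=len(sites))


def dinucleotide_sequence(seq: str) -> list[int]:
    """Overlapping dinucleotide indices (fixed 16-letter order) of a DNA string."""
    if len(seq) < 2:
        raise ValueError("need at least 2 nucleotides")
    enc = encode(seq)
    return [int(d) for d in 4 * enc[:-1] + enc[1:]]


def score(model: MonoPWM | DiPWM, seq: str) -> float:
    """Matching score S(seq): the sum of per-column weights; always <= 0."""
    if len(seq) != model.L:
        raise ValueError(f"sequence length {len(seq)} != motif length {model.L}")
    rows = model.encode_for_scoring(encode(seq))
    return float(model.weights[rows, np.arange(len(rows))].sum())


def column_frequencies(sites: SiteSet) -> np.ndarray:
    """4 x L per-column base fractions (A,T,G,C order) of a site set."""
    enc = sites.encoded()
    counts = np.stack([(enc == b).sum(axis=0) for b in range(4)]).astype(float)
    return counts / counts.sum(axis=0)


def information_content(sites: SiteSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-column information content in bits and per-base contributions.

    IC_i = 2 + sum_b f_bi log2 f_bi (0 log 0 := 0); the 4 x L contribution
    matrix f_bi * IC_i is what sequence-logo letter heights are drawn from.
    No small-sample correction is applied.
    """
    enc = sites.encoded()
    counts = np.stack([(enc == b).sum(axis=0) for b in range(4)]).astype(float)
    f = counts / counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    ic = np.clip(ic, 0.0, 2.0)
    return ic, f * ic
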