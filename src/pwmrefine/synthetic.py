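"""Synthetic inputs: background promoter sets, planted-motif fixtures and
JASPAR-style embedded-site tests with background-reshuffled replicates.

The embedded-site tests mirror the structure used for method comparison:
each (possibly longer-than-motif) binding-site sequence keeps its local
alignment, the aligned block is placed at a fixed position in every test
sequence (e.g. 27), and equally distributed random nucleotides pad both
ends to a common total length (default 300 nt).  Replicates permute only
the random padding — the embedded sites and their unaligned flanks are
preserved verbatim — so the sequence background varies while the truth
does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import decode
from .formats_io import PromoterSet

__all__ = [
    "AlignedSite",
    "GeneratorSpec",
    "SyntheticTest",
    "PlantedBenchmark",
    "generate_promoters",
    "plant_motif",
    "build_site_test",
    "reshuffle_replicates",
    "planted_benchmark",
]


@dataclass
class AlignedSite:
    """A binding-site sequence with the local-alignment block marked.

    ``block_start``/``block_length`` delimit the aligned part within
    ``sequence``; the rest are unaligned flanks that travel with the site.
    """

    sequence: str
    block_start: int = 0
    block_length: int | None = None

    def __post_init__(self) -> None:
        if self.block_length is None:
            self.block_length = len(self.sequence) - self.block_start
        if not (0 <= self.block_start
                and self.block_start + self.block_length <= len(self.sequence)):
            raise ValueError("aligned block outside the site sequence")


@dataclass
class GeneratorSpec:
    """Parameters of an embedded-site synthetic test."""

    total_length: int = 300
    insert_position: int = 27
    background: str | tuple = "uniform"  # "uniform" or 4 base fractions (A,T,G,C)
    n_replicates: int = 10
    n_shuffles: int = 30
    seed: int = 0

    def fractions(self) -> np.ndarray:
        if isinstance(self.background, str):
            if self.background != "uniform":
                raise ValueError(f"unknown background {self.background!r}")
            return np.full(4, 0.25)
        f = np.asarray(self.background, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1) > 1e-9:
            raise ValueError("background fractions must be 4 non-negative values summing to 1")
        return f


@dataclass
class SyntheticTest:
    """Equal-length test sequences with known embedded aligned blocks.

    ``truth`` has one row per sequence: sequence_id, insert_start (start of
    the aligned block), motif_length, and the site footprint
    (site_start, site_end) used to tell padding from preserved content.
    """

    sequences: list[str]
    truth: pd.DataFrame
    identifiers: list[str] = field(default_factory=list)
    replicate_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.identifiers:
            self.identifiers = [f"test_{i}" for i in range(len(self.sequences))]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("test sequences must all have the same length")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)


def _sample_sequences(rng: np.random.Generator, n: int, length: int,
                      fractions: np.ndarray) -> list[str]:
    draws = rng.choice(4, size=(n, length), p=fractions)
    return [decode(row) for row in draws]


def generate_promoters(
    n: int,
    length: int,
    background="uniform",
    seed: int = 0,
    tss_offset: int | None = None,
) -> PromoterSet:
    """i.i.d. promoter sequences from a base-fraction model.

    Defaults emulate a TSS-aligned proximal-promoter set: for 600-nt
    sequences the TSS sits at index 499, i.e. coordinates -499..+100.
    """
    if n <= 0 or length <= 0:
        raise ValueError("n and length must be positive")
    if isinstance(background, str):
        if background != "uniform":
            raise ValueError(f"unknown background {background!r}")
        fractions = np.full(4, 0.25)
    else:
        fractions = np.asarray(background, dtype=float)
        if fractions.shape != (4,) or (fractions < 0).any() \
                or abs(fractions.sum() - 1) > 1e-9:
            raise ValueError("background fractions must be 4 values summing to 1")
    if tss_offset is None:
        tss_offset = length - 101 if length > 101 else 0
    rng = np.random.default_rng(seed)
    seqs = _sample_sequences(rng, n, length, fractions)
    return PromoterSet(seqs, tss_offset=tss_offset,
                       identifiers=[f"promoter_{i}" for i in range(n)])


def plant_motif(
    promoters: PromoterSet,
    frequency_matrix: np.ndarray,
    offset_window: tuple[int, int],
    plant_rate: float,
    seed: int = 0,
) -> tuple[PromoterSet, pd.DataFrame]:
    """Overwrite a sampled motif into a fraction of promoters.

    ``frequency_matrix`` is 4 x L in (A,T,G,C) order with columns summing
    to 1; each planted site is sampled column-wise from it and written at a
    uniform start within ``offset_window`` (inclusive bounds on the start).
    Returns the modified promoters and a truth table with one row per
    insertion (promoter_id, start, motif_length, site).
    """
    fm = np.asarray(frequency_matrix, dtype=float)
    if fm.shape[0] != 4:
        raise ValueError("frequency matrix must be 4 x L (A,T,G,C rows)")
    if not np.allclose(fm.sum(axis=0), 1.0):
        raise ValueError("frequency-matrix columns must sum to 1")
    L = fm.shape[1]
    lo, hi = offset_window
    if not (0 <= lo <= hi and hi + L <= promoters.length):
        raise ValueError("offset window does not fit the motif inside promoters")
    if not 0 <= plant_rate <= 1:
        raise ValueError("plant_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n = len(promoters)
    n_plant = int(round(plant_rate * n))
    chosen = sorted(rng.choice(n, size=n_plant, replace=False)) if n_plant else []
    sequences = list(promoters.sequences)
    records = []
    for idx in chosen:
        start = int(rng.integers(lo, hi + 1))
        site = decode(np.array([rng.choice(4, p=fm[:, j]) for j in range(L)]))
        s = sequences[idx]
        sequences[idx] = s[:start] + site + s[start + L:]
        records.append(
            {
                "promoter_id": promoters.identifiers[idx],
                "start": start,
                "motif_length": L,
                "site": site,
            }
        )
    truth = pd.DataFrame(records,
                         columns=["promoter_id", "start", "motif_length", "site"])
    planted = PromoterSet(sequences, tss_offset=promoters.tss_offset,
                          identifiers=list(promoters.identifiers))
    return planted, truth


@dataclass
class PlantedBenchmark:
    """A parameter-recovery benchmark: promoters with a planted motif, the
    generating frequency matrix, a small initial training site set sampled
    from that matrix, and the ground-truth insertion table."""

    promoters: PromoterSet
    frequency_matrix: np.ndarray
    initial_sites: "SiteSet"
    truth: pd.DataFrame


def planted_benchmark(
    seed: int,
    n_promoters: int = 2000,
    promoter_length: int = 600,
    motif_length: int = 8,
    consensus_probability: float = 0.7,
    offset_window: tuple[int, int] = (500, 510),
    plant_rate: float = 0.10,
    n_initial_sites: int = 10,
) -> PlantedBenchmark:
    """Build the standard planted-motif recovery benchmark.

    A random consensus of ``motif_length`` defines a frequency matrix with
    ``consensus_probability`` on the consensus base and the remainder split
    evenly; sites sampled column-wise from it are planted in a
    ``plant_rate`` fraction of i.i.d. uniform promoters at uniform offsets
    within ``offset_window`` (sitting just downstream of the TSS of
    600-nt, -499..+100 promoters).  ``n_initial_sites`` further samples
    from the same matrix form the initial training set, emulating the
    small curated site collections refinement starts from.
    """
    from .formats_io import SiteSet

    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=motif_length)
    fm = np.full((4, motif_length),
                 (1.0 - consensus_probability) / 3.0)
    fm[consensus, np.arange(motif_length)] = consensus_probability
    promoters = generate_promoters(n_promoters, promoter_length, seed=seed)
    planted, truth = plant_motif(promoters, fm, offset_window, plant_rate,
                                 seed=seed)
    initial = SiteSet(
        [decode(np.array([rng.choice(4, p=fm[:, j])
                          for j in range(motif_length)]))
         for _ in range(n_initial_sites)]
    )
    return PlantedBenchmark(planted, fm, initial, truth)


def build_site_test(sites: list[AlignedSite], spec: GeneratorSpec) -> SyntheticTest:
    """Embed aligned sites into random padding at a fixed block position.

    Each site is placed so that its aligned block starts at
    ``spec.insert_position``; random nucleotides extend both ends to
    ``spec.total_length``.
    """
    if not sites:
        raise ValueError("no sites to embed")
    rng = np.random.default_rng(spec.seed)
    fractions = spec.fractions()
    sequences, rows = [], []
    for i, site in enumerate(sites):
        site_start = spec.insert_position - site.block_start
        site_end = site_start + len(site.sequence)
        if site_start < 0:
            raise ValueError(
                f"site {i}: unaligned left flank does not fit before "
                f"insert position {spec.insert_position}"
            )
        if site_end > spec.total_length:
            raise ValueError(f"site {i} longer than total length {spec.total_length}")
        left = _sample_sequences(rng, 1, site_start, fractions)[0] if site_start else ""
        right_len = spec.total_length - site_end
        right = _sample_sequences(rng, 1, right_len, fractions)[0] if right_len else ""
        sequences.append(left + site.sequence + right)
        rows.append(
            {
                "sequence_id": f"test_{i}",
                "insert_start": spec.insert_position,
                "motif_length": site.block_length,
                "site_start": site_start,
                "site_end": site_end,
            }
        )
    truth = pd.DataFrame(rows)
    return SyntheticTest(sequences, truth, replicate_id=0, seed=spec.seed)


def reshuffle_replicates(
    test: SyntheticTest,
    n_replicates: int = 10,
    n_shuffles: int = 30,
    seed: int = 0,
) -> list[SyntheticTest]:
    """Background-reshuffled copies of an embedded-site test.

    In each replicate only the random padding outside each site footprint
    is permuted (``n_shuffles`` successive permutations, pooled across the
    padding positions of each sequence); embedded sites and their unaligned
    flanks stay verbatim at the same coordinates, so padding base
    composition is conserved exactly.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    replicates = []
    for r, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        sequences = []
        for seq, row in zip(test.sequences, test.truth.itertuples(index=False)):
            arr = np.array(list(seq))
            pad_idx = np.concatenate(
                [np.arange(0, row.site_start),
                 np.arange(row.site_end, len(seq))]
            ).astype(int)
            vals = arr[pad_idx]
            for _ in range(n_shuffles):
                vals = vals[rng.permutation(len(vals))]
            arr[pad_idx] = vals
            sequences.append("".join(arr))
        replicates.append(
            SyntheticTest(
                sequences,
                test.truth.copy(),
                identifiers=list(test.identifiers),
                replicate_id=r + 1,
                seed=seed,
            )
        )
    return replicates
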