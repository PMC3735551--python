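"""Sequence and matrix I/O: FASTA, TRANSFAC-style and JASPAR-PFM count
tables, and tab-separated hit tables.

All coordinates are 0-based, half-open.  TSS-relative positions are derived
as ``index - tss_offset``.  Only the forward strand is represented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import ALPHABET, encode_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PromoterSet",
    "SiteSet",
    "HitTable",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_matrix_table",
    "write_matrix_table",
    "read_hits_table",
    "write_hits_table",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class PromoterSet:
    """Equal-length, TSS-aligned promoter sequences over {A,C,G,T}.

    ``tss_offset`` is the 0-based index of the TSS within each sequence,
    so a 600-nt promoter spanning -499..+100 has ``tss_offset = 499``.
    """

    sequences: list[str]
    tss_offset: int
    identifiers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("empty promoter set")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"promoters have unequal lengths: {sorted(lengths)}")
        if not self.identifiers:
            self.identifiers = [f"promoter_{i}" for i in range(len(self.sequences))]
        if len(self.identifiers) != len(self.sequences):
            raise FormatError("identifiers and sequences differ in number")
        if not 0 <= self.tss_offset < self.length:
            raise ValueError(f"tss_offset {self.tss_offset} outside 0..{self.length - 1}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def encoded(self) -> np.ndarray:
        """(n_promoters, length) int8 matrix of base indices."""
        return encode_matrix(self.sequences)

    def to_tss_relative(self, index: int) -> int:
        return index - self.tss_offset


@dataclass
class SiteSet:
    """Aligned, equal-length, gap-free binding-site sequences."""

    sequences: list[str]
    source_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("empty site set")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"sites have unequal lengths: {sorted(lengths)}")
        bad = set("".join(self.sequences)) - set(ALPHABET)
        if bad:
            raise FormatError(f"sites contain non-ACGT characters: {sorted(bad)}")
        if not self.source_labels:
            self.source_labels = [f"site_{i}" for i in range(len(self.sequences))]

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def encoded(self) -> np.ndarray:
        return encode_matrix(self.sequences)


_HIT_COLUMNS = ["promoter_id", "start", "score", "strand"]


@dataclass
class HitTable:
    """Motif hits: (promoter_id, 0-based start, score, strand='+')."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _HIT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"hit table missing columns {missing}")
        self.frame = self.frame[_HIT_COLUMNS].reset_index(drop=True)
        if len(self.frame) and not np.isfinite(self.frame["score"]).all():
            raise ValueError("hit scores must be finite")

    @classmethod
    def from_records(cls, records: list[tuple]) -> "HitTable":
        return cls(pd.DataFrame(records, columns=_HIT_COLUMNS))

    @classmethod
    def empty(cls) -> "HitTable":
        return cls(pd.DataFrame(columns=_HIT_COLUMNS).astype(
            {"start": int, "score": float}))

    def __len__(self) -> int:
        return len(self.frame)

    def pairs(self) -> set[tuple[str, int]]:
        """Set of (promoter_id, start) identities."""
        return set(zip(self.frame["promoter_id"], self.frame["start"].astype(int)))


def read_fasta(
    path,
    kind: str = "sites",
    tss_offset: int | None = None,
) -> PromoterSet | SiteSet:
    """Load a FASTA file as a :class:`SiteSet` (``kind="sites"``) or a
    :class:`PromoterSet` (``kind="promoters"``).

    Sequences are uppercased.  For promoters, records containing ``N`` are
    dropped and the drop count logged; for sites any non-ACGT character is
    an error.  Both kinds require equal lengths.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    seqs, ids = [], []
    n_dropped = 0
    for rec in records:
        s = str(rec.seq).upper()
        if kind == "promoters" and ("N" in s):
            n_dropped += 1
            continue
        seqs.append(s)
        ids.append(rec.id)
    if n_dropped:
        logger.info("dropped %d promoter record(s) containing N", n_dropped)
    if not seqs:
        raise FormatError(f"no usable records in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        offender = next(i for i, s in zip(ids, seqs) if len(s) != len(seqs[0]))
        raise FormatError(f"unequal sequence lengths in {path}; first offender: {offender}")
    if kind == "promoters":
        if tss_offset is None:
            length = len(seqs[0])
            tss_offset = length - 101 if length > 101 else 0
        return PromoterSet(seqs, tss_offset=tss_offset, identifiers=ids)
    if kind == "sites":
        return SiteSet(seqs, source_labels=ids)
    raise ValueError(f"unknown kind {kind!r}")


def write_fasta(obj: PromoterSet | SiteSet, path) -> None:
    ids = obj.identifiers if isinstance(obj, PromoterSet) else obj.source_labels
    records = [SeqRecord(Seq(s), id=i, description="") for s, i in zip(obj.sequences, ids)]
    SeqIO.write(records, str(path), "fasta")


def read_matrix_table(path, dialect: str = "transfac") -> tuple[np.ndarray, dict]:
    """Read a count matrix in TRANSFAC-style or JASPAR-PFM dialect.

    Returns ``(counts, metadata)`` with counts as a 4 x L array in the fixed
    (A,T,G,C) row order regardless of the file's column order, and metadata
    holding at least ``accession`` and ``name``.
    """
    text = Path(path).read_text()
    if dialect == "transfac":
        try:
            records = motifs.parse(StringIO(text), "TRANSFAC")
        except Exception as exc:  # Bio raises bare ValueError on bad tables
            raise FormatError(f"cannot parse TRANSFAC table {path}: {exc}") from exc
        if not records:
            raise FormatError(f"no TRANSFAC records in {path}")
        motif = records[0]
        meta = {"accession": motif.get("AC", ""), "name": motif.get("ID", "")}
    elif dialect == "jaspar_pfm":
        try:
            motif = motifs.read(StringIO(text), "jaspar")
        except Exception as exc:
            raise FormatError(f"cannot parse JASPAR PFM {path}: {exc}") from exc
        meta = {"accession": getattr(motif, "matrix_id", "") or "",
                "name": motif.name or ""}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    counts = np.array([motif.counts[b] for b in ALPHABET], dtype=float)
    if (counts < 0).any():
        raise FormatError(f"negative counts in {path}")
    if counts.shape[0] != 4 or counts.shape[1] < 1:
        raise FormatError(f"malformed count matrix in {path}")
    return counts, meta


def write_matrix_table(counts: np.ndarray, path, accession: str = "",
                       name: str = "") -> None:
    """Write a 4 x L (A,T,G,C order) count matrix as a TRANSFAC-style table."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4:
        raise ValueError("counts must have 4 rows (A,T,G,C)")
    alphabet = "ACGT"  # TRANSFAC column order
    m = motifs.Motif(alphabet=alphabet, counts={
        b: list(counts[ALPHABET.index(b)]) for b in alphabet})
    text = motifs.write([m], "transfac")
    # Bio.motifs.write emits P0/XX//; prepend AC/ID tags for round-tripping.
    header = ""
    if accession:
        header += f"AC  {accession}\nXX\n"
    if name:
        header += f"ID  {name}\nXX\n"
    Path(path).write_text(header + text)


def write_hits_table(hits: HitTable, path) -> None:
    """Write a hit table as TSV with a comment line documenting coordinates."""
    with open(path, "w") as fh:
        fh.write("# start coordinates are 0-based, forward strand only\n")
        hits.frame.to_csv(fh, sep="\t", index=False)


def read_hits_table(path) -> HitTable:
    frame = pd.read_csv(path, sep="\t", comment="#")
    if frame.empty:
        return HitTable.empty()
    return HitTable(frame)
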