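"""Genomic primitives and shared file formats.

All coordinates are 0-based, half-open internally.  Parsers for 1-based
inputs (VCF/ClinVar-style position columns) subtract 1 at the boundary,
controlled by a ``one_based`` flag.  Sequences are held in memory as
uppercase strings over {A, C, G, T, N}; N is legal in the genome but not
in variant alleles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "GenomicInterval",
    "Variant",
    "ScoreTable",
    "load_fasta",
    "write_fasta",
    "fetch",
    "gc_content",
    "at_fraction",
    "overlaps",
    "variant_span",
    "variant_key",
    "indel_length",
    "read_score_table",
    "write_score_table",
]

_SEQ_ALPHABET = frozenset("ACGTN")
_ALLELE_ALPHABET = frozenset("ACGT")

SCORE_DECIMALS = 6  # fixed serialization precision for stable round trips


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Variant:
    """A sequence variant anchored at the first reference base (0-based).

    For the small-indel operations in this package ``ref`` and ``alt``
    must differ in length; same-length substitutions are valid Variants
    but are rejected by indel-specific pipelines.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vid: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be nonempty")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        for allele in (self.ref, self.alt):
            bad = set(allele) - _ALLELE_ALPHABET
            if bad:
                raise ValueError(
                    f"allele {allele!r} contains illegal characters {sorted(bad)}"
                )


def indel_length(v: Variant) -> int:
    """Allele-length difference |len(ref) - len(alt)|; 0 for substitutions."""
    return abs(len(v.ref) - len(v.alt))


def variant_span(v: Variant) -> GenomicInterval:
    """Reference footprint [pos, pos + len(ref)) of the variant."""
    return GenomicInterval(v.chrom, v.pos, v.pos + len(v.ref))


def variant_key(v: Variant) -> str:
    """Canonical identity string ``chrom:pos:ref:alt``."""
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


@dataclass
class GenomeSequence:
    """In-memory genome: contig name -> uppercase nucleotide string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if len(seq) < 1:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - _SEQ_ALPHABET
            if bad:
                raise ValueError(
                    f"contig {name!r} contains illegal characters {sorted(bad)}"
                )

    def contig_length(self, chrom: str) -> int:
        if chrom not in self.contigs:
            raise KeyError(f"unknown contig {chrom!r}")
        return len(self.contigs[chrom])

    def fetch(self, iv: GenomicInterval) -> str:
        return fetch(self, iv)


def load_fasta(path: str | Path) -> GenomeSequence:
    """Load a (multi-line, case-insensitive) FASTA into memory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch(genome: GenomeSequence, iv: GenomicInterval) -> str:
    """Extract the sequence of an interval; out-of-bounds is an error."""
    seq = genome.contigs.get(iv.chrom)
    if seq is None:
        raise KeyError(f"unknown contig {iv.chrom!r}")
    if iv.end > len(seq):
        raise ValueError(
            f"interval [{iv.start}, {iv.end}) exceeds contig "
            f"{iv.chrom!r} length {len(seq)}"
        )
    return seq[iv.start : iv.end]


def gc_content(seq: str) -> float:
    """(G + C) / length. N counts toward the length but not toward G+C."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def at_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("at_fraction of empty sequence")
    s = seq.upper()
    return (s.count("A") + s.count("T")) / len(s)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

_KEY_RE = re.compile(r"^[^:\s]+:\d+:[ACGT]+:[ACGT]+$")


@dataclass
class ScoreTable:
    """Per-(variant, tissue) functional scores in [0, 1].

    Backed by a DataFrame with columns ``variant_key``, ``tissue``,
    ``score``.  One row per (variant_key, tissue) pair.
    """

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["variant_key", "tissue", "score"]
        )
    )

    def __post_init__(self) -> None:
        required = ["variant_key", "tissue", "score"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"score table missing columns {missing}")
        self.df = self.df[required].reset_index(drop=True)
        scores = self.df["score"].astype(float)
        if len(scores) and ((scores < 0) | (scores > 1)).any():
            bad = scores[(scores < 0) | (scores > 1)].iloc[0]
            raise ValueError(f"score outside [0, 1]: {bad}")
        self.df["score"] = scores
        dup = self.df.duplicated(subset=["variant_key", "tissue"])
        if dup.any():
            pair = self.df.loc[dup.idxmax(), ["variant_key", "tissue"]]
            raise ValueError(
                f"duplicate (variant_key, tissue) pair: {tuple(pair)}"
            )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        return self.df.equals(other.df)

    def lookup(self, keys: Iterable[str], tissue: str | None = None) -> pd.DataFrame:
        """Rows for the query keys; absent keys yield no rows, not errors."""
        keys = list(keys)
        mask = self.df["variant_key"].isin(keys)
        if tissue is not None:
            mask &= self.df["tissue"] == tissue
        return self.df[mask].reset_index(drop=True)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    df = table.df.copy()
    df["score"] = df["score"].map(lambda s: f"{s:.{SCORE_DECIMALS}f}")
    df.to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str, "tissue": str})
    return ScoreTable(df)


# ---------------------------------------------------------------------------
# Variant table parsing helpers
# ---------------------------------------------------------------------------

def parse_variant_row(
    chrom: str, pos: int, ref: str, alt: str, *, one_based: bool = False,
    vid: str | None = None,
) -> Variant:
    """Build a Variant from table columns, converting 1-based input positions."""
    p = int(pos) - 1 if one_based else int(pos)
    return Variant(str(chrom), p, str(ref).upper(), str(alt).upper(), vid=vid)
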