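"""Enrichment of labeled and predicted indels in regulatory regions.

Region sets come from two sources: ChIP-seq-style peaks (standardized to
1000-bp windows around the peak center, significant at FDR < 0.05) and
promoter-centered chromatin interactions (intra-chromosomal, anchor
midpoints within 1 Mb, each anchor standardized to a 2-kb window,
significant at FDR < 0.1).  Negative regions are sampled to equal the
positives in number with a matched GC-content histogram, so base
composition cannot drive apparent enrichment.

Membership is reference-span overlap against half-open intervals; an
indel is inside a chromatin interaction if it hits either anchor window.
Enrichment is the odds ratio of the 2×2 table of variant label × region
class with a one-sided (greater) Fisher's exact test, computed for the
true labels and again for predicted labels thresholded at score > 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .core_io import (
    GenomeSequence,
    GenomicInterval,
    Variant,
    fetch,
    gc_content,
    overlaps,
    variant_span,
)
from .matching import DeficientBinsError, binned_match_indices

__all__ = [
    "Peak",
    "Interaction",
    "RegionSet",
    "ContingencyTable",
    "read_peaks",
    "read_interactions",
    "standardize_peak",
    "anchor_window",
    "build_interaction_sets",
    "build_peak_sets",
    "count_contingency",
    "odds_ratio",
    "fisher_one_sided",
    "enrich_report",
    "DEFAULT_GC_BIN_WIDTH",
]

logger = logging.getLogger(__name__)

DEFAULT_GC_BIN_WIDTH = 0.05
DEFAULT_PEAK_WIDTH = 1000
DEFAULT_ANCHOR_WIDTH = 2000
DEFAULT_PEAK_FDR = 0.05
DEFAULT_INTERACTION_FDR_POS = 0.1
DEFAULT_INTERACTION_FDR_NEG = 0.5
DEFAULT_MAX_INTERACTION_DIST = 1_000_000
DEFAULT_MIN_POSITIVE_INTERACTIONS = 100


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR outside [0, 1]: {self.fdr}")


@dataclass(frozen=True)
class Interaction:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    fdr: float
    itype: str  # "PE" or "PP"

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR outside [0, 1]: {self.fdr}")
        if self.itype not in ("PE", "PP"):
            raise ValueError(f"interaction type must be PE or PP, got {self.itype!r}")

    @property
    def intra_chromosomal(self) -> bool:
        return self.anchor1.chrom == self.anchor2.chrom

    @property
    def midpoint_distance(self) -> int:
        if not self.intra_chromosomal:
            raise ValueError("distance undefined for inter-chromosomal pairs")
        return abs(self.anchor1.midpoint - self.anchor2.midpoint)


@dataclass
class RegionSet:
    """Positive and negative genomic intervals for one enrichment test."""

    positives: list[GenomicInterval]
    negatives: list[GenomicInterval]
    label: str = ""


@dataclass(frozen=True)
class ContingencyTable:
    """n11: positive variants in positive regions; n12: positive variants
    in negative regions; n21/n22: the same for negative variants."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        for v in (self.n11, self.n12, self.n21, self.n22):
            if v < 0 or v != int(v):
                raise ValueError("counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]], dtype=int)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_peaks(path: str | Path) -> list[Peak]:
    """BED3 + fdr column (header optional: detected by a non-numeric
    second field)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if not df.iloc[0, 1].lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    peaks = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(row[0]), int(row[1]), int(row[2]))
        peaks.append(Peak(iv, float(row[3])))
    return peaks


def read_interactions(path: str | Path) -> list[Interaction]:
    """TSV with header chrom1,start1,end1,chrom2,start2,end2,fdr,itype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Interaction(
                GenomicInterval(row.chrom1, int(row.start1), int(row.end1)),
                GenomicInterval(row.chrom2, int(row.start2), int(row.end2)),
                float(row.fdr),
                str(row.itype),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Region standardization
# ---------------------------------------------------------------------------

def _centered_window(
    iv: GenomicInterval, width: int, contig_length: int | None
) -> GenomicInterval | None:
    mid = iv.midpoint
    start = mid - width // 2
    end = start + width
    if start < 0 or (contig_length is not None and end > contig_length):
        return None
    return GenomicInterval(iv.chrom, start, end)


def standardize_peak(
    p: Peak, width: int = DEFAULT_PEAK_WIDTH, contig_length: int | None = None
) -> GenomicInterval | None:
    """Fixed-width window centered on the peak midpoint; None (dropped)
    when the window would leave the contig."""
    win = _centered_window(p.interval, width, contig_length)
    if win is None:
        logger.warning("peak %s out of bounds after standardization", p.interval)
    return win


def anchor_window(
    a: GenomicInterval, width: int = DEFAULT_ANCHOR_WIDTH, contig_length: int | None = None
) -> GenomicInterval | None:
    """Fixed-width window centered on the anchor midpoint."""
    win = _centered_window(a, width, contig_length)
    if win is None:
        logger.warning("anchor %s out of bounds after standardization", a)
    return win


def _window_gc(genome: GenomeSequence, ivs: Iterable[GenomicInterval]) -> float:
    seq = "".join(fetch(genome, iv) for iv in ivs)
    return gc_content(seq)


# ---------------------------------------------------------------------------
# Region-set construction
# ---------------------------------------------------------------------------

def build_interaction_sets(
    interactions: Sequence[Interaction],
    genome: GenomeSequence,
    fdr_pos: float = DEFAULT_INTERACTION_FDR_POS,
    fdr_neg: float = DEFAULT_INTERACTION_FDR_NEG,
    max_dist: int = DEFAULT_MAX_INTERACTION_DIST,
    min_pos: int = DEFAULT_MIN_POSITIVE_INTERACTIONS,
    anchor_width: int = DEFAULT_ANCHOR_WIDTH,
    gc_bin: float = DEFAULT_GC_BIN_WIDTH,
    seed: int = 0,
) -> dict[str, RegionSet]:
    """Per interaction type (PE/PP), positive and GC-matched negative
    anchor-window sets.

    Inter-chromosomal pairs and pairs with anchor-midpoint distance
    beyond ``max_dist`` are removed first.  Positives are interactions
    with FDR < fdr_pos; a type is returned only when it has more than
    ``min_pos`` of them.  Negatives are drawn from FDR > fdr_neg
    interactions, equal in number and matched on the GC content of the
    concatenated standardized anchor windows.
    """
    out: dict[str, RegionSet] = {}
    for itype in ("PE", "PP"):
        kept: list[tuple[Interaction, list[GenomicInterval]]] = []
        for inter in interactions:
            if inter.itype != itype or not inter.intra_chromosomal:
                continue
            if inter.midpoint_distance > max_dist:
                continue
            wins = []
            for a in (inter.anchor1, inter.anchor2):
                w = anchor_window(a, anchor_width, genome.contig_length(a.chrom))
                if w is not None:
                    wins.append(w)
            if len(wins) == 2:
                kept.append((inter, wins))
        pos = [(i, w) for i, w in kept if i.fdr < fdr_pos]
        if len(pos) <= min_pos:
            logger.warning(
                "%s: only %d significant interactions (need > %d); skipped",
                itype, len(pos), min_pos,
            )
            continue
        cand = [(i, w) for i, w in kept if i.fdr > fdr_neg]
        pos_gc = [_window_gc(genome, w) for _, w in pos]
        cand_gc = [_window_gc(genome, w) for _, w in cand]
        idx = binned_match_indices(pos_gc, cand_gc, gc_bin, seed)
        out[itype] = RegionSet(
            positives=[iv for _, w in pos for iv in w],
            negatives=[iv for j in idx for iv in cand[j][1]],
            label=itype,
        )
    return out


def build_peak_sets(
    peaks: Sequence[Peak],
    genome: GenomeSequence,
    fdr_pos: float = DEFAULT_PEAK_FDR,
    width: int = DEFAULT_PEAK_WIDTH,
    gc_bin: float = DEFAULT_GC_BIN_WIDTH,
    seed: int = 0,
    label: str = "peaks",
    max_attempts_per_window: int = 2000,
) -> RegionSet:
    """Significant standardized peak windows plus equally many random
    GC-matched background windows.

    Background windows are rejection-sampled genome-wide: each must fall
    in a still-deficient GC bin and overlap neither a positive window
    nor a previously accepted background window.
    """
    rng = np.random.default_rng(seed)
    positives = []
    for p in peaks:
        if p.fdr < fdr_pos:
            win = standardize_peak(p, width, genome.contig_length(p.interval.chrom))
            if win is not None:
                positives.append(win)
    if not positives:
        raise ValueError("empty positive set: no significant peaks in bounds")

    from .matching import bin_index

    need: dict[int, int] = {}
    for iv in positives:
        b = bin_index(_window_gc(genome, [iv]), gc_bin)
        need[b] = need.get(b, 0) + 1

    contigs = list(genome.contigs)
    lengths = np.array([genome.contig_length(c) for c in contigs], dtype=float)
    weights = lengths / lengths.sum()
    taken: list[GenomicInterval] = list(positives)
    negatives: list[GenomicInterval] = []
    attempts_left = max_attempts_per_window * len(positives)
    while sum(need.values()) > 0:
        if attempts_left <= 0:
            raise ValueError(
                f"could not place GC-matched background windows; "
                f"remaining bins {need}"
            )
        attempts_left -= 1
        ci = int(rng.choice(len(contigs), p=weights))
        chrom = contigs[ci]
        clen = int(lengths[ci])
        if clen < width:
            continue
        start = int(rng.integers(0, clen - width + 1))
        win = GenomicInterval(chrom, start, start + width)
        b = bin_index(_window_gc(genome, [win]), gc_bin)
        if need.get(b, 0) <= 0:
            continue
        if any(overlaps(win, t) for t in taken):
            continue
        need[b] -= 1
        taken.append(win)
        negatives.append(win)
    return RegionSet(positives=positives, negatives=negatives, label=label)


# ---------------------------------------------------------------------------
# Counting and statistics
# ---------------------------------------------------------------------------

def _hits_any(v: Variant, by_chrom: dict[str, list[GenomicInterval]]) -> bool:
    span = variant_span(v)
    return any(overlaps(span, iv) for iv in by_chrom.get(v.chrom, []))


def _index_regions(ivs: Sequence[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    d: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        d.setdefault(iv.chrom, []).append(iv)
    return d


def count_contingency(
    pos_vars: Sequence[Variant],
    neg_vars: Sequence[Variant],
    regions: RegionSet,
    exclusive: bool = False,
) -> ContingencyTable:
    """Count variant membership in positive/negative regions.

    A variant is in a region class when its reference span overlaps any
    interval of that class.  By default a variant overlapping both
    classes counts in both cells of its row; with ``exclusive`` the
    positive class wins.
    """
    pos_idx = _index_regions(regions.positives)
    neg_idx = _index_regions(regions.negatives)
    counts = [0, 0, 0, 0]  # n11, n12, n21, n22
    for row, variants in enumerate((pos_vars, neg_vars)):
        for v in variants:
            in_pos = _hits_any(v, pos_idx)
            in_neg = _hits_any(v, neg_idx)
            if exclusive and in_pos:
                in_neg = False
            if in_pos:
                counts[2 * row] += 1
            if in_neg:
                counts[2 * row + 1] += 1
    return ContingencyTable(*counts)


def odds_ratio(t: ContingencyTable) -> float:
    """(n11·n22)/(n12·n21); +inf when only the numerator is positive,
    an error when both products vanish."""
    num = t.n11 * t.n22
    den = t.n12 * t.n21
    if den == 0:
        if num == 0:
            raise ValueError("odds ratio undefined: both products are zero")
        return float("inf")
    return num / den


def fisher_one_sided(t: ContingencyTable) -> float:
    """One-sided (greater) exact p-value: probability under the
    hypergeometric null, with the observed margins, of n11 at least as
    large as observed."""
    return float(fisher_exact(t.as_array(), alternative="greater")[1])


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    odds_ratio: float
    p_value: float


def enrich_report(
    variants: Sequence[Variant],
    true_labels: Sequence[int],
    predicted_scores: Sequence[float],
    regions: RegionSet,
    threshold: float = 0.5,
) -> dict[str, EnrichmentResult]:
    """Enrichment of the same variants partitioned by true labels and by
    thresholded predictions (score > threshold → predicted positive)."""
    variants = list(variants)
    y = np.asarray(true_labels, dtype=int)
    s = np.asarray(predicted_scores, dtype=float)
    if not (len(variants) == len(y) == len(s)):
        raise ValueError("variants, labels and scores must align")
    out = {}
    for name, mask in (("true", y == 1), ("predicted", s > threshold)):
        pos = [v for v, m in zip(variants, mask) if m]
        neg = [v for v, m in zip(variants, mask) if not m]
        tab = count_contingency(pos, neg, regions)
        try:
            orr = odds_ratio(tab)
        except ValueError:
            orr = float("nan")
        out[name] = EnrichmentResult(tab, orr, fisher_one_sided(tab))
    return out
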