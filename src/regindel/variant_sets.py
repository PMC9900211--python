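"""Tissue-specific labeled sets of non-coding small indels.

Positives are cis-eQTL indels with a significant gene association
(q < 0.05), close to a TSS (< 100 kb) and shorter than 100 bp.  Negative
candidates come from the same kind of summary statistics but with weak
association (q > 0.2), must share a gene with the positive pool and must
not overlap any positive on the reference.  The final negative set is
balanced to the positives with a matched minor-allele-frequency (MAF)
histogram so that allele frequency cannot act as a shortcut feature.

All threshold comparisons are strict (<, >): boundary records (length
exactly 100, q exactly 0.05 or 0.2, TSS distance exactly 100 kb) are
excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core_io import (
    Variant,
    indel_length,
    overlaps,
    parse_variant_row,
    variant_key,
    variant_span,
)
from .matching import binned_match_indices

__all__ = [
    "EqtlRecord",
    "LabeledSet",
    "ClinvarRecord",
    "read_eqtl_records",
    "read_clinvar_records",
    "select_positives",
    "select_negative_candidates",
    "match_maf",
    "build_labeled_set",
    "select_clinvar_sindels",
    "DEFAULT_MAX_INDEL_LEN",
    "DEFAULT_MAX_TSS_DIST",
    "DEFAULT_Q_POSITIVE",
    "DEFAULT_Q_NEGATIVE",
    "DEFAULT_MAF_BIN_WIDTH",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_INDEL_LEN = 100
DEFAULT_MAX_TSS_DIST = 100_000
DEFAULT_Q_POSITIVE = 0.05
DEFAULT_Q_NEGATIVE = 0.2
DEFAULT_MAF_BIN_WIDTH = 0.05

CLINVAR_VARIANT_TYPES = frozenset({"Insertion", "Deletion", "Indel", "Duplication"})
CLINVAR_REVIEW_WHITELIST = frozenset(
    {"multiple submitters, no conflicts", "reviewed by expert panel"}
)


@dataclass(frozen=True)
class EqtlRecord:
    """One variant-gene association from an eQTL summary table."""

    variant: Variant
    gene: str
    tss_distance: int
    q_value: float
    maf: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value outside [0, 1]: {self.q_value}")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"MAF outside (0, 0.5]: {self.maf}")
        object.__setattr__(self, "tss_distance", abs(int(self.tss_distance)))

    @property
    def key(self) -> str:
        return variant_key(self.variant)


@dataclass
class LabeledSet:
    """Positive and negative eQTL records for one tissue.

    ``balanced`` is True for sets built by :func:`build_labeled_set`,
    whose negatives are MAF-matched and equal in number to the
    positives; curated clinical sets keep their natural imbalance.
    """

    tissue: str
    positives: list[EqtlRecord]
    negatives: list[EqtlRecord]
    balanced: bool = True

    def __post_init__(self) -> None:
        pos_keys = {r.key for r in self.positives}
        neg_keys = {r.key for r in self.negatives}
        shared = pos_keys & neg_keys
        if shared:
            raise ValueError(
                f"positive and negative sets share keys: {sorted(shared)[:5]}"
            )
        if self.balanced and len(self.positives) != len(self.negatives):
            raise ValueError(
                f"balanced set with {len(self.positives)} positives but "
                f"{len(self.negatives)} negatives"
            )

    @property
    def positive_keys(self) -> list[str]:
        return [r.key for r in self.positives]

    @property
    def negative_keys(self) -> list[str]:
        return [r.key for r in self.negatives]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, recs in ((1, self.positives), (0, self.negatives)):
            for r in recs:
                rows.append(
                    {
                        "variant_key": r.key,
                        "chrom": r.variant.chrom,
                        "pos": r.variant.pos,
                        "ref": r.variant.ref,
                        "alt": r.variant.alt,
                        "gene": r.gene,
                        "tss_distance": r.tss_distance,
                        "q_value": r.q_value,
                        "maf": r.maf,
                        "label": label,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClinvarRecord:
    variant: Variant
    variant_type: str
    clinical_significance: str
    review_status: str


def read_eqtl_records(path: str | Path, *, one_based: bool = False) -> list[EqtlRecord]:
    """Read an eQTL summary TSV (chrom, pos, ref, alt, gene, tss_distance,
    q_value, maf) into records."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    required = ["chrom", "pos", "ref", "alt", "gene", "tss_distance", "q_value", "maf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"eQTL table {path} missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        v = parse_variant_row(row.chrom, row.pos, row.ref, row.alt, one_based=one_based)
        records.append(
            EqtlRecord(v, str(row.gene), int(row.tss_distance), float(row.q_value), float(row.maf))
        )
    return records


def read_clinvar_records(path: str | Path) -> list[ClinvarRecord]:
    """Read a ClinVar-style variant summary TSV.

    Expects the tab-delimited columns Type, ClinicalSignificance,
    ReviewStatus, Chromosome, Start, ReferenceAllele, AlternateAllele,
    with 1-based Start positions.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [
        "Type",
        "ClinicalSignificance",
        "ReviewStatus",
        "Chromosome",
        "Start",
        "ReferenceAllele",
        "AlternateAllele",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ClinVar table {path} missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        v = parse_variant_row(
            row.Chromosome, int(row.Start), row.ReferenceAllele,
            row.AlternateAllele, one_based=True,
        )
        records.append(
            ClinvarRecord(v, str(row.Type), str(row.ClinicalSignificance), str(row.ReviewStatus))
        )
    return records


def _dedupe_min_q(records: list[EqtlRecord]) -> dict[str, EqtlRecord]:
    """Collapse multi-gene associations: per variant keep the minimum-q
    record, so a variant counts once no matter how many genes it hits."""
    best: dict[str, EqtlRecord] = {}
    for r in records:
        k = r.key
        if k not in best or r.q_value < best[k].q_value:
            best[k] = r
    return best


def select_positives(
    records: list[EqtlRecord],
    max_len: int = DEFAULT_MAX_INDEL_LEN,
    max_tss: int = DEFAULT_MAX_TSS_DIST,
    q_max: float = DEFAULT_Q_POSITIVE,
) -> list[EqtlRecord]:
    """Positive-set filter: indel length < max_len, |TSS distance| <
    max_tss and minimum q across associated genes < q_max."""
    out = []
    for rec in _dedupe_min_q(records).values():
        if indel_length(rec.variant) == 0:
            continue
        if (
            indel_length(rec.variant) < max_len
            and rec.tss_distance < max_tss
            and rec.q_value < q_max
        ):
            out.append(rec)
    return out


def select_negative_candidates(
    records: list[EqtlRecord],
    positives: list[EqtlRecord],
    max_len: int = DEFAULT_MAX_INDEL_LEN,
    max_tss: int = DEFAULT_MAX_TSS_DIST,
    q_min: float = DEFAULT_Q_NEGATIVE,
) -> list[EqtlRecord]:
    """Negative-candidate filter.

    A candidate must be a short indel near a TSS like the positives,
    have minimum q across its genes > q_min, be associated with at least
    one gene of the positive pool, and its reference span must not
    overlap the span of any positive.
    """
    pos_genes = {p.gene for p in positives}
    pos_keys = {p.key for p in positives}
    pos_spans: dict[str, list] = {}
    for p in positives:
        pos_spans.setdefault(p.variant.chrom, []).append(variant_span(p.variant))

    # per-variant minimum q over all its gene associations
    min_q: dict[str, float] = {}
    for r in records:
        k = r.key
        min_q[k] = min(min_q.get(k, 1.0), r.q_value)

    out = []
    seen: set[str] = set()
    for rec in records:
        k = rec.key
        if k in seen or k in pos_keys:
            continue
        if indel_length(rec.variant) == 0:
            continue
        if not (
            indel_length(rec.variant) < max_len
            and rec.tss_distance < max_tss
            and min_q[k] > q_min
            and rec.gene in pos_genes
        ):
            continue
        span = variant_span(rec.variant)
        if any(overlaps(span, s) for s in pos_spans.get(rec.variant.chrom, [])):
            continue
        seen.add(k)
        out.append(rec)
    return out


def match_maf(
    candidates: list[EqtlRecord],
    positives: list[EqtlRecord],
    bin_width: float = DEFAULT_MAF_BIN_WIDTH,
    seed: int = 0,
) -> list[EqtlRecord]:
    """Sample a negative set whose MAF histogram equals the positives'.

    Per MAF bin of the configured width, exactly as many candidates are
    drawn (uniformly, without replacement) as there are positives in the
    bin; raises :class:`~regindel.matching.DeficientBinsError` naming
    the short bins otherwise.
    """
    if not positives:
        raise ValueError("empty positive set")
    if not candidates:
        raise ValueError("empty candidate set")
    idx = binned_match_indices(
        [p.maf for p in positives], [c.maf for c in candidates], bin_width, seed
    )
    return [candidates[i] for i in idx]


def build_labeled_set(
    tissue: str,
    pos_records: list[EqtlRecord],
    neg_records: list[EqtlRecord],
    bin_width: float = DEFAULT_MAF_BIN_WIDTH,
    seed: int = 0,
    max_len: int = DEFAULT_MAX_INDEL_LEN,
    max_tss: int = DEFAULT_MAX_TSS_DIST,
    q_max: float = DEFAULT_Q_POSITIVE,
    q_min: float = DEFAULT_Q_NEGATIVE,
) -> LabeledSet:
    """Full labeling pipeline for one tissue: select positives, filter
    negative candidates, MAF-match to a balanced negative set."""
    positives = select_positives(pos_records, max_len=max_len, max_tss=max_tss, q_max=q_max)
    if not positives:
        raise ValueError("empty positive set")
    candidates = select_negative_candidates(
        neg_records, positives, max_len=max_len, max_tss=max_tss, q_min=q_min
    )
    negatives = match_maf(candidates, positives, bin_width=bin_width, seed=seed)
    logger.info(
        "tissue %s: %d positives, %d candidates, %d matched negatives",
        tissue, len(positives), len(candidates), len(negatives),
    )
    return LabeledSet(tissue, positives, negatives, balanced=True)


def select_clinvar_sindels(
    records: list[ClinvarRecord],
    max_len: int = DEFAULT_MAX_INDEL_LEN,
    tissue: str = "clinvar",
) -> LabeledSet:
    """Pathogenic-vs-benign indel set from a curated clinical table.

    Positives have clinical significance exactly "Pathogenic", negatives
    exactly "Benign"; both restricted to the indel variant types, length
    < max_len and a high-confidence review status.  No balancing.
    """
    pos, neg = [], []
    for rec in records:
        if rec.variant_type not in CLINVAR_VARIANT_TYPES:
            continue
        if rec.review_status not in CLINVAR_REVIEW_WHITELIST:
            continue
        if indel_length(rec.variant) == 0 or indel_length(rec.variant) >= max_len:
            continue
        q = EqtlRecord(rec.variant, gene="NA", tss_distance=0, q_value=0.5, maf=0.25)
        if rec.clinical_significance == "Pathogenic":
            pos.append(q)
        elif rec.clinical_significance == "Benign":
            neg.append(q)
    if not pos:
        logger.warning("clinvar selection produced an empty pathogenic class")
    if not neg:
        logger.warning("clinvar selection produced an empty benign class")
    return LabeledSet(tissue, pos, neg, balanced=False)
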