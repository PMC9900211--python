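"""Synthetic study generator.

Emits every input the pipeline consumes — genome FASTA, eQTL summary
tables with planted labels, a generic-annotation matrix, peak and
interaction tables — with controlled effect sizes, so the whole pipeline
is testable end to end without any external download.

Signal structure
----------------
* labels: positives carry q ~ U(0, 0.05), negative candidates
  q ~ U(0.2, 1); both share a gene pool, TSS distances ~ U(0, 100 kb)
  and a common truncated-Beta MAF law so MAF matching succeeds.
* annotations: ``n_informative_annots`` of the 45 columns are shifted by
  ``annot_effect`` standard deviations for positives.  Three designated
  columns get 2% missing entries (kept and imputed downstream) and one
  gets 12% (always removed by the <10% filter).
* sequence signal: a planted k-mer ("motif") receives extra weight on
  every track of the synthetic profile predictor.  Positive indels are
  placed inside tandem repeats of that motif so that applying the
  alternative allele destroys motif copies; negative indels are placed
  at motif-free edit sites.  At ``profile_effect > 0`` the ref/alt
  profile difference is therefore label-informative.
* regions: the genome is tiled with disjoint 2-kb slots.  Positive
  variants land in "regulatory" slots with probability OR/(1+OR) and in
  "background" slots otherwise; negative variants split 50/50, which
  realizes a planted odds ratio of ``region_or``.  Regulatory slots are
  emitted as significant (FDR < 0.1) interaction anchors, background
  slots as non-significant (FDR > 0.5) anchors; decoy inter-chromosomal
  and over-distance interactions exercise the pipeline filters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import GenomeSequence, GenomicInterval, Variant, variant_key, write_fasta
from .enrichment import Interaction, Peak
from .features import ProfilePredictor, make_synthetic_predictor
from .variant_sets import EqtlRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "Placement",
    "simulate_genome",
    "simulate_eqtl_study",
    "simulate_annotations",
    "plant_profile_signal",
    "simulate_regions",
    "simulate_study",
    "write_study",
]

_BASES = np.array(list("ACGT"))
SLOT_WIDTH = 2000
_EDGE_SLOTS = 2  # slots skipped at each contig edge (window head-room)


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the study conditions
    used throughout the test suite and the reproduction script."""

    genome_length: int = 10_000_000
    n_contigs: int = 2
    gc_target: float = 0.41
    n_pos: int = 1000
    n_neg_candidates: int = 4000
    n_decoys: int = 50
    n_multi_gene: int = 20
    n_genes: int = 300
    n_annots: int = 45
    n_informative_annots: int = 10
    annot_effect: float = 1.0
    profile_effect: float = 1.0
    maf_law: tuple[float, float] = (2.0, 5.0)
    region_or: float = 3.0
    n_pos_regions: int = 500
    n_neg_candidate_regions: int = 750
    n_pp_pos: int = 120
    n_pp_neg: int = 240
    n_decoy_interactions: int = 100
    n_sig_peaks: int = 100
    n_nonsig_peaks: int = 100
    n_tracks: int = 919
    kmer: int = 6
    window: int = 1000
    max_indel_diff: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_target <= 1.0):
            raise ValueError("gc_target must be in [0, 1]")
        if self.region_or < 1.0:
            raise ValueError("region_or must be >= 1")
        if self.genome_length < 10 * self.window:
            raise ValueError("genome too short for the window length")


@dataclass(frozen=True)
class Placement:
    """A planned indel before its alleles are read off the genome."""

    chrom: str
    pos: int
    diff: int  # allele-length difference, >= 1
    insertion: bool
    label: int  # 1 planted positive, 0 otherwise
    slot_class: str  # "regulatory" | "background" | "none"


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for auditing."""

    positive_keys: list[str] = field(default_factory=list)
    candidate_keys: list[str] = field(default_factory=list)
    informative_annots: list[str] = field(default_factory=list)
    dropped_annot: str | None = None
    motif: str | None = None
    predictor_seed: int = 0
    regulatory_slots: list[tuple[str, int]] = field(default_factory=list)
    background_slots: list[tuple[str, int]] = field(default_factory=list)
    membership: dict[str, str] = field(default_factory=dict)
    maf_histogram: dict[int, int] = field(default_factory=dict)


@dataclass
class SimStudy:
    cfg: SimConfig
    genome: GenomeSequence
    pos_records: list[EqtlRecord]
    neg_records: list[EqtlRecord]
    annotations: pd.DataFrame
    peaks: list[Peak]
    interactions: list[Interaction]
    truth: SimTruth

    def make_predictor(self) -> ProfilePredictor:
        strength = 20.0 * self.cfg.profile_effect
        return make_synthetic_predictor(
            self.cfg.n_tracks,
            self.cfg.kmer,
            seed=self.truth.predictor_seed,
            window=self.cfg.window,
            motif=self.truth.motif,
            motif_strength=strength,
        )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenomeSequence:
    """i.i.d. genome with P(G) + P(C) = gc_target, split over contigs."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    per = cfg.genome_length // cfg.n_contigs
    g = cfg.gc_target / 2.0
    at = (1.0 - cfg.gc_target) / 2.0
    p = [at, g, g, at]  # A, C, G, T
    contigs = {}
    for i in range(cfg.n_contigs):
        draws = rng.choice(4, size=per, p=p)
        contigs[f"chr{i + 1}"] = "".join(_BASES[draws])
    return GenomeSequence(contigs)


# ---------------------------------------------------------------------------
# Slot grid
# ---------------------------------------------------------------------------

def _slot_grid(genome: GenomeSequence) -> list[tuple[str, int]]:
    slots = []
    for chrom, seq in genome.contigs.items():
        n = len(seq) // SLOT_WIDTH
        for i in range(_EDGE_SLOTS, n - _EDGE_SLOTS):
            slots.append((chrom, i * SLOT_WIDTH))
    return slots


def slot_interval(slot: tuple[str, int]) -> GenomicInterval:
    chrom, start = slot
    return GenomicInterval(chrom, start, start + SLOT_WIDTH)


# ---------------------------------------------------------------------------
# eQTL study
# ---------------------------------------------------------------------------

def _draw_maf(rng: np.random.Generator, law: tuple[float, float]) -> float:
    while True:
        m = float(rng.beta(*law))
        if 1e-6 < m <= 0.5:
            return m


def _place_in_slot(
    rng: np.random.Generator,
    slot: tuple[str, int],
    occupied: dict[tuple[str, int], list[int]],
    min_gap: int = 100,
) -> int | None:
    chrom, start = slot
    for _ in range(30):
        pos = start + int(rng.integers(40, SLOT_WIDTH - 60))
        if all(abs(pos - q) >= min_gap for q in occupied.get(slot, [])):
            occupied.setdefault(slot, []).append(pos)
            return pos
    return None


def simulate_eqtl_study(
    cfg: SimConfig, genome: GenomeSequence, rng: np.random.Generator | None = None
) -> tuple[list[EqtlRecord], list[EqtlRecord], GenomeSequence, SimTruth]:
    """Plan and emit the labeled study.

    Returns (positive-source records, negative-source records, the
    possibly motif-edited genome, truth).  Variant alleles are read off
    the genome only after :func:`plant_profile_signal` has edited it, so
    reference alleles always match the emitted FASTA.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = SimTruth()
    slots = _slot_grid(genome)
    order = rng.permutation(len(slots))
    cursor = 0

    def take_slots(n: int) -> list[tuple[str, int]]:
        nonlocal cursor
        if cursor + n > len(order):
            raise ValueError("genome too short: slot grid exhausted")
        out = [slots[i] for i in order[cursor : cursor + n]]
        cursor += n
        return out

    reg_slots = take_slots(cfg.n_pos_regions)
    bg_slots = take_slots(cfg.n_neg_candidate_regions)
    truth.regulatory_slots = reg_slots
    truth.background_slots = bg_slots
    # remaining permuted slots are handed to simulate_regions for
    # partner anchors, decoys and peaks
    truth._free_slots = [slots[i] for i in order[cursor:]]  # type: ignore[attr-defined]

    p_reg_pos = cfg.region_or / (1.0 + cfg.region_or)
    p_reg_neg = 0.5
    occupied: dict[tuple[str, int], list[int]] = {}

    def plan(n: int, label: int, p_reg: float) -> list[Placement]:
        # exact-count membership (round(n * p_reg) regulatory, shuffled)
        # rather than independent Bernoulli draws: the realized odds match
        # the target without binomial noise on top of the sampling noise
        flags = np.zeros(n, dtype=bool)
        flags[: int(round(n * p_reg))] = True
        rng.shuffle(flags)
        out = []
        while len(out) < n:
            in_reg = bool(flags[len(out)])
            pool = reg_slots if in_reg else bg_slots
            slot = pool[int(rng.integers(len(pool)))]
            pos = _place_in_slot(rng, slot, occupied)
            if pos is None:
                continue
            out.append(
                Placement(
                    chrom=slot[0],
                    pos=pos,
                    diff=int(rng.integers(1, cfg.max_indel_diff + 1)),
                    insertion=bool(rng.random() < 0.5),
                    label=label,
                    slot_class="regulatory" if in_reg else "background",
                )
            )
        return out

    pos_place = plan(cfg.n_pos, 1, p_reg_pos)
    cand_place = plan(cfg.n_neg_candidates, 0, p_reg_neg)
    decoy_place = plan(cfg.n_decoys, 0, p_reg_neg)

    genome, motif = plant_profile_signal(
        cfg, genome, pos_place + cand_place + decoy_place, rng
    )
    truth.motif = motif
    truth.predictor_seed = int(rng.integers(0, 2**31 - 1))

    genes = [f"g{i:03d}" for i in range(cfg.n_genes)]

    def realize(pl: Placement) -> Variant:
        seq = genome.contigs[pl.chrom]
        if pl.insertion:
            ref = seq[pl.pos]
            ins = "".join(_BASES[rng.integers(0, 4, size=pl.diff)])
            alt = ref + ins
        else:
            ref = seq[pl.pos : pl.pos + pl.diff + 1]
            alt = ref[0]
        return Variant(pl.chrom, pl.pos, ref, alt)

    pos_records: list[EqtlRecord] = []
    pos_genes: list[str] = []
    for pl in pos_place:
        v = realize(pl)
        gene = genes[int(rng.integers(len(genes)))]
        rec = EqtlRecord(
            v,
            gene=gene,
            tss_distance=int(rng.integers(0, 100_000)),
            q_value=float(rng.uniform(0.0, 0.05)),
            maf=_draw_maf(rng, cfg.maf_law),
        )
        pos_records.append(rec)
        pos_genes.append(gene)
        truth.positive_keys.append(rec.key)
        truth.membership[rec.key] = pl.slot_class

    # duplicate-variant rows with a second gene: the selector must
    # still count each variant once
    multi = []
    for rec in pos_records[: cfg.n_multi_gene]:
        other = genes[int(rng.integers(len(genes)))]
        multi.append(
            EqtlRecord(
                rec.variant,
                gene=other,
                tss_distance=rec.tss_distance,
                q_value=float(rng.uniform(rec.q_value, 0.05)),
                maf=rec.maf,
            )
        )

    # decoys violate the TSS-distance criterion and must be filtered out
    decoys = []
    for pl in decoy_place:
        v = realize(pl)
        decoys.append(
            EqtlRecord(
                v,
                gene=genes[int(rng.integers(len(genes)))],
                tss_distance=int(rng.integers(100_001, 200_000)),
                q_value=float(rng.uniform(0.0, 0.05)),
                maf=_draw_maf(rng, cfg.maf_law),
            )
        )

    gene_pool = sorted(set(pos_genes))
    neg_records: list[EqtlRecord] = []
    for pl in cand_place:
        v = realize(pl)
        rec = EqtlRecord(
            v,
            gene=gene_pool[int(rng.integers(len(gene_pool)))],
            tss_distance=int(rng.integers(0, 100_000)),
            q_value=float(rng.uniform(0.2, 1.0)),
            maf=_draw_maf(rng, cfg.maf_law),
        )
        neg_records.append(rec)
        truth.candidate_keys.append(rec.key)
        truth.membership[rec.key] = pl.slot_class

    from .matching import bin_index

    for rec in pos_records:
        b = bin_index(rec.maf, 0.05)
        truth.maf_histogram[b] = truth.maf_histogram.get(b, 0) + 1

    return pos_records + multi + decoys, neg_records, genome, truth


# ---------------------------------------------------------------------------
# Profile signal
# ---------------------------------------------------------------------------

def plant_profile_signal(
    cfg: SimConfig,
    genome: GenomeSequence,
    placements: list[Placement],
    rng: np.random.Generator | None = None,
) -> tuple[GenomeSequence, str | None]:
    """Edit the genome so ref/alt profile differences become
    label-informative, and return the planted motif.

    Around each positive indel the reference is overwritten with tandem
    copies of a random k-mer (the motif); applying the alternative
    allele then breaks copies, so any predictor that up-weights the
    motif separates positives from negatives through its ref−alt
    difference.  Around non-positive edit sites motif occurrences are
    scrubbed.  With ``profile_effect == 0`` the genome is untouched.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if cfg.profile_effect == 0.0:
        return genome, None
    k = cfg.kmer
    # motif composition is constrained to the genome's GC target so the
    # planted tandem repeats do not skew anchor GC and confound GC matching
    while True:
        motif = "".join(_BASES[rng.integers(0, 4, size=k)])
        if abs((motif.count("G") + motif.count("C")) / k - cfg.gc_target) <= 0.13:
            break
    arrays = {c: bytearray(s, "ascii") for c, s in genome.contigs.items()}
    # a short pad keeps the embedded copy count low: the per-track logistic
    # stays in its responsive range, so destroying the junction copy moves
    # the score appreciably instead of sliding along a saturated tail
    pad = max(2, k - 2)
    for pl in placements:
        arr = arrays[pl.chrom]
        span = pl.diff + 1 if not pl.insertion else 1
        if pl.label == 1:
            start = pl.pos - pad
            end = pl.pos + span + pad
            tandem = (motif * ((end - start) // k + 1))[: end - start]
            arr[start:end] = tandem.encode("ascii")
        else:
            lo = max(0, pl.pos - (k + 12))
            hi = min(len(arr), pl.pos + span + k + 12)
            region = arr[lo:hi].decode("ascii")
            guard = 0
            while motif in region and guard < 50:
                i = region.index(motif)
                repl = "".join(_BASES[rng.integers(0, 4, size=k)])
                region = region[:i] + repl + region[i + k :]
                guard += 1
            arr[lo:hi] = region.encode("ascii")
    contigs = {c: a.decode("ascii") for c, a in arrays.items()}
    return GenomeSequence(contigs), motif


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    cfg: SimConfig,
    keys: list[str],
    labels: np.ndarray,
    rng: np.random.Generator | None = None,
    truth: SimTruth | None = None,
) -> pd.DataFrame:
    """Generic-annotation matrix with planted mean shifts and controlled
    missingness (three 2%-missing columns kept by the filter, one
    12%-missing column always removed)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    labels = np.asarray(labels, dtype=int)
    n = len(keys)
    cols = [f"anno{i:02d}" for i in range(1, cfg.n_annots + 1)]
    order = rng.permutation(cfg.n_annots)
    informative = [cols[i] for i in order[: cfg.n_informative_annots]]
    rest = [cols[i] for i in order[cfg.n_informative_annots :]]
    missing_2pct = rest[:3]
    missing_12pct = rest[3]

    data = rng.normal(0.0, 1.0, size=(n, cfg.n_annots))
    df = pd.DataFrame(data, index=pd.Index(keys, name="variant_key"), columns=cols)
    for c in informative:
        df.loc[labels == 1, c] += cfg.annot_effect
    for c in missing_2pct:
        hide = rng.choice(n, size=max(1, int(np.ceil(0.02 * n))), replace=False)
        df.iloc[hide, df.columns.get_loc(c)] = np.nan
    hide = rng.choice(n, size=int(np.ceil(0.12 * n)), replace=False)
    df.iloc[hide, df.columns.get_loc(missing_12pct)] = np.nan

    if truth is not None:
        truth.informative_annots = informative
        truth.dropped_annot = missing_12pct
    return df


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def simulate_regions(
    cfg: SimConfig,
    genome: GenomeSequence,
    truth: SimTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[Peak], list[Interaction]]:
    """Emit interaction and peak tables consistent with the planted
    variant memberships.

    Regulatory slots become anchors of significant (FDR < 0.1) PE
    interactions, background slots anchors of weak (FDR > 0.5) ones;
    partner anchors sit in variant-free slots within 1 Mb.  Decoy
    inter-chromosomal and over-distance interactions plus a PP set and
    significant/non-significant peaks round out the tables.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    free: list[tuple[str, int]] = list(getattr(truth, "_free_slots", []))
    if not free:
        raise ValueError("truth carries no free slots; run simulate_eqtl_study first")
    free_by_chrom: dict[str, list[int]] = {}
    for chrom, start in free:
        free_by_chrom.setdefault(chrom, []).append(start)
    for lst in free_by_chrom.values():
        lst.sort()

    def pop_partner(chrom: str, start: int) -> tuple[str, int]:
        pool = free_by_chrom.get(chrom, [])
        near = [s for s in pool if abs((s + SLOT_WIDTH // 2) - (start + SLOT_WIDTH // 2)) <= 990_000]
        if not near:
            raise ValueError("no free partner slot within distance bound")
        s = near[int(rng.integers(len(near)))]
        pool.remove(s)
        return (chrom, s)

    def pop_any() -> tuple[str, int]:
        chroms = [c for c, lst in free_by_chrom.items() if lst]
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = free_by_chrom[chrom].pop(int(rng.integers(len(free_by_chrom[chrom]))))
        return (chrom, s)

    def anchor(slot: tuple[str, int], narrow: bool) -> GenomicInterval:
        chrom, start = slot
        mid = start + SLOT_WIDTH // 2
        if narrow:
            half = int(rng.integers(25, 251))
            return GenomicInterval(chrom, mid - half, mid + half)
        return GenomicInterval(chrom, start, start + SLOT_WIDTH)

    interactions: list[Interaction] = []

    def emit(slot_a, slot_b, fdr, itype):
        interactions.append(
            Interaction(
                anchor(slot_a, narrow=bool(rng.random() < 0.5)),
                anchor(slot_b, narrow=bool(rng.random() < 0.5)),
                fdr,
                itype,
            )
        )

    for slot in truth.regulatory_slots:
        emit(slot, pop_partner(*slot), float(rng.uniform(0.0, 0.1)), "PE")
    for slot in truth.background_slots:
        emit(slot, pop_partner(*slot), float(rng.uniform(0.5, 1.0)), "PE")
    for _ in range(cfg.n_pp_pos):
        a = pop_any()
        emit(a, pop_partner(*a), float(rng.uniform(0.0, 0.1)), "PP")
    for _ in range(cfg.n_pp_neg):
        a = pop_any()
        emit(a, pop_partner(*a), float(rng.uniform(0.5, 1.0)), "PP")

    # decoys: half inter-chromosomal, half over the distance bound
    chroms = list(genome.contigs)
    for i in range(cfg.n_decoy_interactions):
        a = pop_any()
        if i % 2 == 0 and len(chroms) > 1:
            b = pop_any()
            guard = 0
            while b[0] == a[0] and guard < 20:
                free_by_chrom[b[0]].append(b[1])
                b = pop_any()
                guard += 1
            if b[0] == a[0]:
                continue
        else:
            pool = [s for s in free_by_chrom.get(a[0], []) if abs(s - a[1]) > 1_010_000]
            if not pool:
                continue
            s = pool[int(rng.integers(len(pool)))]
            free_by_chrom[a[0]].remove(s)
            b = (a[0], s)
        emit(a, b, float(rng.uniform(0.0, 0.1)), "PE")

    peaks: list[Peak] = []
    for n_peaks, lo, hi in (
        (cfg.n_sig_peaks, 0.0, 0.05),
        (cfg.n_nonsig_peaks, 0.1, 1.0),
    ):
        for _ in range(n_peaks):
            chrom, start = pop_any()
            mid = start + SLOT_WIDTH // 2
            half = int(rng.integers(150, 401))
            peaks.append(
                Peak(GenomicInterval(chrom, mid - half, mid + half), float(rng.uniform(lo, hi)))
            )
    return peaks, interactions


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimConfig) -> SimStudy:
    """Generate the full synthetic study from one seed."""
    root = np.random.SeedSequence(cfg.seed)
    rg_genome, rg_study, rg_annot, rg_region = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    genome = simulate_genome(cfg, rg_genome)
    pos_records, neg_records, genome, truth = simulate_eqtl_study(cfg, genome, rg_study)
    keys, labels = [], []
    seen = set()
    for rec, lab in [(r, 1) for r in pos_records] + [(r, 0) for r in neg_records]:
        if rec.key in seen:
            continue
        seen.add(rec.key)
        keys.append(rec.key)
        labels.append(1 if rec.key in set(truth.positive_keys) else 0)
    annotations = simulate_annotations(cfg, keys, np.array(labels), rg_annot, truth)
    peaks, interactions = simulate_regions(cfg, genome, truth, rg_region)
    return SimStudy(cfg, genome, pos_records, neg_records, annotations, peaks, interactions, truth)


def eqtl_records_to_frame(records: list[EqtlRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.variant.chrom for r in records],
            "pos": [r.variant.pos for r in records],
            "ref": [r.variant.ref for r in records],
            "alt": [r.variant.alt for r in records],
            "gene": [r.gene for r in records],
            "tss_distance": [r.tss_distance for r in records],
            "q_value": [r.q_value for r in records],
            "maf": [r.maf for r in records],
        }
    )


def write_study(study: SimStudy, outdir: str | Path) -> dict[str, Path]:
    """Write all study files (FASTA, eQTL TSVs, annotations, peaks BED,
    interactions TSV, truth JSON) and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "eqtl_pos": outdir / "eqtl_positive_source.tsv",
        "eqtl_neg": outdir / "eqtl_negative_source.tsv",
        "annotations": outdir / "annotations.tsv",
        "peaks": outdir / "peaks.bed",
        "interactions": outdir / "interactions.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(study.genome, paths["genome"])
    eqtl_records_to_frame(study.pos_records).to_csv(paths["eqtl_pos"], sep="\t", index=False)
    eqtl_records_to_frame(study.neg_records).to_csv(paths["eqtl_neg"], sep="\t", index=False)
    study.annotations.to_csv(paths["annotations"], sep="\t")
    with open(paths["peaks"], "w") as fh:
        for p in study.peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.fdr:.6g}\n"
            )
    pd.DataFrame(
        {
            "chrom1": [i.anchor1.chrom for i in study.interactions],
            "start1": [i.anchor1.start for i in study.interactions],
            "end1": [i.anchor1.end for i in study.interactions],
            "chrom2": [i.anchor2.chrom for i in study.interactions],
            "start2": [i.anchor2.start for i in study.interactions],
            "end2": [i.anchor2.end for i in study.interactions],
            "fdr": [i.fdr for i in study.interactions],
            "itype": [i.itype for i in study.interactions],
        }
    ).to_csv(paths["interactions"], sep="\t", index=False)
    truth_dict = {
        "positive_keys": study.truth.positive_keys,
        "candidate_keys": study.truth.candidate_keys,
        "informative_annots": study.truth.informative_annots,
        "dropped_annot": study.truth.dropped_annot,
        "motif": study.truth.motif,
        "predictor_seed": study.truth.predictor_seed,
        "membership": study.truth.membership,
        "maf_histogram": study.truth.maf_histogram,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_dict, fh, indent=1)
    return paths
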