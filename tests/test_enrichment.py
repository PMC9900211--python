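import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from regindel.core_io import GenomeSequence, GenomicInterval, Variant
from regindel.enrichment import (
    ContingencyTable,
    Interaction,
    Peak,
    RegionSet,
    anchor_window,
    build_interaction_sets,
    build_peak_sets,
    count_contingency,
    enrich_report,
    fisher_one_sided,
    odds_ratio,
    read_interactions,
    read_peaks,
    standardize_peak,
)
from regindel.matching import bin_index


def hypergeom_greater_oracle(t: ContingencyTable) -> float:
    """Exact one-sided p by rational enumeration over the hypergeometric
    support with the table's margins."""
    N = t.n11 + t.n12 + t.n21 + t.n22
    K = t.n11 + t.n12  # row-1 margin
    n = t.n11 + t.n21  # column-1 margin
    if N == 0:
        return 1.0
    denom = math.comb(N, n)
    total = Fraction(0)
    for x in range(max(0, n + K - N), min(K, n) + 1):
        if x >= t.n11:
            total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return float(total)


class TestStandardize:
    def test_peak_midpoint_window(self):
        p = Peak(GenomicInterval("c1", 10_000, 10_400), 0.01)
        w = standardize_peak(p, 1000, contig_length=1_000_000)
        assert (w.start, w.end) == (9_700, 10_700)

    def test_already_standard_peak_unchanged(self):
        p = Peak(GenomicInterval("c1", 9_700, 10_700), 0.01)
        w = standardize_peak(p, 1000, contig_length=1_000_000)
        assert (w.start, w.end) == (9_700, 10_700)

    def test_peak_near_edge_dropped(self):
        p = Peak(GenomicInterval("c1", 100, 700), 0.01)
        assert standardize_peak(p, 1000, contig_length=5_000) is None

    @pytest.mark.parametrize(
        "start,end,expected",
        [(5_000, 7_000, (5_000, 7_000)), (5_000, 5_002, (4_001, 6_001))],
    )
    def test_anchor_window(self, start, end, expected):
        w = anchor_window(GenomicInterval("c1", start, end), 2000, 1_000_000)
        assert (w.start, w.end) == expected

    def test_anchor_at_contig_edge_dropped(self):
        assert anchor_window(GenomicInterval("c1", 0, 10), 2000, 5_000) is None


class TestOddsRatio:
    def test_closed_form(self):
        assert odds_ratio(ContingencyTable(10, 5, 5, 10)) == 4.0

    def test_zero_numerator(self):
        assert odds_ratio(ContingencyTable(0, 5, 5, 10)) == 0.0

    def test_infinite_when_denominator_vanishes(self):
        assert odds_ratio(ContingencyTable(3, 0, 5, 10)) == float("inf")

    def test_undefined_when_both_products_zero(self):
        with pytest.raises(ValueError):
            odds_ratio(ContingencyTable(0, 0, 0, 0))

    @pytest.mark.parametrize("k", [1, 2, 7])
    def test_scale_invariance(self, k):
        assert odds_ratio(ContingencyTable(10 * k, 5 * k, 5 * k, 10 * k)) == 4.0


class TestFisher:
    def test_hand_enumerated_example(self):
        # margins N=8, K=4, n=4: P(X >= 3) = (16 + 1) / 70
        assert fisher_one_sided(ContingencyTable(3, 1, 1, 3)) == pytest.approx(17 / 70)

    def test_degenerate_all_zero(self):
        assert fisher_one_sided(ContingencyTable(0, 0, 0, 0)) == 1.0

    def test_matches_enumeration_oracle_small_sweep(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            t = ContingencyTable(a, b, c, d)
            assert fisher_one_sided(t) == pytest.approx(
                hypergeom_greater_oracle(t), abs=1e-11
            )


GENOME_LEN = 400_000


@pytest.fixture(scope="module")
def gc_genome() -> GenomeSequence:
    rng = np.random.default_rng(99)
    bases = np.array(list("ACGT"))
    return GenomeSequence(
        {
            "chr1": "".join(bases[rng.integers(0, 4, GENOME_LEN)]),
            "chr2": "".join(bases[rng.integers(0, 4, GENOME_LEN)]),
        }
    )


def _interactions(rng, n_pos=40, n_neg=80, chrom="chr1"):
    out = []
    for i in range(n_pos + n_neg):
        s1 = 4_000 + i * 4_000
        s2 = s1 + 40_000
        fdr = rng.uniform(0, 0.1) if i < n_pos else rng.uniform(0.5, 1.0)
        out.append(
            Interaction(
                GenomicInterval(chrom, s1, s1 + 2_000),
                GenomicInterval(chrom, s2, s2 + 2_000),
                float(fdr),
                "PE",
            )
        )
    return out


class TestBuildInteractionSets:
    def test_filters_and_matched_negatives(self, gc_genome):
        rng = np.random.default_rng(4)
        inter = _interactions(rng)
        # decoys: inter-chromosomal and beyond the distance bound
        inter.append(
            Interaction(
                GenomicInterval("chr1", 10_000, 12_000),
                GenomicInterval("chr2", 10_000, 12_000),
                0.01,
                "PE",
            )
        )
        inter.append(
            Interaction(
                GenomicInterval("chr1", 4_000, 6_000),
                GenomicInterval("chr1", 300_000, 302_000),  # 296 kb apart
                0.01,
                "PE",
            )
        )
        sets = build_interaction_sets(
            inter, gc_genome, min_pos=10, max_dist=100_000, seed=0
        )
        rs = sets["PE"]
        assert len(rs.positives) == 2 * 40  # two anchor windows each
        assert len(rs.negatives) == len(rs.positives)
        # decoy anchors must not appear
        assert all(iv.end - iv.start == 2_000 for iv in rs.positives)
        assert all(iv.start < 290_000 for iv in rs.positives)

    def test_min_pos_excludes_sparse_type(self, gc_genome):
        rng = np.random.default_rng(4)
        inter = _interactions(rng, n_pos=5, n_neg=30)
        sets = build_interaction_sets(inter, gc_genome, min_pos=10, seed=0)
        assert sets == {}

    def test_gc_histograms_match(self, gc_genome):
        from regindel.enrichment import _window_gc

        rng = np.random.default_rng(4)
        sets = build_interaction_sets(
            _interactions(rng), gc_genome, min_pos=10, gc_bin=0.05, seed=0
        )
        rs = sets["PE"]
        pairs = lambda ivs: [ivs[i : i + 2] for i in range(0, len(ivs), 2)]
        hp = sorted(
            bin_index(_window_gc(gc_genome, p), 0.05) for p in pairs(rs.positives)
        )
        hn = sorted(
            bin_index(_window_gc(gc_genome, p), 0.05) for p in pairs(rs.negatives)
        )
        assert hp == hn


class TestBuildPeakSets:
    def _peaks(self, rng, n_sig=20, n_other=10):
        out = []
        for i in range(n_sig + n_other):
            s = 10_000 + i * 8_000
            fdr = rng.uniform(0, 0.05) if i < n_sig else rng.uniform(0.1, 1)
            out.append(Peak(GenomicInterval("chr1", s, s + 600), float(fdr)))
        return out

    def test_counts_disjointness_and_determinism(self, gc_genome):
        rng = np.random.default_rng(1)
        peaks = self._peaks(rng)
        rs = build_peak_sets(peaks, gc_genome, seed=7)
        assert len(rs.positives) == 20
        assert len(rs.negatives) == 20
        from regindel.core_io import overlaps

        for neg in rs.negatives:
            assert not any(overlaps(neg, p) for p in rs.positives)
        again = build_peak_sets(peaks, gc_genome, seed=7)
        assert again.negatives == rs.negatives

    def test_gc_histogram_matched(self, gc_genome):
        from regindel.enrichment import _window_gc

        rng = np.random.default_rng(1)
        rs = build_peak_sets(self._peaks(rng), gc_genome, gc_bin=0.05, seed=7)
        hp = sorted(bin_index(_window_gc(gc_genome, [iv]), 0.05) for iv in rs.positives)
        hn = sorted(bin_index(_window_gc(gc_genome, [iv]), 0.05) for iv in rs.negatives)
        assert hp == hn

    def test_no_significant_peaks_is_error(self, gc_genome):
        peaks = [Peak(GenomicInterval("chr1", 10_000, 10_600), 0.5)]
        with pytest.raises(ValueError, match="empty positive"):
            build_peak_sets(peaks, gc_genome, seed=0)


class TestCountContingency:
    REGIONS = RegionSet(
        positives=[GenomicInterval("c1", 100, 200)],
        negatives=[GenomicInterval("c1", 300, 400)],
    )

    def test_single_hit(self):
        t = count_contingency([Variant("c1", 150, "AC", "A")], [], self.REGIONS)
        assert (t.n11, t.n12, t.n21, t.n22) == (1, 0, 0, 0)

    def test_half_open_boundary_not_counted(self):
        # span [200, 202) touches the window end which is exclusive
        t = count_contingency([Variant("c1", 200, "AC", "A")], [], self.REGIONS)
        assert t.n11 == 0

    def test_variant_spanning_into_window_counted(self):
        # deletion starting at 95 spans [95, 101) and overlaps [100, 200)
        t = count_contingency([Variant("c1", 95, "ACGTGA", "A")], [], self.REGIONS)
        assert t.n11 == 1

    def test_second_anchor_hit_counts(self):
        regions = RegionSet(
            positives=[
                GenomicInterval("c1", 100, 200),  # anchor1
                GenomicInterval("c1", 5_000, 5_100),  # anchor2
            ],
            negatives=[],
        )
        t = count_contingency([Variant("c1", 5_050, "A", "AT")], [], regions)
        assert t.n11 == 1

    def test_double_hit_counts_both_unless_exclusive(self):
        regions = RegionSet(
            positives=[GenomicInterval("c1", 100, 200)],
            negatives=[GenomicInterval("c1", 150, 250)],
        )
        v = [Variant("c1", 160, "AC", "A")]
        t = count_contingency(v, [], regions)
        assert (t.n11, t.n12) == (1, 1)
        t = count_contingency(v, [], regions, exclusive=True)
        assert (t.n11, t.n12) == (1, 0)

    def test_row_conservation(self):
        rng = np.random.default_rng(3)
        regions = RegionSet(
            positives=[GenomicInterval("c1", i * 1000, i * 1000 + 300) for i in range(10)],
            negatives=[GenomicInterval("c1", i * 1000 + 500, i * 1000 + 800) for i in range(10)],
        )
        pos = [Variant("c1", int(rng.integers(0, 10_000)), "AC", "A") for _ in range(50)]
        neg = [Variant("c1", int(rng.integers(0, 10_000)), "AC", "A") for _ in range(50)]
        t = count_contingency(pos, neg, regions)
        in_any = lambda vs: sum(
            1
            for v in vs
            if any(
                iv.chrom == "c1" and v.pos < iv.end and iv.start < v.pos + 2
                for iv in regions.positives + regions.negatives
            )
        )
        assert t.n11 + t.n12 >= in_any(pos)  # double hits may exceed
        assert t.n21 + t.n22 >= in_any(neg)


class TestEnrichReport:
    REGIONS = RegionSet(
        positives=[GenomicInterval("c1", 0, 1000)],
        negatives=[GenomicInterval("c1", 2000, 3000)],
    )

    def _variants(self):
        pos = [Variant("c1", 100 + i * 50, "AC", "A") for i in range(8)]
        neg = [Variant("c1", 2100 + i * 50, "AC", "A") for i in range(8)]
        return pos + neg, [1] * 8 + [0] * 8

    def test_perfect_predictions_reproduce_true_tables(self):
        variants, labels = self._variants()
        scores = [0.9] * 8 + [0.1] * 8
        rep = enrich_report(variants, labels, scores, self.REGIONS)
        assert rep["true"].table == rep["predicted"].table
        assert rep["true"].odds_ratio == rep["predicted"].odds_ratio

    def test_all_scores_at_threshold_predict_no_positives(self):
        variants, labels = self._variants()
        rep = enrich_report(variants, labels, [0.5] * 16, self.REGIONS)
        # strict threshold: nobody is predicted positive; all 16 variants
        # land in the predicted-negative row
        assert rep["predicted"].table.n11 == 0 and rep["predicted"].table.n12 == 0
        assert rep["predicted"].table.n21 + rep["predicted"].table.n22 == 16


class TestReaders:
    def test_peaks_bed_with_and_without_header(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t100\t700\t0.01\nchr1\t900\t1500\t0.2\n")
        peaks = read_peaks(p)
        assert len(peaks) == 2 and peaks[0].fdr == 0.01
        p.write_text("chrom\tstart\tend\tfdr\nchr1\t100\t700\t0.01\n")
        assert len(read_peaks(p)) == 1

    def test_interactions_round_trip(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text(
            "chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tfdr\titype\n"
            "chr1\t100\t2100\tchr1\t50000\t52000\t0.05\tPE\n"
        )
        (i,) = read_interactions(p)
        assert i.itype == "PE" and i.midpoint_distance == 49_900
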