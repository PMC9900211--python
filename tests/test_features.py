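import numpy as np
import pandas as pd
import pytest

from regindel.core_io import GenomeSequence, Variant, variant_key
from regindel.features import (
    assemble_features,
    build_alt_window,
    decode_one_hot,
    diff_features,
    extract_ref_window,
    filter_and_impute,
    kmer_counts,
    make_synthetic_predictor,
    make_window,
    one_hot,
    read_annotation_matrix,
)


class TestFilterAndImpute:
    def test_five_percent_missing_kept_and_median_imputed(self):
        col = [float(i) for i in range(19)] + [np.nan]  # 5% missing
        m = pd.DataFrame({"a": col})
        out = filter_and_impute(m)
        assert list(out.columns) == ["a"]
        assert out["a"].iloc[-1] == np.median(col[:19])

    def test_ten_percent_missing_removed_strictly(self):
        m = pd.DataFrame(
            {"bad": [np.nan] + [1.0] * 9, "good": [1.0] * 10}
        )  # exactly 10% missing -> removed
        out = filter_and_impute(m)
        assert list(out.columns) == ["good"]

    def test_fully_observed_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        pd.testing.assert_frame_equal(filter_and_impute(m), m)

    def test_all_columns_removed_is_error(self):
        m = pd.DataFrame({"a": [np.nan, 1.0]})
        with pytest.raises(ValueError):
            filter_and_impute(m)

    def test_reader_round_trip(self, tmp_path):
        p = tmp_path / "annot.tsv"
        p.write_text("variant_key\ta\tb\nk1\t1.5\t\nk2\t2.5\t3.0\n")
        m = read_annotation_matrix(p)
        assert m.loc["k1", "a"] == 1.5
        assert np.isnan(m.loc["k1", "b"])


class TestWindows:
    GENOME = GenomeSequence({"c1": "ACGTACGTACGTACGT"})

    def test_ref_window_centers_variant(self):
        v = Variant("c1", 4, "AC", "A")
        w = extract_ref_window(self.GENOME, v, L=8)
        assert w == "ACGTACGT"
        assert w[4] == "A"

    def test_ref_window_out_of_bounds(self):
        with pytest.raises(ValueError, match="out of bounds"):
            extract_ref_window(self.GENOME, Variant("c1", 2, "GT", "G"), L=8)

    def test_deletion_pulls_downstream_bases_in(self):
        v = Variant("c1", 4, "AC", "A")
        assert build_alt_window(self.GENOME, v, L=8) == "ACGTAGTA"

    def test_insertion_shifts_and_trims_tail(self):
        v = Variant("c1", 4, "A", "ACC")
        assert build_alt_window(self.GENOME, v, L=8) == "ACGTACCC"

    def test_substitution_limit_case_differs_only_at_anchor(self):
        v = Variant("c1", 4, "A", "C")
        ref = extract_ref_window(self.GENOME, v, L=8)
        alt = build_alt_window(self.GENOME, v, L=8)
        assert alt[:4] == ref[:4] and alt[5:] == ref[5:] and alt[4] == "C"

    def test_window_invariants_over_random_indels(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, size=6000)])
        g = GenomeSequence({"chr": seq})
        L = 1000
        for _ in range(500):
            pos = int(rng.integers(L // 2, 6000 - L))
            diff = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # deletion
                ref = seq[pos : pos + diff + 1]
                alt = ref[0]
            else:  # insertion
                ref = seq[pos]
                alt = ref + "".join(bases[rng.integers(0, 4, size=diff)])
            v = Variant("chr", pos, ref, alt)
            w = make_window(g, v, L)
            assert w.length == L and len(w.alt_seq) == L
            # upstream half identical; allele placed at the anchor
            assert w.alt_seq[: L // 2] == w.ref_seq[: L // 2]
            assert w.ref_seq[L // 2 : L // 2 + len(ref)] == ref
            assert w.alt_seq[L // 2 : L // 2 + len(alt)] == alt


class TestOneHot:
    def test_stated_encoding(self):
        np.testing.assert_array_equal(
            one_hot("AG"), [[1, 0, 0, 0], [0, 1, 0, 0]]
        )
        np.testing.assert_array_equal(one_hot("T"), [[0, 0, 0, 1]])
        np.testing.assert_array_equal(one_hot("C"), [[0, 0, 1, 0]])

    def test_n_is_all_zero(self):
        np.testing.assert_array_equal(one_hot("N"), [[0, 0, 0, 0]])

    def test_illegal_character(self):
        with pytest.raises(ValueError):
            one_hot("AXG")

    def test_row_sums(self):
        m = one_hot("ACGTN")
        np.testing.assert_array_equal(m.sum(axis=1), [1, 1, 1, 1, 0])

    def test_decode_inverts(self):
        assert decode_one_hot(one_hot("ACGTN")) == "ACGTN"


class TestSyntheticPredictor:
    def test_deterministic_and_in_range(self):
        rng = np.random.default_rng(1)
        p = make_synthetic_predictor(n_tracks=50, seed=3, window=100)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            seq = "".join(bases[rng.integers(0, 4, size=100)])
            out = p.predict(seq)
            assert out.shape == (50,)
            assert ((out >= 0) & (out <= 1)).all()
            np.testing.assert_array_equal(out, p.predict(seq))

    def test_default_track_count(self):
        p = make_synthetic_predictor(seed=0, window=1000)
        seq = "ACGT" * 250
        assert p.predict(seq).shape == (919,)

    def test_single_base_change_moves_some_track(self):
        p = make_synthetic_predictor(n_tracks=50, seed=3, window=100)
        seq = "ACGT" * 25
        other = seq[:50] + "C" + seq[51:]
        assert (p.predict(seq) != p.predict(other)).any()

    def test_reversal_changes_output(self):
        p = make_synthetic_predictor(n_tracks=50, seed=3, window=100)
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        assert (p.predict(seq) != p.predict(seq[::-1])).any()

    def test_accepts_one_hot_input(self):
        p = make_synthetic_predictor(n_tracks=5, seed=0, window=12)
        seq = "ACGTACGTACGT"
        np.testing.assert_array_equal(p.predict(seq), p.predict(one_hot(seq)))

    def test_wrong_length_rejected(self):
        p = make_synthetic_predictor(n_tracks=5, seed=0, window=10)
        with pytest.raises(ValueError, match="length"):
            p.predict("ACGT")

    def test_kmer_counts_skip_n(self):
        c = kmer_counts("ACGNACG", 2)
        # AC, CG appear twice; k-mers spanning N are skipped
        assert c.sum() == 4


def _windows_and_annots(n, n_annots, L, seed=0):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    g = GenomeSequence({"c": "".join(bases[rng.integers(0, 4, size=20 * L)])})
    windows, keys = [], []
    for i in range(n):
        pos = int(L // 2 + i * 2 * L)
        ref = g.contigs["c"][pos : pos + 3]
        v = Variant("c", pos, ref, ref[0])
        windows.append(make_window(g, v, L))
        keys.append(variant_key(v))
    annots = pd.DataFrame(
        rng.normal(size=(n, n_annots)),
        index=keys,
        columns=[f"a{j}" for j in range(n_annots)],
    )
    return windows, annots


class TestAssemble:
    @pytest.mark.parametrize(
        "feature_set,n_tracks,width",
        [
            ("generic", 0, 45),
            ("generic+ref", 919, 45 + 919),
            ("generic+ref+alt", 919, 45 + 1838),
        ],
    )
    def test_widths_with_reference_track_count(self, feature_set, n_tracks, width):
        windows, annots = _windows_and_annots(3, 45, L=64)
        pred = (
            make_synthetic_predictor(n_tracks, k=3, seed=0, window=64)
            if n_tracks
            else None
        )
        fm = assemble_features(annots, windows, pred, feature_set)
        assert fm.df.shape == (3, width)
        if feature_set == "generic+ref+alt":
            assert fm.block("ref").shape[1] + fm.block("alt").shape[1] == 1838

    @pytest.mark.parametrize("n_tracks", [3, 10, 919])
    def test_total_width_property(self, n_tracks):
        windows, annots = _windows_and_annots(2, 7, L=64)
        pred = make_synthetic_predictor(n_tracks, k=3, seed=0, window=64)
        fm = assemble_features(annots, windows, pred, "generic+ref+alt")
        assert fm.df.shape[1] == 7 + 2 * n_tracks

    def test_key_mismatch_is_error(self):
        windows, annots = _windows_and_annots(3, 5, L=64)
        with pytest.raises(KeyError):
            assemble_features(annots.iloc[:2], windows, None, "generic")

    def test_missing_values_rejected(self):
        windows, annots = _windows_and_annots(3, 5, L=64)
        annots.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            assemble_features(annots, windows, None, "generic")

    def test_diff_features_width_and_zero_case(self):
        windows, annots = _windows_and_annots(3, 5, L=64)
        pred = make_synthetic_predictor(10, k=3, seed=0, window=64)
        fm = assemble_features(annots, windows, pred, "generic+ref+alt")
        d = diff_features(fm.block("ref"), fm.block("alt"))
        assert d.shape == (3, 20)
        same = diff_features(fm.block("ref"), fm.block("ref"))
        assert (same.to_numpy() == 0).all()
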