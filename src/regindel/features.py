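"""Per-variant feature construction.

Two feature families feed the classifier:

* generic annotations — a numeric variant × annotation matrix, filtered
  to columns with < 10% missing values and median-imputed;
* epigenomic profiles — for each variant a fixed-length window (default
  1000 bp) is taken around the variant on the reference, an equal-length
  alternative-allele window is built by applying the allele edit and
  re-padding from downstream reference sequence, and a multi-track
  sequence model maps each window to per-track scores in [0, 1].

With the 919-track reference configuration the profile block is
919 + 919 = 1838 columns wide and the full matrix 45 + 1838 = 1883.

The bundled predictor is a deterministic k-mer model: track scores are a
logistic transform of seeded random weights dotted with the window's
k-mer count vector.  It is a synthetic stand-in exposing the same
contract as a trained deep sequence model (fixed input length, per-track
probabilities, determinism), used for testing and simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomeSequence, Variant, variant_key

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_N_TRACKS",
    "SequenceWindow",
    "ProfilePredictor",
    "FeatureMatrix",
    "read_annotation_matrix",
    "filter_and_impute",
    "extract_ref_window",
    "build_alt_window",
    "make_window",
    "one_hot",
    "predict_profiles",
    "make_synthetic_predictor",
    "assemble_features",
    "diff_features",
]

DEFAULT_WINDOW = 1000
DEFAULT_N_TRACKS = 919
DIFF_EPSILON = 1e-6

# one-hot channel order: A, G, C, T; N maps to an all-zero row
_ONEHOT_CHANNELS = "AGCT"
_BASE_TO_CHANNEL = {"A": 0, "G": 1, "C": 2, "T": 3, "N": -1}


@dataclass(frozen=True)
class SequenceWindow:
    """Equal-length reference and alternative windows for one variant."""

    key: str
    ref_seq: str
    alt_seq: str

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError(
                f"window length mismatch for {self.key}: "
                f"{len(self.ref_seq)} vs {len(self.alt_seq)}"
            )

    @property
    def length(self) -> int:
        return len(self.ref_seq)


# ---------------------------------------------------------------------------
# Generic annotations
# ---------------------------------------------------------------------------

def read_annotation_matrix(path: str | Path) -> pd.DataFrame:
    """Annotation TSV: first column variant_key, remaining columns numeric
    with empty cells denoting missing values."""
    df = pd.read_csv(path, sep="\t")
    key_col = df.columns[0]
    df = df.set_index(key_col)
    df.index.name = "variant_key"
    return df.astype(float)


def filter_and_impute(m: pd.DataFrame, max_missing_frac: float = 0.10) -> pd.DataFrame:
    """Keep columns whose missing fraction is strictly below the threshold
    and median-impute what remains; column order is preserved."""
    if m.empty:
        raise ValueError("empty annotation matrix")
    frac = m.isna().mean(axis=0)
    keep = [c for c in m.columns if frac[c] < max_missing_frac]
    if not keep:
        raise ValueError(
            f"no annotation column has missing fraction < {max_missing_frac}"
        )
    out = m[keep].copy()
    medians = out.median(axis=0, skipna=True)
    return out.fillna(medians)


# ---------------------------------------------------------------------------
# Sequence windows
# ---------------------------------------------------------------------------

def extract_ref_window(genome: GenomeSequence, v: Variant, L: int = DEFAULT_WINDOW) -> str:
    """Reference window of length L with the variant's first ref base at
    index L/2; out-of-bounds windows are an error."""
    if L % 2:
        raise ValueError("window length must be even")
    start = v.pos - L // 2
    end = start + L
    if start < 0 or end > genome.contig_length(v.chrom):
        raise ValueError(
            f"window [{start}, {end}) out of bounds for contig {v.chrom!r}"
        )
    seq = genome.contigs[v.chrom][start:end]
    expected = genome.contigs[v.chrom][v.pos : v.pos + len(v.ref)]
    if expected != v.ref:
        raise ValueError(
            f"reference allele mismatch at {variant_key(v)}: genome has "
            f"{expected!r}"
        )
    return seq


def build_alt_window(genome: GenomeSequence, v: Variant, L: int = DEFAULT_WINDOW) -> str:
    """Alternative-allele window of the same length L.

    The upstream half is identical to the reference window; at the
    anchor the alt allele replaces the ref allele, and the downstream
    tail is refilled from reference sequence past the ref allele, then
    the whole string is truncated to L.  Deletions therefore pull extra
    downstream bases in; insertions push the tail out of the window.
    """
    if L % 2:
        raise ValueError("window length must be even")
    half = L // 2
    start = v.pos - half
    if start < 0:
        raise ValueError(f"window start {start} out of bounds")
    contig = genome.contigs[v.chrom]
    # enough downstream reference to refill after a deletion
    down_end = v.pos + len(v.ref) + (half + len(v.ref))
    if down_end > len(contig):
        raise ValueError(
            f"insufficient downstream sequence for {variant_key(v)}"
        )
    upstream = contig[start : v.pos]
    downstream = contig[v.pos + len(v.ref) : down_end]
    alt = (upstream + v.alt + downstream)[:L]
    if len(alt) != L:
        raise ValueError(f"insufficient sequence for {variant_key(v)}")
    return alt


def make_window(genome: GenomeSequence, v: Variant, L: int = DEFAULT_WINDOW) -> SequenceWindow:
    return SequenceWindow(
        variant_key(v),
        extract_ref_window(genome, v, L),
        build_alt_window(genome, v, L),
    )


def one_hot(seq: str) -> np.ndarray:
    """len(seq) × 4 one-hot encoding, channels ordered (A, G, C, T);
    N encodes as an all-zero row."""
    out = np.zeros((len(seq), 4), dtype=np.float32)
    for i, base in enumerate(seq):
        try:
            ch = _BASE_TO_CHANNEL[base]
        except KeyError:
            raise ValueError(f"illegal base {base!r} at position {i}") from None
        if ch >= 0:
            out[i, ch] = 1.0
    return out


# ---------------------------------------------------------------------------
# Profile predictor
# ---------------------------------------------------------------------------

@dataclass
class ProfilePredictor:
    """Deterministic map from a length-L window to n_tracks scores in [0, 1].

    ``fn`` receives the nucleotide string; :func:`predict_profiles`
    also accepts a one-hot matrix and decodes it first.
    """

    n_tracks: int
    window: int
    fn: Callable[[str], np.ndarray]
    name: str = "predictor"

    def predict(self, seq: str | np.ndarray) -> np.ndarray:
        if isinstance(seq, np.ndarray):
            seq = decode_one_hot(seq)
        if len(seq) != self.window:
            raise ValueError(
                f"predictor {self.name!r} expects length {self.window}, "
                f"got {len(seq)}"
            )
        out = np.asarray(self.fn(seq), dtype=np.float64)
        if out.shape != (self.n_tracks,):
            raise ValueError("predictor returned wrong number of tracks")
        return out

    def predict_batch(self, seqs: Sequence[str]) -> np.ndarray:
        return np.stack([self.predict(s) for s in seqs])


def decode_one_hot(mat: np.ndarray) -> str:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError("one-hot matrix must have shape (L, 4)")
    chars = []
    for row in mat:
        hits = np.flatnonzero(row)
        chars.append("N" if hits.size == 0 else _ONEHOT_CHANNELS[int(hits[0])])
    return "".join(chars)


def predict_profiles(p: ProfilePredictor, seq: str | np.ndarray) -> np.ndarray:
    return p.predict(seq)


def kmer_counts(seq: str, k: int) -> np.ndarray:
    """4**k k-mer count vector; k-mers containing N are skipped."""
    counts = np.zeros(4 ** k, dtype=np.float64)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    idx = 0
    valid = 0  # number of consecutive non-N bases ending here
    mask = 4 ** k
    for base in seq:
        c = code.get(base)
        if c is None:
            idx, valid = 0, 0
            continue
        idx = (idx * 4 + c) % mask
        valid += 1
        if valid >= k:
            counts[idx] += 1
    return counts


def kmer_string_to_index(kmer: str) -> int:
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    idx = 0
    for b in kmer:
        idx = idx * 4 + code[b]
    return idx


def make_synthetic_predictor(
    n_tracks: int = DEFAULT_N_TRACKS,
    k: int = 6,
    seed: int = 0,
    *,
    window: int = DEFAULT_WINDOW,
    motif: str | None = None,
    motif_strength: float = 0.0,
) -> ProfilePredictor:
    """Seeded k-mer logistic predictor.

    Track t scores sigmoid(w_t · c / sqrt(L - k + 1)) where c is the
    window's k-mer count vector and w_t are standard-normal weights
    drawn once from the seed.  Optionally one k-mer ("motif") receives
    an extra ±motif_strength weight on every track, making windows that
    gain or lose copies of that k-mer shift many tracks at once — the
    hook the simulator uses to plant sequence-level signal.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if not (1 <= k <= 8):
        raise ValueError("k must be in [1, 8]")
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, 1.0, size=(4 ** k, n_tracks))
    if motif is not None and motif_strength != 0.0:
        signs = rng.choice([-1.0, 1.0], size=n_tracks)
        W[kmer_string_to_index(motif)] += signs * motif_strength
    scale = np.sqrt(window - k + 1)

    def fn(seq: str) -> np.ndarray:
        z = kmer_counts(seq, k) @ W / scale
        return 1.0 / (1.0 + np.exp(-z))

    return ProfilePredictor(
        n_tracks=n_tracks,
        window=window,
        fn=fn,
        name=f"kmer{k}-seed{seed}" + (f"-motif{motif}" if motif else ""),
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

FeatureSet = Literal["generic", "generic+ref", "generic+ref+alt"]

FEATURE_SET_ALIASES = {
    "generic": "generic",
    "ref": "generic+ref",
    "generic+ref": "generic+ref",
    "ref_alt": "generic+ref+alt",
    "generic+ref+alt": "generic+ref+alt",
}


@dataclass
class FeatureMatrix:
    """Variants × features with named blocks (cadd:, ref:, alt:)."""

    df: pd.DataFrame
    n_generic: int
    n_tracks: int
    feature_set: str

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def keys(self) -> list[str]:
        return list(self.df.index)

    def block(self, prefix: str) -> pd.DataFrame:
        cols = [c for c in self.df.columns if c.startswith(prefix + ":")]
        return self.df[cols]

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=np.float32)


def assemble_features(
    annots: pd.DataFrame,
    windows: Sequence[SequenceWindow],
    predictor: ProfilePredictor | None,
    feature_set: str = "generic+ref+alt",
) -> FeatureMatrix:
    """Assemble the classifier input for one cohort of variants.

    Row order follows ``windows``; every window key must be present in
    the (already filtered/imputed) annotation matrix.  Column blocks
    are prefixed ``cadd:``, ``ref:`` and ``alt:``.
    """
    try:
        feature_set = FEATURE_SET_ALIASES[feature_set]
    except KeyError:
        raise ValueError(f"unknown feature set {feature_set!r}") from None
    if annots.isna().any().any():
        raise ValueError("annotation matrix contains missing values; "
                         "run filter_and_impute first")
    keys = [w.key for w in windows]
    missing = [k for k in keys if k not in annots.index]
    if missing:
        raise KeyError(f"windows without annotations: {missing[:5]}")
    generic = annots.loc[keys]
    generic.columns = [f"cadd:{c}" for c in generic.columns]

    blocks = [generic]
    n_tracks = 0
    if feature_set != "generic":
        if predictor is None:
            raise ValueError(f"feature set {feature_set!r} requires a predictor")
        n_tracks = predictor.n_tracks
        track_names = [f"t{i:04d}" for i in range(n_tracks)]
        ref_mat = predictor.predict_batch([w.ref_seq for w in windows])
        blocks.append(
            pd.DataFrame(ref_mat, index=keys, columns=[f"ref:{t}" for t in track_names])
        )
        if feature_set == "generic+ref+alt":
            alt_mat = predictor.predict_batch([w.alt_seq for w in windows])
            blocks.append(
                pd.DataFrame(alt_mat, index=keys, columns=[f"alt:{t}" for t in track_names])
            )
    df = pd.concat(blocks, axis=1)
    df.index.name = "variant_key"
    return FeatureMatrix(
        df=df,
        n_generic=generic.shape[1],
        n_tracks=n_tracks,
        feature_set=feature_set,
    )


def diff_features(
    ref_block: pd.DataFrame,
    alt_block: pd.DataFrame,
    eps: float = DIFF_EPSILON,
) -> pd.DataFrame:
    """Absolute and relative ref/alt profile differences,
    [|ref−alt| ; (ref−alt)/(ref+eps)] — the feature transform of the
    boosted-logistic-regression sequence baseline."""
    if ref_block.shape != alt_block.shape:
        raise ValueError("ref and alt blocks must align")
    r = ref_block.to_numpy(dtype=np.float64)
    a = alt_block.to_numpy(dtype=np.float64)
    absd = np.abs(r - a)
    reld = (r - a) / (r + eps)
    tracks = [c.split(":", 1)[-1] for c in ref_block.columns]
    out = pd.DataFrame(
        np.hstack([absd, reld]),
        index=ref_block.index,
        columns=[f"absdiff:{t}" for t in tracks] + [f"reldiff:{t}" for t in tracks],
    )
    return out
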