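"""Feature construction: coverage profiles and the self-standardized
k-mer composition signature.

Each contig c is represented by a row of the feature matrix

    F = [Q  H]

where Q holds the contig's coverage profile across the M samples
(pseudo-counted, normalized first across contigs per sample and then
across samples per contig, so every row of Q sums to 1), and H holds a
probabilistic k-mer signature.

The signature treats the count X_cw of a canonical k-mer class w in
contig c as a Binomial variable: under an i.i.d. nucleotide model with
per-base probabilities p_c(a) estimated from the contig itself, the
occurrence probability of the class is P_cw, so

    mu_cw    = P_cw * L(x_c)
    sigma^2  = P_cw * (1 - P_cw) * L(x_c)
    Xtilde   = (X_cw - mu_cw) / sigma_cw.

Standardizing against the contig's *own* base composition removes the
bias that the most probable k-mers would otherwise contribute to any
distance between count vectors, and makes contigs of different lengths
comparable.  Xtilde is finally normalized across contigs (column-wise)
into H.

Canonical k-mer classes pool a k-mer with its reverse complement
(contigs are sequenced from either strand); the class representative is
the lexicographically smaller of the pair, and for even k there are
V = (4^k + 4^(k/2)) / 2 classes (k=4 gives 136).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    DimensionMismatchError,
    NoInformativeBasesError,
    NoLongContigsError,
    ZeroVarianceError,
)
from .io import ContigRecord, ContigSet, CoverageMatrix

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# byte -> 2-bit code; 4 flags N (and anything else, though io rejects it)
_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _decode(code: int, k: int) -> str:
    out = []
    for j in range(k - 1, -1, -1):
        out.append(_BASES[(code >> (2 * j)) & 3])
    return "".join(out)


@lru_cache(maxsize=None)
def kmer_class_index(k: int) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Canonical class table for even k.

    Returns (representatives, class_of, palindrome) where
    ``representatives`` lists the V class labels in lexicographic order,
    ``class_of[code]`` maps every 2-bit-encoded k-mer to its class, and
    ``palindrome`` flags classes whose k-mer equals its own reverse
    complement.
    """
    if k % 2 != 0 or not (2 <= k <= 8):
        raise ValueError("k must be even and in [2, 8]")
    n = 4**k
    codes = np.arange(n, dtype=np.int64)
    # reverse complement in code space: complement each 2-bit digit (x ^ 3)
    # and reverse digit order
    rc = np.zeros(n, dtype=np.int64)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | ((tmp & 3) ^ 3)
        tmp >>= 2
    canon = np.minimum(codes, rc)
    reps = np.unique(canon)
    class_of = np.searchsorted(reps, canon)
    palindrome = reps == rc[reps]
    rep_strings = tuple(_decode(int(c), k) for c in reps)
    return rep_strings, class_of, palindrome


@dataclass
class CompositionMatrix:
    """N x V matrix of canonical k-mer class counts (possibly pseudo-counted,
    in which case entries are counts + 1)."""

    counts: np.ndarray
    k: int
    kmer_index: tuple[str, ...]

    @property
    def V(self) -> int:
        return self.counts.shape[1]


@dataclass
class NucleotideModel:
    """Per-contig base probabilities p_c(a) under the i.i.d. model."""

    probs: dict[str, float]
    smoothed: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.probs[b] for b in _BASES], dtype=float)


@dataclass
class StandardizedComposition:
    """Binomial z-scores Xtilde and their column-normalized form H."""

    zscores: np.ndarray
    normalized: np.ndarray


@dataclass
class FeatureMatrix:
    """N x (M + V) matrix F = [Q H]; coverage columns come first."""

    values: np.ndarray
    n_coverage: int
    n_composition: int

    @property
    def column_roles(self) -> tuple[int, int]:
        return (self.n_coverage, self.n_composition)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_canonical_kmers(contigs: ContigSet, k: int = 4) -> CompositionMatrix:
    """Count canonical k-mer classes per contig.

    Every window of the forward sequence contributes one count to the
    class of {w, rc(w)}; palindromic k-mers therefore count once per
    occurrence.  Windows containing N are skipped.  Contigs shorter than
    k get a zero row (with a logged warning).
    """
    reps, class_of, _ = kmer_class_index(k)
    V = len(reps)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    counts = np.zeros((contigs.N, V), dtype=np.int64)
    for c, rec in enumerate(contigs):
        if rec.length < k:
            logger.warning("contig %s shorter than k=%d; zero composition row", rec.id, k)
            continue
        codes = _encode(rec.sequence)
        win = sliding_window_view(codes, k)
        valid = (win < 4).all(axis=1)
        if not valid.any():
            continue
        kcodes = win[valid] @ powers
        counts[c] = np.bincount(class_of[kcodes], minlength=V)
    return CompositionMatrix(counts=counts, k=k, kmer_index=reps)


def add_pseudocounts(
    Z: CompositionMatrix, Y: CoverageMatrix
) -> tuple[CompositionMatrix, CoverageMatrix]:
    """Return pseudo-counted copies Z' = Z + 1 and Y' = Y + 0.01.

    The +1 on composition is small relative to k-mer counts; the +0.01 on
    coverage is negligible relative to real read depth.  Both remove the
    zeros that would break the subsequent normalizations.
    """
    Zp = CompositionMatrix(counts=Z.counts + 1, k=Z.k, kmer_index=Z.kmer_index)
    Yp = CoverageMatrix(
        values=Y.values + 0.01,
        sample_ids=list(Y.sample_ids),
        contig_ids=list(Y.contig_ids),
    )
    return Zp, Yp


def normalize_coverage(Yp: CoverageMatrix) -> np.ndarray:
    """Two-step coverage normalization.

    Step 1 rescales each sample column to sum to 1 across contigs
    (removing per-sample sequencing depth); step 2 rescales each contig
    row to sum to 1 across samples, yielding the coverage profile Q.
    """
    values = Yp.values
    if np.any(values <= 0):
        raise ValueError("normalize_coverage expects strictly positive (pseudo-counted) values")
    col_sums = values.sum(axis=0)
    if np.any(col_sums == 0):
        raise ValueError("zero column sum in coverage")
    Ypp = values / col_sums
    Q = Ypp / Ypp.sum(axis=1, keepdims=True)
    return Q


def nucleotide_model(contig: ContigRecord, smooth: bool = True) -> NucleotideModel:
    """Estimate p_c(a) = n_c(a) / L from the contig's own bases.

    N bases are excluded from both numerator and denominator.  With
    ``smooth`` (default) add-one smoothing makes every probability
    strictly positive, which keeps the binomial variance nonzero for
    every k-mer class.
    """
    seq = contig.sequence
    counts = {b: seq.count(b) for b in _BASES}
    total = sum(counts.values())
    if total == 0:
        raise NoInformativeBasesError(f"contig {contig.id!r} has no informative bases")
    if smooth:
        probs = {b: (counts[b] + 1) / (total + 4) for b in _BASES}
    else:
        probs = {b: counts[b] / total for b in _BASES}
    return NucleotideModel(probs=probs, smoothed=smooth)


def kmer_probability(model: NucleotideModel, w: str, mode: str = "pair") -> float:
    """Occurrence probability of the canonical class of w at a fixed position.

    ``strict`` returns the plain product of per-base probabilities of w.
    ``pair`` (default) adds the product for rc(w) when w is not its own
    reverse complement, matching the fact that the class count pools both
    strands; with only the single product, the expected z-score of the
    pooled count would be systematically positive.
    """
    if any(b not in _COMPLEMENT for b in w):
        raise ValueError(f"k-mer {w!r} not over ACGT")
    p = model.probs
    forward = float(np.prod([p[b] for b in w]))
    if mode == "strict":
        return forward
    if mode == "pair":
        rc = reverse_complement(w)
        if rc == w:
            return forward
        return forward + float(np.prod([p[b] for b in rc]))
    raise ValueError(f"unknown mode {mode!r}")


def _class_probabilities(
    P_base: np.ndarray, k: int, mode: str
) -> np.ndarray:
    """Vectorized P_cw for all contigs x canonical classes.

    P_base is N x 4 (per-contig base probabilities).  Returns N x V.
    """
    reps, _, palindrome = kmer_class_index(k)
    V = len(reps)
    rep_digits = np.array([[_BASES.index(b) for b in w] for w in reps], dtype=np.int64)
    rc_digits = np.array(
        [[_BASES.index(b) for b in reverse_complement(w)] for w in reps], dtype=np.int64
    )
    N = P_base.shape[0]
    P_fwd = np.ones((N, V))
    P_rc = np.ones((N, V))
    for j in range(k):
        P_fwd *= P_base[:, rep_digits[:, j]]
        P_rc *= P_base[:, rc_digits[:, j]]
    if mode == "strict":
        return P_fwd
    if mode == "pair":
        return np.where(palindrome[None, :], P_fwd, P_fwd + P_rc)
    raise ValueError(f"unknown mode {mode!r}")


def standardize_composition(
    Zp: CompositionMatrix,
    contigs: ContigSet,
    mode: str = "pair",
    smooth: bool = True,
    column_mode: str = "abs",
) -> StandardizedComposition:
    """Standardize class counts as per-contig binomial z-scores.

    For each contig c and class w:  mu = P_cw * L(x_c),
    sigma^2 = P_cw (1 - P_cw) L(x_c),  Xtilde = (X - mu) / sigma, with X
    the counts of the supplied matrix.  The pipeline standardizes the raw
    counts: the +1 pseudo-count exists to protect divisions elsewhere,
    and carrying it into the z-score would shift every class by 1/sigma
    (~0.1-0.16 for 10 kb contigs at k=4), breaking the statistic's
    centering under its own null model.  Zero counts are harmless here
    because the smoothed nucleotide model keeps sigma > 0.  The z-scores
    are then column-normalized into H (see :func:`normalize_columns`).
    """
    if Zp.counts.shape[0] != contigs.N:
        raise DimensionMismatchError("composition rows do not match contig count")
    P_base = np.stack([nucleotide_model(rec, smooth=smooth).as_array() for rec in contigs])
    P = _class_probabilities(P_base, Zp.k, mode)
    L = contigs.lengths().astype(float)[:, None]
    mu = P * L
    var = P * (1.0 - P) * L
    if np.any(var <= 0):
        c, w = np.argwhere(var <= 0)[0]
        raise ZeroVarianceError(
            f"zero variance for contig {contigs[int(c)].id!r}, "
            f"k-mer class {Zp.kmer_index[int(w)]!r} (use a smoothed nucleotide model)"
        )
    zscores = (Zp.counts - mu) / np.sqrt(var)
    H = normalize_columns(zscores, mode=column_mode)
    return StandardizedComposition(zscores=zscores, normalized=H)


def normalize_columns(Xt: np.ndarray, mode: str = "abs") -> np.ndarray:
    """Normalize z-scores across contigs (column-wise) into H.

    ``abs`` (default) divides each column by the sum of its absolute
    values, so every column's absolute values sum to 1 while signs are
    preserved.  ``strict`` divides by the signed column sum, which can be
    arbitrarily close to zero for a near-null column and blow the scale
    up.  Columns with a zero denominator are left as zeros (warned).
    """
    Xt = np.asarray(Xt, dtype=float)
    if not np.all(np.isfinite(Xt)):
        raise ValueError("non-finite values in z-score matrix")
    if mode == "abs":
        denom = np.abs(Xt).sum(axis=0)
    elif mode == "strict":
        denom = Xt.sum(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    zero = np.isclose(denom, 0.0)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} composition column(s) with zero denominator set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, denom)
    H = Xt / safe
    H[:, zero] = 0.0
    return H


def assemble_features(Q: np.ndarray, H: np.ndarray) -> FeatureMatrix:
    """Concatenate coverage and composition profiles into F = [Q H]."""
    Q = np.asarray(Q, dtype=float)
    H = np.asarray(H, dtype=float)
    if Q.shape[0] != H.shape[0]:
        raise DimensionMismatchError(
            f"row mismatch: Q has {Q.shape[0]} rows, H has {H.shape[0]}"
        )
    if not (np.all(np.isfinite(Q)) and np.all(np.isfinite(H))):
        raise ValueError("non-finite values in feature inputs")
    return FeatureMatrix(
        values=np.hstack([Q, H]), n_coverage=Q.shape[1], n_composition=H.shape[1]
    )


def split_by_length(
    contigs: ContigSet,
    threshold_bp: int = 2000,
    mode: str = "fixed",
    short_fraction: float = 0.20,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition contig indices into (long, short).

    ``fixed`` mode labels contigs of length >= threshold_bp as long
    (2000 bp is a good compromise that typically leaves ~20% of assembled
    contigs short).  ``quantile`` mode instead labels exactly the
    floor(short_fraction * N) shortest contigs as short, ties broken by
    input order.
    """
    lengths = contigs.lengths()
    idx = np.arange(contigs.N)
    if mode == "fixed":
        if threshold_bp < 1:
            raise ValueError("threshold_bp must be >= 1")
        long_mask = lengths >= threshold_bp
        long_idx, short_idx = idx[long_mask], idx[~long_mask]
    elif mode == "quantile":
        if not (0 <= short_fraction < 1):
            raise ValueError("short_fraction must be in [0, 1)")
        n_short = int(short_fraction * contigs.N)
        order = np.argsort(lengths, kind="stable")
        short_idx = np.sort(order[:n_short])
        long_idx = np.sort(order[n_short:])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if long_idx.size == 0:
        raise NoLongContigsError("no long contigs for phase 1")
    return long_idx, short_idx


def relative_composition(Zp: CompositionMatrix) -> np.ndarray:
    """Scale each composition row to relative class frequencies (rows sum
    to 1), making count vectors of contigs of different lengths
    comparable in the phase-2 assignment space."""
    counts = Zp.counts.astype(float)
    sums = counts.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("composition row with zero total count")
    return counts / sums
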