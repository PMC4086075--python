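"""Profile k-mer feature map and normalized string kernel.

A k-mer beta "hits" window position ``pos`` of a profile when its summed
per-position cost ``sum_j scores[pos+j, beta_j]`` is strictly below the
threshold ``theta``.  The feature map counts, over all window positions, how
often each k-mer of the 20-letter alphabet hits; the kernel is the cosine
similarity of two such sparse count vectors.

The production feature map walks the k-mer trie level by level with the
partial-score pruning rule (a prefix whose cost already reaches theta cannot
yield a hit), vectorised across all window positions at once.  A brute-force
enumerator over all ``20**k`` k-mers serves as an independent oracle for
small k.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp

from loctree.errors import ValidationError
from loctree.records import ALPHABET, ALPHABET_INDEX, SequenceProfile

__all__ = [
    "KernelParams",
    "KmerFeatureVector",
    "brute_force_feature_map",
    "default_theta",
    "feature_map",
    "kernel",
    "kernel_matrix",
    "kmer_position_score",
]

# fabricated-profile column costs for p_self = 0.9: the matching letter costs
# -ln(0.9), every other letter -ln(0.1/19).
_SELF_COST = -math.log(0.9)
_OTHER_COST = -math.log(0.1 / 19.0)
# margin keeping the single-substitution shell strictly inside the threshold
_THETA_MARGIN = 0.05

_MAX_ORACLE_KMERS = 10**6
_MAX_K = 6


def default_theta(k: int) -> float:
    """Default hit threshold for k-mer length *k*.

    Calibrated on the fabricated-profile scale (p_self = 0.9): admits the
    exact-match k-mer plus every single-substitution neighbour, i.e.
    ``1 + 19k`` hits per window position on that scale — sparse relative to
    ``20**k`` yet never empty.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    return (k - 1) * _SELF_COST + _OTHER_COST + _THETA_MARGIN


@dataclass(frozen=True)
class KernelParams:
    """k-mer length and hit threshold of the profile kernel.

    Defaults per domain of life are k = 6 (eukaryota), 5 (bacteria) and
    3 (archaea); ``theta`` defaults to :func:`default_theta` of k.
    """

    k: int
    theta: float | None = None
    alphabet: str = ALPHABET
    allow_large_k: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.k > _MAX_K and not self.allow_large_k:
            raise ValidationError(
                f"k = {self.k} > {_MAX_K} rejected by default "
                "(set allow_large_k to override)"
            )
        if self.theta is None:
            object.__setattr__(self, "theta", default_theta(self.k))
        if self.theta <= 0:
            raise ValidationError(f"theta must be > 0, got {self.theta}")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValidationError("alphabet letters must be unique")


@dataclass
class KmerFeatureVector:
    """Sparse k-mer count vector.

    Stored as parallel arrays of base-|alphabet| integer codes (sorted,
    unique) and positive counts; the ``counts`` mapping view decodes codes
    back to k-mer strings.
    """

    k: int
    codes: np.ndarray
    count_values: np.ndarray
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.count_values = np.asarray(self.count_values, dtype=np.int64)
        if self.codes.shape != self.count_values.shape:
            raise ValidationError("codes/counts shape mismatch")
        if self.count_values.size and self.count_values.min() < 1:
            raise ValidationError("feature counts must be >= 1")

    @property
    def norm(self) -> float:
        return float(np.sqrt(np.sum(self.count_values.astype(float) ** 2)))

    @property
    def total(self) -> int:
        return int(self.count_values.sum())

    def __len__(self) -> int:
        return int(self.codes.size)

    def _decode(self, code: int) -> str:
        letters = []
        for _ in range(self.k):
            code, rem = divmod(code, len(self.alphabet))
            letters.append(self.alphabet[rem])
        return "".join(reversed(letters))

    @cached_property
    def counts(self) -> dict[str, int]:
        """k-mer string -> count mapping (built on demand)."""
        return {self._decode(int(c)): int(n)
                for c, n in zip(self.codes, self.count_values)}


def kmer_position_score(profile: SequenceProfile, pos: int, kmer: str) -> float:
    """Summed profile cost of placing *kmer* at window position *pos*."""
    k = len(kmer)
    if pos < 0 or pos + k > profile.length:
        raise ValidationError(
            f"position {pos} out of range for k={k}, L={profile.length}")
    total = 0.0
    for j, letter in enumerate(kmer):
        if letter not in ALPHABET_INDEX:
            raise ValidationError(f"letter {letter!r} outside kernel alphabet")
        total += profile.scores[pos + j, ALPHABET_INDEX[letter]]
    return total


def _check_length(profile: SequenceProfile, k: int) -> None:
    if profile.length < k:
        raise ValidationError(
            f"{profile.id}: profile length {profile.length} shorter than k={k}")


def feature_map(profile: SequenceProfile, params: KernelParams) -> KmerFeatureVector:
    """Count every k-mer that hits at every window position.

    Traverses the k-mer trie one level at a time, carrying the surviving
    (window position, prefix) states as flat arrays; a prefix is pruned the
    moment its partial cost reaches theta, which can never be undone since
    scores are non-negative.
    """
    k, theta = params.k, params.theta
    _check_length(profile, k)
    n_letters = len(ALPHABET)
    scores = profile.scores
    n_pos = profile.length - k + 1

    pos = np.arange(n_pos, dtype=np.int64)
    code = np.zeros(n_pos, dtype=np.int64)
    partial = np.zeros(n_pos, dtype=float)
    for depth in range(k):
        totals = partial[:, None] + scores[pos + depth]     # (n_states, 20)
        state_idx, letter_idx = np.nonzero(totals < theta)
        if state_idx.size == 0:
            return KmerFeatureVector(k, np.empty(0, np.int64), np.empty(0, np.int64))
        pos = pos[state_idx]
        code = code[state_idx] * n_letters + letter_idx
        partial = totals[state_idx, letter_idx]
    codes, counts = np.unique(code, return_counts=True)
    return KmerFeatureVector(k, codes, counts)


def brute_force_feature_map(profile: SequenceProfile,
                            params: KernelParams) -> KmerFeatureVector:
    """Oracle feature map by explicit enumeration of all ``20**k`` k-mers."""
    k, theta = params.k, params.theta
    _check_length(profile, k)
    n_letters = len(ALPHABET)
    if n_letters ** k > _MAX_ORACLE_KMERS:
        raise ValidationError(
            f"brute force infeasible: {n_letters}**{k} > {_MAX_ORACLE_KMERS}")
    kmer_idx = np.array(list(itertools.product(range(n_letters), repeat=k)),
                        dtype=np.int64)
    powers = n_letters ** np.arange(k - 1, -1, -1, dtype=np.int64)
    kmer_codes = kmer_idx @ powers
    counts: dict[int, int] = {}
    for pos in range(profile.length - k + 1):
        total = np.zeros(len(kmer_codes))
        for j in range(k):
            total += profile.scores[pos + j, kmer_idx[:, j]]
        for c in kmer_codes[total < theta]:
            counts[int(c)] = counts.get(int(c), 0) + 1
    if not counts:
        return KmerFeatureVector(k, np.empty(0, np.int64), np.empty(0, np.int64))
    codes = np.array(sorted(counts), dtype=np.int64)
    values = np.array([counts[int(c)] for c in codes], dtype=np.int64)
    return KmerFeatureVector(k, codes, values)


def kernel(u: KmerFeatureVector, v: KmerFeatureVector) -> float:
    """Cosine similarity of two feature vectors; exactly 1 for u == v."""
    if u.k != v.k:
        raise ValidationError(f"mismatched k: {u.k} vs {v.k}")
    if len(u) == 0 or len(v) == 0:
        raise ValidationError("kernel undefined for an empty feature vector")
    if u is v or (u.codes.shape == v.codes.shape
                  and np.array_equal(u.codes, v.codes)
                  and np.array_equal(u.count_values, v.count_values)):
        return 1.0
    _, ia, ib = np.intersect1d(u.codes, v.codes,
                               assume_unique=True, return_indices=True)
    dot = float(np.dot(u.count_values[ia].astype(float),
                       v.count_values[ib].astype(float)))
    return dot / (u.norm * v.norm)


def features_to_csr(vectors: list[KmerFeatureVector],
                    vocabulary: np.ndarray | None = None
                    ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Stack feature vectors into a row-normalized CSR matrix.

    Returns the matrix and the sorted vocabulary (k-mer codes) defining its
    columns.  Codes outside a supplied vocabulary are dropped — harmless for
    dot products against rows built on that vocabulary.
    """
    if vocabulary is None:
        all_codes = [v.codes for v in vectors if len(v)]
        vocabulary = (np.unique(np.concatenate(all_codes))
                      if all_codes else np.empty(0, np.int64))
    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for v in vectors:
        cols = np.searchsorted(vocabulary, v.codes)
        valid = (cols < len(vocabulary))
        if np.any(valid):
            valid &= vocabulary[np.minimum(cols, len(vocabulary) - 1)] == v.codes
        cols = cols[valid]
        vals = v.count_values[valid].astype(float)
        norm = v.norm
        if norm > 0:
            vals = vals / norm
        indices.append(cols)
        data.append(vals)
        indptr.append(indptr[-1] + len(cols))
    matrix = sp.csr_matrix(
        (np.concatenate(data) if data else np.empty(0),
         np.concatenate(indices) if indices else np.empty(0, np.int64),
         np.array(indptr)),
        shape=(len(vectors), len(vocabulary)),
    )
    return matrix, vocabulary


def kernel_matrix_from_features(vectors: list[KmerFeatureVector]) -> np.ndarray:
    for v in vectors:
        if len(v) == 0:
            raise ValidationError("kernel undefined for an empty feature vector")
    matrix, _ = features_to_csr(vectors)
    gram = np.asarray((matrix @ matrix.T).todense(), dtype=float)
    gram = (gram + gram.T) / 2.0
    np.fill_diagonal(gram, 1.0)
    return gram


def kernel_matrix(profiles: list[SequenceProfile],
                  params: KernelParams) -> np.ndarray:
    """Symmetric normalized Gram matrix over a list of profiles."""
    return kernel_matrix_from_features(
        [feature_map(p, params) for p in profiles])
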