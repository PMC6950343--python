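"""Column-state alphabet prefilter.

Comparing every pair in a large profile library with the full co-emission
dynamic program is quadratic in library size with an expensive kernel.  The
prefilter sidesteps most of that work: every match column of a profile is
assigned one of K representative amino-acid distributions ("column
states", default K = 219), turning each profile into a plain string over a
K-letter alphabet.  Strings are compared by Smith-Waterman local alignment
over a mutational log-odds substitution matrix between states, and only
pairs whose string score is promising are forwarded to the full aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .model import N_AA, ProfileHMM, default_background

#: Default number of column states.
DEFAULT_K = 219

#: Co-emission log-odds floor, in bits, for orthogonal state pairs.
FLOOR_BITS = -16.0


class AlphabetError(ValueError):
    """Invalid alphabet construction or use."""


@dataclass
class ColumnStateAlphabet:
    """K discrete column states with a quantized substitution matrix.

    ``state_profiles`` holds one 20-dim amino-acid distribution per state;
    ``subst_matrix`` the K x K integer log-odds scores
    round(scale * log2 co-emission odds), floored at
    round(scale * FLOOR_BITS).  ``offset`` records any additive shift
    applied during quantization (0 by default).
    """

    state_profiles: np.ndarray
    subst_matrix: np.ndarray
    scale: float = 2.0
    offset: float = 0.0
    background: np.ndarray = None

    def __post_init__(self) -> None:
        self.state_profiles = np.asarray(self.state_profiles, float)
        self.subst_matrix = np.asarray(self.subst_matrix)
        if self.background is None:
            self.background = default_background()
        K = self.state_profiles.shape[0]
        if K < 1:
            raise AlphabetError("alphabet needs at least one state")
        if self.state_profiles.shape[1] != N_AA:
            raise AlphabetError("state profiles must be 20-dimensional")
        if np.abs(self.state_profiles.sum(axis=1) - 1.0).max() > 1e-6:
            raise AlphabetError("state profiles must sum to 1")
        if self.subst_matrix.shape != (K, K):
            raise AlphabetError("substitution matrix shape mismatch")
        if not np.array_equal(self.subst_matrix, self.subst_matrix.T):
            raise AlphabetError("substitution matrix must be symmetric")

    @property
    def n_states(self) -> int:
        return self.state_profiles.shape[0]


@dataclass
class StateSequence:
    """A profile reduced to its per-column state letters."""

    name: str
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    def __len__(self) -> int:
        return self.states.size


def _kmeans_sqrt(vectors: np.ndarray, K: int, seed: int):
    """K-means on square-root-transformed non-negative vectors.

    The square-root map places probability vectors on the unit sphere,
    where Euclidean k-means respects the Hellinger geometry of
    distributions.  Returns (centers mapped back by squaring, labels);
    callers renormalize the centers for their own layout.
    """
    vectors = np.asarray(vectors, float)
    if vectors.shape[0] < K:
        raise AlphabetError(
            f"{vectors.shape[0]} input columns for K={K} states; use a smaller K"
        )
    x = np.sqrt(np.clip(vectors, 0.0, None))
    km = KMeans(n_clusters=K, random_state=seed, n_init=4)
    labels = km.fit_predict(x)
    centers = np.clip(km.cluster_centers_, 0.0, None) ** 2
    return centers, labels


def train_alphabet(
    columns: np.ndarray,
    K: int = DEFAULT_K,
    seed: int = 0,
    background: Optional[np.ndarray] = None,
    scale: float = 2.0,
) -> ColumnStateAlphabet:
    """Cluster profile columns into a K-state alphabet.

    Columns (N x 20 probability vectors, N >= K) are clustered by k-means
    after a square-root transform; the back-transformed centroids are
    renormalized to probabilities and the state substitution matrix is
    computed from them.  Deterministic for a fixed seed.
    """
    columns = np.asarray(columns, float)
    f = default_background() if background is None else np.asarray(background, float)
    centers, _ = _kmeans_sqrt(columns, K, seed)
    profiles = centers / centers.sum(axis=1, keepdims=True)
    matrix = state_substitution_matrix(profiles, f, scale)
    return ColumnStateAlphabet(
        state_profiles=profiles, subst_matrix=matrix, scale=scale, background=f
    )


def state_substitution_matrix(
    profiles: np.ndarray, background: np.ndarray, scale: float = 2.0
) -> np.ndarray:
    """Integer mutational substitution scores between column states.

    S(a, b) = round(scale * log2 sum_x p_a(x) p_b(x) / f(x)), floored at
    round(scale * FLOOR_BITS) for orthogonal (zero co-emission) pairs.
    Symmetric by construction.
    """
    profiles = np.asarray(profiles, float)
    f = np.asarray(background, float)
    if np.any(f <= 0):
        raise AlphabetError("background must be strictly positive")
    odds = profiles @ (profiles / f[None, :]).T
    odds = 0.5 * (odds + odds.T)
    floor = round(scale * FLOOR_BITS)
    with np.errstate(divide="ignore"):
        bits = np.log2(odds)
    scores = np.where(
        np.isfinite(bits), np.round(scale * bits), float(floor)
    )
    return np.maximum(scores, floor).astype(np.int64)


def discretize(model: ProfileHMM, alphabet: ColumnStateAlphabet) -> StateSequence:
    """Assign each match column its best co-emission state letter.

    The state maximizing log2 sum_x p_state(x) col(x) / f(x) wins; ties go
    to the lowest state index (numpy argmax convention).
    """
    f = alphabet.background
    odds = model.match_emissions @ (alphabet.state_profiles / f[None, :]).T
    return StateSequence(name=model.name, states=np.argmax(odds, axis=1))


def smith_waterman(
    s1: StateSequence | Sequence[int],
    s2: StateSequence | Sequence[int],
    alphabet: ColumnStateAlphabet,
    gap_open: int = 6,
    gap_extend: int = 1,
) -> int:
    """Best local-alignment score with affine gaps over the state matrix.

    A gap of length k costs gap_open + (k - 1) * gap_extend, in matrix
    units.  The score is non-negative (empty alignment allowed) and
    symmetric in its arguments.
    """
    a = s1.states if isinstance(s1, StateSequence) else np.asarray(s1, int)
    b = s2.states if isinstance(s2, StateSequence) else np.asarray(s2, int)
    if a.size == 0 or b.size == 0:
        return 0
    S = alphabet.subst_matrix
    n = b.size
    NEG = -(10 ** 9)
    h_prev = np.zeros(n + 1, dtype=np.int64)
    f_prev = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, a.size + 1):
        row_scores = S[a[i - 1]][b]
        h_cur = np.zeros(n + 1, dtype=np.int64)
        f_cur = np.empty(n + 1, dtype=np.int64)
        f_cur[0] = NEG
        e = NEG
        hc = h_cur  # local aliases for speed
        hp = h_prev
        for j in range(1, n + 1):
            e = max(hc[j - 1] - gap_open, e - gap_extend)
            f_cur[j] = max(hp[j] - gap_open, f_prev[j] - gap_extend)
            h = hp[j - 1] + row_scores[j - 1]
            if e > h:
                h = e
            if f_cur[j] > h:
                h = f_cur[j]
            if h < 0:
                h = 0
            hc[j] = h
            if h > best:
                best = h
        h_prev, f_prev = h_cur, f_cur
    return int(best)


def prefilter_pairs(
    library: Sequence[StateSequence],
    alphabet: ColumnStateAlphabet,
    mode: str = "threshold",
    value: float = 0.0,
    gap_open: int = 6,
    gap_extend: int = 1,
) -> set[tuple[int, int]]:
    """Select candidate pairs for full alignment by state-string score.

    ``threshold`` keeps pairs with SW score >= value; ``topN`` keeps, for
    every query, its value highest-scoring partners (union over queries,
    so the output is symmetric).  Self pairs are always retained.
    """
    if not library:
        raise AlphabetError("empty library")
    n = len(library)
    if mode not in ("threshold", "topN"):
        raise AlphabetError(f"unknown prefilter mode {mode!r}")
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            scores[i, j] = scores[j, i] = smith_waterman(
                library[i], library[j], alphabet, gap_open, gap_extend
            )
    keep: set[tuple[int, int]] = {(i, i) for i in range(n)}
    if mode == "threshold":
        for i in range(n):
            for j in range(i + 1, n):
                if scores[i, j] >= value:
                    keep.add((i, j))
                    keep.add((j, i))
    else:
        top = int(value)
        if top < 0:
            raise AlphabetError("topN value must be >= 0")
        for i in range(n):
            order = np.argsort(-scores[i])
            partners = [j for j in order if j != i][:top]
            for j in partners:
                keep.add((i, j))
                keep.add((j, i))
    return keep
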