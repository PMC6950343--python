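"""Build profile HMMs from single sequences or multiple alignments.

Profile construction follows the classical recipe: alignment columns with
less than 50% gaps become match states, sequences receive position-based
(Henikoff) weights, and the weighted residue counts are regularized with
pseudocounts before normalization.  Three pseudocount flavours are
offered:

``none``
    Raw weighted frequencies (zero-count columns fall back to background).
``substitution``
    Matrix pseudocounts g(a) = sum_b f_obs(b) P(a|b), with the conditional
    substitution probabilities P(a|b) reconstructed from BLOSUM62 and the
    background composition.
``context``
    Context-specific pseudocounts: a library of window profiles is matched
    against the count neighbourhood of each column and the pseudocount
    vector is the responsibility-weighted mixture of the contexts'
    pseudocount emissions.

The observed frequencies and the pseudocount vector are combined by the
admixture tau = min(1, c / N_eff), where N_eff is the effective sequence
number of the alignment, so that deep alignments are trusted and shallow
ones are smoothed heavily.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .model import (
    AA_INDEX,
    AMINO_ACIDS,
    N_AA,
    ProfileHMM,
    ROBINSON_BACKGROUND,
    T_DD,
    T_DM,
    T_II,
    T_IM,
    T_MD,
    T_MI,
    T_MM,
    default_background,
)

GAP = "-"
_ALLOWED = set(AMINO_ACIDS) | {GAP, "X"}


class BuildError(ValueError):
    """Profile construction failed (empty/degenerate input)."""


# ---------------------------------------------------------------------------
# alignment container


@dataclass
class Msa:
    """An aligned block of amino-acid sequences.

    Rows must have equal length and may contain the 20 canonical residues,
    ``X`` (unknown, carries no count) and ``-`` (gap).  Any other symbol is
    mapped to ``X`` with a warning.
    """

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise BuildError("alignment has no sequences")
        if len({len(r) for r in self.rows}) != 1:
            raise BuildError("alignment rows differ in length")
        if len(self.rows[0]) == 0:
            raise BuildError("alignment of zero-length sequences")
        cleaned = []
        for name, row in zip(self.names, self.rows):
            row = row.upper()
            if not set(row) <= _ALLOWED:
                bad = sorted(set(row) - _ALLOWED)
                warnings.warn(
                    f"sequence {name!r}: non-standard symbols {bad} mapped to X"
                )
                row = "".join(c if c in _ALLOWED else "X" for c in row)
            cleaned.append(row)
        self.rows = cleaned

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    @property
    def n_col(self) -> int:
        return len(self.rows[0])

    def gap_fraction(self) -> np.ndarray:
        """Per-column fraction of gap characters."""
        arr = self._char_array()
        return (arr == GAP).mean(axis=0)

    def _char_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])

    @classmethod
    def from_fasta(cls, path_or_stream) -> "Msa":
        records = list(SeqIO.parse(path_or_stream, "fasta"))
        if not records:
            raise BuildError("no FASTA records found")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    @classmethod
    def from_sequence(cls, name: str, seq: str) -> "Msa":
        return cls([name], [seq])


# ---------------------------------------------------------------------------
# sequence weighting and effective sequence number


def henikoff_weights(msa: Msa) -> np.ndarray:
    """Position-based sequence weights, normalized to sum to 1.

    At each column a sequence holding residue ``a`` receives 1/(r * n_a),
    where ``r`` is the number of distinct residues in the column and
    ``n_a`` the multiplicity of ``a``; gaps and ``X`` receive nothing.
    Duplicated sequences therefore share one sequence's worth of weight.
    """
    arr = msa._char_array()
    weights = np.zeros(msa.n_seq)
    for j in range(msa.n_col):
        col = arr[:, j]
        residues = [c for c in col if c in AA_INDEX]
        if not residues:
            continue
        uniq, counts = np.unique(residues, return_counts=True)
        r = len(uniq)
        mult = dict(zip(uniq.tolist(), counts.tolist()))
        for i, c in enumerate(col):
            if c in AA_INDEX:
                weights[i] += 1.0 / (r * mult[c])
    total = weights.sum()
    if total <= 0:
        return np.full(msa.n_seq, 1.0 / msa.n_seq)
    return weights / total


def effective_sequence_number(
    counts: np.ndarray, msa: Msa, mode: str = "entropy"
) -> float:
    """Effective number of independent sequences.

    ``entropy`` (default): exp of the mean per-column Shannon entropy of
    the weighted residue frequencies — 1.0 for a single sequence, growing
    with observed diversity.  ``unique``: the number of distinct rows.
    """
    if mode == "unique":
        return float(len(set(msa.rows)))
    if mode != "entropy":
        raise BuildError(f"unknown N_eff mode {mode!r}")
    entropies = []
    for row in counts:
        tot = row.sum()
        if tot <= 0:
            continue
        p = row / tot
        nz = p[p > 0]
        entropies.append(-(nz * np.log(nz)).sum())
    if not entropies:
        return 1.0
    return float(np.exp(np.mean(entropies)))


# ---------------------------------------------------------------------------
# substitution pseudocounts


def blosum_conditional(background: Optional[np.ndarray] = None) -> np.ndarray:
    """Conditional substitution probabilities P[a, b] = P(a | b).

    Reconstructed from the BLOSUM62 half-bit log-odds scores S(a, b) via
    q(a, b) proportional to f(a) f(b) 2^(S/2), then normalized per
    conditioning residue.  Columns sum to 1.
    """
    f = default_background() if background is None else np.asarray(background, float)
    blosum = substitution_matrices.load("BLOSUM62")
    S = np.empty((N_AA, N_AA))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            S[i, j] = blosum[a, b]
    q = np.outer(f, f) * np.exp2(S / 2.0)
    q = q / q.sum()
    cond = q / q.sum(axis=0, keepdims=True)
    return cond


def substitution_pseudocounts(
    counts: np.ndarray,
    admix: float,
    background: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mix observed frequencies with matrix pseudocounts at fraction admix."""
    if not 0.0 <= admix <= 1.0:
        raise BuildError(f"admix must be in [0, 1], got {admix}")
    f = default_background() if background is None else np.asarray(background, float)
    cond = blosum_conditional(f)
    fobs = _normalize_counts(counts, f)
    g = fobs @ cond.T  # g[i, a] = sum_b fobs[i, b] P(a | b)
    return (1.0 - admix) * fobs + admix * g


def _normalize_counts(counts: np.ndarray, background: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    fobs = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0),
                    background[None, :])
    return fobs


# ---------------------------------------------------------------------------
# context-specific pseudocounts


@dataclass
class ContextLibrary:
    """A library of sequence-context profiles for pseudocount generation.

    Each of the K contexts is a window profile (w columns of 20
    probabilities, w odd), a prior weight, and a pseudocount emission
    vector.  The emission defaults to the window's central column; it is
    kept as a separate field so the window-1 library derived from a
    substitution matrix (point-mass windows, conditional-row emissions)
    reproduces matrix pseudocounts exactly.
    """

    priors: np.ndarray          # (K,)
    windows: np.ndarray         # (K, w, 20)
    pc_profiles: Optional[np.ndarray] = None  # (K, 20)

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, float)
        self.windows = np.asarray(self.windows, float)
        if self.pc_profiles is None:
            self.pc_profiles = self.windows[:, self.window_length // 2, :].copy()
        self.pc_profiles = np.asarray(self.pc_profiles, float)
        self.validate()

    @property
    def n_contexts(self) -> int:
        return self.windows.shape[0]

    @property
    def window_length(self) -> int:
        return self.windows.shape[1]

    def validate(self) -> "ContextLibrary":
        K, w, A = self.windows.shape
        if A != N_AA:
            raise BuildError("context windows must have 20 columns")
        if w < 1 or w % 2 == 0:
            raise BuildError(f"window length must be odd and >= 1, got {w}")
        if K < 1:
            raise BuildError("context library is empty")
        if abs(self.priors.sum() - 1.0) > 1e-6:
            raise BuildError("context priors must sum to 1")
        colsums = self.windows.sum(axis=2)
        if np.abs(colsums - 1.0).max() > 1e-6:
            raise BuildError("context window columns must sum to 1")
        return self


def substitution_context_library(
    background: Optional[np.ndarray] = None,
) -> ContextLibrary:
    """The window-1 library equivalent to BLOSUM62 matrix pseudocounts.

    Twenty contexts, one per residue: the window profile is a point mass
    on the residue, the prior its background frequency, and the
    pseudocount emission the BLOSUM conditional P(. | residue).
    """
    f = default_background() if background is None else np.asarray(background, float)
    cond = blosum_conditional(f)
    windows = np.eye(N_AA)[:, None, :]
    return ContextLibrary(priors=f / f.sum(), windows=windows,
                          pc_profiles=cond.T.copy())


def context_pseudocounts(
    counts: np.ndarray,
    library: ContextLibrary,
    admix: float,
    background: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Context-specific pseudocount smoothing of an L x 20 count matrix.

    For every column the count neighbourhood (window, edges padded with
    the background composition) is compared against each context profile.
    The responsibility of context k is its prior times the mean
    likelihood-ratio of the neighbourhood's residues under the context,

        resp_k  propto  prior_k * sum_{j,a} c~(j, a) * p_k(j, a) / f(a),

    a linearized Bayes rule: it equals the exact posterior when the window
    holds a single observation and stays well defined for fractional
    counts.  The pseudocount vector is the responsibility-weighted mixture
    of the contexts' pseudocount emissions, and the returned rows are the
    admixture (1 - admix) * f_obs + admix * pseudocount.
    """
    if not 0.0 <= admix <= 1.0:
        raise BuildError(f"admix must be in [0, 1], got {admix}")
    f = default_background() if background is None else np.asarray(background, float)
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    L = counts.shape[0]
    fobs = _normalize_counts(counts, f)
    w = library.window_length
    half = w // 2
    # Padded, per-column-normalized count profile with background edges.
    padded = np.vstack([np.tile(f, (half, 1)), fobs, np.tile(f, (half, 1))])
    ratio = library.windows / f[None, None, :]  # (K, w, 20)
    resp = np.empty((L, library.n_contexts))
    for i in range(L):
        window = padded[i : i + w]  # (w, 20)
        lik = (ratio * window[None, :, :]).sum(axis=(1, 2)) / w
        resp[i] = library.priors * lik
    totals = resp.sum(axis=1, keepdims=True)
    resp = np.where(totals > 0, resp / np.where(totals > 0, totals, 1.0),
                    library.priors[None, :])
    pc = resp @ library.pc_profiles
    pc = pc / pc.sum(axis=1, keepdims=True)
    return (1.0 - admix) * fobs + admix * pc


def read_context_library(path_or_stream) -> ContextLibrary:
    """Read the plain-text context-library format.

    Line 1: ``K w``; then K blocks of one prior line followed by w lines
    of 20 probabilities.  The same format with w = 1 serves as the
    column-state alphabet file.
    """
    if hasattr(path_or_stream, "read"):
        tokens = path_or_stream.read().split()
    else:
        with open(path_or_stream) as fh:
            tokens = fh.read().split()
    it = iter(tokens)
    K = int(next(it))
    w = int(next(it))
    priors = np.empty(K)
    windows = np.empty((K, w, N_AA))
    for k in range(K):
        priors[k] = float(next(it))
        for j in range(w):
            windows[k, j] = [float(next(it)) for _ in range(N_AA)]
    return ContextLibrary(priors=priors, windows=windows)


def write_context_library(library: ContextLibrary, path_or_stream) -> None:
    lines = [f"{library.n_contexts} {library.window_length}"]
    for k in range(library.n_contexts):
        lines.append(f"{library.priors[k]:.8g}")
        for j in range(library.window_length):
            lines.append(" ".join(f"{p:.8g}" for p in library.windows[k, j]))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)


def train_context_library(
    columns: np.ndarray, K: int, w: int = 1, seed: int = 0
) -> ContextLibrary:
    """Train a small context library by k-means over profile windows.

    ``columns`` is an (N, 20) stack of profile columns; overlapping
    windows of length w are clustered (square-root transform, see the
    alphabet trainer) and cluster means become context windows with
    priors proportional to cluster sizes.
    """
    from .alphabet import _kmeans_sqrt  # shared clustering kernel

    columns = np.asarray(columns, float)
    half = w // 2
    padded = np.vstack(
        [np.tile(ROBINSON_BACKGROUND, (half, 1)), columns,
         np.tile(ROBINSON_BACKGROUND, (half, 1))]
    )
    n = columns.shape[0]
    windows = np.stack([padded[i : i + w].ravel() for i in range(n)])
    centers, labels = _kmeans_sqrt(windows, K, seed)
    sizes = np.bincount(labels, minlength=K).astype(float)
    sizes = np.where(sizes > 0, sizes, 1.0)
    win = centers.reshape(K, w, N_AA)
    win = win / win.sum(axis=2, keepdims=True)
    return ContextLibrary(priors=sizes / sizes.sum(), windows=win)


# ---------------------------------------------------------------------------
# profile construction


@dataclass
class BuildParams:
    """Tunable knobs for profile construction.

    ``pseudocount_c`` sets the admixture tau = min(1, c / N_eff); ``tau``
    overrides it with a fixed value.  ``match_threshold`` is the gap
    fraction below which a column becomes a match state.  ``laplace`` is
    the additive smoothing applied to transition counts.
    """

    pseudocount_c: float = 1.0
    tau: Optional[float] = None
    match_threshold: float = 0.5
    transition_prior: "str | float" = "plan7"
    neff_mode: str = "entropy"
    background: np.ndarray = field(default_factory=default_background)


#: Transition prior counts per group, the peaked plan7-style Dirichlet
#: parameters standard for profile HMM estimation.  A flat (Laplace) prior
#: grossly over-weights rare M->I / M->D events on shallow alignments and
#: buries the alignment signal under transition costs.
PLAN7_TRANSITION_PRIOR = {
    "match": (0.7939, 0.0278, 0.0135),   # M->M, M->I, M->D
    "insert": (0.1551, 0.1331),          # I->M, I->I
    "delete": (0.9002, 0.5630),          # D->M, D->D
}


def build_hmm(
    msa: Msa,
    pseudocount_mode: str = "substitution",
    context_library: Optional[ContextLibrary] = None,
    params: Optional[BuildParams] = None,
    name: Optional[str] = None,
) -> ProfileHMM:
    """Build a :class:`ProfileHMM` from an alignment (or single sequence).

    See the module docstring for the construction recipe.  Raises
    :class:`BuildError` if no column qualifies as a match state.
    """
    if pseudocount_mode not in ("none", "substitution", "context"):
        raise BuildError(f"unknown pseudocount mode {pseudocount_mode!r}")
    if pseudocount_mode == "context" and context_library is None:
        raise BuildError("context pseudocounts require a context library")
    params = params or BuildParams()
    f = np.asarray(params.background, float)

    gap_frac = msa.gap_fraction()
    match_cols = np.where(gap_frac < params.match_threshold)[0]
    if match_cols.size == 0:
        raise BuildError("no match columns: alignment is predominantly gaps")
    L = match_cols.size

    weights = henikoff_weights(msa)
    arr = msa._char_array()

    counts = np.zeros((L, N_AA))
    for k, j in enumerate(match_cols):
        for i in range(msa.n_seq):
            c = arr[i, j]
            if c in AA_INDEX:
                counts[k, AA_INDEX[c]] += weights[i]

    n_eff = effective_sequence_number(counts, msa, params.neff_mode)
    tau = params.tau if params.tau is not None else min(
        1.0, params.pseudocount_c / n_eff
    )

    if pseudocount_mode == "none":
        match_emissions = _normalize_counts(counts, f)
    elif pseudocount_mode == "substitution":
        match_emissions = substitution_pseudocounts(counts, tau, f)
    else:
        match_emissions = context_pseudocounts(counts, context_library, tau, f)
    match_emissions = match_emissions / match_emissions.sum(axis=1, keepdims=True)

    transitions = _count_transitions(arr, match_cols, weights,
                                     params.transition_prior)

    model = ProfileHMM(
        name=name or (msa.names[0] if msa.n_seq == 1 else "msa"),
        match_emissions=match_emissions,
        insert_emissions=np.tile(f, (L, 1)),
        transitions=transitions,
        background=f.copy(),
        metadata={
            "ALPH": "amino",
            "NSEQ": msa.n_seq,
            "EFFN": f"{n_eff:.6f}",
            "MATCH_COLUMNS": match_cols.tolist(),
        },
    )
    return model.validate()


def _count_transitions(
    arr: np.ndarray,
    match_cols: np.ndarray,
    weights: np.ndarray,
    prior: "str | float" = "plan7",
) -> np.ndarray:
    """Weighted transition counts with additive prior smoothing.

    Every sequence contributes a plan7-legal state path: match columns are
    M (residue or X) or D (gap); residues in non-match columns are
    inserts.  Inserts adjacent to deletions are attributed through M (the
    standard trace-repair simplification).  ``prior`` is either the peaked
    ``"plan7"`` Dirichlet counts or a float for flat Laplace smoothing.
    """
    n_seq, n_col = arr.shape
    L = len(match_cols)
    counts = np.zeros((L + 1, 7))
    is_match = np.zeros(n_col, dtype=bool)
    is_match[match_cols] = True
    col_to_node = {j: k for k, j in enumerate(match_cols)}

    for i in range(n_seq):
        w = weights[i]
        prev_state = "M"  # BEGIN behaves like a match state
        prev_node = 0
        pending_inserts = 0
        for j in range(n_col):
            c = arr[i, j]
            if is_match[j]:
                node = col_to_node[j] + 1
                state = "D" if c == GAP else "M"
                _add_transition(counts, prev_node, prev_state, state,
                                pending_inserts, w)
                prev_state, prev_node, pending_inserts = state, node, 0
            elif c != GAP:
                pending_inserts += 1
        # exit: treat END as a match state
        _add_transition(counts, prev_node, prev_state, "M", pending_inserts, w)

    if prior == "plan7":
        counts[:, [T_MM, T_MI, T_MD]] += PLAN7_TRANSITION_PRIOR["match"]
        counts[:, [T_IM, T_II]] += PLAN7_TRANSITION_PRIOR["insert"]
        counts[:, [T_DM, T_DD]] += PLAN7_TRANSITION_PRIOR["delete"]
    else:
        counts += float(prior)
    # structural zeros of the plan7 layout
    counts[0, T_DM] = 1.0
    counts[0, T_DD] = 0.0
    counts[L, T_MD] = 0.0
    counts[L, T_DD] = 0.0
    counts[L, T_DM] = 1.0

    out = np.zeros_like(counts)
    for cols in ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)):
        block = counts[:, list(cols)]
        sums = block.sum(axis=1, keepdims=True)
        out[:, list(cols)] = np.where(sums > 0, block / np.where(sums > 0, sums, 1),
                                      0.0)
    return out


def _add_transition(counts, from_node, from_state, to_state, n_ins, w) -> None:
    if n_ins == 0:
        idx = {
            ("M", "M"): T_MM, ("M", "D"): T_MD,
            ("D", "M"): T_DM, ("D", "D"): T_DD,
        }[(from_state, to_state)]
        counts[from_node, idx] += w
    else:
        # inserts cannot follow D or precede D in plan7; route through M
        if from_state == "D":
            counts[from_node, T_DM] += w
        else:
            counts[from_node, T_MI] += w
        counts[from_node, T_II] += (n_ins - 1) * w
        counts[from_node, T_IM] += w


def read_fasta_sequences(path_or_stream) -> list[tuple[str, str]]:
    """All (name, ungapped sequence) pairs from a FASTA file."""
    records = list(SeqIO.parse(path_or_stream, "fasta"))
    return [(r.id, str(r.seq).replace(GAP, "").upper()) for r in records]
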