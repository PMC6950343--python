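"""Core profile hidden Markov model container.

A profile HMM describes a protein family as a chain of *nodes*, one per
conserved alignment column.  Each node ``k`` carries a match state ``M_k``
with a 20-dimensional amino-acid emission distribution, an insert state
``I_k`` (emissions near the background composition), and a silent delete
state ``D_k``.  Transition probabilities connect consecutive nodes in the
seven-way pattern ``M->M, M->I, M->D, I->M, I->I, D->M, D->D``; a virtual
BEGIN node (row 0) feeds the first real node.

All probabilities are stored linearly (not as logs); serialization to the
HMMER3 negative-log text format lives in :mod:`coemit.hmmer_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Canonical amino-acid ordering (alphabetical one-letter codes, the HMMER
#: column ordering).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

# Robinson & Robinson (1991) amino-acid frequencies, the standard null
# model composition for protein profile software.
ROBINSON_BACKGROUND = np.array(
    [
        0.0787945,  # A
        0.0151600,  # C
        0.0535222,  # D
        0.0668298,  # E
        0.0397062,  # F
        0.0695071,  # G
        0.0229198,  # H
        0.0590092,  # I
        0.0594422,  # K
        0.0963728,  # L
        0.0237718,  # M
        0.0414386,  # N
        0.0482904,  # P
        0.0395639,  # Q
        0.0540978,  # R
        0.0683364,  # S
        0.0540687,  # T
        0.0673417,  # V
        0.0114135,  # W
        0.0304133,  # Y
    ]
)
ROBINSON_BACKGROUND = ROBINSON_BACKGROUND / ROBINSON_BACKGROUND.sum()

# Transition column indices, in file order.
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)
TRANSITION_LABELS = ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")

# Groups of transition columns that form conditional distributions.
_TRANSITION_GROUPS = ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD))


class ModelError(ValueError):
    """A profile HMM violates a structural invariant."""


def default_background() -> np.ndarray:
    """A fresh copy of the standard amino-acid background."""
    return ROBINSON_BACKGROUND.copy()


@dataclass
class ProfileHMM:
    """A profile HMM over the 20-letter amino-acid alphabet.

    Parameters
    ----------
    name:
        Model identifier; must be unique within a library.
    match_emissions:
        ``(L, 20)`` row-stochastic matrix, one row per match state.
    insert_emissions:
        ``(L, 20)`` row-stochastic matrix, one row per insert state.
    transitions:
        ``(L + 1, 7)`` matrix in the order
        ``M->M, M->I, M->D, I->M, I->I, D->M, D->D``.  Row 0 is the BEGIN
        node; row ``L`` carries the exit transitions (``M->M`` there is the
        probability of moving to the END state).
    background:
        20 background frequencies (the null model); defaults to the
        Robinson & Robinson composition.
    metadata:
        Free-form key/value annotation (format version, alphabet tag,
        effective sequence number, per-node MAP/RF/CS columns, ...).
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray = field(default_factory=default_background)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        """Number of match states ``L``."""
        return self.match_emissions.shape[0]

    # Alias used throughout profile-HMM literature.
    L = length

    def validate(self, tol: float = 1e-6) -> "ProfileHMM":
        """Check all structural invariants; return self or raise ModelError."""
        L = self.length
        if L < 1:
            raise ModelError(f"model {self.name!r}: L must be >= 1, got {L}")
        if self.match_emissions.shape != (L, N_AA):
            raise ModelError(f"model {self.name!r}: match_emissions shape")
        if self.insert_emissions.shape != (L, N_AA):
            raise ModelError(f"model {self.name!r}: insert_emissions shape")
        if self.transitions.shape != (L + 1, 7):
            raise ModelError(
                f"model {self.name!r}: transitions must be (L+1, 7), got "
                f"{self.transitions.shape}"
            )
        alph = self.metadata.get("ALPH", "amino")
        if str(alph).lower() != "amino":
            raise ModelError(f"model {self.name!r}: alphabet must be amino, got {alph!r}")
        for arr, what in (
            (self.match_emissions, "match emissions"),
            (self.insert_emissions, "insert emissions"),
            (self.transitions, "transitions"),
            (self.background, "background"),
        ):
            if not np.all(np.isfinite(arr)):
                raise ModelError(f"model {self.name!r}: non-finite {what}")
            if arr.min() < -tol or arr.max() > 1 + tol:
                raise ModelError(f"model {self.name!r}: {what} outside [0, 1]")
        for mat, what in (
            (self.match_emissions, "match emission"),
            (self.insert_emissions, "insert emission"),
        ):
            sums = mat.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > tol)[0]
            if bad.size:
                raise ModelError(
                    f"model {self.name!r}: {what} row {bad[0]} sums to {sums[bad[0]]:.8f}"
                )
        for cols in _TRANSITION_GROUPS:
            sums = self.transitions[:, list(cols)].sum(axis=1)
            # A group is "defined" when it carries any mass at all; the last
            # node's M->D / D->D entries are structurally zero.
            defined = sums > 1e-3
            bad = np.where(defined & (np.abs(sums - 1.0) > tol))[0]
            if bad.size:
                labels = "/".join(TRANSITION_LABELS[c] for c in cols)
                raise ModelError(
                    f"model {self.name!r}: transition group {labels} at node "
                    f"{bad[0]} sums to {sums[bad[0]]:.8f}"
                )
        return self

    def reversed(self) -> "ProfileHMM":
        """The position-reversed model (an involution).

        Match and insert columns are reversed and transition row ``k`` is
        taken from row ``L - k``, preserving the seven-way layout.  Used by
        the reverse-score normalization.
        """
        L = self.length
        return ProfileHMM(
            name=self.name + "_rev",
            match_emissions=self.match_emissions[::-1].copy(),
            insert_emissions=self.insert_emissions[::-1].copy(),
            transitions=self.transitions[::-1].copy(),
            background=self.background.copy(),
            metadata=dict(self.metadata),
        )


def sequence_to_indices(seq: str) -> np.ndarray:
    """Map an amino-acid string to column indices; unknowns raise KeyError."""
    return np.array([AA_INDEX[c] for c in seq], dtype=int)
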