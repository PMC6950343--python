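"""Profile-profile alignment by co-emission scoring.

Two profile HMMs are compared with a pair-state dynamic program over the
five joint states

========  =====================================================
``MM``    both models co-emit a match column
``MI``    model 1 emits a match while model 2 loops in an insert
``IM``    the mirror image of ``MI``
``DG``    model 1 passes through a delete, model 2 is gapped
``GD``    the mirror image of ``DG``
========  =====================================================

The ``MM`` state is scored with the column co-emission log-odds
log2 sum_a q1(a) q2(a) / f(a) — the probability that the two columns emit
the same residue relative to background.  Every pair step is weighted by
the product of the two models' own transition probabilities for their
component moves; insert emissions are not co-emitted by default (inserts
are near-background, so their contribution is noise).

The *Viterbi* score is the best single alignment path, the *forward*
score the log-sum over all paths; forward in local mode is the "simple"
co-emission score used for distance-matrix and tree construction.  Scores
are reported in bits.  In local mode a path may enter and leave the
lattice at any ``MM`` cell; in global mode paths are anchored at the model
ends through the BEGIN/END transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import (
    ProfileHMM,
    T_DD,
    T_DM,
    T_II,
    T_IM,
    T_MD,
    T_MI,
    T_MM,
    default_background,
)

LN2 = math.log(2.0)

#: Column co-emission log-odds floor (bits) for orthogonal columns.
FLOOR_BITS = -16.0

#: Effectively minus infinity that still survives arithmetic without NaNs.
_NEG = -1.0e30

_STATES = ("MM", "MI", "IM", "DG", "GD")


class AlignError(ValueError):
    """Invalid alignment request."""


@dataclass
class PairScore:
    """Result of comparing two profile HMMs.

    ``forward_bits``/``viterbi_bits`` may individually be ``None`` when
    only one variant was requested.  ``trace`` lists the Viterbi path as
    ``(i, j, pair_state)`` steps with 1-based node coordinates.
    """

    name1: str
    name2: str
    forward_bits: Optional[float] = None
    viterbi_bits: Optional[float] = None
    mode: str = "local"
    trace: Optional[list[tuple[int, int, str]]] = None


def coemission_column_score(q1, q2, background=None) -> float:
    """Co-emission log-odds of two profile columns, in bits.

    log2 sum_a q1(a) q2(a) / f(a); symmetric; floored at FLOOR_BITS when
    the columns are orthogonal.  A background with zeros is rejected.
    """
    f = default_background() if background is None else np.asarray(background, float)
    if np.any(f <= 0):
        raise AlignError("background frequencies must be strictly positive")
    q1 = np.asarray(q1, float)
    q2 = np.asarray(q2, float)
    s = float(np.sum(q1 * q2 / f))
    if s <= 0.0:
        return FLOOR_BITS
    return max(math.log2(s), FLOOR_BITS)


def _log(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, _NEG, dtype=float)
    np.log(p, out=out, where=p > 0)
    return out


def _coemission_log_matrix(h1, h2, f) -> np.ndarray:
    odds = (h1.match_emissions / f[None, :]) @ h2.match_emissions.T
    out = np.full_like(odds, FLOOR_BITS * LN2)
    np.log(odds, out=out, where=odds > 0)
    return np.maximum(out, FLOOR_BITS * LN2)


def _resolve_background(h1, h2, null: str) -> np.ndarray:
    if null == "standard":
        return default_background()
    if null == "compo":
        f = 0.5 * (h1.background + h2.background)
        return f / f.sum()
    raise AlignError(f"unknown null model {null!r} (standard or compo)")


def _scan(A: np.ndarray, c: np.ndarray, op) -> np.ndarray:
    """Solve u_j = op(A_j, u_{j-1} + c_j) for j = 1..n with u_0 implicit -inf.

    Via prefix sums per segment: u = C + op-accumulate(A - C) with
    C_j = sum c_m.  A zero-probability extension weight (c_j at the
    sentinel floor) kills the running chain, so the scan restarts there —
    both for correctness and to keep the prefix sums well conditioned.
    """
    n = A.size
    out = np.empty(n)
    blocked = np.flatnonzero(c <= _NEG / 2)
    seg_starts = np.unique(np.concatenate(([0], blocked)))
    for k, s in enumerate(seg_starts):
        e = seg_starts[k + 1] if k + 1 < seg_starts.size else n
        cl = c[s:e].copy()
        cl[0] = 0.0  # the first extension weight of a segment is unused
        C = np.cumsum(cl)
        out[s:e] = C + op.accumulate(A[s:e] - C)
    return out


def _pair_dp(
    h1: ProfileHMM,
    h2: ProfileHMM,
    mode: str,
    kind: str,
    null: str = "standard",
    keep_tables: bool = False,
):
    """Run the five-state DP; returns (bits, tables-or-None, aux).

    ``kind`` selects max (viterbi) or log-sum-exp (forward) semiring.
    Natural-log domain throughout; converted to bits on exit.
    """
    if mode not in ("local", "global"):
        raise AlignError(f"unknown mode {mode!r}")
    op = np.maximum if kind == "viterbi" else np.logaddexp
    f = _resolve_background(h1, h2, null)
    coem = _coemission_log_matrix(h1, h2, f)  # (m, n)
    q = _log(h1.transitions)  # (m+1, 7)
    t = _log(h2.transitions)  # (n+1, 7)
    m, n = h1.length, h2.length

    rows = {s: np.full(n + 1, _NEG) for s in _STATES}
    if mode == "global":
        rows["MM"][0] = 0.0
    # row 0 boundary chains (N-terminal inserts/deletes)
    rows["IM"][1:] = _scan(
        rows["MM"][:-1] + q[0, T_MI] + t[:n, T_MM], q[0, T_II] + t[:n, T_MM], op
    )
    rows["GD"][1:] = _scan(rows["MM"][:-1] + t[:n, T_MD], t[:n, T_DD], op)

    tables = {s: [rows[s].copy()] for s in _STATES} if keep_tables else None
    local_total = _NEG

    for i in range(1, m + 1):
        prev = rows
        cur = {s: np.full(n + 1, _NEG) for s in _STATES}
        stay = np.empty((5, n))
        stay[0] = prev["MM"][:-1] + q[i - 1, T_MM] + t[:n, T_MM]
        stay[1] = prev["MI"][:-1] + q[i - 1, T_MM] + t[:n, T_IM]
        stay[2] = prev["IM"][:-1] + q[i - 1, T_IM] + t[:n, T_MM]
        stay[3] = prev["DG"][:-1] + q[i - 1, T_DM] + t[:n, T_MM]
        stay[4] = prev["GD"][:-1] + q[i - 1, T_MM] + t[:n, T_DM]
        inner = op.reduce(stay, axis=0)
        if mode == "local":
            inner = op(inner, 0.0)
        cur["MM"][1:] = coem[i - 1] + inner
        cur["MI"] = op(
            prev["MM"] + q[i - 1, T_MM] + t[:, T_MI],
            prev["MI"] + q[i - 1, T_MM] + t[:, T_II],
        )
        cur["DG"] = op(prev["MM"] + q[i - 1, T_MD], prev["DG"] + q[i - 1, T_DD])
        cur["IM"][1:] = _scan(
            cur["MM"][:-1] + q[i, T_MI] + t[:n, T_MM], q[i, T_II] + t[:n, T_MM], op
        )
        cur["GD"][1:] = _scan(cur["MM"][:-1] + t[:n, T_MD], t[:n, T_DD], op)
        if mode == "local":
            local_total = float(op.reduce(np.append(cur["MM"][1:], local_total)))
        if keep_tables:
            for s in _STATES:
                tables[s].append(cur[s].copy())
        rows = cur

    if mode == "local":
        score_ln = local_total
    else:
        exits = np.array(
            [
                rows["MM"][n] + q[m, T_MM] + t[n, T_MM],
                rows["MI"][n] + q[m, T_MM] + t[n, T_IM],
                rows["IM"][n] + q[m, T_IM] + t[n, T_MM],
                rows["DG"][n] + q[m, T_DM] + t[n, T_MM],
                rows["GD"][n] + q[m, T_MM] + t[n, T_DM],
            ]
        )
        score_ln = float(op.reduce(exits))
    bits = score_ln / LN2
    if keep_tables:
        tables = {s: np.vstack(tables[s]) for s in _STATES}
    return bits, tables, (coem, q, t)


def pair_forward(
    h1: ProfileHMM, h2: ProfileHMM, mode: str = "local", null: str = "standard"
) -> PairScore:
    """Forward (all-paths) co-emission score of two profiles, in bits.

    Local-mode forward is the simple score used for all-vs-all comparison
    and tree building.
    """
    bits, _, _ = _pair_dp(h1, h2, mode, "forward", null)
    return PairScore(h1.name, h2.name, forward_bits=bits, mode=mode)


def pair_viterbi(
    h1: ProfileHMM,
    h2: ProfileHMM,
    mode: str = "local",
    null: str = "standard",
    trace: bool = True,
) -> PairScore:
    """Best-path co-emission score, with the alignment trace.

    Set ``trace=False`` to skip the traceback tables (rolling-row memory,
    useful for very long models).
    """
    bits, tables, aux = _pair_dp(h1, h2, mode, "viterbi", null, keep_tables=trace)
    result = PairScore(h1.name, h2.name, viterbi_bits=bits, mode=mode)
    if trace:
        result.trace = _traceback(tables, aux, mode, h1.length, h2.length)
    return result


def compare(
    h1: ProfileHMM, h2: ProfileHMM, mode: str = "local", null: str = "standard"
) -> PairScore:
    """Both forward and Viterbi scores (plus the Viterbi trace)."""
    fwd = pair_forward(h1, h2, mode, null)
    vit = pair_viterbi(h1, h2, mode, null)
    return PairScore(
        h1.name, h2.name, forward_bits=fwd.forward_bits,
        viterbi_bits=vit.viterbi_bits, mode=mode, trace=vit.trace,
    )


def reverse_score(
    h1: ProfileHMM, h2: ProfileHMM, mode: str = "local", null: str = "standard"
) -> float:
    """Simple score minus the score against the position-reversed h2.

    An optional normalization: similarity that survives reversal is
    composition bias, so subtracting the reversed-model score removes it.
    """
    fwd = pair_forward(h1, h2, mode, null).forward_bits
    rev = pair_forward(h1, h2.reversed(), mode, null).forward_bits
    return fwd - rev


# ---------------------------------------------------------------------------
# Viterbi traceback


def _traceback(tables, aux, mode, m, n):
    MM, MI, IM, DG, GD = (tables[s] for s in _STATES)
    coem, q, t = aux
    tol = 1e-9

    def close(a, b):
        return abs(a - b) <= tol * max(1.0, abs(a), abs(b))

    # locate the end point
    if mode == "local":
        flat = np.argmax(MM[1:, 1:])
        i, j = np.unravel_index(flat, (m, n))
        i, j = int(i) + 1, int(j) + 1
        state = "MM"
    else:
        exits = [
            ("MM", MM[m, n] + q[m, T_MM] + t[n, T_MM]),
            ("MI", MI[m, n] + q[m, T_MM] + t[n, T_IM]),
            ("IM", IM[m, n] + q[m, T_IM] + t[n, T_MM]),
            ("DG", DG[m, n] + q[m, T_DM] + t[n, T_MM]),
            ("GD", GD[m, n] + q[m, T_MM] + t[n, T_DM]),
        ]
        state = max(exits, key=lambda kv: kv[1])[0]
        i, j = m, n

    path: list[tuple[int, int, str]] = []
    while True:
        path.append((i, j, state))
        if state == "MM":
            here = MM[i, j] - coem[i - 1, j - 1]
            if mode == "local" and close(here, 0.0):
                break
            if mode == "global" and i == 1 and j == 1 and close(
                here, q[0, T_MM] + t[0, T_MM]
            ):
                break
            cands = [
                ("MM", MM[i - 1, j - 1] + q[i - 1, T_MM] + t[j - 1, T_MM]),
                ("MI", MI[i - 1, j - 1] + q[i - 1, T_MM] + t[j - 1, T_IM]),
                ("IM", IM[i - 1, j - 1] + q[i - 1, T_IM] + t[j - 1, T_MM]),
                ("DG", DG[i - 1, j - 1] + q[i - 1, T_DM] + t[j - 1, T_MM]),
                ("GD", GD[i - 1, j - 1] + q[i - 1, T_MM] + t[j - 1, T_DM]),
            ]
            state = _pick(cands, here)
            i, j = i - 1, j - 1
            if mode == "global" and i == 0 and j == 0:
                break
        elif state == "MI":
            here = MI[i, j]
            cands = [
                ("MM", MM[i - 1, j] + q[i - 1, T_MM] + t[j, T_MI]),
                ("MI", MI[i - 1, j] + q[i - 1, T_MM] + t[j, T_II]),
            ]
            state = _pick(cands, here)
            i = i - 1
        elif state == "IM":
            here = IM[i, j]
            cands = [
                ("MM", MM[i, j - 1] + q[i, T_MI] + t[j - 1, T_MM]),
                ("IM", IM[i, j - 1] + q[i, T_II] + t[j - 1, T_MM]),
            ]
            state = _pick(cands, here)
            j = j - 1
        elif state == "DG":
            here = DG[i, j]
            cands = [
                ("MM", MM[i - 1, j] + q[i - 1, T_MD]),
                ("DG", DG[i - 1, j] + q[i - 1, T_DD]),
            ]
            state = _pick(cands, here)
            i = i - 1
        else:  # GD
            here = GD[i, j]
            cands = [
                ("MM", MM[i, j - 1] + t[j - 1, T_MD]),
                ("GD", GD[i, j - 1] + t[j - 1, T_DD]),
            ]
            state = _pick(cands, here)
            j = j - 1
        if i == 0 and j == 0:
            break
        if i < 0 or j < 0:  # pragma: no cover - defensive
            raise AlignError("traceback escaped the lattice")
    path.reverse()
    return path


def _pick(cands, target):
    best_state, best_val = max(cands, key=lambda kv: kv[1])
    return best_state
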