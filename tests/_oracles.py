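"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reusing the package's
dynamic programs: path scores are found by exhaustive enumeration,
clustering by full-matrix rescans, so the production implementations can
be checked against slow but obviously-correct code.
"""

import math

import numpy as np
from scipy.special import logsumexp

from coemit.model import (
    T_DD,
    T_DM,
    T_II,
    T_IM,
    T_MD,
    T_MI,
    T_MM,
    default_background,
)

FLOOR_BITS = -16.0
LN2 = math.log(2.0)


def _coem(h1, h2, f):
    """Column co-emission natural-log odds with the -16 bit floor."""
    m, n = h1.length, h2.length
    out = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            s = float(np.sum(h1.match_emissions[i] * h2.match_emissions[j] / f))
            out[i, j] = math.log(s) if s > 0 else FLOOR_BITS * LN2
            out[i, j] = max(out[i, j], FLOOR_BITS * LN2)
    return out


def enumerate_pair_paths(h1, h2, mode):
    """All pair-state alignment paths, fully enumerated.

    Returns (forward_bits, viterbi_bits): log-sum and max over complete
    path scores.  Feasible for models of length <= ~4.
    """
    f = default_background()
    coem = _coem(h1, h2, f)
    with np.errstate(divide="ignore"):
        q = np.log(h1.transitions)
        t = np.log(h2.transitions)
    m, n = h1.length, h2.length
    scores = []

    def moves(i, j, state):
        out = []
        if state in ("MM", "start"):
            if i < m and j < n:
                out.append((i + 1, j + 1, "MM",
                            q[i, T_MM] + t[j, T_MM] + coem[i, j]))
            if i < m:
                out.append((i + 1, j, "MI", q[i, T_MM] + t[j, T_MI]))
                out.append((i + 1, j, "DG", q[i, T_MD]))
            if j < n:
                out.append((i, j + 1, "IM", q[i, T_MI] + t[j, T_MM]))
                out.append((i, j + 1, "GD", t[j, T_MD]))
        elif state == "MI":
            if i < m:
                out.append((i + 1, j, "MI", q[i, T_MM] + t[j, T_II]))
            if i < m and j < n:
                out.append((i + 1, j + 1, "MM",
                            q[i, T_MM] + t[j, T_IM] + coem[i, j]))
        elif state == "IM":
            if j < n:
                out.append((i, j + 1, "IM", q[i, T_II] + t[j, T_MM]))
            if i < m and j < n:
                out.append((i + 1, j + 1, "MM",
                            q[i, T_IM] + t[j, T_MM] + coem[i, j]))
        elif state == "DG":
            if i < m:
                out.append((i + 1, j, "DG", q[i, T_DD]))
            if i < m and j < n:
                out.append((i + 1, j + 1, "MM",
                            q[i, T_DM] + t[j, T_MM] + coem[i, j]))
        else:  # GD
            if j < n:
                out.append((i, j + 1, "GD", t[j, T_DD]))
            if i < m and j < n:
                out.append((i + 1, j + 1, "MM",
                            q[i, T_MM] + t[j, T_DM] + coem[i, j]))
        return [mv for mv in out if np.isfinite(mv[3])]

    if mode == "global":
        exit_w = {
            "MM": q[m, T_MM] + t[n, T_MM],
            "MI": q[m, T_MM] + t[n, T_IM],
            "IM": q[m, T_IM] + t[n, T_MM],
            "DG": q[m, T_DM] + t[n, T_MM],
            "GD": q[m, T_MM] + t[n, T_DM],
        }

        def rec(i, j, state, lp):
            if i == m and j == n and state != "start":
                if np.isfinite(exit_w[state]):
                    scores.append(lp + exit_w[state])
            for ii, jj, ss, w in moves(i, j, state):
                rec(ii, jj, ss, lp + w)

        rec(0, 0, "start", 0.0)
    elif mode == "local":

        def rec(i, j, state, lp):
            if state == "MM":
                scores.append(lp)
            for ii, jj, ss, w in moves(i, j, state):
                rec(ii, jj, ss, lp + w)

        for i in range(m):
            for j in range(n):
                rec(i + 1, j + 1, "MM", coem[i, j])
    else:
        raise ValueError(mode)

    if not scores:
        return -math.inf, -math.inf
    return logsumexp(scores) / LN2, max(scores) / LN2


def naive_upgma_merges(matrix):
    """O(n^3) UPGMA: full rescan for the closest pair at every step.

    Same tie rule as the production code (lexicographically smallest slot
    pair; a merged cluster keeps the smaller slot, i.e. the smallest
    original index among its members).  Returns the merge list
    [(frozenset(member leaves), height), ...] in merge order.
    """
    D = np.array(matrix, dtype=float)
    n = D.shape[0]
    active = list(range(n))
    sizes = {k: 1.0 for k in active}
    members = {k: frozenset([k]) for k in active}
    merges = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                key = (D[i, j], min(i, j), max(i, j))
                if best is None or key < best:
                    best = key
        dist, i, j = best
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (sizes[i] * D[i, k] + sizes[j] * D[j, k]) / (
                sizes[i] + sizes[j]
            )
        members[i] = members[i] | members[j]
        sizes[i] += sizes[j]
        merges.append((members[i], dist / 2.0))
        active.remove(j)
    return merges


def smith_waterman_bruteforce(a, b, S, gap_open, gap_extend):
    """Best local alignment score by exhaustive path enumeration.

    Recursively explores every gapped alignment of every substring pair;
    a gap of length k costs gap_open + (k - 1) * gap_extend.  Feasible
    for sequences of length <= ~6.
    """
    best = 0

    def rec(i, j, score, state):
        nonlocal best
        if state == "M":
            best = max(best, score)
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + S[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if state == "E" else gap_open
            rec(i + 1, j, score - cost, "E")
        if j < len(b):
            cost = gap_extend if state == "F" else gap_open
            rec(i, j + 1, score - cost, "F")

    for i in range(len(a)):
        for j in range(len(b)):
            rec(i, j, 0, "start")
    return best
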