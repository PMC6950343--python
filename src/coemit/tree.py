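"""Distance matrices and O(n^2) UPGMA trees from all-vs-all profile scores.

The all-vs-all simple co-emission scores are turned into distances with
the self-score normalization d(i, j) = 1 - max(0, s_ij) / max(s_ii, s_jj)
(0 for identical models, 1 for unrelated ones) and clustered with UPGMA
(average linkage).  The agglomeration keeps a nearest-neighbour candidate
per cluster, the device MUSCLE and Clustal Omega use to bring the naive
cubic UPGMA down to quadratic work in practice, and resolves ties
deterministically on the smallest original-index pair so that results are
bit-reproducible.  Outputs serialize as square PHYLIP matrices and Newick
trees.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .align import pair_forward, pair_viterbi
from .model import ProfileHMM


class TreeError(ValueError):
    """Invalid distance matrix or tree request."""


# ---------------------------------------------------------------------------
# distance matrix


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal, finite distance matrix with labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise TreeError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise TreeError("duplicate labels in distance matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise TreeError("distances must be finite")
        if np.any(self.matrix < 0):
            raise TreeError("distances must be non-negative")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-9:
            raise TreeError("distance matrix must be symmetric")
        if np.abs(np.diag(self.matrix)).max() > 1e-9:
            raise TreeError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)


def score_to_distance(
    scores: np.ndarray, labels: Sequence[str]
) -> DistanceMatrix:
    """Convert a (possibly incomplete) score matrix to distances.

    d(i, j) = 1 - max(0, s_ij) / max(s_ii, s_jj), clipped to [0, 1];
    the diagonal is zero.  Missing off-diagonal scores (NaN: pairs the
    prefilter skipped) are imputed with the maximum observed distance,
    since skipping signals non-homology and UPGMA needs a complete matrix.
    """
    s = np.asarray(scores, dtype=float)
    n = s.shape[0]
    self_scores = np.diag(s)
    for k in range(n):
        if not np.isfinite(self_scores[k]) or self_scores[k] <= 0:
            raise TreeError(
                f"model {labels[k]!r}: self-score must be positive, got "
                f"{self_scores[k]}"
            )
    denom = np.maximum.outer(self_scores, self_scores)
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.maximum(s, 0.0) / denom
    d = np.clip(d, 0.0, 1.0)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    missing = ~np.isfinite(d)
    if missing.any():
        observed_max = d[~missing].max() if np.isfinite(d).any() else 1.0
        d[missing] = observed_max
    return DistanceMatrix(list(labels), d)


# ---------------------------------------------------------------------------
# all-vs-all scoring


def all_vs_all(
    library: Sequence[ProfileHMM],
    prefilter_config=None,
    mode: str = "local",
    score: str = "forward",
    null: str = "standard",
    pairs: Optional[set] = None,
) -> tuple[list[str], np.ndarray]:
    """Score every pair in a profile library against each other.

    Returns (labels, matrix) with simple co-emission scores in bits;
    entries the prefilter rejected are NaN; the diagonal holds
    self-scores.  ``prefilter_config`` is a
    :class:`coemit.pipeline.PrefilterConfig` (or None for exhaustive
    comparison); ``pairs`` overrides it with an explicit candidate set.
    """
    if len(library) < 2:
        raise TreeError("all-vs-all needs a library of >= 2 models")
    labels = [m.name for m in library]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise TreeError(f"duplicate model names: {dupes}")
    n = len(library)
    if pairs is None:
        if prefilter_config is not None and prefilter_config.mode != "off":
            pairs = prefilter_config.candidate_pairs(library)
        else:
            pairs = {(i, j) for i in range(n) for j in range(n)}
    score_fn = _score_function(score, mode, null)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = score_fn(library[i], library[i])
        for j in range(i + 1, n):
            if (i, j) in pairs or (j, i) in pairs:
                out[i, j] = out[j, i] = score_fn(library[i], library[j])
    return labels, out


def _score_function(score: str, mode: str, null: str) -> Callable:
    if score == "forward":
        return lambda a, b: pair_forward(a, b, mode, null).forward_bits
    if score == "viterbi":
        return lambda a, b: pair_viterbi(a, b, mode, null, trace=False).viterbi_bits
    raise TreeError(f"unknown score variant {score!r}")


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeNode:
    """A node of a rooted ultrametric tree (height above the leaves)."""

    height: float
    label: Optional[str] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class UltrametricTree:
    """A rooted binary UPGMA tree; branch = parent height - child height."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        out: list[str] = []

        def rec(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.label)
            for c in node.children:
                rec(c)

        rec(self.root)
        return out

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (equal for an ultrametric tree)."""
        out: dict[str, float] = {}

        def rec(node: TreeNode, depth: float) -> None:
            if node.is_leaf:
                out[node.label] = depth
            for c in node.children:
                rec(c, depth + (node.height - c.height))

        rec(self.root, 0.0)
        return out

    def merge_heights(self) -> list[float]:
        out = []

        def rec(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node.height)
                for c in node.children:
                    rec(c)

        rec(self.root)
        return out

    def validate(self, tol: float = 1e-9) -> "UltrametricTree":
        depths = list(self.leaf_depths().values())
        if max(depths) - min(depths) > tol:
            raise TreeError("tree is not ultrametric")

        def rec(node: TreeNode) -> None:
            for c in node.children:
                if c.height > node.height + tol:
                    raise TreeError("child height above parent height")
                rec(c)

        rec(self.root)
        return self


def upgma(d: DistanceMatrix) -> UltrametricTree:
    """Average-linkage agglomeration of a distance matrix.

    The distance between clusters is the size-weighted arithmetic mean of
    member distances; each merge creates a node at half the merge
    distance.  A per-cluster nearest-neighbour candidate list keeps total
    work quadratic for typical inputs (the reducibility of average linkage
    guarantees a merge can never create a *closer* neighbour, so only
    clusters whose candidate was consumed — or tied by the new cluster —
    rescan their row).  Ties are broken on the lexicographically smallest
    pair of cluster indices, a cluster inheriting the smallest original
    leaf index among its members.
    """
    n = d.n
    if n < 2:
        raise TreeError("UPGMA needs at least two items")
    D = d.matrix.copy()
    active = list(range(n))
    sizes = np.ones(n)
    nodes = {i: TreeNode(height=0.0, label=d.labels[i]) for i in range(n)}

    def pair_key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def nearest(k: int) -> tuple[float, int]:
        best_dist, best_p = np.inf, -1
        for p in active:
            if p == k:
                continue
            dist = D[k, p]
            if dist < best_dist or (
                dist == best_dist and pair_key(k, p) < pair_key(k, best_p)
            ):
                best_dist, best_p = dist, p
        return best_dist, best_p

    near: dict[int, tuple[float, int]] = {k: nearest(k) for k in active}

    while len(active) > 1:
        s = min(active, key=lambda k: (near[k][0], pair_key(k, near[k][1])))
        dist, p = near[s]
        i, j = pair_key(s, p)
        h = dist / 2.0
        nodes[i] = TreeNode(height=h, children=[nodes[i], nodes[j]])
        del nodes[j]
        # size-weighted average distances to the merged cluster
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = (
                sizes[i] * D[i, k] + sizes[j] * D[j, k]
            ) / (sizes[i] + sizes[j])
        sizes[i] += sizes[j]
        active.remove(j)
        del near[j]
        if len(active) == 1:
            break
        near[i] = nearest(i)
        for k in active:
            if k == i:
                continue
            dist_k, p_k = near[k]
            if p_k in (i, j):
                near[k] = nearest(k)
            elif D[k, i] < dist_k or (
                D[k, i] == dist_k and pair_key(k, i) < pair_key(k, p_k)
            ):
                near[k] = (D[k, i], i)
    (root_slot,) = active
    return UltrametricTree(root=nodes[root_slot]).validate(tol=1e-6)


# ---------------------------------------------------------------------------
# PHYLIP distance matrix I/O


def _sanitize(label: str) -> str:
    clean = re.sub(r"\s", "_", label)
    if clean != label:
        warnings.warn(f"label {label!r} contains whitespace; written as {clean!r}")
    return clean


def write_phylip(d: DistanceMatrix, path_or_stream, strict: bool = False) -> None:
    """Write a square PHYLIP distance matrix.

    Relaxed dialect (default): full-length whitespace-delimited labels.
    Strict dialect: labels truncated/padded to 10 characters, uniqueness
    restored with numeric suffixes.
    """
    labels = [_sanitize(x) for x in d.labels]
    if strict:
        labels = _strict_labels(labels)
    lines = [f"{d.n}"]
    for lab, row in zip(labels, d.matrix):
        if strict:
            lines.append(lab.ljust(10) + "  " + "  ".join(f"{x:.6f}" for x in row))
        else:
            lines.append(f"{lab}  " + "  ".join(f"{x:.6f}" for x in row))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)


def _strict_labels(labels: list[str]) -> list[str]:
    out: list[str] = []
    seen: dict[str, int] = {}
    for lab in labels:
        short = lab[:10]
        if short in seen:
            seen[short] += 1
            suffix = str(seen[short])
            short = short[: 10 - len(suffix)] + suffix
        else:
            seen[short] = 0
        out.append(short)
    return out


def read_phylip(path_or_stream) -> DistanceMatrix:
    """Read a square PHYLIP matrix (relaxed or strict dialect)."""
    if hasattr(path_or_stream, "read"):
        lines = path_or_stream.read().splitlines()
    else:
        with open(path_or_stream) as fh:
            lines = fh.read().splitlines()
    lines = [x for x in lines if x.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        tokens = line.split()
        labels.append(tokens[0])
        rows.append([float(x) for x in tokens[1 : n + 1]])
    return DistanceMatrix(labels, np.array(rows))


# ---------------------------------------------------------------------------
# Newick output

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,\"']")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(t: UltrametricTree, path_or_stream) -> None:
    """Write a Newick tree with 6-significant-digit branch lengths."""

    def fmt(node: TreeNode, parent_height: Optional[float]) -> str:
        if node.is_leaf:
            body = _newick_label(node.label)
        else:
            body = "(" + ",".join(fmt(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.height:.6g}"

    text = fmt(t.root, None) + ";\n"
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)
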