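"""Synthetic protein families with a known phylogeny.

The generator evolves a random root sequence down a Newick guide tree
whose leaves are *families*: per branch, every site substitutes with
probability 1 - exp(-t) (uniform replacement among the other 19
residues) and suffers rare geometric-length indels.  Each family leaf is
then expanded into several sequences by evolving short additional
branches, giving realistic within-family diversity.  A truth table maps
every sequence to its family and tree position so end-to-end tree
reconstruction can be checked against the generating topology.

The substitution process is deliberately uniform (no WAG/LG matrix, no
rate heterogeneity): the fixtures exercise the machinery, not
evolutionary realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .model import (
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
)

#: Four families at ~20% cross-family and ~75% within-family identity.
DEFAULT_GUIDE_TREE = "((fam1:0.9,fam2:0.9):0.35,(fam3:0.9,fam4:0.9):0.35);"

TRUTH_HEADER = ("sequence", "family", "tree_position")


class SimulationError(ValueError):
    """Invalid family specification."""


@dataclass
class FamilySpec:
    """The stated world of the synthetic families.

    ``guide_tree``: Newick with branch lengths, one leaf per family.
    ``root_length``: length of the ancestral sequence (>= 10).
    ``indel_rate``: per-site, per-unit-branch-length indel event rate.
    ``seqs_per_leaf``: sequences sampled from each family.
    ``leaf_branch_length``: extra divergence of each sampled sequence from
    its family ancestor (shallow intra-family branches).
    """

    guide_tree: str = DEFAULT_GUIDE_TREE
    root_length: int = 120
    indel_rate: float = 0.01
    seqs_per_leaf: int = 6
    leaf_branch_length: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 10:
            raise SimulationError("root_length must be >= 10")
        if not 0.0 <= self.indel_rate < 1.0:
            raise SimulationError("indel_rate must be in [0, 1)")
        if self.seqs_per_leaf < 1:
            raise SimulationError("seqs_per_leaf must be >= 1")
        if self.leaf_branch_length < 0:
            raise SimulationError("leaf_branch_length must be >= 0")


def substitution_probability(branch_length: float) -> float:
    """Per-site substitution probability on a branch: 1 - exp(-t)."""
    if branch_length < 0:
        raise SimulationError("branch lengths must be >= 0")
    return 1.0 - float(np.exp(-branch_length))


def _evolve(seq: str, t: float, indel_rate: float, rng: np.random.Generator) -> str:
    p_sub = substitution_probability(t)
    chars = list(seq)
    # substitutions: uniform among the other 19 residues
    for i, c in enumerate(chars):
        if rng.random() < p_sub:
            j = rng.integers(N_AA - 1)
            alt = AMINO_ACIDS.replace(c, "") if c in AMINO_ACIDS else AMINO_ACIDS
            chars[i] = alt[j % len(alt)]
    # indels: rare per-site events, geometric length, 50/50 ins vs del
    p_indel = min(1.0, indel_rate * t)
    if p_indel > 0:
        out = []
        i = 0
        while i < len(chars):
            if rng.random() < p_indel:
                length = int(rng.geometric(0.5))
                if rng.random() < 0.5:  # deletion
                    i += length
                    continue
                ins = rng.choice(list(AMINO_ACIDS), size=length,
                                 p=ROBINSON_BACKGROUND)
                out.extend(ins.tolist())
            out.append(chars[i])
            i += 1
        chars = out if out else chars[:1]
    return "".join(chars)


def simulate_families(
    spec: FamilySpec,
) -> tuple[list[tuple[str, str]], list[tuple[str, str, str]]]:
    """Evolve sequences down the guide tree.

    Returns ``(records, truth)``: FASTA-ready ``(name, sequence)`` pairs
    and truth rows ``(sequence name, family, tree position)``.
    Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    tree = dendropy.Tree.get(data=spec.guide_tree, schema="newick")
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        import warnings

        warnings.warn("guide tree has a single leaf; emitting one family")
    root_seq = "".join(
        rng.choice(list(AMINO_ACIDS), size=spec.root_length,
                   p=ROBINSON_BACKGROUND)
    )
    seqs: dict[int, str] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        seqs[id(node)] = _evolve(seqs[id(node.parent_node)], t,
                                 spec.indel_rate, rng)
    records: list[tuple[str, str]] = []
    truth: list[tuple[str, str, str]] = []
    for leaf in leaves:
        family = leaf.taxon.label.replace(" ", "_") if leaf.taxon else "fam"
        ancestor = seqs[id(leaf)]
        for s in range(1, spec.seqs_per_leaf + 1):
            seq = _evolve(ancestor, spec.leaf_branch_length, spec.indel_rate,
                          rng)
            name = f"{family}_{s:02d}"
            records.append((name, seq))
            truth.append((name, family, family))
    return records, truth


def write_truth_table(truth, path_or_stream) -> None:
    """Tab-separated truth table with a header line."""
    lines = ["\t".join(TRUTH_HEADER)]
    lines += ["\t".join(row) for row in truth]
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)


def write_fasta(records, path_or_stream) -> None:
    text = "".join(f">{name}\n{seq}\n" for name, seq in records)
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# toy profiles for oracle tests


def make_toy_hmms(
    n: int, L: int, seed: int = 0, concentration: float = 0.5
) -> list[ProfileHMM]:
    """Random valid profiles: Dirichlet emissions, sticky transitions.

    Small ``concentration`` gives peaked (informative) match emissions;
    transitions strongly favour match-to-match, as real profiles do.
    """
    if n < 1 or L < 1:
        raise SimulationError("need n >= 1 and L >= 1")
    rng = np.random.default_rng(seed)
    models = []
    for k in range(n):
        match = rng.dirichlet(np.full(N_AA, concentration), size=L)
        insert = np.tile(ROBINSON_BACKGROUND, (L, 1))
        tr = np.zeros((L + 1, 7))
        mmm = rng.dirichlet([16.0, 1.0, 1.0], size=L + 1)
        imi = rng.dirichlet([3.0, 1.0], size=L + 1)
        dmd = rng.dirichlet([3.0, 1.0], size=L + 1)
        tr[:, [T_MM, T_MI, T_MD]] = mmm
        tr[:, [T_IM, T_II]] = imi
        tr[:, [T_DM, T_DD]] = dmd
        # structural constraints of the plan7 layout
        tr[0, T_DM], tr[0, T_DD] = 1.0, 0.0
        tr[L, T_MD] = 0.0
        tr[L, [T_MM, T_MI]] /= tr[L, [T_MM, T_MI]].sum()
        tr[L, T_DM], tr[L, T_DD] = 1.0, 0.0
        models.append(
            ProfileHMM(
                name=f"toy{k:03d}",
                match_emissions=match,
                insert_emissions=insert,
                transitions=tr,
                metadata={"ALPH": "amino"},
            ).validate()
        )
    return models
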