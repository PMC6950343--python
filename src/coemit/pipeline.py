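"""End-to-end workflow: cluster -> align -> build profiles -> tree.

The pipeline mirrors the standard protein-family protocol: sequences are
greedily clustered at an identity threshold (default 70%), each cluster
is aligned, every cluster alignment (and every singleton sequence)
becomes a profile HMM, the profile library is scored all-vs-all by
co-emission, and the resulting distance matrix is clustered into a UPGMA
tree.  External clustering/alignment tools can be swapped in; the
built-in greedy clusterer and center-star aligner keep the pipeline
dependency-free for testing (they are simpler, lower-quality stand-ins
for dedicated tools such as CD-HIT or kalignP/MAFFT).
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from . import alphabet as alphabet_mod
from .align import pair_forward
from .build import BuildParams, Msa, build_hmm, read_fasta_sequences
from .hmmer_io import write_hmmer3
from .model import ProfileHMM
from .tree import (
    DistanceMatrix,
    UltrametricTree,
    all_vs_all,
    score_to_distance,
    upgma,
    write_newick,
    write_phylip,
)

log = logging.getLogger("coemit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PrefilterConfig:
    """How (and whether) to prefilter the all-vs-all comparison.

    ``mode`` is ``off``, ``threshold`` (keep pairs with state-string SW
    score >= value) or ``topN`` (keep each query's best N partners).  The
    column-state alphabet is loaded from ``alphabet_path`` (context
    library format, window 1) or trained from the input library's own
    columns under ``seed``.
    """

    mode: str = "off"
    value: float = 0.0
    k_states: int = alphabet_mod.DEFAULT_K
    seed: int = 0
    gap_open: int = 6
    gap_extend: int = 1
    alphabet_path: Optional[str] = None
    _alphabet: Optional[alphabet_mod.ColumnStateAlphabet] = None

    def resolve_alphabet(
        self, library: Sequence[ProfileHMM]
    ) -> alphabet_mod.ColumnStateAlphabet:
        if self._alphabet is not None:
            return self._alphabet
        if self.alphabet_path:
            self._alphabet = load_alphabet(self.alphabet_path)
            return self._alphabet
        columns = np.vstack([m.match_emissions for m in library])
        k = min(self.k_states, columns.shape[0])
        if k < self.k_states:
            warnings.warn(
                f"library has only {columns.shape[0]} columns; training a "
                f"{k}-state alphabet instead of {self.k_states}"
            )
        self._alphabet = alphabet_mod.train_alphabet(columns, K=k, seed=self.seed)
        return self._alphabet

    def candidate_pairs(self, library: Sequence[ProfileHMM]) -> set:
        alpha = self.resolve_alphabet(library)
        seqs = [alphabet_mod.discretize(m, alpha) for m in library]
        return alphabet_mod.prefilter_pairs(
            seqs, alpha, self.mode, self.value, self.gap_open, self.gap_extend
        )


def load_alphabet(path) -> alphabet_mod.ColumnStateAlphabet:
    """Load a column-state alphabet from a window-1 context-library file."""
    from .build import read_context_library

    lib = read_context_library(path)
    if lib.window_length != 1:
        raise PipelineError("alphabet file must have window length 1")
    profiles = lib.windows[:, 0, :]
    matrix = alphabet_mod.state_substitution_matrix(
        profiles, alphabet_mod.default_background()
    )
    return alphabet_mod.ColumnStateAlphabet(profiles, matrix)


@dataclass
class PipelineConfig:
    """All pipeline knobs; see the YAML mirror in the CLI."""

    identity: float = 0.70
    pseudocount_mode: str = "substitution"
    prefilter: PrefilterConfig = field(default_factory=PrefilterConfig)
    score: str = "forward"
    mode: str = "local"
    distance: str = "selfnorm"
    aligner: str = "center_star"
    seed: int = 0
    build: BuildParams = field(default_factory=BuildParams)

    def __post_init__(self) -> None:
        if not 0.0 < self.identity <= 1.0:
            raise PipelineError(f"identity must be in (0, 1], got {self.identity}")
        for value, options in (
            (self.pseudocount_mode, ("none", "substitution", "context")),
            (self.score, ("forward", "viterbi")),
            (self.mode, ("local", "global")),
            (self.distance, tuple(DISTANCE_TRANSFORMS)),
            (self.aligner, ("center_star", "mafft")),
            (self.prefilter.mode, ("off", "threshold", "topN")),
        ):
            if value not in options:
                raise PipelineError(f"{value!r} not one of {options}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pf = PrefilterConfig(**raw.pop("prefilter", {}))
        build = BuildParams(**raw.pop("build", {}))
        return cls(prefilter=pf, build=build, **raw)


#: Pluggable score-to-distance transforms.
DISTANCE_TRANSFORMS = {"selfnorm": score_to_distance}


# ---------------------------------------------------------------------------
# greedy clustering


_aligner = None


def _global_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _aligner = a
    return _aligner


def pairwise_identity(seq1: str, seq2: str) -> tuple[float, tuple[str, str]]:
    """Global-alignment identity: matches / alignment length.

    Returns the identity and the pair of gapped aligned strings.
    """
    seq1 = _safe(seq1)
    seq2 = _safe(seq2)
    aln = _global_aligner().align(seq1, seq2)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a), (a, b)


def _safe(seq: str) -> str:
    # BLOSUM62 in biopython covers the 20 residues plus B/Z/X/*; map rare
    # symbols to X so alignment never fails.
    allowed = set("ACDEFGHIKLMNPQRSTVWYBZX")
    return "".join(c if c in allowed else "X" for c in seq.upper())


def greedy_cluster(
    sequences: Sequence[tuple[str, str]], identity: float = 0.70
) -> tuple[list[list[tuple[str, str]]], list[tuple[str, str]]]:
    """Incremental greedy clustering at a global-identity threshold.

    Sequences are visited by decreasing length (name as tie-break); each
    joins the first cluster whose founder it matches at >= identity, else
    founds its own.  Returns (clusters with >= 2 members, singletons).
    """
    if not sequences:
        raise PipelineError("greedy_cluster: no sequences")
    order = sorted(sequences, key=lambda ns: (-len(ns[1]), ns[0]))
    clusters: list[list[tuple[str, str]]] = []
    for name, seq in order:
        placed = False
        for cluster in clusters:
            ident, _ = pairwise_identity(cluster[0][1], seq)
            if ident >= identity:
                cluster.append((name, seq))
                placed = True
                break
        if not placed:
            clusters.append([(name, seq)])
    multi = [c for c in clusters if len(c) >= 2]
    singletons = [c[0] for c in clusters if len(c) == 1]
    return multi, singletons


# ---------------------------------------------------------------------------
# center-star alignment (internal fallback aligner)


def center_star_align(members: Sequence[tuple[str, str]]) -> Msa:
    """Progressive center-star alignment around the cluster founder.

    Every member is globally aligned to the founder; insertions relative
    to the founder are merged by padding.  A simple testing-grade stand-in
    for a real multiple aligner.
    """
    names = [n for n, _ in members]
    seqs = [s for _, s in members]
    if len(members) == 1:
        return Msa(names, seqs)
    center = seqs[0]
    m = len(center)
    # per-member: insertions before center position k (k = m means trailing)
    member_parts: list[list[str]] = []
    max_ins = [0] * (m + 1)
    for seq in seqs[1:]:
        _, (ca, sa) = pairwise_identity(center, seq)
        parts = [""] * (m + 1)  # residues of seq opposite center pos k
        aligned = [""] * m  # residue (or -) opposite center residue k
        k = 0
        for x, y in zip(ca, sa):
            if x == "-":
                parts[k] += y
            else:
                aligned[k] = y
                k += 1
        member_parts.append(parts + aligned)
        for k in range(m + 1):
            max_ins[k] = max(max_ins[k], len(parts[k]))

    def build_row(parts, aligned) -> str:
        out = []
        for k in range(m):
            out.append(parts[k].ljust(max_ins[k], "-"))
            out.append(aligned[k])
        out.append(parts[m].ljust(max_ins[m], "-"))
        return "".join(out)

    rows = [build_row([""] * (m + 1), list(center))]
    for rec in member_parts:
        rows.append(build_row(rec[: m + 1], rec[m + 1 :]))
    return Msa(names, rows)


def mafft_align(members: Sequence[tuple[str, str]]) -> Msa:
    """Align a cluster with an external ``mafft`` executable (optional hook)."""
    if shutil.which("mafft") is None:
        raise PipelineError("mafft requested but not found on PATH")
    if len(members) == 1:
        return Msa([members[0][0]], [members[0][1]])
    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        for name, seq in members:
            fh.write(f">{name}\n{seq}\n")
        tmp = fh.name
    try:
        out = subprocess.run(
            ["mafft", "--quiet", "--auto", tmp],
            capture_output=True, text=True, check=True,
        ).stdout
    finally:
        Path(tmp).unlink(missing_ok=True)
    import io

    return Msa.from_fasta(io.StringIO(out))


_ALIGNERS = {"center_star": center_star_align, "mafft": mafft_align}


# ---------------------------------------------------------------------------
# the pipeline itself


@dataclass
class PipelineResult:
    library: list[ProfileHMM]
    clusters: list[list[tuple[str, str]]]
    singletons: list[tuple[str, str]]
    scores: Optional[np.ndarray]
    distances: Optional[DistanceMatrix]
    tree: Optional[UltrametricTree]
    outdir: Path
    manifest: dict


def build_library(
    clusters: Sequence[Sequence[tuple[str, str]]],
    singletons: Sequence[tuple[str, str]],
    config: PipelineConfig,
    context_library=None,
) -> tuple[list[ProfileHMM], list[Msa]]:
    """Profiles for every cluster alignment and every singleton sequence."""
    align_fn = _ALIGNERS[config.aligner]
    models: list[ProfileHMM] = []
    msas: list[Msa] = []
    for idx, cluster in enumerate(clusters, start=1):
        try:
            msa = align_fn(cluster)
            msas.append(msa)
            models.append(
                build_hmm(
                    msa,
                    config.pseudocount_mode,
                    context_library,
                    config.build,
                    name=f"cluster{idx:04d}",
                )
            )
        except Exception as exc:
            raise PipelineError(
                f"stage build-hmms failed on cluster {idx} "
                f"(founder {cluster[0][0]!r}): {exc}"
            ) from exc
    for name, seq in singletons:
        try:
            models.append(
                build_hmm(
                    Msa.from_sequence(name, seq),
                    config.pseudocount_mode,
                    context_library,
                    config.build,
                    name=name,
                )
            )
        except Exception as exc:
            raise PipelineError(
                f"stage build-hmms failed on singleton {name!r}: {exc}"
            ) from exc
    return models, msas


def run_pipeline(
    config: PipelineConfig,
    input_fasta,
    outdir,
    context_library=None,
) -> PipelineResult:
    """Run the full workflow and write every stage artifact to ``outdir``.

    Artifacts: per-cluster MSA FASTA files, the profile library
    (``library.hmm``), the raw score matrix (TSV), the PHYLIP distance
    matrix, the Newick UPGMA tree and a YAML run manifest with per-stage
    counts.  Tree building is skipped (with a log message) when the
    library holds fewer than two profiles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences = read_fasta_sequences(input_fasta)
    if not sequences:
        raise PipelineError("stage input: no sequences in input FASTA")
    log.info("input: %d sequences", len(sequences))

    clusters, singletons = greedy_cluster(sequences, config.identity)
    log.info("cluster: %d clusters, %d singletons", len(clusters), len(singletons))

    models, msas = build_library(clusters, singletons, config, context_library)
    msa_dir = outdir / "msas"
    msa_dir.mkdir(exist_ok=True)
    for idx, msa in enumerate(msas, start=1):
        with open(msa_dir / f"cluster{idx:04d}.afa", "w") as fh:
            for name, row in zip(msa.names, msa.rows):
                fh.write(f">{name}\n{row}\n")
    write_hmmer3(models, outdir / "library.hmm")
    log.info("build-hmms: %d profiles", len(models))

    manifest = {
        "sequences": len(sequences),
        "clusters": len(clusters),
        "singletons": len(singletons),
        "hmms": len(models),
        "config": _config_dict(config),
    }

    scores = distances = tree = None
    if len(models) >= 2:
        labels, scores = all_vs_all(
            models, config.prefilter, config.mode, config.score
        )
        n_scored = int(np.isfinite(scores).sum() - len(models)) // 2
        n_skipped = (len(models) * (len(models) - 1)) // 2 - n_scored
        log.info("allvsall: %d pairs scored, %d prefiltered away",
                 n_scored, n_skipped)
        manifest["pairs_scored"] = n_scored
        manifest["pairs_prefiltered"] = n_skipped
        _write_scores(labels, scores, outdir / "scores.tsv")
        distances = DISTANCE_TRANSFORMS[config.distance](scores, labels)
        write_phylip(distances, outdir / "distances.phylip")
        tree = upgma(distances)
        write_newick(tree, outdir / "tree.nwk")
        log.info("tree: %d leaves", len(tree.leaf_labels()))
    else:
        log.info("tree building skipped: need >= 2 profiles, have %d",
                 len(models))
        manifest["tree_skipped"] = "fewer than two profiles"

    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return PipelineResult(
        library=models, clusters=clusters, singletons=singletons,
        scores=scores, distances=distances, tree=tree, outdir=outdir,
        manifest=manifest,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["build"].pop("background", None)
    d["prefilter"].pop("_alphabet", None)
    return d


def _write_scores(labels, scores, path) -> None:
    with open(path, "w") as fh:
        fh.write("query\ttarget\tbits\n")
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if j < i:
                    continue
                value = scores[i, j]
                text = "NA" if not np.isfinite(value) else f"{value:.6f}"
                fh.write(f"{a}\t{b}\t{text}\n")


# ---------------------------------------------------------------------------
# classification of new sequences


@dataclass
class ClassifyResult:
    """Ranked library hits for a query, plus the best hit's tree clade."""

    query: str
    hits: list[tuple[str, float]]  # (model name, forward bits), descending
    best: str
    clade: list[str]  # leaves of the best hit's parent clade (if tree given)


def classify(
    query,
    library: Sequence[ProfileHMM],
    tree: Optional[UltrametricTree] = None,
    config: Optional[PipelineConfig] = None,
) -> ClassifyResult:
    """Score a query (sequence tuple or profile) against a profile library.

    Returns hits ranked by local forward co-emission bits and, when a
    tree is supplied, the leaf set of the clade containing the best hit.
    """
    if not library:
        raise PipelineError("classify: empty profile library")
    config = config or PipelineConfig()
    if isinstance(query, ProfileHMM):
        qmodel = query
    else:
        name, seq = query
        qmodel = build_hmm(
            Msa.from_sequence(name, seq),
            config.pseudocount_mode if config.pseudocount_mode != "context"
            else "substitution",
            None,
            config.build,
            name=name,
        )
    hits = sorted(
        (
            (m.name, pair_forward(qmodel, m, config.mode).forward_bits)
            for m in library
        ),
        key=lambda kv: (-kv[1], kv[0]),
    )
    best = hits[0][0]
    clade: list[str] = [best]
    if tree is not None:
        clade = _sibling_clade(tree, best)
    return ClassifyResult(query=qmodel.name, hits=hits, best=best, clade=clade)


def _sibling_clade(tree: UltrametricTree, leaf: str) -> list[str]:
    """Leaves under the parent of the named leaf."""

    def rec(node):
        if node.is_leaf:
            return None
        for child in node.children:
            if child.is_leaf and child.label == leaf:
                return node
            found = rec(child)
            if found is not None:
                return found
        return None

    parent = rec(tree.root)
    if parent is None:
        return [leaf]
    out: list[str] = []

    def collect(node):
        if node.is_leaf:
            out.append(node.label)
        for c in node.children:
            collect(c)

    collect(parent)
    return out
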