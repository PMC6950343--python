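# Methods

This note documents the models and numerical choices behind `coemit`:
what is computed, which knobs matter, and what the synthetic-data tests
do and do not establish.

## Profile HMM representation

A profile of length L holds L match-emission rows, L insert-emission
rows (kept at the background composition; inserts are never co-emitted
by default), and (L+1)×7 transition probabilities in the order
M→M, M→I, M→D, I→M, I→I, D→M, D→D, with row 0 the BEGIN node and row L
the exit row. Serialization uses the HMMER3 text format (dialects 3/b
through 3/f read, 3/f written; 5-decimal negative natural logs, `*` for
probability zero). Round-tripping is exact to well below 1e-9 because a
5-decimal log value re-encodes to itself; the format's own quantization
means parsed emission rows sum to 1 only within ~1e-5, so the parser
validates at 1e-4.

The null model is the Robinson & Robinson amino-acid composition by
default. HMMER3 files carry no explicit null; when a file provides a
COMPO (average composition) line it is stored and can be selected with
`null="compo"` in the scoring functions, which then uses the mean of the
two models' compositions. The default is the fixed standard table so
that scores do not depend on which pair is being compared.

## Profile construction

- **Match columns**: gap fraction < 0.5 (the standard convention; the
  threshold is a parameter).
- **Sequence weights**: position-based Henikoff weights, normalized to
  sum to one, so duplicated sequences share one sequence's weight and an
  alignment of n identical rows builds exactly the single-sequence
  model.
- **Effective sequence number**: N_eff = exp(mean per-column Shannon
  entropy of the weighted frequencies) — 1.0 for a single sequence,
  growing with diversity. A `unique` row-count mode is available.
- **Emission pseudocounts**: admixture τ = min(1, c/N_eff) with c = 1 by
  default (τ can be fixed explicitly). `substitution` mode mixes in
  g(a) = Σ_b f_obs(b) P(a|b), with P(a|b) reconstructed from BLOSUM62
  half-bit scores and the background (q_ab ∝ f_a f_b 2^{S/2}). For a
  single sequence τ = 1 and the match row becomes the BLOSUM conditional
  of the observed residue — the standard single-sequence profile.
- **Transition smoothing**: weighted transition counts receive peaked
  plan7-style Dirichlet prior counts (match 0.7939/0.0278/0.0135, insert
  0.1551/0.1331, delete 0.9002/0.5630). A flat Laplace prior is
  available but *not* the default: with one observed sequence a flat
  prior yields t(M→M) ≈ 0.6, i.e. about −1.5 bits of transition cost per
  aligned column, which drowns the co-emission signal entirely (measured:
  within-family and between-family library scores become
  indistinguishable, 16.5 vs 15.6 bits; with the peaked prior they
  separate at 97 vs 20 bits).
- **Trace repair**: inserts cannot neighbour deletes in the plan7
  topology; the rare illegal contexts in an input alignment are
  attributed through M, the usual simplification.

### Context-specific pseudocounts

A context library holds K contexts: a prior, a w×20 window profile
(w odd), and a pseudocount emission vector. For each column the count
neighbourhood (edges padded with background) is scored against every
context with a *linearized* Bayes rule: the responsibility of context k
is its prior times the mean likelihood ratio
Σ_{j,a} ĉ(j,a)·p_k(j,a)/f(a). This equals the exact posterior when the
window holds a single observation, stays well defined for fractional
counts (a product-form likelihood degenerates on point-mass windows),
and is linear in the observed frequencies. The pseudocount vector is the
responsibility-weighted mixture of the contexts' emission vectors.

The emission vector defaults to the window's central column but is kept
as a separate field: the window-1 library with point-mass windows,
background priors and BLOSUM-conditional emissions then reproduces
substitution-matrix pseudocounts *exactly* (this equivalence is a unit
test). With emissions hard-wired to the central column that reduction is
impossible for any responsibility rule — matching against a profile and
emitting the same profile always applies the substitution operator
twice. Libraries can be read/written in a plain text format
(`K w`, then per context one prior line and w probability rows) and a
small library can be trained by k-means over profile windows.

## Column-state alphabet and prefilter

Profile columns are clustered by k-means after a square-root transform
(Hellinger geometry; centroids are squared back and renormalized), K =
219 by default. Note the K = 1 centroid is therefore the *Hellinger*
mean of the columns, not the arithmetic mean. The state-level
substitution matrix is S(a,b) = round(scale·log2 Σ_x p_a(x)p_b(x)/f(x))
at scale 2, floored at round(scale·(−16)) for orthogonal states.
Discretization assigns each match column its argmax co-emission state
(ties to the lowest index). Candidate pairs are selected by
Smith-Waterman over state strings with affine gaps (open 6, extend 1, in
matrix units; a k-gap costs open + (k−1)·extend), either by score
threshold or per-query top-N; self pairs are always kept and the kept
set is symmetrized. Pairs the prefilter rejects are assigned the maximum
observed distance (missingness signals non-homology; UPGMA needs a
complete matrix). The alphabet is trained from the input library's own
columns under a fixed seed, or loaded from a window-1 context-library
file, so no external alphabet download is required. SIMD striping is a
performance detail of other implementations; here the contract is the
exact Smith-Waterman score, verified against exhaustive enumeration.

## Pair alignment

The five-state recursion is evaluated in natural-log space, row by row,
with numpy ufunc accumulations for the within-row insert/delete chains
(`logaddexp.accumulate` / `maximum.accumulate` on prefix-sum-transformed
values; the scan restarts at zero-probability extension weights both for
correctness and conditioning). Impossible states carry a −1e30 sentinel
rather than −inf so no NaNs arise. Local mode allows free entry and exit
at any MM cell; global mode anchors paths at the model ends through the
BEGIN/END transitions. Forward and Viterbi differ only in the semiring.
Scores are reported in bits. Both programs agree with exhaustive path
enumeration to 1e-9 bits on fuzzed models of length ≤ 3, are symmetric
in their arguments to 1e-9, and remain finite for models of length 2000.
Whether the "simple" score is forward or Viterbi is a configuration
choice; forward (local) is the default used for trees, since summing
over alignments is the more stable similarity for distantly related
profiles. A reverse-model normalization (score minus score against the
position-reversed partner) is available to cancel composition bias.

## Distances and UPGMA

d(i,j) = 1 − max(0, s_ij)/max(s_ii, s_jj), clipped to [0,1]; the
transform is pluggable (`DISTANCE_TRANSFORMS`) so an alternative formula
can be dropped in without touching the tree builder. UPGMA uses
size-weighted average linkage with one nearest-neighbour candidate per
cluster; reducibility of average linkage guarantees a merge never
creates a closer neighbour, so only clusters whose candidate was
consumed (or tied by the new cluster) rescan a row — quadratic total
work in practice. Ties break on the lexicographically smallest pair of
cluster indices, a cluster inheriting the smallest original leaf index
among its members; this makes the algorithm bit-identical to a naive
full-rescan implementation (tested on 200 random matrices, ties forced)
and makes degenerate all-equal inputs resolve to the index-ordered
caterpillar deterministically. Merge height is half the merge distance,
so trees are ultrametric by construction (validated to 1e-9 in tests).
PHYLIP square matrices are written in a relaxed full-label dialect by
default, with a strict 10-character dialect (uniqueness suffixes) behind
a flag; Newick output carries 6-significant-digit branch lengths and
quotes labels containing structural characters.

## Pipeline

Greedy clustering visits sequences by decreasing length and joins the
first cluster whose founder matches at ≥ identity (global BLOSUM62
alignment, identity = matches/alignment-length; default threshold 0.70).
Clusters are aligned center-star around the founder — a deliberately
simple internal aligner, adequate for testing and for the shallow
(≥ 70% identity) clusters this stage produces; an external `mafft` hook
can be configured for production alignments. Each cluster alignment and
each singleton becomes one profile; the library is scored all-vs-all
(optionally prefiltered) and clustered into the UPGMA tree. All stage
artifacts (per-cluster MSAs, HMMER3 library, score TSV, PHYLIP matrix,
Newick tree, YAML manifest with per-stage counts) are written to the
output directory; outputs contain no timestamps, so a rerun with the
same seed is byte-identical. Classification scores a query sequence
(built into a single-sequence profile) or profile against the library
and reports ranked forward-bit hits plus the best hit's clade in the
tree.

## Synthetic data

The fixture generator evolves a random root sequence (Robinson
composition, default length 120) down a Newick guide tree: per branch of
length t each site substitutes with probability 1 − e^(−t) (uniform
among the other 19 residues) and suffers rare indels (per-site event
rate 0.01·t, geometric length, mean 2). Each family leaf expands into 6
sequences via extra branches of length 0.25. The default guide tree
`((fam1:0.9,fam2:0.9):0.35,(fam3:0.9,fam4:0.9):0.35)` puts within-family
identity at ~55–65% — just below the 70% clustering threshold, matching
the regime of real superfamily datasets where a large fraction of
sequences remain singletons — and between-family identity at ~15–20%,
near the random-collision baseline. The generator is deliberately
simple: uniform substitution (no WAG/LG), no rate heterogeneity, no
domain architecture. A green end-to-end test therefore establishes that
the machinery recovers a clean, clock-like four-family phylogeny; it
says nothing about performance under rate variation, heterotachy or
alignment error.

## Known limitations

- The score-to-distance transform is the self-score normalization
  described above; other profile-tree tools may use a different formula,
  so trees are comparable in topology but not guaranteed bit-identical
  to theirs.
- Insert emissions are excluded from co-emission by design; there is no
  switch yet to include them.
- E-value calibration of pair scores is out of scope; scores are raw
  bits.
- The center-star aligner is a testing-grade fallback, not a substitute
  for a real MSA tool.
- Greedy clustering computes founder alignments with quadratic cost in
  library size; it is meant for 10^2–10^3 sequences, not 10^5.
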