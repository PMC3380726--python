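# Methods

## Model and procedure

`phenomod` identifies cellular subsystems associated with a binary organism
phenotype by comparative network analysis at the orthologous-group (COG)
level. The underlying assumptions are:

* Functional associations (STRING-style scored edges) approximate shared
  pathway or complex membership; a score cutoff selects trustworthy edges.
* Orthology (the protein → COG map) makes edges comparable across
  organisms; an association between COGs u and v exists in an organism as
  soon as *any* protein pair (x ∈ u, y ∈ v) is associated (existential
  semantics — appropriate because association evidence is sparse and
  false-negative-prone, so requiring all protein pairs would be far too
  strict).
* A subsystem contributing to a phenotype should be conserved across
  *several* expressing organisms — but not necessarily all of them, because
  phenotypes have alternative routes (sub-phenotypes). Biclusters capture
  this: any organism subset of size ≥ 2 may support a module.
* Conservation alone is not evidence of phenotype relevance (it may reflect
  shared ancestry or housekeeping functions); hence the two statistical
  filters — the cross-class hypergeometric bias and the density null.

Pipeline: project each network to COG level → build the binary
organisms × COG-pairs incidence matrix for the expressing class → enumerate
all inclusion-maximal biclusters (≥ 2 organisms) → score each bicluster's
bias against the non-expressing class and keep bias ≤ α₁ → split each
retained COG edge set into connected components → keep components whose
density beats the Monte Carlo random-subset null at α₂.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `score_cutoff` | 700 | STRING "high confidence" combined score (0–1000). |
| `min_orgs` | 2 | conservation floor; two organisms is the weakest meaningful notion of "conserved". |
| `min_pairs` | 1 | column floor for biclusters; 1 admits trivial two-COG modules, which the density filter then judges. |
| `bias_alpha` | 0.05 | hypergeometric bias cutoff. |
| `bias_mode` | `point` | the bias statistic is the hypergeometric *point* probability C(S,Y)C(P−S,X−Y)/C(P,X); `tail` gives the conventional upper-tail enrichment p-value. The point mass is the default because it is the statistic as defined; note it is not a tail probability, so its null distribution is not uniform. |
| `bias_correction` | `none` | raw cutoff by default; `bh` applies Benjamini–Hochberg across the bicluster batch. |
| `mc_samples` (W) | 1000 | Monte Carlo draws per module; resolution of the empirical p-value is 1/W. |
| `mc_alpha` | 0.05 | density-significance cutoff. |
| `mc_subset_size_rule` | `nodes` | random subsets have the module's node count \|V\|; `edges` draws \|E\|-sized subsets instead (see Open choices). |
| `mc_background` | `expressing` | null-model edge set: union of expressing-class COG networks (`all` adds the non-expressing ones). |
| `mc_universe` | `mapping` | the COG universe M sampled from: every COG named by the mapping (plus any incident to edges); `incident` restricts M to COGs touching the background edge set. |
| `seed` | 0 | master seed; per-module generator streams are spawned from (seed, module index) so module order cannot perturb results. |

## Statistics

**Bias.** For a bicluster conserved in Y of the S expressing organisms and
X organisms overall (P total), Y is exactly the bicluster's organism count
— maximality guarantees no further expressing organism contains all its
pairs — and X = Y plus the number of non-expressing organisms containing
every pair (computed on the non-expressing incidence matrix).
Hypergeometric probabilities are evaluated through scipy's log-space
implementation and clamped to [0, 1]; the test suite certifies them to
< 1e−10 relative error against exact rational arithmetic.

**Density null.** A module S = (V, E) has density β = 2|E|/(|V|(|V|−1)).
W random subsets of size |V| are drawn uniformly without replacement from
M; each is scored by the density its members induce in the background
graph (a disconnected or edgeless subset scores 0, a subset of < 2 nodes
scores 0). p = R/W with ties (density equal to β) counted in R, exactly as
defined — no +1 pseudo-count is added, so p = 0 can occur at finite W and
is flagged "< 1/W" in the output rather than altered. An exhaustive
enumerator over all C(|M|, |V|) subsets provides the exact reference for
small universes and is used to calibrate the sampler (agreement within 3
binomial standard errors).

## Algorithms and numerical choices

* **Bicluster enumeration.** Inclusion-maximal all-ones submatrices are the
  formal concepts of the binary incidence relation. Because the organism
  side is small (panels of tens of organisms), we enumerate closed organism
  sets: the per-column support sets are closed under intersection (pruning
  below `min_orgs`, which is safe since intersections only shrink), each
  closed extent's intent is the AND of its rows, and each concept is
  emitted once from its own closed extent. This is provably complete and
  certified in tests against an exponential column-subset oracle (and a
  row-subset oracle). Enumeration refuses to emit more than
  `max_biclusters` (default 100 000) results with a hard error — silent
  truncation would bias everything downstream; tighten the floors instead.
* **Determinism.** Biclusters are ordered by descending organism count,
  then descending pair count, then lexicographic pair list; components by
  descending node count then smallest node; modules by size then node
  list. All randomness flows from the master seed through named
  SeedSequence streams. Two runs with identical inputs and seed produce
  byte-identical output tables.
* **Degenerate inputs.** Self protein edges and within-COG (paralog)
  associations are dropped — a self-pair cannot contribute to density as
  defined. Unmapped proteins drop their edges with a logged count. An
  empty network after score filtering is a warning, not an error; a panel
  without non-expressing organisms is allowed (X = Y). Conflicting COG
  assignments in the mapping are a hard error naming the proteins.
* **Tie tolerance.** Sampled densities are exact multiples of
  2/(k(k−1)); the ≥ comparison uses a 1e−12 epsilon purely to guard float
  representation of those rationals.

## Open choices made

* **Subset size for the null: |V| (default).** The two natural readings —
  "same number of nodes" vs "|E| COGs" — disagree whenever β ≠ 1. We draw
  node-count-sized subsets because the statistic compared is a density over
  node sets; the |E| reading remains available (`mc_subset_size_rule=edges`).
* **The universe M: the mapping's full COG set (default).** The null asks
  "how dense would a random same-size COG set be?"; restricting M to COGs
  that already have edges conditions the null on the observed graph and, in
  sparse panels, can shrink M to the module itself, making every module
  trivially non-significant. The `incident` option provides that stricter,
  graph-conditioned null for users who want it.
* **Background edges: expressing-class union (default).** The modules are
  mined from the expressing class, so that union is the space their density
  should be compared in; `all` includes non-expressing edges.
* **Bias statistic: point mass (default), tail optional** — see table.

## Synthetic panels: what they do and do not show

The generator emulates the pipeline's three inputs for a panel with a known
ground truth: a COG universe, independent per-organism Bernoulli background
COG edges, and planted modules (fixed COG edge sets) inserted into chosen
numbers of expressing/non-expressing carriers; COG edges are rendered as
protein-level edges between randomly chosen member proteins (default 2
proteins per COG, so the many-to-one projection is exercised), with planted
scores ≥ 900 and background scores in [701, 1000].

Defaults describe the benchmark condition used throughout the tests: 10+10
organisms, 30 COGs, background probability 0.02, one planted 5-COG/6-edge
module (a 5-cycle plus a chord, density 0.6) in 8 expressing and 1
non-expressing carrier — giving conservation counts (P, S, X, Y) =
(20, 10, 9, 8) and point bias C(10,8)·C(10,1)/C(20,9) ≈ 2.68 × 10⁻³.

Deliberately *not* modelled: phylogenetic correlation between organisms
(background edges are independent, so conserved-by-ancestry false positives
cannot arise here), realistic STRING score distributions or evidence
channels, COG-size variation, and missing-data structure. Passing the
recovery tests therefore shows the machinery is correct on its own model,
not that real panels are free of phylogenetic confounding — for real data
the organism selection still matters.

## Problem sizes

Tests and the acceptance script run on deliberately small instances chosen
to keep exhaustive oracles exact and runs quick: 8×12 matrices for
enumeration cross-checks, P ≤ 30 for the exact hypergeometric comparison,
|M| = 12 with W = 10 000 for Monte Carlo calibration, and the 20-organism
benchmark panel for end-to-end recovery. The implementation itself is
sparse-matrix- and bitset-based and comfortably handles panels of tens of
organisms with tens of thousands of COG pairs.

## Known limitations

* Exact (all-ones) biclusters only: one missing edge in one organism
  splits or shrinks a module; no quasi-biclique relaxation is provided.
* The bicluster count can grow exponentially in pathological dense
  matrices; the hard `max_biclusters` cap surfaces this instead of hiding it.
* The point-mass bias is not a tail p-value; users wanting conventional
  enrichment semantics should use `bias_mode=tail`.
* No phylogenetic-diversity weighting of organism panels and no COG
  functional annotation; module COG lists are meant to be joined against
  external description tables.
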