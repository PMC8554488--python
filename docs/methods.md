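# Methods

## The optimization model

The integration step is a Prize-Collecting Steiner Forest. Nodes of an
undirected interactome carry nonnegative prizes p(v) encoding
experimental evidence; edges carry confidences s ∈ (0, 1] mapped to
costs c(e) = 1 − s, floored at 10⁻⁶ so a perfectly confident edge is
still not free. The solver maximizes

    f(F) = β·Σ_{v∈V_F} p(v) − Σ_{e∈E_F} c′(e) − ω·κ

over forests F, where κ is the number of trees. The per-tree term is
equivalent to a rooted construction in which a virtual root v0 is joined
to every node by an edge of cost ω and each tree attaches to v0 through
exactly one root edge. Two readings of the ω term are possible — a
per-tree bonus or a per-tree cost — and only the cost reading is
consistent with the root construction (a bonus would reward shattering
the solution into singletons); the penalty form is therefore the
default, with `Hyperparameters(omega_sign="bonus")` kept as a comparison
switch.

Hub bias is controlled by regularizing edge costs with the node degrees
d_a, d_b in an interactome of N nodes:

    c′(e) = c(e) + α·(d_a·d_b) / ((N−d_a−1)(N−d_b−1) + d_a·d_b)

The penalty lies in [0, α], increases monotonically in each degree, and
equals α exactly when either endpoint has full degree N−1.

### Solver

Within any fixed node subset V the optimal edge choice decomposes:
starting from all-singleton trees, merging two components through an
edge of cost c changes f by (ω − c), so a Kruskal sweep accepting merges
only when c < ω yields the optimal forest on V (greedy exchange on the
graphic matroid). The heuristic therefore searches over node subsets
only: deterministic starts (empty set, all prized nodes) plus seeded
random subsets of the prized nodes, each improved by best-improvement
single-node toggles and, at local optima, pair toggles that rescue
two-step Steiner structures. Ties in objective break toward the
lexicographically smallest sorted node tuple, making solutions
bit-reproducible for a given seed. An exhaustive-enumeration solver
(`brute_force_pcsf`, capped at 14 nodes) provides the independent
optimum; the test suite requires objective equality on 200 random
instances with ≤ 10 nodes spanning β ∈ {0.5, 1, 2}, ω ∈ {0.05, 0.5},
α ∈ {0, 1}.

### Ensembles and parameter selection

- **Robustness**: each replicate multiplies every base edge cost by
  exp(Normal(0, noise_sd)) — multiplicative log-normal noise, sd
  default 0.3 — recomputes the degree penalty on top, re-solves, and
  records the solution nodes. The top_k most frequent nodes are kept
  (ties: higher prize, then lexicographic) and nodes with no interactome
  edge to another selected node are dropped. Library defaults are
  reps = 100 and top_k = 400, the scale used on full interactomes; the
  desk-scale tests use reps = 20 and top_k equal to the planted module
  size on the 300-node synthetic bundle, which keeps the whole
  20-seed recovery suite under half a minute.
- **Specificity**: each replicate places the multiset of prize values on
  uniformly random nodes and re-solves; a node that appears regardless
  of where the prizes sit (typically a hub) is structurally favored, so
  high frequency means low specificity.
- **Grid selection** applies three criteria to each hyperparameter
  setting: the solution must not retain 100% of the prized nodes
  (feature selection), its nodes' mean random-prize frequency must be
  ≤ 0.3, and the two-sample Kolmogorov–Smirnov distance between the
  degree distributions of solution nodes and prized nodes must be
  ≤ 0.2. Among passing settings the largest retained-prize fraction
  wins; failures return per-criterion diagnostics rather than raising.

### Prize mappings

The prize functional forms are simple monotone encodings of evidence
strength and are pluggable: protein prize = |log2FC| for proteins
significant at FDR < 0.1; TF prize = min(1, −log10(enrichment FDR)/10).
Forcing a node (used for a disease gene undetected by proteomics)
assigns it 10× the current maximum prize; calling it twice multiplies
again relative to the new maximum, by declared semantics. Prizes are not
normalized before β-scaling; β itself absorbs the overall scale.

## Transcription-factor inference

Peaks are assigned to the nearest TSS by midpoint distance (coordinates
0-based half-open, BED convention; the choice of midpoint is ours — only
the 2.5 kb promoter and 50 kb assignment windows are given), with
equidistant ties going to the lexicographically smaller gene id. CpG
content uses the observed/expected ratio (#CG·L)/(#C·#G) with a high/low
cutoff of 0.6; the metric in the original workflow was taken from an
external reference without a printed formula, so this standard o/e ratio
is a documented stand-in and both metric and cutoff are configurable.
PWM scanning scores windows by Σ log2(p_pos(base)/background(base)) on
both strands, overlapping hits counted separately, windows containing N
never hitting; the default hit threshold is 80% of the consensus score.
Enrichment is at peak level — a peak is a binary hit if it has ≥ 1
window above threshold — so the one-sided hypergeometric is over peaks,
not positions (the position-level alternative was the other defensible
reading). Both ±10 kb and ±50 kb DEG windows are supported for
foreground construction, with 10 kb the default. A TF is predicted
active in the condition whose peak class gives its motif the smallest
enrichment p (ties: more foreground hits, then the ALS class), and the
prediction is concordant when the TF transcript moves the same way.

## Statistics

- Overlap tests are one-sided (enrichment) by construction:
  `hypergeom_upper` is the exact upper tail P(X ≥ k), and
  `fisher_overlap` conditions on both margins. Both are validated
  against exhaustive draw enumeration for backgrounds ≤ 12.
- Empirical p-values count strict exceedances b of the observed
  statistic among R null replicates. Two conventions are emitted,
  because published empirical bounds are often loose: the plain
  exceedance fraction b/R with a "<(b+1)/R" bound string, and the
  conservative (b+1)/(R+1), which can never be zero.
- The sign-consistency test is a two-sided normal-approximation sign
  test, z = (n_same − n/2)/√(n/4), no continuity correction; an exact
  binomial oracle is exposed alongside and the suite checks the
  approximation stays within a factor of 3 of it at moderate n.
- The built-in differential caller (`simple_de`) is a Welch t-test per
  gene on log2 counts-per-million with a 0.5 offset, with BH q-values.
  It is deliberately simple: the permutation machinery it drives
  (condition-label shuffles of the DEG count, subnet-overlap nulls) is
  agnostic to the plugged-in caller, and a negative-binomial GLM caller
  can be substituted without touching that machinery. Likewise log-CPM
  stands in for voom-style normalization throughout.
- Variant–expression association is per-pair OLS of normalized
  expression on genotype dosage, reporting the slope,
  adjusted R² = 1 − (1−R²)(n−1)/(n−2), the slope t-test p, and BH
  q-values across the tested family; constant-genotype pairs are flagged
  untestable and excluded from the family.

## Fly screen and concordant paths

Per-fly scores within a biological replicate are averaged, replicate
means are averaged, and the result is rounded to the nearest 0.5 — half
cases away from zero (the rounding direction at exact halves was
unspecified). Any lethal replicate makes the record lethal. Human-gene
scores are DIOPT-weighted averages over high- and moderate-rank
orthologs only. Modifier calls use the ±1 threshold with suppressor =
score ≤ −1 (the rescue end of the −4…+4 scale) and enhancer = ≥ +1; the
magnitude is stated in the source workflow, the sign convention is our
reading of "−4 = complete rescue". Classification crosses protein
direction with the call: (up, suppressor) and (down, enhancer) are
causal; (up, enhancer) and (down, suppressor) are compensatory; "none"
is non-contributory. The lethal/non-modifier experiment filter consumes
per-record boolean flags (the driver-only control criterion that marks
non-modifiers is external and not quantified, so it arrives as data).

The concordant-path network enumerates, for every ordered pair of
causal/compensatory genes, simple directed paths with at most two edges.
A path is discarded if any intermediate node is outside the expressed
set (top 70% of mean normalized expression, ties at the cutoff all
included) or if any edge is sign-discordant: an activating edge predicts
its target moves with its source, an inhibiting edge predicts the
opposite, and predictions are checked against measured protein
directions. Path endpoints are exempt from the expression filter — they
are measured proteins — a choice the source leaves open; nodes lacking
a measured direction drop the paths through them and are counted in a
report. The builder is verified against exhaustive filtered enumeration
on 200 random signed digraphs of up to 30 nodes.

## Synthetic data

Defaults describe a desk-scale study in the spirit of the measured one:
4 samples per condition (the study had 3–4 lines per arm), 1000 genes,
a 300-node preferential-attachment interactome (complete seed graph on
m nodes, m = 2 distinct attachments per arrival, hence exactly
m(n−m)+C(m,2) edges — the skewed degree distribution exercises the hub
penalty), a 15-node planted module grown by random BFS (connectivity
guaranteed by construction) with folded-normal prizes
|N(5, 1.25)|, edge confidences U(0.3, 0.95), NB counts with dispersion
0.1 and a 10% DE fraction with truncated-normal log2FC (|lfc| ≥ 0.25 so
"differential" is unambiguous), 200 peaks of 200 bp with a planted
8-mer motif at rate 0.8 in differential peaks and a never-planted decoy
motif, CpG bimodality via a Markov chain with P(G|C) = 0.45 (island-like)
vs 0.03 (depleted), genotypes from Binomial(2, maf) with maf ~ U(0.1,
0.5) and one in ten variants linked to a gene at effect 1.5 on log-CPM
expression, and a fly screen with 15%/10% causal/compensatory genes at
base scores ∓2 and replicate noise sd 0.15. Effect sizes are
calibration choices — the study publishes no effect-size distributions —
chosen so that planted structure is comfortably detectable at these
sample sizes; they are fixed in `SyntheticConfig` defaults.

All randomness flows from one root seed; each stage hashes
"seed:stage-name" (SHA-256, first four bytes, mod 2³¹) into its own
sub-seed, so bundles are pure functions of the config and stages can be
regenerated in isolation.

What the generators do **not** emulate: read-level sequencing artifacts,
linkage disequilibrium between variants, protein missingness mechanisms,
correlated gene–gene expression structure, GC-matched backgrounds, or
the true density of pathway databases. Passing tests therefore
demonstrate correctness of the algorithms and calibration of the
statistics under the stated generative models — not performance on real
cohorts, where signal-to-noise is far less favorable.

## Numerical choices and limitations

- Objective comparisons in the solver use a 10⁻¹² slack; reported
  objectives are reproducible to relative 10⁻⁹ across runs.
- Tie-breaks are lexicographic after the stated keys everywhere
  (subset choice, top-k selection, TSS assignment, TF class choice), so
  every deterministic stage is bit-reproducible.
- Degenerate inputs: empty forests score 0; an empty gene list leaves a
  peak unassigned rather than erroring; missing peak sequences and
  missing protein directions are reported, not fatal; α = 0 bypasses
  the degree-penalty domain checks (the penalty is identically zero).
- The local-search solver is a heuristic: equality with the exact
  optimum is verified only at small scale, and on large instances with
  ω comparable to typical edge costs it can in principle land in local
  optima; more restarts (`n_restarts`) trade time for quality.
- The brute-force solver is exponential and guarded at 14 nodes.
- The umbrella pipeline runs on synthetic bundles; external datasets go
  through the per-stage CLI commands with the documented TSV/BED/FASTA/
  JASPAR schemas.
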