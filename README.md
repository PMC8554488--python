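# omicsforest

Network integration of multi-omic measurements from disease-model
cultures — built around the analysis style used for C9ORF72 ALS
iPSC-derived motor neurons, where transcriptomics, proteomics and
chromatin accessibility from a handful of patient and control lines must
be combined into coherent, statistically defensible pathway hypotheses.

The package is aimed at computational biologists who want the full
chain as tested, reusable code:

1. **Transcription-factor inference** — ATAC peaks annotated to the
   nearest TSS (promoter = within 2.5 kb, assignable up to 50 kb),
   partitioned by CpG observed/expected ratio, scanned with PWMs, and
   tested for motif enrichment by a one-sided hypergeometric test of
   hit-peaks in foreground vs background, with RNA-concordance calls per
   TF.
2. **Prize-collecting Steiner forest (PCSF) integration** — differential
   proteins and inferred TFs become prized nodes on a confidence-weighted
   interactome, and the solver seeks a forest F(V_F, E_F) maximizing

   f(F) = β·Σ_{v∈V_F} p(v) − Σ_{e∈E_F} c′(e) − ω·κ

   with degree-regularized edge costs

   c′(e) = c(e) + α·(d_a·d_b)/((N−d_a−1)(N−d_b−1) + d_a·d_b)

   plus noise-robustness and random-prize specificity ensembles, a
   three-criterion hyperparameter grid selector, and forced inclusion of
   a disease gene missing from the proteomics.
3. **Validation statistics** — overlap enrichment on assay-intersection
   backgrounds (hypergeometric / Fisher), empirical p-values from
   randomized-input networks and condition-label permutations, the
   sign-consistency test between replicate cultures, fold-change
   correlations, and per-pair variant–expression regression with
   Benjamini–Hochberg control.
4. **Fly-screen causal/compensatory network** — rough-eye modifier
   scores (−4 complete rescue … +4 no eye) averaged and rounded to the
   half-point, aggregated to human genes by DIOPT-weighted means,
   crossed with protein direction to label genes causal, compensatory or
   non-contributory, and connected through signed directed pathway edges
   by sign-concordant paths of at most two steps.

A first-class synthetic-data module generates every input with planted
ground truth (scale-free interactome with a planted prized module,
negative-binomial counts, peak sequences with planted motifs and bimodal
CpG, genotypes with planted eQTLs, a fly screen with planted labels), so
the whole pipeline is testable end to end without any downloads.

## Worked example

```python
from omicsforest.synthetic import SyntheticConfig, build_bundle
from omicsforest.pcsf import Hyperparameters, solve_pcsf, robustness_ensemble
from omicsforest.stats import sign_consistency_test

bundle = build_bundle(SyntheticConfig(seed=1))      # 300-node interactome,
params = Hyperparameters(beta=1.0, omega=0.1,        # planted 15-node module
                         alpha=1.0, reps=20, top_k=15)
forest = solve_pcsf(bundle.interactome, bundle.prizes, params, seed=1)
print(len(forest.nodes), round(forest.objective, 2))

summary = robustness_ensemble(bundle.interactome, bundle.prizes, params, seed=1)
truth = bundle.truth["module_nodes"]
sel = set(summary.selected)
print(round(len(sel & truth) / len(sel | truth), 2))

print(f"{sign_consistency_test(133, 40):.1e}")
```

prints

```
15 65.92
1.0
1.5e-12
```

i.e. the solver keeps exactly the 15 planted prized nodes (objective
65.92 = β-scaled prize mass minus edge and tree-opening costs), the
robustness-selected set
recovers the planted module at Jaccard 1.0, and 133 same-direction vs 40
opposite-direction proteins give a two-sided sign-test p of 1.5×10⁻¹².

The same stages are available from a shell:

```sh
omicsforest simulate --seed 1 --out bundle
omicsforest pcsf --interactome bundle/interactome.tsv --prizes bundle/prizes.tsv \
    --beta 1 --omega 0.1 --alpha 1 --out forest.json
omicsforest run --seed 1 --out full_run     # whole pipeline + manifest
```

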