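# phasecore

Density-dependent phase polyphenism — the switch between a crowded
*gregarious* (G) and an isolated *solitary* (S) phenotype, classically
studied in locusts — leaves transcriptional traces across developmental
stages, tissues and phase-transition time courses.  The hard part of
finding the *core* signature is that stage, tissue and time are far
stronger sources of expression variation than phase itself.  `phasecore`
is a tested, reusable implementation of an integrative pipeline for this
problem, aimed at computational biologists who want to run or stress-test
the method on their own (or simulated) multi-design expression compendia.

## What it computes

1. **Confounder-adjusted PCA.**  For a preprocessed samples x genes matrix
   `X` and replicate groups encoding the confounder design, the leading
   loading maximizes `v'X'Xv - lambda * sum_g ||H_g X v||^2` — captured
   variance minus within-replicate-group projection scatter.  PC1 then
   separates phase where ordinary PCA tracks stage/tissue/time.  Includes
   lambda tuning and sign-based phase prediction for new samples.
2. **Directional Borda aggregation.**  Per-dataset PC1 rankings are
   aggregated by median rank, run once gregarious-top and once
   solitary-top, and merged alternately; the top 10% is the core
   ("PhaseCore") gene set.  Leave-one-out and cross-dataset validation
   over gene bins quantify how deep the signal runs.
3. **Gene features.**  Specificity index tau, CpG observed/expected ratio,
   gene-body methylation summaries, topological-overlap (TOM) network
   connectivity, the Audic-Claverie no-replicate differential test and
   phase-related-gene calls, plus rank-bin trend summaries.
4. **Ensemble regulatory network.**  Six TF->target scorers (CLR, ARACNE,
   TOM, tree importance, shrinkage partial correlation, K-means/BIC module
   surrogate) aggregated by Borda median, with promiscuous-target
   filtering, per-TF networks, and hypergeometric "PhaseCoreTF" enrichment
   with BH adjustment.
5. **Behavioral classifier.**  The published logistic model
   `P_greg = expit(-2.11 + 0.005*AI + 0.012*TDM + 0.015*TDMV)` scoring how
   gregarious an individual's arena behavior is, with Mann-Whitney group
   comparisons.
6. **Synthetic studies.**  A generator emulating the three study designs
   (development 6x2, tissue 8x2, time course 2x2x6 with a converged final
   time point) with planted core genes, a planted TF network, sequences,
   methylation tables and behavior records — so the whole pipeline is
   testable without any downloads.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from phasecore import SimulationConfig, simulate_studies
from phasecore.pipeline import study_core_genes, pooled_normalized_matrix, \
    score_all_methods, edge_auroc
from phasecore.trn import ensemble_network

study = simulate_studies(SimulationConfig(seed=1))   # 2,000 genes, 52 samples
merged, core = study_core_genes(study, fraction=0.10)
truth = set(study.truth_core.index)
print(f"core recovery: {len(truth & set(core)) / len(truth):.3f}")

X = pooled_normalized_matrix(study)
mats = score_all_methods(X, study.tf_ids, seed=7)
net = ensemble_network(mats, top_k_per_method=5000, top_k_final=5000)
agg = net.aggregate.set_index(["tf", "target"])["agg_rank"]
print(f"ensemble AUROC: "
      f"{edge_auroc(agg, study.truth_edges, study.tf_ids, X.columns):.3f}")
```

Output:

```
core recovery: 0.855
ensemble AUROC: 0.833
```

85.5% of the 200 planted phase-biased genes land in the top-10%
directional Borda list even though the confounder effect is five times the
phase effect, and the Borda ensemble of six network scorers recovers the
planted 1,000-edge TF network with AUROC 0.83 — above the median single
method (0.71).

A command-line interface mirrors the library
(`phasecore simulate / preprocess / acpca / rank / features / trn /
enrich / behavior`); run `phasecore --help`.

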