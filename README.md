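# fcnet

Graph analysis of stimulus-driven functional connectivity, with a
planted-effect cohort simulator for end-to-end validation.

Functional MRI studies of mild traumatic brain injury (mTBI) increasingly
summarize how injury reorganizes cortical networks: per-subject timeseries
are correlated node-by-node, thresholded into binary graphs, and compared
between groups through graph measures of integration and segregation.
`fcnet` packages that workflow for researchers who want to run it — or
stress-test it — without access to clinical data: a synthetic cohort
generator plants known group effects in stochastic-block-model graphs, and
the full pipeline (correlation → FDR thresholding → network metrics →
mixed-model inference) is validated by recovering them.

## The model in brief

For each recording (subject × viewing condition × movie clip) with
timeseries matrix X (n nodes × T timepoints):

1. **Correlation graph.** Pearson r_ij for all pairs; two-sided p from
   t = r√((T−2)/(1−r²)); Benjamini–Hochberg step-up over the n(n−1)/2
   p-values at q\* = 0.001; survivors become edges of a binary undirected
   graph G.
2. **Network measures.** Mean degree D(G); global efficiency
   E = (1/(n(n−1))) Σ_{i≠j} 1/d_{ij}; Newman modularity
   Q = (1/2k) Σ_{ij} (A_ij − d_i d_j/2k) δ(r_i, r_j) over the fixed
   parcellation partition; average clustering C̄. The same battery runs on
   induced subgraphs per processing stream (early / ventral / dorsal /
   fronto-parietal) and, for efficiency, per region.
3. **Group inference.** Per metric and scope, a linear mixed model
   `value ~ group * movie` with per-subject random intercepts; the group
   coefficient β_tbi (mTBI − control) is the readout, BH-adjusted across
   stream and region families.

The simulator plants the hypothesized injury signature — higher
within-region density (degree, clustering ↑), more between-region mixing
(efficiency ↑, modularity ↓), with early visual areas spared — and the
pipeline is expected to recover exactly that sign pattern. See
`docs/methods.md` for the generative model and its deliberate limitations.

## Worked example

Run the whole pipeline on a freshly simulated default cohort (17 patients,
54 controls, 2 conditions × 2 clips, 400 nodes):

```python
from fcnet import fit_group_model
from fcnet.pipeline import cohort_metric_table, default_config

cfg = default_config(seed=1)
table, retained = cohort_metric_table(cfg, scopes=("global", "streams"))
print(f"retained {100 * retained['proportion_retained'].mean():.2f}% of pairs")
for metric in ("mean_degree", "efficiency", "modularity", "clustering"):
    res = fit_group_model(table, metric, "global")
    print(f"{metric:12s} beta_tbi={res.beta_tbi:+.4f}  p={res.p_raw:.2g}")
```

prints (numbers from this exact invocation):

```
retained 0.38% of pairs
mean_degree  beta_tbi=+0.0511  p=0.21
efficiency   beta_tbi=+0.0003  p=0.1
modularity   beta_tbi=-0.0049  p=0.00034
clustering   beta_tbi=+0.0084  p=0.26
```

β_tbi is the model's estimate of how much the metric shifts in the mTBI
group: here patients come out denser (positive degree and clustering),
better integrated (positive efficiency) and less modular (negative
modularity) — the planted pattern. Any single cohort is noisy (only
modularity clears p < 0.05 in this draw); the acceptance study below
repeats this over many cohorts.

The same analysis is scriptable from the shell:

```bash
fcnet run-all --outdir out --seed 1          # or: fcnet simulate / connect / metrics / stats
```

which writes the cohort (`out/cohort/`), per-recording edge lists
(`out/graphs/`), the long-format metric table (`out/metrics.tsv`) and the
effect table (`out/results.tsv`), every file stamped with a config hash so
stages refuse mismatched artifacts.

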