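# Methods

`fcnet` re-implements, as a tested and reusable pipeline, a graph analysis
of stimulus-driven functional connectivity: per-recording Pearson
correlation graphs from BOLD-like timeseries, FDR-thresholded binarization,
four network measures on whole graphs and parcellation-defined subgraphs,
and Group × Movie mixed factorial inference. Because the clinical fMRI data
this style of analysis is applied to is not publicly available, the package
ships a synthetic cohort generator with *planted*, known group effects;
every downstream stage is validated by recovering what was planted.

## The analysis model

**From timeseries to graphs.** A recording is a nodes × timepoints matrix
(T = 120 by default, matching a typical retained-volume count after scanner
equilibration). For each of the m = n(n−1)/2 node pairs the sample
product-moment correlation r_ij is tested with the parametric transform
t = r√((T−2)/(1−r²)) against a two-sided Student t with T−2 degrees of
freedom. The Benjamini–Hochberg step-up procedure at level q\* = 0.001
(Benjamini–Yekutieli available as an option) is applied to the m
upper-triangle p-values; surviving pairs become edges of a binary,
undirected, simple graph. Edge sign is ignored by default — thresholding is
on significance, not direction — and a `positive_only` switch restricts
edges to positive correlations. Constant (zero-variance) node series are
flagged and can never form edges.

**Network measures.** On a graph G = (V, E) with |V| = n, |E| = k and
adjacency A:

* mean degree D(G) = (1/n) Σ_i d(v_i) — overall connectivity;
* global efficiency E_global = (1/(n(n−1))) Σ_{i≠j} 1/d_{i,j}, with hop
  distances d_{i,j} from per-source breadth-first search and unreachable
  pairs contributing 0 — integration;
* Newman modularity Q = (1/2k) Σ_{i,j} (A_ij − d_i d_j / 2k) δ(r_i, r_j)
  against the *fixed* parcellation partition (region labels by default,
  streams as an option; no community detection is performed) — segregation;
* average clustering C̄, where C_i is the fraction of ordered neighbour
  pairs of v_i that are themselves connected; C_i := 0 for degree < 2
  (an `exclude_low_degree` switch drops such nodes from the average
  instead) — local cohesiveness.

Q is undefined on an edgeless graph and is reported as absent rather than
coerced to 0. Subgraph ("subnetwork") analysis restricts the graph to the
nodes of one stream or one region, keeping exactly the edges of the full
graph that join retained nodes. Per stream the battery reports degree,
efficiency, clustering, and — to mirror the reported analyses even though
modularity inside a subnetwork is conceptually strained — modularity of the
region partition restricted to that stream. Per region only efficiency is
reported.

**Group inference.** Each metric at each scope is modelled as
`value ~ group + movie + group:movie` with a per-subject random intercept
(movie is within-subject), fit by REML, treatment coding with control/2D
reference. β_tbi — the mTBI-minus-control offset — is the primary readout;
Wald two-sided p-values are reported. A short warm-started BFGS polish pass
tightens REML convergence so that in the balanced case the Wald F for the
group main effect reproduces the classical two-way mixed-ANOVA F
essentially to machine precision (verified in the test suite). Clips are
averaged within subject × condition before fitting (`clip_handling:
replicate` keeps them as repeated rows instead). β_tbi p-values are BH
adjusted within families — the four stream scopes of each metric form one
family, the region-efficiency scopes another — while global-scope tests are
reported unadjusted, mirroring how a primary whole-graph analysis is
usually presented.

## The synthetic cohort generator

The generator targets the statistical structure the analysis assumes, not
fMRI physics: no hemodynamic response, no autocorrelated noise, no motion,
no surface geometry. What it does emulate:

* an unbalanced cohort, 17 patients vs. 54 controls;
* a 2-level within-subject stimulus factor (2D/3D) with two clips per
  condition → 4 recordings per subject, 284 recordings per cohort;
* a visual-cortex style parcellation — retinotopic areas × two hemispheres,
  50 regions of 8 nodes (400 nodes), grouped into early, ventral, dorsal
  and fronto-parietal streams. The large early areas (V1–V3) are
  subdivided into foveal/peripheral eccentricity bands, reflecting their
  greater cortical extent, so the early stream holds roughly half the
  nodes (24 of 50 regions);
* community structure aligned with the parcellation: each recording draws a
  stochastic block model graph with within-region edge probability 0.93 and
  between-region probability 10⁻⁴. Real surface-sampled BOLD is spatially
  smooth, so same-area node pairs are very strongly correlated — hence the
  near-clique regions;
* planted effects as probability increments: patients +0.065 on
  within-region pairs (density → degree and clustering up) and +0.0002 on
  between-region pairs (mixing → efficiency up, modularity down); the 3D
  condition adds +0.0001 globally (a stimulus main effect, no interaction
  planted). Patient increments are suppressed on any pair touching the
  early stream, planting the "effects outside early visual areas" pattern
  as ground truth.

**Timeseries model.** Given a planted adjacency A, timepoints are i.i.d.
draws from N(0, Σ) with Σ = snr·A + c·I (snr = 10). Adjacent pairs then
have population correlation snr/c and non-adjacent pairs exactly zero, so
sample correlation concentrates edges on the planted graph — the simplest
generative model under which the analysis is consistent.

The loading c must make Σ positive definite, i.e. c ≥ snr·(−λ_min(A)).
Using each recording's own minimal loading would make c — and with it every
edge's correlation — covary with planted density: denser (patient) graphs
would be *harder* to detect, biasing group contrasts toward the wrong sign.
The generator therefore computes one **design-level loading floor**: the
maximum loading requirement over a fixed-seed set of draws from all four
group × condition cells, plus a pad. Every recording of every replicate
cohort of that design shares this floor (the rare realization exceeding it
falls back to its own minimal loading, which keeps Σ valid). Direct calls
to `graph_to_timeseries` without a floor use the per-graph minimal loading.

**Why detection is partial.** Bernoulli block graphs with near-clique
regions have λ_min ≈ −2 to −3, driven by local defects: a clique missing a
matching contributes −2, a node bridging several cliques ≈ −2.3,
independent of block size. This caps the attainable edge correlation at
snr/c ≈ 0.33–0.40, while the q\* = 0.001 step-up over ~80 000 pairs at
T = 120 needs r ≈ 0.36+ — the operating point is partial detection (about
a fifth to a quarter of planted edges), uniform across groups because the
loading is shared. Group contrasts survive because detection thins the
planted graph evenly; the retained proportion (~0.4% of pairs at desk
scale) is much lower than in real-BOLD studies, whose inter-node
correlations are far stronger than this covariance model can produce.

**Reproducibility.** All randomness derives from `numpy` SeedSequence
substreams keyed by (subject index, condition index, clip index) under one
master seed, so cohorts are bit-reproducible and enlarging a cohort never
perturbs earlier subjects' data. The loading floor ignores the master seed
(replicate cohorts of one design share the signal scaling). The CLI stamps
every output with a hash of the scientific configuration and refuses to mix
artifacts across hashes.

## Numerical choices

* p-values via `scipy.special.stdtr` (direct incomplete-beta evaluation);
  exact |r| = 1 pairs get p = 0; series whose standard deviation is at
  rounding-error scale (≤ 10⁻¹² of their magnitude) are treated as
  constant.
* Efficiency runs BFS from every source in batches (default 256 sources),
  never materializing a dense n × n distance matrix; a 5%-dense
  2 000-node graph is handled comfortably.
* BH ties: the step-up rule is applied to a stable sort, so exactly tied
  p-values share one rejection decision.
* Degenerate inputs: zero-variance responses yield a flagged degenerate
  fit (zero effects, p = 1) rather than an optimizer failure; scopes whose
  rows are undefined for some recordings (e.g. modularity of an edgeless
  subgraph) are skipped with a warning; single-group tables are refused.

## Problem sizes used by the test suite

Simulation-backed checks run at sizes chosen to make their statistical
claims decisive while keeping the suite quick: metric oracles on 200 random
graphs (n ≤ 12) against Floyd–Warshall / double-loop / triple-enumeration
references at 10⁻¹² tolerance; FDR behaviour on 1 000 random p-value sets
plus 60 null recordings; type-I calibration on 200 reduced cohorts
(10 + 20 subjects, 40 nodes); planted-sign recovery on 50 full default
cohorts; end-to-end byte-level determinism on a compact configuration.

## What passing tests do and do not show

Recovery of planted effects demonstrates that the pipeline's statistics
faithfully propagate group differences of the kind hypothesized — density,
integration, segregation — through thresholding and graph summaries. It
does not validate the generative model against real BOLD data: real
functional connectivity has heavy-tailed, spatially structured correlations,
autocorrelated noise and inter-subject registration error, none of which
are modelled. Conclusions about real cohorts still require real data.

## Known limitations

* The covariance construction cannot reach the correlation strengths of
  real BOLD, so desk-scale retained proportions sit well below the 5–10%
  typical of empirical studies.
* Per-recording adaptive FDR couples detection mildly across the whole
  graph: a genuinely denser graph eases the threshold everywhere, leaking
  a small apparent effect even into spared (null) subnetworks. This is a
  property of the analysis itself, visible here because the ground truth
  is known.
* Wald p-values use the normal reference; at very small cohort sizes they
  are mildly anticonservative (covered by the calibration test's band).
* Weighted graphs, partial correlation, dynamic connectivity and rewired
  null models are out of scope.
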