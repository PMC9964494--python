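# Methods

## Network model

A subject's structural connectome is an undirected weighted graph on the 116
AAL regions: `w_ij` is the streamline count between regions *i* and *j*, an
edge exists wherever `w_ij > 0` (no count threshold is applied), the diagonal
is zero and the matrix is symmetric to 1e-9 (larger asymmetry is treated as a
corrupted export and rejected). Node order everywhere is the label-list
order; outputs report 1-based indices with region names.

## Metric definitions and conventions

Edge length is the reciprocal weight `1/w_ij`; shortest path lengths `L_ij`
are exact (Dijkstra from every source via `scipy.sparse.csgraph`; lengths are
nonnegative so the greedy search is exact). Where a verbal "fewest edges"
reading of the shortest path might be entertained, the weighted
minimum-total-length definition is used — it is the only one consistent with
the efficiency formulas.

- `S_p` — mean `L_ij` over ordered reachable pairs. Unreachable pairs are
  *excluded* from the average and an explicit `disconnected` flag is set, so
  partial connectivity can never silently bias the mean. An edgeless graph
  raises.
- `E_glob`, `E_nodal` — mean of `1/L_ij`; unreachable pairs contribute 0
  (Latora–Marchiori convention). `E_nodal_i = 0` exactly when node *i* is
  isolated.
- Nodal shortest path — mean `L_ij` over reachable partners; NaN sentinel
  for an isolated node.
- `C_p(i)` — geometric-mean triangle intensity over scaled weights,
  `C_p(i) = 2/(k_i(k_i−1)) Σ_{j<k} (ŵ_ij ŵ_ik ŵ_jk)^{1/3}`. The scaling
  mean in `ŵ = w/mean(w)` is taken over **nonzero** off-diagonal weights with
  each undirected edge counted once; including structural zeros would make
  `C_p` depend on network size in a way the weighted-clustering literature
  does not intend. Nodes with `k_i < 2` get `C_p(i) = 0` and stay in the
  global average (`C_p = mean_i C_p(i)`), matching common toolbox behaviour.
  With uniform weights this reduces exactly to the binary clustering
  coefficient (tested).
- Scale laws (tested to 1e-12): multiplying all weights by `a > 0` scales
  efficiencies by `a`, path lengths by `1/a`, and leaves every `C_p(i)` and
  sigma unchanged.

## Small-world sigma

`σ = (C_p/C̄_p^rand) / (S_p/S̄_p^rand)` with the reference means taken over an
ensemble of random networks (default 100; tests and the acceptance script use
10–50 to keep runtimes in minutes — results are means, so the ensemble size
only affects Monte-Carlo error, not bias). References are built by
Maslov–Sneppen double-edge swaps (default 10 swaps per edge) on the binary
topology, preserving every node's degree exactly; the original nonzero-weight
multiset is then reassigned to the randomized edges uniformly at random.
Degree-plus-weight-multiset preservation is the weakest null sufficient for
the sigma ratio; strength-preserving reassignment would be a stricter
alternative and is deliberately not the default. A reference that comes out
disconnected (undefined `S_p`) or triangle-free (degenerate `C_p` ratio) is
re-drawn, at most 10 times, then errors. On near-complete graphs few or no
legal swaps exist; the achieved partial rewiring still preserves degrees and
is used as-is. All replicates derive from `(seed, replicate index)` so sigma
is bit-reproducible.

## Group inference

"Controlling gender and age" is implemented as pooled-sample OLS
residualization of each metric on intercept + age + gender, followed by a
pooled-variance two-sample t on the residuals and a label-permutation null
(default 10,000 relabelings sampled uniformly with independent draws;
duplicates allowed). The two-sided p uses add-one smoothing,
`p = (1 + #{|t*| ≥ |t|})/(1 + n_perm)`, so sampled permutations never return
p = 0. Freedman–Lane-style permutation of residuals under the reduced model
would be the main alternative; plain residualization was chosen as the
simplest scheme consistent with a label-permutation null. A constant
covariate column (e.g. single-gender cohort) is dropped with a warning
rather than failing.

FDR is Benjamini–Hochberg (via `statsmodels`), applied separately to the
global family — all 4 of `S_p`, `E_glob`, `C_p`, sigma, sigma included even
though its raw p is often reported unadjusted elsewhere — and to each nodal
metric's 116-node family. Reported group means/SDs are on the raw metric
scale (the t is on residuals), with the sign convention patients − controls.

Demographics use the standard tests: Pearson χ² (optionally Yates-corrected)
for 2×2 tables, Student/Welch t for normal continuous variables,
Mann–Whitney U with midrank ties and tie-corrected normal z otherwise, and
Pearson r with the t-transform p for correlations.

## Classification

Per global metric, a logistic model `group ~ metric + age + gender` is fit by
IRLS (predictors standardized internally; convergence when the largest
coefficient step < 1e-8, cap 100 iterations; coefficients reported on the
original scale). Perfect separation is flagged and standardized coefficients
capped at ±30 instead of diverging — permutation replicates may separate even
when the observed fit does not. The ROC curve sweeps all distinct fitted
probabilities; the AUROC is computed by the Mann–Whitney pair-counting
identity (ties count half). The operating point maximizes Youden's
J = sensitivity + specificity − 1, ties broken toward higher sensitivity.
AUROC significance permutes *only* the label vector — covariates stay
attached to their subjects — refits the full model each time, and counts
strictly greater permuted AUROCs without smoothing, so p = 0 is possible by
construction; this exact counting rule is kept because it is the convention
the pipeline is meant to reproduce.

## Synthetic cohorts

The generator emulates what the analysis assumes about real streamline
networks, not the biophysics: 116 nodes in 8 near-equal modules, Bernoulli
edges (within-module 0.45, between-module 0.08 → density ≈ 0.12, comfortably
connected, no isolated nodes), integer weights from a log-normal
(log-mean 2.0, log-SD 1.0, floored at 1) giving the heavy right tail typical
of streamline counts. The patient effect acts on weights only:
between-module weights × `effect_between` (default 1.115), within-module
weights × `effect_within` (default 0.90). This raises patients' global
efficiency, shortens their paths and lowers their clustering simultaneously —
the qualitative triple the pipeline must detect. `effect_between` was set by
the package's own bisection calibration (`calibrate_effect`) so the realized
Cohen's d on `E_glob` is ≈ 0.5, the magnitude of the anchor case–control
contrast; the acceptance script re-measures it (0.50 at 250 subjects/group,
seed 1).

Covariates: ages are group-specific normals truncated to the 18–60 inclusion
window (means 34.09/36.88, SDs 9.55/9.82); gender is Bernoulli (male
probability 29/81 patients, 14/48 controls); PDSS is normal (12.28, 2.68)
truncated above the inclusion floor of 7, patients only; HAMD is a truncated
normal (9, 4) on [0, 17] for patients and 0 for controls; illness duration is
log-normal with median 12 months and log-SD 1.54 (matching quartiles of
roughly 4 and 34 months).

What the generator does **not** emulate: spatial embedding and
distance-dependent connectivity, hemispheric symmetry, hub architecture
beyond what modular randomness produces, and any topological (rather than
weight) group difference. Passing tests therefore demonstrate that the
*pipeline* is correct and calibrated, not that the biological findings would
replicate.

Determinism: each subject's topology and covariates come from
`SeedSequence([master_seed, counter])` streams, so cohorts are reproducible
and order-independent.

## Problem sizes and numerical choices

Defaults follow the full design (10,000 group permutations, 1000 ROC refits,
100 reference networks). The test suite and acceptance script scale down
where the quantity is a Monte-Carlo mean or a rate: 50 reference networks ×
10 subjects for the small-world check, 2,000–10,000 permutations, 200 null
datasets for the type-I calibration, 25 cohort replicates for power; these
sizes put Monte-Carlo error well inside each assertion's tolerance. The
power and type-I simulations use the three directly computed global metrics
(`S_p`, `E_glob`, `C_p`) as the FDR family; sigma joins the family whenever
it is computed (as in `run_analysis`), but simulating reference ensembles for
every subject of every replicate would multiply runtimes ~100-fold while
leaving the Eglob detection-rate question unchanged.

Other numerics: matrix symmetry tolerance 1e-9; logistic convergence 1e-8
with standardized predictors; permutation t computed by vectorized
group-sum algebra (identical to the naive loop to float precision);
`1/∞ = 0` handled explicitly rather than through floating-point division.

## Known limitations

- Residualization-then-permutation is approximate when covariates are
  strongly group-imbalanced (exchangeability holds only under the null of no
  covariate-adjusted group effect); Freedman–Lane is noted as future work.
- The strict-inequality unsmoothed ROC p can return 0; treat small values as
  "< 1/n_perm".
- `S_p` over reachable pairs only is one of several disconnection
  conventions; the `disconnected` flag marks every affected result.
- The AAL node count (116) is a convention, not a constraint — any
  consistent label list works.
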