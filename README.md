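# connstats

Graph-theory analysis of weighted structural brain connectomes for two-group
case–control studies.

Diffusion-MRI tractography summarises a subject's white-matter anatomy as a
*connectome*: a symmetric matrix `W` whose entry `w_ij` counts the
streamlines connecting brain regions *i* and *j* of a parcellation atlas
(here, the 116-region AAL atlas). `connstats` implements the full
statistical pipeline that turns a cohort of such matrices — patients with
panic disorder (PD) versus healthy controls (HC) in the motivating design —
into group-level findings:

1. **Weighted network metrics.** Edge length is the reciprocal weight
   `l_ij = 1/w_ij`; `L_ij` is the shortest path length. Globally and per
   node the pipeline computes the mean shortest path `S_p`, efficiency

   `E_glob = (1/(N(N−1))) Σ_{i≠j} 1/L_ij`,  `E_nodal_i = (1/(N−1)) Σ_{j≠i} 1/L_ij`,

   the mean-scaled weighted clustering coefficient

   `C_p(i) = (2/(k_i(k_i−1))) Σ_{j,k} (ŵ_ij ŵ_ik ŵ_jk)^{1/3}`, `ŵ = w / mean(w)`,

   and the small-world coefficient
   `σ = (C_p/C_p^rand) / (S_p/S_p^rand)` against degree-preserving
   (Maslov–Sneppen) random reference networks.
2. **Group inference.** Each metric is residualized on age and gender
   (pooled OLS), compared with a pooled-variance t statistic, and tested by
   permuting group labels (10,000 draws by default). Benjamini–Hochberg FDR
   is applied over the 4 global metrics and over the 116 nodes of each nodal
   metric separately.
3. **Classification.** Logistic models `group ~ metric + age + gender`, ROC
   curves from in-sample fitted probabilities, AUROC, the Youden-optimal
   operating point, and a label-permutation AUROC significance test
   (1000 refits; `p = #{AUROC* > AUROC}/n_perm`, unsmoothed).
4. **Clinical correlations.** Pearson correlations of metrics with symptom
   scores (PDSS, HAMD, illness duration) in the patient group.
5. **Synthetic cohorts.** A calibrated generator of modular, integer-weighted
   small-world connectomes with a patient effect of Cohen's *d* ≈ 0.5 on
   global efficiency, so the whole pipeline is testable without MRI data.

Intended users are neuroimaging researchers who already have region×region
connectivity matrices (from PANDA, GRETNA, MRtrix, …) and want a scripted,
reproducible, permutation-based group analysis.

## Worked example

Simulate a small cohort, compute metrics, and run the group comparison:

```bash
connstats simulate --seed 7 --n-pd 12 --n-hc 10 --out demo/data
connstats metrics  --manifest demo/data/manifest.csv --labels demo/data/labels.txt \
                   --n-random 20 --seed 7 --out demo/metrics
connstats compare  --metrics-dir demo/metrics --n-perm 5000 --seed 7 --out demo/results
connstats roc      --metrics-dir demo/metrics --n-perm 500  --seed 7 --out demo/results
```

`demo/results/global_comparison.csv` then contains (abridged):

```
metric  pd_mean  pd_sd   hc_mean  hc_sd   t       p_perm  p_fdr
Sp      0.1329   0.0057  0.1378   0.0075  -1.803  0.091   0.200
Eglob   8.912    0.380   8.577    0.529    1.779  0.100   0.200
Cp      0.1145   0.0082  0.1168   0.0076  -0.950  0.356   0.356
sigma   1.312    0.095   1.353    0.092   -1.304  0.207   0.276
```

The patient group shows the injected pattern — higher global efficiency,
lower shortest path and clustering — but at n = 12 vs 10 none of it survives
permutation testing with FDR (`p_fdr` ≥ 0.2), which is the correct reading:
the default effect size (*d* ≈ 0.5) needs the full-size design (81 vs 48) for
~80–90 % power. Every `sigma` is well above 1, i.e. all simulated networks
are small-world. `demo/results/roc.csv` reports, per metric, the AUROC of
the covariate-adjusted logistic model, its permutation p, and the
sensitivity/specificity at the Youden-optimal threshold.

The same analysis runs end-to-end with
`connstats all --manifest … --labels … --seed 7 --out report/`, and
programmatically via `connstats.run_analysis`.

## Input formats

- **Matrix**: plain-text N×N table (TSV/CSV/whitespace), no header.
- **Labels**: one region name per line, AAL-style (`Precentral_L`, …).
- **Manifest**: CSV with columns `subject_id, group, age, gender, pdss,
  hamd, duration_months, matrix_file` (`group` ∈ {PD, HC}; `pdss` may be
  empty for HC).

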