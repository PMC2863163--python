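# sepindex

A separability index for censored time-to-event outcomes, built for
**meta-selection of prognostic genes across heterogeneous survival studies**,
together with four classical likelihood-based predictive-accuracy indices, the
Monte-Carlo machinery to compare them, and a cross-study intersection
selection procedure.

## The problem

Per-gene survival screening fits a univariate Cox model per gene and ranks
genes by the hazard ratio or by a test statistic. Neither ranking combines
well across studies of different sizes: hazard ratios ignore the variability
of the data, and every test statistic grows with *n*, so intersecting
p-value-ranked lists from a 286-patient cohort and a 30-patient cohort
systematically favors the large study. What is needed is an effect-size-like
quantity on a fixed [0, 1] scale whose expectation does not depend on *n*.

## The index

For one gene with expression values *Z*ᵢ and follow-up data
(*X̃*ᵢ = min(*T*ᵢ, *C*ᵢ), δᵢ), decompose the observed times into *N* distinct
times *t*₁ < … < *t_N* with death sets *D*(*t_j*), risk sets *R*(*t_j*) and
counts *d_j*, *n_j*. The component of the Cox (Breslow) score at β = 0,

  *U_j* = Σ_{i∈D(t_j)} *Z*ᵢ − *d_j* · mean_{R(t_j)}(*Z*),

is, up to the factor *d_j*(*n_j* − *d_j*)/*n_j*, the difference between the
mean expression of the patients failing at *t_j* and that of the patients at
risk who do not fail — a per-time measure of separability between the event
and non-event groups. Because the *U_j* are serially dependent, they are
replaced by robust components *W_j* (Lin–Wei score residuals aggregated by
distinct time), which are asymptotically i.i.d. and satisfy
Σ *W_j* = Σ *U_j* = Δ₀ exactly. By the Cauchy–Schwarz inequality

  Δ₀² ≤ *D*max = *N* · Σ_j *W_j*²,

with the bound approached as |β| → ∞, so

  **I = Δ₀² / D**max **= S₀ / N ∈ [0, 1]**,  S₀ = (Σ *W_j*)² / Σ *W_j*²,

where S₀ is the robust score statistic, asymptotically χ²(1) under the null.
The index is 0 without separability, grows with the hazard ratio, is stable
in *n*, and carries a test for free (p-values and Storey q-values).

The four comparators, evaluated at the partial-likelihood MLE with LR the
likelihood-ratio statistic, *k* the number of failures and ℓ(0) the null
partial log-likelihood: Allison's 1 − e^(−LR/n), its modified version
1 − e^(−LR/k), Nagelkerke's (Allison's divided by 1 − e^(2ℓ(0)/n)), and the
Xu–O'Quigley information-gain index 1 − e^(−2Γ) with Γ a Kaplan–Meier-weighted
Kullback–Leibler divergence between fitted and null risk-set selection
probabilities.

## Worked example

Generate the two-study synthetic benchmark (1,000 genes; genes 1–100 truly
prognostic; clumpy correlation ρ = 0.5; ~30% uniform censoring) and run the
meta-selection:

```sh
sepindex make-fixture --n 150 --effect 3 --rho 0.5 --seed 7 --out-dir demo/study1
sepindex make-fixture --n 50  --effect 3 --rho 0.5 --seed 8 --out-dir demo/study2
sepindex compute --expr demo/study1/expr.tsv --surv demo/study1/surv.tsv \
    --out demo/s1.tsv --with-comparisons --with-qvalues --log-expression
sepindex meta --studies demo/study1 --studies demo/study2 \
    --criterion index --log-expression --out demo/meta.tsv
```

`compute` writes one row per gene, sorted by index:

```
gene    index     delta0   direction  score_stat  pvalue     qvalue    allison  xu_oquigley
g43     0.203877  -95.925  HR<1       30.5815     3.20e-08   1.9e-05   0.173263 0.221243
g10     0.198029  -107.63  HR<1       29.7044     5.03e-08   1.9e-05   0.159801 0.206876
g94     0.178271  -83.607  HR<1       26.7407     2.33e-07   4.0e-05   0.188488 0.240133
...
```

g43 separates ~20% of the way to perfect separation; its expression is higher
in long survivors (HR<1, negative Δ₀), as constructed for genes 1–100.

`meta` scans intersection thresholds and keeps the loosest one where the
observed number of genes selected in both studies exceeds twice the count
expected under independent rankings:

```
threshold 0.03436 (index): 97 genes in common; curve written alongside
```

```
top_fraction  threshold  observed  expected  ratio   qualifying
0.005         0.173      1         0.155     6.452   True
0.055         0.092      33        6.215     5.310   True
0.105         0.052      77        24.255    3.175   True
0.155         0.033      99        50.530    1.959   False
```

Of the 97 selected genes, 88 belong to the 100 truly prognostic ones, and
every selection has a concordant effect direction across the two studies.

A replicated index-comparison study over a simulation grid is available as
`sepindex simulate --config grid.yaml --out table.csv`, and from Python via
`sepindex.run_index_study` / `sepindex.run_meta_study`.

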