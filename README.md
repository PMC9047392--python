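# csearch

**csearch** discovers genes that *positively modulate treatment effect* in
right-censored survival cohorts: genes whose carriers benefit from a
treatment that does little for non-carriers.  It is aimed at
clinical-genomics settings — a few binary mutation profiles per patient,
age/sex-level clinical covariates, a treatment indicator, and overall
survival — where per-gene subgroups are far too small for classical
conditional-effect estimation and a per-gene log-rank screen needs
thousands of patients to reach power.

## The method

For a treated patient *i* the untreated potential outcome is unobservable.
csearch scores *i* against every untreated counterpart *j* as a censored
pairwise comparison ("does *i* outlive *j*?") and weights each comparison
by how exchangeable the pair is, measured through two *basal* risk
projections — ridge-penalized Cox linear predictors `P(Y|V)` (clinical
block) and `P(Y|G)` (genetic block) — turned into Boltzmann similarity
weights over the untreated pool:

    W(i,j) ∝ exp( −|P_i − P_j| / kτ ),        Σ_j W(i,j) = 1

Pairwise win scores follow the Wilcoxon–Mann–Whitney comparability rules
for censored data (the smaller observed time must be an event; undecidable
pairs carry no evidence).  Each patient's evidence accumulates conjugately
into a Beta posterior for their **win probability** Pw_i:

    Pw_i ~ Beta( α₀ + Σ_j s_j·W_ij ,  β₀ + Σ_j (1−s_j)·W_ij )

with the combined clinical×genetic weights renormalized so every patient
contributes exactly one pseudo-observation.  Per gene g_k, the win
probabilities of treated carriers and treated non-carriers pool into two
Beta posteriors, `P("win"|g_k=1)` and `P("win"|g_k=0)` (optionally
inverse-propensity weighted by ê(V)·ê(G)).  A gene is *decided causal*
when the 95% equal-tailed credible interval of the carrier posterior lies
entirely above the non-carrier interval; genes are ranked by that
separation margin.

The package also ships the conventional comparator (per-gene log-rank among
propensity-matched treated patients with Benjamini–Hochberg FDR control), a
benchmark cohort simulator with planted modulators and hidden confounders,
and the evaluation harness that compares the two methods across cohort
sizes.

## Worked example

Simulate a 600-patient cohort (300 genes, 10 hidden causal modulators, 10
hidden confounders) and run the discovery:

```bash
$ csearch simulate --n 600 --seed 7 --out demo/sim
wrote cohort (n=600, 300 genes) and truth list to demo/sim

$ csearch discover --clinical demo/sim/clinical.tsv \
                   --mutations demo/sim/mutations.tsv --out demo/disc
suggested genes: g069, g098, g254, g172, g208, g019, g262, g184, g074, g005
```

`demo/disc/results.tsv` holds one row per gene; the top of the ranking
looks like:

| gene | mean_carrier | mean_noncarrier | separation | n_carriers |
|------|-------------:|----------------:|-----------:|-----------:|
| g069 | 0.591        | 0.515           | −0.048     | 33         |
| g098 | 0.583        | 0.516           | −0.059     | 32         |
| g254 | 0.564        | 0.517           | −0.069     | 36         |

`mean_carrier` is the posterior mean win probability of treated carriers —
g069's treated carriers outlive a matched untreated counterpart 59% of the
time versus 51.5% for treated non-carriers.  Negative `separation` means
the 95% credible intervals still overlap at this sample size (600 patients
⇒ ~30 treated carriers per gene), so no gene is *decided* causal, but the
ranking is already informative: 6 of the 10 suggested genes are true
planted modulators (`demo/sim/truth.txt`), and recovery reaches 9–10 of 10
by n ≈ 1500–4000 (see below).  The log-rank comparator and the full
benchmark run as `csearch baseline ...` and `csearch evaluate ...`.

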