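# omicox

Multi-omic prognostic signatures for right-censored clinical outcomes:
L1-penalized Cox regression paths over an integrated feature space, tuned
by cross-validated concordance, with tertile risk stratification and
patient-specific median time-to-event prediction.

## Who this is for

Biostatisticians and computational biologists who have per-patient
profiles on several genomic platforms — mRNA expression, DNA methylation
beta values, copy-number values, microRNA expression — together with
follow-up times (e.g. progression-free or overall survival, in months)
and want a sparse, interpretable signature that (a) stratifies patients
into low/intermediate/high risk groups and (b) predicts each patient's
median time to event. A synthetic-cohort generator with known ground
truth is a first-class part of the package, so every stage can be
exercised and calibrated without access to protected clinical data.

## The model

Patient *i* has covariates *x<sub>i</sub>* and right-censored follow-up
(*y<sub>i</sub>*, δ<sub>i</sub>). Under the Cox proportional hazards
model, coefficients β maximize the partial likelihood over risk sets
R<sub>i</sub> = {j : y<sub>j</sub> ≥ y<sub>i</sub>} (Breslow convention
for ties). The path solver minimizes the penalized objective

    −log L(β) + λ‖β‖₁ + λ₂‖β‖₂²

for a whole grid of penalties from λ_max (the smallest λ at which β = 0)
down toward 0, warm-starting each solve from the previous one; λ₂ is a
fixed small ridge constant that stabilizes the fit under strongly
correlated covariates. Each grid point is certified against the KKT
conditions of the objective.

**Integration.** Non-mRNA features are admitted only when their Spearman
rank correlation with the matched mRNA (same gene for copy number and
methylation; target genes for microRNAs) clears a per-platform cutoff;
mRNA passes through unfiltered. Retention and standardization use
training samples only.

**Tuning.** Two-fold cross-validation, repeated 10 times, scores every
λ by the Gönen–Heller concordance probability estimate (CPE) of the
held-fold prognostic index, anchored to held-fold outcomes through a
single refitted calibration coefficient; the selected λ maximizes the
mean cross-validated CPE (ties go to the sparsest model).

**Prognosis.** The signature's linear predictor (c-score) and the
difference-of-means index over poor/good prognosis features (t-score)
are each cut at training tertiles; test cohorts reuse the training
cutoffs verbatim. The Breslow baseline cumulative hazard H₀ converts a
patient's score η into a survival curve S(t|x) = exp(−H₀(t)·e^η), whose
0.5 crossing is the predicted median time to event.

## Worked example

```python
from omicox import RunConfig, run_study

cfg = RunConfig(n_samples=300, n_genes=60, n_mirnas=20, n_causal=10,
                causal_effect=0.5, censor_target=0.45, seed=7)
res = run_study(cfg)
```

This simulates a 300-patient cohort on four linked platforms with ten
causal features of |β| = 0.5, integrates, splits 240/60, tunes the
penalty and evaluates on the withheld 60 patients. The run prints:

```
combined features after integration: 198
selected lambda: 8.190
signature size: 62 (recovered 9/10 causal features)
CPE.test = 0.686
3-group log-rank p = 1.56e-03
HR(high vs low) = 5.40 (95% CI 1.98-14.69)
sample_id   c_score   t_score      stratum  predicted_median_months  not_reached
    S0009 -0.410347 -0.371635 intermediate                50.097393        False
    S0011  1.813853  0.570011         high                 4.525653        False
    S0018  0.868394  0.349549         high                13.922660        False
```

The signature found 62 features including 9 of the 10 planted causal
ones; on the withheld patients the concordance probability is 0.69,
the tertile strata separate strongly (log-rank p ≈ 0.002), and
high-risk patients progress 5.4 times faster than low-risk ones. The
per-patient table gives each test patient's scores, risk stratum and
predicted median months (NaN/flag when the survival curve never falls
to 0.5 within follow-up).

The same pipeline is available from the shell:

```
omicox simulate --out-dir sim
omicox integrate --data-dir sim --out-dir integ
omicox fit --matrix integ/integrated_matrix.tsv --clinical sim/clinical.tsv --out-dir fit
omicox run --out-dir study        # end to end
```

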