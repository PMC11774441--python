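# radharm

Harmonization strategies for radiomic features of benign and malignant
pulmonary nodules.

## The problem

Radiomic features extracted from chest CT depend on how the image was
acquired — contrast enhancement (CE), tube voltage (KVP), focal spot size,
scanner manufacturer.  ComBat harmonization removes such batch effects, but
a diagnostic dataset mixes benign and malignant nodules whose tissues may
respond *differently* to the same protocol (e.g. contrast accumulates in
tumours far more than in benign tissue), and CE is quasi-systematically
confounded with malignancy: contrast is ordered when there is already cause
for concern.  A single pooled correction can then remove biology along with
the batch effect, or leave subgroup-specific acquisition effects in place.

`radharm` implements and compares three ways of applying permutation-
optimized nested ComBat to such tables:

* **collective** — one fit over all scans, no distinction between tissues;
* **covariate** — one fit with the subgroup (benign / malignant / LCS) as a
  preserved covariate: same corrective slope, subgroup-specific intercept;
* **separate** — independent fits per subgroup.

## The model

Per feature *g*, scan *j* acquired with instance *i* of a protocol
parameter:

    y_ijg = α_g + X_j β_g + γ_ig + δ_ig ε_ijg ,   ε_ijg ~ N(0, σ_g²)

ComBat estimates α, β, γ by least squares under Σᵢ nᵢ γ̂_ig = 0,
standardizes, then shrinks the per-batch location/scale estimates with
parametric empirical Bayes (Normal prior on γ, inverse-gamma on δ²,
method-of-moments hyperparameters) and returns

    y*_ijg = σ̂_g (z_ijg − γ*_ig) / δ*_ig + α̂_g + X_j β̂_g .

Nested harmonization applies this per acquisition parameter sequentially;
the ordering is chosen by exhaustive permutation search to maximize the
number of **acquisition-independent** features — features for which no
Kruskal–Wallis test across a parameter's instances, run separately on the
benign and the malignant subgroup, is significant at p ≤ 0.05.  Surviving
features feed a LASSO (α = 0.05, penalty on the ½n-scaled squared loss)
whose selection trains a linear SVM (C = 1) to predict malignancy; fitted
harmonization plans and models are applied unchanged to unseen test scans.
Everything is evaluated with repeated stratified 5-fold cross-validation,
paired DeLong ROC-AUC comparisons per trial, and Holm–Bonferroni
adjustment across trials.

The clinical dataset behind this design is not public, so the package ships
a synthetic-cohort generator that reproduces its structure (567 scans, 305
nodules, 193 patients; benign / malignant / lung-cancer-screening
subgroups; CE–malignancy confounding) with known ground-truth biology and
known, optionally subgroup-specific, batch effects — every stage of the
pipeline is testable against that ground truth.

## Worked example

```python
from radharm import default_config, generate_cohort, run_experiment

cfg = default_config(seed=1, n_scans=500, n_nodules=270, n_patients=170)
table = generate_cohort(cfg)          # divergent CE effects by subgroup
summary = run_experiment(table, cfg.acquisition_schema, k=5, repeats=2,
                         seed=2, methods=("collective", "covariate", "separate"))
for m in ("collective", "covariate", "separate"):
    e = summary.method_summary[m]
    print(m, round(e["independent_fraction"]["mean"], 1),
          e["n_usable"], "/", e["n_trials"])
```

prints (10 trials on a cohort whose CE effects have opposite signs for
benign and malignant tissue):

```
collective 24.3 7 / 10
covariate 41.5 10 / 10
separate 99.6 10 / 10
```

i.e. the mean percentage of features the Kruskal–Wallis gate declares
acquisition-independent, and how many trials produced a usable classifier.
Collective harmonization leaves most divergent effects in place and in 3 of
10 trials selects no feature at all, falling back to an all-benign
predictor (sensitivity 0, specificity 100, balanced accuracy 50); covariate
harmonization fixes what is shared but not what diverges; separate
harmonization recovers nearly all features.  The same ordering — separate >
covariate > collective — is the package's central reproduced behaviour.

The same run from a shell:

```bash
radharm simulate --seed 1 --out cohort.csv
radharm run-experiment --table cohort.csv --k 5 --repeats 2 --seed 2 --out results/
```

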