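"""Repeated cross-validated comparison of harmonization strategies.

Each trial (repeat, fold) of a stratified k-fold split runs, per method:
shared exclusion of unharmonizable scans, permutation-optimized nested
ComBat on the training scans, the Kruskal-Wallis independence gate, LASSO
selection, linear-SVM training, application of the frozen plan and model to
the untouched test fold, and metric computation overall and on the
lung-cancer-screening (LCS) subset.  Across trials the harness aggregates
means with t-based 95% confidence intervals and compares methods' ROC-AUCs
per trial with the paired DeLong test, Holm-Bonferroni-adjusted across
trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold, KFold
from statsmodels.stats.multitest import multipletests

from .kwgate import independence_report, kw_statistic_matrix
from .nested import apply_plan, exclude_unharmonizable, fit_plan, optimize_permutation
from .pipeline import FALLBACK_SCORE, LassoSvmClassifier, predict_scores
from .schema import (
    AcquisitionSchema,
    StratificationError,
    TestInapplicableError,
    TrialUnusableError,
    feature_names,
)

__all__ = [
    "make_splits",
    "compute_metrics",
    "delong_test",
    "holm_bonferroni",
    "run_trial",
    "run_experiment",
    "uniform_group_check",
    "ExperimentSummary",
]

DEFAULT_METHODS = ("unharmonized", "collective", "covariate", "separate")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def make_splits(table: pd.DataFrame, k: int = 5, repeats: int = 10, seed: int = 0):
    """Stratified k-fold splits, repeated; stratification on
    subgroup x malignancy label.  Returns ``k * repeats`` pairs of
    positional (train_idx, test_idx) arrays; within each repeat the test
    folds partition the scans."""
    strata = (
        table["subgroup"].astype(str) + "|" + table["malignancy_label"].astype(str)
    ).to_numpy()
    counts = pd.Series(strata).value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise StratificationError(
            f"stratum smaller than k={k}: {small.to_dict()}"
        )
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    dummy = np.zeros(len(table))
    return [(tr.copy(), te.copy()) for tr, te in cv.split(dummy, strata)]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(scores, predicted_labels, true_labels, subset_mask=None):
    """Sensitivity, specificity, balanced accuracy, and rank-based ROC-AUC
    (fractions in [0, 1]; ``None`` marks a metric undefined on a one-class
    or empty subset)."""
    scores = np.asarray(scores, dtype=float)
    pred = np.asarray(predicted_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if subset_mask is not None:
        m = np.asarray(subset_mask, dtype=bool)
        scores, pred, true = scores[m], pred[m], true[m]
    if len(true) == 0:
        return {"sensitivity": None, "specificity": None,
                "balanced_accuracy": None, "auc": None}
    pos = true == 1
    neg = ~pos
    sens = float((pred[pos] == 1).mean()) if pos.any() else None
    spec = float((pred[neg] == 0).mean()) if neg.any() else None
    bal = (sens + spec) / 2.0 if (sens is not None and spec is not None) else None
    auc = float(roc_auc_score(true, scores)) if (pos.any() and neg.any()) else None
    return {"sensitivity": sens, "specificity": spec,
            "balanced_accuracy": bal, "auc": auc}


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _placements(scores, y):
    """Midrank placement components of the AUC (per-positive V01 and
    per-negative V10) for one score vector."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]), method="average")
    pos_ranks = stats.rankdata(pos, method="average")
    neg_ranks = stats.rankdata(neg, method="average")
    v01 = (all_ranks[:m] - pos_ranks) / n
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v01.mean()
    return auc, v01, v10


def delong_test(scores_a, scores_b, true_labels):
    """Paired DeLong comparison of two correlated ROC-AUCs.

    Returns ``(auc_a, auc_b, p)`` with a two-sided normal p-value for the
    AUC difference; the variance of the difference comes from the
    structural components over the shared samples.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    if len(a) != len(y) or len(b) != len(y):
        raise TestInapplicableError("score and label vectors must align")
    if len(np.unique(y)) < 2:
        raise TestInapplicableError("both classes must be present")
    auc_a, v01_a, v10_a = _placements(a, y)
    auc_b, v01_b, v10_b = _placements(b, y)
    m, n = len(v01_a), len(v10_a)

    def _cov(x, z):
        if len(x) < 2:
            return 0.0
        return float(np.cov(x, z, ddof=1)[0, 1])

    var = (
        _cov(v01_a, v01_a) + _cov(v01_b, v01_b) - 2 * _cov(v01_a, v01_b)
    ) / m + (
        _cov(v10_a, v10_a) + _cov(v10_b, v10_b) - 2 * _cov(v10_a, v10_b)
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


def holm_bonferroni(pvalues):
    """Step-down Holm adjustment, returned in the original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# Experiment harness
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSummary:
    """Per-trial records plus cross-trial aggregates.

    ``trials`` holds one row per (trial, method) with metric fractions;
    ``method_summary`` reports means and 95% t-intervals on the percent
    scale for rates (AUC stays on [0, 1]); ``comparisons`` holds the
    pairwise per-trial DeLong results with Holm-adjusted significance
    counts per direction.
    """

    trials: pd.DataFrame
    method_summary: dict
    comparisons: pd.DataFrame
    n_trials: int
    dropped_trials: list = field(default_factory=list)
    k: int = 5
    repeats: int = 10
    seed: int = 0

    def to_dict(self):
        return {
            "n_trials": self.n_trials,
            "dropped_trials": [list(t) for t in self.dropped_trials],
            "method_summary": self.method_summary,
            "comparisons": self.comparisons.to_dict(orient="records"),
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
        }


def run_trial(train, test, schema, methods=DEFAULT_METHODS, gate_alpha=0.05,
              lasso_alpha=0.05, C=1.0, optimize=True, parameter_order=None,
              min_batch_size=3, gate_unharmonized=True, return_models=False):
    """Run one train/test trial for every requested method.

    Exclusion is computed once (separate-mode cell counts, which subsume the
    collective rule) and shared by all methods, so every method sees the
    identical train/test partition.  Raises :class:`TrialUnusableError` when
    exclusion empties a fitting scope.
    """
    train_x, test_x, excl_log = exclude_unharmonizable(
        train, test, schema, min_batch_size=min_batch_size, mode="separate"
    )
    feats = feature_names(train_x, schema)
    true = test_x["malignancy_label"].to_numpy(dtype=int)
    lcs_mask = (test_x["subgroup"] == "LCS").to_numpy()

    out = {}
    for method in methods:
        if method == "unharmonized":
            htrain, htest, plan = train_x, test_x, None
        else:
            if optimize:
                plan = optimize_permutation(
                    train_x, schema, method, alpha=gate_alpha,
                    min_batch_size=min_batch_size,
                )
            else:
                order = parameter_order or schema.parameters
                plan = fit_plan(train_x, schema, method, order, alpha=gate_alpha,
                                min_batch_size=min_batch_size)
            htrain = plan.harmonized_train
            htest = apply_plan(plan, test_x)

        if method == "unharmonized" and not gate_unharmonized:
            indep = list(feats)
        else:
            report = independence_report(htrain, schema, alpha=gate_alpha)
            indep = report.independent_features
        frac = len(indep) / len(feats)

        clf = None
        if indep:
            clf = LassoSvmClassifier(lasso_alpha=lasso_alpha, C=C).fit(
                htrain[indep], htrain["malignancy_label"].to_numpy(dtype=int)
            )
            scores, pred = predict_scores(clf, htest[indep])
            usable = not clf.fallback_
            selected = clf.selected_features_
        else:
            scores = np.full(len(htest), FALLBACK_SCORE)
            pred = np.zeros(len(htest), dtype=int)
            usable = False
            selected = []

        rec = {
            "independent_fraction": frac,
            "n_independent": len(indep),
            "selected_features": selected,
            "usable": usable,
            "overall": compute_metrics(scores, pred, true),
            "lcs": compute_metrics(scores, pred, true, subset_mask=lcs_mask),
            "scores": scores,
            "true": true,
            "lcs_mask": lcs_mask,
            "exclusions": len(excl_log),
        }
        if return_models:
            rec["plan"] = plan
            rec["classifier"] = clf
        out[method] = rec
    return out


def _t_ci(values, level=0.95):
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return None, None, None
    mean = float(v.mean())
    if v.size == 1:
        return mean, mean, mean
    half = stats.t.ppf(0.5 + level / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return mean, mean - float(half), mean + float(half)


def run_experiment(table, schema, k=5, repeats=10, seed=0, methods=DEFAULT_METHODS,
                   gate_alpha=0.05, lasso_alpha=0.05, C=1.0, optimize=True,
                   parameter_order=None, min_batch_size=3, gate_unharmonized=True):
    """The full harness: repeated stratified CV over every method, with
    cross-trial aggregation and pairwise DeLong/Holm comparisons.

    Trials whose exclusion step empties a fitting scope are dropped
    entirely; per-method fallback (no usable features) trials keep their
    metrics recorded but are excluded from that method's metric means.
    """
    splits = make_splits(table, k=k, repeats=repeats, seed=seed)
    rows = []
    dropped = []
    trial_payloads = {}
    for t, (tr_idx, te_idx) in enumerate(splits):
        repeat, fold = divmod(t, k)
        try:
            res = run_trial(
                table.iloc[tr_idx], table.iloc[te_idx], schema, methods=methods,
                gate_alpha=gate_alpha, lasso_alpha=lasso_alpha, C=C,
                optimize=optimize, parameter_order=parameter_order,
                min_batch_size=min_batch_size, gate_unharmonized=gate_unharmonized,
            )
        except TrialUnusableError as e:
            dropped.append((repeat, fold, str(e)))
            continue
        trial_payloads[(repeat, fold)] = res
        for method, rec in res.items():
            row = {
                "repeat": repeat,
                "fold": fold,
                "method": method,
                "usable": rec["usable"],
                "independent_fraction": rec["independent_fraction"],
                "n_selected": len(rec["selected_features"]),
            }
            for scope in ("overall", "lcs"):
                for metric, val in rec[scope].items():
                    row[f"{scope}_{metric}"] = np.nan if val is None else val
            rows.append(row)
    trials = pd.DataFrame(rows)
    if trials.empty:
        raise RuntimeError("every trial was unusable; experiment failed")

    metric_cols = [
        c for c in trials.columns
        if c.startswith(("overall_", "lcs_")) or c == "independent_fraction"
    ]
    method_summary = {}
    for method in methods:
        sub = trials[trials.method == method]
        usable = sub[sub.usable]
        entry = {"n_trials": int(len(sub)), "n_usable": int(len(usable))}
        for col in metric_cols:
            # independence fractions are defined for every trial; predictive
            # metrics only over trials where a model could be trained
            src = sub if col == "independent_fraction" else usable
            mean, lo, hi = _t_ci(src[col].to_numpy(dtype=float))
            if mean is not None and not col.endswith("auc"):
                mean, lo, hi = 100 * mean, 100 * lo, 100 * hi  # percent scale
            entry[col] = {"mean": mean, "ci95": [lo, hi]}
        method_summary[method] = entry

    comp_rows = []
    for m_a, m_b in combinations(methods, 2):
        for scope in ("overall", "lcs"):
            ps, diffs, ids = [], [], []
            for key, res in trial_payloads.items():
                ra, rb = res[m_a], res[m_b]
                mask = np.ones(len(ra["true"]), dtype=bool) if scope == "overall" \
                    else ra["lcs_mask"]
                y = ra["true"][mask]
                if len(np.unique(y)) < 2:
                    continue
                auc_a, auc_b, p = delong_test(
                    ra["scores"][mask], rb["scores"][mask], y
                )
                ps.append(p)
                diffs.append(auc_a - auc_b)
                ids.append(key)
            if ps:
                adj = holm_bonferroni(ps)
                sig = adj <= 0.05
                diffs = np.asarray(diffs)
                comp_rows.append(
                    {
                        "method_a": m_a,
                        "method_b": m_b,
                        "scope": scope,
                        "n_trials": len(ps),
                        "n_significant": int(sig.sum()),
                        "n_sig_favor_a": int((sig & (diffs > 0)).sum()),
                        "n_sig_favor_b": int((sig & (diffs < 0)).sum()),
                        "mean_auc_diff": float(diffs.mean()),
                    }
                )
    comparisons = pd.DataFrame(comp_rows)
    return ExperimentSummary(
        trials=trials,
        method_summary=method_summary,
        comparisons=comparisons,
        n_trials=trials[["repeat", "fold"]].drop_duplicates().shape[0],
        dropped_trials=dropped,
        k=k,
        repeats=repeats,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Uniform-acquisition sanity check
# ---------------------------------------------------------------------------

def uniform_group_check(table, schema, k=5, alpha=0.05, seed=0,
                        subgroups=("benign", "malignant")):
    """Calibration check of the KW gate on unharmonized data.

    Scans sharing every acquisition-parameter instance form a uniform group;
    within each group of size >= 2k, a k-fold split is drawn and, per fold
    and subgroup, every feature is KW-tested between the train and test
    portions.  With no acquisition variability the test should be
    non-significant for about (1 - alpha) of features.  Returns
    ``(per_group, overall, skipped)``.
    """
    feats = feature_names(table, schema)
    param_cols = list(schema.parameters)
    per_group = {}
    skipped = []
    fractions = []
    for key, grp in table.groupby(param_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if len(grp) < 2 * k:
            skipped.append((key, len(grp)))
            continue
        strata = grp["subgroup"].astype(str).to_numpy()
        min_stratum = pd.Series(strata).value_counts().min()
        if min_stratum >= k:
            cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = cv.split(np.zeros(len(grp)), strata)
        else:
            cv = KFold(n_splits=k, shuffle=True, random_state=seed)
            folds = cv.split(np.zeros(len(grp)))
        group_fracs = []
        for tr_idx, te_idx in folds:
            for sub in subgroups:
                in_sub = (strata == sub)
                tr_m = np.zeros(len(grp), dtype=bool)
                te_m = np.zeros(len(grp), dtype=bool)
                tr_m[tr_idx] = True
                te_m[te_idx] = True
                tr_m &= in_sub
                te_m &= in_sub
                if tr_m.sum() < 2 or te_m.sum() < 2:
                    continue
                vals = grp[feats].to_numpy(dtype=float)
                sel = tr_m | te_m
                codes = te_m[sel].astype(int)
                _, p = kw_statistic_matrix(vals[sel], codes, 2)
                group_fracs.append(float((p > alpha).mean()))
        if group_fracs:
            per_group[key] = float(np.mean(group_fracs))
            fractions.append(per_group[key])
        else:
            skipped.append((key, len(grp)))
    if not fractions:
        raise TestInapplicableError("no uniform acquisition group of size >= 2k")
    return per_group, float(np.mean(fractions)), skipped
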