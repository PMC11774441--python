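"""Evaluation harness: splits, metrics, DeLong, Holm, leakage protection,
and the uniform-acquisition calibration check."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radharm import (
    compute_metrics,
    delong_test,
    generate_cohort,
    holm_bonferroni,
    make_splits,
    null_config,
    run_trial,
    uniform_group_check,
)
from radharm.schema import StratificationError, TestInapplicableError


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def test_splits_partition_and_count(cohort500):
    _, table = cohort500
    splits = make_splits(table, k=5, repeats=10, seed=0)
    assert len(splits) == 50
    n = len(table)
    for r in range(10):
        test_sets = [set(splits[5 * r + f][1]) for f in range(5)]
        assert sum(len(s) for s in test_sets) == n
        assert set().union(*test_sets) == set(range(n))
    # reproducible
    again = make_splits(table, k=5, repeats=10, seed=0)
    for (a, b), (c, d) in zip(splits, again):
        np.testing.assert_array_equal(a, c)
        np.testing.assert_array_equal(b, d)


def test_splits_are_stratified():
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "scan_id": [f"s{i}" for i in range(100)],
            "subgroup": ["benign"] * 50 + ["malignant"] * 50,
            "malignancy_label": [0] * 50 + [1] * 50,
        }
    )
    for _, te in make_splits(table, k=5, repeats=1, seed=1):
        assert len(te) == 20
        labels = table.iloc[te]["malignancy_label"]
        assert abs((labels == 1).sum() - 10) <= 1


def test_small_stratum_raises():
    table = pd.DataFrame(
        {
            "scan_id": list("abcdefgh"),
            "subgroup": ["benign"] * 6 + ["malignant"] * 2,
            "malignancy_label": [0] * 6 + [1] * 2,
        }
    )
    with pytest.raises(StratificationError):
        make_splits(table, k=5, repeats=1, seed=0)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_all_benign_predictor_metrics():
    scores = np.full(10, -1.0)
    pred = np.zeros(10, dtype=int)
    true = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 0])
    m = compute_metrics(scores, pred, true)
    assert (m["sensitivity"], m["specificity"], m["balanced_accuracy"]) == (0.0, 1.0, 0.5)


def test_perfect_predictor_metrics():
    true = np.array([1, 0, 1, 0])
    scores = np.array([2.0, -2.0, 1.0, -1.0])
    m = compute_metrics(scores, (scores > 0).astype(int), true)
    assert m == {"sensitivity": 1.0, "specificity": 1.0,
                 "balanced_accuracy": 1.0, "auc": 1.0}


def test_auc_concordant_pair_oracle():
    """scores (0.9, 0.3, 0.6, 0.2), labels (1,1,0,0): 3 of 4
    positive/negative pairs concordant -> AUC 0.75."""
    m = compute_metrics([0.9, 0.3, 0.6, 0.2], [1, 0, 1, 0], [1, 1, 0, 0])
    assert m["auc"] == 0.75


def test_one_class_subset_marks_undefined():
    m = compute_metrics([1.0, 2.0], [1, 1], [1, 1])
    assert m["sensitivity"] == 1.0
    assert m["specificity"] is None and m["auc"] is None
    assert compute_metrics([], [], [])["auc"] is None


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def test_delong_identical_scores():
    y = np.array([1, 0, 1, 0, 1, 0])
    s = np.array([0.9, 0.1, 0.8, 0.4, 0.7, 0.2])
    auc_a, auc_b, p = delong_test(s, s, y)
    assert auc_a == auc_b
    assert p == 1.0


def test_delong_single_class_inapplicable():
    with pytest.raises(TestInapplicableError):
        delong_test([1.0, 2.0], [1.0, 2.0], [1, 1])


def test_delong_agrees_with_paired_bootstrap():
    """On a 20-sample fixture the DeLong p matches a 1e5-replicate paired
    bootstrap (normal approximation on the bootstrap SE of the AUC
    difference) within 0.02."""
    rng = np.random.default_rng(42)
    y = np.array([1] * 8 + [0] * 12)
    latent = y * 0.8 + rng.normal(0, 1, 20)
    a = latent + rng.normal(0, 0.6, 20)
    b = latent + rng.normal(0, 0.9, 20)
    auc_a, auc_b, p = delong_test(a, b, y)

    B = 100_000
    boot = np.random.default_rng(123)
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    pi = boot.choice(pos, size=(B, len(pos)))
    ni = boot.choice(neg, size=(B, len(neg)))

    def auc_mw(scores):
        # pairwise concordance count (independent AUC formulation)
        sp = scores[pi][:, :, None]
        sn = scores[ni][:, None, :]
        return ((sp > sn) + 0.5 * (sp == sn)).mean(axis=(1, 2))

    diffs = auc_mw(a) - auc_mw(b)
    p_boot = 2 * stats.norm.sf(abs(auc_a - auc_b) / diffs.std(ddof=1))
    assert abs(p - p_boot) < 0.02


def test_delong_null_size():
    """1000 null replicates (two noisy copies of one latent score):
    rejection rate at 0.05 within [0.03, 0.07]."""
    rng = np.random.default_rng(7)
    rej = 0
    N = 1000
    y = np.array([1] * 25 + [0] * 35)
    for _ in range(N):
        latent = y * 1.0 + rng.normal(0, 1, 60)
        a = latent + rng.normal(0, 0.7, 60)
        b = latent + rng.normal(0, 0.7, 60)
        _, _, p = delong_test(a, b, y)
        rej += p <= 0.05
    assert 0.03 <= rej / N <= 0.07


# ---------------------------------------------------------------------------
# Holm
# ---------------------------------------------------------------------------

def test_holm_hand_oracle():
    np.testing.assert_allclose(holm_bonferroni([0.03]), [0.03])
    np.testing.assert_allclose(holm_bonferroni([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])
    np.testing.assert_allclose(holm_bonferroni([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_holm_never_decreases_and_validates():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=20)
    adj = holm_bonferroni(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
    with pytest.raises(ValueError):
        holm_bonferroni([0.5, 1.5])


# ---------------------------------------------------------------------------
# trial-level harness
# ---------------------------------------------------------------------------

def test_no_information_leak_from_test_labels(trial500):
    """Shuffling the test fold's labels must leave every fitted object
    untouched (all fitting uses training scans only)."""
    cfg, train, test = trial500
    schema = cfg.acquisition_schema
    res = run_trial(train, test, schema, methods=("covariate",), return_models=True)
    shuffled = test.copy()
    shuffled["malignancy_label"] = (
        shuffled["malignancy_label"].sample(frac=1.0, random_state=0).to_numpy()
    )
    res2 = run_trial(train, shuffled, schema, methods=("covariate",),
                     return_models=True)
    m1 = res["covariate"]["plan"].models
    m2 = res2["covariate"]["plan"].models
    assert set(m1) == set(m2)
    for key in m1:
        np.testing.assert_array_equal(m1[key].eb_location_, m2[key].eb_location_)
        np.testing.assert_array_equal(m1[key].grand_effects_, m2[key].grand_effects_)
    c1, c2 = res["covariate"]["classifier"], res2["covariate"]["classifier"]
    assert c1.selected_features_ == c2.selected_features_
    np.testing.assert_array_equal(c1.weights_, c2.weights_)
    np.testing.assert_array_equal(res["covariate"]["scores"],
                                  res2["covariate"]["scores"])


def test_trial_partition_identical_across_methods(trial500):
    """Every method scores the same test scans (shared exclusion set)."""
    cfg, train, test = trial500
    res = run_trial(train, test, cfg.acquisition_schema)
    lengths = {m: len(r["true"]) for m, r in res.items()}
    assert len(set(lengths.values())) == 1
    for m, r in res.items():
        np.testing.assert_array_equal(r["true"], res["unharmonized"]["true"])


# ---------------------------------------------------------------------------
# uniform-acquisition calibration
# ---------------------------------------------------------------------------

def _uniform_table(seed, n=200, n_features=107, hidden=False):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n, n_features))
    if hidden:
        # unmodelled batch factor cutting across both subgroups
        vals[::2, :40] += 2.0
    from conftest import make_table

    sub = ["benign"] * (n // 2) + ["malignant"] * (n // 2)
    labels = [0] * (n // 2) + [1] * (n // 2)
    t = make_table(vals, ["x"] * n, subgroup=sub, labels=labels)
    return t


def test_uniform_group_null_pass_rate():
    """One uniform group of 200 null scans: ~95% of per-feature KW tests
    between train and test portions are non-significant at alpha 0.05."""
    from radharm import AcquisitionSchema

    schema = AcquisitionSchema(["b"], {"b": ["x", "y"]})
    t = _uniform_table(0)
    per_group, overall, skipped = uniform_group_check(t, schema, k=5, seed=0)
    assert abs(overall - 0.95) <= 0.02
    assert not skipped


def test_uniform_group_too_small_is_skipped():
    from radharm import AcquisitionSchema

    schema = AcquisitionSchema(["b"], {"b": ["x", "y"]})
    t = _uniform_table(1, n=8)
    with pytest.raises(TestInapplicableError):
        uniform_group_check(t, schema, k=5, seed=0)


def test_hidden_batch_factor_depresses_pass_rate():
    from radharm import AcquisitionSchema

    schema = AcquisitionSchema(["b"], {"b": ["x", "y"]})
    t = _uniform_table(3, hidden=True)
    _, overall, _ = uniform_group_check(t, schema, k=5, seed=0)
    t0 = _uniform_table(3, hidden=False)
    _, overall0, _ = uniform_group_check(t0, schema, k=5, seed=0)
    assert overall < overall0
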