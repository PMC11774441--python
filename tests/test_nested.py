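"""Nested harmonization: exclusion rules, sequential fitting, permutation
optimization, and routing of unseen scans."""

import numpy as np
import pandas as pd
import pytest

from radharm import (
    AcquisitionSchema,
    SimulationConfig,
    apply_plan,
    exclude_unharmonizable,
    fit_plan,
    generate_cohort,
    independence_report,
    optimize_permutation,
)
from radharm.nested import HarmonizationPlan, NestedComBat
from radharm.schema import TrialUnusableError

from conftest import make_table

SCHEMA2 = AcquisitionSchema(
    ["CE", "KVP"], {"CE": ["no", "yes"], "KVP": ["100", "120", "140"]}
)


def _cohort2(seed=0, n=400, loc=None, scale=None, subgroups=None, n_features=10):
    freqs = {}
    for s in ("benign", "malignant", "LCS"):
        freqs[("CE", s)] = {"no": 0.5, "yes": 0.5}
        freqs[("KVP", s)] = {"100": 0.3, "120": 0.4, "140": 0.3}
    return generate_cohort(
        SimulationConfig(
            n_patients=n // 2,
            n_nodules=n // 2,
            n_scans=n,
            subgroup_proportions=subgroups
            or {"benign": 0.3, "malignant": 0.4, "LCS": 0.3},
            n_features=n_features,
            acquisition_schema=SCHEMA2,
            instance_frequencies=freqs,
            batch_location=loc or {},
            batch_scale=scale or {},
            seed=seed,
        )
    )


# ---------------------------------------------------------------------------
# exclusion
# ---------------------------------------------------------------------------

def test_exclusion_noop_when_all_cells_large():
    t = _cohort2(seed=1)
    tr, te = t.iloc[:300], t.iloc[300:]
    tr2, te2, log = exclude_unharmonizable(tr, te, SCHEMA2, min_batch_size=3)
    assert log == []
    assert len(tr2) == len(tr) and len(te2) == len(te)


def test_rare_and_unseen_instance_rule_trace(two_level_schema):
    """The sole training carrier of an instance is removed as
    rare_instance, and test scans with that instance become
    unseen_instance."""
    rng = np.random.default_rng(0)
    tr = make_table(rng.normal(size=(10, 2)), ["x"] * 9 + ["y"],
                    subgroup=["benign"] * 10)
    te = make_table(rng.normal(size=(3, 2)), ["x", "y", "x"],
                    subgroup=["benign"] * 3)
    tr2, te2, log = exclude_unharmonizable(tr, te, two_level_schema,
                                           min_batch_size=3, mode="collective")
    reasons = dict(log)
    assert reasons[tr.scan_id.iloc[9]] == "rare_instance"
    assert reasons[te.scan_id.iloc[1]] == "unseen_instance"
    assert set(tr2.b) == {"x"} and set(te2.b) == {"x"}


def test_exclusion_never_removes_well_supported_scans():
    """Brute-force recount: every surviving (parameter, instance, subgroup)
    cell has >= min_batch_size scans, and no scan whose every cell was
    always large got removed."""
    for seed in range(5):
        t = _cohort2(seed=seed, n=220)
        tr, te = t.iloc[:170], t.iloc[170:]
        tr2, _, log = exclude_unharmonizable(tr, te, SCHEMA2, min_batch_size=5,
                                             mode="separate")
        for param in SCHEMA2.parameters:
            counts = tr2.groupby(["subgroup", param]).size()
            assert (counts >= 5).all(), counts
        removed = {s for s, r in log if r == "rare_instance"}
        # scans whose every original cell was large must survive
        for _, row in tr.iterrows():
            safe = all(
                (
                    (tr.subgroup == row.subgroup) & (tr[p] == row[p])
                ).sum() >= 5 + 20  # generous margin: cells that large never shrink below 5 here
                for p in SCHEMA2.parameters
            )
            if safe:
                assert row.scan_id not in removed


def test_exclusion_emptying_a_scope_is_trial_unusable(two_level_schema):
    rng = np.random.default_rng(1)
    tr = make_table(rng.normal(size=(4, 2)), ["x", "x", "y", "y"],
                    subgroup=["benign"] * 4)
    te = make_table(rng.normal(size=(2, 2)), ["x", "y"], subgroup=["benign"] * 2)
    with pytest.raises(TrialUnusableError):
        exclude_unharmonizable(tr, te, two_level_schema, min_batch_size=3,
                               mode="separate")


# ---------------------------------------------------------------------------
# fit_plan / apply_plan
# ---------------------------------------------------------------------------

def test_single_subgroup_collective_equals_covariate():
    t = _cohort2(seed=2, subgroups={"benign": 1.0})
    pa = fit_plan(t, SCHEMA2, "collective", SCHEMA2.parameters)
    pb = fit_plan(t, SCHEMA2, "covariate", SCHEMA2.parameters)
    pd.testing.assert_frame_equal(pa.harmonized_train, pb.harmonized_train)


def test_apply_plan_reproduces_harmonized_train():
    t = _cohort2(seed=3)
    for mode in ("collective", "covariate", "separate"):
        plan = fit_plan(t, SCHEMA2, mode, SCHEMA2.parameters)
        redo = apply_plan(plan, t)
        pd.testing.assert_frame_equal(redo, plan.harmonized_train)


def test_separate_mode_routes_by_subgroup():
    """A benign test scan is transformed by exactly the benign-scope models
    in order."""
    t = _cohort2(seed=4)
    plan = fit_plan(t, SCHEMA2, "separate", SCHEMA2.parameters)
    one = t[t.subgroup == "benign"].iloc[[0]]
    routed = apply_plan(plan, one)
    manual = one
    for param in plan.parameter_order:
        m = plan.models.get((param, "benign"))
        if m is not None:
            manual = m.transform(manual)
    feats = [c for c in t.columns if c.startswith("feature_")]
    np.testing.assert_allclose(routed[feats].to_numpy(), manual[feats].to_numpy())


def test_models_fit_sequentially_in_order():
    """Model k is fitted on data transformed by models 1..k-1: fitting the
    second parameter on the first parameter's output reproduces the plan's
    second model."""
    from radharm.combat import ComBat

    t = _cohort2(seed=5)
    plan = fit_plan(t, SCHEMA2, "collective", ("CE", "KVP"))
    step1 = plan.models[("CE", "all")].transform(t)
    m2 = ComBat("KVP", SCHEMA2).fit(step1)
    np.testing.assert_allclose(
        m2.eb_location_, plan.models[("KVP", "all")].eb_location_
    )


def test_shared_vs_subgroup_specific_mode_gap():
    """With shared effects, separate- and covariate-mode independent
    fractions agree within 5 points; with opposite-sign CE effects the
    separate fraction strictly exceeds the collective one."""
    g = np.zeros(80)
    g[:48] = 1.5
    shared_loc = {("CE", "yes", s): g for s in ("benign", "malignant", "LCS")}
    # two balanced subgroups: the regime where the pooled (covariate) fit
    # gives every subgroup enough weight that its within-subgroup residuals
    # are conservative, like the per-subgroup fits are
    t = _cohort2(seed=6, n=3000, loc=shared_loc, n_features=80,
                 subgroups={"benign": 0.5, "malignant": 0.5})
    fracs = {}
    for mode in ("covariate", "separate"):
        plan = fit_plan(t, SCHEMA2, mode, SCHEMA2.parameters)
        rep = independence_report(plan.harmonized_train, SCHEMA2)
        fracs[mode] = rep.independent_fraction
    assert abs(fracs["separate"] - fracs["covariate"]) < 0.05

    div_loc = {
        ("CE", "yes", "malignant"): g,
        ("CE", "yes", "benign"): -g,
        ("CE", "yes", "LCS"): -g,
    }
    t = _cohort2(seed=7, n=1500, loc=div_loc, n_features=80)
    fracs = {}
    for mode in ("collective", "separate"):
        plan = fit_plan(t, SCHEMA2, mode, SCHEMA2.parameters)
        rep = independence_report(plan.harmonized_train, SCHEMA2)
        fracs[mode] = rep.independent_fraction
    assert fracs["separate"] > fracs["collective"]


# ---------------------------------------------------------------------------
# permutation optimization
# ---------------------------------------------------------------------------

def test_single_parameter_permutation_is_trivial():
    schema1 = AcquisitionSchema(["CE"], {"CE": ["no", "yes"]})
    freqs = {("CE", s): {"no": 0.5, "yes": 0.5} for s in ("benign", "malignant", "LCS")}
    t = generate_cohort(
        SimulationConfig(
            n_patients=100, n_nodules=100, n_scans=200,
            subgroup_proportions={"benign": 0.5, "malignant": 0.5},
            n_features=5, acquisition_schema=schema1,
            instance_frequencies=freqs, seed=0,
        )
    )
    plan = optimize_permutation(t, schema1, "collective")
    assert plan.parameter_order == ("CE",)


def test_two_parameter_argmax_matches_brute_force():
    """The optimizer's choice equals an external enumeration of both
    orders, including the lexicographic tie rule."""
    rng = np.random.default_rng(0)
    for trial in range(6):
        g = np.zeros(10)
        g[rng.choice(10, 4, replace=False)] = rng.normal(0, 1.5, 4)
        h = np.zeros(10)
        h[rng.choice(10, 4, replace=False)] = rng.normal(0, 1.5, 4)
        loc = {("CE", "yes", s): g for s in ("benign", "malignant", "LCS")}
        loc.update({("KVP", "140", s): h for s in ("benign", "malignant", "LCS")})
        t = _cohort2(seed=100 + trial, n=300, loc=loc)
        chosen = optimize_permutation(t, SCHEMA2, "collective")
        best_order, best_score = None, -1
        for order in (("CE", "KVP"), ("KVP", "CE")):  # lexicographic order
            plan = fit_plan(t, SCHEMA2, "collective", order)
            score = len(
                independence_report(plan.harmonized_train, SCHEMA2).independent_features
            )
            if score > best_score:
                best_order, best_score = order, score
        assert chosen.parameter_order == best_order
        assert chosen.score == best_score


def test_zero_effect_tie_breaks_lexicographically():
    t = _cohort2(seed=8, n=300)
    plan = optimize_permutation(t, SCHEMA2, "collective")
    # all orders tie on null data only if scores are equal; the winner must
    # then be the lexicographically first permutation
    scores = {}
    for order in (("CE", "KVP"), ("KVP", "CE")):
        p = fit_plan(t, SCHEMA2, "collective", order)
        scores[order] = len(
            independence_report(p.harmonized_train, SCHEMA2).independent_features
        )
    if scores[("CE", "KVP")] == scores[("KVP", "CE")]:
        assert plan.parameter_order == ("CE", "KVP")


def test_optimizer_score_matches_gate_recount():
    t = _cohort2(seed=9, n=400)
    plan = optimize_permutation(t, SCHEMA2, "separate")
    rep = independence_report(plan.harmonized_train, SCHEMA2)
    assert plan.score == len(rep.independent_features)


def test_plan_json_roundtrip():
    import json

    t = _cohort2(seed=10)
    plan = fit_plan(t, SCHEMA2, "separate", SCHEMA2.parameters)
    clone = HarmonizationPlan.from_dict(json.loads(json.dumps(plan.to_dict())))
    pd.testing.assert_frame_equal(apply_plan(clone, t), apply_plan(plan, t))


def test_estimator_facade_matches_functions():
    t = _cohort2(seed=12)
    est = NestedComBat(SCHEMA2, mode="covariate", optimize=False).fit(t)
    plan = fit_plan(t, SCHEMA2, "covariate", SCHEMA2.parameters)
    pd.testing.assert_frame_equal(est.transform(t), apply_plan(plan, t))
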