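"""Optimized-permutation nested ComBat over several acquisition parameters.

Harmonization runs sequentially, one acquisition parameter after another,
each ComBat fit on the output of the previous one.  Because the result
depends on the order, the optimizer enumerates every permutation of the
parameters and keeps the one whose harmonized training table leaves the
most features acquisition-independent under the Kruskal-Wallis gate.

Three modes are supported:

* ``collective`` — one fit per parameter on all scans, no covariate;
* ``covariate``  — one fit per parameter with subgroup as a preserved
  covariate (same corrective slope, subgroup-specific intercept);
* ``separate``   — independent fits per subgroup, each subgroup getting its
  own corrective transformations.

Scans acquired with instances too rare to support a fit are excluded from
the training set, and test scans carrying instances absent from the
surviving training set are excluded as well; both removals are logged so a
trial's accounting is explicit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .combat import ComBat
from .kwgate import independence_report
from .schema import (
    SUBGROUPS,
    TrialUnusableError,
    UnharmonizableLevelError,
    UnseenLevelError,
    feature_names,
)

__all__ = [
    "HarmonizationPlan",
    "NestedComBat",
    "exclude_unharmonizable",
    "fit_plan",
    "optimize_permutation",
    "apply_plan",
    "MODES",
]

MODES = ("collective", "covariate", "separate")


@dataclass
class HarmonizationPlan:
    """A mode, a parameter ordering, and every fitted ComBat model needed to
    transform unseen scans.  ``models`` maps (parameter, scope) to a fitted
    :class:`ComBat`; scope is ``"all"`` except in separate mode, where it is
    the subgroup name.  (parameter, scope) pairs with a single surviving
    instance have no model and are applied as identity."""

    mode: str
    parameter_order: tuple
    models: dict
    exclusion_log: list = field(default_factory=list)
    skipped_scopes: list = field(default_factory=list)
    harmonized_train: pd.DataFrame | None = None
    score: int | None = None

    def to_dict(self):
        return {
            "mode": self.mode,
            "parameter_order": list(self.parameter_order),
            "models": {f"{p}|{s}": m.to_dict() for (p, s), m in self.models.items()},
            "exclusion_log": [list(e) for e in self.exclusion_log],
            "skipped_scopes": [list(s) for s in self.skipped_scopes],
            "score": self.score,
        }

    @classmethod
    def from_dict(cls, d):
        models = {}
        for key, md in d["models"].items():
            p, s = key.split("|", 1)
            models[(p, s)] = ComBat.from_dict(md)
        return cls(
            mode=d["mode"],
            parameter_order=tuple(d["parameter_order"]),
            models=models,
            exclusion_log=[tuple(e) for e in d["exclusion_log"]],
            skipped_scopes=[tuple(s) for s in d["skipped_scopes"]],
            score=d.get("score"),
        )


def _scopes(subgroup_values, mode):
    if mode == "separate":
        present = set(subgroup_values)
        return [s for s in SUBGROUPS if s in present]
    return ["all"]


def exclude_unharmonizable(train, test, schema, min_batch_size=3, mode="separate"):
    """Drop scans that would make a ComBat fit or its application fail.

    Training scans whose (parameter, instance[, subgroup]) cell holds fewer
    than ``min_batch_size`` scans are removed (reason ``rare_instance``),
    iterating until counts are stable.  Test scans carrying an instance
    absent from the surviving training set within their fitting scope are
    then removed (reason ``unseen_instance``).  Raises
    :class:`TrialUnusableError` if a required fitting scope empties.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    train = train.copy()
    log = []
    initial_scopes = _scopes(train["subgroup"], mode)

    changed = True
    while changed:
        changed = False
        for param in schema.parameters:
            for scope in _scopes(train["subgroup"], mode):
                sub = train if scope == "all" else train[train["subgroup"] == scope]
                counts = sub[param].value_counts()
                rare = counts[counts < min_batch_size].index
                if len(rare) == 0:
                    continue
                mask = sub[param].isin(rare)
                for sid in sub.loc[mask, "scan_id"]:
                    log.append((sid, "rare_instance"))
                train = train.drop(index=sub.index[mask])
                changed = True

    for scope in initial_scopes:
        remaining = train if scope == "all" else train[train["subgroup"] == scope]
        if remaining.empty:
            raise TrialUnusableError(
                f"exclusion emptied fitting scope {scope!r}; trial unusable"
            )

    test = test.copy()
    drop_idx = []
    for idx, row in test.iterrows():
        scope_tab = (
            train if mode != "separate" else train[train["subgroup"] == row["subgroup"]]
        )
        if scope_tab.empty:
            drop_idx.append(idx)
            log.append((row["scan_id"], "unseen_instance"))
            continue
        for param in schema.parameters:
            if row[param] not in set(scope_tab[param].unique()):
                drop_idx.append(idx)
                log.append((row["scan_id"], "unseen_instance"))
                break
    test = test.drop(index=drop_idx)
    return train.reset_index(drop=True), test.reset_index(drop=True), log


def _rebuild(table, feats, vals):
    out = pd.concat(
        [table.drop(columns=feats), pd.DataFrame(vals, columns=feats, index=table.index)],
        axis=1,
    )
    return out[table.columns]


def fit_plan(train, schema, mode, parameter_order, alpha=0.05, min_batch_size=3):
    """Fit the sequential harmonization plan for one parameter ordering.

    The training table must already have passed
    :func:`exclude_unharmonizable` for this mode.  Model k is fitted on data
    already transformed by models 1..k-1.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    order = tuple(parameter_order)
    if sorted(order) != sorted(schema.parameters):
        raise ValueError("parameter_order must be a permutation of the schema parameters")

    feats = feature_names(train, schema)
    vals = train[feats].to_numpy(dtype=float).copy()
    subgroup = train["subgroup"].astype(str).to_numpy()
    batches = {p: train[p].astype(str).to_numpy() for p in schema.parameters}

    models = {}
    skipped = []
    for param in order:
        if mode in ("collective", "covariate"):
            cov = subgroup if (mode == "covariate" and len(set(subgroup)) > 1) else None
            if len(set(batches[param])) < 2:
                skipped.append((param, "all"))  # nothing to correct
                continue
            m = ComBat(
                param, schema,
                covariate="subgroup" if cov is not None else None,
                min_batch_size=min_batch_size,
            )
            m.feature_names_ = feats
            try:
                m._fit_core(vals, batches[param], cov)
            except UnharmonizableLevelError as e:
                raise UnharmonizableLevelError(
                    f"fitting {param!r} (scope all): {e}", levels=e.levels
                ) from e
            vals = m._transform_core(vals, batches[param], cov)
            models[(param, "all")] = m
        else:
            for sub in _scopes(subgroup, "separate"):
                rows = subgroup == sub
                if len(set(batches[param][rows])) < 2:
                    skipped.append((param, sub))
                    continue
                m = ComBat(param, schema, covariate=None, min_batch_size=min_batch_size)
                m.feature_names_ = feats
                try:
                    m._fit_core(vals[rows], batches[param][rows], None)
                except UnharmonizableLevelError as e:
                    raise UnharmonizableLevelError(
                        f"fitting {param!r} (scope {sub!r}): {e}", levels=e.levels
                    ) from e
                vals[rows] = m._transform_core(vals[rows], batches[param][rows], None)
                models[(param, sub)] = m

    return HarmonizationPlan(
        mode=mode,
        parameter_order=order,
        models=models,
        skipped_scopes=skipped,
        harmonized_train=_rebuild(train, feats, vals),
    )


def optimize_permutation(train, schema, mode, alpha=0.05, min_batch_size=3,
                         subgroups=("benign", "malignant")):
    """Exhaustively search parameter orderings; keep the one whose harmonized
    training set has the most acquisition-independent features.

    Permutations are visited in lexicographic order of parameter names and a
    strictly-greater score is required to displace the incumbent, so ties
    resolve to the lexicographically first ordering.
    """
    best = None
    failures = []
    for perm in itertools.permutations(sorted(schema.parameters)):
        try:
            plan = fit_plan(train, schema, mode, perm, alpha=alpha,
                            min_batch_size=min_batch_size)
        except (UnharmonizableLevelError, TrialUnusableError) as e:
            failures.append((perm, str(e)))
            continue
        report = independence_report(
            plan.harmonized_train, schema, subgroups=subgroups, alpha=alpha
        )
        plan.score = len(report.independent_features)
        if best is None or plan.score > best.score:
            best = plan
    if best is None:
        raise TrialUnusableError(
            f"all parameter permutations failed fitting: {failures[:3]}"
        )
    return best


def apply_plan(plan: HarmonizationPlan, table: pd.DataFrame) -> pd.DataFrame:
    """Apply every fitted model in the plan's order to an unseen table.

    In separate mode each scan is routed to its own subgroup's models; a
    scan from a subgroup or instance never fitted raises
    :class:`UnseenLevelError`.
    """
    some_model = next(iter(plan.models.values()), None)
    if some_model is None:
        return table.copy()
    feats = some_model.feature_names_
    vals = table[feats].to_numpy(dtype=float).copy()
    subgroup = table["subgroup"].astype(str).to_numpy()
    ids = table["scan_id"].tolist() if "scan_id" in table.columns else None
    for param in plan.parameter_order:
        batches = table[param].astype(str).to_numpy()
        if plan.mode in ("collective", "covariate"):
            m = plan.models.get((param, "all"))
            if m is not None:
                cov = subgroup if m.covariate is not None else None
                vals = m._transform_core(vals, batches, cov, scan_ids=ids)
            continue
        for sub in _scopes(subgroup, "separate"):
            rows = subgroup == sub
            m = plan.models.get((param, sub))
            if m is None:
                if (param, sub) not in plan.skipped_scopes:
                    offenders = (
                        [i for i, r in zip(ids, rows) if r][:5] if ids else []
                    )
                    raise UnseenLevelError(
                        f"no model for ({param!r}, {sub!r}); scans {offenders} "
                        "cannot be harmonized"
                    )
                continue
            sub_ids = [i for i, r in zip(ids, rows) if r] if ids else None
            vals[rows] = m._transform_core(vals[rows], batches[rows], None,
                                           scan_ids=sub_ids)
    return _rebuild(table, feats, vals)


class NestedComBat(BaseEstimator):
    """Estimator facade over the nested-harmonization plan machinery.

    ``fit`` expects a training table that already passed exclusion for this
    mode; ``transform`` applies the frozen plan to any conforming table.
    """

    def __init__(self, schema, mode="separate", optimize=True, parameter_order=None,
                 alpha=0.05, min_batch_size=3, subgroups=("benign", "malignant")):
        self.schema = schema
        self.mode = mode
        self.optimize = optimize
        self.parameter_order = parameter_order
        self.alpha = alpha
        self.min_batch_size = min_batch_size
        self.subgroups = subgroups

    def fit(self, table, y=None):
        if self.optimize:
            self.plan_ = optimize_permutation(
                table, self.schema, self.mode, alpha=self.alpha,
                min_batch_size=self.min_batch_size, subgroups=self.subgroups,
            )
        else:
            order = self.parameter_order or self.schema.parameters
            self.plan_ = fit_plan(
                table, self.schema, self.mode, order, alpha=self.alpha,
                min_batch_size=self.min_batch_size,
            )
        return self

    def transform(self, table):
        if not hasattr(self, "plan_"):
            raise RuntimeError("NestedComBat instance is not fitted")
        return apply_plan(self.plan_, table)

    def fit_transform(self, table, y=None):
        self.fit(table)
        return self.plan_.harmonized_train.copy()
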