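"""Kruskal-Wallis acquisition-independence testing.

After harmonization, a feature should be indistinguishable across scans
acquired with different instances of a protocol parameter.  The gate runs a
k-group Kruskal-Wallis test per (feature, parameter, subgroup) — separately
on the benign and malignant subgroups, because their underlying feature
distributions legitimately differ — and declares a feature
acquisition-independent only if no test in either subgroup is significant
at the chosen raw threshold (no multiple-testing correction; the gate is
deliberately strict).

The H statistic uses midranks and the standard tie correction
1 - sum(t^3 - t)/(N^3 - N); p comes from the chi-square upper tail with
(#groups - 1) degrees of freedom.  The core is vectorized over feature
columns because the permutation optimizer evaluates the whole gate for
every candidate parameter ordering; ``scipy.stats.kruskal`` serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import AcquisitionSchema, TestInapplicableError, feature_names

__all__ = ["kruskal_wallis_test", "kw_statistic_matrix", "independence_report",
           "IndependenceReport"]


def kw_statistic_matrix(values: np.ndarray, group_codes: np.ndarray, n_groups: int):
    """Kruskal-Wallis H and p for every column of ``values`` at once.

    Parameters
    ----------
    values : (N, G) float array
    group_codes : (N,) int array with codes 0..n_groups-1, each present
    n_groups : number of groups

    Returns
    -------
    (H, p) : two (G,) arrays.  Columns whose values are all identical get
    H = 0, p = 1 (no evidence of any difference).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    N, G = values.shape
    ranks = stats.rankdata(values, axis=0, method="average")
    indicator = np.zeros((n_groups, N))
    indicator[group_codes, np.arange(N)] = 1.0
    counts = indicator.sum(axis=1)
    rank_sums = indicator @ ranks  # (n_groups, G)
    H = 12.0 / (N * (N + 1.0)) * (rank_sums ** 2 / counts[:, None]).sum(axis=0) - 3.0 * (
        N + 1.0
    )
    # tie correction per column; continuous columns (no ties) skip the
    # per-column unique pass
    tie_term = np.zeros(G)
    srt = np.sort(values, axis=0)
    has_ties = (srt[1:] == srt[:-1]).any(axis=0) if N > 1 else np.zeros(G, bool)
    for g in np.flatnonzero(has_ties):
        _, t = np.unique(values[:, g], return_counts=True)
        tie_term[g] = (t ** 3 - t).sum()
    correction = 1.0 - tie_term / (N ** 3 - N)
    H_adj = np.zeros(G)
    p = np.ones(G)
    ok = correction > 0  # correction == 0 iff all values identical
    H_adj[ok] = H[ok] / correction[ok]
    p[ok] = stats.chi2.sf(H_adj[ok], n_groups - 1)
    return H_adj, p


def kruskal_wallis_test(values, groups):
    """H statistic and chi-square p-value for one feature vector.

    ``groups`` is any categorical vector aligned with ``values``; at least
    two non-empty groups are required.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise TestInapplicableError("values and groups have different lengths")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise TestInapplicableError(
            f"need >= 2 non-empty groups, got {len(labels)}"
        )
    H, p = kw_statistic_matrix(values[:, None], codes, len(labels))
    return float(H[0]), float(p[0])


@dataclass
class IndependenceReport:
    """Per-(feature, parameter, subgroup) KW results and the resulting
    acquisition-independent feature set.

    ``records`` is a long-format DataFrame with columns feature, parameter,
    subgroup, H, p, flagged.  ``skipped`` lists (parameter, subgroup) scopes
    that could not be tested (empty subgroup or a single instance present);
    untestable scopes count as passes.
    """

    alpha: float
    records: pd.DataFrame
    independent_features: list
    failure_counts: dict
    skipped: list = field(default_factory=list)

    @property
    def independent_fraction(self):
        return len(self.independent_features) / self.n_features

    @property
    def n_features(self):
        return len(self._all_features)

    _all_features: list = field(default_factory=list)

    def pvalue(self, feature, parameter, subgroup):
        r = self.records
        row = r[(r.feature == feature) & (r.parameter == parameter) & (r.subgroup == subgroup)]
        if row.empty:
            raise KeyError((feature, parameter, subgroup))
        return float(row.p.iloc[0])

    def to_frame(self):
        return self.records.copy()

    def to_dict(self):
        return {
            "alpha": self.alpha,
            "independent_features": list(self.independent_features),
            "failure_counts": {f"{p}|{s}": c for (p, s), c in self.failure_counts.items()},
            "skipped": [list(x) for x in self.skipped],
            "n_features": self.n_features,
        }


def independence_report(
    table: pd.DataFrame,
    schema: AcquisitionSchema,
    subgroups=("benign", "malignant"),
    alpha: float = 0.05,
) -> IndependenceReport:
    """Run the full acquisition-independence gate on a (harmonized) table.

    A feature is independent iff no (parameter, subgroup) test over the
    requested subgroups has p <= alpha.
    """
    feats = feature_names(table, schema)
    rows = []
    skipped = []
    flagged = np.zeros(len(feats), dtype=bool)
    failure_counts = {}
    for param in schema.parameters:
        for sub in subgroups:
            sub_tab = table[table["subgroup"] == sub]
            if sub_tab.empty:
                skipped.append((param, sub))
                continue
            labels, codes = np.unique(sub_tab[param].astype(str), return_inverse=True)
            if len(labels) < 2:
                skipped.append((param, sub))
                continue
            H, p = kw_statistic_matrix(
                sub_tab[feats].to_numpy(dtype=float), codes, len(labels)
            )
            fail = p <= alpha
            flagged |= fail
            failure_counts[(param, sub)] = int(fail.sum())
            rows.append(
                pd.DataFrame(
                    {
                        "feature": feats,
                        "parameter": param,
                        "subgroup": sub,
                        "H": H,
                        "p": p,
                        "flagged": fail,
                    }
                )
            )
    records = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["feature", "parameter", "subgroup", "H", "p", "flagged"])
    )
    independent = [f for f, bad in zip(feats, flagged) if not bad]
    return IndependenceReport(
        alpha=alpha,
        records=records,
        independent_features=independent,
        failure_counts=failure_counts,
        skipped=skipped,
        _all_features=feats,
    )
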