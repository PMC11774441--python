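"""Parametric empirical-Bayes ComBat for one acquisition parameter.

The model per feature g, scan j in batch (instance) i is

    y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig eps_ijg

with X the one-hot covariate design (reference level dropped), gamma a
batch location effect and delta a batch scale effect.  Fitting proceeds in
the standard three steps: least squares for alpha, beta, gamma under the
weighted constraint sum_i n_i gamma_ig = 0; standardization by the pooled
residual scale; then parametric empirical Bayes — a Normal prior on gamma
and an inverse-gamma prior on delta^2, hyperparameters by method of moments
across features, and iteration of the conditional posterior means to a
fixed point.  Harmonized values are

    y*_ijg = sigma_g (z_ijg - gamma*_ig) / delta*_ig + alpha_g + X_j beta_g.

``fit`` learns everything from a training table; ``transform`` applies the
frozen estimates to any table whose batch (and covariate) levels were seen
at fit time, so train/test semantics are strict.  The numerical core works
on plain arrays (the nested harmonizer re-fits it hundreds of times while
searching parameter orderings); the pandas interface is a thin shell.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .schema import (
    AcquisitionSchema,
    SchemaError,
    UnharmonizableLevelError,
    UnseenLevelError,
    feature_names,
)

__all__ = ["ComBat", "fit_combat", "apply_combat"]


def _postmean(g_hat, g_bar, n, d_old, t2):
    return (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterate the conditional posterior updates for one batch.

    ``sdat`` is the (n_i, G) standardized data of the batch.  Matches the
    reference parametric ComBat iteration, including its convergence
    measure, so results are reproducible against independent
    implementations to numerical precision.
    """
    n = float(sdat.shape[0])
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            change = max(
                np.max(np.abs(g_new - g_old) / g_old),
                np.max(np.abs(d_new - d_old) / d_old),
            )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


class ComBat(BaseEstimator):
    """Harmonize one acquisition parameter of a feature table.

    Parameters
    ----------
    parameter : str
        Acquisition-parameter column treated as the batch variable.
    schema : AcquisitionSchema
        Identifies metadata/parameter columns so the rest are features.
    covariate : str or None, default None
        Metadata column (typically ``"subgroup"``) whose biological effect
        is preserved during correction; one-hot encoded with the most
        frequent level as reference.  ``None`` gives plain collective
        harmonization.
    min_batch_size : int, default 3
        Smallest admissible batch; fitting with a rarer level raises
        :class:`UnharmonizableLevelError` so the caller can exclude it.
    conv, max_iter :
        Convergence tolerance (max relative change) and cap for the
        empirical-Bayes iteration.

    Attributes (set by :meth:`fit`)
    -------------------------------
    batch_levels_, batch_counts_ : fitted instance labels and sizes n_i
    grand_effects_ : per-feature alpha-hat
    covariate_coefficients_ : (n_cov_columns, G) beta-hat
    pooled_sd_ : per-feature sigma-hat
    gamma_hat_, delta_hat_ : pre-EB per-(level, feature) estimates
    eb_location_, eb_scale_ : posterior gamma*, delta*
    prior_hyperparams_ : per-level dict (gamma_bar, t2, a_prior, b_prior)
    degenerate_features_ : zero-variance features passed through untouched
    """

    def __init__(self, parameter, schema, covariate=None, min_batch_size=3,
                 conv=1e-4, max_iter=500):
        self.parameter = parameter
        self.schema = schema
        self.covariate = covariate
        self.min_batch_size = min_batch_size
        self.conv = conv
        self.max_iter = max_iter

    # -- array-level core ----------------------------------------------
    def _covariate_design(self, labels: np.ndarray, fit: bool) -> np.ndarray:
        if fit:
            uniq, counts = np.unique(labels, return_counts=True)
            ref = uniq[np.argmax(counts)]  # most frequent level is reference
            self.covariate_levels_ = [ref] + sorted(l for l in uniq if l != ref)
        levels = self.covariate_levels_
        unseen = set(np.unique(labels)) - set(levels)
        if unseen:
            raise UnseenLevelError(
                f"unseen covariate level(s) {sorted(unseen)} for {self.covariate!r}"
            )
        cols = [(labels == l).astype(float) for l in levels[1:]]
        return np.column_stack(cols) if cols else np.zeros((len(labels), 0))

    def _fit_core(self, data: np.ndarray, batches: np.ndarray,
                  cov_labels: np.ndarray | None):
        n, G = data.shape
        levels = sorted(np.unique(batches).tolist())
        if len(levels) < 2:
            raise UnharmonizableLevelError(
                f"parameter {self.parameter!r} has a single level "
                f"{levels!r}: nothing to harmonize",
                levels=levels,
            )
        masks = [batches == l for l in levels]
        counts = np.array([m.sum() for m in masks])
        small = [l for l, c in zip(levels, counts) if c < max(self.min_batch_size, 2)]
        if small:
            raise UnharmonizableLevelError(
                f"level(s) {small!r} of {self.parameter!r} have fewer than "
                f"{self.min_batch_size} scans",
                levels=small,
            )
        self.batch_levels_ = levels
        self.batch_counts_ = counts

        batch_design = np.column_stack([m.astype(float) for m in masks])
        if cov_labels is not None:
            cov_design = self._covariate_design(cov_labels, fit=True)
        else:
            self.covariate_levels_ = []
            cov_design = np.zeros((n, 0))
        design = np.hstack([batch_design, cov_design])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise SchemaError(
                f"batch x covariate design for {self.parameter!r} is confounded "
                "to singularity"
            )

        L = len(levels)
        B_hat = np.linalg.solve(design.T @ design, design.T @ data)
        grand = (counts / n) @ B_hat[:L]
        resid = data - design @ B_hat
        var_pooled = (resid ** 2).mean(axis=0)

        good = var_pooled > 0
        if not good.all():
            bad_idx = np.flatnonzero(~good)
            self._degenerate_idx_ = bad_idx
            warnings.warn(
                f"{len(bad_idx)} zero-variance feature(s) passed through "
                "unharmonized",
                RuntimeWarning,
                stacklevel=3,
            )
        else:
            self._degenerate_idx_ = np.zeros(0, dtype=int)

        self.grand_effects_ = grand
        self.covariate_coefficients_ = B_hat[L:]
        self.pooled_sd_ = np.sqrt(np.where(good, var_pooled, 1.0))
        self._good_ = good

        stand_mean = grand[None, :] + cov_design @ self.covariate_coefficients_
        z = (data[:, good] - stand_mean[:, good]) / self.pooled_sd_[None, good]

        Gg = int(good.sum())
        gamma_hat = np.empty((L, Gg))
        delta_hat = np.empty((L, Gg))
        for i, m in enumerate(masks):
            gamma_hat[i] = z[m].mean(axis=0)
            delta_hat[i] = z[m].var(axis=0, ddof=1)

        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        priors = []
        if Gg >= 2:
            gamma_bar = gamma_hat.mean(axis=1)
            t2 = gamma_hat.var(axis=1, ddof=1)
            mdh = delta_hat.mean(axis=1)
            s2 = delta_hat.var(axis=1, ddof=1)
            a_prior = (2.0 * s2 + mdh ** 2) / s2
            b_prior = (mdh * s2 + mdh ** 3) / s2
            for i, m in enumerate(masks):
                gamma_star[i], delta_star[i] = _it_sol(
                    z[m], gamma_hat[i], delta_hat[i],
                    gamma_bar[i], t2[i], a_prior[i], b_prior[i],
                    conv=self.conv, max_iter=self.max_iter,
                )
                priors.append(
                    {"gamma_bar": gamma_bar[i], "t2": t2[i],
                     "a_prior": a_prior[i], "b_prior": b_prior[i]}
                )
        else:
            # EB shrinkage needs several features to estimate priors from;
            # fall back to the direct per-batch estimates.
            gamma_star[:] = gamma_hat
            delta_star[:] = delta_hat
            priors = [{} for _ in levels]

        self.gamma_hat_ = gamma_hat
        self.delta_hat_ = delta_hat
        self.eb_location_ = gamma_star
        self.eb_scale_ = delta_star
        self.prior_hyperparams_ = priors
        return self

    def _transform_core(self, data: np.ndarray, batches: np.ndarray,
                        cov_labels: np.ndarray | None,
                        scan_ids=None) -> np.ndarray:
        unseen = set(np.unique(batches)) - set(self.batch_levels_)
        if unseen:
            detail = ""
            if scan_ids is not None:
                offenders = [s for s, b in zip(scan_ids, batches) if b in unseen]
                detail = f" (scans {offenders[:5]})"
            raise UnseenLevelError(
                f"instance(s) {sorted(unseen)} of {self.parameter!r} were not "
                f"in the training set{detail}"
            )
        if self.covariate is not None and cov_labels is not None:
            cov_design = self._covariate_design(cov_labels, fit=False)
        else:
            cov_design = np.zeros((len(data), 0))
        good = self._good_
        stand_mean = (
            self.grand_effects_[None, :] + cov_design @ self.covariate_coefficients_
        )
        z = (data[:, good] - stand_mean[:, good]) / self.pooled_sd_[None, good]
        adj = z.copy()
        for i, l in enumerate(self.batch_levels_):
            rows = batches == l
            if rows.any():
                adj[rows] = (z[rows] - self.eb_location_[i][None, :]) / np.sqrt(
                    self.eb_scale_[i]
                )[None, :]
        out = data.copy()
        out[:, good] = adj * self.pooled_sd_[None, good] + stand_mean[:, good]
        return out

    # -- estimator API (pandas shell) ----------------------------------
    def fit(self, table: pd.DataFrame, y=None):
        feats = feature_names(table, self.schema)
        self.feature_names_ = feats
        data = table[feats].to_numpy(dtype=float)
        batches = table[self.parameter].astype(str).to_numpy()
        cov = (
            table[self.covariate].astype(str).to_numpy()
            if self.covariate is not None
            else None
        )
        self._fit_core(data, batches, cov)
        return self

    @property
    def degenerate_features_(self):
        return [self.feature_names_[i] for i in self._degenerate_idx_]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "eb_location_"):
            raise RuntimeError("ComBat instance is not fitted")
        feats = self.feature_names_
        missing = [f for f in feats if f not in table.columns]
        if missing:
            raise SchemaError(f"table lacks fitted feature columns {missing[:5]}...")
        data = table[feats].to_numpy(dtype=float)
        batches = table[self.parameter].astype(str).to_numpy()
        cov = (
            table[self.covariate].astype(str).to_numpy()
            if self.covariate is not None
            else None
        )
        ids = table["scan_id"].tolist() if "scan_id" in table.columns else None
        vals = self._transform_core(data, batches, cov, scan_ids=ids)
        out = pd.concat(
            [
                table.drop(columns=feats),
                pd.DataFrame(vals, columns=feats, index=table.index),
            ],
            axis=1,
        )
        return out[table.columns]

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(table).transform(table)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "schema": self.schema.to_dict(),
            "covariate": self.covariate,
            "min_batch_size": self.min_batch_size,
            "conv": self.conv,
            "max_iter": self.max_iter,
            "feature_names": self.feature_names_,
            "batch_levels": self.batch_levels_,
            "batch_counts": self.batch_counts_.tolist(),
            "covariate_levels": self.covariate_levels_,
            "grand_effects": self.grand_effects_.tolist(),
            "covariate_coefficients": self.covariate_coefficients_.tolist(),
            "pooled_sd": self.pooled_sd_.tolist(),
            "good": self._good_.tolist(),
            "gamma_hat": self.gamma_hat_.tolist(),
            "delta_hat": self.delta_hat_.tolist(),
            "eb_location": self.eb_location_.tolist(),
            "eb_scale": self.eb_scale_.tolist(),
            "prior_hyperparams": self.prior_hyperparams_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComBat":
        m = cls(
            parameter=d["parameter"],
            schema=AcquisitionSchema.from_dict(d["schema"]),
            covariate=d["covariate"],
            min_batch_size=d["min_batch_size"],
            conv=d["conv"],
            max_iter=d["max_iter"],
        )
        m.feature_names_ = list(d["feature_names"])
        m.batch_levels_ = list(d["batch_levels"])
        m.batch_counts_ = np.array(d["batch_counts"])
        m.covariate_levels_ = list(d["covariate_levels"])
        m.grand_effects_ = np.array(d["grand_effects"])
        m.covariate_coefficients_ = np.array(d["covariate_coefficients"]).reshape(
            -1, len(m.grand_effects_)
        )
        m.pooled_sd_ = np.array(d["pooled_sd"])
        m._good_ = np.array(d["good"], dtype=bool)
        m._degenerate_idx_ = np.flatnonzero(~m._good_)
        m.gamma_hat_ = np.array(d["gamma_hat"])
        m.delta_hat_ = np.array(d["delta_hat"])
        m.eb_location_ = np.array(d["eb_location"])
        m.eb_scale_ = np.array(d["eb_scale"])
        m.prior_hyperparams_ = d["prior_hyperparams"]
        return m


def fit_combat(table, parameter, schema, covariate_labels=None, min_batch_size=3):
    """Functional wrapper: fit a :class:`ComBat` model on a training table.

    ``covariate_labels`` names a metadata column (e.g. ``"subgroup"``) or is
    None for collective harmonization.
    """
    return ComBat(
        parameter, schema, covariate=covariate_labels, min_batch_size=min_batch_size
    ).fit(table)


def apply_combat(model: ComBat, table) -> pd.DataFrame:
    """Apply a fitted model to (possibly unseen) scans; never refits."""
    return model.transform(table)
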