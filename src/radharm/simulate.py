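"""Synthetic radiomic cohorts with known biology and known batch effects.

The generator emulates the statistical structure of a clinical chest-CT
radiomics cohort: patients carry one or more pulmonary nodules, nodules are
scanned one or more times, scans belong to a benign, malignant, or
lung-cancer-screening (LCS) subgroup, and each scan records categorical
acquisition parameters (contrast enhancement, tube voltage, focal spot,
manufacturer) plus ~107 real-valued features.

Per feature g the clean value of a scan is

    y = mu_g + a * kappa_g + eps,   eps ~ Normal(0, sigma_g^2)

where ``kappa_g`` is the benign->malignant mean shift and ``a`` is 1 for
malignant scans, 0 for benign and presumed-benign LCS scans, and an
attenuation factor (default 0.5) for LCS nodules that later turn malignant
(their biology at scan time is unknown).  Acquisition batch effects are then
injected additively in location and multiplicatively in scale,

    y <- mu-part + sum_p gamma_{p,i,s,g} + (prod_p delta_{p,i,s,g}) * eps-part,

indexed by parameter p, instance i, subgroup s, feature g.  Contrast
enhancement is quasi-systematically confounded with malignancy: malignant
scans are far more likely to be contrast-enhanced than benign or screening
scans, which is exactly the confounding that makes collective harmonization
hazardous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    META_COLUMNS,
    SUBGROUPS,
    AcquisitionSchema,
    ConfigurationError,
    SchemaError,
    default_schema,
)

__all__ = [
    "SimulationConfig",
    "default_config",
    "shared_effects_config",
    "null_config",
    "generate_cohort",
    "inject_batch_effects",
]


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort.

    ``batch_location`` maps ``(parameter, instance, subgroup)`` to a
    per-feature location shift vector (gamma); ``batch_scale`` maps the same
    keys to a per-feature positive scale factor vector (delta).  Missing keys
    mean "no effect" (gamma = 0, delta = 1).  ``instance_frequencies`` maps
    ``(parameter, subgroup)`` to a dict instance -> probability.
    """

    n_patients: int = 193
    n_nodules: int = 305
    n_scans: int = 567
    subgroup_proportions: dict = field(
        default_factory=lambda: {"LCS": 323 / 567, "benign": 58 / 567, "malignant": 186 / 567}
    )
    n_features: int = 107
    acquisition_schema: AcquisitionSchema = field(default_factory=default_schema)
    instance_frequencies: dict = field(default_factory=dict)
    baseline_means: np.ndarray | None = None
    baseline_sds: np.ndarray | None = None
    malignancy_effects: np.ndarray | None = None
    batch_location: dict = field(default_factory=dict)
    batch_scale: dict = field(default_factory=dict)
    effect_sharing: str = "subgroup_specific"
    lcs_future_malignant_fraction: float = 0.076
    lcs_effect_attenuation: float = 0.5
    feature_correlation: float = 0.0
    mean_scans_per_nodule: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.baseline_means is None:
            self.baseline_means = np.zeros(self.n_features)
        if self.baseline_sds is None:
            self.baseline_sds = np.ones(self.n_features)
        if self.malignancy_effects is None:
            self.malignancy_effects = np.zeros(self.n_features)
        self.baseline_means = np.asarray(self.baseline_means, dtype=float)
        self.baseline_sds = np.asarray(self.baseline_sds, dtype=float)
        self.malignancy_effects = np.asarray(self.malignancy_effects, dtype=float)
        if not self.instance_frequencies:
            self.instance_frequencies = _default_frequencies(self.acquisition_schema)
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self):
        if self.n_features <= 0:
            raise ConfigurationError("n_features must be positive")
        if not (self.n_scans >= self.n_nodules >= self.n_patients >= 1):
            raise ConfigurationError("need n_scans >= n_nodules >= n_patients >= 1")
        total = sum(self.subgroup_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"subgroup_proportions sum to {total}, not 1")
        if set(self.subgroup_proportions) - set(SUBGROUPS):
            raise ConfigurationError("unknown subgroup in subgroup_proportions")
        for g in (self.baseline_means, self.malignancy_effects):
            if g.shape != (self.n_features,):
                raise ConfigurationError("per-feature vectors must have length n_features")
        if self.baseline_sds.shape != (self.n_features,) or (self.baseline_sds <= 0).any():
            raise ConfigurationError("baseline_sds must be positive, length n_features")
        schema = self.acquisition_schema
        for (param, sub), freqs in self.instance_frequencies.items():
            if param not in schema.parameters:
                raise ConfigurationError(f"frequencies for unknown parameter {param!r}")
            if set(freqs) - set(schema.levels[param]):
                raise ConfigurationError(f"frequencies name unknown instances of {param!r}")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"instance frequencies for ({param!r}, {sub!r}) do not sum to 1"
                )
        for key, vec in self.batch_scale.items():
            if (np.asarray(vec) <= 0).any():
                raise ConfigurationError(f"batch_scale for {key} must be positive")
        for effects, neutral in ((self.batch_location, 0.0), (self.batch_scale, 1.0)):
            for (param, inst, sub) in effects:
                if param not in schema.parameters or inst not in schema.levels[param]:
                    raise ConfigurationError(f"batch effect for unknown ({param!r}, {inst!r})")
        if self.effect_sharing == "shared_across_subgroups":
            self._check_shared(self.batch_location, np.zeros(self.n_features))
            self._check_shared(self.batch_scale, np.ones(self.n_features))
        elif self.effect_sharing != "subgroup_specific":
            raise ConfigurationError(f"unknown effect_sharing {self.effect_sharing!r}")
        if not (0.0 <= self.lcs_future_malignant_fraction <= 1.0):
            raise ConfigurationError("lcs_future_malignant_fraction must be in [0, 1]")

    def _check_shared(self, effects, neutral):
        keys = {(p, i) for (p, i, _s) in effects}
        for p, i in keys:
            vecs = [
                np.asarray(effects.get((p, i, s), neutral), dtype=float) for s in SUBGROUPS
            ]
            for v in vecs[1:]:
                if not np.allclose(v, vecs[0]):
                    raise ConfigurationError(
                        f"effect_sharing=shared_across_subgroups but ({p!r}, {i!r}) "
                        "differs between subgroups"
                    )

    # -- lookups -------------------------------------------------------
    def location_effect(self, param, instance, subgroup):
        vec = self.batch_location.get((param, instance, subgroup))
        if vec is None:
            return np.zeros(self.n_features)
        return np.asarray(vec, dtype=float)

    def scale_effect(self, param, instance, subgroup):
        vec = self.batch_scale.get((param, instance, subgroup))
        if vec is None:
            return np.ones(self.n_features)
        return np.asarray(vec, dtype=float)

    def biological_shift_factor(self, subgroup, malignancy_label):
        """Multiplier ``a`` of kappa for one scan."""
        if subgroup == "malignant":
            return 1.0
        if subgroup == "LCS" and malignancy_label == 1:
            return self.lcs_effect_attenuation
        return 0.0


def _default_frequencies(schema: AcquisitionSchema) -> dict:
    """Instance frequencies with the CE-malignancy confounding: contrast is
    mostly reserved for scans already suspicious for cancer."""
    ce = {"benign": {"no": 0.8, "yes": 0.2},
          "malignant": {"no": 0.3, "yes": 0.7},
          "LCS": {"no": 0.9, "yes": 0.1}}
    shared = {
        "KVP": {"100": 0.2, "120": 0.6, "140": 0.2},
        "focal_spot": {"small": 0.6, "large": 0.4},
        "manufacturer": {"A": 0.45, "B": 0.35, "C": 0.2},
    }
    freqs = {}
    for sub in SUBGROUPS:
        if "CE" in schema.parameters:
            freqs[("CE", sub)] = dict(ce[sub])
        for p in schema.parameters:
            if p == "CE":
                continue
            if p in shared:
                freqs[(p, sub)] = dict(shared[p])
            else:  # uniform over instances of non-default parameters
                k = len(schema.levels[p])
                freqs[(p, sub)] = {i: 1.0 / k for i in schema.levels[p]}
    return freqs


# ---------------------------------------------------------------------------
# Scenario builders
# ---------------------------------------------------------------------------

def _base_effect_layout(n_features):
    """Feature index blocks used by the built-in scenarios."""
    return {
        "biology": np.arange(0, min(25, n_features)),
        "ce": np.arange(25, min(75, n_features)),
        "shared": np.arange(75, min(90, n_features)),
    }


def default_config(seed: int = 0, n_features: int = 107, **overrides) -> SimulationConfig:
    """Cohort with subgroup-specific (divergent) acquisition effects.

    This is the regime the harmonization comparison is designed around:
    contrast enhancement shifts features of malignant nodules in the opposite
    direction from benign ones (enhanced permeability and retention in
    tumours vs. little uptake in benign tissue), while tube voltage, focal
    spot and manufacturer act identically on all tissue.  Features 0-24 carry
    the malignancy signal (kappa = 2 sd), features 25-74 carry the divergent
    CE effect (+/-1.5 sd, with a divergent scale effect on 25-39), features
    75-89 carry shared protocol effects, and the remainder are pure noise.
    """
    idx = _base_effect_layout(n_features)
    kappa = np.zeros(n_features)
    kappa[idx["biology"]] = 2.0

    loc, scale = {}, {}
    # Divergent CE location effects (opposite sign for malignant tissue).
    for sub, sign in (("malignant", +1.0), ("benign", -1.0), ("LCS", -1.0)):
        v = np.zeros(n_features)
        v[idx["ce"]] = sign * 1.5
        loc[("CE", "yes", sub)] = v
        s = np.ones(n_features)
        s[idx["ce"][: len(idx["ce"]) // 3]] = 1.6 if sign > 0 else 0.8
        scale[("CE", "yes", sub)] = s
    # Shared (tissue-independent) protocol effects.
    for sub in SUBGROUPS:
        v = np.zeros(n_features)
        v[idx["shared"]] = 0.8
        loc[("manufacturer", "B", sub)] = v
        w = np.zeros(n_features)
        w[idx["shared"]] = -0.6
        loc[("KVP", "140", sub)] = w
        s = np.ones(n_features)
        s[idx["shared"]] = 1.4
        scale[("focal_spot", "large", sub)] = s

    cfg = dict(
        n_features=n_features,
        malignancy_effects=kappa,
        batch_location=loc,
        batch_scale=scale,
        effect_sharing="subgroup_specific",
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def shared_effects_config(seed: int = 0, n_features: int = 107, **overrides) -> SimulationConfig:
    """Same cohort structure, but every acquisition effect is identical across
    subgroups (the regime where a covariate suffices and separate fits buy
    nothing)."""
    idx = _base_effect_layout(n_features)
    kappa = np.zeros(n_features)
    kappa[idx["biology"]] = 2.0

    loc, scale = {}, {}
    for sub in SUBGROUPS:
        v = np.zeros(n_features)
        v[idx["ce"]] = 1.5
        loc[("CE", "yes", sub)] = v
        s = np.ones(n_features)
        s[idx["ce"][: len(idx["ce"]) // 3]] = 1.6
        scale[("CE", "yes", sub)] = s
        w = np.zeros(n_features)
        w[idx["shared"]] = 0.8
        loc[("manufacturer", "B", sub)] = w
        u = np.zeros(n_features)
        u[idx["shared"]] = -0.6
        loc[("KVP", "140", sub)] = u
        t = np.ones(n_features)
        t[idx["shared"]] = 1.4
        scale[("focal_spot", "large", sub)] = t

    cfg = dict(
        n_features=n_features,
        malignancy_effects=kappa,
        batch_location=loc,
        batch_scale=scale,
        effect_sharing="shared_across_subgroups",
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def null_config(seed: int = 0, n_features: int = 107, **overrides) -> SimulationConfig:
    """No biology, no batch effects: every feature is i.i.d. Gaussian noise.
    Used for type-I-error calibration of the acquisition-independence gate."""
    cfg = dict(
        n_features=n_features,
        effect_sharing="shared_across_subgroups",
        lcs_future_malignant_fraction=0.076,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, proportions: dict, minimum: int = 0) -> dict:
    """Apportion ``total`` over keys proportionally (largest-remainder rule,
    ties broken by key order); each key receives at least ``minimum``."""
    keys = list(proportions)
    raw = np.array([proportions[k] * total for k in keys])
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = total - base.sum()
    order = np.argsort(-rem, kind="stable")
    for j in order[:short]:
        base[j] += 1
    out = {k: int(b) for k, b in zip(keys, base)}
    for k in keys:
        if out[k] < minimum:
            donor = max(out, key=out.get)
            out[donor] -= minimum - out[k]
            out[k] = minimum
    return out


def _composition(total: int, parts: int, rng: np.random.Generator,
                 mean_per_part: float | None = None) -> np.ndarray:
    """Split ``total`` items into ``parts`` groups of size >= 1.

    Sizes are drawn i.i.d. from a geometric distribution truncated at 8
    (mean set by ``mean_per_part``, mimicking longitudinal re-scanning),
    then repaired by random unit moves until they sum to ``total`` exactly.
    """
    if parts == 0:
        return np.zeros(0, dtype=int)
    mean = mean_per_part if mean_per_part is not None else max(total / parts, 1.0)
    p = min(1.0, 1.0 / mean)
    sizes = np.minimum(rng.geometric(p, size=parts), 8)
    diff = total - int(sizes.sum())
    while diff != 0:
        j = rng.integers(parts)
        if diff > 0:
            sizes[j] += 1
            diff -= 1
        elif sizes[j] > 1:
            sizes[j] -= 1
            diff += 1
    return sizes


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a full synthetic cohort as a feature table.

    Subgroup scan/nodule/patient counts follow the configured proportions via
    largest-remainder apportionment (so the default configuration reproduces
    the reference cohort sizes exactly); nodules nest in patients and scans
    nest in nodules; all scans of a nodule share its subgroup and labels but
    redraw noise and acquisition.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_struct, rng_label, rng_acq, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    schema = config.acquisition_schema

    present = {s: p for s, p in config.subgroup_proportions.items() if p > 0}
    scans_per_sub = _largest_remainder(config.n_scans, present, minimum=1)
    nod_per_sub = _largest_remainder(config.n_nodules, present, minimum=1)
    pat_per_sub = _largest_remainder(config.n_patients, present, minimum=1)
    for s in present:  # nesting sanity: patients <= nodules <= scans
        nod_per_sub[s] = min(max(nod_per_sub[s], pat_per_sub[s]), scans_per_sub[s])
    # re-balance nodules to the exact total after clamping
    drift = config.n_nodules - sum(nod_per_sub.values())
    subs_sorted = sorted(present, key=lambda s: -scans_per_sub[s])
    k = 0
    while drift != 0:
        s = subs_sorted[k % len(subs_sorted)]
        lo, hi = pat_per_sub[s], scans_per_sub[s]
        if drift > 0 and nod_per_sub[s] < hi:
            nod_per_sub[s] += 1
            drift -= 1
        elif drift < 0 and nod_per_sub[s] > lo:
            nod_per_sub[s] -= 1
            drift += 1
        k += 1

    rows = []
    pat_counter = nod_counter = scan_counter = 0
    for sub in [s for s in SUBGROUPS if s in present]:
        n_p, n_n, n_s = pat_per_sub[sub], nod_per_sub[sub], scans_per_sub[sub]
        nodules_per_patient = _composition(n_n, n_p, rng_struct, mean_per_part=n_n / n_p)
        scans_per_nodule = _composition(
            n_s, n_n, rng_struct, mean_per_part=config.mean_scans_per_nodule or n_s / n_n
        )
        # which LCS nodules later turn malignant
        if sub == "LCS":
            n_flag = int(round(config.lcs_future_malignant_fraction * n_n))
            flagged = set(rng_label.choice(n_n, size=n_flag, replace=False).tolist())
        else:
            flagged = set()
        nod_idx = 0
        for p_i in range(n_p):
            pat_counter += 1
            pid = f"P{pat_counter:04d}"
            for _ in range(nodules_per_patient[p_i]):
                nod_counter += 1
                nid = f"N{nod_counter:04d}"
                if sub == "benign":
                    label = 0
                elif sub == "malignant":
                    label = 1
                else:
                    label = int(nod_idx in flagged)
                for _ in range(scans_per_nodule[nod_idx]):
                    scan_counter += 1
                    rows.append(
                        {
                            "scan_id": f"S{scan_counter:04d}",
                            "patient_id": pid,
                            "nodule_id": nid,
                            "subgroup": sub,
                            "malignancy_label": label,
                        }
                    )
                nod_idx += 1

    table = pd.DataFrame(rows)
    n = len(table)

    # acquisition instances per scan
    for param in schema.parameters:
        col = np.empty(n, dtype=object)
        for sub in present:
            mask = (table["subgroup"] == sub).to_numpy()
            freqs = config.instance_frequencies[(param, sub)]
            insts = list(freqs)
            probs = np.array([freqs[i] for i in insts])
            col[mask] = rng_acq.choice(insts, size=int(mask.sum()), p=probs)
        table[param] = col

    # clean feature values
    feat_names = [f"feature_{g:03d}" for g in range(config.n_features)]
    a = np.array(
        [
            config.biological_shift_factor(s, l)
            for s, l in zip(table["subgroup"], table["malignancy_label"])
        ]
    )
    mu_part = config.baseline_means[None, :] + a[:, None] * config.malignancy_effects[None, :]
    eps = rng_noise.standard_normal((n, config.n_features))
    if config.feature_correlation:
        rho = config.feature_correlation
        common = rng_noise.standard_normal((n, 1))
        eps = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * eps
    clean = mu_part + config.baseline_sds[None, :] * eps
    table = pd.concat([table, pd.DataFrame(clean, columns=feat_names)], axis=1)

    return inject_batch_effects(table, config)


def inject_batch_effects(clean_table: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Overlay acquisition batch effects on a clean table.

    Location effects add across parameters and scale effects multiply; the
    result is deterministic given the clean table.  The biological mean part
    is reconstructed from subgroup and label, so the transformation acts only
    on the noise component.
    """
    schema = config.acquisition_schema
    feat_names = [c for c in clean_table.columns
                  if c not in META_COLUMNS and c not in schema.parameters]
    if len(feat_names) != config.n_features:
        raise SchemaError(
            f"table has {len(feat_names)} feature columns, config expects {config.n_features}"
        )
    for param in schema.parameters:
        bad = set(clean_table[param].unique()) - set(schema.levels[param])
        if bad:
            raise SchemaError(f"unknown instances {sorted(bad)} for parameter {param!r}")

    y = clean_table[feat_names].to_numpy(dtype=float)
    a = np.array(
        [
            config.biological_shift_factor(s, l)
            for s, l in zip(clean_table["subgroup"], clean_table["malignancy_label"])
        ]
    )
    mu_part = config.baseline_means[None, :] + a[:, None] * config.malignancy_effects[None, :]
    eps_part = y - mu_part

    loc = np.zeros_like(y)
    scale = np.ones_like(y)
    for param in schema.parameters:
        for sub in SUBGROUPS:
            sub_mask = (clean_table["subgroup"] == sub).to_numpy()
            if not sub_mask.any():
                continue
            for inst in schema.levels[param]:
                mask = sub_mask & (clean_table[param] == inst).to_numpy()
                if not mask.any():
                    continue
                loc[mask] += config.location_effect(param, inst, sub)[None, :]
                scale[mask] *= config.scale_effect(param, inst, sub)[None, :]

    out = clean_table.copy()
    out[feat_names] = mu_part + loc + scale * eps_part
    return out
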