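"""Feature-table conventions, the acquisition schema, and CSV I/O.

A feature table is a plain :class:`pandas.DataFrame` with one row per scan:
five metadata columns (``scan_id``, ``patient_id``, ``nodule_id``,
``subgroup``, ``malignancy_label``), one categorical column per acquisition
parameter, and one real-valued column per radiomic feature.  The
:class:`AcquisitionSchema` names the acquisition-parameter columns and their
admissible instances; every remaining column is a feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Metadata columns every feature table carries, in canonical order.
META_COLUMNS = ["scan_id", "patient_id", "nodule_id", "subgroup", "malignancy_label"]

SUBGROUPS = ("benign", "malignant", "LCS")


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(ValueError):
    """A table does not conform to the acquisition schema / column contract."""


class UnharmonizableLevelError(ValueError):
    """A batch level has too few scans (or only one level exists) to fit ComBat."""

    def __init__(self, message, levels=None):
        super().__init__(message)
        self.levels = list(levels) if levels is not None else []


class UnseenLevelError(ValueError):
    """A scan carries a batch/covariate level never seen at fit time."""


class TrialUnusableError(RuntimeError):
    """Exclusion emptied a required fitting scope; the whole trial is dropped."""


class StratificationError(ValueError):
    """A stratum is too small for the requested number of folds."""


class TestInapplicableError(ValueError):
    """A statistical test cannot be computed on the given grouping."""

    __test__ = False  # not a pytest collection target


@dataclass(frozen=True)
class AcquisitionSchema:
    """Ordered acquisition parameters and their categorical instances.

    Parameters
    ----------
    parameters : list of str
        Acquisition-parameter (batch variable) names, e.g. contrast
        enhancement or scanner manufacturer.  Order fixes the default
        harmonization sequence before permutation optimization.
    levels : dict of str -> list of str
        Admissible instance labels per parameter; each parameter needs at
        least two instances for harmonization to be meaningful.
    """

    parameters: tuple
    levels: dict = field(compare=False)

    def __init__(self, parameters, levels):
        params = tuple(parameters)
        if len(set(params)) != len(params):
            raise ConfigurationError("acquisition parameter names must be unique")
        for p in params:
            if p not in levels:
                raise ConfigurationError(f"no instance labels given for parameter {p!r}")
            if len(levels[p]) < 2:
                raise ConfigurationError(
                    f"parameter {p!r} needs >= 2 instance labels, got {len(levels[p])}"
                )
        object.__setattr__(self, "parameters", params)
        object.__setattr__(self, "levels", {p: list(levels[p]) for p in params})

    def to_dict(self):
        return {"parameters": list(self.parameters), "levels": dict(self.levels)}

    @classmethod
    def from_dict(cls, d):
        return cls(d["parameters"], d["levels"])


def default_schema() -> AcquisitionSchema:
    """The four-parameter CT acquisition schema used throughout: contrast
    enhancement, tube voltage, focal spot size, scanner manufacturer."""
    return AcquisitionSchema(
        parameters=["CE", "KVP", "focal_spot", "manufacturer"],
        levels={
            "CE": ["no", "yes"],
            "KVP": ["100", "120", "140"],
            "focal_spot": ["small", "large"],
            "manufacturer": ["A", "B", "C"],
        },
    )


def feature_names(table: pd.DataFrame, schema: AcquisitionSchema) -> list:
    """Columns of ``table`` that are radiomic features (neither metadata nor
    acquisition parameters), in table order."""
    non_features = set(META_COLUMNS) | set(schema.parameters)
    return [c for c in table.columns if c not in non_features]


def validate_table(table: pd.DataFrame, schema: AcquisitionSchema) -> None:
    """Check the column contract and raise :class:`SchemaError` on violation."""
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing metadata columns: {missing}")
    for p in schema.parameters:
        if p not in table.columns:
            raise SchemaError(f"missing acquisition parameter column: {p!r}")
        bad = set(table[p].unique()) - set(schema.levels[p])
        if bad:
            raise SchemaError(f"unknown instances {sorted(bad)} for parameter {p!r}")
    feats = feature_names(table, schema)
    if not feats:
        raise SchemaError("table has no feature columns")
    values = table[feats].to_numpy()
    import numpy as np

    if not np.isfinite(values).all():
        raise SchemaError("non-finite feature values present")
    bad_sub = set(table["subgroup"].unique()) - set(SUBGROUPS)
    if bad_sub:
        raise SchemaError(f"unknown subgroup labels: {sorted(bad_sub)}")


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as UTF-8 CSV with a header row."""
    table.to_csv(path, index=False, encoding="utf-8")


def read_feature_table(path, schema: AcquisitionSchema | None = None) -> pd.DataFrame:
    """Read a feature table CSV; parameter columns come back as strings."""
    df = pd.read_csv(path, encoding="utf-8")
    for c in ("scan_id", "patient_id", "nodule_id", "subgroup"):
        if c in df.columns:
            df[c] = df[c].astype(str)
    if schema is not None:
        for p in schema.parameters:
            if p in df.columns:
                df[p] = df[p].astype(str)
        validate_table(df, schema)
    return df
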