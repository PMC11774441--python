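import numpy as np
import pandas as pd
import pytest

from radharm import AcquisitionSchema, default_config, generate_cohort


def make_table(values, batch, subgroup=None, labels=None, batch_col="b"):
    """Minimal conforming feature table around a value matrix."""
    values = np.atleast_2d(np.asarray(values, dtype=float).T).T
    n = len(values)
    meta = pd.DataFrame(
        {
            "scan_id": [f"s{i:05d}" for i in range(n)],
            "patient_id": [f"p{i:05d}" for i in range(n)],
            "nodule_id": [f"n{i:05d}" for i in range(n)],
            "subgroup": subgroup if subgroup is not None else "benign",
            "malignancy_label": labels if labels is not None else 0,
            batch_col: batch,
        }
    )
    feats = pd.DataFrame(values, columns=[f"f{g}" for g in range(values.shape[1])])
    return pd.concat([meta, feats], axis=1)


@pytest.fixture(scope="session")
def two_level_schema():
    return AcquisitionSchema(["b"], {"b": ["x", "y"]})


@pytest.fixture(scope="session")
def cohort500():
    """Scaled default cohort (subgroup-specific divergent effects)."""
    cfg = default_config(seed=11, n_scans=500, n_nodules=270, n_patients=170)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def trial500(cohort500):
    """One stratified train/test split of the scaled cohort."""
    from radharm import make_splits

    cfg, table = cohort500
    tr_idx, te_idx = make_splits(table, k=5, repeats=1, seed=4)[0]
    return cfg, table.iloc[tr_idx], table.iloc[te_idx]
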