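import numpy as np
import pandas as pd
import pytest

from degratex.pipeline import full_run, load_config


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """One full synthetic three-site analysis run, shared across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = load_config(None)
    full_run(cfg, out, seed=7)
    return out


@pytest.fixture(scope="session")
def separable_cells():
    """Grid-cell table with large class-mean separation in feature space."""
    rng = np.random.default_rng(42)
    rows = []
    centers = {"intact": 0.0, "logged": 4.0, "burned": -4.0}
    for site in ("a", "b"):
        for cls, mu in centers.items():
            for _ in range(60):
                feats = rng.normal(mu, 1.0, size=10)
                rows.append(
                    {"site_id": site, "ref_class": cls,
                     "purity": float(rng.uniform(0.55, 1.0)),
                     **{f"f{i}": v for i, v in enumerate(feats)}}
                )
    return pd.DataFrame(rows)
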