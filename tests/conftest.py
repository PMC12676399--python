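import numpy as np
import pandas as pd
import pytest

from omixvar.containers import DomainMap, FeatureMatrix
from omixvar.synthetic import TruthSpec, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """One synthetic cohort shared by read-only tests."""
    return generate_bundle(TruthSpec(n_samples=600, seed=123))


@pytest.fixture()
def raw_matrix():
    """Tiny handwritten raw metabolite matrix with known QC behaviour."""
    vals = pd.DataFrame(
        {
            "ok": [4.0, 8.0, 6.0, 10.0],
            "const": [3.0, 3.0, 3.0, 3.0],
            "one_obs": [np.nan, np.nan, np.nan, 5.0],
            "gappy": [np.nan, np.nan, 2.0, 4.0],  # 50% missing
        },
        index=[f"s{i}" for i in range(4)],
    )
    return FeatureMatrix(vals, omic_type="metabolite", scale_state="raw")


def orthogonal_covariates(n: int, n_per_domain: int, domains, seed: int):
    """Mutually independent standard-normal covariates, ``n_per_domain`` per
    domain, with the matching DomainMap. Used as an orthogonal-design oracle."""
    rng = np.random.default_rng(seed)
    cols, mapping = {}, {}
    for d in domains:
        for j in range(n_per_domain):
            name = f"{d}_{j}"
            cols[name] = rng.standard_normal(n)
            mapping[name] = d
    cov = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    return cov, DomainMap(mapping=mapping)
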