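import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import spatqreg as sq

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid28():
    return sq.gen_adjacency("grid", 28)


def make_categorical_dataset(rng, n, coefs=(0.4, -0.3), sd=0.5, intercept=3.0):
    """Two-binary-covariate dataset for fixed-effects-only fits."""
    g1 = rng.choice(["a", "b"], n)
    g2 = rng.choice(["u", "v"], n)
    y = (intercept + coefs[0] * (g1 == "b") + coefs[1] * (g2 == "v")
         + sd * rng.standard_normal(n))
    schema = sq.DataSchema(
        categoricals={"g1": ["a", "b"], "g2": ["u", "v"]},
        references={"g1": "a", "g2": "u"},
        metricals=(), response="y", district="d")
    df = pd.DataFrame({"y": y, "g1": g1, "g2": g2, "d": "D01"})
    data = sq.Dataset(df=df, schema=schema,
                      category_levels={"g1": ["a", "b"], "g2": ["u", "v"]})
    spec = sq.ModelSpec(
        tau=0.5,
        fixed_terms=[sq.FixedTerm("g1", "a"), sq.FixedTerm("g2", "u")],
        smooth_terms=[], spatial_term=None)
    return data, spec


@pytest.fixture(scope="session")
def small_ald_fit(grid28):
    """One moderate ALD-mode fit shared by summary/DIC tests."""
    data, truth = sq.simulate_dataset(1200, grid28, noise="ald", tau=0.05,
                                      seed=17)
    spec = sq.default_spec(0.05)
    fit = sq.fit_model(data, grid28, spec,
                       sq.MCMCSettings(seed=18, iters=1500, burnin=500, thin=2))
    return data, truth, fit
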