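import numpy as np
import pandas as pd
import pytest

import periskin as ps


@pytest.fixture(scope="session")
def build_cohort() -> pd.DataFrame:
    """Model-building design cohort (n = 2,000, 400 per decade)."""
    return ps.generate_cohort(ps.build_cohort_config(seed=0))


@pytest.fixture(scope="session")
def validation_cohort() -> pd.DataFrame:
    """Independent validation design cohort (n = 515, 103 per decade)."""
    return ps.generate_cohort(ps.validation_cohort_config(seed=1))


@pytest.fixture(scope="session")
def face():
    """One default synthetic face patch with landmarks and ground truth."""
    return ps.generate_periorbital_image(ps.FaceImageSpec(seed=2))


def make_linear_cohort(
    betas: dict[str, float],
    intercept: float,
    n: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort whose age is an exact (or noisy) linear function of features."""
    rng = np.random.default_rng(seed)
    data = {"id": [f"L{i:04d}" for i in range(n)]}
    for name in ps.FEATURES:
        data[name] = rng.uniform(0, 100, n)
    df = pd.DataFrame(data)
    age = intercept + sum(b * df[f] for f, b in betas.items())
    if noise_sd:
        age = age + rng.normal(0, noise_sd, n)
    df["age"] = age
    return df
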