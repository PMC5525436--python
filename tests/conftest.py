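import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from epilipid.genotypes import GenotypeMatrix, snp_meta_frame

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genotypes(dosages, snp_ids=None, sample_ids=None, pos=None):
    """GenotypeMatrix from a plain array with generated IDs."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if snp_ids is None:
        snp_ids = [f"snp{j + 1:03d}" for j in range(m)]
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(
        dosages,
        np.array(sample_ids, dtype=object),
        snp_meta_frame(snp_ids, pos=pos),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20170724)


@pytest.fixture
def small_genotypes(rng):
    """100 samples x 6 independent SNPs, MAF 0.3, no missingness."""
    d = rng.binomial(2, 0.3, size=(100, 6)).astype(float)
    return make_genotypes(d)


@pytest.fixture
def covariate_frame(rng):
    n = 100
    data = {
        "age": rng.uniform(21, 80, n),
        "sex": rng.binomial(1, 0.5, n).astype(float),
        "smoking": rng.binomial(1, 0.25, n).astype(float),
        "t2d": rng.binomial(1, 0.1, n).astype(float),
        "medication": rng.binomial(1, 0.15, n).astype(float),
        "bmi": rng.normal(27, 4.5, n),
    }
    for i in range(1, 11):
        data[f"PC{i}"] = rng.standard_normal(n)
    return pd.DataFrame(data)
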