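import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sigscore import Signature

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.normal(size=(6, 4)),
        index=[f"g{i}" for i in range(1, 7)],
        columns=[f"s{j}" for j in range(1, 5)],
    )


@pytest.fixture
def small_signature() -> Signature:
    return Signature(name="sig_a", features=("g1", "g2", "g3"))


def random_matrix(rng, n_feat, n_samp, prefix="g"):
    return pd.DataFrame(
        rng.normal(size=(n_feat, n_samp)),
        index=[f"{prefix}{i:04d}" for i in range(n_feat)],
        columns=[f"s{j:03d}" for j in range(n_samp)],
    )
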