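import numpy as np
import pytest

from imgsurv import SurvivalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_survival_records(rng, n, censor_frac=0.3, scale=300.0, prefix="s"):
    """Exponential event times with roughly the requested censoring fraction."""
    times = rng.exponential(scale, n)
    censored = rng.random(n) < censor_frac
    return [
        SurvivalRecord(f"{prefix}{i}", float(max(t, 1e-3)), int(not c))
        for i, (t, c) in enumerate(zip(times, censored))
    ]
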