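import numpy as np
import pytest

from tmesuite.io_core import SurvivalTable
from tmesuite.signature_scoring import SignatureScoreMatrix
from tmesuite.synthetic_data import (
    BulkSimConfig,
    SCSimConfig,
    gen_bulk_cohort,
    gen_sc_cohort,
)


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default five-subtype bulk cohort with strong separation."""
    return gen_bulk_cohort(BulkSimConfig(seed=11))


@pytest.fixture(scope="session")
def small_bulk_cohort():
    """Small three-subtype cohort for quick subtype tests."""
    cfg = BulkSimConfig(k_true=3, n_per_subtype=20, n_signatures=12,
                        genes_per_signature=4, seed=3)
    return gen_bulk_cohort(cfg)


@pytest.fixture(scope="session")
def sc_cohort():
    return gen_sc_cohort(SCSimConfig(seed=5))


def random_survival(rng: np.random.Generator, n: int, beta: float = 0.0,
                    x: np.ndarray | None = None, censor_rate: float = 0.3
                    ) -> tuple[np.ndarray, SurvivalTable]:
    """Exponential survival with optional covariate effect; no exact ties."""
    if x is None:
        x = rng.normal(size=n)
    rate = 0.05 * np.exp(beta * x)
    t_event = rng.exponential(1.0 / rate)
    t_cens = (rng.exponential(1.0 / (rate * censor_rate / (1 - censor_rate)))
              if censor_rate > 0 else np.full(n, np.inf))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return x, SurvivalTable([f"s{i}" for i in range(n)], time, event)


def scores_from_array(arr: np.ndarray, prefix: str = "SIG") -> SignatureScoreMatrix:
    n_sig, n_samp = arr.shape
    return SignatureScoreMatrix(
        [f"{prefix}{i:03d}" for i in range(n_sig)],
        [f"s{i}" for i in range(n_samp)],
        arr,
    )
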