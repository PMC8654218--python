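import numpy as np
import pytest

from fepcycles import LegEstimate, WindowPair
from fepcycles.energetics import R_KCAL

RT298 = R_KCAL * 298.0


def crooks_gaussian_pair(dg, sigma, n, seed, temperature=298.0):
    """WindowPair whose two ΔU ensembles satisfy the Crooks relation
    for true free energy ``dg`` (the analytic BAR test bed)."""
    rng = np.random.default_rng(seed)
    rt = R_KCAL * temperature
    shift = sigma * sigma / (2.0 * rt)
    return WindowPair(
        lambda_i=0.0, lambda_j=1.0,
        du_from_i=rng.normal(dg + shift, sigma, n),
        du_from_j=rng.normal(dg - shift, sigma, n))


def make_estimate(mean, sem, state="R", env="apo", transformation="mut",
                  n_replicas=10):
    """Hand-built LegEstimate with the given summary statistics."""
    return LegEstimate(per_replica_dg=(mean,) * n_replicas, mean_dg=mean,
                       sem_dg=sem, n_replicas=n_replicas,
                       state_label=state, environment=env,
                       transformation=transformation)


@pytest.fixture
def gaussian_pair():
    return crooks_gaussian_pair(2.0, 1.0, 100_000, seed=0)
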