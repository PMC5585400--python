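import numpy as np
import pytest

from tandem5ss.motif_scoring import load_esefinder_srsf1
from tandem5ss.synthetic_data import SimulationConfig, simulate_events


@pytest.fixture(scope="session")
def srsf1_matrix():
    return load_esefinder_srsf1()


@pytest.fixture()
def small_cohort():
    """Ten mixed-strand events with known truth, for plumbing tests."""
    config = SimulationConfig(n_events=10, seed=42, strand_mix=0.5)
    events, truth = simulate_events(config)
    return config, events, truth


def beta_moments(n_distal, n_proximal):
    """Closed-form posterior moments for equal effective lengths."""
    from scipy import stats

    a, b = n_proximal + 1, n_distal + 1
    dist = stats.beta(a, b)
    return dist.mean(), dist.ppf(0.025), dist.ppf(0.975)


def fine_grid_posterior_mean(n_distal, n_proximal, l_inc, l_exc, n_points=100_001):
    """Independent trapezoid-quadrature oracle at a very fine grid."""
    psi = np.linspace(1e-9, 1 - 1e-9, n_points)
    p = psi * l_inc / (psi * l_inc + (1 - psi) * l_exc)
    log_like = n_proximal * np.log(p) + n_distal * np.log1p(-p)
    like = np.exp(log_like - log_like.max())
    return np.trapezoid(psi * like, psi) / np.trapezoid(like, psi)
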