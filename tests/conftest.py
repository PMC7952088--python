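"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from polfret import simulate


@pytest.fixture(scope="session")
def pol1_scheme():
    return simulate.pol1_scheme1_default()


@pytest.fixture(scope="session")
def photophysics():
    return simulate.PhotophysicsModel()


@pytest.fixture(scope="session")
def default_dataset(pol1_scheme, photophysics):
    """200 scheme-1 traces, 60 s at 100 ms/frame, under default conditions."""
    return simulate.simulate_dataset(
        pol1_scheme, photophysics, n_traces=200, duration=60.0,
        frame_dt=0.1, labeling_scheme=1, seed=0,
    )


@pytest.fixture(scope="session")
def pn_scheme():
    """Two bound states P <-> N (0.8 / 0.6, SD 0.05), k = 1 /s both ways."""
    q = np.array([[0.0, 1.0], [1.0, 0.0]])
    return simulate.KineticScheme(
        state_names=["P", "N"],
        rate_matrix=q,
        bound_flags=np.array([True, True]),
        fret_means=np.array([0.8, 0.6]),
        fret_sds=np.array([0.05, 0.05]),
    )


@pytest.fixture(scope="session")
def pn_observations(pn_scheme):
    """Observation arrays + true paths drawn from the P/N scheme."""
    rng = np.random.default_rng(42)
    paths, obs = [], []
    for _ in range(40):
        p = simulate.simulate_state_path(pn_scheme, 60.0, 0.1, rng)
        e = pn_scheme.fret_means[p] + 0.05 * rng.standard_normal(p.size)
        paths.append(p)
        obs.append(e)
    return obs, paths
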