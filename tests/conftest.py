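import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hetwalk import data_io, hetnet, similarity
from hetwalk.synthetic import ScenarioConfig, degenerate_fixtures, generate_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_scenario():
    """The standard planted-structure dataset: 60 lncRNAs, 40 proteins,
    4 groups, interaction noise 0.1, seed 1."""
    return generate_scenario(ScenarioConfig())


@pytest.fixture(scope="session")
def tiny():
    return degenerate_fixtures()


def build_network(scen):
    """Registry, similarity matrices and interaction matrix for a scenario."""
    registry = data_io.NodeRegistry.from_tables(scen.interactions, scen.expression, scen.ppi)
    sl = similarity.expression_similarity(scen.expression, registry)
    sp = similarity.normalize_ppi(scen.ppi, registry)
    imat = hetnet.build_interaction_matrix(scen.interactions, registry)
    return registry, sl, sp, imat


@pytest.fixture(scope="session")
def default_network(default_scenario):
    return build_network(default_scenario)


def random_small_scenario(seed: int):
    """A randomly sized scenario with at most 200 nodes."""
    rng = np.random.default_rng(seed)
    return generate_scenario(
        ScenarioConfig(
            n_lncrnas=int(rng.integers(10, 120)),
            n_proteins=int(rng.integers(8, 80)),
            n_conditions=int(rng.integers(4, 24)),
            n_groups=int(rng.integers(1, 5)),
            noise_rate=float(rng.uniform(0, 0.5)),
            mean_interactions_per_lncrna=2.0,
            seed=seed,
        )
    )


def solve_stationary(w: np.ndarray, y0: np.ndarray, delta: float) -> np.ndarray:
    """Closed-form fixed point delta (Id - (1-delta) W^T)^{-1} y0 — the
    independent oracle for the iterative walk."""
    n = w.shape[0]
    return delta * np.linalg.solve(np.eye(n) - (1.0 - delta) * w.T, y0)
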