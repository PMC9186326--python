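import numpy as np
import pytest

import scrpath as sp


@pytest.fixture(scope="session")
def default_survey():
    """One simulated survey at the default design, shared across tests."""
    traps = sp.gen_trap_array("curvilinear", 42, 1500.0, seed=11)
    truth = sp.TruthSpec(seed=11)
    data = sp.simulate_scr(truth, traps, seed=11)
    return truth, traps, data


@pytest.fixture(scope="session")
def tiny_problem():
    """A 2-trap, 2-occasion, 3-mesh-point problem for enumeration checks."""
    traps = sp.TrapArray(ids=["a", "b"],
                         xy=np.array([[0.0, 0.0], [2000.0, 0.0]]),
                         usage=np.array([[1.0, 0.5], [1.0, 1.0]]))
    mesh = sp.HabitatMesh(np.array([[0.0, 0.0], [1000.0, 500.0],
                                    [2000.0, -500.0]]), spacing=1000.0)
    omega = np.zeros((2, 2, 2), dtype=np.uint8)
    omega[0, 0, 0] = 1   # ind 0: trap a, occasion 1
    omega[0, 1, 0] = 1   # ind 0: trap a again (bk active)
    omega[1, 1, 1] = 1   # ind 1: trap b, occasion 2
    data = sp.CaptureHistories(omega, np.array(["F", "M"]))
    return traps, mesh, data


def random_tiny_config(rng, n_traps=2, n_occ=2, n_mesh=3, mixture=False):
    """Random small SECR configuration for oracle comparisons."""
    traps = sp.TrapArray(
        ids=[f"t{j}" for j in range(n_traps)],
        xy=rng.uniform(-2000, 2000, (n_traps, 2)),
        usage=rng.choice([0.0, 0.4, 0.7, 1.0], size=(n_traps, n_occ),
                         p=[0.1, 0.2, 0.2, 0.5]),
    )
    mesh = sp.HabitatMesh(rng.uniform(-3000, 3000, (n_mesh, 2)),
                          spacing=1000.0)
    n = int(rng.integers(1, 4))
    omega = np.zeros((n, n_occ, n_traps), dtype=np.uint8)
    usable = traps.usage.T > 0          # (S, K)
    for i in range(n):
        while not omega[i].any():
            draw = rng.random((n_occ, n_traps)) < 0.45
            omega[i] = (draw & usable)
    sex = rng.choice(["F", "M"], n)
    data = sp.CaptureHistories(omega, sex)
    params = sp.DetectionParams(
        beta0=rng.uniform(-2.5, -0.5),
        beta_male=rng.uniform(-0.5, 0.5),
        beta_bk=rng.uniform(-1.0, 1.0),
        gamma0=np.log(rng.uniform(800, 3000)),
        gamma_male=rng.uniform(-0.3, 0.6),
        gamma_h2=rng.uniform(0.2, 1.2) if mixture else 0.0,
        logit_pi=rng.uniform(-1.0, 1.0) if mixture else 0.0,
    )
    spec = sp.ModelSpec(mixture=mixture)
    return traps, mesh, data, params, spec
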