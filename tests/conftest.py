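import numpy as np
import pytest

import fearsis as fs

SEED = 20260926


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def table_params():
    """The default study parameter set (beta=1.5, k=0.4, alpha=0.95)."""
    return fs.TABLE_DEFAULT


def draw_params(rng, k_max=2.0, alpha_range=(0.5, 1.0)):
    """One random admissible parameter set at the scale of the default scenario."""
    return fs.ModelParams(
        Lambda=rng.uniform(1.0, 20.0),
        k=rng.uniform(0.0, k_max),
        mu=rng.uniform(0.1, 2.0),
        beta=rng.uniform(0.01, 2.0),
        omega=rng.uniform(0.1, 2.0),
        delta=rng.uniform(0.1, 2.0),
        m=rng.uniform(0.5, 8.0),
        a=rng.uniform(0.1, 2.0),
        n=rng.uniform(0.1, 2.0),
        d=rng.uniform(0.1, 2.0),
        alpha=rng.uniform(*alpha_range),
    )


def draw_params_table_scale(rng, alpha_range=(0.7, 1.0)):
    """Random parameter set within 25% of the default scenario (the regime
    whose local rates the default step size resolves)."""
    base = fs.TABLE_DEFAULT.to_dict()
    out = {name: base[name] * rng.uniform(0.8, 1.25) for name in base}
    out["alpha"] = rng.uniform(*alpha_range)
    return fs.ModelParams(**out)


@pytest.fixture(scope="session")
def long_run_cache():
    """Session-wide cache of expensive long integrations keyed by beta.

    Attractor classification uses t_end=2000 so the algebraic (t^-alpha)
    transients of the fractional dynamics have died down.
    """
    cache = {}

    def get(beta: float) -> fs.Trajectory:
        if beta not in cache:
            p = fs.TABLE_DEFAULT.replace(beta=beta)
            cfg = fs.SolverConfig(h=0.05, t_end=2000.0)
            cache[beta] = fs.simulate(p, fs.perturbed_equilibrium(p), cfg)
        return cache[beta]

    return get
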