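import numpy as np
import pandas as pd
import pytest

import oligonet as on


@pytest.fixture(scope="session")
def default_spec():
    return on.CommunitySimSpec(seed=7)


@pytest.fixture(scope="session")
def sim(default_spec):
    """Default two-year simulation shared across tests: (env, t1, t2, truth)."""
    env = on.generate_env(default_spec)
    t1, t2, truth = on.generate_community(default_spec, env)
    return env, t1, t2, truth


@pytest.fixture(scope="session")
def pipeline(sim):
    """Full network pipeline on the default simulation.

    Returns a dict with the yearly SparCC networks, consensus TOM, merged
    module set and clr data, so the heavy stages run once per session.
    """
    env, t1, t2, truth = sim
    net1 = on.sparcc(t1.counts, seed=71)
    net2 = on.sparcc(t2.counts, seed=72)
    tom1 = on.tom_similarity(on.rescale_cor(net1.rho.to_numpy()))
    tom2 = on.tom_similarity(on.rescale_cor(net2.rho.to_numpy()))
    cons = on.consensus_tom(tom1, on.scale_tom(tom2, tom1))
    ids = pd.Index(t1.counts.columns)
    detected = on.detect_modules(cons, ids=ids)
    clr_by_year = {1: on.clr_transform(t1), 2: on.clr_transform(t2)}
    merged = on.merge_modules(detected, clr_by_year)
    return {
        "env": env,
        "tables": (t1, t2),
        "truth": truth,
        "networks": (net1, net2),
        "consensus": cons,
        "detected": detected,
        "merged": merged,
        "clr": clr_by_year,
        "ids": ids,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
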