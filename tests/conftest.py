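import numpy as np
import pytest

from panelfcm import MainFactor, SystemModel
from panelfcm import io as pio


@pytest.fixture(scope="session")
def final_model() -> SystemModel:
    """Text-attested final consensus model (display edges only)."""
    return pio.load_final_model()


@pytest.fixture(scope="session")
def final_model_full() -> SystemModel:
    """Final model including the below-display-threshold relations."""
    return pio.load_final_model(include_sub_display=True)


def build_model(edges, impacts=None, factors=None) -> SystemModel:
    """Small-model builder: edges as (source, target, weight[, sign])."""
    nodes = set(factors or [])
    for e in edges:
        nodes.update(e[:2])
    m = SystemModel(factors=sorted(nodes))
    for fid, imp in (impacts or {}).items():
        m.set_impact(fid, imp)
    for e in edges:
        s, t, w = e[:3]
        sign = e[3] if len(e) > 3 else 1
        m.add_edge(s, t, w, sign=sign)
    return m


def random_model(rng: np.random.Generator, n_factors=None, density=None,
                 allow_nondisplay=False) -> SystemModel:
    """Random weighted digraph for property tests (weights on (0, 10])."""
    n = int(n_factors if n_factors is not None else rng.integers(2, 9))
    density = float(rng.uniform(0.1, 0.9)) if density is None else density
    ids = [f"n{i}" for i in range(n)]
    m = SystemModel(factors=ids,
                    impacts={f: float(rng.uniform(0, 1)) for f in ids})
    for s in ids:
        for t in ids:
            if s != t and rng.random() < density:
                display = bool(rng.random() < 0.8) if allow_nondisplay else True
                m.add_edge(s, t, float(rng.uniform(0.1, 10.0)),
                           sign=int(rng.choice([1, -1])) if allow_nondisplay else 1,
                           display=display)
    return m
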