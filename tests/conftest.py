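"""Shared fixtures: parameter sets and random valid configurations."""

from __future__ import annotations

import numpy as np
import pytest

from vesiflex import Conformation, ModelParams
from vesiflex.build import init_polymer, init_vesicle


@pytest.fixture
def params() -> ModelParams:
    """Full-size defaults (N=60, kappa=10, eps_vp=2)."""
    return ModelParams()


@pytest.fixture
def small_params() -> ModelParams:
    """A small but otherwise identical system for fast tests."""
    return ModelParams(n_bonds=12, kappa=5.0, eps_vp=2.0)


def jittered_conformation(p: ModelParams, rng: np.random.Generator,
                          jitter: float = 0.04) -> Conformation:
    """A random valid configuration: polygon vesicle and tangent polymer,
    both with small random bead displacements, close enough to interact.

    Retries the jitter until every bond stays inside (l_min, l_max).
    """
    ves0 = init_vesicle(p.n_beads, p.l0)
    pol0 = init_polymer(p.n_beads, p.l0, ves0, rng, params=p)
    for _ in range(100):
        conf = Conformation(
            ves0 + rng.normal(scale=jitter, size=ves0.shape),
            pol0 + rng.normal(scale=jitter, size=pol0.shape),
        )
        if conf.is_valid(p):
            return conf
    raise RuntimeError("could not build a valid jittered configuration")


@pytest.fixture
def random_conformation(small_params) -> Conformation:
    return jittered_conformation(small_params, np.random.default_rng(11))
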