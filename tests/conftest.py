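"""Shared fixtures: small synthetic screens and fitted posteriors.

MCMC fits are session-scoped because they are the expensive ingredients; the
problem sizes (tens of guides, hundreds of clones per guide, two short
chains) are chosen so each fit takes seconds while leaving enough information
for the statistical assertions.
"""

import numpy as np
import pytest

import umifit as u


@pytest.fixture(scope="session")
def lib48():
    return u.make_random_library(36, 12, seed=3)


@pytest.fixture(scope="session")
def lib24():
    return u.make_random_library(18, 6, seed=9, name="lib24")


@pytest.fixture(scope="session")
def sim_neutral48(lib48):
    """All guides neutral; mix-NB clone sizes; 48 guides x ~200 clones."""
    cfg = u.SimulationConfig(
        library=lib48,
        seed=11,
        clones_per_guide=200,
        family="mix_nb",
        family_params=dict(mu1=5.0, mu2=50.0, r1=1.0, r2=1.0, w=0.3),
    )
    return u.simulate_screen(cfg)


@pytest.fixture(scope="session")
def fit_neutral48(sim_neutral48):
    spec = u.ModelSpec(chains=2, warmup=500, draws=400, seed=5, ppc_draws=200)
    return u.fit_fitness_model(sim_neutral48.dataset, spec)


def _hetero_factors(lib):
    """Deterministic spread of true effects: 2x up for the first 4 genes,
    2x down for the next 4, neutral elsewhere."""
    eps, phi = {}, {}
    for g in lib.guides:
        if g.gene in ("gene001", "gene002", "gene003", "gene004"):
            eps[g.guide_id] = 2.0
            phi[g.guide_id] = 2.0
        elif g.gene in ("gene005", "gene006", "gene007", "gene008"):
            eps[g.guide_id] = 0.5
            phi[g.guide_id] = 0.5
    return eps, phi


@pytest.fixture(scope="session")
def sim_hetero48(lib48):
    eps, phi = _hetero_factors(lib48)
    cfg = u.SimulationConfig(
        library=lib48,
        seed=21,
        clones_per_guide=300,
        eps_star=eps,
        phi_star=phi,
        family="mix_nb",
        family_params=dict(mu1=5.0, mu2=50.0, r1=1.0, r2=1.0, w=0.3),
    )
    return u.simulate_screen(cfg)


@pytest.fixture(scope="session")
def fit_hetero48(sim_hetero48):
    spec = u.ModelSpec(chains=2, warmup=600, draws=400, seed=7, ppc_draws=100)
    return u.fit_fitness_model(sim_hetero48.dataset, spec)
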