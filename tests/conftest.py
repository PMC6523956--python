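"""Shared fixtures: one default synthetic genome (with its all-vs-all
score matrix and mined members) is built once per session and reused by
the duplication, microsynteny and acceptance tests."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from soxkit import homology
from soxkit.simulate import SimConfig, simulate_genome

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic genome (seeded): 312 genes, 18 planted members."""
    return simulate_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_profile(default_sim):
    return homology.DomainProfile.from_alignment(
        list(default_sim.references.values())
    )


@pytest.fixture(scope="session")
def mined_members(default_sim, sim_profile):
    return homology.mine_family(
        default_sim.proteins, default_sim.seeds, sim_profile,
        references=default_sim.references,
    )


@pytest.fixture(scope="session")
def sim_scores(default_sim):
    """All-vs-all exact local-alignment scores for the default genome."""
    return homology.all_vs_all_scores(default_sim.proteins)


@pytest.fixture(scope="session")
def sim_ranks(default_sim):
    return {g.gene_id: g for g in default_sim.genes}


@pytest.fixture(scope="session")
def sim_gene_map(default_sim):
    return {p.protein_id: p.gene_id for p in default_sim.proteins}
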