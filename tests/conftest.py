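"""Shared fixtures: small maps, cached forward traces and simulation pools.

The expensive objects (forward traces, the SPC reference pool, the
reduced-scale reference table) are session-scoped so that unit and
acceptance tests share them.
"""

import pytest

from danubesim import continuity, fixtures, inference, sumstats, world
from danubesim.coalescent import MutationModel


@pytest.fixture(scope="session")
def mini_map():
    return fixtures.make_map("mini")


@pytest.fixture(scope="session")
def strip_map():
    return fixtures.make_map("strip_1d")


@pytest.fixture(scope="session")
def europe_map():
    return fixtures.make_map("europe_like")


@pytest.fixture(scope="session")
def mini_scheme(mini_map):
    return fixtures.make_sampling_scheme("danubian_7groups_small", mini_map)


@pytest.fixture(scope="session")
def mini_trace_sn2(mini_map):
    """SN2 trace on the mini map, mid-prior parameters."""
    hg, fa = fixtures.default_layers(K_fa=800.0, fixture=mini_map)
    scen = fixtures.scenario_for(mini_map, "SN2", gamma=0.2, mdec=5.0)
    return world.run_forward(mini_map.world_config(), hg, fa, scen)


@pytest.fixture(scope="session")
def mini_trace_nogamma(mini_map):
    hg, fa = fixtures.default_layers(K_fa=800.0, fixture=mini_map)
    scen = fixtures.scenario_for(mini_map, "SN1", gamma=0.0, mdec=1.0)
    return world.run_forward(mini_map.world_config(), hg, fa, scen)


@pytest.fixture(scope="session")
def mutation_model():
    return MutationModel()


@pytest.fixture(scope="session")
def spc_pool_raw(mini_map):
    """Continuity reference pool (unclamped PhiST), 2,000 simulations."""
    sim = fixtures.spc_simulator(mini_map)
    return continuity.spc_reference_pool(
        sim, continuity.SPC_PRIORS, n_sims=2000, seed=20260901, clamp=False
    )


@pytest.fixture(scope="session")
def sn1_reference_table(mini_map, mini_scheme):
    """Reduced-scale SN1 reference table (2,000 simulations) for parameter
    recovery and calibration checks."""

    def sim(params, seed):
        return fixtures.simulate_scenario_stats(
            mini_map, mini_scheme, "SN1", params, seed
        )

    return inference.build_reference_table(
        sim,
        inference.DEFAULT_PRIORS,
        n_sims=2000,
        seed=20260902,
        scenario_id="SN1",
        stat_labels=sumstats.STAT_NAMES,
    )


def toy_sample(seqs):
    """HaplotypeSample from raw strings, for statistic oracles."""
    from danubesim.coalescent import HaplotypeSample

    return HaplotypeSample(group_id="toy", sequences=list(seqs))
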