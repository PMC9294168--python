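import pytest

import cytomr as c


@pytest.fixture(scope="session")
def fixture_pairs():
    return c.make_fixture_pairs()


@pytest.fixture(scope="session")
def il17(fixture_pairs):
    """Two-SNP IL-17 -> stomach cancer reconstruction."""
    return fixture_pairs["IL17_stomach"]


@pytest.fixture(scope="session")
def il18(fixture_pairs):
    """Sixteen-SNP IL-18 -> AML reconstruction."""
    return fixture_pairs["IL18_AML"]


@pytest.fixture
def sim_instruments():
    """Factory: harmonized instruments from a seeded simulated pair."""

    def make(seed=0, **kwargs):
        cfg = c.SimulationConfig(seed=seed, **kwargs)
        exposure, outcome, ld, truth = c.simulate_pair(cfg)
        insts, drops = c.harmonize_pairs(exposure, outcome)
        assert not drops
        return insts, truth

    return make
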