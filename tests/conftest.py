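"""Shared fixtures: one modest diploid simulation reused across test modules."""

import pytest

from asmtrio import asm, phasing
from asmtrio import simulate as sim


@pytest.fixture(scope="session")
def demo_config() -> sim.SimConfig:
    return sim.SimConfig(seed=1)


@pytest.fixture(scope="session")
def demo_truth(demo_config):
    reference = sim.simulate_reference(demo_config)
    truth = sim.simulate_diploid(reference, demo_config)
    sim.simulate_parents(truth, informative_fraction=1.0)
    return truth


@pytest.fixture(scope="session")
def demo_reads(demo_truth):
    return sim.simulate_reads(demo_truth)


@pytest.fixture(scope="session")
def demo_trio(demo_truth):
    return phasing.trio_bin(demo_truth.variants, demo_truth.parents)


@pytest.fixture(scope="session")
def demo_tagged(demo_reads, demo_trio):
    return phasing.tag_reads(demo_reads, demo_trio)


@pytest.fixture(scope="session")
def demo_counts(demo_tagged):
    return asm.pileup_cpg(demo_tagged)


@pytest.fixture(scope="session")
def demo_calls(demo_counts):
    return asm.call_asm(demo_counts)
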