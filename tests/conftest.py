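import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from castworks import simgen  # noqa: E402


@pytest.fixture(scope="session")
def scenario():
    """One simulated insertion experiment shared across profiler tests:
    genome with a planted '+' target, a delivery vector, 40 mixed events
    (15% cointegrates, 10% off-target)."""
    genome = simgen.make_genome(seed=11)
    genome, target = simgen.plant_target(genome, 0, seed=11)
    vector = simgen.make_vector(seed=11)
    truth = simgen.simulate_insertions(genome, target, vector, n_events=40,
                                       cointegrate_rate=0.15,
                                       off_target_rate=0.10, seed=11)
    return {"genome": genome, "target": target, "vector": vector,
            "truth": truth, "transposon": simgen.transposon_record(vector)}


@pytest.fixture(scope="session")
def clean_reads(scenario):
    """Error-free reads over the scenario events (exact-recovery tests)."""
    reads, truth_df = simgen.simulate_long_reads(
        scenario["genome"], scenario["truth"], scenario["vector"],
        n_reads=40, per_base_error=0.0, seed=21)
    return reads, truth_df


@pytest.fixture(scope="session")
def noisy_reads(scenario):
    """Reads at 5% per-base error (robustness tests)."""
    reads, truth_df = simgen.simulate_long_reads(
        scenario["genome"], scenario["truth"], scenario["vector"],
        n_reads=50, per_base_error=0.05, seed=22)
    return reads, truth_df


@pytest.fixture(scope="session")
def design_genome():
    """Smaller genome for designer tests (2 converging safe sites)."""
    return simgen.make_genome(length=20_000, n_converging_pairs=2, seed=5)
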