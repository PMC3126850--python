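import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def small_bundle():
    """A small simulated dataset with truth: 12 families, ~8x coverage."""
    from spinkit.simulate import (ReadSimParams, TranscriptomeModel,
                                  build_truth_assembly, generate_transcriptome,
                                  simulate_reads)

    model = TranscriptomeModel(n_families=12, seed=7, spidroin_fraction=0.0,
                               paralogs_per_family=1.0)
    transcripts, truth = generate_transcriptome(model)
    params = ReadSimParams(mean_coverage=8, antisense_prob=0.1, seed=8)
    reads, truth = simulate_reads(transcripts, params, truth)
    assembly = build_truth_assembly(transcripts, reads, truth)
    return transcripts, reads, truth, assembly
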