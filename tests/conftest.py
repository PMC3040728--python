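import pytest

from txsurvey import synthetic_data as sd


@pytest.fixture(scope="session")
def small_truth() -> sd.GroundTruth:
    """A compact simulated transcriptome shared across tests."""
    cfg = sd.SimConfig(
        n_genes=12, n_paralog_pairs=2, isoform_probability=0.3, n_reads=1200,
        gamma=0.0, k_min=1, seed=1,
    )
    return sd.simulate_transcriptome(cfg)


@pytest.fixture(scope="session")
def small_reads(small_truth) -> sd.ReadSet:
    return sd.simulate_reads(small_truth, "N", seed=2)


@pytest.fixture(scope="session")
def small_assembly(small_truth, small_reads) -> sd.EmulatedAssembly:
    return sd.emulate_assembly(small_reads, small_truth)
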