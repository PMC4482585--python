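import numpy as np
import pytest

from polygbs import simdata


@pytest.fixture(scope="session")
def small_truth():
    """20 loci x 2x6 samples, fixed seed."""
    model = simdata.PopulationModel.random(20, 6, seed=11)
    return simdata.simulate_population(model)


@pytest.fixture(scope="session")
def noiseless_readset(small_truth):
    """Error-free reads at comfortable depth for exact-recovery checks."""
    return simdata.sample_gbs_reads(
        small_truth,
        simdata.DepthModel(mean_depth=30, dropout_prob=0.0),
        simdata.ErrorModel(substitution_rate=0.0),
    )


@pytest.fixture(scope="session")
def amplicon_panel(small_truth):
    """Error-free amplicon reads over the first 8 loci and 8 samples."""
    samples = small_truth.samples[:4] + small_truth.samples[-4:]
    designs = simdata.design_amplicons(small_truth, loci=list(range(8)),
                                       samples=samples)
    reads = simdata.sample_amplicon_reads(
        small_truth, designs, depth_per_amplicon=300,
        err=simdata.ErrorModel(homopolymer_indel_rate=0.0))
    return samples, designs, reads
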