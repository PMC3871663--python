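import numpy as np
import pytest

from sweepqtl import simdata


@pytest.fixture(scope="session")
def small_bundle():
    """A ~1.5 Mb single-chromosome synthetic dataset with one planted
    sweep and planted screen variants; shared read-only across tests."""
    model = simdata.default_model()
    cfg = simdata.GenomeConfig(
        chrom_lengths={"chr1": 1_500_000},
        sweeps=(simdata.SweepSpec("chr1", 750_000, 150_000.0),),
        missing_rate=0.03,
    )
    bundle = simdata.synthesize_genome(cfg, model, seed=2024)
    return simdata.plant_screen_variants(bundle, "chr1",
                                         (300_000, 1_200_000), seed=7)


@pytest.fixture(scope="session")
def neutral_panel():
    """One neutral two-population 300-kb locus (no missing data)."""
    model = simdata.default_model()
    return simdata.simulate_locus(model, 10, 22, 300_000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
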