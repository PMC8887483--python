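import pytest

from l1context import GeneratorConfig, run_pipeline, simulate


@pytest.fixture(scope="session")
def default_sim():
    """Full synthetic dataset under the default study conditions."""
    return simulate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_table(default_sim):
    """Feature table from the end-to-end pipeline on the default dataset."""
    sim = default_sim
    return run_pipeline(
        sim.loci,
        sim.fragments,
        atac_track=sim.atac_track,
        histone_tracks=sim.histone_tracks,
        meth_records=sim.meth_records,
        loops=sim.loops,
        threshold=20,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down dataset for the slower per-stage checks."""
    cfg = GeneratorConfig(
        n_loci=40,
        chrom_length=1_500_000,
        n_l1hs_present=5,
        n_l1hs_absent=5,
        n_decoy_pairs=20,
        n_background_fragments=50,
        seed=7,
    )
    return simulate(cfg)
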