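import warnings

import pytest

from methbrain.synthetic_data import SimulationConfig, write_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The packaged default synthetic study (seed 0), written once per session."""
    outdir = tmp_path_factory.mktemp("default_dataset")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = write_dataset(SimulationConfig(seed=0), outdir)
    bundle["path"] = outdir
    return bundle


def small_sim_config(**overrides) -> SimulationConfig:
    """A fast 1-chromosome study used by unit tests that need real files."""
    base = dict(
        seed=3,
        n_chroms=1,
        chrom_length=400_000,
        n_genes=30,
        n_cgis=20,
        n_repeats={"LINE": 6, "SINE": 8, "LTR": 3, "Simple_repeat": 2},
        n_repeat_cgis=2,
        n_regions=3,
        n_planted_dms=40,
        n_cluster_genes_per_region=5,
        n_planted_corr_pos=2,
        n_planted_corr_neg=1,
        n_noncpg_sites=500,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_dataset")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = write_dataset(small_sim_config(), outdir)
    bundle["path"] = outdir
    return bundle
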