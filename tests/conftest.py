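import warnings

import pytest

from treesilience import (RunConfig, SyntheticConfig, assemble_dataset,
                          generate_bundle, generate_dataset, run_pipeline)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_sites=3, trees_per_site_surviving=6,
                           trees_per_site_dead=6, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """In-memory bundle: (series, metadata, climate, soil, ledger)."""
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def bundle_dir(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return generate_dataset(small_config, out)


@pytest.fixture(scope="session")
def small_dataset(bundle_dir):
    with warnings.catch_warnings():
        warnings.simplefilter("error")      # generator contract: no warnings
        return assemble_dataset(bundle_dir["rwl"], bundle_dir["metadata"],
                                bundle_dir["climate"], bundle_dir["soil"])


@pytest.fixture(scope="session")
def smoke_run(tmp_path_factory):
    """One completed 3-site pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("run") / "r1"
    cfg = RunConfig(out_dir=str(out),
                    synthetic=SyntheticConfig(n_sites=3,
                                              trees_per_site_surviving=8,
                                              trees_per_site_dead=8, seed=5),
                    n_boot=200, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_pipeline(cfg)
    return out, cfg
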