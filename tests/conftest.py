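import pytest

from strataviper import pipeline, simzw


@pytest.fixture(scope="session")
def small_config():
    return pipeline.small_preset(seed=1)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """One desk-scale synthetic study shared across tests (read-only)."""
    return simzw.generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_model(small_bundle):
    return small_bundle.model


@pytest.fixture(scope="session")
def small_calls(small_bundle):
    from strataviper import sexassign

    lengths = {sc.id: sc.length for sc in small_bundle.model.scaffolds}
    stats = sexassign.summarize_coverage(
        small_bundle.depth_f, small_bundle.depth_m, lengths
    )
    calls, summary = sexassign.classify_all(stats)
    return calls, summary


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest config that still has every compartment; for I/O round trips."""
    return pipeline.small_preset(
        seed=7,
        n_autosomes=1,
        autosome_len=400_000,
        z_len=770_000,
        strata_boundaries=(420_000, 560_000),
        scaffold_len=70_000,
        w_frag_mean_len=8_000,
        n_gametolog_genes=6,
    )


@pytest.fixture(scope="session")
def tiny_bundle_dir(tiny_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_bundle")
    bundle = simzw.generate_bundle(tiny_config)
    files = simzw.write_bundle(bundle, out, include_fasta=True)
    return out, files, bundle
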