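import pytest

from phagecore import synthetic


@pytest.fixture(scope="session")
def small_panel(tmp_path_factory):
    """A small planted panel (12 in-group genomes, 60 genes, 3 blocks) with files."""
    out = tmp_path_factory.mktemp("small_panel")
    truth = synthetic.generate_panel(
        n_ingroup=12, n_outgroup=3, n_genes=60, n_core=15, n_unique=5,
        n_blocks=3, seed=0, out_dir=out,
    )
    return truth


@pytest.fixture(scope="session")
def default_panel(tmp_path_factory):
    """The full default study panel: 66 in-group genomes, 317 genes, 72 core
    (21 unique) in 7 blocks."""
    out = tmp_path_factory.mktemp("default_panel")
    return synthetic.generate_panel(seed=0, out_dir=out)
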