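import pytest

from tolorf import DesignConfig, design, synth_reporter_orf, tol_scale_panel


@pytest.fixture(scope="session")
def toy_genes():
    """Two small deterministic synthetic genes (30 and 41 protein codons)."""
    return [
        synth_reporter_orf(30, seed=101, gene_id="toyA"),
        synth_reporter_orf(41, seed=202, gene_id="toyB"),
    ]


@pytest.fixture(scope="session")
def panel():
    """The eight-gene reporter-scale synthetic panel."""
    return tol_scale_panel(seed=7)


@pytest.fixture(scope="session")
def toy_design(toy_genes):
    """A complete default design on the toy genes."""
    construct, coverage, report = design(toy_genes, DesignConfig(seed=11))
    return toy_genes, construct, coverage, report


@pytest.fixture(scope="session")
def panel_design(panel):
    """A complete default design on the eight-gene panel."""
    construct, coverage, report = design(panel, DesignConfig(seed=11))
    return panel, construct, coverage, report


@pytest.fixture
def genes_fasta(panel, tmp_path):
    """The panel written to a multi-FASTA on disk."""
    from tolorf import write_genes

    path = tmp_path / "panel.fasta"
    write_genes(panel, path)
    return path
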