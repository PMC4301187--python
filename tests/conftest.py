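import pytest

from gcident import LibraryEntry, MassSpectrum
from gcident import synthetic


def make_entry(name="Phenylalanine_(1TMS)_BP_RI:1551_pubDB", spectrum=None, quant_masses=()):
    """A hand-rolled library entry for unit tests."""
    from gcident.io_formats import parse_entry_name

    metabolite, deriv, product, ri, source = parse_entry_name(name)
    return LibraryEntry(
        raw_name=name,
        metabolite=metabolite,
        derivatization=deriv,
        product=product,
        reference_ri=ri,
        source_db=source,
        spectrum=spectrum if spectrum is not None else MassSpectrum({100: 500.0, 200: 300.0, 250: 100.0}),
        quant_masses=list(quant_masses),
    )


@pytest.fixture(scope="session")
def small_project(tmp_path_factory):
    """A compact noisy synthetic project (3 samples x 4 metabolites)."""
    out = tmp_path_factory.mktemp("small_project")
    spec = synthetic.ProjectSpec(n_samples=3, n_metabolites=4, decoys_per_sample=6)
    paths, truth = synthetic.generate_project(out, seed=1234, spec=spec)
    return paths, truth


@pytest.fixture(scope="session")
def small_pipeline(small_project):
    """The small project run end to end through the library pipeline."""
    from gcident import ProjectConfig, run_pipeline

    paths, truth = small_project
    config = ProjectConfig.from_yaml(paths.config)
    report = run_pipeline(config)
    return paths, truth, config, report
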