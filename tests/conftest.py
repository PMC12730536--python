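import pytest

from xkmir.duplex import ADMISSIBLE_PAIRS, EnergyParameters
from xkmir.pipeline import PipelineConfig, run_all
from xkmir.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def toy_params() -> EnergyParameters:
    """Flat toy energy table: every admissible stack -2.0, helix init +4.0."""
    return EnergyParameters(
        stack_energy={
            (a, b): -2.0 for a in ADMISSIBLE_PAIRS for b in ADMISSIBLE_PAIRS
        },
        helix_init=4.0,
        bulge_open=3.0,
        bulge_per_nt=0.5,
        internal_open=4.0,
        internal_per_nt=0.3,
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle, shared across the suite."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def bundle_paths(default_bundle, tmp_path_factory):
    return default_bundle.write(tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def pipeline_result(default_bundle, bundle_paths, tmp_path_factory):
    cfg = PipelineConfig(
        mirna_table=str(bundle_paths["mirnas"]),
        transcripts_fasta=str(bundle_paths["transcripts_fasta"]),
        annotation=str(bundle_paths["annotation"]),
        gene_sets=[str(bundle_paths["gene_sets"])],
        host_mirnas=str(bundle_paths["host_mirnas"]),
        multispecies_fasta=str(bundle_paths["multispecies_fasta"]),
        out_dir=str(tmp_path_factory.mktemp("pipeline")),
    )
    return run_all(cfg)
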