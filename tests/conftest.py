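"""Shared fixtures: small hand-built proteins and one simulated experiment."""

import pytest

from epitile import (
    PipelineConfig,
    ProteinRecord,
    SimulationConfig,
    build_library,
    run_pipeline,
    simulate_experiment,
)

# Printed reactivity-table sequences used as fixed inputs: an 81-residue
# protective chimera peptide annotated at positions 104-184 of its reference,
# and the interaction-domain peptide at 123-184 (a suffix of the former).
Q38_PEPTIDE = (
    "SPTGLSPGGLLSPVRRDQPLFTFRQVGLICERMMKERESQIRDEYDHVLSAKLAEQYDTFVKFTYDQIQ"
    "KRFEGATPSYLS"
)
INTERACTION_DOMAIN_PEPTIDE = (
    "LFTFRQVGLICERMMKERESQIRDEYDHVLSAKLAEQYDTFVKFTYDQIQKRFEGATPSYLS"
)
MARKER_15MER = "TSGLLSPVRRDQPLF"


@pytest.fixture(scope="session")
def toy_protein() -> ProteinRecord:
    return ProteinRecord(id="toy", sequence="MACATLKRTHDWDPLHSPNG", species_tag="T.y")


@pytest.fixture(scope="session")
def experiment(tmp_path_factory):
    """Default synthetic experiment (3x157-residue proteins, seed 1)."""
    outdir = tmp_path_factory.mktemp("sim")
    return simulate_experiment(SimulationConfig(seed=1), outdir)


@pytest.fixture(scope="session")
def pipeline_result(experiment, tmp_path_factory):
    cfg = PipelineConfig(
        fasta=str(experiment.fasta_path),
        gal=str(experiment.gal_path),
        gpr={g: str(p) for g, p in experiment.gpr_paths.items()},
        outdir=str(tmp_path_factory.mktemp("res")),
        log_level="WARNING",
    )
    return run_pipeline(cfg)


def protein_with_marker(marker: str, at: int, length: int, seed: int = 7) -> ProteinRecord:
    """Random protein with `marker` placed so its first residue is `at`.

    Rejection-samples until the marker occurs exactly once.
    """
    import numpy as np

    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    rng = np.random.default_rng(seed)
    while True:
        seq = "".join(rng.choice(alphabet, size=length))
        seq = seq[: at - 1] + marker + seq[at - 1 + len(marker):]
        if seq.count(marker) == 1:
            return ProteinRecord(id="synth", sequence=seq, species_tag="S.y")
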