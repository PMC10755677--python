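import numpy as np
import pytest

from ribopause import (
    AnalysisParams,
    GeneModel,
    SimConfig,
    TrackSet,
    Transcriptome,
    simulate_footprints,
    simulate_transcriptome,
)

TOY_CDS = "ATGAAAATTCCTTCTTAA"  # MKIPS + stop


@pytest.fixture
def toy_gene() -> GeneModel:
    seq = "G" * 10 + TOY_CDS + "C" * 10
    return GeneModel("g1", seq, 10, 10)


@pytest.fixture
def toy_txome(toy_gene) -> Transcriptome:
    return Transcriptome.from_genes([toy_gene])


@pytest.fixture
def params() -> AnalysisParams:
    return AnalysisParams()


@pytest.fixture
def loose_params() -> AnalysisParams:
    """Default conventions, but no motif-occurrence filter (toy scale)."""
    return AnalysisParams(min_motif_occurrences=1)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study shared across tests: one planted KIP motif."""
    cfg = SimConfig(
        seed=5,
        n_genes=10,
        cds_len_range=(600, 900),
        motif_multipliers={"KIP": 5.0},
        planted_sites=10,
        base_depth=3.0,
        dispersion=10.0,
    )
    txome = simulate_transcriptome(cfg)
    sim = simulate_footprints(txome, cfg, sample="treated", seed=5)
    return cfg, txome, sim


def uniform_tracks(txome: Transcriptome, value: float = 1.0, sample="u") -> TrackSet:
    return TrackSet(
        sample,
        "three_prime_end",
        10**6,
        {g.gene_id: np.full(len(g), value) for g in txome},
    )
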