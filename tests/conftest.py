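import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitohet.reference import CircularReference, GeneAnnotation
from mitohet.simulate import (
    COMPLEMENT,
    FounderVariant,
    RNAConfig,
    SimulationConfig,
    _break_a_runs,
    _random_cds,
    default_scenario,
    simulate_cohort,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_toy_reference(seed: int = 0) -> CircularReference:
    """An 800 bp circle with one protein gene per strand, a tRNA and a D-loop.

    Coding sequences are stop-free (terminated by TAA) so full-CDS
    retranslation is a clean oracle for the codon-level annotator.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=800))
    genes = (
        GeneAnnotation("D-loop", 1, 100, "+", "noncoding"),
        GeneAnnotation("TOYF", 101, 400, "+", "protein_coding"),
        GeneAnnotation("TOYT", 420, 440, "+", "tRNA"),
        GeneAnnotation("TOYR", 451, 750, "-", "protein_coding"),
    )
    seq[100:400] = list(_random_cds(100, rng))
    cds_r = _random_cds(100, rng)
    seq[450:750] = [COMPLEMENT[b] for b in reversed(cds_r)]
    _break_a_runs(seq)  # C substitutions cannot create mitochondrial stops
    return CircularReference("toy", "".join(seq), genes)


def small_config(seed: int = 11) -> tuple[SimulationConfig, CircularReference]:
    """A fast, fully featured miniature of the default study conditions."""
    ref = make_toy_reference(seed)
    founders = (
        FounderVariant(pos=8, af=0.4),  # within 25 bp of the origin
        FounderVariant(pos=150, af=0.5),
        FounderVariant(pos=500, af=0.2),
        FounderVariant(pos=780, af=0.1),
    )
    cfg = SimulationConfig(
        seed=seed,
        n_cells=12,
        generations=6,
        mtdna_copies=50,
        founder_variants=founders,
        mutation_rate=0.0,
        genome_length=ref.length,
        mean_depth=300.0,
        fragment_bias_sd=0.1,
        fragment_x=(120, 420),
        n_low_depth_cells=0,
        rna=RNAConfig(
            n_cells=8,
            n_genes=40,
            mean_depth=120.0,
            reads_per_cell=10,
            read_length=60,
            feature_mean=30.0,
            feature_sd=3.0,
            n_high_mito=0,
            n_low_features=0,
            n_high_features=0,
            n_low_depth=0,
        ),
    )
    return cfg, ref


@pytest.fixture(scope="session")
def toy_ref():
    return make_toy_reference(0)


@pytest.fixture(scope="session")
def small_cohort():
    cfg, ref = small_config()
    return simulate_cohort(cfg, ref)


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged study conditions: 88 DNA cells (4 degraded), 300 RNA cells."""
    cfg, ref = default_scenario(seed=1)
    return simulate_cohort(cfg, ref)
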