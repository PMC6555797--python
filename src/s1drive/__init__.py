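"""s1drive: the S1 gamete killer-protector model of rice hybrid sterility.

Predict gamete viability, hybrid fertility and progeny segregation for
arbitrary crosses under a sporophytic-killer / gametophytic-protector
model; test observed segregation against model expectations; estimate
killing penetrance; simulate multi-generation allele-frequency drive;
and classify S1-locus haplotype structures from SNP panels and
per-base depth profiles.
"""

from importlib.resources import files as _files

from .model import (
    NULL_ALLELE,
    Allele,
    ConfigError,
    FertilityPrediction,
    Gamete,
    GameteDistribution,
    KillerProtectorSpec,
    Locus,
    ModelConfig,
    ProgenyDistribution,
    SporophyteGenotype,
    allele_frequency,
    apply_viability,
    arm_killer,
    cross_progeny,
    default_model,
    enumerate_gametes,
    gamete_pool,
    load_model,
    predict_fertility,
    save_model,
)
from .segregation import (
    CrossDesign,
    GofResult,
    KillingEstimate,
    ModelContradictionError,
    NonIdentifiableError,
    ObservedCounts,
    chi_square_gof,
    estimate_k_from_fertility,
    estimate_killing_efficiency,
    expected_class_probs,
    read_counts_tsv,
    transmission_ratio,
    write_counts_tsv,
)
from .drive import (
    PopulationState,
    Trajectory,
    deterministic_step,
    run_trajectory,
    wright_fisher_sim,
)
from .haplotypes import (
    DEFAULT_PANEL,
    DepthProfile,
    HaplotypeCall,
    PresenceCall,
    SnpPanelDef,
    SnpSite,
    UntypableError,
    call_presence,
    classify_allele,
    classify_panel,
    classify_structure,
    load_catalog,
    summarize_calls,
    type_accession,
    type_tpr,
)
from .simulate import (
    GENE_INTERVALS,
    LineageSpec,
    PanelPaths,
    default_lineages,
    sample_progeny_counts,
    simulate_accession_panel,
    simulate_depth_profile,
)

__version__ = "1.0.0"


def bundled_catalog_path() -> str:
    """Path to the bundled synthetic placeholder allele catalog."""
    return str(_files("s1drive").joinpath("data/allele_catalog.yaml"))
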