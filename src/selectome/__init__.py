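"""Quantitative protease-specificity profiling from substrate phage display.

The package turns deep-sequenced substrate phage selections into a
quantitative specificity profile: hexamer substrates are extracted from
amplicon reads, clustered by their P3-P1' tetramers, scored by relative
probability (RP) against the naive library, and thresholded by the
zero-crossing of the cumulative Kullback-Leibler divergence to yield the
protease's *selectome* — the set of tetramer motifs that, as a whole,
carries its specificity.  Companion modules validate RP against measured
catalytic constants, profile positional composition, annotate cleavage
sites in proteins, and simulate entire selection experiments from a known
specificity landscape.
"""

from .extract import (
    AA_ALPHABET,
    FlankSpec,
    HexamerSet,
    ReadBatch,
    build_hexamer_set,
    extract_insert,
    read_batch_from_file,
    subtract_control,
    translate_six_frames,
)
from .clustering import (
    ClusterTable,
    MAX_CLUSTER_SIZE,
    N_TETRAMERS,
    TetramerCluster,
    candidate_tetramers,
    cluster_naive,
    cluster_selection,
    enumerate_hexamers_containing,
    max_hexamers_containing,
    read_cluster_tsv,
    write_cluster_tsv,
)
from .stats import (
    ProbabilityTable,
    RPTable,
    SelectomeComparison,
    SelectomeResult,
    UNIFORM_TETRAMER_ENTROPY,
    cluster_probabilities,
    compare_selectomes,
    extract_selectome,
    fold_specificity,
    kl_divergence,
    relative_probability,
    selection_completeness,
    selectome_threshold,
    shannon_entropy,
    stats_table,
    summary_dict,
)
from .profiles import (
    PositionFrequencyMatrix,
    WINDOW_POSITIONS,
    align_members,
    build_pfm,
    decile_pfms,
    pfm_for_clusters,
    rp_decile_groups,
    write_pfm_tsv,
)
from .validation import (
    BinnedCorrelation,
    ClassificationMetrics,
    KineticRecord,
    binary_classification,
    binned_correlation,
    match_kinetics,
    read_kinetics_tsv,
    resolve_tetramer,
)
from .annotation import (
    CleavageSite,
    EnrichmentStats,
    classify_sites,
    enrichment_stats,
    ie_positive,
    map_peptide_to_position,
    parse_octamer,
    project_tetramer,
    selectivity_correlation,
    sites_from_table,
)
from .simulate import (
    SelectionConfig,
    SimulatedExperiment,
    SpecificityLandscape,
    emit_kinetics_table,
    make_landscape,
    plant_cleavage_sites,
    simulate_experiment,
    simulate_naive_library,
    simulate_selection,
    write_experiment,
)

__version__ = "0.1.0"


def selection_pipeline(selection, control, naive):
    """Convenience: hexamer sets -> (RPTable, SelectomeResult).

    Subtracts the control, clusters the selection with redundancy
    elimination and the naive library with multi-membership, computes RP
    and the selectome at the cumulative-divergence threshold.
    """
    cleaned = subtract_control(selection, control) if control is not None else selection
    sel_table = cluster_selection(cleaned)
    naive_table = cluster_naive(naive)
    rp = relative_probability(
        cluster_probabilities(sel_table), cluster_probabilities(naive_table)
    )
    threshold = selectome_threshold(rp)
    result = extract_selectome(rp, threshold)
    return rp, result
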