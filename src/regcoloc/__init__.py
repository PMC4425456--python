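"""regcoloc: integrative ChIP-seq co-localization analysis.

Replicate-consensus binding sites, genomic-context annotation with
bidirectional nearest-TSS gene assignment, co-occupancy statistics against a
length-matched random-interval null (Fisher's exact test, F-score),
ChIA-PET anchor-to-promoter direct-target calling, RPKM/GSEA expression
integration, and a ground-truth synthetic data generator.
"""

__version__ = "0.1.0"

from .intervals import (
    GenomicInterval,
    IntervalSet,
    merge_overlapping,
    read_genome,
    read_intervals,
    window_hits,
    write_intervals,
)
from .consensus import (
    ConsensusPeakSet,
    SiteCluster,
    call_consensus,
    cluster_replicates,
    consensus_sites,
    parse_merged_name,
    subtract_control,
)
from .annotation import (
    Gene,
    GeneAnnotation,
    GeneAssignment,
    Transcript,
    annotate_peaks,
    assign_target_genes,
    classify_context,
    read_gtf,
    tss_distance_summary,
    write_gtf,
)
from .colocalization import (
    CoOccupancyProfile,
    OverlapTestResult,
    coloc_panel,
    cooccupancy_profile,
    f_score,
    fisher_overlap_test,
    format_p,
    overlap_stats,
    sample_random_intervals,
)
from .chiapet import (
    InteractionPair,
    MappedLink,
    TargetRecord,
    classify_interaction,
    direct_target_table,
    intra_distance_summary,
    map_interactions,
    read_interactions,
    write_interactions,
)
from .expression import (
    ExpressionMatrix,
    GSEAResult,
    gsea,
    gsea_enrichment_score,
    gsea_permutation_fdr,
    rank_by_fold_change,
    rpkm,
)
from .simulate import GroundTruth, SimulationConfig, Simulator, simulate_all
from .pipeline import load_config, run_pipeline


def published_target_table():
    """The published ChIA-PET direct-target table (22 SIM2 target genes).

    Columns: gene, log_fc, fdr, peak, linkage — one row per (gene, peak)
    link; distances are printed with thousands separators, inter-chromosomal
    links as ``Inter (<geneChrom>-<peakChrom>)``.
    """
    import importlib.resources

    import pandas as pd

    ref = importlib.resources.files("regcoloc").joinpath("data/sim2_chiapet_targets.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
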