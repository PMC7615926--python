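"""leakytx: classify active versus leaky transcription in bulk RNA-seq.

Protein-coding transcripts in a homogeneous cell population split into a
higher-expressed class (the functional transcriptome) and a lower-expressed
class attributed to leaky, presumed nonfunctional transcription.  This
package classifies each detected gene in each dataset by two complementary
methods — a two-component Gaussian-mixture posterior on log2(TPM) and the
KDE-peak half-Gaussian z-score (zTPM) — aggregates calls across a
compendium of datasets, and scores any classifier against curated marker
lists with a confusion-matrix protocol.
"""

from .compendium import (
    CompendiumSummary,
    GroupSummary,
    summaries_to_frame,
    summarize_gene,
    summarize_table,
)
from .evaluation import (
    METHODS,
    EvaluationResult,
    MarkerSet,
    confusion_matrix,
    evaluate_all,
    predict_for_method,
)
from .gmm import (
    EmError,
    GmmDatasetResult,
    GmmFit,
    PosteriorCall,
    assess_eligibility,
    classify_by_posterior,
    fit_two_component_gmm,
    gmm_classify_dataset,
    posterior_active,
)
from .io import (
    ExpressionDataset,
    GeneUniverse,
    QcReport,
    coding_log2_values,
    load_expression,
    load_gene_universe,
    load_manifest,
    load_marker_table,
    qc_gate,
    write_expression,
)
from .pipeline import DatasetCalls, classify_compendium, read_calls, write_calls
from .simulate import (
    GroupSpec,
    PlantedMarker,
    SimConfig,
    TruthTable,
    default_marker_panel,
    plant_marker_panel,
    simulate_compendium,
)
from .ztpm import (
    ZTPM_THRESHOLD,
    ZtpmCall,
    ZtpmDatasetResult,
    ZtpmFit,
    fit_ztpm,
    ztpm_classify_dataset,
    ztpm_transform,
)

__version__ = "0.1.0"
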