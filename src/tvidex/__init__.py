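"""tvidex: time-varying-intercept differential expression for longitudinal cohorts.

Detects genes whose expression trajectories differ between two outcome
groups using a one-knot spline model, an RSS-ratio statistic, and a residual
bootstrap, with replication, random-set sensitivity, and over-representation
stages, plus a synthetic cohort generator for testing and calibration.
"""

from importlib import resources

from .dataio import (
    AnnotationMap,
    ExpressionMatrix,
    SampleManifest,
    SampleRecord,
    map_probes_to_genes,
    read_annotation,
    read_expression_matrix,
    read_sample_manifest,
    summarize_manifest,
    write_expression_matrix,
    write_results_table,
    write_sample_manifest,
)
from .discovery import (
    GeneTestResult,
    ScanConfig,
    baseline_comparison,
    classify_pattern,
    fdr_qvalues,
    run_timecourse_scan,
    select_significant,
)
from .enrichment import category_coverage_report, fisher_overrepresentation
from .preprocess import adjust_age_sex, filter_low_expression, sex_check
from .replication import replicate_selected, sensitivity_null_sets
from .synthetic_cohort import (
    CohortDesign,
    SignalSpec,
    design_from_template,
    ground_truth_table,
    simulate_expression,
    simulate_manifest,
)
from .tvi_core import (
    SplineBasis,
    TviTester,
    bootstrap_pvalue,
    build_tvi_basis,
    fit_curve,
    tvi_statistic,
)

__version__ = "0.1.0"


def bundled_annotation_path(name: str = "replicated_probe_genes.tsv"):
    """Path to a bundled example annotation table (probe id -> gene symbol)."""
    return resources.files("tvidex").joinpath("data", name)
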