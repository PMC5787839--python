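"""bsmeth: whole-genome bisulfite methylome analysis.

Context-aware methylation quantification with nonconversion correction,
windowed Fisher-exact DMR calling, gene/TE differential methylation,
metagene and quintile profiling, methylation-expression integration, and a
fully ground-truthed synthetic methylome generator.
"""

from importlib import resources

from .core import (
    benjamini_hochberg,
    call_methylated_sites,
    classify_contexts,
    compute_site_methylation,
    correct_ml,
    estimate_nonconversion,
    global_summary,
    merge_symmetric_cpg,
    pool_replicates,
    window_summarize,
)
from .dmr import (
    assign_dmr_features,
    call_dmrs,
    fisher_exact_two_sided,
    test_te_differential,
)
from .integrate import (
    group_expression_comparison,
    integration_table,
    overlap_dmg_deg,
    relative_expression_ddct,
    venn_counts,
    wilcoxon_rank_sum,
)
from .profiles import (
    compartment_methylation,
    expression_by_methylation_group,
    metagene_profile,
    profile_by_group,
    quintile_partition,
    te_length_quintiles,
    te_profile,
)
from .simulate import SimulationConfig, simulate_study
from .types import GeneModel, GenomeSequence, TEAnnotation

__version__ = "0.1.0"


def demo_config_path() -> str:
    """Path of the packaged demo simulation config."""
    return str(resources.files("bsmeth").joinpath("data/demo.yaml"))
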