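"""Integration of differential methylation with gene expression:
DMG x DEG overlaps, Venn counts, Wilcoxon group comparisons with boxplot
statistics, and the comparative-Ct qPCR utility.

Differential-expression labels are inputs (from the expression table or the
simulator truth); no DE caller is implemented here.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import boxplot_stats
from .types import ValidationError


def _status_sets(dmfeatures: pd.DataFrame) -> tuple[set[str], set[str]]:
    genes = dmfeatures[dmfeatures.get("feature_type", "gene") == "gene"] \
        if "feature_type" in dmfeatures.columns else dmfeatures
    hyper = set(genes.loc[genes["status"] == "hyper", "feature_id"])
    hypo = set(genes.loc[genes["status"] == "hypo", "feature_id"])
    return hyper, hypo


def overlap_dmg_deg(
    dmfeatures: pd.DataFrame, expression: pd.DataFrame
) -> dict:
    """Overlap differentially methylated genes with DE labels.

    Returns counts and gene lists for hyper&down, hypo&up, hyper&up,
    hypo&down, plus a hypergeometric enrichment p-value for each overlap
    against the expression-table universe. A gene hyper in one region and
    hypo in another counts in both methylation sets (regions are accounted
    separately). Duplicate expression rows are deduplicated with a warning;
    an identifier mismatch above 50% raises an error.
    """
    expr = expression
    if expr["gene_id"].duplicated().any():
        warnings.warn("duplicate gene ids in expression table; deduplicated")
        expr = expr.drop_duplicates(subset="gene_id")
    hyper, hypo = _status_sets(dmfeatures)
    universe = set(expr["gene_id"])
    dm_genes = hyper | hypo
    if dm_genes and len(dm_genes & universe) / len(dm_genes) < 0.5:
        raise ValidationError(
            "more than half of the differentially methylated gene ids are absent "
            "from the expression table; check that annotations match"
        )
    labels = expr.set_index("gene_id")["de_label"] if "de_label" in expr.columns else pd.Series(dtype=object)
    up = set(labels.index[labels == "up"])
    down = set(labels.index[labels == "down"])

    def entry(meth: set[str], de: set[str]) -> dict:
        inter = sorted(meth & de)
        m, d = len(meth & universe), len(de)
        n_u = len(universe)
        # P(X >= |inter|) drawing |de| genes from the universe with m marked
        p = float(stats.hypergeom.sf(len(inter) - 1, n_u, m, d)) if n_u else float("nan")
        return {"count": len(inter), "genes": inter, "enrichment_p": p}

    return {
        "hyper_down": entry(hyper, down),
        "hypo_up": entry(hypo, up),
        "hyper_up": entry(hyper, up),
        "hypo_down": entry(hypo, down),
        "n_hyper": len(hyper),
        "n_hypo": len(hypo),
        "n_up": len(up),
        "n_down": len(down),
        "n_universe": len(universe),
    }


def venn_counts(named_sets: dict[str, set]) -> dict[str, int]:
    """Exclusive region counts for a Venn diagram of >= 2 named sets.

    Keys are '&'-joined sorted member names; each element is counted in the
    single region matching exactly the sets that contain it, so region
    counts sum to the size of the union.
    """
    if len(named_sets) < 2:
        raise ValidationError("need at least 2 sets")
    names = sorted(named_sets)
    counts: dict[str, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(
                set(), *(named_sets[n] for n in names if n not in combo)
            )
            counts["&".join(combo)] = len(inside - outside)
    return counts


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact (full null distribution) when the smaller sample has <= 8
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        ).pvalue
    )


def group_expression_comparison(
    all_genes_values,
    hyper_values,
    hypo_values,
    min_group: int = 3,
) -> pd.DataFrame:
    """Boxplot statistics and Wilcoxon tests of DMG groups against all genes.

    Values are per-gene log2 expression changes (case vs control). Each DMG
    group is compared with the all-genes reference by the two-sided Wilcoxon
    rank-sum test; groups smaller than ``min_group`` still get statistics
    but their p is flagged unreliable.
    """
    ref = np.asarray(all_genes_values, dtype=float)
    rows = []
    for label, values in (
        ("all", ref),
        ("hyper", np.asarray(hyper_values, dtype=float)),
        ("hypo", np.asarray(hypo_values, dtype=float)),
    ):
        row = {"group": label, "n": len(values), **boxplot_stats(values)}
        if label == "all":
            row["wilcoxon_p"] = np.nan
            row["p_reliable"] = False
        elif len(values) == 0:
            row["wilcoxon_p"] = np.nan
            row["p_reliable"] = False
        else:
            row["wilcoxon_p"] = wilcoxon_rank_sum(values, ref)
            row["p_reliable"] = len(values) >= min_group
        rows.append(row)
    return pd.DataFrame(rows)


def log2_expression_change(
    expression: pd.DataFrame,
    case_column: str = "fpkm_case",
    control_column: str = "fpkm_control",
    offset: float = 0.01,
) -> pd.Series:
    """Per-gene log2((FPKM_case + offset) / (FPKM_control + offset))."""
    ratio = (
        (expression[case_column] + offset) / (expression[control_column] + offset)
    ).to_numpy()
    return pd.Series(
        np.log2(ratio), index=expression["gene_id"].to_numpy(), name="log2fc"
    )


def integration_table(
    dmfeatures: pd.DataFrame,
    expression: pd.DataFrame,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """One row per gene: methylation status per region, DE label, log2 change.

    ``gene_ids`` fixes the gene universe (default: the expression table).
    The per-region status is hyper/hypo/both/none depending on the DMRs
    assigned to that region in any context; ``overall`` aggregates regions.
    """
    expr = expression.drop_duplicates(subset="gene_id").set_index("gene_id")
    if gene_ids is None:
        gene_ids = list(expr.index)
    genes_dm = dmfeatures[dmfeatures.get("feature_type", pd.Series(dtype=object)).eq("gene")] \
        if "feature_type" in dmfeatures.columns else dmfeatures
    rows = []
    have_both_fpkm = {"fpkm_case", "fpkm_control"}.issubset(expr.columns)
    log2fc = (
        log2_expression_change(expression.drop_duplicates(subset="gene_id"))
        if have_both_fpkm
        else None
    )
    for gene_id in gene_ids:
        sub = genes_dm[genes_dm["feature_id"] == gene_id]
        row: dict = {"gene_id": gene_id}
        statuses = set()
        for region in ("promoter", "body", "ttr"):
            region_status = set(sub.loc[sub["region"] == region, "status"])
            if {"hyper", "hypo"} <= region_status:
                row[f"{region}_status"] = "both"
            elif region_status:
                row[f"{region}_status"] = next(iter(region_status))
            else:
                row[f"{region}_status"] = "none"
            statuses |= region_status
        if {"hyper", "hypo"} <= statuses:
            row["overall"] = "both"
        elif statuses:
            row["overall"] = next(iter(statuses))
        else:
            row["overall"] = "none"
        row["de_label"] = (
            expr.at[gene_id, "de_label"]
            if gene_id in expr.index and "de_label" in expr.columns
            else "none"
        )
        row["log2fc"] = (
            float(log2fc.loc[gene_id]) if log2fc is not None and gene_id in log2fc.index else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def relative_expression_ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Comparative-Ct (2^-ddCt) relative expression.

    ddCt = (Ct_target,treated - Ct_ref,treated) -
    (Ct_target,control - Ct_ref,control); returns 2**(-ddCt).
    """
    for ct in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if ct <= 0:
            raise ValidationError("Ct values must be positive")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(math.pow(2.0, -ddct))
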