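"""Differentially methylated region (DMR) calling and differential
methylation of annotated features.

DMRs are found by a sliding-window scan (1000 bp window, 100 bp step): in
each window the pooled methylated/unmethylated read counts of the two
conditions form a 2x2 table tested with Fisher's exact test; q-values are
Benjamini-Hochberg adjusted per context genome-wide, and significant
same-direction windows (q < alpha and |delta ML| >= min_delta) are merged
when overlapping or book-ended. TEs are tested feature-wise with the same
2x2 Fisher construction plus a >2-fold methylation-level criterion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import benjamini_hochberg, correct_ml, window_spans
from .features import gene_region_interval, overlaps
from .types import CONTEXTS, GeneModel, TEAnnotation, ValidationError

#: relative slack used when comparing hypergeometric probabilities for ties
_TIE_SLACK = 1.0 + 1e-7


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities of all tables (with the
    observed margins) whose probability does not exceed that of the observed
    table, with a small relative slack for floating-point ties. An all-zero
    table yields p = 1 with a warning.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("Fisher table entries must be non-negative")
    if a + b + c + d == 0:
        warnings.warn("all-zero 2x2 table; p = 1")
        return 1.0
    return float(
        fisher_exact_many(
            np.array([a]), np.array([b]), np.array([c]), np.array([d])
        )[0]
    )


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _hypergeom_pmf(k, n, r1, c1):
    """pmf of k successes among c1 draws from n items with r1 marked."""
    return np.exp(_log_choose(r1, k) + _log_choose(n - r1, c1 - k) - _log_choose(n, c1))


def fisher_exact_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
    chunk_cells: int = 4_000_000,
) -> np.ndarray:
    """Vectorised two-sided Fisher exact p-values for many 2x2 tables."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo = np.maximum(0, r1 + c1 - n)
    hi = np.minimum(r1, c1)
    p = np.ones(len(a), dtype=float)
    todo = np.nonzero(n > 0)[0]
    # group by support width so padding stays cheap
    widths = (hi - lo + 1)[todo]
    order = todo[np.argsort(widths, kind="stable")]
    i = 0
    while i < len(order):
        w = int(hi[order[i]] - lo[order[i]] + 1)
        rows = max(1, chunk_cells // max(w, 1))
        idx = order[i : i + rows]
        i += rows
        wmax = int((hi[idx] - lo[idx]).max()) + 1
        k = lo[idx, None] + np.arange(wmax)[None, :]
        valid = k <= hi[idx, None]
        pmf = np.where(
            valid,
            _hypergeom_pmf(
                np.where(valid, k, 0), n[idx, None], r1[idx, None], c1[idx, None]
            ),
            0.0,
        )
        p_obs = _hypergeom_pmf(a[idx], n[idx], r1[idx], c1[idx])
        p[idx] = np.minimum(
            (pmf * (pmf <= p_obs[:, None] * _TIE_SLACK)).sum(axis=1), 1.0
        )
    return p


# ---------------------------------------------------------------------------
# Window tests and DMR merging


def _pooled_counts_in_span(
    sites: pd.DataFrame, chrom: str, start: int, end: int, context: str
) -> tuple[int, int]:
    sel = sites[
        (sites["chrom"] == chrom)
        & (sites["context"] == context)
        & (sites["pos"] >= start)
        & (sites["pos"] <= end)
        & sites["covered"]
    ]
    return int(sel["count_meth"].sum()), int(sel["count_unmeth"].sum())


def window_tests(
    case_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 1000,
    step: int = 100,
    min_sites: int = 5,
    contexts: tuple[str, ...] = CONTEXTS,
) -> pd.DataFrame:
    """Fisher-test every sliding window with enough covered sites per context.

    Counts are pooled over covered sites of the window; a window is tested
    only when both conditions have at least ``min_sites`` covered cytosines
    of the context in it. q-values are BH-adjusted per context across all
    tested windows genome-wide.
    """
    from .core import _window_sums  # shared cumulative-sum helper

    frames = []
    case_cov = case_sites[case_sites["covered"]]
    ctrl_cov = control_sites[control_sites["covered"]]
    for chrom, length in chrom_lengths.items():
        spans = window_spans(length, window, step)
        if not spans:
            continue
        spans_arr = np.array(spans)
        case_chrom = case_cov[case_cov["chrom"] == chrom]
        ctrl_chrom = ctrl_cov[ctrl_cov["chrom"] == chrom]
        for context in contexts:
            cols = {}
            for label, tab in (("case", case_chrom), ("control", ctrl_chrom)):
                sub = tab[tab["context"] == context]
                pos = sub["pos"].to_numpy()
                order = np.argsort(pos, kind="stable")
                pos = pos[order]
                cols[f"{label}_meth"] = _window_sums(
                    pos, sub["count_meth"].to_numpy()[order], spans_arr
                )
                cols[f"{label}_unmeth"] = _window_sums(
                    pos, sub["count_unmeth"].to_numpy()[order], spans_arr
                )
                cols[f"{label}_sites"] = _window_sums(
                    pos, np.ones_like(pos), spans_arr
                )
            df = pd.DataFrame(cols)
            df.insert(0, "chrom", chrom)
            df.insert(1, "start", spans_arr[:, 0])
            df.insert(2, "end", spans_arr[:, 1])
            df.insert(3, "context", context)
            frames.append(df)
    if not frames:
        return pd.DataFrame()
    tests = pd.concat(frames, ignore_index=True)
    tests = tests[
        (tests["case_sites"] >= min_sites) & (tests["control_sites"] >= min_sites)
    ].reset_index(drop=True)
    if len(tests) == 0:
        warnings.warn("no windows passed the coverage filter; empty result")
        tests["p"] = tests["q"] = tests["ml_case"] = tests["ml_control"] = tests["delta_ml"] = []
        return tests
    tot_case = tests["case_meth"] + tests["case_unmeth"]
    tot_ctrl = tests["control_meth"] + tests["control_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        tests["ml_case"] = np.where(tot_case > 0, tests["case_meth"] / tot_case.where(tot_case > 0, 1), np.nan)
        tests["ml_control"] = np.where(tot_ctrl > 0, tests["control_meth"] / tot_ctrl.where(tot_ctrl > 0, 1), np.nan)
    tests["delta_ml"] = tests["ml_case"] - tests["ml_control"]
    tests["p"] = fisher_exact_many(
        tests["case_meth"].to_numpy(),
        tests["case_unmeth"].to_numpy(),
        tests["control_meth"].to_numpy(),
        tests["control_unmeth"].to_numpy(),
    )
    tests["q"] = np.nan
    for context in contexts:
        mask = tests["context"] == context
        if mask.any():
            tests.loc[mask, "q"] = benjamini_hochberg(tests.loc[mask, "p"].to_numpy())
    return tests


def merge_significant_windows(
    tests: pd.DataFrame,
    case_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    q_alpha: float = 0.05,
    min_delta: float = 0.1,
) -> pd.DataFrame:
    """Merge significant same-direction, same-context windows into DMRs.

    Windows are significant when q < ``q_alpha`` and |delta ML| >=
    ``min_delta``; overlapping or book-ended significant windows of the same
    context and direction merge, and the merged span's methylation levels
    are recomputed from pooled counts. Status is hyper when the case
    (treatment) level exceeds the control level.
    """
    cols = [
        "chrom", "start", "end", "context", "status", "ml_case", "ml_control",
        "delta_ml", "p_min", "q_min", "n_windows",
    ]
    if len(tests) == 0:
        return pd.DataFrame(columns=cols)
    sig = tests[(tests["q"] < q_alpha) & (tests["delta_ml"].abs() >= min_delta)].copy()
    if len(sig) == 0:
        return pd.DataFrame(columns=cols)
    sig["status"] = np.where(sig["delta_ml"] > 0, "hyper", "hypo")
    dmrs = []
    for (chrom, context, status), grp in sig.groupby(["chrom", "context", "status"]):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None:
                cur = {"start": row.start, "end": row.end, "p_min": row.p, "q_min": row.q, "n": 1}
            elif row.start <= cur["end"] + 1:
                cur["end"] = max(cur["end"], row.end)
                cur["p_min"] = min(cur["p_min"], row.p)
                cur["q_min"] = min(cur["q_min"], row.q)
                cur["n"] += 1
            else:
                dmrs.append((chrom, context, status, cur))
                cur = {"start": row.start, "end": row.end, "p_min": row.p, "q_min": row.q, "n": 1}
        if cur is not None:
            dmrs.append((chrom, context, status, cur))
    rows = []
    for chrom, context, status, cur in dmrs:
        cm, cu = _pooled_counts_in_span(case_sites, chrom, cur["start"], cur["end"], context)
        km, ku = _pooled_counts_in_span(control_sites, chrom, cur["start"], cur["end"], context)
        ml_case = cm / (cm + cu) if cm + cu else np.nan
        ml_control = km / (km + ku) if km + ku else np.nan
        rows.append(
            {
                "chrom": chrom,
                "start": cur["start"],
                "end": cur["end"],
                "context": context,
                "status": status,
                "ml_case": ml_case,
                "ml_control": ml_control,
                "delta_ml": ml_case - ml_control,
                "p_min": cur["p_min"],
                "q_min": cur["q_min"],
                "n_windows": cur["n"],
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start", "context", "status"]).reset_index(drop=True)


def call_dmrs(
    case_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 1000,
    step: int = 100,
    q_alpha: float = 0.05,
    min_delta: float = 0.1,
    min_sites: int = 5,
    contexts: tuple[str, ...] = CONTEXTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full DMR scan: window tests then merging.

    ``case_sites``/``control_sites`` are site-methylation tables with
    replicates already pooled per condition (see
    :func:`bsmeth.core.pool_replicates`). Returns ``(dmrs, window_tests)``.
    """
    tests = window_tests(
        case_sites, control_sites, chrom_lengths,
        window=window, step=step, min_sites=min_sites, contexts=contexts,
    )
    dmrs = merge_significant_windows(
        tests, case_sites, control_sites, q_alpha=q_alpha, min_delta=min_delta
    )
    return dmrs, tests


# ---------------------------------------------------------------------------
# Feature assignment


def assign_dmr_features(
    dmrs: pd.DataFrame,
    genes: list[GeneModel],
    tes: list[TEAnnotation] | None = None,
    promoter_span: int = 2000,
    ttr_span: int = 2000,
) -> pd.DataFrame:
    """Assign DMRs to gene regions (and optionally TE spans) by >=1 bp overlap.

    A gene is hyper-/hypomethylated in a region when at least one DMR of
    that status overlaps the region; a gene may appear with both statuses
    via different regions or contexts. Returns one row per (feature, region,
    context, status) with the strongest (minimum-q) supporting DMR.
    """
    rows = []
    regions = ("promoter", "body", "ttr")
    spans = {"promoter": promoter_span, "body": 0, "ttr": ttr_span}
    for gene in genes:
        sub = dmrs[dmrs["chrom"] == gene.chrom]
        for region in regions:
            start, end = gene_region_interval(gene, region, spans[region] or 2000)
            hits = sub[(sub["start"] <= end) & (sub["end"] >= start)]
            for (context, status), grp in hits.groupby(["context", "status"]):
                best = grp.loc[grp["q_min"].idxmin()]
                rows.append(
                    {
                        "feature_id": gene.gene_id,
                        "feature_type": "gene",
                        "region": region,
                        "context": context,
                        "status": status,
                        "delta_ml": best["delta_ml"],
                        "p": best["p_min"],
                        "q": best["q_min"],
                    }
                )
    for te in tes or []:
        sub = dmrs[dmrs["chrom"] == te.chrom]
        hits = sub[(sub["start"] <= te.end) & (sub["end"] >= te.start)]
        for (context, status), grp in hits.groupby(["context", "status"]):
            best = grp.loc[grp["q_min"].idxmin()]
            rows.append(
                {
                    "feature_id": te.te_id,
                    "feature_type": "te",
                    "region": "TE",
                    "context": context,
                    "status": status,
                    "delta_ml": best["delta_ml"],
                    "p": best["p_min"],
                    "q": best["q_min"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "feature_type", "region", "context", "status",
            "delta_ml", "p", "q",
        ],
    )


# ---------------------------------------------------------------------------
# Per-TE differential methylation


def test_te_differential(
    tes: list[TEAnnotation],
    case_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    contexts: tuple[str, ...] = CONTEXTS + ("combined",),
    q_alpha: float = 0.05,
    min_fold: float = 2.0,
    min_sites: int = 5,
    pseudocount: float = 0.01,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Per-TE Fisher exact test of pooled counts with a fold-change criterion.

    For each TE and context (plus a ``combined`` all-context test), counts
    of covered sites within the TE span are pooled per condition and tested;
    p-values are BH-adjusted across TEs within a context. A TE is called
    differentially methylated when (q if ``use_fdr`` else p) < ``q_alpha``
    and the methylation-level fold change (with ``pseudocount`` added to
    both levels) exceeds ``min_fold``. TEs with fewer than ``min_sites``
    covered cytosines in either condition are skipped for that context.
    """
    def pooled(tab: pd.DataFrame, te: TEAnnotation, context: str):
        sel = tab[
            (tab["chrom"] == te.chrom)
            & (tab["pos"] >= te.start)
            & (tab["pos"] <= te.end)
            & tab["covered"]
        ]
        if context != "combined":
            sel = sel[sel["context"] == context]
        return (
            int(sel["count_meth"].sum()),
            int(sel["count_unmeth"].sum()),
            len(sel),
        )

    rows = []
    for context in contexts:
        for te in tes:
            cm, cu, n_case = pooled(case_sites, te, context)
            km, ku, n_ctrl = pooled(control_sites, te, context)
            if n_case < min_sites or n_ctrl < min_sites:
                continue
            ml_case = cm / (cm + cu) if cm + cu else np.nan
            ml_control = km / (km + ku) if km + ku else np.nan
            fold = (ml_case + pseudocount) / (ml_control + pseudocount)
            if fold < 1:
                fold = 1.0 / fold
            rows.append(
                {
                    "feature_id": te.te_id,
                    "te_class": te.te_class,
                    "context": context,
                    "case_meth": cm,
                    "case_unmeth": cu,
                    "control_meth": km,
                    "control_unmeth": ku,
                    "ml_case": ml_case,
                    "ml_control": ml_control,
                    "fold_change": fold,
                }
            )
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    out["p"] = fisher_exact_many(
        out["case_meth"].to_numpy(),
        out["case_unmeth"].to_numpy(),
        out["control_meth"].to_numpy(),
        out["control_unmeth"].to_numpy(),
    )
    out["q"] = np.nan
    for context, grp in out.groupby("context"):
        out.loc[grp.index, "q"] = benjamini_hochberg(grp["p"].to_numpy())
    crit = out["q"] if use_fdr else out["p"]
    out["status"] = np.where(out["ml_case"] > out["ml_control"], "hyper", "hypo")
    out["differential"] = (crit < q_alpha) & (out["fold_change"] > min_fold)
    out.loc[out["ml_case"] == out["ml_control"], "status"] = "none"
    return out.reset_index(drop=True)
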