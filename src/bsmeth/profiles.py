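"""Metagene and TE methylation profiles, compartment-level methylation, and
quintile stratifications (expression, methylation level, TE length).

All profile values are count-pooled methylation levels — sum(m)/sum(m+u)
over the covered cytosines contributing to a bin — never means of per-site
levels. Metagene axes rescale each feature to a fixed number of bins per
segment (promoter / 5'UTR / gene body / 3'UTR / downstream), with 2-kb
flanks, strand-aware so '-'-strand genes are traversed 5'->3'.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .features import COMPARTMENTS, paint_compartments, site_compartments
from .types import CONTEXTS, GeneModel, GenomeSequence, TEAnnotation, ValidationError

GENE_SEGMENTS = ("promoter", "utr5", "body", "utr3", "downstream")
DEFAULT_GENE_BINS = {"promoter": 20, "utr5": 5, "body": 20, "utr3": 5, "downstream": 20}
TE_SEGMENTS = ("upstream", "body", "downstream")

QUINTILE_LABELS = ("1st", "2nd", "3rd", "4th", "5th")


# ---------------------------------------------------------------------------
# Compartment-level methylation


def compartment_methylation(
    site_methylation: pd.DataFrame,
    genome: GenomeSequence,
    genes: list[GeneModel],
    tes: list[TEAnnotation],
) -> pd.DataFrame:
    """Count-pooled ML per compartment per context.

    Compartment precedence for overlapping bases is TE > gene subfeature >
    promoter/downstream > intergenic. Compartments with no covered sites are
    reported with ml = NaN (flagged missing, not zero).
    """
    arrays = paint_compartments(genome, genes, tes)
    sm = site_methylation[site_methylation["covered"]].copy()
    sm["compartment"] = site_compartments(sm, arrays)
    rows = []
    grouped = sm.groupby(["compartment", "context"], observed=True).agg(
        sum_meth=("count_meth", "sum"),
        sum_unmeth=("count_unmeth", "sum"),
        n_sites=("pos", "size"),
    )
    for comp in COMPARTMENTS:
        if comp == "spike_in" and genome.spike_in_chrom is None:
            continue
        for ctx in CONTEXTS:
            if (comp, ctx) in grouped.index:
                g = grouped.loc[(comp, ctx)]
                total = int(g["sum_meth"] + g["sum_unmeth"])
                ml = g["sum_meth"] / total if total else np.nan
                rows.append(
                    dict(compartment=comp, context=ctx, sum_meth=int(g["sum_meth"]),
                         sum_unmeth=int(g["sum_unmeth"]), n_sites=int(g["n_sites"]), ml=ml)
                )
            else:
                rows.append(
                    dict(compartment=comp, context=ctx, sum_meth=0, sum_unmeth=0,
                         n_sites=0, ml=np.nan)
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metagene / TE profiles


def _gene_segments(gene: GeneModel, flank: int) -> dict[str, tuple[int, int] | None]:
    """Genomic interval of each metagene segment (None when empty).

    Segments tile [transcript_start - flank, transcript_end + flank] exactly
    (promoter and downstream swap ends on the '-' strand), so every cytosine
    in the feature plus flanks lands in exactly one segment.
    """
    ts, te = gene.transcript_start, gene.transcript_end
    utr5 = (min(s for s, _ in gene.utr5), max(e for _, e in gene.utr5)) if gene.utr5 else None
    utr3 = (min(s for s, _ in gene.utr3), max(e for _, e in gene.utr3)) if gene.utr3 else None
    if gene.strand == "+":
        low_utr, high_utr = utr5, utr3
        low_name, high_name = "utr5", "utr3"
        upstream, downstream = (max(1, ts - flank), ts - 1), (te + 1, te + flank)
        up_name, down_name = "promoter", "downstream"
    else:
        low_utr, high_utr = utr3, utr5
        low_name, high_name = "utr3", "utr5"
        upstream, downstream = (te + 1, te + flank), (max(1, ts - flank), ts - 1)
        up_name, down_name = "promoter", "downstream"
    body_start = (low_utr[1] + 1) if low_utr else ts
    body_end = (high_utr[0] - 1) if high_utr else te
    segs: dict[str, tuple[int, int] | None] = {
        up_name: upstream if upstream[1] >= upstream[0] else None,
        low_name: low_utr,
        "body": (body_start, body_end) if body_start <= body_end else None,
        high_name: high_utr,
        down_name: downstream if downstream[1] >= downstream[0] else None,
    }
    return segs


def _assign_bins(
    pos: np.ndarray, seg: tuple[int, int], n_bins: int, reverse: bool
) -> np.ndarray:
    start, end = seg
    length = end - start + 1
    offset = (end - pos) if reverse else (pos - start)
    return np.minimum((offset * n_bins) // length, n_bins - 1).astype(int)


def _profile_axis(bins_per_segment: dict[str, int], segments: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    global_bin = 0
    for seg in segments:
        for b in range(bins_per_segment[seg]):
            rows.append({"segment": seg, "segment_bin": b, "bin": global_bin})
            global_bin += 1
    return pd.DataFrame(rows)


def _pool_profile(
    sm: pd.DataFrame,
    features: list,
    segment_fn,
    bins_per_segment: dict[str, int],
    segments: tuple[str, ...],
) -> pd.DataFrame:
    axis = _profile_axis(bins_per_segment, segments)
    offset = {seg: int(axis.loc[axis["segment"] == seg, "bin"].min()) for seg in segments}
    n_bins_total = len(axis)
    sums = {ctx: np.zeros((n_bins_total, 3)) for ctx in CONTEXTS}  # meth, unmeth, n
    by_chrom = {
        chrom: grp.sort_values("pos").reset_index(drop=True)
        for chrom, grp in sm.groupby("chrom")
    }
    for feat in features:
        grp = by_chrom.get(feat.chrom if hasattr(feat, "chrom") else feat["chrom"])
        if grp is None:
            continue
        reverse = (feat.strand == "-")
        pos_all = grp["pos"].to_numpy()
        for seg, interval in segment_fn(feat).items():
            if interval is None:
                continue
            lo = np.searchsorted(pos_all, interval[0], side="left")
            hi = np.searchsorted(pos_all, interval[1], side="right")
            if hi <= lo:
                continue
            sub = grp.iloc[lo:hi]
            bins = _assign_bins(
                sub["pos"].to_numpy(), interval, bins_per_segment[seg], reverse
            ) + offset[seg]
            for ctx in CONTEXTS:
                mask = (sub["context"] == ctx).to_numpy()
                if not mask.any():
                    continue
                np.add.at(sums[ctx][:, 0], bins[mask], sub["count_meth"].to_numpy()[mask])
                np.add.at(sums[ctx][:, 1], bins[mask], sub["count_unmeth"].to_numpy()[mask])
                np.add.at(sums[ctx][:, 2], bins[mask], 1)
    frames = []
    for ctx in CONTEXTS:
        total = sums[ctx][:, 0] + sums[ctx][:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            ml = np.where(total > 0, sums[ctx][:, 0] / np.where(total > 0, total, 1), np.nan)
        frame = axis.copy()
        frame["context"] = ctx
        frame["sum_meth"] = sums[ctx][:, 0].astype(int)
        frame["sum_unmeth"] = sums[ctx][:, 1].astype(int)
        frame["n_sites"] = sums[ctx][:, 2].astype(int)
        frame["ml"] = ml
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_features"] = len(features)
    return out


def metagene_profile(
    site_methylation: pd.DataFrame,
    genes: list[GeneModel],
    flank: int = 2000,
    bins_per_segment: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Average methylation over genes rescaled to a fixed bin axis.

    Axis: promoter flank, 5'UTR, gene body, 3'UTR, downstream flank
    (default 20/5/20/5/20 bins). Count-pooled per bin across all genes;
    '-'-strand genes are mirrored so bin 0 is always the far 5' end.
    """
    if not genes:
        raise ValidationError("no features")
    bins = dict(DEFAULT_GENE_BINS)
    if bins_per_segment:
        bins.update(bins_per_segment)
    sm = site_methylation[site_methylation["covered"]]
    return _pool_profile(
        sm, genes, lambda g: _gene_segments(g, flank), bins, GENE_SEGMENTS
    )


def te_profile(
    site_methylation: pd.DataFrame,
    tes: list[TEAnnotation],
    flank: int = 2000,
    body_bins: int = 20,
    flank_bins: int = 20,
) -> pd.DataFrame:
    """TE metagene profile: upstream flank, TE body, downstream flank."""
    if not tes:
        raise ValidationError("no features")
    bins = {"upstream": flank_bins, "body": body_bins, "downstream": flank_bins}

    def segs(te: TEAnnotation) -> dict[str, tuple[int, int] | None]:
        if te.strand == "+":
            up = (max(1, te.start - flank), te.start - 1)
            down = (te.end + 1, te.end + flank)
        else:
            up = (te.end + 1, te.end + flank)
            down = (max(1, te.start - flank), te.start - 1)
        return {
            "upstream": up if up[1] >= up[0] else None,
            "body": (te.start, te.end),
            "downstream": down if down[1] >= down[0] else None,
        }

    sm = site_methylation[site_methylation["covered"]]
    return _pool_profile(sm, tes, segs, bins, TE_SEGMENTS)


# ---------------------------------------------------------------------------
# Quintiles


def quintile_partition(
    values: pd.Series,
    special_mask: pd.Series | None = None,
    special_label: str = "none",
) -> pd.Series:
    """Rank items ascending and split into five near-equal quintiles.

    ``values`` is indexed by item id. Items flagged by ``special_mask`` are
    extracted first into ``special_label`` (e.g. FPKM < 0.1 -> "none";
    unmethylated regions -> "unmethylated"). The remainder is split into
    groups whose sizes differ by at most one, larger groups at the low end;
    ties are broken by stable input order. Labels: '1st' (lowest) .. '5th'.
    """
    out = pd.Series(index=values.index, dtype=object, name="group")
    if special_mask is not None:
        out[special_mask] = special_label
        work = values[~special_mask]
    else:
        work = values
    n = len(work)
    if n < 5:
        raise ValidationError(f"need at least 5 items to form quintiles, got {n}")
    order = np.argsort(work.to_numpy(), kind="stable")
    base, rem = divmod(n, 5)
    sizes = [base + 1] * rem + [base] * (5 - rem)
    start = 0
    ranked_index = work.index.to_numpy()[order]
    for label, size in zip(QUINTILE_LABELS, sizes):
        out[ranked_index[start : start + size]] = label
        start += size
    return out


def profile_by_group(
    site_methylation: pd.DataFrame,
    genes: list[GeneModel],
    grouping: pd.Series,
    flank: int = 2000,
    bins_per_segment: dict[str, int] | None = None,
) -> pd.DataFrame:
    """One metagene profile per group, on a shared bin axis.

    ``grouping`` maps gene_id -> group label. Empty groups are omitted with
    a warning. Returns a long table with a ``group`` column.
    """
    by_id = {g.gene_id: g for g in genes}
    frames = []
    for label in pd.unique(grouping.dropna()):
        members = [by_id[g] for g in grouping.index[grouping == label] if g in by_id]
        if not members:
            warnings.warn(f"group {label!r} has no genes; omitted")
            continue
        prof = metagene_profile(site_methylation, members, flank, bins_per_segment)
        prof["group"] = label
        frames.append(prof)
    if not frames:
        raise ValidationError("no non-empty groups")
    return pd.concat(frames, ignore_index=True)


def boxplot_stats(values: np.ndarray) -> dict[str, float]:
    """Quartiles (linear interpolation) and 1.5-IQR whiskers.

    The whisker is the most extreme data point within 1.5 interquartile
    ranges of the nearer quartile.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return {k: float("nan") for k in ("q1", "median", "q3", "whisker_lo", "whisker_hi")}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_lo": float(in_lo.min()),
        "whisker_hi": float(in_hi.max()),
    }


def expression_by_methylation_group(
    expression: pd.DataFrame,
    region_ml: pd.DataFrame,
    fpkm_column: str = "fpkm_control",
    log_offset: float = 0.01,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Expression distributions of genes grouped by region methylation.

    Genes whose region has no covered cytosines are excluded (their count is
    the returned tally). The remainder splits into ``unmethylated`` (region
    not called methylated) plus five quintiles of the region's count-pooled
    ML among methylated genes. Expression is summarised on
    log10(FPKM + ``log_offset``).

    Returns ``(summary, assignment, n_excluded)``.
    """
    merged = region_ml.merge(expression, on="gene_id", how="inner")
    excluded = merged["n_sites"] == 0
    n_excluded = int(excluded.sum())
    work = merged[~excluded].set_index("gene_id")
    groups = quintile_partition(
        work["ml"], special_mask=~work["methylated"], special_label="unmethylated"
    )
    logfpkm = np.log10(work[fpkm_column] + log_offset)
    rows = []
    for label in ["unmethylated", *QUINTILE_LABELS]:
        sel = logfpkm[groups == label]
        if len(sel) == 0:
            continue
        stats_ = boxplot_stats(sel.to_numpy())
        rows.append({"group": label, "n": len(sel), **stats_})
    return pd.DataFrame(rows), groups, n_excluded


def te_length_quintiles(
    tes: list[TEAnnotation],
    site_methylation: pd.DataFrame,
    min_class_size: int = 5,
) -> pd.DataFrame:
    """Count-pooled ML per TE class, per TE-length quintile, per context.

    Classes with fewer than ``min_class_size`` members are skipped with a
    warning. Quintile 1 holds the shortest TEs, quintile 5 the longest.
    """
    sm = site_methylation[site_methylation["covered"]]
    by_chrom = {
        chrom: grp.sort_values("pos").reset_index(drop=True)
        for chrom, grp in sm.groupby("chrom")
    }
    rows = []
    classes = sorted({te.te_class for te in tes})
    for te_class in classes:
        members = [te for te in tes if te.te_class == te_class]
        if len(members) < min_class_size:
            warnings.warn(f"TE class {te_class!r} has {len(members)} members; skipped")
            continue
        lengths = pd.Series(
            [te.length for te in members], index=[te.te_id for te in members], dtype=float
        )
        groups = quintile_partition(lengths)
        by_id = {te.te_id: te for te in members}
        for label in QUINTILE_LABELS:
            sums = {ctx: [0, 0, 0] for ctx in CONTEXTS}
            for te_id in groups.index[groups == label]:
                te = by_id[te_id]
                grp = by_chrom.get(te.chrom)
                if grp is None:
                    continue
                pos = grp["pos"].to_numpy()
                lo = np.searchsorted(pos, te.start, side="left")
                hi = np.searchsorted(pos, te.end, side="right")
                sub = grp.iloc[lo:hi]
                for ctx in CONTEXTS:
                    m = sub[sub["context"] == ctx]
                    sums[ctx][0] += int(m["count_meth"].sum())
                    sums[ctx][1] += int(m["count_unmeth"].sum())
                    sums[ctx][2] += len(m)
            for ctx in CONTEXTS:
                total = sums[ctx][0] + sums[ctx][1]
                rows.append(
                    {
                        "te_class": te_class,
                        "quintile": label,
                        "context": ctx,
                        "n_tes": int((groups == label).sum()),
                        "n_sites": sums[ctx][2],
                        "ml": sums[ctx][0] / total if total else np.nan,
                    }
                )
    return pd.DataFrame(rows)
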