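"""Genomic compartments and gene-region arithmetic shared by the simulator,
the profile module and DMR-to-feature assignment.

Compartment precedence for overlapping bases: TE > gene subfeature
(5'UTR/exon/intron/3'UTR) > promoter/downstream flank > intergenic; the
spike-in chromosome is its own compartment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import GeneModel, GenomeSequence, TEAnnotation

COMPARTMENTS = (
    "intergenic",
    "downstream",
    "promoter",
    "intron",
    "exon",
    "utr5",
    "utr3",
    "te",
    "spike_in",
)
_CODE = {name: i for i, name in enumerate(COMPARTMENTS)}

PROMOTER_SPAN = 2000
DOWNSTREAM_SPAN = 2000


def promoter_interval(gene: GeneModel, span: int = PROMOTER_SPAN) -> tuple[int, int]:
    """Strand-aware promoter: ``span`` bp upstream of the transcript start."""
    if gene.strand == "+":
        return max(1, gene.transcript_start - span), gene.transcript_start - 1
    return gene.transcript_end + 1, gene.transcript_end + span


def downstream_interval(gene: GeneModel, span: int = DOWNSTREAM_SPAN) -> tuple[int, int]:
    """Strand-aware downstream flank (also used as the TTR region)."""
    if gene.strand == "+":
        return gene.transcript_end + 1, gene.transcript_end + span
    return max(1, gene.transcript_start - span), gene.transcript_start - 1


def gene_region_interval(gene: GeneModel, region: str, span: int = 2000) -> tuple[int, int]:
    """Genomic interval of a named gene region: promoter, body or TTR."""
    if region == "promoter":
        return promoter_interval(gene, span)
    if region == "body":
        return gene.transcript_start, gene.transcript_end
    if region in ("ttr", "TTR", "downstream"):
        return downstream_interval(gene, span)
    raise ValueError(f"unknown region {region!r}")


def _paint(arr: np.ndarray, start: int, end: int, code: int) -> None:
    lo = max(start - 1, 0)
    hi = min(end, len(arr))
    if hi > lo:
        arr[lo:hi] = code


def paint_compartments(
    genome: GenomeSequence,
    genes: list[GeneModel],
    tes: list[TEAnnotation],
    promoter_span: int = PROMOTER_SPAN,
    downstream_span: int = DOWNSTREAM_SPAN,
) -> dict[str, np.ndarray]:
    """Per-chromosome arrays of compartment codes (index 0 = base 1).

    Painted in ascending precedence so higher-precedence compartments
    overwrite lower ones.
    """
    arrays = {
        name: np.zeros(length, dtype=np.uint8)
        for name, length in genome.lengths.items()
    }
    for gene in genes:
        arr = arrays[gene.chrom]
        _paint(arr, *downstream_interval(gene, downstream_span), _CODE["downstream"])
        _paint(arr, *promoter_interval(gene, promoter_span), _CODE["promoter"])
        _paint(arr, gene.transcript_start, gene.transcript_end, _CODE["intron"])
        for start, end in gene.exons:
            _paint(arr, start, end, _CODE["exon"])
        for start, end in gene.utr5:
            _paint(arr, start, end, _CODE["utr5"])
        for start, end in gene.utr3:
            _paint(arr, start, end, _CODE["utr3"])
    for te in tes:
        _paint(arrays[te.chrom], te.start, te.end, _CODE["te"])
    if genome.spike_in_chrom is not None:
        arrays[genome.spike_in_chrom][:] = _CODE["spike_in"]
    return arrays


def site_compartments(
    sites: pd.DataFrame, compartment_arrays: dict[str, np.ndarray]
) -> pd.Series:
    """Compartment name of every site (by its 1-based position)."""
    names = np.array(COMPARTMENTS)
    out = np.empty(len(sites), dtype=object)
    for chrom, arr in compartment_arrays.items():
        mask = (sites["chrom"] == chrom).to_numpy()
        if mask.any():
            out[mask] = names[arr[sites.loc[mask, "pos"].to_numpy() - 1]]
    return pd.Series(out, index=sites.index, name="compartment")


def region_methylation(
    site_methylation: pd.DataFrame,
    genes: list[GeneModel],
    region: str,
    span: int = 2000,
    context: str | None = None,
    min_sites: int = 5,
    mc_calls: pd.Series | None = None,
) -> pd.DataFrame:
    """Count-pooled methylation level of a gene region for every gene.

    Returns one row per gene: gene_id, n_sites (covered cytosines in the
    region), sum_meth, sum_unmeth, ml, n_mc (methylated-site calls within the
    region when ``mc_calls`` is given; else NaN), and ``methylated`` — True
    when the region has >= ``min_sites`` covered cytosines and at least one
    called methylated site (always False without calls).
    """
    sm = site_methylation[site_methylation["covered"]]
    if context is not None:
        sm = sm[sm["context"] == context]
    calls = mc_calls.loc[sm.index] if mc_calls is not None else None
    rows = []
    by_chrom = {chrom: grp.sort_values("pos") for chrom, grp in sm.groupby("chrom")}
    for gene in genes:
        grp = by_chrom.get(gene.chrom)
        n_sites = sum_m = sum_u = 0
        n_mc: float = np.nan
        if grp is not None:
            start, end = gene_region_interval(gene, region, span)
            pos = grp["pos"].to_numpy()
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n_sites = hi - lo
            sum_m = int(grp["count_meth"].to_numpy()[lo:hi].sum())
            sum_u = int(grp["count_unmeth"].to_numpy()[lo:hi].sum())
            if calls is not None:
                n_mc = int(calls.to_numpy()[lo:hi].sum())
        total = sum_m + sum_u
        ml = sum_m / total if total else np.nan
        methylated = bool(n_sites >= min_sites and not np.isnan(n_mc) and n_mc >= 1)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "n_sites": n_sites,
                "sum_meth": sum_m,
                "sum_unmeth": sum_u,
                "ml": ml,
                "n_mc": n_mc,
                "methylated": methylated,
            }
        )
    return pd.DataFrame(rows)


def overlaps(start1: int, end1: int, start2: int, end2: int) -> bool:
    """1 bp or more of overlap between two 1-based inclusive intervals."""
    return start1 <= end2 and start2 <= end1
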