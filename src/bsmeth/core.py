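"""Context classification, methylation levels, nonconversion correction,
sliding-window summaries and global methylome summaries.

The per-site methylation level is ML = m / (m + u) where m and u are
methylated and unmethylated read counts. Because a fraction r of
unmethylated cytosines escapes bisulfite conversion and falsely reads as
methylated, the corrected level is ML_corr = (ML - r) / (1 - r), clamped to
[0, 1]; r is estimated from an unmethylated spike-in (lambda) genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CONTEXTS, GenomeSequence, ValidationError

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")
_COMP = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCAN"):
    _COMP[x] = y


def _tri_strings(codes: np.ndarray) -> np.ndarray:
    """Rows of 3 uint8 base codes -> array of 3-mer strings."""
    if len(codes) == 0:
        return np.array([], dtype=object)
    return codes.astype(np.uint8).view("S3")[:, 0].astype("U3")


def _context_codes(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Context from the two downstream bases; -1 = excluded (N present)."""
    h1 = (b1 == _A) | (b1 == _C) | (b1 == _T)
    h2 = (b2 == _A) | (b2 == _C) | (b2 == _T)
    out = np.full(b1.shape, -1, dtype=np.int8)
    valid = (b1 != _N) & (b2 != _N)
    out[valid & (b1 == _G)] = 0  # CG
    out[valid & h1 & (b2 == _G)] = 1  # CHG
    out[valid & h1 & h2] = 2  # CHH
    return out


def classify_contexts(genome: GenomeSequence) -> pd.DataFrame:
    """Enumerate every cytosine site on both strands with its context.

    A site is a C on the + strand or a G on the - strand (a C when the -
    strand is read 5'->3'). The context is determined by the two bases
    immediately downstream on the site's own strand; sites whose downstream
    bases fall off the chromosome or contain N are excluded. The
    trinucleotide is reported 5'->3' on the site's strand.

    Returns a table with columns chrom, pos (1-based), strand, context,
    trinucleotide, sorted by (chromosome order, pos, strand).
    """
    frames = []
    ctx_names = np.array(CONTEXTS)
    for name in genome.names:
        arr = np.frombuffer(genome.chroms[name].encode("ascii"), dtype=np.uint8)
        n = len(arr)
        # + strand: C at i (0-based), downstream at i+1, i+2
        idx = np.nonzero(arr == _C)[0]
        idx = idx[idx <= n - 3]
        if len(idx):
            ctx = _context_codes(arr[idx + 1], arr[idx + 2])
            keep = ctx >= 0
            idx, ctx = idx[keep], ctx[keep]
            tri = _tri_strings(np.column_stack([arr[idx], arr[idx + 1], arr[idx + 2]]))
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "pos": idx + 1,
                        "strand": "+",
                        "context": ctx_names[ctx],
                        "trinucleotide": tri,
                    }
                )
            )
        # - strand: G at i, downstream (on -) at i-1, i-2, complemented
        idx = np.nonzero(arr == _G)[0]
        idx = idx[idx >= 2]
        if len(idx):
            b1 = _COMP[arr[idx - 1]]
            b2 = _COMP[arr[idx - 2]]
            ctx = _context_codes(b1, b2)
            keep = ctx >= 0
            idx, ctx = idx[keep], ctx[keep]
            tri = _tri_strings(np.column_stack([_COMP[arr[idx]], b1[keep], b2[keep]]))
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "pos": idx + 1,
                        "strand": "-",
                        "context": ctx_names[ctx],
                        "trinucleotide": tri,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "trinucleotide"]
        )
    out = pd.concat(frames, ignore_index=True)
    order = {name: i for i, name in enumerate(genome.names)}
    out["_o"] = out["chrom"].map(order)
    out = out.sort_values(["_o", "pos", "strand"], kind="stable").drop(columns="_o")
    return out.reset_index(drop=True)


def estimate_nonconversion(
    records: pd.DataFrame, spike_in_chrom: str, min_reads: int = 10_000
) -> tuple[float, float]:
    """Estimate the bisulfite nonconversion rate r from spike-in records.

    r is the pooled fraction of reads reporting methylation over the
    unmethylated spike-in chromosome; the conversion rate is 1 - r.

    Returns ``(r, conversion_rate)``.
    """
    spike = records[records["chrom"] == spike_in_chrom]
    total = int(spike["count_meth"].sum() + spike["count_unmeth"].sum())
    if total < min_reads:
        raise ValidationError(
            f"spike-in chromosome {spike_in_chrom!r} has only {total} pooled reads "
            f"(< {min_reads}); pass an explicit nonconversion rate instead"
        )
    r = float(spike["count_meth"].sum()) / total
    return r, 1.0 - r


def correct_ml(ml_raw: np.ndarray | float, r: float) -> np.ndarray | float:
    """Nonconversion correction (ML - r) / (1 - r), clamped to [0, 1]."""
    return np.clip((np.asarray(ml_raw, dtype=float) - r) / (1.0 - r), 0.0, 1.0)


def compute_site_methylation(
    records: pd.DataFrame, r: float = 0.0, min_coverage: int = 4
) -> pd.DataFrame:
    """Add raw and corrected methylation levels and a coverage flag.

    ``covered`` marks sites with at least ``min_coverage`` reads; downstream
    summaries use covered sites only.
    """
    if not 0.0 <= r < 1.0:
        raise ValidationError(f"nonconversion rate r must be in [0, 1), got {r}")
    sm = records.copy()
    cov = (sm["count_meth"] + sm["count_unmeth"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ml = np.where(cov > 0, sm["count_meth"].to_numpy() / np.where(cov > 0, cov, 1), np.nan)
    sm["ml_raw"] = ml
    sm["ml_corrected"] = np.where(np.isnan(ml), np.nan, correct_ml(np.nan_to_num(ml), r))
    sm["covered"] = cov >= min_coverage
    return sm


def call_methylated_sites(
    site_methylation: pd.DataFrame, r: float, fdr_alpha: float = 0.05
) -> pd.Series:
    """Per-site binary methylation call (Lister-style binomial test).

    Each covered site's methylated count is tested one-sided against the
    nonconversion error rate r; Benjamini-Hochberg FDR is applied across all
    covered sites and a site is called methylated iff q < ``fdr_alpha``.
    Uncovered sites are False. Returns a boolean Series aligned to the input.
    """
    sm = site_methylation
    is_mc = pd.Series(False, index=sm.index, name="is_mc")
    cov_mask = sm["covered"].to_numpy()
    if not cov_mask.any():
        return is_mc
    k = sm.loc[cov_mask, "count_meth"].to_numpy()
    n = (sm.loc[cov_mask, "count_meth"] + sm.loc[cov_mask, "count_unmeth"]).to_numpy()
    if r == 0.0:
        p = np.where(k >= 1, 0.0, 1.0)
    else:
        p = stats.binom.sf(k - 1, n, r)
    q = benjamini_hochberg(p)
    is_mc.iloc[np.nonzero(cov_mask)[0]] = q < fdr_alpha
    return is_mc


def benjamini_hochberg(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clamped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def merge_symmetric_cpg(site_methylation: pd.DataFrame) -> pd.DataFrame:
    """Pool counts of symmetric CpG partners (+ at pos, - at pos+1).

    Input must contain CG-context sites only. Partners merge by count
    summation onto the + strand coordinate; unpaired sites pass through with
    ``paired`` False. Idempotent: merging an already merged table is a
    no-op. Levels (``ml_raw``) are recomputed from the pooled counts;
    corrected levels and the coverage flag must be recomputed afterwards
    with :func:`compute_site_methylation` since the pooled coverage changed.
    """
    sm = site_methylation
    if not (sm["context"] == "CG").all():
        raise ValidationError("merge_symmetric_cpg expects CG sites only")
    plus = sm[sm["strand"] == "+"].copy()
    minus = sm[sm["strand"] == "-"].copy()
    plus_keys = set(zip(plus["chrom"], plus["pos"]))
    minus_paired = np.array(
        [(c, p - 1) in plus_keys for c, p in zip(minus["chrom"], minus["pos"])],
        dtype=bool,
    )
    partner = minus[minus_paired].copy()
    partner["pos"] = partner["pos"] - 1
    partner_counts = partner.set_index(["chrom", "pos"])[["count_meth", "count_unmeth"]]
    plus_idx = pd.MultiIndex.from_arrays([plus["chrom"], plus["pos"]])
    add = partner_counts.reindex(plus_idx).fillna(0).astype(int)
    plus["count_meth"] = plus["count_meth"].to_numpy() + add["count_meth"].to_numpy()
    plus["count_unmeth"] = plus["count_unmeth"].to_numpy() + add["count_unmeth"].to_numpy()
    newly_paired = plus_idx.isin(partner_counts.index)
    if "paired" in plus.columns:  # keep flags from an earlier merge (idempotence)
        plus["paired"] = plus["paired"].to_numpy() | newly_paired
    else:
        plus["paired"] = newly_paired
    lone_minus = minus[~minus_paired].copy()
    lone_minus["paired"] = False
    out = pd.concat([plus, lone_minus], ignore_index=True)
    out = out.drop(columns=[c for c in ("ml_corrected", "covered") if c in out.columns])
    cov = (out["count_meth"] + out["count_unmeth"]).to_numpy(dtype=float)
    if "ml_raw" in out.columns:
        with np.errstate(invalid="ignore"):
            out["ml_raw"] = np.where(cov > 0, out["count_meth"] / np.where(cov > 0, cov, 1), np.nan)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sliding windows


def window_spans(
    chrom_length: int, window_size: int, step: int
) -> list[tuple[int, int]]:
    """1-based inclusive window spans: starts 1, 1+step, ...

    Terminal windows truncated by the chromosome end are kept only when at
    least half a window remains; shorter slivers are dropped.
    """
    spans = []
    start = 1
    while start <= chrom_length:
        end = start + window_size - 1
        if end > chrom_length:
            if chrom_length - start + 1 >= window_size / 2:
                spans.append((start, chrom_length))
            break
        spans.append((start, end))
        start += step
    return spans


def _window_sums(pos: np.ndarray, values: np.ndarray, spans: np.ndarray) -> np.ndarray:
    """Sum ``values`` of sites at sorted positions ``pos`` over each span."""
    csum = np.concatenate([[0], np.cumsum(values)])
    lo = np.searchsorted(pos, spans[:, 0], side="left")
    hi = np.searchsorted(pos, spans[:, 1], side="right")
    return csum[hi] - csum[lo]


def window_summarize(
    site_methylation: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_size: int = 3000,
    step: int = 600,
    r: float = 0.0,
    correct: bool = True,
) -> pd.DataFrame:
    """Pool read counts of covered sites in sliding windows, per context.

    The window methylation level is the count-pooled (weighted) level
    sum(m) / sum(m + u) over covered sites in the window — never the mean of
    per-site levels. Windows with no covered reads of a context are flagged
    undefined (ml = NaN). With ``correct`` the pooled level is
    nonconversion-corrected with ``r``.
    """
    rows = []
    sm = site_methylation[site_methylation["covered"]]
    for chrom, length in chrom_lengths.items():
        spans = window_spans(length, window_size, step)
        if not spans:
            continue
        spans_arr = np.array(spans)
        chrom_sites = sm[sm["chrom"] == chrom]
        for context in CONTEXTS:
            sites = chrom_sites[chrom_sites["context"] == context]
            pos = sites["pos"].to_numpy()
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            meth = sites["count_meth"].to_numpy()[order]
            unmeth = sites["count_unmeth"].to_numpy()[order]
            sum_m = _window_sums(pos, meth, spans_arr)
            sum_u = _window_sums(pos, unmeth, spans_arr)
            n_sites = _window_sums(pos, np.ones_like(pos), spans_arr)
            total = sum_m + sum_u
            with np.errstate(invalid="ignore", divide="ignore"):
                ml = np.where(total > 0, sum_m / np.where(total > 0, total, 1), np.nan)
            if correct:
                ml = np.where(np.isnan(ml), np.nan, correct_ml(np.nan_to_num(ml), r))
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": spans_arr[:, 0],
                        "end": spans_arr[:, 1],
                        "context": context,
                        "sum_meth": sum_m,
                        "sum_unmeth": sum_u,
                        "n_sites": n_sites,
                        "ml": ml,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "context", "sum_meth", "sum_unmeth", "n_sites", "ml"]
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Global summary


@dataclass
class GlobalSummary:
    """Genome-wide methylome summary.

    ``pct_methylation``: percentage of covered C sites called methylated,
    per context (the "percentage of methylation levels" summary).
    ``relative_mc_proportion``: share of each context among all methylated
    sites (sums to 100%). ``density``: per-chromosome binned counts of
    methylated sites (bedGraph-like table).
    """

    pct_methylation: dict[str, float]
    relative_mc_proportion: dict[str, float]
    density: pd.DataFrame
    n_covered: dict[str, int]
    n_mc: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "context": list(CONTEXTS),
                "n_covered": [self.n_covered[c] for c in CONTEXTS],
                "n_mc": [self.n_mc[c] for c in CONTEXTS],
                "pct_methylation": [self.pct_methylation[c] for c in CONTEXTS],
                "relative_mc_proportion": [self.relative_mc_proportion[c] for c in CONTEXTS],
            }
        )


def global_summary(
    site_methylation: pd.DataFrame,
    mc_calls: pd.Series,
    chrom_lengths: dict[str, int],
    bin_size: int = 10_000,
) -> GlobalSummary:
    """Compute genome-wide percentages, relative proportions and density tracks."""
    sm = site_methylation
    covered = sm["covered"]
    if not covered.any():
        raise ValidationError("no covered sites")
    n_covered, n_mc, pct = {}, {}, {}
    for context in CONTEXTS:
        mask = covered & (sm["context"] == context)
        n_covered[context] = int(mask.sum())
        n_mc[context] = int((mask & mc_calls).sum())
        pct[context] = (
            100.0 * n_mc[context] / n_covered[context] if n_covered[context] else float("nan")
        )
    total_mc = sum(n_mc.values())
    rel = {
        c: (100.0 * n_mc[c] / total_mc if total_mc else float("nan")) for c in CONTEXTS
    }
    if total_mc == 0:
        warnings.warn("no methylated sites called; relative proportions undefined")
    rows = []
    mc_sites = sm[mc_calls & covered]
    for chrom, length in chrom_lengths.items():
        n_bins = int(np.ceil(length / bin_size))
        edges = np.arange(n_bins + 1) * bin_size
        chrom_mc = mc_sites[mc_sites["chrom"] == chrom]
        for context in CONTEXTS:
            pos = chrom_mc.loc[chrom_mc["context"] == context, "pos"].to_numpy()
            counts, _ = np.histogram(pos - 1, bins=edges)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": edges[:-1] + 1,
                        "end": np.minimum(edges[1:], length),
                        "context": context,
                        "n_mc": counts,
                    }
                )
            )
    density = pd.concat(rows, ignore_index=True)
    return GlobalSummary(
        pct_methylation=pct,
        relative_mc_proportion=rel,
        density=density,
        n_covered=n_covered,
        n_mc=n_mc,
    )


def pool_replicates(record_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum read counts of biological replicates site by site.

    All replicates must enumerate the same sites (the usual cytosine-report
    layout); counts are added, site annotation is taken from the first table.
    """
    if not record_tables:
        raise ValidationError("no replicates to pool")
    base = record_tables[0].copy()
    key = ["chrom", "pos", "strand"]
    for other in record_tables[1:]:
        if len(other) != len(base) or not (
            other[key].reset_index(drop=True) == base[key].reset_index(drop=True)
        ).all().all():
            other = other.set_index(key).reindex(
                pd.MultiIndex.from_frame(base[key])
            ).reset_index()
        base["count_meth"] = base["count_meth"].to_numpy() + other["count_meth"].fillna(0).to_numpy(dtype=int)
        base["count_unmeth"] = base["count_unmeth"].to_numpy() + other["count_unmeth"].fillna(0).to_numpy(dtype=int)
    return base
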