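"""Synthetic two-condition bisulfite methylome generator with ground truth.

The generator emulates the study design of a plant WGBS experiment: an
annotated genome (genes with exon/intron/UTR structure plus transposable
elements), a compartment-structured methylome in CG/CHG/CHH contexts, an
unmethylated lambda spike-in chromosome, Poisson read coverage around 10x,
a small bisulfite nonconversion rate (default 0.0012, i.e. 99.88%
conversion), two biological replicates per condition, planted differentially
methylated regions of configurable effect size, and an expression table with
optional coupling between promoter hypermethylation and down-regulation.

The truth model is the standard bimodal methylome mixture: each cytosine is
methylated with a compartment- and context-specific probability (the
"context level": the fraction of methylated sites, ~54%/38%/8.5% genome-wide
for CG/CHG/CHH in apple-like defaults); methylated sites draw their true
methylation level from a Beta distribution, unmethylated sites have level 0.
Observed methylated read counts are Binomial(coverage, ML + (1-ML)*r), the
exact noise model that the nonconversion correction (ML-r)/(1-r) inverts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import classify_contexts
from .features import COMPARTMENTS, paint_compartments, site_compartments, promoter_interval
from .types import (
    CapacityError,
    GeneModel,
    GenomeSequence,
    TEAnnotation,
    ValidationError,
)

#: Beta(a, b) of the true ML of *methylated* sites, per context.
DEFAULT_ML_BETA = {"CG": (8.0, 2.0), "CHG": (5.0, 3.0), "CHH": (2.5, 4.5)}

#: probability that a site is methylated, per compartment and context
#: (apple-like: TEs hypermethylated, 5'UTR dip, CHH highest in promoters).
DEFAULT_CONTEXT_LEVELS = {
    "te": {"CG": 0.92, "CHG": 0.85, "CHH": 0.25},
    "promoter": {"CG": 0.55, "CHG": 0.42, "CHH": 0.13},
    "utr5": {"CG": 0.12, "CHG": 0.08, "CHH": 0.03},
    "exon": {"CG": 0.40, "CHG": 0.15, "CHH": 0.04},
    "intron": {"CG": 0.48, "CHG": 0.28, "CHH": 0.06},
    "utr3": {"CG": 0.30, "CHG": 0.14, "CHH": 0.05},
    "downstream": {"CG": 0.50, "CHG": 0.35, "CHH": 0.08},
    "intergenic": {"CG": 0.50, "CHG": 0.38, "CHH": 0.08},
    "spike_in": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
}

DEFAULT_TE_CLASS_MIX = {
    "LTR_Gypsy": 4.0,
    "LTR_Copia": 2.0,
    "hAT_Tag1": 1.0,
    "hAT_Tip100": 1.0,
    "other": 2.0,
}

CONDITIONS = ("control", "case")


@dataclass
class ExpressionModel:
    """Baseline FPKM distribution and differential-expression structure."""

    log_mean: float = 1.0  # natural-log scale of expressed-gene FPKM
    log_sigma: float = 1.2
    nonexpressed_fraction: float = 0.15  # genes forced below FPKM 0.1
    de_fraction: float = 0.10
    de_fold_range: tuple[float, float] = (2.0, 6.0)
    couple_promoter_hyper: bool = False  # promoter-hyper genes biased to "down"
    coupling_prob: float = 0.7


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: list[int] = field(default_factory=lambda: [300_000, 300_000])
    gene_count: int = 120
    mean_exons: float = 4.0
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (80, 300)
    utr5_length_range: tuple[int, int] = (60, 150)
    utr3_length_range: tuple[int, int] = (80, 200)
    te_fraction: float = 0.30
    te_class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TE_CLASS_MIX)
    )
    te_length_log_mean: float = math.log(1500.0)
    te_length_log_sigma: float = 0.6
    te_length_range: tuple[int, int] = (200, 8000)
    gc_content: float = 0.38
    min_gap: int = 100
    context_levels: dict = field(
        default_factory=lambda: {
            comp: {ctx: dict(p=p, a=DEFAULT_ML_BETA[ctx][0], b=DEFAULT_ML_BETA[ctx][1])
                   for ctx, p in ctxs.items()}
            for comp, ctxs in DEFAULT_CONTEXT_LEVELS.items()
        }
    )
    te_chh_length_slope: float = 0.0  # >0: CHH level declines with TE length
    coverage_mean: float = 10.0
    nonconversion_rate: float = 0.0012
    overconversion_rate: float = 0.0
    spike_in_length: int = 48_502  # lambda phage genome size
    n_dmrs: int = 20
    dmr_length_range: tuple[int, int] = (1000, 2000)
    dmr_effect: float = 0.4
    dmr_context: str = "CG"
    dmr_margin: int = 2000  # bp kept clear between planted intervals
    replicates_per_condition: int = 2
    expression: ExpressionModel = field(default_factory=ExpressionModel)

    def __post_init__(self) -> None:
        for prob in (
            self.te_fraction,
            self.nonconversion_rate,
            self.overconversion_rate,
            self.expression.nonexpressed_fraction if isinstance(self.expression, ExpressionModel) else 0,
        ):
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(f"probability {prob} outside [0, 1]")
        if isinstance(self.expression, dict):
            self.expression = ExpressionModel(**self.expression)
        for comp, ctxs in self.context_levels.items():
            for ctx, level in ctxs.items():
                if not 0.0 <= level.get("p", 0.0) <= 1.0:
                    raise ValidationError(f"context level p outside [0,1] for {comp}/{ctx}")
                if "fixed" not in level and (
                    level.get("a", 1.0) <= 0 or level.get("b", 1.0) <= 0
                ):
                    raise ValidationError(f"nonpositive Beta parameters for {comp}/{ctx}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        for key in ("chrom_lengths",):
            if key in raw:
                raw[key] = list(raw[key])
        for key in (
            "exon_length_range", "intron_length_range", "utr5_length_range",
            "utr3_length_range", "te_length_range", "dmr_length_range",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "expression" in raw and isinstance(raw["expression"], dict):
            expr = dict(raw["expression"])
            if "de_fold_range" in expr:
                expr["de_fold_range"] = tuple(expr["de_fold_range"])
            raw["expression"] = ExpressionModel(**expr)
        # partial context_levels overrides merge into the defaults
        if "context_levels" in raw:
            base = cls().context_levels
            for comp, ctxs in raw["context_levels"].items():
                for ctx, level in ctxs.items():
                    base.setdefault(comp, {})[ctx] = dict(level)
            raw["context_levels"] = base
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Simulator ground truth for one two-condition study.

    ``sites`` carries per-cytosine true methylation levels for both
    conditions plus the compartment assignment; ``planted_dmrs`` the planted
    differential intervals; ``r_true`` the simulated nonconversion rate.
    """

    sites: pd.DataFrame
    chrom_lengths: dict[str, int]
    spike_in_chrom: str | None
    r_true: float
    seed: int
    planted_dmrs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "context", "direction", "effect", "n_sites"]
        )
    )
    true_de: pd.DataFrame | None = None

    def truth_json(self) -> dict:
        out = {
            "r_true": self.r_true,
            "seed": self.seed,
            "spike_in_chrom": self.spike_in_chrom,
            "planted_dmrs": self.planted_dmrs.to_dict(orient="records"),
        }
        if self.true_de is not None:
            out["true_de"] = dict(
                zip(self.true_de["gene_id"], self.true_de["de_label"])
            )
        return out


# ---------------------------------------------------------------------------
# Genome simulation


def _allocate(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``total`` items by weights."""
    shares = total * weights / weights.sum()
    base = np.floor(shares).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(shares - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _sample_gene_structure(rng: np.random.Generator, cfg: SimulationConfig) -> dict:
    n_exons = 1 + int(rng.poisson(max(cfg.mean_exons - 1.0, 0.0)))
    exon_lens = rng.integers(
        cfg.exon_length_range[0], cfg.exon_length_range[1] + 1, size=n_exons
    )
    utr5 = int(rng.integers(cfg.utr5_length_range[0], cfg.utr5_length_range[1] + 1))
    utr3 = int(rng.integers(cfg.utr3_length_range[0], cfg.utr3_length_range[1] + 1))
    exon_lens = exon_lens.astype(int)
    # UTRs live in the terminal exons; widen those exons so CDS remains
    exon_lens[0] += utr5
    exon_lens[-1] += utr3
    intron_lens = (
        rng.integers(
            cfg.intron_length_range[0], cfg.intron_length_range[1] + 1,
            size=n_exons - 1,
        ).astype(int)
        if n_exons > 1
        else np.array([], dtype=int)
    )
    length = int(exon_lens.sum() + intron_lens.sum())
    strand = "+" if rng.random() < 0.5 else "-"
    return {
        "kind": "gene",
        "length": length,
        "exon_lens": exon_lens,
        "intron_lens": intron_lens,
        "utr5": utr5,
        "utr3": utr3,
        "strand": strand,
    }


def _build_gene(struct: dict, gene_id: str, chrom: str, start: int) -> GeneModel:
    exons = []
    cursor = start
    for i, elen in enumerate(struct["exon_lens"]):
        exons.append((cursor, cursor + int(elen) - 1))
        cursor += int(elen)
        if i < len(struct["intron_lens"]):
            cursor += int(struct["intron_lens"][i])
    tstart, tend = exons[0][0], exons[-1][1]
    utr5_len, utr3_len = struct["utr5"], struct["utr3"]
    if struct["strand"] == "+":
        utr5_iv = [(exons[0][0], exons[0][0] + utr5_len - 1)]
        utr3_iv = [(exons[-1][1] - utr3_len + 1, exons[-1][1])]
    else:
        # transcript runs right to left: 5'UTR at the high-coordinate end
        utr5_iv = [(exons[-1][1] - utr5_len + 1, exons[-1][1])]
        utr3_iv = [(exons[0][0], exons[0][0] + utr3_len - 1)]
    cds = []
    for start_, end_ in exons:
        lo, hi = start_, end_
        for ustart, uend in utr5_iv + utr3_iv:
            if ustart <= lo <= uend:
                lo = uend + 1
            if ustart <= hi <= uend:
                hi = ustart - 1
        if lo <= hi:
            cds.append((lo, hi))
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=struct["strand"],
        transcript_start=tstart,
        transcript_end=tend,
        exons=exons,
        cds=cds,
        utr5=utr5_iv,
        utr3=utr3_iv,
    )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs).tobytes().decode()


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel], list[TEAnnotation]]:
    """Build a random annotated genome plus a lambda spike-in chromosome.

    Genes and TEs are placed without overlap; raises
    :class:`~bsmeth.types.CapacityError` when the requested features do not
    fit. With a fixed seed the output is byte-identical across runs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lengths = np.asarray(config.chrom_lengths, dtype=float)
    genes_per_chrom = _allocate(config.gene_count, lengths)
    chroms: dict[str, str] = {}
    genes: list[GeneModel] = []
    tes: list[TEAnnotation] = []
    class_names = list(config.te_class_mix)
    class_probs = np.array([config.te_class_mix[c] for c in class_names], dtype=float)
    class_probs = class_probs / class_probs.sum()
    gene_counter = te_counter = 0
    for ci, chrom_len in enumerate(config.chrom_lengths):
        chrom = f"chr{ci + 1}"
        feats: list[dict] = []
        for _ in range(int(genes_per_chrom[ci])):
            feats.append(_sample_gene_structure(rng, config))
        te_quota = int(round(config.te_fraction * chrom_len))
        te_bp = 0
        while te_bp < te_quota:
            length = int(
                np.clip(
                    rng.lognormal(config.te_length_log_mean, config.te_length_log_sigma),
                    *config.te_length_range,
                )
            )
            if te_bp + length > te_quota:
                length = te_quota - te_bp
                if length < config.te_length_range[0]:
                    break
            te_class = class_names[int(rng.choice(len(class_names), p=class_probs))]
            strand = "+" if rng.random() < 0.5 else "-"
            feats.append(
                {"kind": "te", "length": length, "te_class": te_class, "strand": strand}
            )
            te_bp += length
        order = rng.permutation(len(feats))
        feats = [feats[i] for i in order]
        total_feat = sum(f["length"] for f in feats)
        n_gaps = len(feats) + 1
        free = chrom_len - total_feat
        if free < n_gaps * config.min_gap:
            raise CapacityError(
                f"{chrom}: features need {total_feat} bp plus {n_gaps * config.min_gap} bp "
                f"of gaps but the chromosome has only {chrom_len} bp"
            )
        extra = free - n_gaps * config.min_gap
        gaps = rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps)) + config.min_gap
        cursor = 1 + int(gaps[0])
        for gi, feat in enumerate(feats):
            if feat["kind"] == "gene":
                gene_counter += 1
                genes.append(_build_gene(feat, f"g{gene_counter:04d}", chrom, cursor))
            else:
                te_counter += 1
                tes.append(
                    TEAnnotation(
                        te_id=f"te{te_counter:05d}",
                        chrom=chrom,
                        strand=feat["strand"],
                        start=cursor,
                        end=cursor + feat["length"] - 1,
                        te_class=feat["te_class"],
                    )
                )
            cursor += feat["length"] + int(gaps[gi + 1])
        chroms[chrom] = _random_sequence(rng, chrom_len, config.gc_content)
    spike = None
    if config.spike_in_length > 0:
        spike = "lambda"
        chroms[spike] = _random_sequence(rng, config.spike_in_length, 0.50)
    genome = GenomeSequence(chroms=chroms, spike_in_chrom=spike)
    return genome, genes, tes


# ---------------------------------------------------------------------------
# Truth methylome


def _draw_levels(
    rng: np.random.Generator, n: int, level: dict
) -> np.ndarray:
    """True MLs for n sites of one compartment/context cell."""
    p = float(level.get("p", 0.0))
    meth = rng.random(n) < p
    ml = np.zeros(n)
    if meth.any():
        if "fixed" in level:
            ml[meth] = float(level["fixed"])
        else:
            ml[meth] = rng.beta(float(level["a"]), float(level["b"]), size=int(meth.sum()))
    return ml


def assign_true_methylation(
    genome: GenomeSequence,
    genes: list[GeneModel],
    tes: list[TEAnnotation],
    config: SimulationConfig,
) -> TruthSet:
    """Draw the condition-1 (control) truth methylome, compartment-aware.

    Every cytosine belongs to exactly one compartment (TE > gene subfeature
    > promoter/downstream > intergenic; the spike-in chromosome is all
    ``spike_in`` and always unmethylated).
    """
    sites = classify_contexts(genome)
    arrays = paint_compartments(genome, genes, tes)
    sites = sites.assign(compartment=site_compartments(sites, arrays))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    true_ml = np.zeros(len(sites))
    comp_values = sites["compartment"].to_numpy()
    ctx_values = sites["context"].to_numpy()
    te_q = None
    if config.te_chh_length_slope != 0.0 and tes:
        te_lengths = np.array([te.length for te in tes], dtype=float)
        ranks = pd.Series(te_lengths).rank(method="average").to_numpy()
        quantiles = (ranks - 1) / max(len(tes) - 1, 1)
        qarr = {
            name: np.full(length, np.nan, dtype=np.float32)
            for name, length in genome.lengths.items()
        }
        for te, q in zip(tes, quantiles):
            qarr[te.chrom][te.start - 1 : te.end] = q
        te_q = np.full(len(sites), np.nan, dtype=np.float32)
        for chrom, arr in qarr.items():
            mask = (sites["chrom"] == chrom).to_numpy()
            if mask.any():
                te_q[mask] = arr[sites.loc[mask, "pos"].to_numpy() - 1]
    for comp in COMPARTMENTS:
        ctx_levels = config.context_levels.get(comp, config.context_levels["intergenic"])
        for ctx in ("CG", "CHG", "CHH"):
            mask = (comp_values == comp) & (ctx_values == ctx)
            n = int(mask.sum())
            if n == 0:
                continue
            level = dict(ctx_levels[ctx])
            if (
                comp == "te"
                and ctx == "CHH"
                and config.te_chh_length_slope != 0.0
                and te_q is not None
            ):
                # per-site level probability declines with TE length quantile
                q = te_q[mask]
                p_eff = np.clip(
                    level.get("p", 0.0)
                    * (1.0 + config.te_chh_length_slope * (0.5 - np.nan_to_num(q, nan=0.5))),
                    0.0,
                    1.0,
                )
                meth = rng.random(n) < p_eff
                ml = np.zeros(n)
                if meth.any():
                    if "fixed" in level:
                        ml[meth] = float(level["fixed"])
                    else:
                        ml[meth] = rng.beta(level["a"], level["b"], size=int(meth.sum()))
                true_ml[mask] = ml
            else:
                true_ml[mask] = _draw_levels(rng, n, level)
    sites = sites.assign(true_ml_control=true_ml, true_ml_case=true_ml.copy())
    return TruthSet(
        sites=sites,
        chrom_lengths=genome.lengths,
        spike_in_chrom=genome.spike_in_chrom,
        r_true=config.nonconversion_rate,
        seed=config.seed,
    )


def plant_dmrs(truth: TruthSet, config: SimulationConfig) -> TruthSet:
    """Plant differential intervals into the case condition.

    Within each planted interval, true MLs of the chosen context shift by
    +/- ``dmr_effect`` (clamped to [0, 1]); the direction is chosen so the
    shift can actually move the pooled level (hyper where the local baseline
    is low, hypo where it is high). Outside planted intervals the case truth
    equals the control truth.
    """
    sites = truth.sites
    sites["true_ml_case"] = sites["true_ml_control"].to_numpy().copy()
    if config.n_dmrs == 0:
        truth.planted_dmrs = truth.planted_dmrs.iloc[0:0]
        return truth
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    eligible = {
        name: length
        for name, length in truth.chrom_lengths.items()
        if name != truth.spike_in_chrom
    }
    if not eligible:
        raise CapacityError("no non-spike-in chromosomes to plant DMRs in")
    chrom_names = list(eligible)
    chrom_weights = np.array([eligible[c] for c in chrom_names], dtype=float)
    chrom_weights /= chrom_weights.sum()
    planted: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    by_chrom_ctx = {
        c: grp
        for c, grp in sites[sites["context"] == config.dmr_context].groupby("chrom")
    }
    case = sites["true_ml_case"].to_numpy()
    for _ in range(config.n_dmrs):
        for _attempt in range(2000):
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_weights))]
            length = int(rng.integers(config.dmr_length_range[0], config.dmr_length_range[1] + 1))
            if eligible[chrom] <= length + 2:
                continue
            start = int(rng.integers(1, eligible[chrom] - length + 1))
            end = start + length - 1
            margin = config.dmr_margin
            if any(
                start - margin <= e and s <= end + margin for s, e in occupied[chrom]
            ):
                continue
            grp = by_chrom_ctx.get(chrom)
            if grp is None:
                continue
            in_iv = grp[(grp["pos"] >= start) & (grp["pos"] <= end)]
            if len(in_iv) < 5:
                continue
            baseline = float(sites.loc[in_iv.index, "true_ml_control"].mean())
            direction = "hyper" if baseline < 0.5 else "hypo"
            shift = config.dmr_effect if direction == "hyper" else -config.dmr_effect
            idx = sites.index.get_indexer(in_iv.index)
            case[idx] = np.clip(case[idx] + shift, 0.0, 1.0)
            occupied[chrom].append((start, end))
            planted.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "context": config.dmr_context,
                    "direction": direction,
                    "effect": config.dmr_effect,
                    "n_sites": len(in_iv),
                }
            )
            break
        else:
            raise CapacityError(
                f"could not place DMR {len(planted) + 1}/{config.n_dmrs}; "
                "genome too small for the requested number and margin"
            )
    sites["true_ml_case"] = case
    truth.planted_dmrs = pd.DataFrame(planted).sort_values(["chrom", "start"]).reset_index(drop=True)
    return truth


# ---------------------------------------------------------------------------
# Read-count and expression sampling


def simulate_counts(
    truth: TruthSet,
    config: SimulationConfig,
    condition: str,
    replicate: int,
) -> pd.DataFrame:
    """Sample a cytosine report for one sample-replicate.

    Coverage is Poisson(``coverage_mean``) per site; methylated counts are
    Binomial(coverage, ML*(1-o) + (1-ML)*r) with nonconversion rate r and
    optional over-conversion rate o. The replicate RNG stream is derived
    deterministically from (seed, condition, replicate).
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    cond_idx = CONDITIONS.index(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 4, cond_idx, int(replicate)])
    )
    sites = truth.sites
    ml = sites[f"true_ml_{condition}"].to_numpy()
    r = config.nonconversion_rate
    o = config.overconversion_rate
    p_obs = ml * (1.0 - o) + (1.0 - ml) * r
    coverage = rng.poisson(config.coverage_mean, size=len(sites))
    count_meth = rng.binomial(coverage, p_obs)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "strand": sites["strand"].to_numpy(),
            "count_meth": count_meth,
            "count_unmeth": coverage - count_meth,
            "context": sites["context"].to_numpy(),
            "trinucleotide": sites["trinucleotide"].to_numpy(),
        }
    )


def simulate_expression(
    truth: TruthSet,
    genes: list[GeneModel],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Sample per-gene FPKM for both conditions with DE labels.

    A configured fraction of genes is nonexpressed (FPKM < 0.1 in both
    conditions); expressed genes draw a log-normal baseline and a configured
    fraction is differentially expressed with a fold change in
    ``de_fold_range``. With ``couple_promoter_hyper`` on, genes whose
    promoter overlaps a planted hypermethylated interval are biased toward
    the "down" label, emulating promoter-methylation-driven repression.
    """
    em = config.expression
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    n = len(genes)
    fpkm = rng.lognormal(em.log_mean, em.log_sigma, size=n)
    # expressed genes must sit above the 0.1 nonexpression threshold
    low = fpkm < 0.1
    while low.any():
        fpkm[low] = rng.lognormal(em.log_mean, em.log_sigma, size=int(low.sum()))
        low = fpkm < 0.1
    nonexp = rng.random(n) < em.nonexpressed_fraction
    fpkm[nonexp] = rng.uniform(0.0, 0.1, size=int(nonexp.sum()))
    labels = np.array(["none"] * n, dtype=object)
    de = (~nonexp) & (rng.random(n) < em.de_fraction)
    up = rng.random(n) < 0.5
    labels[de & up] = "up"
    labels[de & ~up] = "down"
    if em.couple_promoter_hyper and len(truth.planted_dmrs):
        hyper = truth.planted_dmrs[truth.planted_dmrs["direction"] == "hyper"]
        for i, gene in enumerate(genes):
            if nonexp[i]:
                continue
            pstart, pend = promoter_interval(gene)
            hits = hyper[
                (hyper["chrom"] == gene.chrom)
                & (hyper["start"] <= pend)
                & (hyper["end"] >= pstart)
            ]
            if len(hits) and rng.random() < em.coupling_prob:
                labels[i] = "down"
    folds = rng.uniform(em.de_fold_range[0], em.de_fold_range[1], size=n)
    fpkm_case = fpkm.copy()
    fpkm_case[labels == "up"] = fpkm[labels == "up"] * folds[labels == "up"]
    fpkm_case[labels == "down"] = fpkm[labels == "down"] / folds[labels == "down"]
    expr = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "fpkm_control": fpkm,
            "fpkm_case": fpkm_case,
            "de_label": labels,
        }
    )
    truth.true_de = expr[["gene_id", "de_label"]].copy()
    return expr


# ---------------------------------------------------------------------------
# One-call study bundle


@dataclass
class SimulatedStudy:
    genome: GenomeSequence
    genes: list[GeneModel]
    tes: list[TEAnnotation]
    truth: TruthSet
    counts: dict[tuple[str, int], pd.DataFrame]
    expression: pd.DataFrame
    config: SimulationConfig


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full two-condition study: genome, truth, counts, expression."""
    genome, genes, tes = simulate_genome(config)
    truth = assign_true_methylation(genome, genes, tes, config)
    truth = plant_dmrs(truth, config)
    counts = {
        (condition, rep): simulate_counts(truth, config, condition, rep)
        for condition in CONDITIONS
        for rep in range(1, config.replicates_per_condition + 1)
    }
    expression = simulate_expression(truth, genes, config)
    return SimulatedStudy(
        genome=genome,
        genes=genes,
        tes=tes,
        truth=truth,
        counts=counts,
        expression=expression,
        config=config,
    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, str]:
    """Write a study to disk (FASTA, GFF3, BED, reports, expression, truth JSON)."""
    from . import io as bio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    bio.write_fasta(study.genome, out / "genome.fa")
    paths["genome"] = "genome.fa"
    bio.write_gff3(study.genes, out / "genes.gff3")
    paths["genes"] = "genes.gff3"
    bio.write_te_bed(study.tes, out / "tes.bed")
    paths["tes"] = "tes.bed"
    for (condition, rep), records in sorted(study.counts.items()):
        name = f"{condition}_rep{rep}.cx_report.tsv"
        bio.write_cytosine_report(records, out / name)
        paths[f"{condition}_rep{rep}"] = name
    bio.write_expression_table(study.expression, out / "expression.tsv")
    paths["expression"] = "expression.tsv"
    with open(out / "truth.json", "w") as handle:
        json.dump(study.truth.truth_json(), handle, indent=1, sort_keys=True)
    paths["truth"] = "truth.json"
    return paths
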