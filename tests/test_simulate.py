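"""Synthetic-data generator: determinism, composition, truth model,
DMR planting, count sampling and expression coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bsmeth import core, io as bio
from bsmeth.simulate import (
    SimulationConfig,
    assign_true_methylation,
    plant_dmrs,
    simulate_counts,
    simulate_expression,
    simulate_genome,
    simulate_study,
)
from bsmeth.types import CapacityError, ValidationError


def small_config(**overrides):
    base = dict(
        seed=13,
        chrom_lengths=[60_000, 60_000],
        gene_count=20,
        te_fraction=0.3,
        n_dmrs=3,
        spike_in_length=15_000,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def point_mass_config(**overrides):
    """Every compartment/context: always methylated at exactly ML 0.5."""
    cfg = small_config(**overrides)
    for comp, ctxs in cfg.context_levels.items():
        if comp == "spike_in":
            continue
        for ctx in ctxs:
            ctxs[ctx] = {"p": 1.0, "fixed": 0.5}
    return cfg


class TestGenome:
    def test_requested_composition(self):
        cfg = small_config()
        genome, genes, tes = simulate_genome(cfg)
        assert len(genes) == cfg.gene_count
        main_bp = sum(cfg.chrom_lengths)
        te_bp = sum(te.length for te in tes)
        assert te_bp / main_bp == pytest.approx(cfg.te_fraction, abs=0.02)
        assert genome.spike_in_chrom == "lambda"
        assert genome.lengths["lambda"] == cfg.spike_in_length

    def test_features_do_not_overlap(self):
        _, genes, tes = simulate_genome(small_config())
        spans = sorted(
            [(g.chrom, g.transcript_start, g.transcript_end) for g in genes]
            + [(t.chrom, t.start, t.end) for t in tes]
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 < s2

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = small_config()
        for run in ("a", "b"):
            genome, genes, tes = simulate_genome(small_config())
            bio.write_fasta(genome, tmp_path / f"{run}.fa")
            bio.write_gff3(genes, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_te_class_mix_ratio(self):
        cfg = small_config(
            chrom_lengths=[150_000, 150_000],
            te_class_mix={"LTR_Gypsy": 2.0, "LTR_Copia": 1.0},
        )
        _, _, tes = simulate_genome(cfg)
        n = len(tes)
        gypsy = sum(te.te_class == "LTR_Gypsy" for te in tes)
        # multinomial: 3 sigma around expectation 2/3
        sigma = np.sqrt(n * (2 / 3) * (1 / 3))
        assert abs(gypsy - 2 * n / 3) <= 3 * sigma

    def test_infeasible_packing_raises_capacity_error(self):
        with pytest.raises(CapacityError):
            simulate_genome(small_config(chrom_lengths=[5_000, 5_000], gene_count=50))

    def test_gene_structure_invariants(self):
        _, genes, _ = simulate_genome(small_config())
        for g in genes:
            exonic = sum(e - s + 1 for s, e in g.exons)
            parts = sum(e - s + 1 for s, e in g.utr5 + g.cds + g.utr3)
            assert parts == exonic  # UTRs and CDS partition the exons


class TestTruthModel:
    def test_point_mass_levels(self):
        cfg = point_mass_config()
        genome, genes, tes = simulate_genome(cfg)
        truth = assign_true_methylation(genome, genes, tes, cfg)
        main = truth.sites[truth.sites["chrom"] != "lambda"]
        assert set(main["true_ml_control"].unique()) == {0.5}

    def test_spike_in_unmethylated(self):
        cfg = small_config()
        genome, genes, tes = simulate_genome(cfg)
        truth = assign_true_methylation(genome, genes, tes, cfg)
        lam = truth.sites[truth.sites["chrom"] == "lambda"]
        assert (lam["true_ml_control"] == 0).all()
        assert (lam["compartment"] == "spike_in").all()

    def test_compartment_ordering_te_above_exon(self):
        """Configured TE > exon CG levels are realized in the truth draw."""
        cfg = small_config(chrom_lengths=[120_000, 120_000], gene_count=40)
        genome, genes, tes = simulate_genome(cfg)
        truth = assign_true_methylation(genome, genes, tes, cfg)
        cg = truth.sites[truth.sites["context"] == "CG"]
        te_mean = cg.loc[cg["compartment"] == "te", "true_ml_control"].mean()
        exon_mean = cg.loc[cg["compartment"] == "exon", "true_ml_control"].mean()
        assert te_mean > exon_mean

    def test_nonpositive_beta_rejected(self):
        cfg = small_config()
        cfg.context_levels["exon"]["CG"] = {"p": 0.5, "a": -1.0, "b": 2.0}
        with pytest.raises(ValidationError, match="Beta"):
            SimulationConfig(**{**cfg.to_dict()})


class TestPlantedDmrs:
    def test_no_dmrs_means_identical_conditions(self):
        cfg = small_config(n_dmrs=0)
        genome, genes, tes = simulate_genome(cfg)
        truth = plant_dmrs(assign_true_methylation(genome, genes, tes, cfg), cfg)
        assert len(truth.planted_dmrs) == 0
        np.testing.assert_array_equal(
            truth.sites["true_ml_case"], truth.sites["true_ml_control"]
        )

    def test_shift_and_clamp(self):
        # baseline fixed at 0.3 -> hyper direction -> 0.7 inside intervals
        cfg = point_mass_config(n_dmrs=2)
        for comp, ctxs in cfg.context_levels.items():
            if comp != "spike_in":
                for ctx in ctxs:
                    ctxs[ctx] = {"p": 1.0, "fixed": 0.3}
        genome, genes, tes = simulate_genome(cfg)
        truth = plant_dmrs(assign_true_methylation(genome, genes, tes, cfg), cfg)
        assert (truth.planted_dmrs["direction"] == "hyper").all()
        for dmr in truth.planted_dmrs.itertuples():
            inside = truth.sites[
                (truth.sites["chrom"] == dmr.chrom)
                & (truth.sites["pos"] >= dmr.start)
                & (truth.sites["pos"] <= dmr.end)
                & (truth.sites["context"] == dmr.context)
            ]
            np.testing.assert_allclose(inside["true_ml_case"], 0.7)
        # clamping: effect larger than headroom saturates at 1
        cfg2 = point_mass_config(n_dmrs=1, dmr_effect=0.8)
        for comp, ctxs in cfg2.context_levels.items():
            if comp != "spike_in":
                for ctx in ctxs:
                    ctxs[ctx] = {"p": 1.0, "fixed": 0.4}
        genome, genes, tes = simulate_genome(cfg2)
        truth2 = plant_dmrs(assign_true_methylation(genome, genes, tes, cfg2), cfg2)
        dmr = truth2.planted_dmrs.iloc[0]
        inside = truth2.sites[
            (truth2.sites["chrom"] == dmr["chrom"])
            & (truth2.sites["pos"] >= dmr["start"])
            & (truth2.sites["pos"] <= dmr["end"])
            & (truth2.sites["context"] == dmr["context"])
        ]
        np.testing.assert_allclose(inside["true_ml_case"], 1.0)

    def test_outside_intervals_untouched(self, study):
        sites = study.truth.sites
        outside = np.ones(len(sites), dtype=bool)
        for dmr in study.truth.planted_dmrs.itertuples():
            outside &= ~(
                (sites["chrom"] == dmr.chrom).to_numpy()
                & (sites["pos"] >= dmr.start).to_numpy()
                & (sites["pos"] <= dmr.end).to_numpy()
            )
        np.testing.assert_array_equal(
            sites.loc[outside, "true_ml_case"], sites.loc[outside, "true_ml_control"]
        )

    def test_observed_delta_has_planted_sign(self, study, pooled):
        """Pooled observed delta ML inside each planted interval matches its direction."""
        for dmr in study.truth.planted_dmrs.itertuples():
            deltas = {}
            for cond in ("case", "control"):
                tab = pooled[cond]
                sel = tab[
                    (tab["chrom"] == dmr.chrom)
                    & (tab["pos"] >= dmr.start)
                    & (tab["pos"] <= dmr.end)
                    & (tab["context"] == dmr.context)
                ]
                deltas[cond] = sel["count_meth"].sum() / (
                    sel["count_meth"].sum() + sel["count_unmeth"].sum()
                )
            diff = deltas["case"] - deltas["control"]
            assert (diff > 0) == (dmr.direction == "hyper")

    def test_infeasible_placement_raises(self):
        cfg = small_config(n_dmrs=200)  # cannot fit with the 2 kb margin
        genome, genes, tes = simulate_genome(cfg)
        with pytest.raises(CapacityError):
            plant_dmrs(assign_true_methylation(genome, genes, tes, cfg), cfg)


class TestCounts:
    def test_fully_methylated_no_unmethylated_reads(self):
        cfg = point_mass_config(nonconversion_rate=0.0)
        for comp, ctxs in cfg.context_levels.items():
            if comp != "spike_in":
                for ctx in ctxs:
                    ctxs[ctx] = {"p": 1.0, "fixed": 1.0}
        genome, genes, tes = simulate_genome(cfg)
        truth = plant_dmrs(assign_true_methylation(genome, genes, tes, cfg), cfg)
        rec = simulate_counts(truth, cfg, "control", 1)
        main = rec[rec["chrom"] != "lambda"]
        assert (main["count_unmeth"] == 0).all()

    def test_unmethylated_sites_report_nonconversion_rate(self):
        """Pooled observed level at true ML 0 converges to r (3 sigma)."""
        cfg = small_config(n_dmrs=0, coverage_mean=50.0)
        genome, genes, tes = simulate_genome(cfg)
        truth = plant_dmrs(assign_true_methylation(genome, genes, tes, cfg), cfg)
        rec = simulate_counts(truth, cfg, "control", 1)
        lam = rec[rec["chrom"] == "lambda"]
        n = int((lam["count_meth"] + lam["count_unmeth"]).sum())
        assert n > 1e5
        observed = lam["count_meth"].sum() / n
        r = cfg.nonconversion_rate
        assert abs(observed - r) <= 3 * np.sqrt(r * (1 - r) / n)

    def test_pooled_level_matches_noise_model(self, study, pooled):
        """Pooled observed ML per context ~= truth_mean*(1-r)+r."""
        sites = study.truth.sites
        r = study.config.nonconversion_rate
        tab = pooled["control"]
        for ctx in ("CG", "CHG", "CHH"):
            mask = (sites["context"] == ctx) & (sites["chrom"] != "lambda")
            sel = tab[(tab["context"] == ctx) & (tab["chrom"] != "lambda")]
            total = (sel["count_meth"] + sel["count_unmeth"]).sum()
            observed = sel["count_meth"].sum() / total
            # coverage-weighted truth expectation; Poisson coverage is
            # independent of ML so the site mean is the right center
            expected = sites.loc[mask, "true_ml_control"].mean() * (1 - r) + r
            assert observed == pytest.approx(expected, abs=0.01)

    def test_replicate_stream_determinism(self, tmp_path, study):
        rec1 = simulate_counts(study.truth, study.config, "case", 2)
        rec2 = simulate_counts(study.truth, study.config, "case", 2)
        pd.testing.assert_frame_equal(rec1, rec2)
        other = simulate_counts(study.truth, study.config, "case", 1)
        assert not rec1["count_meth"].equals(other["count_meth"])

    def test_invalid_condition_rejected(self, study):
        with pytest.raises(ValidationError):
            simulate_counts(study.truth, study.config, "treated", 1)


class TestExpression:
    def test_zero_de_fraction_all_none(self):
        cfg = small_config()
        cfg.expression.de_fraction = 0.0
        cfg.expression.couple_promoter_hyper = False
        genome, genes, tes = simulate_genome(cfg)
        truth = plant_dmrs(assign_true_methylation(genome, genes, tes, cfg), cfg)
        expr = simulate_expression(truth, genes, cfg)
        assert (expr["de_label"] == "none").all()
        np.testing.assert_array_equal(expr["fpkm_case"], expr["fpkm_control"])

    def test_nonexpressed_fraction_realized(self):
        from bsmeth.simulate import TruthSet
        from bsmeth.types import GeneModel

        cfg = small_config(n_dmrs=0)
        cfg.expression.nonexpressed_fraction = 0.2
        cfg.expression.couple_promoter_hyper = False
        genes = [
            GeneModel(f"g{i}", "chr1", "+", 1 + 100 * i, 50 + 100 * i)
            for i in range(1000)
        ]
        truth = TruthSet(
            sites=pd.DataFrame(), chrom_lengths={"chr1": 100_100},
            spike_in_chrom=None, r_true=cfg.nonconversion_rate, seed=cfg.seed,
        )
        expr = simulate_expression(truth, genes, cfg)
        n_low = int((expr["fpkm_control"] < 0.1).sum())
        sigma = np.sqrt(1000 * 0.2 * 0.8)
        assert abs(n_low - 200) <= 3 * sigma

    def test_promoter_hyper_down_coupling_enriched(self, study):
        """Genes under planted promoter-hyper intervals are enriched for 'down'."""
        from bsmeth.features import promoter_interval

        expr = study.expression.set_index("gene_id")
        hyper = study.truth.planted_dmrs[study.truth.planted_dmrs["direction"] == "hyper"]
        coupled, uncoupled = [], []
        for gene in study.genes:
            start, end = promoter_interval(gene)
            hit = (
                (hyper["chrom"] == gene.chrom)
                & (hyper["start"] <= end)
                & (hyper["end"] >= start)
            ).any()
            (coupled if hit else uncoupled).append(
                expr.loc[gene.gene_id, "de_label"] == "down"
            )
        if coupled:  # odds ratio of down-labels: coupled vs background
            a, b = sum(coupled), len(coupled) - sum(coupled)
            c, d = sum(uncoupled), len(uncoupled) - sum(uncoupled)
            assert (a + 0.5) / (b + 0.5) > (c + 0.5) / (d + 0.5)


class TestStudyBundle:
    def test_truth_json_schema(self, study):
        blob = study.truth.truth_json()
        assert set(blob) >= {"r_true", "planted_dmrs", "spike_in_chrom", "true_de"}
        assert blob["r_true"] == study.config.nonconversion_rate
        assert len(blob["planted_dmrs"]) == study.config.n_dmrs

    def test_full_study_determinism(self, tmp_path, study):
        from bsmeth.simulate import write_study

        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        write_study(study, d1)
        write_study(simulate_study(study.config), d2)
        for f1 in sorted(d1.iterdir()):
            assert (d2 / f1.name).read_bytes() == f1.read_bytes()
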