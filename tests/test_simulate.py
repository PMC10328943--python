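"""Synthetic study generator: determinism, planted-effect recovery,
analytic limits and structural invariants."""

import numpy as np
import pandas as pd
import pytest

from methylink import digest, simulate
from methylink.simulate import SimulationConfig


class TestConfig:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="de_fraction"):
            SimulationConfig(de_fraction=1.5).validate()

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            SimulationConfig(groups=(("A", 1), ("B", 6))).validate()

    def test_default_design_matches_study_groups(self):
        cfg = SimulationConfig()
        sizes = {g: n for g, n in cfg.groups}
        assert sizes == {"Attacker": 6, "Parental": 6, "Father": 5, "Mother": 6}


class TestGenome:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=3, n_contigs=1, contig_len=30_000, n_genes=10)
        g1, genes1 = simulate.simulate_genome(cfg)
        g2, genes2 = simulate.simulate_genome(cfg)
        assert g1[0].sequence == g2[0].sequence
        assert [(g.gene_id, g.start, g.end, g.strand) for g in genes1] == [
            (g.gene_id, g.start, g.end, g.strand) for g in genes2
        ]

    def test_zero_ccgg_rate_gives_empty_background(self):
        cfg = SimulationConfig(seed=1, n_contigs=1, contig_len=30_000, n_genes=5,
                               ccgg_rate=0.0)
        genome, _ = simulate.simulate_genome(cfg)
        assert len(digest.digest_genome(genome)) == 0

    def test_unpackable_gene_count_errors(self):
        cfg = SimulationConfig(seed=1, n_contigs=1, contig_len=5_000, n_genes=50)
        with pytest.raises(ValueError, match="pack"):
            simulate.simulate_genome(cfg)

    def test_genes_non_overlapping_with_exons(self, small_study):
        by_contig = {}
        for g in small_study.genes:
            by_contig.setdefault(g.contig, []).append(g)
        for gs in by_contig.values():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert a.end <= b.start
            for g in gs:
                assert len(g.exons) >= 1


class TestExpression:
    def test_null_groups_have_equal_means(self):
        cfg = SimulationConfig(seed=2, de_fraction=0.0)
        rng = np.random.default_rng(0)
        truth = simulate.GroundTruth()
        gene_ids = [f"g{i}" for i in range(2000)]
        cm = simulate.simulate_expression(cfg, gene_ids, truth, rng)
        a = cm.counts[cm.samples_in_group("Attacker")].to_numpy().mean()
        b = cm.counts[cm.samples_in_group("Parental")].to_numpy().mean()
        assert abs(np.log2(a / b)) < 0.15

    def test_planted_fold_change_monte_carlo(self):
        """Planted log2FC=1 at high counts: group mean ratio ~ 2."""
        cfg = SimulationConfig(
            seed=3, mean_count_log_mean=np.log(1000), mean_count_log_sd=0.0,
            size_factor_sd=0.0, nb_dispersion=0.05,
        )
        gene_ids = [f"g{i}" for i in range(10_000)]
        truth = simulate.GroundTruth(
            de_genes={g: ("Attacker", 1.0) for g in gene_ids}
        )
        cm = simulate.simulate_expression(cfg, gene_ids, truth, np.random.default_rng(1))
        ratio = (
            cm.counts[cm.samples_in_group("Attacker")].to_numpy().mean()
            / cm.counts[cm.samples_in_group("Parental")].to_numpy().mean()
        )
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_zero_dispersion_is_poisson(self):
        cfg = SimulationConfig(seed=4, nb_dispersion=0.0, de_fraction=0.0,
                               mean_count_log_sd=0.0, size_factor_sd=0.0)
        gene_ids = [f"g{i}" for i in range(5000)]
        cm = simulate.simulate_expression(cfg, gene_ids, simulate.GroundTruth(),
                                          np.random.default_rng(2))
        x = cm.counts.to_numpy(dtype=float)
        # variance/mean ratio across everything ~ 1 for Poisson
        assert x.var() / x.mean() == pytest.approx(1.0, rel=0.05)


class TestMethylation:
    def test_records_only_at_background_positions(self, small_study):
        bg = small_study.background.positions
        observed = set(
            zip(small_study.meth.records["contig"], small_study.meth.records["pos"])
        )
        assert observed == bg

    def test_planted_delta_recovered_in_group_means(self):
        cfg = SimulationConfig(seed=5, n_contigs=1, contig_len=120_000, n_genes=20,
                               ccgg_rate=0.001, dmc_fraction=0.0)
        rng = np.random.default_rng(3)
        genome, genes = simulate.simulate_genome(cfg, rng)
        bg = digest.digest_genome(genome)
        sites = bg.sorted_positions()
        # plant delta=0.3 for Attacker at every site with a mid-range baseline
        truth = simulate.GroundTruth(dmcs={s: ("Attacker", 0.3) for s in sites})
        meth = simulate.simulate_methylation(cfg, bg, truth, rng)
        rec = meth.records
        rec = rec.assign(total=rec["n_meth"] + rec["n_unmeth"],
                         group=rec["sample_id"].map(meth.group_of))
        grp = rec.groupby("group")[["n_meth", "total"]].sum()
        diff = (grp.loc["Attacker", "n_meth"] / grp.loc["Attacker", "total"]
                - grp.loc["Parental", "n_meth"] / grp.loc["Parental", "total"])
        # clamping near the boundaries shrinks the average planted shift a bit
        assert 0.15 < diff < 0.35

    def test_zero_betabin_dispersion_is_binomial(self):
        cfg = SimulationConfig(seed=6, n_contigs=1, contig_len=60_000, n_genes=10,
                               ccgg_rate=0.001, betabin_dispersion=0.0,
                               dmc_fraction=0.0, coverage_mean=50)
        rng = np.random.default_rng(4)
        genome, _ = simulate.simulate_genome(cfg, rng)
        bg = digest.digest_genome(genome)
        meth = simulate.simulate_methylation(cfg, bg, simulate.GroundTruth(), rng)
        rec = meth.records.assign(total=lambda d: d["n_meth"] + d["n_unmeth"])
        # per-site across-sample variance of proportions should match binomial
        rec["p"] = rec["n_meth"] / rec["total"].clip(lower=1)
        site = rec.groupby("pos").agg(v=("p", "var"), m=("p", "mean"),
                                      cov=("total", "mean"))
        site = site[(site["m"] > 0.2) & (site["m"] < 0.8)]
        expected = (site["m"] * (1 - site["m"]) / site["cov"]).mean()
        assert site["v"].mean() == pytest.approx(expected, rel=0.2)


class TestCoupling:
    def test_coupled_promoter_deltas_anticorrelate_with_lfc(self):
        cfg = SimulationConfig(seed=7, n_contigs=2, contig_len=200_000, n_genes=150,
                               ccgg_rate=0.002, de_fraction=0.5, coupling_rho=0.8)
        study = simulate.simulate_study(cfg)
        truth = study.truth
        assert len(truth.coupled_genes) > 10
        lfc = [truth.de_genes[g][1] for g in truth.coupled_genes]
        # each coupled gene's promoter delta (same for all its promoter CpGs)
        from methylink.simulate import _promoter_cpgs

        pmap = _promoter_cpgs(study.genes, study.background, cfg.promoter_up)
        deltas = [truth.dmcs[pmap[g][0]][1] for g in truth.coupled_genes]
        rho = pd.Series(lfc).corr(pd.Series(deltas), method="spearman")
        assert rho < -0.4


class TestStudyDeterminism:
    def test_full_study_reproducible(self):
        cfg = SimulationConfig(seed=11, n_contigs=1, contig_len=80_000, n_genes=40,
                               ccgg_rate=0.001)
        s1 = simulate.simulate_study(cfg)
        s2 = simulate.simulate_study(cfg)
        pd.testing.assert_frame_equal(s1.counts.counts, s2.counts.counts)
        pd.testing.assert_frame_equal(s1.meth.records, s2.meth.records)
        assert s1.truth.de_genes == s2.truth.de_genes
        assert s1.truth.dmcs == s2.truth.dmcs

    def test_truth_roundtrip_json(self, tmp_path, small_study):
        p = tmp_path / "truth.json"
        small_study.truth.to_json(p)
        back = simulate.GroundTruth.from_json(p)
        assert back.de_genes == small_study.truth.de_genes
        assert back.dmcs == small_study.truth.dmcs
        assert back.coupled_genes == small_study.truth.coupled_genes
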