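"""Differential expression: filtering rule, TMM factors, LRT oracles, DEG
thresholds and clustering determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln
from scipy.stats import chi2, kstest

from methylink import de
from methylink.types import CountMatrix


def make_counts(arr, groups):
    arr = np.asarray(arr)
    df = pd.DataFrame(
        arr.astype(np.int64),
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=list(groups),
    )
    return CountMatrix(df, groups)


TWO_GROUPS_6 = {f"A{i}": "A" for i in range(6)} | {f"B{i}": "B" for i in range(6)}


class TestFilterGenes:
    def test_gene_missing_in_half_a_group_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(200, (3, 12))
        counts[0, :3] = 0  # zero in 3 of 6 samples of group A
        cm = make_counts(counts, TWO_GROUPS_6)
        kept = de.filter_genes(cm, min_cpm=1.0)
        assert "g0" not in kept.gene_ids
        assert {"g1", "g2"} <= set(kept.gene_ids)

    def test_gene_expressed_everywhere_kept(self):
        cm = make_counts(np.full((2, 12), 100), TWO_GROUPS_6)
        assert de.filter_genes(cm).gene_ids == ["g0", "g1"]

    def test_all_zero_matrix_warns_empty(self):
        counts = np.zeros((3, 12), dtype=int)
        counts[0] = 100  # keep library sizes positive
        cm = make_counts(counts, TWO_GROUPS_6)
        kept = de.filter_genes(cm, min_cpm=1e9)
        assert kept.gene_ids == []

    def test_any_mode_is_laxer(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(200, (5, 12))
        counts[1, :6] = 0  # absent from all of group A only
        cm = make_counts(counts, TWO_GROUPS_6)
        assert "g1" not in de.filter_genes(cm, mode="every").gene_ids
        assert "g1" in de.filter_genes(cm, mode="any").gene_ids


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        base = np.random.default_rng(2).poisson(100, 60)
        cm = make_counts(np.tile(base[:, None], (1, 12)), TWO_GROUPS_6)
        np.testing.assert_allclose(de.size_factors(cm), 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        # doubling a column is a depth change, not a composition change:
        # TMM factors stay 1 and effective library sizes carry the ratio
        base = np.random.default_rng(3).poisson(100, 200)
        mat = np.tile(base[:, None], (1, 12))
        mat[:, 0] *= 2
        cm = make_counts(mat, TWO_GROUPS_6)
        factors = de.size_factors(cm)
        np.testing.assert_allclose(factors, 1.0, atol=1e-9)
        eff = de.effective_lib_sizes(cm, factors)
        assert eff.iloc[0] / eff.iloc[1] == pytest.approx(2.0, rel=1e-9)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(4)
        cm = make_counts(rng.poisson(rng.lognormal(4, 1, (300, 1)), (300, 12)), TWO_GROUPS_6)
        f = de.size_factors(cm)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_errors(self):
        mat = np.full((5, 12), 10)
        mat[:, 3] = 0
        with pytest.raises(ValueError, match="all-zero"):
            de.size_factors(make_counts(mat, TWO_GROUPS_6))


def poisson_lrt_oracle(y, offsets, na):
    """Closed-form Poisson GLM LRT: MLE of the rate is sum(y)/sum(offset)."""
    def ll(y, off):
        m = y.sum() / off.sum()
        mu = np.maximum(m * off, 1e-12)
        return float((y * np.log(mu) - mu - gammaln(y + 1)).sum())

    full = ll(y[:na], offsets[:na]) + ll(y[na:], offsets[na:])
    null = ll(y, offsets)
    return chi2.sf(2 * (full - null), df=1)


class TestNbLrt:
    def test_zero_dispersion_matches_poisson_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(80, (40, 12))
        cm = make_counts(counts, TWO_GROUPS_6)
        zero = pd.Series(0.0, index=cm.gene_ids)
        ones = pd.Series(1.0, index=cm.sample_ids)
        res = de.nb_lrt(cm, "A", "B", factors=ones, dispersions=zero)
        eff = de.effective_lib_sizes(cm, ones).to_numpy()
        for i, g in enumerate(cm.gene_ids):
            expected = poisson_lrt_oracle(counts[i].astype(float), eff, 6)
            assert res.loc[g, "pvalue"] == pytest.approx(expected, abs=1e-6)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(6)
        phi = 0.1
        mu = rng.lognormal(np.log(100), 1.0, 2000)[:, None] * np.ones(12)
        y = rng.poisson(rng.gamma(1 / phi, mu * phi))
        cm = make_counts(y, TWO_GROUPS_6)
        res = de.nb_lrt(cm, "A", "B")
        stat = kstest(res["pvalue"], "uniform")
        assert stat.pvalue > 1e-4  # not grossly non-uniform

    def test_planted_fold_change_recovered(self):
        # plant log2FC=1 in a 10% subset so normalization stays anchored
        rng = np.random.default_rng(7)
        mu = np.full((1000, 12), 100.0)
        mu[:100, :6] *= 2.0
        y = rng.poisson(rng.gamma(10.0, mu / 10.0))
        cm = make_counts(y, TWO_GROUPS_6)
        res = de.nb_lrt(cm, "A", "B")
        assert np.median(res["log2fc"].iloc[:100]) == pytest.approx(1.0, abs=0.1)

    def test_sign_convention_positive_means_higher_in_first_group(self):
        y = np.full((40, 12), 100)
        y[:20, :6] = 400  # higher in group A for half the genes
        res = de.nb_lrt(make_counts(y, TWO_GROUPS_6), "A", "B")
        assert (res["log2fc"].iloc[:20] > 0).all()
        res_rev = de.nb_lrt(make_counts(y, TWO_GROUPS_6), "B", "A")
        assert (res_rev["log2fc"].iloc[:20] < 0).all()


class TestCallDegs:
    @pytest.mark.parametrize(
        "log2fc,pvalue,expected",
        [
            (0.50, 0.01, False),   # boundary fold change excluded
            (0.51, 0.049, True),
            (-2.0, 0.06, False),   # p at/above 0.05 excluded
            (-0.51, 0.0499, True),
            (0.49, 0.001, False),
            (3.0, 0.05, False),    # p exactly 0.05 excluded
        ],
    )
    def test_threshold_semantics(self, log2fc, pvalue, expected):
        df = pd.DataFrame({"log2fc": [log2fc], "pvalue": [pvalue]},
                          index=pd.Index(["g"], name="gene_id"))
        assert bool(de.call_degs(df)["is_deg"].iloc[0]) is expected


class TestClustering:
    def test_two_blobs_perfectly_separated(self):
        rng = np.random.default_rng(8)
        up = rng.poisson([300, 300, 300, 10, 10, 10, 10, 10, 10, 10, 10, 10], (20, 12))
        down = rng.poisson([10, 10, 10, 300, 300, 300, 300, 300, 300, 300, 300, 300], (20, 12))
        groups = {f"A{i}": "A" for i in range(3)} | {f"B{i}": "B" for i in range(9)}
        cm = make_counts(np.vstack([up, down]), groups)
        out = de.zscore_and_cluster(cm.gene_ids, cm, k=2, seed=0)
        first = set(out["cluster"].iloc[:20])
        second = set(out["cluster"].iloc[20:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_zscores_standardized_per_gene(self, two_group_counts):
        out = de.zscore_and_cluster(two_group_counts.gene_ids[:10], two_group_counts, k=2, seed=0)
        z = out[[c for c in out.columns if c.startswith("z_")]].to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_fixed_seed_is_deterministic(self, two_group_counts):
        a = de.zscore_and_cluster(two_group_counts.gene_ids, two_group_counts, k=3, seed=5)
        b = de.zscore_and_cluster(two_group_counts.gene_ids, two_group_counts, k=3, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_k_larger_than_genes_errors(self, two_group_counts):
        with pytest.raises(ValueError, match="exceeds"):
            de.zscore_and_cluster(two_group_counts.gene_ids[:3], two_group_counts, k=8, seed=0)
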