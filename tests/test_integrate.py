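"""Integration: DEG-DMC pairing, quantile boundaries, Spearman behavior."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methylink import integrate
from methylink.annotate import build_index
from methylink.types import GeneModel


@pytest.fixture
def toy_index():
    genes = [
        GeneModel("gUp", "c1", "+", 10000, 13000, ((10000, 13000),)),
        GeneModel("gDown", "c1", "+", 30000, 33000, ((30000, 33000),)),
    ]
    return build_index(genes)


def _degs(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue", "is_deg"])
    return df.set_index("gene_id")


def _dmcs(rows):
    return pd.DataFrame(rows, columns=["contig", "pos", "delta", "pvalue", "status"])


class TestPairing:
    def test_gene_with_two_body_dmcs_gives_two_pairs(self, toy_index):
        # an up-regulated gene carrying two gene-body hypermethylated sites
        degs = _degs([("gUp", 1.862, 0.001, True)])
        dmcs = _dmcs([("c1", 11000, 0.3, 0.01, "hyper"), ("c1", 12000, 0.4, 0.01, "hyper")])
        pairs = integrate.pair_deg_dmc(degs, dmcs, toy_index, "gene_body")
        assert len(pairs) == 2
        assert set(pairs["pos"]) == {11000, 12000}
        assert (pairs["gene_id"] == "gUp").all()

    def test_deg_without_dmc_gives_no_pairs(self, toy_index):
        degs = _degs([("gUp", 1.0, 0.001, True)])
        pairs = integrate.pair_deg_dmc(degs, _dmcs([]), toy_index, "gene_body")
        assert pairs.empty

    def test_promoter_dmc_of_down_gene(self, toy_index):
        # a down-regulated gene with a promoter hypermethylated CpG
        degs = _degs([("gDown", -0.6, 0.01, True)])
        dmcs = _dmcs([("c1", 29000, 0.743, 0.001, "hyper")])
        pairs = integrate.pair_deg_dmc(degs, dmcs, toy_index, "promoter")
        assert len(pairs) == 1
        assert pairs.iloc[0]["delta_meth"] == pytest.approx(0.743)

    def test_non_deg_and_ns_dmcs_excluded(self, toy_index):
        degs = _degs([("gUp", 0.2, 0.5, False)])
        dmcs = _dmcs([("c1", 11000, 0.3, 0.01, "hyper"), ("c1", 12000, 0.02, 0.9, "ns")])
        assert integrate.pair_deg_dmc(degs, dmcs, toy_index, "gene_body").empty


class TestQuantiles:
    def test_sixteen_genes_eight_quantiles_two_each(self):
        pairs = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(16)], "log2fc": np.arange(16.0),
             "delta_meth": 0.2}
        )
        out = integrate.quantile_stratify(pairs, 8)
        assert out["quantile_index"].value_counts().eq(2).all()

    def test_type7_boundaries_hand_computed(self):
        # values 1..8, m=4: type-7 quantiles at 0.25/0.5/0.75 are 2.75, 4.5, 6.25
        vals = np.arange(1.0, 9.0)
        pairs = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(8)], "log2fc": vals, "delta_meth": 0.2}
        )
        out = integrate.quantile_stratify(pairs, 4).set_index("gene_id")
        expected = {1.0: 1, 2.0: 1, 3.0: 2, 4.0: 2, 5.0: 3, 6.0: 3, 7.0: 4, 8.0: 4}
        for g, v in zip(pairs["gene_id"], vals):
            assert out.loc[g, "quantile_index"] == expected[v]

    def test_boundary_tie_goes_to_lower_quantile(self):
        # with values 0,1,2,3 and m=2 the median boundary is 1.5; a gene at
        # exactly the boundary of a coarser grid must fall left
        pairs = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "log2fc": [0.0, 1.0, 2.0], "delta_meth": 0.0}
        )
        out = integrate.quantile_stratify(pairs, 2).set_index("gene_id")
        assert out.loc["b", "quantile_index"] == 1  # 1.0 == type-7 median boundary

    def test_all_equal_lfc_errors(self):
        pairs = pd.DataFrame(
            {"gene_id": ["a", "b", "c", "d"], "log2fc": 1.0, "delta_meth": 0.1}
        )
        with pytest.raises(ValueError, match="degenerate"):
            integrate.quantile_stratify(pairs, 2)

    def test_too_few_genes_errors_with_suggestion(self):
        pairs = pd.DataFrame(
            {"gene_id": ["a", "b"], "log2fc": [0.0, 1.0], "delta_meth": 0.1}
        )
        with pytest.raises(ValueError, match="reduce the number of quantiles"):
            integrate.quantile_stratify(pairs, 8)

    def test_multi_dmc_genes_do_not_distort_boundaries(self):
        base = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(8)], "log2fc": np.arange(8.0),
             "delta_meth": 0.2}
        )
        dup = pd.concat([base, base.iloc[[0]].assign(delta_meth=0.5)] * 5,
                        ignore_index=True)
        out_base = integrate.quantile_stratify(base, 4)
        out_dup = integrate.quantile_stratify(dup, 4)
        merged = out_dup.drop_duplicates("gene_id").set_index("gene_id")["quantile_index"]
        assert (merged == out_base.set_index("gene_id")["quantile_index"]).all()


class TestSpearman:
    def _pairs(self, x, y, q=1):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(x))], "log2fc": x,
             "delta_meth": y, "quantile_index": q}
        )

    def test_monotone_rho_one(self):
        out = integrate.spearman_by_quantile(self._pairs([1, 2, 3], [2, 3, 5]))
        assert out.iloc[0]["rho"] == pytest.approx(1.0)

    def test_antimonotone_rho_minus_one(self):
        out = integrate.spearman_by_quantile(self._pairs([1, 2, 3], [5, 3, 2]))
        assert out.iloc[0]["rho"] == pytest.approx(-1.0)

    def test_bonferroni_alpha_is_alpha_over_m(self):
        pairs = pd.concat(
            [self._pairs([1, 2, 3], [1, 2, 3], q=q) for q in range(1, 9)],
            ignore_index=True,
        )
        out = integrate.spearman_by_quantile(pairs, alpha=0.05)
        assert np.allclose(out["bonferroni_alpha"], 0.05 / 8)
        assert out["bonferroni_alpha"].iloc[0] == pytest.approx(0.00625)

    def test_small_quantile_flagged(self):
        out = integrate.spearman_by_quantile(self._pairs([1, 2], [1, 2]))
        assert np.isnan(out.iloc[0]["rho"]) and not out.iloc[0]["significant"]

    def test_exact_permutation_p_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        out = integrate.spearman_by_quantile(self._pairs(x, y))
        # independent enumeration over all 120 permutations of y's ranks
        rx = np.argsort(np.argsort(x)).astype(float)
        ry = np.argsort(np.argsort(y)).astype(float)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            abs(np.corrcoef(rx, np.array(p, dtype=float))[0, 1]) >= obs - 1e-12
            for p in itertools.permutations(ry)
        )
        assert out.iloc[0]["pvalue"] == pytest.approx(count / 120)


class TestJointChangeGenes:
    def test_promoter_and_body_dmcs_qualify_intergenic_excluded(self, toy_index):
        degs = _degs([("gUp", 1.2, 0.001, True), ("gDown", -0.264, 0.01, True)])
        dmcs = _dmcs(
            [
                ("c1", 29000, 0.743, 0.001, "hyper"),   # gDown promoter
                ("c1", 11000, -0.3, 0.01, "hypo"),      # gUp body
                ("c1", 60000, 0.5, 0.001, "hyper"),     # intergenic
            ]
        )
        assert integrate.joint_change_genes(degs, dmcs, toy_index) == ["gDown", "gUp"]

    def test_deg_with_only_intergenic_dmc_excluded(self, toy_index):
        degs = _degs([("gUp", 1.2, 0.001, True)])
        dmcs = _dmcs([("c1", 60000, 0.5, 0.001, "hyper")])
        assert integrate.joint_change_genes(degs, dmcs, toy_index) == []

    def test_empty_dmcs_give_empty_list(self, toy_index):
        degs = _degs([("gUp", 1.2, 0.001, True)])
        assert integrate.joint_change_genes(degs, _dmcs([]), toy_index) == []
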