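"""Stratification, pseudo-bulk NB Wald testing, consensus, and per-cell GLM."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spatipath.diffexp import (
    deg_consensus,
    glm_vs_hsnca,
    nb_wald_de,
    pseudobulk_aggregate,
    size_factors,
    stratify_by_percentile,
    three_way_de,
)
from spatipath.io_formats import CountMatrix


def _cm(dense, genes=None, panel=None, ids=None):
    dense = np.asarray(dense)
    return CountMatrix(
        sp.csr_matrix(dense),
        ids or [f"c{i}" for i in range(dense.shape[0])],
        genes or [f"g{j}" for j in range(dense.shape[1])],
        panel or [],
    )


class TestStratify:
    def _cells(self, values, psyn, ctype="T"):
        ids = [f"c{i}" for i in range(len(values))]
        cells = pd.DataFrame({"cell_id": ids, "cell_type": ctype, "psyn": psyn})
        return cells, pd.Series(values, index=ids, dtype=float)

    def test_quantile_thresholds_linear_interpolation(self):
        values = [1, 2, 3, 4, 5, 6, 7, 8]
        psyn = [True, True, False, False, False, False, False, False]
        cells, expr = self._cells(values, psyn)
        out = stratify_by_percentile(cells, expr, min_cells_per_stratum=1)
        s = out["T"]
        assert s.q75 == pytest.approx(6.25)
        assert s.q25 == pytest.approx(2.75)
        assert sorted(expr.loc[s.high]) == [7, 8]
        assert sorted(expr.loc[s.low]) == [1, 2]

    def test_all_negative_skipped(self):
        cells, expr = self._cells(list(range(1, 9)), [False] * 8)
        assert stratify_by_percentile(cells, expr, min_cells_per_stratum=1) == {}

    def test_all_positive_skipped(self):
        cells, expr = self._cells(list(range(1, 9)), [True] * 8)
        assert stratify_by_percentile(cells, expr, min_cells_per_stratum=1) == {}

    def test_min_stratum_size_enforced(self, rng):
        values = rng.gamma(2, 1, 40)
        psyn = rng.random(40) < 0.5
        cells, expr = self._cells(values, psyn)
        out = stratify_by_percentile(cells, expr, min_cells_per_stratum=50)
        assert out == {}


class TestPseudobulk:
    def test_group_sum(self):
        cm = _cm([[1, 2, 0], [3, 4, 1]])
        cells = pd.DataFrame({"cell_id": ["c0", "c1"], "grp": ["a", "a"]})
        pb, sizes = pseudobulk_aggregate(cm, cells, keys=("grp",), min_cells=1)
        assert pb.loc[("a",)].tolist() == [4, 6, 1]
        assert sizes.loc[("a",)] == 2

    def test_cell_order_invariance_and_conservation(self, rng):
        dense = rng.poisson(2, size=(30, 8))
        cm = _cm(dense)
        cells = pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(30)], "grp": rng.choice(["a", "b"], 30)}
        )
        pb1, _ = pseudobulk_aggregate(cm, cells, keys=("grp",), min_cells=1)
        pb2, _ = pseudobulk_aggregate(
            cm, cells.sample(frac=1.0, random_state=1), keys=("grp",), min_cells=1
        )
        pd.testing.assert_frame_equal(pb1, pb2)
        assert pb1.to_numpy().sum() == dense.sum()

    def test_small_groups_dropped(self, rng):
        cm = _cm(rng.poisson(2, size=(12, 4)))
        cells = pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(12)], "grp": ["a"] * 10 + ["b"] * 2}
        )
        pb, _ = pseudobulk_aggregate(cm, cells, keys=("grp",), min_cells=5)
        assert list(pb.index.get_level_values("grp")) == ["a"]


class TestSizeFactors:
    def test_identical_samples_equal_factors(self, rng):
        row = rng.poisson(20, 10) + 1
        pb = pd.DataFrame(np.tile(row, (4, 1)))
        s = size_factors(pb)
        assert np.allclose(s, 1.0)

    def test_doubling_a_sample_doubles_its_factor(self, rng):
        row = rng.poisson(20, 10) + 1
        pb = pd.DataFrame(np.vstack([row, row, row, 2 * row]))
        s = size_factors(pb)
        assert s[3] / s[0] == pytest.approx(2.0)

    def test_all_zero_gene_fallback(self):
        pb = pd.DataFrame([[0, 3], [0, 6]])  # no all-nonzero... gene 2 is
        s = size_factors(pb)
        assert s[1] / s[0] == pytest.approx(2.0)


class TestNbWaldDe:
    def _pb(self, rng, n_genes=30, lfc=None, n_per_group=4, dispersion=0.1):
        base = rng.lognormal(3, 1, n_genes)
        lfc = np.zeros(n_genes) if lfc is None else lfc
        size = 1 / dispersion
        rows = []
        for i in range(2 * n_per_group):
            mult = 2.0**lfc if i >= n_per_group else 1.0
            mu = base * mult
            rows.append(rng.negative_binomial(size, size / (size + mu)))
        groups = np.array(["a"] * n_per_group + ["b"] * n_per_group)
        return pd.DataFrame(rows, columns=[f"g{j}" for j in range(n_genes)]), groups

    def test_identical_groups_null(self, rng):
        half = rng.poisson(50, size=(4, 10)) + 1
        pb = pd.DataFrame(np.vstack([half, half]), columns=[f"g{j}" for j in range(10)])
        res = nb_wald_de(pb, ["a"] * 4 + ["b"] * 4)
        assert np.all(np.abs(res["log2fc"]) < 1e-8)
        assert np.all(res["p"] > 0.9)

    def test_label_swap_negates_log2fc(self, rng):
        pb, groups = self._pb(rng)
        res1 = nb_wald_de(pb, groups).set_index("gene")
        swapped = np.where(groups == "a", "b", "a")
        res2 = nb_wald_de(pb, swapped).set_index("gene")
        assert np.allclose(res1["log2fc"], -res2["log2fc"], atol=1e-8)

    def test_planted_twofold_recovered(self, rng):
        lfc = np.zeros(100)
        lfc[:10] = 1.0
        ests = []
        for _ in range(5):
            pb, groups = self._pb(rng, n_genes=100, lfc=lfc)
            res = nb_wald_de(pb, groups).set_index("gene")
            ests.append(res.iloc[:10]["log2fc"].mean())
        assert 0.8 <= np.mean(ests) <= 1.2

    def test_requires_replicates(self, rng):
        pb, _ = self._pb(rng, n_per_group=1)
        with pytest.raises(ValueError, match="replicates"):
            nb_wald_de(pb, ["a", "b"])

    def test_all_zero_gene_excluded(self, rng):
        pb, groups = self._pb(rng, n_genes=5)
        pb["dead"] = 0
        res = nb_wald_de(pb, groups)
        assert "dead" not in set(res["gene"])

    def test_fdr_at_least_p(self, rng):
        pb, groups = self._pb(rng)
        res = nb_wald_de(pb, groups)
        assert (res["fdr"] >= res["p"] - 1e-15).all()


class TestConsensus:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "cell_type", "log2fc", "fdr"]
        ).assign(comparison="x")

    def test_two_types_same_direction_included(self):
        res = self._results([("g", "A", 1.0, 0.01), ("g", "B", 0.5, 0.02)])
        out = deg_consensus(res)
        assert out.loc["g", "direction"] == "up"
        assert out.loc["g", "n_types"] == 2

    def test_opposite_directions_excluded(self):
        res = self._results([("g", "A", 1.0, 0.01), ("g", "B", -0.5, 0.02)])
        assert len(deg_consensus(res)) == 0

    def test_single_type_excluded(self):
        res = self._results([("g", "A", 1.0, 0.01), ("g", "B", 1.0, 0.5)])
        assert len(deg_consensus(res)) == 0


class TestThreeWayDe:
    def test_single_tg_sample_errors(self, rng):
        n = 80
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "sample_id": ["nt1"] * 20 + ["nt2"] * 20 + ["tg1"] * 40,
                "genotype": ["non_tg"] * 40 + ["tg"] * 40,
                "cell_type": "T ExN",
                "psyn": [False] * 40 + [True] * 20 + [False] * 20,
            }
        )
        cm = _cm(rng.poisson(5, size=(n, 6)), panel=["custom"] * 6,
                 ids=list(cells["cell_id"]))
        with pytest.raises(ValueError, match="replicates|enough"):
            three_way_de(cm, cells, min_cells=5)

    def test_requires_both_genotypes(self, rng):
        cells = pd.DataFrame(
            {
                "cell_id": ["c0", "c1"],
                "sample_id": "s1",
                "genotype": "tg",
                "cell_type": "T",
                "psyn": [True, False],
            }
        )
        cm = _cm(rng.poisson(5, size=(2, 3)), ids=["c0", "c1"])
        with pytest.raises(ValueError, match="genotype"):
            three_way_de(cm, cells)


class TestGlmVsHsnca:
    def _dataset(self, rng, n=800):
        lib_bulk = rng.poisson(200, n)
        tg = rng.poisson(6.0, n)
        other = rng.poisson(10.0, n)
        dense = np.column_stack([lib_bulk, tg, other])
        ids = [f"c{i}" for i in range(n)]
        cm = _cm(dense, genes=["Bulk", "hSNCA", "Other"],
                 panel=["base", "custom", "custom"], ids=ids)
        return cm, pd.DataFrame({"cell_id": ids})

    def test_transgene_on_itself_positive(self, rng):
        cm, cells = self._dataset(rng)
        res = glm_vs_hsnca(cm, cells, ["hSNCA"], scale_factor=100.0)
        assert res.loc["hSNCA", "beta"] > 0
        assert res.loc["hSNCA", "q"] < 1e-6

    def test_independent_gene_not_significant(self, rng):
        cm, cells = self._dataset(rng)
        res = glm_vs_hsnca(cm, cells, ["Other"], scale_factor=100.0)
        assert res.loc["Other", "q"] > 0.01

    def test_gaussian_family_flag(self, rng):
        cm, cells = self._dataset(rng)
        res = glm_vs_hsnca(cm, cells, ["Other"], scale_factor=100.0, family="gaussian")
        assert "beta" in res.columns and np.isfinite(res.loc["Other", "beta"])

    def test_q_at_least_p(self, rng):
        cm, cells = self._dataset(rng)
        res = glm_vs_hsnca(cm, cells, ["hSNCA", "Other"], scale_factor=100.0)
        assert (res["q"] >= res["p"] - 1e-15).all()
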