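"""Normalization identities, annotation, and cross-platform comparison."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spatipath.expression import (
    ExpressionMatrix,
    annotate_by_reference,
    compare_platforms_genewise,
    compare_platforms_profiles,
    lognormalize,
    mean_expression,
    scale_profiles,
)
from spatipath.io_formats import CountMatrix


def _cm(dense, genes=None):
    dense = np.asarray(dense)
    return CountMatrix(
        sp.csr_matrix(dense),
        [f"c{i}" for i in range(dense.shape[0])],
        genes or [f"g{j}" for j in range(dense.shape[1])],
    )


class TestLognormalize:
    def test_formula_value(self):
        expr = lognormalize(_cm([[1, 0, 3]]), scale_factor=1e4)
        assert expr.values[0, 0] == pytest.approx(np.log(1 + 2500), abs=1e-10)
        assert expr.values[0, 0] == pytest.approx(7.8244, abs=1e-4)

    def test_zero_count_maps_to_zero(self):
        expr = lognormalize(_cm([[1, 0, 3]]))
        assert expr.values[0, 1] == 0.0

    def test_expm1_inverse_identity(self, rng):
        dense = rng.poisson(2.0, size=(40, 15))
        dense[dense.sum(axis=1) == 0, 0] = 1
        cm = _cm(dense)
        expr = lognormalize(cm, scale_factor=1e4)
        lib = cm.library_sizes()[:, None]
        assert np.allclose(np.expm1(expr.values), dense / lib * 1e4, atol=1e-12, rtol=1e-12)

    def test_zero_library_rejected_by_name(self):
        with pytest.raises(ValueError, match="c1"):
            lognormalize(_cm([[1, 2], [0, 0]]))

    def test_scale_factor_doubling_identity(self, rng):
        """Doubling scale_factor maps v -> ln(1 + 2*expm1(v)) exactly."""
        dense = rng.poisson(3.0, size=(20, 10)) + 1
        v1 = lognormalize(_cm(dense), 1e4).values
        v2 = lognormalize(_cm(dense), 2e4).values
        assert np.allclose(v2, np.log1p(2 * np.expm1(v1)), atol=1e-12)


class TestMeanExpression:
    def _expr(self, values, ids=None):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            values, ids or [f"c{i}" for i in range(len(values))],
            [f"g{j}" for j in range(values.shape[1])], "lognorm", 1e4,
        )

    def test_single_cell_group_is_expm1(self):
        expr = self._expr([[np.log(3.0)]])
        out = mean_expression(expr, ["T"])
        assert out.loc["T", "g0"] == pytest.approx(2.0)

    def test_two_cell_hand_arithmetic(self):
        expr = self._expr([[np.log(2.0)], [np.log(4.0)]])
        out = mean_expression(expr, ["T", "T"])
        assert out.loc["T", "g0"] == pytest.approx(2.0)  # (1 + 3)/2

    def test_lognorm_mean_mode(self):
        expr = self._expr([[2.0], [4.0]])
        out = mean_expression(expr, ["T", "T"], mode="lognorm_mean")
        assert out.loc["T", "g0"] == pytest.approx(3.0)

    def test_cell_order_invariance(self, rng):
        vals = rng.normal(size=(30, 5))
        groups = rng.choice(["a", "b", "c"], size=30)
        expr = self._expr(vals)
        perm = rng.permutation(30)
        expr_p = self._expr(vals[perm])
        pd.testing.assert_frame_equal(
            mean_expression(expr, groups), mean_expression(expr_p, groups[perm])
        )


class TestAnnotate:
    def _reference(self):
        ref = pd.DataFrame(
            [[5.0, 0.1, 0.1], [0.1, 5.0, 0.1], [0.1, 0.1, 5.0]],
            index=["A", "B", "C"], columns=["m1", "m2", "m3"],
        )
        return scale_profiles(ref)

    def test_exact_profile_match(self):
        ref = self._reference()
        expr = ExpressionMatrix(
            ref.loc[["B"]].to_numpy(), ["cell1"], list(ref.columns), "lognorm"
        )
        labels = annotate_by_reference(expr, ref)
        assert labels.loc["cell1"] == "B"

    def test_all_zero_cell_unassigned(self):
        ref = self._reference()
        expr = ExpressionMatrix(np.zeros((1, 3)), ["z"], list(ref.columns), "lognorm")
        assert annotate_by_reference(expr, ref).loc["z"] is None

    def test_gene_order_permutation_invariance(self, rng):
        ref = self._reference()
        vals = rng.normal(size=(20, 3))
        expr = ExpressionMatrix(vals, [f"c{i}" for i in range(20)], list(ref.columns), "lognorm")
        perm = [2, 0, 1]
        expr_p = ExpressionMatrix(
            vals[:, perm], expr.cell_ids, [expr.gene_names[i] for i in perm], "lognorm"
        )
        pd.testing.assert_series_equal(
            annotate_by_reference(expr, ref), annotate_by_reference(expr_p, ref)
        )

    def test_needs_two_types(self):
        ref = self._reference().iloc[:1]
        expr = ExpressionMatrix(np.ones((1, 3)), ["c"], list(ref.columns), "lognorm")
        with pytest.raises(ValueError, match=">= 2"):
            annotate_by_reference(expr, ref)


class TestScaleProfiles:
    def test_idempotent(self, rng):
        prof = pd.DataFrame(rng.normal(2, 3, size=(6, 10)))
        once = scale_profiles(prof)
        twice = scale_profiles(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)
        assert np.allclose(once.mean(axis=0), 0, atol=1e-12)


class TestComparePlatforms:
    def _profiles(self, rng, n_types=8, n_genes=20):
        return pd.DataFrame(
            rng.normal(size=(n_types, n_genes)),
            index=[f"t{i}" for i in range(n_types)],
            columns=[f"g{j}" for j in range(n_genes)],
        )

    def test_self_comparison_r2_one(self, rng):
        prof = self._profiles(rng)
        res = compare_platforms_genewise(prof, prof)
        assert np.allclose(res["r2"], 1.0, atol=1e-9)

    def test_negated_profiles_slope_minus_one(self, rng):
        prof = self._profiles(rng)
        res = compare_platforms_genewise(prof, -prof)
        assert np.allclose(res["r2"], 1.0, atol=1e-9)
        assert np.allclose(res["slope"], -1.0, atol=1e-9)

    def test_too_few_types_rejected(self, rng):
        prof = self._profiles(rng, n_types=2)
        with pytest.raises(ValueError, match="3 shared"):
            compare_platforms_genewise(prof, prof)

    def test_mean_r2_decreases_with_noise(self, rng):
        prof = self._profiles(rng, n_types=8, n_genes=100)
        means = []
        for sigma in (0.1, 0.5, 1.0):
            r2s = [
                compare_platforms_genewise(
                    prof, prof + rng.normal(0, sigma, size=prof.shape)
                )["r2"].mean()
                for _ in range(5)
            ]
            means.append(np.mean(r2s))
        assert means[0] > means[1] > means[2]

    def test_profile_matrix_identity_diagonal(self, rng):
        prof = self._profiles(rng)
        corr = compare_platforms_profiles(prof, prof)
        assert np.allclose(np.diag(corr), 1.0, atol=1e-12)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)

    def test_orthogonal_profiles_near_zero_offdiag(self, rng):
        prof_a = self._profiles(rng, n_types=6, n_genes=200)
        prof_b = self._profiles(rng, n_types=6, n_genes=200)
        corr = compare_platforms_profiles(prof_a, prof_b)
        assert abs(corr.to_numpy().mean()) < 0.1

    def test_zero_variance_profile_missing(self, rng):
        prof = self._profiles(rng, n_types=3)
        flat = prof.copy()
        flat.iloc[0] = 1.0
        corr = compare_platforms_profiles(flat, prof)
        assert corr.iloc[0].isna().all()
        assert corr.iloc[1:].notna().all().all()
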