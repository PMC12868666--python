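"""Distributional and determinism properties of the tissue simulator."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import single_type_config
from spatipath.expression import lognormalize, mean_expression
from spatipath.synthetic_data import (
    GeneSpec,
    PathologyParams,
    _place_cells,
    assign_pathology,
    default_config,
    generate_sample,
    generate_tissue,
    logit,
    mechanism_config,
    render_if_image,
    sample_counts,
)


def _make_cells(cfg, n_per_type, prefix="c"):
    names = [t.name for t in cfg.cell_types]
    libs = {t.name: t.mean_library_size for t in cfg.cell_types}
    df = pd.DataFrame({"cell_type": np.repeat(names, n_per_type)})
    df["mean_lib"] = df["cell_type"].map(libs)
    df["cell_id"] = [f"{prefix}{i}" for i in range(len(df))]
    return df


class TestGenerateTissue:
    def test_same_seed_identical_bundles(self, small_config):
        b1, t1 = generate_tissue(small_config, seed=5, render_images=True)
        b2, t2 = generate_tissue(small_config, seed=5, render_images=True)
        assert len(b1) == len(b2) == 4  # 2 genotypes x 2 sexes x 1
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        for a, b in zip(b1, b2):
            assert (a.counts.counts != b.counts.counts).nnz == 0
            assert np.array_equal(a.image, b.image)
            assert np.allclose(a.affine.matrix, b.affine.matrix)
            assert [p.vertices for p in a.polygons] == [p.vertices for p in b.polygons]

    def test_cell_count_poisson_bound(self):
        cfg = single_type_config()
        rng = np.random.default_rng(3)
        counts = [len(_place_cells(cfg, rng)) for _ in range(5)]
        expected = 300.0 * 0.4 * 0.4  # density x area in mm^2
        sigma = np.sqrt(expected)
        assert abs(np.mean(counts) - expected) < 4 * sigma

    def test_infeasible_density_raises(self):
        cfg = single_type_config(
            cell_types=(
                replace(single_type_config().cell_types[0], density_per_mm2=20000.0),
            ),
            width_um=100.0,
            height_um=100.0,
        )
        with pytest.raises(RuntimeError, match="lower density"):
            _place_cells(cfg, np.random.default_rng(0))

    def test_non_tg_has_zero_transgene(self, small_config):
        bundles, _ = generate_tissue(small_config, seed=2, render_images=False)
        for b in bundles:
            h = b.counts.counts[:, b.counts.gene_index("hSNCA")]
            if b.genotype == "non_tg":
                assert h.sum() == 0
            else:
                assert h.sum() > 0


class TestSampleCounts:
    def test_poisson_limit_variance(self, rng):
        cfg = single_type_config()  # both genes dispersion 0
        cells = _make_cells(cfg, 10000)
        cells["mean_lib"] = 100.0
        cfg0 = replace(cfg, library_size_cv=0.0)
        cm = sample_counts(cells, cfg0, rng)
        col = np.asarray(cm.counts[:, 0].todense()).ravel()  # mu = 10
        assert 0.9 <= col.var() / col.mean() <= 1.1

    def test_zero_rate_gene_all_zero(self, rng):
        cfg = single_type_config(genes=(
            GeneSpec("G1", "base", {"T": 0.0}),
            GeneSpec("G2", "base", {"T": 5.0}),
        ))
        cm = sample_counts(_make_cells(cfg, 500), cfg, rng)
        assert cm.counts[:, 0].sum() == 0

    def test_transgene_higher_in_excitatory_neurons(self, rng):
        """Planted rates order mean normalized hSNCA: ExN above InN."""
        cfg = default_config()
        cells = _make_cells(cfg, 400)
        cm = sample_counts(cells, cfg, rng, genotype="tg")
        me = mean_expression(lognormalize(cm), cells["cell_type"].to_numpy())
        exn = [t.name for t in cfg.cell_types if t.cell_class == "ExN"]
        assert me.loc[exn, "hSNCA"].min() > me.loc["InN", "hSNCA"]

    def test_genotype_spike_multiplies_rate(self, rng):
        cfg = default_config(spike_genotype={"Filler01": 2.0})
        cells = _make_cells(cfg, 2000)
        base = sample_counts(cells, default_config(), rng, genotype="tg")
        spiked = sample_counts(cells, cfg, np.random.default_rng(1), genotype="tg")
        j = base.gene_index("Filler01")
        ratio = spiked.counts[:, j].sum() / max(base.counts[:, j].sum(), 1)
        assert 3.0 < ratio < 5.5  # ~4-fold, modulo normalization drag


class TestAssignPathology:
    def test_flat_logistic_rate_recovered(self, rng):
        cfg = single_type_config(pathology=PathologyParams(logit(0.3), 0.0, 0.0))
        cells = _make_cells(cfg, 5000)
        psyn = assign_pathology(cells, np.zeros(5000), np.zeros(5000), cfg, rng)
        sigma = np.sqrt(0.3 * 0.7 / 5000)
        assert abs(psyn.mean() - 0.3) < 4 * sigma

    def test_minus_infinity_intercept_no_positives(self, rng):
        cfg = single_type_config(pathology=PathologyParams(-1e9, 0.0, 0.0))
        cells = _make_cells(cfg, 1000)
        assert assign_pathology(cells, np.zeros(1000), np.zeros(1000), cfg, rng).sum() == 0

    def test_non_tg_always_negative(self, rng):
        cfg = single_type_config(pathology=PathologyParams(10.0, 0.0, 0.0))
        cells = _make_cells(cfg, 100)
        psyn = assign_pathology(
            cells, np.zeros(100), np.zeros(100), cfg, rng, genotype="non_tg"
        )
        assert psyn.sum() == 0

    def test_kinase_gradient_orders_vulnerability(self, rng):
        """With beta_plk2 > 0, per-type pSyn rates track mean Plk2 rates."""
        cfg = mechanism_config(beta_plk2=1.0)
        cells = _make_cells(cfg, 400)
        cm = sample_counts(cells, cfg, rng, genotype="tg")
        e = lognormalize(cm)
        psyn = assign_pathology(cells, e.gene("hSNCA"), e.gene("Plk2"), cfg, rng)
        df = pd.DataFrame({"type": cells["cell_type"], "psyn": psyn, "plk2": e.gene("Plk2")})
        per_type = df.groupby("type").agg(pct=("psyn", "mean"), plk2=("plk2", "mean"))
        rho = stats.spearmanr(per_type["plk2"], per_type["pct"]).statistic
        assert rho > 0


class TestRenderImage:
    def test_no_positives_all_background(self, rng):
        cfg = single_type_config()
        cfg = replace(cfg, imaging=replace(cfg.imaging, noise_sd=0.0))
        cells = _make_cells(cfg, 50)
        cells["x_um"] = rng.uniform(10, 390, 50)
        cells["y_um"] = rng.uniform(10, 390, 50)
        img, _, _ = render_if_image(cells, np.zeros(50, bool), cfg, rng)
        assert (img == cfg.imaging.background_level).all()

    def test_identity_affine_centroid_within_1px(self, small_config, rng):
        """Noise-free, unperturbed: detected centroid hits the planted point."""
        from spatipath.pathology_overlay import map_centroids, threshold_inclusions

        cfg = replace(
            small_config, imaging=replace(small_config.imaging, noise_sd=0.0)
        )
        bundle, truth, affine = generate_sample(
            cfg, "s", "tg", "F", rng, perturb_affine=False
        )
        inc = map_centroids(threshold_inclusions(bundle.image, 100, 4), affine)
        planted = truth.loc[truth["psyn"], ["incl_x_um", "incl_y_um"]].to_numpy()
        detected = inc.centroids_spatial()
        assert len(detected) == len(planted)
        for p in planted:
            assert np.min(np.hypot(*(detected - p).T)) <= cfg.imaging.pixel_size_um

    def test_perturbed_affine_recovers_planted_centroids(self, small_config, rng):
        """Rotation/translation: stored affine maps detections back within 1 px."""
        from spatipath.pathology_overlay import map_centroids, threshold_inclusions

        bundle, truth, affine = generate_sample(
            small_config, "s", "tg", "M", rng, perturb_affine=True
        )
        inc = map_centroids(threshold_inclusions(bundle.image, 100, 4), affine)
        planted = truth.loc[truth["psyn"], ["incl_x_um", "incl_y_um"]].to_numpy()
        detected = inc.centroids_spatial()
        assert len(detected) == len(planted)
        for p in planted:
            assert np.min(np.hypot(*(detected - p).T)) <= small_config.imaging.pixel_size_um
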