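"""Spatial analysis: thresholding, subregion fractions, eigen-image PCA
identities, local normalization against hand computation, and cluster
assignment against a brute-force Pearson argmax oracle."""

import numpy as np
import pandas as pd
import pytest

from blapipe import simdata, spatialmap
from blapipe.markersel import ClusterProfile
from blapipe.simdata import ParameterError
from blapipe.spatialmap import (
    SpatialConfig,
    assign_cells_to_clusters,
    call_positive_cells,
    compute_eigen_images,
    local_normalize,
    subregion_correlation,
    subregion_fractions,
)
from conftest import pearson


def cell_table(values: dict, section="anterior", subregion="aLA", coords=None):
    """Minimal FishCellTable from {gene: [values per cell]}."""
    n = len(next(iter(values.values())))
    if coords is None:
        coords = [(100.0 * i, 0.0) for i in range(n)]
    df = pd.DataFrame(
        {
            "cell_id": [f"f{i}" for i in range(n)],
            "section": section,
            "subregion": subregion,
            "x_um": [c[0] for c in coords],
            "y_um": [c[1] for c in coords],
        }
    )
    for g, v in values.items():
        df[g] = np.asarray(v, dtype=float)
    return df


class TestPositiveCalling:
    def test_fixed_threshold(self):
        cells = cell_table({"gA": [1.0, 3.0]})
        cfg = SpatialConfig(threshold_method="fixed", fixed_thresholds={"gA": 2.0})
        out = call_positive_cells(cells, cfg)
        assert list(out["pos_gA"]) == [False, True]
        assert out.attrs["thresholds"]["gA"] == 2.0

    def test_all_below_threshold_gives_zero_positives(self):
        cells = cell_table({"gA": [0.5, 0.2, 0.1]})
        cfg = SpatialConfig(threshold_method="fixed", fixed_thresholds={"gA": 5.0})
        with pytest.warns(UserWarning):
            out = call_positive_cells(cells, cfg)
        assert not out["pos_gA"].any()

    def test_otsu_separates_bimodal_values(self):
        cells = cell_table({"gA": [1, 1, 1, 9, 9, 9]})
        out = call_positive_cells(cells, SpatialConfig(threshold_method="otsu"))
        thr = out.attrs["thresholds"]["gA"]
        assert 1.0 < thr < 9.0
        assert out["pos_gA"].sum() == 3

    def test_otsu_matches_between_class_variance_search(self):
        # exhaustive threshold search maximizing between-class variance
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.uniform(0, 2, 40), rng.uniform(8, 12, 20)])
        cells = cell_table({"gA": vals})
        out = call_positive_cells(cells, SpatialConfig(threshold_method="otsu"))
        logv = np.log1p(vals)
        best, best_sep = None, -1.0
        for t in np.unique(logv)[:-1]:
            lo, hi = logv[logv <= t], logv[logv > t]
            sep = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
            if sep > best_sep:
                best, best_sep = t, sep
        n_pos_oracle = int((logv > best).sum())
        assert out["pos_gA"].sum() == n_pos_oracle

    def test_constant_gene_warns_threshold_zero(self):
        cells = cell_table({"gA": [0.0, 0.0, 0.0]})
        with pytest.warns(UserWarning):
            out = call_positive_cells(cells, SpatialConfig(threshold_method="otsu"))
        assert out.attrs["thresholds"]["gA"] == 0.0


class TestSubregionFractions:
    def test_hand_counts(self):
        cells = cell_table({"gA": [1.0] * 4 + [0.0] * 6, "gB": [1.0] * 10}, subregion="aLA")
        cfg = SpatialConfig(threshold_method="fixed", fixed_thresholds={"gA": 0.5, "gB": 0.5})
        fr = subregion_fractions(call_positive_cells(cells, cfg))
        assert fr.fractions.loc["aLA", "gA"] == pytest.approx(40.0)
        assert fr.fractions.loc["aLA", "gB"] == pytest.approx(100.0)

    def test_multipositive_cell_counts_once_per_gene(self):
        # one cell positive for two genes in a 1-cell subregion: 100 + 100
        cells = cell_table({"gA": [2.0], "gB": [2.0]})
        cfg = SpatialConfig(threshold_method="fixed", fixed_thresholds={"gA": 1.0, "gB": 1.0})
        fr = subregion_fractions(call_positive_cells(cells, cfg))
        assert fr.fractions.loc["aLA"].sum() == pytest.approx(200.0)

    def test_requires_flags(self):
        with pytest.raises(ParameterError):
            subregion_fractions(cell_table({"gA": [1.0]}))

    def test_order_invariance(self, profiles5):
        layout = simdata.layout_one_per_subregion(profiles5.clusters)
        cells, _ = simdata.gen_fish_dataset(profiles5, layout, 200, noise_sd=2.0, seed=31)
        pos = call_positive_cells(cells, SpatialConfig())
        shuffled = pos.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = subregion_fractions(pos).fractions.sort_index()
        b = subregion_fractions(shuffled).fractions.sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestSubregionCorrelation:
    def _fractions(self, mat, subs):
        fr = pd.DataFrame(mat, index=subs, columns=[f"g{i}" for i in range(len(mat[0]))])
        return spatialmap.SubregionFractions(fr, pd.Series(10, index=subs), [])

    def test_identical_and_reversed_vectors(self):
        fr = self._fractions([[10, 20, 30], [10, 20, 30], [30, 20, 10]], ["a", "b", "c"])
        corr, order = subregion_correlation(fr)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(8)
        mat = rng.uniform(0, 100, size=(3, 6))
        fr = self._fractions(mat, ["a", "b", "c"])
        corr, _ = subregion_correlation(fr)
        for i, si in enumerate("abc"):
            for j, sj in enumerate("abc"):
                assert corr.loc[si, sj] == pytest.approx(pearson(mat[i], mat[j]))

    def test_zero_variance_row_reported_missing(self):
        fr = self._fractions([[5, 5, 5], [10, 20, 30], [30, 20, 10]], ["a", "b", "c"])
        corr, order = subregion_correlation(fr)
        assert np.isnan(corr.loc["a", "b"])
        assert "a" not in order and set(order) == {"b", "c"}


class TestEigenImages:
    def _posed(self, values, coords, section="anterior"):
        cells = cell_table(values, coords=coords, section=section)
        thr = {g: 0.5 for g in values}
        return call_positive_cells(
            cells, SpatialConfig(threshold_method="fixed", fixed_thresholds=thr)
        )

    def test_single_nonzero_gene_is_one_component(self):
        coords = [(i * 60.0, (i % 3) * 60.0) for i in range(12)]
        cells = self._posed({"gA": [1.0] * 12, "gB": [0.0] * 12}, coords)
        with pytest.warns(UserWarning):
            res = compute_eigen_images(cells, SpatialConfig(), "anterior")
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_identical_maps_collapse_to_pc1(self):
        coords = [(i * 60.0, (i * 37) % 300) for i in range(20)]
        vals = [1.0 if i % 2 else 0.0 for i in range(20)]
        cells = self._posed({"gA": vals, "gB": vals}, coords)
        res = compute_eigen_images(cells, SpatialConfig(), "anterior")
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_sorted_sum_to_one_and_reconstruct(self, profiles5):
        layout = simdata.layout_one_per_subregion(profiles5.clusters)
        cells, _ = simdata.gen_fish_dataset(profiles5, layout, 300, noise_sd=2.0, seed=32)
        pos = call_positive_cells(cells, SpatialConfig())
        res = compute_eigen_images(pos, SpatialConfig(), "anterior")
        vf = res.variance_fraction
        assert vf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(vf) <= 1e-12).all() and (vf >= 0).all()
        # reconstruction from all PCs reproduces the centred pixel matrix
        from scipy.ndimage import gaussian_filter

        scores = res.score_maps.reshape(len(vf), -1).T
        recon = scores @ res.loadings.T
        ny, nx = res.shape_px
        x0, y0 = res.origin_um
        sec = pos[pos["section"] == "anterior"]
        rasters = np.zeros((len(res.genes), ny, nx))
        for gi, g in enumerate(res.genes):
            sel = sec[sec[f"pos_{g}"].to_numpy(bool)]
            ix = np.minimum(((sel["x_um"] - x0) / res.pixel_size_um).astype(int), nx - 1)
            iy = np.minimum(((sel["y_um"] - y0) / res.pixel_size_um).astype(int), ny - 1)
            np.add.at(rasters[gi], (iy, ix), 1.0)
            rasters[gi] = gaussian_filter(rasters[gi], 1.0)
        X = rasters.reshape(len(res.genes), -1).T
        Xc = X - X.mean(axis=0, keepdims=True)
        assert np.allclose(recon, Xc, atol=1e-8)


class TestLocalNormalize:
    def test_isolated_cell_keeps_own_values(self):
        coords = [(0.0, 0.0), (500.0, 0.0), (1000.0, 0.0)]
        cells = cell_table({"gA": [1.0, 5.0, 9.0]}, coords=coords)
        feats = local_normalize(cells, SpatialConfig(neighbor_radius_um=50))
        sums = np.array([1.0, 5.0, 9.0])  # no neighbors within 50 um
        z = (sums - sums.mean()) / sums.std()
        assert np.allclose(feats["gA"].to_numpy(), z)

    def test_identical_values_give_zero_z(self):
        cells = cell_table({"gA": [2.0, 2.0, 2.0]})
        feats = local_normalize(cells, SpatialConfig())
        assert np.allclose(feats["gA"], 0.0)

    def test_collinear_cells_hand_computation(self):
        # 3 cells 40 um apart: neighborhoods {0,1}, {0,1,2}, {1,2}
        coords = [(0.0, 0.0), (40.0, 0.0), (80.0, 0.0)]
        v = np.array([1.0, 2.0, 4.0])
        cells = cell_table({"gA": v}, coords=coords)
        feats = local_normalize(cells, SpatialConfig(neighbor_radius_um=50))
        sums = np.array([v[0] + v[1], v.sum(), v[1] + v[2]])
        z = (sums - sums.mean()) / sums.std()
        assert np.allclose(feats["gA"].to_numpy(), z)

    def test_tiny_section_left_undefined(self):
        cells = cell_table({"gA": [3.0]})
        feats = local_normalize(cells, SpatialConfig())
        assert np.isnan(feats["gA"]).all()


class TestAssignment:
    def _profile(self):
        return ClusterProfile.from_aggregate(
            ["cl1", "cl2"],
            ["gA", "gB", "gC"],
            [[10.0, 1.0, 1.0], [1.0, 10.0, 5.0]],
        )

    def test_exact_profile_copy_scores_one(self):
        prof = self._profile()
        feats = pd.DataFrame(
            {"cell_id": ["x"], "gA": [prof.scaled[1, 0] * 3 + 1],
             "gB": [prof.scaled[1, 1] * 3 + 1], "gC": [prof.scaled[1, 2] * 3 + 1]}
        )
        res = assign_cells_to_clusters(feats, prof)
        assert res.assignments.loc[0, "cluster"] == "cl2"
        assert res.assignments.loc[0, "r"] == pytest.approx(1.0)

    def test_constant_vector_unassigned(self):
        prof = self._profile()
        feats = pd.DataFrame({"cell_id": ["x"], "gA": [2.0], "gB": [2.0], "gC": [2.0]})
        res = assign_cells_to_clusters(feats, prof)
        assert pd.isna(res.assignments.loc[0, "cluster"])
        assert res.n_unassigned == 1

    def test_matches_brute_force_argmax_oracle(self, profiles5):
        rng = np.random.default_rng(9)
        n = 400
        F = rng.uniform(0, 5, size=(n, len(profiles5.genes)))
        feats = pd.DataFrame(F, columns=profiles5.genes)
        feats.insert(0, "cell_id", [f"c{i}" for i in range(n)])
        res = assign_cells_to_clusters(feats, profiles5)
        clusters = sorted(profiles5.clusters)
        rows = {cl: profiles5.row(cl) for cl in clusters}
        for i in range(n):
            rs = [pearson(F[i], rows[cl]) for cl in clusters]
            assert res.assignments.loc[i, "cluster"] == clusters[int(np.argmax(rs))]
            assert res.assignments.loc[i, "r"] == pytest.approx(max(rs))

    def test_gene_mismatch_rejected(self):
        prof = self._profile()
        feats = pd.DataFrame({"cell_id": ["x"], "gA": [1.0], "gB": [2.0]})
        with pytest.raises(Exception):
            assign_cells_to_clusters(feats, prof)

    def test_recovery_from_synthetic_fish(self, profiles5):
        layout = simdata.layout_one_per_subregion(profiles5.clusters)
        cells, truth = simdata.gen_fish_dataset(profiles5, layout, 300, noise_sd=0.0, seed=33)
        genes = list(profiles5.genes)
        feats = cells[["cell_id"] + genes]
        res = assign_cells_to_clusters(feats, profiles5)
        acc = (res.assignments["cluster"].to_numpy() == truth.cells["cluster"].to_numpy()).mean()
        assert acc == 1.0
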