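"""Quantification pipeline: masks, gating, background, deconvolution,
cluster metrics, nearest-neighbor distances, aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from azphys.errors import InvalidParameterError, WindowError
from azphys.params import ImageSceneParams, PipelineParams
from azphys.sted_quant import (AzMask, ClusterSet, aggregate_per_animal,
                               deconvolve_sted, estimate_background,
                               gate_azs, integrate_az_intensity,
                               intensity_distribution_tables, make_az_masks,
                               nearest_neighbor_distances, quantify_field,
                               segment_clusters, unsharp_binarize)
from azphys.synth_imaging import StedImageSet, render_sted_field


def disk_image(shape, centers, radius, value, background=0.0):
    img = np.full(shape, background)
    for c in centers:
        rr, cc = np.mgrid[:shape[0], :shape[1]]
        img[(rr - c[0]) ** 2 + (cc - c[1]) ** 2 <= radius**2] = value
    return img


class TestUnsharpBinarize:
    def test_ten_disks_ten_components(self):
        centers = [(r, c) for r in (40, 120, 200, 280, 360)
                   for c in (60, 200)]
        img = disk_image((420, 300), centers, 12, 100.0, background=1.0)
        mask = unsharp_binarize(img, 5.0, 1.0, 2000.0, 10.0)
        from skimage.measure import label
        assert label(mask, connectivity=2).max() == 10

    def test_constant_image_empty(self):
        assert not unsharp_binarize(np.full((64, 64), 7.0), 5, 1, 100,
                                    10).any()
        assert not unsharp_binarize(np.zeros((64, 64)), 5, 1, 100, 10).any()

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        img = disk_image((200, 200), [(60, 60), (140, 140)], 15, 80.0,
                         background=2.0) + rng.normal(0, 0.5, (200, 200))
        m1 = unsharp_binarize(img, 5, 1, 500, 10)
        m2 = unsharp_binarize(img * 17.0, 5, 1, 500, 10)
        assert np.array_equal(m1, m2)

    def test_min_area_removal(self):
        img = disk_image((128, 128), [(64, 64)], 10, 50.0)
        img[10, 10] = 50.0   # single-pixel speck
        mask = unsharp_binarize(img, 3, 1, 1000, 10.0)
        assert not mask[10, 10]
        assert mask[64, 64]


class TestAzMasks:
    def test_label_count_matches_truth(self, clean_scene):
        img, truth = render_sted_field(clean_scene, "WT", seed=4)
        az = make_az_masks(img, PipelineParams())
        assert az.n_azs == len(truth.azs)

    def test_disk_area_recovered(self, clean_scene):
        """Mask area of a clean rendered pedestal disk matches pi r^2
        within a pixel-perimeter tolerance."""
        img, truth = render_sted_field(clean_scene, "WT", seed=4)
        az = make_az_masks(img, PipelineParams())
        px = clean_scene.pixel_nm
        margin = clean_scene.pedestal_margin_nm
        truth_centers = np.array([a["center_px"] for a in truth.azs])
        for _, row in az.table.iterrows():
            d = np.hypot(*(truth_centers
                           - np.array([row["centroid_row"],
                                       row["centroid_col"]])).T)
            a = truth.azs[int(d.argmin())]
            r_nm = a["radius_px"] * px + margin
            want = np.pi * r_nm**2
            tol = 2 * np.pi * r_nm * 1.5 * px   # ~1.5 px perimeter band
            assert abs(row["area_nm2"] - want) < tol

    def test_merged_azs_single_label(self):
        """Two overlapping bright disks produce one connected label."""
        munc = disk_image((256, 256), [(128, 110), (128, 130)], 18, 60.0,
                          background=1.0)
        imgset = StedImageSet(munc.astype(np.uint16),
                              np.zeros((256, 256), np.uint16),
                              np.zeros((256, 256), np.uint16),
                              np.zeros((256, 256), np.uint16), 10.0)
        az = make_az_masks(imgset, PipelineParams())
        assert az.n_azs == 1


class TestGating:
    def test_small_terminal_azs_excluded(self, small_scene):
        """AZs placed in sub-threshold VGLUT1 blobs fail the terminal-size
        gate; AZs in the mossy-fiber bouton pass."""
        img, truth = render_sted_field(small_scene, "WT", seed=2)
        az = gate_azs(make_az_masks(img, PipelineParams()), img,
                      PipelineParams())
        small_centers = np.array([a["center_px"] for a in truth.azs
                                  if a["in_small_terminal"]])
        large_centers = np.array([a["center_px"] for a in truth.azs
                                  if not a["in_small_terminal"]])
        assert len(small_centers) and len(large_centers)
        for _, row in az.table.iterrows():
            c = np.array([row["centroid_row"], row["centroid_col"]])
            d_small = (np.min(np.hypot(*(small_centers - c).T))
                       if len(small_centers) else np.inf)
            d_large = (np.min(np.hypot(*(large_centers - c).T))
                       if len(large_centers) else np.inf)
            if d_small < d_large:
                assert not row["large_terminal"]
            else:
                assert bool(row["gated"])

    def test_no_psd_no_gate(self, small_scene):
        from dataclasses import replace

        scene = replace(small_scene, psd_intensity=0.0, noise_model="none")
        img, _ = render_sted_field(scene, "WT", seed=2)
        az = gate_azs(make_az_masks(img, PipelineParams()), img,
                      PipelineParams())
        assert not az.table["gated"].any()

    def test_gating_idempotent(self, small_scene):
        img, _ = render_sted_field(small_scene, "WT", seed=3)
        p = PipelineParams()
        once = gate_azs(make_az_masks(img, p), img, p)
        twice = gate_azs(once, img, p)
        pd.testing.assert_frame_equal(once.table, twice.table)


class TestBackground:
    def make_az(self, shape=(256, 256)):
        labels = np.zeros(shape, int)
        labels[100:140, 100:140] = 1
        table = pd.DataFrame([{"az_label": 1, "area_nm2": 1600 * 100.0,
                               "centroid_row": 120.0,
                               "centroid_col": 120.0}])
        return AzMask(labels, 10.0, table)

    def test_flat_background(self):
        az = self.make_az()
        img = np.full((256, 256), 10.0)
        img[az.labels == 1] += 500
        assert estimate_background(img, az) == 10.0

    def test_gradient_background_median(self):
        az = self.make_az()
        img = np.tile(np.linspace(0, 20, 256), (256, 1))
        bg = estimate_background(img, az)
        assert 5.0 < bg < 15.0

    def test_all_az_image_errors(self):
        labels = np.ones((64, 64), int)
        az = AzMask(labels, 10.0, pd.DataFrame(
            [{"az_label": 1, "area_nm2": 1.0, "centroid_row": 32.0,
              "centroid_col": 32.0}]))
        with pytest.raises(WindowError):
            estimate_background(np.ones((64, 64)), az)

    def test_integral_arithmetic(self):
        """Uniform 100 counts over a 200 px AZ at background 10 gives
        (100-10)*200 = 18,000."""
        labels = np.zeros((64, 64), int)
        labels[10:20, 10:30] = 1
        az = AzMask(labels, 10.0, pd.DataFrame(
            [{"az_label": 1, "area_nm2": 200 * 100.0, "centroid_row": 15.0,
              "centroid_col": 20.0}]))
        img = np.full((64, 64), 10.0)
        img[labels == 1] = 100.0
        value, clamped = integrate_az_intensity(img, az, 1, 10.0)
        assert value == 18000.0 and not clamped
        value, clamped = integrate_az_intensity(np.full((64, 64), 10.0), az,
                                                1, 10.0)
        assert value == 0.0 and not clamped
        value, clamped = integrate_az_intensity(np.full((64, 64), 5.0), az,
                                                1, 10.0)
        assert value == 0.0 and clamped


class TestDeconvolution:
    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        img = disk_image((256, 256), [(128, 128)], 30, 50.0, background=2.0)
        img = ndimage.gaussian_filter(img, 3) + rng.normal(5, 0.5,
                                                           (256, 256))
        img = np.maximum(img, 0)
        dec = deconvolve_sted(img, 10.0, 40.0, 20)
        assert dec.sum() == pytest.approx(img.sum(), rel=0.01)
        assert dec.min() >= 0

    def test_psf_input_concentrates(self):
        """Deconvolving the PSF itself concentrates >= 90% of the mass
        within one sigma of the center."""
        sigma_px = 4.0
        rr, cc = np.mgrid[:129, :129]
        img = np.exp(-((rr - 64.0) ** 2 + (cc - 64.0) ** 2)
                     / (2 * sigma_px**2))
        dec = deconvolve_sted(img, 10.0, sigma_nm=40.0, iterations=25)
        within = (rr - 64.0) ** 2 + (cc - 64.0) ** 2 <= sigma_px**2
        assert dec[within].sum() / dec.sum() >= 0.90

    def test_single_peak_stays_put(self):
        img = np.full((65, 65), 1e-3)
        img[32, 40] = 100.0
        dec = deconvolve_sted(img, 10.0, 40.0, 10)
        assert np.unravel_index(np.argmax(dec), dec.shape) == (32, 40)

    def test_resolution_doubling(self):
        """Two spots 80 nm apart under sigma = 40 nm blur merge in the raw
        binarization but split after matched-kernel deconvolution (the
        dip develops slowly for a 2-sigma pair: ~200 iterations)."""
        img = np.zeros((256, 256))
        img[128, 124] = 1000.0
        img[128, 132] = 1000.0   # 8 px = 80 nm apart
        blurred = ndimage.gaussian_filter(img, 4.0) * 1e3 + 1.0
        pre = unsharp_binarize(blurred, 3.0, 1.0, 300, 10.0)
        from skimage.measure import label
        assert label(pre, connectivity=2).max() == 1
        dec = deconvolve_sted(blurred, 10.0, sigma_nm=40.0, iterations=200)
        post = unsharp_binarize(dec, 3.0, 1.0, 300, 10.0)
        assert label(post, connectivity=2).max() == 2

    def test_agrees_with_skimage_reference(self):
        """Cross-check the FFT implementation against
        skimage.restoration.richardson_lucy away from the border."""
        from skimage.restoration import richardson_lucy

        rng = np.random.default_rng(1)
        img = np.zeros((96, 96))
        for r, c in [(30, 30), (30, 60), (64, 45)]:
            img[r, c] = 300.0
        img = ndimage.gaussian_filter(img, 3.0) + 1.0
        img += rng.normal(0, 0.05, img.shape)
        img = np.maximum(img, 0)
        mine = deconvolve_sted(img, 10.0, sigma_nm=30.0, iterations=15)
        psf_half = 12
        rr, cc = np.mgrid[-psf_half:psf_half + 1, -psf_half:psf_half + 1]
        psf = np.exp(-(rr**2 + cc**2) / (2 * 3.0**2))
        ref = richardson_lucy(img / img.max(), psf / psf.sum(),
                              num_iter=15, clip=False) * img.max()
        core = (slice(20, 76), slice(20, 76))
        denom = np.abs(ref[core]).max()
        assert np.max(np.abs(mine[core] - ref[core])) / denom < 0.05

    def test_nonpositive_image_rejected(self):
        with pytest.raises(InvalidParameterError):
            deconvolve_sted(np.zeros((32, 32)), 10.0)


class TestClusterSegmentation:
    def test_two_programmed_clusters(self):
        """An AZ rendered with two Cav clusters 150 nm apart yields two
        segmented clusters assigned to it."""
        scene = ImageSceneParams(field_px=384, n_terminals=1,
                                 n_small_terminals=0,
                                 az_per_terminal_mean=3.0,
                                 noise_model="none")
        p = PipelineParams()
        for seed in range(20):
            img, truth = render_sted_field(scene, "WT", seed=seed)
            two = [a for a in truth.azs if a["n_cav_clusters"] == 2]
            ok = [a for a in two
                  if np.hypot(*(np.array(a["cav_centroids_px"][0])
                                - np.array(a["cav_centroids_px"][1]))) > 12]
            if ok:
                break
        else:
            pytest.fail("no suitable AZ realized")
        az = gate_azs(make_az_masks(img, p), img, p)
        dec = deconvolve_sted(img.cav, 10.0, p.psf_kernel_radius_nm,
                              p.rl_iterations,
                              post_smooth_px=p.rl_post_smooth_px)
        clusters = segment_clusters(dec, img.cav, az, p)
        target = np.array(ok[0]["center_px"])
        gated = az.table
        d = np.hypot(*(gated[["centroid_row", "centroid_col"]].to_numpy()
                       - target).T)
        lab = int(gated.iloc[int(d.argmin())]["az_label"])
        assert len(clusters.in_az(lab)) == 2

    def test_straddling_cluster_counted_once(self):
        labels = np.zeros((64, 64), int)
        labels[20:30, 10:30] = 1
        az = AzMask(labels, 10.0, pd.DataFrame(
            [{"az_label": 1, "area_nm2": 1.0, "centroid_row": 25.0,
              "centroid_col": 20.0}]))
        dec = np.zeros((64, 64))
        dec[24:27, 28:34] = 50.0   # straddles the AZ boundary at col 30
        clusters = segment_clusters(dec, dec, az, PipelineParams(
            min_cluster_area_nm2=300))
        tab = clusters.table
        assert len(tab) == 1
        assert tab["az_label"].iloc[0] == 1


class TestNND:
    def make_cluster_set(self, rows):
        return ClusterSet(np.zeros((8, 8), int), 10.0, pd.DataFrame(rows))

    def make_az(self):
        return AzMask(np.zeros((8, 8), int), 10.0,
                      pd.DataFrame([{"az_label": 1, "area_nm2": 1.0,
                                     "centroid_row": 0.0,
                                     "centroid_col": 0.0}]))

    def test_geometry(self):
        cav = self.make_cluster_set([
            {"cluster_label": 1, "az_label": 1, "centroid_row": 0.0,
             "centroid_col": 0.0}])
        munc = self.make_cluster_set([
            {"cluster_label": 1, "az_label": 1, "centroid_row": 0.0,
             "centroid_col": 5.0},
            {"cluster_label": 2, "az_label": 1, "centroid_row": 0.0,
             "centroid_col": 12.0}])
        nnd = nearest_neighbor_distances(cav, munc, self.make_az())
        assert nnd["nnd_nm"].tolist() == [50.0]

    def test_coincident_zero(self):
        pt = [{"cluster_label": 1, "az_label": 1, "centroid_row": 3.0,
               "centroid_col": 3.0}]
        nnd = nearest_neighbor_distances(self.make_cluster_set(pt),
                                         self.make_cluster_set(pt),
                                         self.make_az())
        assert nnd["nnd_nm"].tolist() == [0.0]

    def test_empty_az_skipped(self):
        cav = self.make_cluster_set([
            {"cluster_label": 1, "az_label": 1, "centroid_row": 0.0,
             "centroid_col": 0.0}])
        munc = self.make_cluster_set(
            [{"cluster_label": 1, "az_label": 2, "centroid_row": 0.0,
              "centroid_col": 1.0}])
        nnd = nearest_neighbor_distances(cav, munc, self.make_az())
        assert len(nnd) == 0
        assert nnd.attrs["skipped_azs"] == [1]

    def test_symmetric_option(self):
        cav = self.make_cluster_set([
            {"cluster_label": 1, "az_label": 1, "centroid_row": 0.0,
             "centroid_col": 0.0}])
        munc = self.make_cluster_set([
            {"cluster_label": 1, "az_label": 1, "centroid_row": 0.0,
             "centroid_col": 4.0}])
        nnd = nearest_neighbor_distances(cav, munc, self.make_az(),
                                         symmetric=True)
        assert set(nnd["direction"]) == {"cav_to_munc", "munc_to_cav"}
        assert np.allclose(nnd["nnd_nm"], 40.0)


class TestScaling:
    def test_nm_outputs_scale_with_pixel_size(self):
        """The same physical scene sampled at 5 and 10 nm/px yields the
        same nm-valued distances and areas within discretization error."""
        results = {}
        for px in (10.0, 5.0):
            n = int(2560 / px)
            rr, cc = np.mgrid[:n, :n] * px          # nm coordinates
            munc = np.full((n, n), 1.0)
            disk = (rr - 1280) ** 2 + (cc - 1280) ** 2 <= 150.0**2
            munc[disk] = 40.0
            zero = np.zeros((n, n), np.uint16)
            az = make_az_masks(StedImageSet(munc.astype(np.uint16), zero,
                                            zero, zero, px),
                               PipelineParams(unsharp_sigma_px=50.0 / px))
            results[px] = az.table["area_nm2"].max()
        assert results[5.0] == pytest.approx(results[10.0], rel=0.05)
        assert results[10.0] == pytest.approx(np.pi * 150**2, rel=0.1)


class TestAggregation:
    def make_records(self):
        return pd.DataFrame([
            {"genotype": "WT", "animal_id": "a1", "cav_intensity": 10.0,
             "munc_intensity": 1.0, "n_cav_clusters": 2,
             "mean_nnd_nm": 60.0, "area_nm2": 4e4},
            {"genotype": "WT", "animal_id": "a1", "cav_intensity": 20.0,
             "munc_intensity": 2.0, "n_cav_clusters": 3,
             "mean_nnd_nm": 70.0, "area_nm2": 5e4},
            {"genotype": "WT", "animal_id": "a2", "cav_intensity": 30.0,
             "munc_intensity": 3.0, "n_cav_clusters": 1,
             "mean_nnd_nm": 50.0, "area_nm2": 6e4},
        ])

    def test_hand_computed_means(self):
        per = aggregate_per_animal(self.make_records())
        a1 = per[per["animal_id"] == "a1"].iloc[0]
        assert a1["cav_intensity"] == 15.0
        assert a1["n_cav_clusters"] == 2.5
        assert a1["n_azs"] == 2

    def test_unit_of_analysis_is_animals(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame({
            "genotype": "WT", "animal_id": rng.choice(list("abcd"), 600),
            "cav_intensity": rng.gamma(4, 100, 600),
            "n_cav_clusters": rng.integers(1, 5, 600)})
        per = aggregate_per_animal(rec)
        assert len(per) == 4

    def test_cdf_tables(self):
        hist, cdf = intensity_distribution_tables(self.make_records())
        c = cdf[cdf["genotype"] == "WT"]["cdf"].to_numpy()
        assert np.all(np.diff(c) >= 0)
        assert c[-1] == 1.0
        assert hist["count"].sum() == 3


class TestEndToEnd:
    def test_quantified_field_schema(self, quantified_field):
        rec = quantified_field
        assert len(rec) > 0
        for col in ("cav_intensity", "n_cav_clusters", "mean_nnd_nm",
                    "area_nm2", "animal_id", "genotype"):
            assert col in rec.columns
        assert (rec["cav_intensity"] >= 0).all()
        assert (rec["n_cav_clusters"] >= 0).all()

    def test_rerun_identical(self, rendered_field, quantified_field):
        imgset, _ = rendered_field
        again = quantify_field(imgset, PipelineParams())
        pd.testing.assert_frame_equal(quantified_field, again)
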