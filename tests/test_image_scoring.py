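"""Scoring-protocol tests with generator ground truth and moment oracles."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from ki67prog import image_scoring as sc
from ki67prog import synthetic_data as sd
from ki67prog._types import CoreImage, StainVectors


def brute_force_features(mask, mpp):
    """Independent pixel-moment computation of the five shape features."""
    ys, xs = np.nonzero(mask)
    area = len(xs) * mpp**2
    cx, cy = xs.mean(), ys.mean()
    mxx = np.mean((xs - cx) ** 2)
    myy = np.mean((ys - cy) ** 2)
    mxy = np.mean((xs - cx) * (ys - cy))
    tr, det = mxx + myy, mxx * myy - mxy**2
    l1 = tr / 2 + np.sqrt(max(tr**2 / 4 - det, 0))
    l2 = tr / 2 - np.sqrt(max(tr**2 / 4 - det, 0))
    major = 4 * np.sqrt(l1) * mpp
    minor = 4 * np.sqrt(l2) * mpp
    return {
        "spot_width_um": 2 * np.sqrt(area / np.pi),
        "width_um": minor,
        "axis_ratio": minor / major if major > 0 else 1.0,
    }


def disk_mask(radius, pad=3):
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


class TestOdTransform:
    def test_white_pixel_zero_od(self):
        img = np.full((2, 2, 3), 255, dtype=np.uint8)
        od = sc.od_transform(img)
        np.testing.assert_allclose(od, 0.0, atol=1e-6)

    def test_closed_form_single_channel(self):
        img = np.full((1, 1, 3), 255, dtype=np.uint8)
        img[0, 0, 1] = 26  # ~25.5 -> OD ~1.0 on that channel
        od = sc.od_transform(img)
        assert od[0, 0, 1] == pytest.approx(1.0, abs=0.01)
        assert od[0, 0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_monotone_decreasing_in_intensity(self):
        ramp = np.arange(1, 256, dtype=np.uint8).reshape(-1, 1)
        img = np.repeat(ramp[:, :, None], 3, axis=2)
        od = sc.od_transform(img)
        assert np.all(np.diff(od[:, 0, 0]) < 0)

    def test_round_trip_through_rendering(self):
        rng = np.random.default_rng(0)
        img = rng.integers(1, 256, size=(32, 32, 3)).astype(np.uint8)
        od = sc.od_transform(img)
        back = np.round(255.0 * np.power(10.0, -od))
        assert np.max(np.abs(back - img)) <= 1.0

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError, match="RGB"):
            sc.od_transform(np.zeros((4, 4)))


class TestDeconvolve:
    def test_pure_stain_basis_cases(self):
        stains = StainVectors()
        m = stains.matrix()
        od = (0.5 * m[:, 0])[None, None, :]
        conc = sc.deconvolve(od, stains)
        np.testing.assert_allclose(conc[0, 0], [0.5, 0.0, 0.0], atol=1e-12)
        od2 = (0.5 * m[:, 0] + 0.3 * m[:, 1])[None, None, :]
        conc2 = sc.deconvolve(od2, stains)
        np.testing.assert_allclose(conc2[0, 0], [0.5, 0.3, 0.0], atol=1e-12)

    def test_singular_matrix_reports_condition_number(self):
        bad = StainVectors(hematoxylin_od=(1, 0, 0), dab_od=(1, 0, 0), residual_od=(0, 1, 0))
        with pytest.raises(ValueError, match="condition number"):
            sc.deconvolve(np.zeros((1, 1, 3)), bad)

    def test_recovers_generator_concentrations(self, rendered_core):
        img, _, conc_true = rendered_core
        od = sc.od_transform(img)
        conc = sc.deconvolve(od, StainVectors())
        for ch in (0, 1):
            r = np.corrcoef(conc[..., ch].ravel(), conc_true[..., ch].ravel())[0, 1]
            assert r >= 0.99
            assert np.abs(conc[..., ch] - conc_true[..., ch]).mean() < 0.02


class TestShapeFeatures:
    def test_disk_is_round(self):
        feats = sc.compute_shape_features(disk_mask(10), mpp=1.0)
        assert feats["axis_ratio"] == pytest.approx(1.0, abs=0.05)
        assert feats["roundness"] == pytest.approx(1.0, rel=0.1)
        assert feats["spot_width_um"] == pytest.approx(20.0, rel=0.05)
        assert feats["roundness"] * feats["compactness"] == pytest.approx(1.0, abs=1e-9)

    def test_two_to_one_ellipse_axis_ratio(self):
        yy, xx = np.mgrid[:61, :61]
        mask = ((xx - 30) / 24) ** 2 + ((yy - 30) / 12) ** 2 <= 1
        feats = sc.compute_shape_features(mask, mpp=1.0)
        assert feats["axis_ratio"] == pytest.approx(0.5, abs=0.05)
        assert feats["width_um"] == pytest.approx(24.0, rel=0.07)

    def test_matches_brute_force_moments(self):
        rng = np.random.default_rng(2)
        yy, xx = np.mgrid[:41, :41]
        mask = ((xx - 20) / 15) ** 2 + ((yy - 20) / 9) ** 2 <= 1
        feats = sc.compute_shape_features(mask, mpp=0.5)
        oracle = brute_force_features(mask, mpp=0.5)
        assert feats["spot_width_um"] == pytest.approx(oracle["spot_width_um"], rel=1e-6)
        assert feats["width_um"] == pytest.approx(oracle["width_um"], rel=0.02)
        assert feats["axis_ratio"] == pytest.approx(oracle["axis_ratio"], rel=0.02)

    def test_single_pixel_flagged_with_perimeter_floor(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        feats = sc.compute_shape_features(mask, mpp=1.0)
        assert feats["flagged"]
        assert np.isfinite(feats["roundness"])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sc.compute_shape_features(np.zeros((4, 4), dtype=bool), mpp=1.0)


class TestSegmentation:
    def _conc_of(self, truth, seed=0):
        img, _ = sd.generate_core_image(truth, seed=seed)
        od = sc.od_transform(img)
        return sc.deconvolve(od, StainVectors())

    def test_disjoint_disks_counted(self):
        nuclei = [
            sd.Nucleus(x=30 + 50 * (i % 5), y=30 + 50 * (i // 5), major_px=12,
                       minor_px=11, orientation=0, malignant=True)
            for i in range(10)
        ]
        truth = sd.SimImageTruth(nuclei=nuclei, mpp=1.0, shape=(300, 300))
        recs = sc.segment_nuclei(self._conc_of(truth), sc.ScoringProtocol(), 1.0)
        assert len(recs) == 10

    def test_blank_background_empty(self):
        truth = sd.SimImageTruth(nuclei=[], mpp=1.0, shape=(64, 64))
        recs = sc.segment_nuclei(self._conc_of(truth), sc.ScoringProtocol(), 1.0)
        assert recs == []

    def test_overlapping_pair_split_by_watershed(self):
        # two ellipses overlapping by ~20 % of a radius
        nuclei = [
            sd.Nucleus(x=40, y=40, major_px=12, minor_px=11, orientation=0, malignant=True),
            sd.Nucleus(x=50, y=40, major_px=12, minor_px=11, orientation=0, malignant=True),
        ]
        truth = sd.SimImageTruth(nuclei=nuclei, mpp=1.0, shape=(90, 90))
        recs = sc.segment_nuclei(self._conc_of(truth), sc.ScoringProtocol(), 1.0)
        assert len(recs) == 2
        found = np.array([r.centroid_xy for r in recs])
        want = np.array([[40, 40], [50, 40]])
        d, _ = cKDTree(want).query(found)
        assert np.all(d < 2.0)


class TestClassification:
    def _record(self, **over):
        base = dict(
            label=1, centroid_xy=(0, 0), area_px=80.0, spot_width_um=10.0,
            width_um=9.0, roundness=1.0, compactness=1.0, axis_ratio=0.9,
            mean_od_hem=0.5, mean_od_dab=0.0,
        )
        base.update(over)
        return sc.NucleusRecord(**base)

    def test_in_range_and_dab_positive(self):
        rec = self._record(mean_od_dab=0.4)
        sc.classify_nuclei([rec], sc.ScoringProtocol())
        assert rec.malignant and rec.positive

    def test_shape_out_of_range_overrides_colour(self):
        rec = self._record(axis_ratio=0.3, mean_od_dab=0.9)
        sc.classify_nuclei([rec], sc.ScoringProtocol())
        assert not rec.malignant and not rec.positive

    def test_raising_dab_cut_never_increases_score(self):
        rng = np.random.default_rng(1)
        recs = [self._record(mean_od_dab=float(v)) for v in rng.uniform(0, 0.6, 50)]
        prev = None
        for cut in (0.05, 0.15, 0.3, 0.5):
            prot = sc.ScoringProtocol(dab_od_cut=cut)
            sc.classify_nuclei(recs, prot)
            n_pos = sum(r.positive for r in recs)
            if prev is not None:
                assert n_pos <= prev
            prev = n_pos

    def test_class_accuracy_on_separated_distributions(self, rendered_core):
        img, truth, _ = rendered_core
        recs, _ = sc.analyse_core(img)
        txy = np.array([[n.x, n.y] for n in truth.nuclei])
        tmal = np.array([n.malignant for n in truth.nuclei])
        rxy = np.array([r.centroid_xy for r in recs])
        _, idx = cKDTree(txy).query(rxy)
        pred = np.array([r.malignant for r in recs])
        assert np.mean(pred == tmal[idx]) >= 0.95


class TestScoreCore:
    @pytest.mark.parametrize("frac,expect", [(0.0, 0.0), (1.0, 100.0)])
    def test_extreme_fractions_exact(self, frac, expect):
        truth = sd.random_core_truth(300, frac_positive=frac, seed=8)
        img, _ = sd.generate_core_image(truth, seed=8)
        score = sc.score_core(img)
        assert score.n_total_malignant > 0
        assert score.ki67_pct == pytest.approx(expect, abs=1.5)

    def test_binomial_ground_truth_recovered(self, rendered_core):
        img, truth, _ = rendered_core
        score = sc.score_core(img)
        assert score.ki67_pct == pytest.approx(truth.true_ki67_pct, abs=3.0)

    def test_zero_malignant_recorded_for_qc(self):
        img = CoreImage(pixels=np.full((64, 64, 3), 250, dtype=np.uint8), mpp=1.0)
        score = sc.score_core(img)
        assert score.n_total_malignant == 0
        assert np.isnan(score.ki67_pct)


class TestCavGridCount:
    def test_partition_conserves_whole_core_counts(self, rendered_core):
        img, _, _ = rendered_core
        recs, score = sc.analyse_core(img)
        cav = sc.cav_grid_count(recs, mpp=img.mpp)
        assert cav.n_counted == score.n_total_malignant
        assert cav.n_positive == score.n_positive
        assert cav.tiles["n_negative"].sum() + cav.tiles["n_positive"].sum() == cav.n_counted

    def test_low_count_core_flagged_unsatisfactory(self):
        truth = sd.random_core_truth(400, frac_positive=0.2, frac_malignant=0.8, seed=6)
        img, _ = sd.generate_core_image(truth, seed=6)
        cav = sc.cav_grid_count(img)
        assert cav.n_counted < 500
        assert not cav.satisfactory
        assert not cav.reached_target

    def test_boundary_nuclei_counted_once_half_open(self):
        # centroids exactly on a 250-um tile boundary fall in the upper tile
        recs = []
        for i, x in enumerate([250.0, 499.9, 500.0]):
            recs.append(
                sc.NucleusRecord(
                    label=i, centroid_xy=(x, 10.0), area_px=80, spot_width_um=10,
                    width_um=9, roundness=1.0, compactness=1.0, axis_ratio=0.9,
                    mean_od_hem=0.5, mean_od_dab=0.0, malignant=True, positive=False,
                )
            )
        cav = sc.cav_grid_count(recs, mpp=1.0, grid_side_um=250.0)
        assert cav.n_counted == 3
        by_tile = cav.tiles.set_index("tile_ix")["n_negative"]
        assert by_tile.get(1, 0) == 2      # [250, 500): x=250 and x=499.9
        assert by_tile.get(2, 0) == 1      # [500, 750): x=500

    def test_single_tile_fallback(self):
        rec = sc.NucleusRecord(
            label=0, centroid_xy=(5.0, 5.0), area_px=80, spot_width_um=10, width_um=9,
            roundness=1.0, compactness=1.0, axis_ratio=0.9, mean_od_hem=0.5,
            mean_od_dab=0.3, malignant=True, positive=True,
        )
        cav = sc.cav_grid_count([rec], mpp=1.0, grid_side_um=250.0)
        assert len(cav.tiles) == 1
        assert cav.ki67_pct == 100.0


class TestProtocolCalibration:
    def test_calibrated_protocol_beats_95pct(self, rendered_core):
        img, truth, _ = rendered_core
        recs, _ = sc.analyse_core(img)
        txy = np.array([[n.x, n.y] for n in truth.nuclei])
        tmal = np.array([n.malignant for n in truth.nuclei])
        rxy = np.array([r.centroid_xy for r in recs])
        _, idx = cKDTree(txy).query(rxy)
        prot = sc.calibrate_protocol(recs, tmal[idx])
        sc.classify_nuclei(recs, prot)
        pred = np.array([r.malignant for r in recs])
        assert np.mean(pred == tmal[idx]) >= 0.95

    def test_protocol_yaml_roundtrip(self, tmp_path):
        prot = sc.ScoringProtocol(dab_od_cut=0.22)
        path = tmp_path / "protocol.yaml"
        prot.to_yaml(path)
        back = sc.ScoringProtocol.from_yaml(path)
        assert back.dab_od_cut == 0.22
        assert back.shape_ranges == prot.shape_ranges

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sc.ScoringProtocol(shape_ranges={"roundness": (1.0, 1.0)})
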