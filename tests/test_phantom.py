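"""Phantom generator: geometry, ground-truth painting, signal synthesis, cohorts."""

import numpy as np
import pytest
from scipy import stats as sps

from wmh_penumbra import phantom as ph
from wmh_penumbra import relaxometry as rx
from wmh_penumbra import rois


def face_adjacent_brute(a, b):
    """Brute-force neighbor scan: any a-voxel sharing a face with a b-voxel."""
    for i, j, k in np.argwhere(a):
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            x, y, z = i + di, j + dj, k + dk
            if 0 <= x < b.shape[0] and 0 <= y < b.shape[1] and 0 <= z < b.shape[2]:
                if b[x, y, z]:
                    return True
    return False


class TestLabelVolume:
    def test_periventricular_blob_touches_ventricle(self):
        lv = ph.make_label_volume((48, 48, 48), (1, 1, 1), 2, 1, False, seed=7)
        cls = rois.classify_wmh(lv.mask("wmh"), lv.mask("ventricular_csf"))
        pv = cls == 1
        assert pv.any()
        assert face_adjacent_brute(pv, lv.mask("ventricular_csf"))

    def test_deep_blobs_keep_distance_from_ventricles(self):
        lv = ph.make_label_volume((48, 48, 48), (1, 1, 1), 2, 1, False, seed=7)
        cls = rois.classify_wmh(lv.mask("wmh"), lv.mask("ventricular_csf"))
        deep = cls == 2
        assert deep.any()
        d = rois.distance_map_mm(lv.mask("ventricular_csf"), lv.voxel_size_mm)
        assert d[deep].min() >= 2.0

    def test_zero_lesion_volume(self):
        lv = ph.make_label_volume((36, 36, 36), (1.5, 1.5, 1.5), 0, 0, False, seed=3)
        assert not lv.mask("wmh").any()

    def test_deterministic_under_fixed_seed(self):
        a = ph.make_label_volume((40, 40, 40), (1, 1, 1), 1, 1, True, seed=11)
        b = ph.make_label_volume((40, 40, 40), (1, 1, 1), 1, 1, True, seed=11)
        assert np.array_equal(a.labels, b.labels)

    def test_stroke_confined_to_one_hemisphere(self):
        lv = ph.make_label_volume((44, 44, 44), (1, 1, 1), 1, 1, True, seed=2,
                                  stroke_side="right")
        xs = np.argwhere(lv.mask("stroke"))[:, 0]
        assert xs.min() > lv.labels.shape[0] // 2

    def test_ventricles_form_connected_components(self):
        import scipy.ndimage as ndi

        lv = ph.make_label_volume(seed=5)
        _, n = ndi.label(lv.mask("ventricular_csf"))
        assert n >= 1

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            ph.make_label_volume((16, 16, 16), (1, 1, 1), 0, 0, False, seed=0)

    def test_impossible_placement_names_the_blob(self):
        with pytest.raises(ph.PlacementError, match="deep WMH"):
            ph.make_label_volume((32, 32, 32), (1, 1, 1), 5, 0, False, seed=0,
                                 wmh_radius_mm=14.0)


@pytest.fixture(scope="module")
def world():
    return ph.make_label_volume((40, 40, 40), (1, 1, 1), 1, 1, False, seed=9)


class TestPaintGroundTruth:

    def test_lesion_and_baseline_endpoints(self, world):
        gt = ph.paint_ground_truth(world, group="stroke", seed=0)
        wmh = world.mask("wmh")
        nawm = world.mask("nawm")
        d = rois.distance_map_mm(wmh, world.voxel_size_mm)
        assert np.allclose(gt.ie_t2_true[wmh], 100.0)
        assert np.allclose(gt.md_true[wmh], 1.10e-3)
        far = nawm & (d >= 6.0)
        assert np.allclose(gt.ie_t2_true[far], 80.0)
        assert np.allclose(gt.md_true[far], 0.75e-3)
        assert np.allclose(gt.fa_true[far], 0.45)

    def test_profile_conservation_in_nawm(self, world):
        """Painted fluid-linked values reproduce the profile formula at each
        voxel's distance-map value, to machine precision."""
        profile = ph.default_gmt2_profile(110.0)
        gt = ph.paint_ground_truth(world, profile_gmt2=profile, group="older_adult", seed=1)
        nawm = world.mask("nawm")
        d = rois.distance_map_mm(world.mask("wmh"), world.voxel_size_mm)
        np.testing.assert_allclose(gt.ie_t2_true[nawm], profile(d)[nawm], rtol=1e-14)

    def test_older_adult_mwf_is_programmed_null(self, world):
        gt = ph.paint_ground_truth(world, group="older_adult", seed=0)
        wmh, nawm = world.mask("wmh"), world.mask("nawm")
        assert np.max(np.abs(gt.mwf_true[wmh] - ph.NAWM_MWF)) == 0.0
        assert np.all(gt.mwf_true[nawm] == ph.NAWM_MWF)

    def test_stroke_group_wmh_myelin_deficit(self, world):
        gt = ph.paint_ground_truth(world, group="stroke", seed=0, wmh_mwf=0.06)
        assert np.all(gt.mwf_true[world.mask("wmh")] == 0.06)
        assert np.all(gt.mwf_true[world.mask("nawm")] == ph.NAWM_MWF)

    def test_flip_field_within_range(self, world):
        gt = ph.paint_ground_truth(world, group="stroke", seed=4)
        assert gt.flip_angle_true.min() >= 110.0 - 1e-9
        assert gt.flip_angle_true.max() <= 180.0 + 1e-9

    def test_invalid_lesion_value_rejected(self, world):
        bad = ph.GradientProfile(baseline=80.0, lesion_value=300.0)
        with pytest.raises(ValueError):
            ph.paint_ground_truth(world, profile_gmt2=bad, group="stroke", seed=0)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            ph.GradientProfile(baseline=80.0, lesion_value=100.0, reach_mm=0.0)


class TestEchoSimulation:
    def test_single_pool_ideal_refocusing_is_monoexponential(self, seq32):
        train = ph.simulate_echo_train(0.0, 80.0, 180.0, seq32, s0=1.0)
        np.testing.assert_allclose(
            train.signal, np.exp(-seq32.echo_times_ms / 80.0), atol=1e-12
        )

    def test_two_pool_matches_epg_forward_model(self, seq32):
        train = ph.simulate_echo_train(0.15, 80.0, 140.0, seq32, s0=1.0)
        expected = 0.15 * rx.epg_basis_curve(20.0, seq32, 140.0) + 0.85 * rx.epg_basis_curve(
            80.0, seq32, 140.0
        )
        np.testing.assert_allclose(train.signal, expected, rtol=1e-12)

    def test_pure_noise_is_rayleigh(self, seq32):
        """With s0 = 0 the magnitude echoes follow a Rayleigh(sigma) law."""
        rng = np.random.default_rng(4)
        sigma = 3.0
        draws = np.concatenate(
            [
                ph.simulate_echo_train(0.1, 80.0, 160.0, seq32, 0.0, sigma, rng).signal
                for _ in range(320)
            ]
        )  # > 1e4 samples
        assert draws.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)
        _, p = sps.kstest(draws, "rayleigh", args=(0, sigma))
        assert p > 0.01

    def test_validation(self, seq32):
        with pytest.raises(ValueError):
            ph.simulate_echo_train(1.5, 80.0, 140.0, seq32)
        with pytest.raises(ValueError):
            ph.simulate_echo_train(0.1, 80.0, 200.0, seq32)
        with pytest.raises(ValueError):
            ph.simulate_echo_train(0.1, 80.0, 140.0, seq32, noise_sigma=-1.0)

    def test_volume_synthesis_matches_scalar_path(self, seq32):
        lv = ph.make_label_volume((36, 36, 36), (1.5, 1.5, 1.5), 1, 1, False, seed=9)
        gt = ph.paint_ground_truth(lv, group="older_adult", seed=9)
        mask = lv.mask("nawm")
        vol = ph.simulate_echo_volume(gt, mask, seq32, s0=100.0, snr=0.0)
        idx = tuple(np.argwhere(mask)[0])
        expected = ph.simulate_echo_train(
            gt.mwf_true[idx], gt.ie_t2_true[idx], gt.flip_angle_true[idx], seq32, 100.0
        )
        np.testing.assert_allclose(vol[idx], expected.signal, rtol=1e-6)


class TestCohort:
    def test_manifest_of_written_cohort(self, tmp_path):
        records, _ = ph.simulate_cohort(
            2, 2, ph.CohortConfig(shape=(32, 32, 32), voxel_size_mm=(2, 2, 2)),
            seed=1, out_dir=tmp_path,
        )
        assert len(records) == 4
        for rec in records:
            sdir = tmp_path / rec.subject_id
            for name in ("labels.nii.gz", "echo.nii.gz", "dwi.nii.gz", "bval", "bvec"):
                assert (sdir / name).exists(), name
        assert (tmp_path / "participants.tsv").exists()

    def test_tsv_byte_identical_across_reruns(self, tmp_path):
        cfg = ph.CohortConfig(shape=(32, 32, 32), voxel_size_mm=(2, 2, 2))
        ph.simulate_cohort(2, 2, cfg, seed=1, out_dir=tmp_path / "a")
        ph.simulate_cohort(2, 2, cfg, seed=1, out_dir=tmp_path / "b")
        assert (tmp_path / "a/participants.tsv").read_bytes() == (
            tmp_path / "b/participants.tsv"
        ).read_bytes()

    def test_stroke_group_has_larger_wmh_volumes(self):
        records = ph.make_subject_records(20, 20, ph.CohortConfig(), seed=42)
        older = [r.wmh_volume_ml for r in records if r.group == "older_adult"]
        stroke = [r.wmh_volume_ml for r in records if r.group == "stroke"]
        assert np.median(stroke) > np.median(older)
        assert max(older) < 10.0

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            ph.SubjectRecord("s", "stroke", 60, 25, "A_32echo", "none", 3.0)
        with pytest.raises(ValueError):
            ph.SubjectRecord("s", "older_adult", 60, 27, "A_32echo", "none", 12.0)

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValueError):
            ph.simulate_cohort(0, 2, seed=0)

    def test_roi_table_layout(self):
        tab = ph.simulate_roi_table(3, 3, seed=0)
        assert set(tab["metric"]) == {"FA", "MD", "MWF", "GMT2"}
        assert set(tab["distance_level"]) == {"WMH", "2", "4", "6", "8", "10"}
        # one row per subject x level x metric
        assert len(tab) == 6 * 6 * 4

    def test_roi_table_null_profile_is_flat(self):
        eff = {"GMT2": dict(profile=ph.GradientProfile(80.0, 80.0), sd=0.0)}
        tab = ph.simulate_roi_table(2, 2, effects=eff, seed=0,
                                    scanner_sd_frac=0.0, subject_sd_frac=0.0)
        assert tab["value"].std() == pytest.approx(0.0, abs=1e-12)
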