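"""Pore size, crown deformation, hairpin tilt, circularity/cracks, thinning."""

import numpy as np
import pytest

from poremetrics.pore_geometry import (circle_fit, deformation_profile,
                                       detect_cracks, hairpin_tilt,
                                       hairpin_tilts,
                                       interface_contact_counts,
                                       membrane_thinning, pore_radius,
                                       ring_circularity_and_cracks,
                                       subunit_centroids)
from poremetrics.structures import Frame, assign_leaflets
from poremetrics.synthetic import (synth_crack_trajectory,
                                   synth_membrane_patch, synth_ring)


def patch(seed=0, **kwargs):
    system, frame, truth = synth_membrane_patch(
        kwargs.pop("inner", {"POPC": 150}), kwargs.pop("outer", {"POPC": 150}),
        box_xy=kwargs.pop("box_xy", 24.0), seed=seed, **kwargs)
    assign_leaflets(system, frame)
    return system, frame, truth


class TestPoreRadius:
    def test_intact_membrane_has_no_pore(self, flat_patch):
        system, frame, _ = flat_patch
        assert pore_radius(frame, system) is None

    def test_printed_pore_width_fixture(self):
        """A planted 10.8 nm lipid-free disc reads back as a ~21.6 nm wide
        pore, within the raster resolution."""
        system, frame, _ = patch(seed=4, pore_radius=10.8)
        measure = pore_radius(frame, system)
        assert measure is not None
        assert measure.diameter == pytest.approx(21.6, abs=2 * 0.5)

    @pytest.mark.parametrize("planted", [2.0, 5.0, 10.0])
    @pytest.mark.parametrize("seed", range(5))
    def test_radius_sweep_within_one_grid_cell(self, planted, seed):
        system, frame, _ = patch(seed=seed, pore_radius=planted)
        measure = pore_radius(frame, system, grid=0.5)
        assert measure is not None
        assert measure.radius == pytest.approx(planted, abs=0.5)

    def test_monotone_in_planted_radius(self):
        radii = []
        for planted in (2.0, 5.0, 10.0):
            system, frame, _ = patch(seed=8, pore_radius=planted)
            radii.append(pore_radius(frame, system).radius)
        assert radii == sorted(radii)

    def test_translation_invariance_in_xy(self):
        system, frame, _ = patch(seed=3, pore_radius=5.0)
        m1 = pore_radius(frame, system)
        shift = np.array([1.0, 2.0, 0.0])
        moved = Frame(time=0, positions=frame.positions + shift,
                      box=frame.box + np.array([4.0, 4.0, 0.0]))
        m2 = pore_radius(moved, system,
                         center=(m1.center[0] + 1.0, m1.center[1] + 2.0))
        assert m2.radius == pytest.approx(m1.radius, abs=0.5)

    def test_coarse_grid_rejected(self, flat_patch):
        system, frame, _ = flat_patch
        with pytest.raises(ValueError, match="coarse"):
            pore_radius(frame, system, grid=2.5)


class TestCrown:
    def test_flat_patch_is_flat(self, flat_patch):
        system, frame, _ = flat_patch
        profile = deformation_profile(frame, system)
        assert profile.crown_height == pytest.approx(0.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_crown_recovered(self, seed):
        system, frame, _ = patch(seed=seed, inner={"POPC": 300},
                                 outer={"POPC": 300}, box_xy=30.0,
                                 crown_height=2.0, ring_radius=15.0)
        profile = deformation_profile(frame, system)
        assert profile.crown_height == pytest.approx(2.0, abs=0.1)

    def test_invariant_under_z_translation(self):
        system, frame, _ = patch(seed=1, inner={"POPC": 300},
                                 outer={"POPC": 300}, box_xy=30.0,
                                 crown_height=2.0, ring_radius=15.0)
        p1 = deformation_profile(frame, system)
        moved = Frame(time=0, positions=frame.positions + [0, 0, 7.0],
                      box=frame.box + [0.0, 0.0, 20.0])
        p2 = deformation_profile(moved, system)
        assert p2.crown_height == pytest.approx(p1.crown_height, abs=1e-9)


class TestHairpinTilt:
    def test_planted_55_degrees(self):
        system, frame, _ = synth_ring(8, hairpin_tilt_deg=55.0)
        tilts = hairpin_tilts(frame, system)
        np.testing.assert_allclose(tilts, 55.0, atol=0.5)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 90.0])
    def test_reference_angles(self, angle):
        """0 deg lies in the membrane plane, 90 deg along the normal; the
        30 deg case mirrors a surface-tilted amphipathic helix."""
        system, frame, _ = synth_ring(4, hairpin_tilt_deg=angle)
        assert hairpin_tilt(frame, system, 2) == pytest.approx(angle, abs=1e-9)

    def test_unknown_subunit_raises(self):
        system, frame, _ = synth_ring(4)
        with pytest.raises(ValueError, match="subunit"):
            hairpin_tilt(frame, system, 11)


class TestRingAndCracks:
    def test_perfect_ring_residual_is_zero(self):
        system, frame, _ = synth_ring(33, arc_fraction=1.0)
        cent = subunit_centroids(frame, system)
        (_, _), radius, rms = circle_fit(cent[:, :2])
        assert rms < 1e-9
        assert radius > 0

    def test_arc_gap_angle_matches_construction(self):
        n, frac = 16, 16 / 33
        system, frame, truth = synth_ring(n, arc_fraction=frac)
        cent = subunit_centroids(frame, system)
        center = np.array(truth.params["center_xy"])
        angles = np.sort(np.arctan2(*(cent[:, :2] - center).T[::-1]) % (2 * np.pi))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
        slot = 2 * np.pi * frac / n
        assert gaps.max() == pytest.approx(2 * np.pi * (1 - frac) + slot,
                                           abs=1e-6)

    def test_planted_crack_reported_at_planted_time(self):
        system, frames, truth = synth_crack_trajectory(
            n_subunits=16, crack_interface=(8, 9), crack_frame=890,
            n_frames=1000, dt_ns=1.0)
        counts = {k: np.empty(len(frames), dtype=int)
                  for k in interface_contact_counts(frames[0], system)}
        for t, f in enumerate(frames):
            for k, v in interface_contact_counts(f, system).items():
                counts[k][t] = v
        centroid_series = np.array([subunit_centroids(f, system)
                                    for f in frames[::200]])
        residuals, report = ring_circularity_and_cracks(
            centroid_series, counts, threshold=5, persistence_frames=50,
            dt_ns=1.0)
        assert report.cracked == {(8, 9): pytest.approx(890.0)}
        assert residuals[0] < 1e-9          # pre-crack arc is on a circle

    def test_zero_threshold_never_cracks(self):
        counts = {(0, 1): np.zeros(200, dtype=int)}
        report = detect_cracks(counts, threshold=0, persistence_frames=10)
        assert report.cracked == {}

    def test_short_dip_below_persistence_ignored(self):
        series = np.full(300, 20)
        series[100:140] = 0                 # 40 < 50 frames
        report = detect_cracks({(3, 4): series}, threshold=5,
                               persistence_frames=50)
        assert report.cracked == {}

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            circle_fit(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestThinning:
    def test_flat_patch_uniform_thickness(self, flat_patch):
        system, frame, truth = flat_patch
        thickness, bulk = membrane_thinning(frame, system, bin_xy=4.0)
        sep = truth.params["leaflet_separation_nm"]
        assert bulk == pytest.approx(sep, abs=0.01)
        finite = thickness[np.isfinite(thickness)]
        np.testing.assert_allclose(finite, sep, atol=0.01)

    def test_planted_thinned_annulus(self):
        system, frame, _ = patch(seed=6, inner={"POPC": 400},
                                 outer={"POPC": 400}, box_xy=30.0,
                                 thin_annulus=(6.0, 10.0, 0.7))
        thickness, bulk = membrane_thinning(frame, system, bin_xy=2.0)
        nx, ny = thickness.shape
        # bins centered inside the annulus carry ~0.7x the bulk thickness
        centers = [(i, j) for i in range(nx) for j in range(ny)
                   if 6.5 < np.hypot((i + 0.5) * 2 - 15, (j + 0.5) * 2 - 15) < 9.5]
        vals = np.array([thickness[i, j] for i, j in centers])
        vals = vals[np.isfinite(vals)]
        assert len(vals) > 5
        np.testing.assert_allclose(vals.mean(), 0.7 * bulk, rtol=0.1)

    def test_empty_bin_is_nan_not_zero(self):
        system, frame, _ = patch(seed=2, pore_radius=8.0)
        thickness, _ = membrane_thinning(frame, system, bin_xy=2.0)
        nx, ny = thickness.shape
        center_val = thickness[nx // 2, ny // 2]
        assert np.isnan(center_val)
        assert not np.any(thickness[np.isfinite(thickness)] == 0)
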