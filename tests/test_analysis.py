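"""Measurement layer: angles, onset/completion detection, branch counting,
3-D branching angles and outcome classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import branchsim.analysis as an


class TestApproachDirection:
    @pytest.mark.parametrize(
        "offset,expected",
        [
            ((-0.02, -0.02), -3 * np.pi / 4),
            ((-0.02, 0.0), np.pi),
            ((0.02, 0.02), np.pi / 4),
        ],
    )
    def test_cardinal_cases(self, z_star, offset, expected):
        assert an.approach_direction(z_star + offset, z_star) == pytest.approx(expected)

    def test_undefined_at_singular_point(self, z_star):
        with pytest.raises(ValueError):
            an.approach_direction(z_star, z_star)


class TestGOrientation:
    @pytest.mark.parametrize(
        "cov,expected",
        [
            ([[2, 0], [0, 1]], 0.0),
            ([[1, 0.5], [0.5, 1]], np.pi / 4),
            ([[1, -0.5], [-0.5, 1]], 3 * np.pi / 4),
            ([[1, 0], [0, 2]], np.pi / 2),
        ],
    )
    def test_reference_covariances(self, cov, expected):
        assert an.g_orientation(np.array(cov, float)) == pytest.approx(expected)

    def test_zero_covariance_undefined(self):
        with pytest.raises(ValueError):
            an.g_orientation(np.zeros((2, 2)))

    @settings(max_examples=50, deadline=None)
    @given(theta=st.floats(0, np.pi), seed=st.integers(0, 10_000))
    def test_rotation_equivariance(self, theta, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(60, 2)) @ np.diag([2.0, 0.5])
        base = an.g_orientation(pts)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        rotated = an.g_orientation(pts @ rot.T)
        d = (rotated - base - theta) % np.pi
        assert min(d, np.pi - d) < 1e-9

    def test_weighted_orientation_matches_expanded_sample(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [0.5, 1.0]])
        w = np.array([1, 2, 1], float)
        expanded = np.repeat(pts, [1, 2, 1], axis=0)
        assert an.g_orientation(pts, weights=w) == pytest.approx(
            an.g_orientation(expanded), abs=1e-12
        )


class TestOnset:
    def _traj(self, series):
        class T:
            fitness_variance = np.asarray(series, float)
            completion_generation = None

        return T()

    def test_argmin_after_first_generation(self):
        assert an.detect_onset(self._traj([9.0, 5.0, 3.0, 1.0, 4.0])) == 4

    def test_tie_goes_earliest(self):
        assert an.detect_onset(self._traj([9.0, 2.0, 1.0, 1.0])) == 3

    def test_strictly_decreasing_series(self):
        assert an.detect_onset(self._traj([9.0, 5.0, 4.0, 3.0])) == 4

    def test_initial_transient_ignored(self):
        """A minimum before the variance peak (founder relaxation) is skipped."""
        assert an.detect_onset(self._traj([9.0, 0.5, 8.0, 3.0, 2.0, 6.0])) == 5

    def test_short_series_error(self):
        with pytest.raises(ValueError):
            an.detect_onset(self._traj([1.0]))


class TestCompletion:
    @staticmethod
    def _mock(traits_list):
        class T:
            snapshots = [(500 * (i + 1), t) for i, t in enumerate(traits_list)]

        return T()

    def test_bimodal_projection_completes(self, rng):
        uni = rng.normal(0, 0.01, size=(10_000, 2))
        bi = np.concatenate(
            [rng.normal(-1, 0.01, (5000, 2)), rng.normal(1, 0.01, (5000, 2))]
        )
        assert an.detect_completion_ibs(self._mock([uni, bi])) == 1000

    def test_unimodal_never_completes(self, rng):
        uni = rng.normal(0, 0.01, size=(10_000, 2))
        assert an.detect_completion_ibs(self._mock([uni, uni])) is None

    def test_threshold_is_strict(self, monkeypatch, rng):
        traj = self._mock([rng.normal(size=(100, 2))])
        monkeypatch.setattr(an, "projected_dip", lambda *a, **k: 0.15)
        assert an.detect_completion_ibs(traj) is None
        monkeypatch.setattr(an, "projected_dip", lambda *a, **k: 0.15 + 1e-9)
        assert an.detect_completion_ibs(traj) == 500

    def test_projected_dip_values(self, rng):
        bi = np.column_stack(
            [
                np.concatenate([rng.normal(-1, 0.01, 5000), rng.normal(1, 0.01, 5000)]),
                rng.normal(0, 0.01, 10_000),
            ]
        )
        assert an.projected_dip(bi) > 0.15
        assert an.projected_dip(rng.normal(size=(10_000, 2))) < 0.15


class TestBranchCounting:
    def test_cloud_counts(self, rng):
        one = rng.normal(0, 0.003, (400, 2))
        assert an.count_branches(one + [0.08, 0.08]) == 1
        two = np.concatenate([one + [0.02, 0.02], one + [0.15, 0.15]])
        assert an.count_branches(two) == 2
        three = np.concatenate(
            [one + [0.02, 0.02], one + [0.15, 0.02], one + [0.02, 0.15]]
        )
        assert an.count_branches(three) == 3

    def test_branching_direction_equals_orientation(self, rng):
        snap = np.concatenate(
            [
                rng.normal(0, 0.003, (300, 2)) + [0.05, 0.11],
                rng.normal(0, 0.003, (300, 2)) + [0.11, 0.05],
            ]
        )
        assert an.branching_direction(snap) == an.g_orientation(snap)
        assert an.branching_direction(snap) == pytest.approx(3 * np.pi / 4, abs=0.05)


class TestAngles3D:
    Z0 = np.array([0.02, 0.02, 0.02])
    STAR = np.array([0.08, 0.08, 0.08])

    def _frames(self):
        e_app = (self.Z0 - self.STAR) / np.linalg.norm(self.Z0 - self.STAR)
        r = np.array([1.0, 2.0, 3.0]) - self.STAR
        e_i = r - (r @ e_app) * e_app
        e_i /= np.linalg.norm(e_i)
        return e_app, e_i, np.cross(e_app, e_i)

    def test_line_along_intersection(self):
        _, e_i, _ = self._frames()
        a = an.angles_3d(e_i, self.Z0, self.STAR)
        assert a.phi == pytest.approx(0.0, abs=1e-9)
        assert a.psi == pytest.approx(0.0, abs=1e-9)

    def test_line_along_approach(self):
        e_app, _, _ = self._frames()
        a = an.angles_3d(e_app, self.Z0, self.STAR)
        assert a.phi == pytest.approx(np.pi / 2, abs=1e-9)

    def test_line_in_perpendicular_plane(self):
        _, e_i, e_w = self._frames()
        theta = 0.7
        a = an.angles_3d(np.cos(theta) * e_i + np.sin(theta) * e_w, self.Z0, self.STAR)
        assert a.phi == pytest.approx(0.0, abs=1e-9)
        assert a.psi == pytest.approx(theta, abs=1e-9)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            an.angles_3d([0, 0, 0], self.Z0, self.STAR)


class TestOutcomeClassification:
    def test_reference_patterns(self, z_star):
        assert an.classify_outcome([[0.2, 0.2], [0.0, 0.0]], z_star).label == "CD"
        assert an.classify_outcome([[0.2, 0.0], [0.0, 0.2]], z_star).label == "DOL"
        assert an.classify_outcome([[0.2, 0.2], [0.2, 0.0]], z_star).label == "OTHER"

    def test_swap_invariance(self, z_star, rng):
        for _ in range(20):
            strains = rng.uniform(0, 0.2, size=(2, 2))
            a = an.classify_outcome(strains, z_star).label
            b = an.classify_outcome(strains[:, ::-1], z_star).label
            assert a == b

    def test_tolerance_band_forces_other(self, z_star):
        near_line = [[z_star[0] + 0.001, 0.2], [0.0, 0.0]]
        out = an.classify_outcome(near_line, z_star, tol_band=0.005)
        assert out.label == "OTHER"
        assert out.warning is not None
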