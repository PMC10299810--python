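"""Rotation statistics, positioning, filament calling and the Hill dose-response fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagecore.imaging import (
    BETWEEN_TWO,
    NOT_BETWEEN_TWO,
    SINGLE_NUCLEOID,
    UNSUPPORTED,
    CellGeometry,
    DoseResponseData,
    RotationTrack,
    angular_velocity,
    call_filament,
    fit_dose_response,
    load_dose_response_csv,
    load_geometries_csv,
    load_tracks_csv,
    nucleoid_context,
    positioning_ratio,
    rotating_fraction,
    rotation_speed,
)
from phagecore import synthetic


def circle_track(radius=311.0, omega_deg_s=10.1, dt=4.0, duration=120.0, phase=0.0,
                 center=(0.0, 0.0)):
    t = np.arange(0.0, duration + dt / 2, dt)
    theta = phase + np.deg2rad(omega_deg_s) * t
    return RotationTrack(
        t=t,
        x=center[0] + radius * np.cos(theta),
        y=center[1] + radius * np.sin(theta),
        nucleus_radius=radius,
    )


class TestRotationSpeed:
    def test_total_path_over_time(self):
        # 500 nm traveled in 10 s -> 50 nm/s (square path, 4 x 125 nm legs)
        t = np.array([0.0, 2.5, 5.0, 7.5, 10.0])
        x = np.array([0.0, 125.0, 125.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, 125.0, 125.0, 0.0])
        speed, duration = rotation_speed(RotationTrack(t, x, y, nucleus_radius=100.0))
        assert speed == pytest.approx(50.0)
        assert duration == pytest.approx(10.0)

    def test_stationary_point(self):
        tr = RotationTrack(np.arange(5.0), np.zeros(5), np.zeros(5), nucleus_radius=100.0)
        assert rotation_speed(tr)[0] == 0.0

    def test_circle_geometry_oracle(self):
        """On a noise-free circular track the chord sum equals
        n_steps * 2 r sin(omega dt / 2); with chord-to-arc correction the
        speed equals omega * r, ~54.8 nm/s at 10.1 deg/s on a 311 nm radius."""
        r, w, dt, T = 311.0, 10.1, 4.0, 120.0
        tr = circle_track(r, w, dt, T)
        n_steps = len(tr.t) - 1
        chord = 2 * r * math.sin(math.radians(w * dt) / 2)
        speed_raw, _ = rotation_speed(tr)
        assert speed_raw == pytest.approx(n_steps * chord / T, rel=1e-9)
        speed_arc, _ = rotation_speed(tr, chord_correction=True)
        assert speed_arc == pytest.approx(r * math.radians(w), rel=1e-9)
        assert speed_arc == pytest.approx(54.8, rel=0.01)

    def test_track_validation(self):
        with pytest.raises(ValueError):
            RotationTrack(np.array([0.0]), np.array([0.0]), np.array([0.0]), 100.0)
        with pytest.raises(ValueError):  # non-increasing time -> zero/negative duration
            RotationTrack(np.array([0.0, 0.0]), np.zeros(2), np.zeros(2), 100.0)
        with pytest.raises(ValueError):
            RotationTrack(np.array([0.0, 1.0]), np.zeros(2), np.zeros(2), 0.0)


class TestAngularVelocity:
    def test_full_circumference_gives_360_over_T(self):
        tr = circle_track(radius=200.0, omega_deg_s=360.0 / 80.0, dt=1.0, duration=80.0)
        ang = angular_velocity(tr, chord_correction=True)
        assert ang.omega_deg_per_s == pytest.approx(360.0 / 80.0, rel=1e-9)
        assert ang.total_angle_deg == pytest.approx(360.0, rel=1e-9)

    def test_arithmetic_oracle_54_8_nm_over_311_nm(self):
        # a straight 54.8 nm step in 1 s on a 311 nm radius: 10.1 deg/s
        tr = RotationTrack(np.array([0.0, 1.0]), np.array([0.0, 54.8]),
                           np.zeros(2), nucleus_radius=311.0)
        ang = angular_velocity(tr)
        assert ang.omega_deg_per_s == pytest.approx(10.1, abs=0.05)

    def test_doubling_radius_halves_omega(self):
        t = np.array([0.0, 1.0, 2.0])
        x = np.array([0.0, 30.0, 60.0])
        y = np.zeros(3)
        w1 = angular_velocity(RotationTrack(t, x, y, 100.0)).omega_deg_per_s
        w2 = angular_velocity(RotationTrack(t, x, y, 200.0)).omega_deg_per_s
        assert w1 == pytest.approx(2 * w2, rel=1e-12)

    @given(
        st.lists(st.tuples(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4)),
                 min_size=2, max_size=20),
        st.floats(10.0, 2000.0),
        st.floats(-1e5, 1e5),
        st.floats(-1e5, 1e5),
        st.floats(0, 2 * math.pi),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_identity_and_rigid_motion_invariance(self, pts, radius, dx, dy, rot):
        """omega * r * pi/180 equals the linear speed exactly, and both are
        invariant under rigid rotation + translation of the frame."""
        t = np.arange(len(pts), dtype=float)
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        tr = RotationTrack(t, x, y, radius)
        speed, _ = rotation_speed(tr)
        ang = angular_velocity(tr)
        assert ang.omega_deg_per_s * radius * math.pi / 180 == pytest.approx(
            speed, rel=1e-12, abs=1e-12)
        c, s = math.cos(rot), math.sin(rot)
        tr2 = RotationTrack(t, c * x - s * y + dx, s * x + c * y + dy, radius)
        assert rotation_speed(tr2)[0] == pytest.approx(speed, rel=1e-9, abs=1e-7)


class TestRotatingFraction:
    @pytest.mark.parametrize("k,n,expected", [(0, 100, 0.0), (50, 100, 50.0)])
    def test_simple_fractions(self, k, n, expected):
        pct, n_out = rotating_fraction([True] * k + [False] * (n - k))
        assert pct == pytest.approx(expected) and n_out == n

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            rotating_fraction([])

    def test_planted_cohort_recovered_within_binomial_ci(self):
        flags = synthetic.generate_rotating_cohort(n_cells=858, p_rotating=0.04, seed=0)
        pct, n = rotating_fraction(flags)
        assert n == 858
        sd = 100 * math.sqrt(0.04 * 0.96 / 858)
        assert abs(pct - 4.0) < 3 * sd


class TestPositioning:
    @pytest.mark.parametrize(
        "center,length,expected",
        [(2.0, 4.0, 0.5), (0.0, 4.0, 0.0), (1.0, 4.0, 0.25), (3.0, 4.0, 0.25)],
    )
    def test_nearer_pole_examples(self, center, length, expected):
        g = CellGeometry(cell_length=length, nucleus_center=center)
        assert positioning_ratio(g) == pytest.approx(expected)

    def test_designated_pole(self):
        g = CellGeometry(cell_length=4.0, nucleus_center=3.0)
        assert positioning_ratio(g, pole_policy="designated") == pytest.approx(0.75)

    @given(st.floats(0.5, 20.0), st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_nearer_ratio_bounded(self, length, frac):
        g = CellGeometry(cell_length=length, nucleus_center=frac * length)
        assert 0.0 <= positioning_ratio(g) <= 0.5

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            CellGeometry(cell_length=4.0, nucleus_center=5.0)
        with pytest.raises(ValueError):
            CellGeometry(4.0, 2.0, ((1.0, 0.5),))
        with pytest.raises(ValueError):
            CellGeometry(4.0, 2.0, ((0.5, 2.0), (1.5, 3.0)))  # overlapping


class TestNucleoidContext:
    def test_between_two(self):
        g = CellGeometry(4.0, 2.0, ((0.2, 1.2), (2.8, 3.8)))
        assert nucleoid_context(g) == BETWEEN_TWO

    def test_inside_a_nucleoid(self):
        g = CellGeometry(4.0, 0.7, ((0.2, 1.2), (2.8, 3.8)))
        assert nucleoid_context(g) == NOT_BETWEEN_TWO

    def test_boundary_contact_is_not_between(self):
        g = CellGeometry(4.0, 1.2, ((0.2, 1.2), (2.8, 3.8)))
        assert nucleoid_context(g) == NOT_BETWEEN_TWO

    def test_single_nucleoid(self):
        g = CellGeometry(4.0, 2.0, ((1.0, 3.0),))
        assert nucleoid_context(g) == SINGLE_NUCLEOID

    def test_three_nucleoids_unsupported(self):
        g = CellGeometry(6.0, 3.0, ((0.2, 1.0), (2.0, 2.5), (4.0, 5.0)))
        assert nucleoid_context(g) == UNSUPPORTED


class TestFilamentCall:
    @pytest.mark.parametrize("ratio,expected", [(2.1, True), (1.9, False), (2.0, True)])
    def test_double_background_threshold_inclusive(self, ratio, expected):
        assert call_filament(ratio * 150.0, 150.0) is expected

    def test_background_must_be_positive(self):
        with pytest.raises(ValueError):
            call_filament(100.0, 0.0)


class TestDoseResponse:
    def test_exact_curve_recovered_to_three_significant_figures(self):
        # counts realized on the planted curve with n large enough that
        # rounding is negligible
        bottom, top, ec50, hill = 0.0, 100.0, 0.03, 2.0
        conc = np.array([0.003, 0.01, 0.02, 0.04, 0.1, 0.3])
        p = (bottom + (top - bottom) / (1 + (ec50 / conc) ** hill)) / 100
        n = 10**6
        data = DoseResponseData(conc, np.full(6, n), np.round(p * n).astype(int))
        fit = fit_dose_response(data)
        assert fit.success
        assert fit.ec50 == pytest.approx(ec50, rel=5e-4)
        assert fit.hill == pytest.approx(hill, rel=5e-4)
        assert fit.top == pytest.approx(top, rel=5e-4)
        assert abs(fit.bottom - bottom) < 0.05

    def test_flat_response_reports_failure(self):
        data = DoseResponseData(
            np.array([0.001, 0.01, 0.1, 1.0]), np.full(4, 50), np.full(4, 25)
        )
        fit = fit_dose_response(data)
        assert not fit.success
        assert "flat" in fit.message
        assert math.isnan(fit.ec50)

    def test_too_few_concentrations_reports_failure(self):
        data = DoseResponseData(np.array([0.01, 0.1, 1.0]), np.full(3, 50),
                                np.array([0, 25, 50]))
        fit = fit_dose_response(data)
        assert not fit.success and "4" in fit.message

    def test_zero_concentration_floored_one_decade_below_minimum(self):
        data, _ = synthetic.generate_dose_response(seed=1)
        fit = fit_dose_response(data)
        assert fit.zero_floor == pytest.approx(min(c for c in data.concentrations if c > 0) / 10)

    def test_binomial_sampling_recovery(self):
        data, truth = synthetic.generate_dose_response(n_per_conc=50, seed=0)
        fit = fit_dose_response(data)
        assert fit.success
        assert fit.ec50 == pytest.approx(truth["ec50"], rel=0.10)

    def test_count_validation(self):
        with pytest.raises(ValueError):
            DoseResponseData(np.array([0.1]), np.array([10]), np.array([11]))
        with pytest.raises(ValueError):
            DoseResponseData(np.array([-0.1]), np.array([10]), np.array([1]))


class TestTabularIO:
    def test_tracks_round_trip(self, tmp_path):
        tracks, _ = synthetic.generate_tracks(n_tracks=3, seed=2, out_dir=tmp_path)
        loaded = load_tracks_csv(tmp_path / "tracks.csv", tmp_path / "tracks_meta.csv")
        assert len(loaded) == 3
        for a, b in zip(tracks, loaded):
            assert a.track_id == b.track_id
            assert rotation_speed(a)[0] == pytest.approx(rotation_speed(b)[0], rel=1e-9)

    def test_geometries_round_trip(self, tmp_path):
        cells, _ = synthetic.generate_geometries(n_cells=5, seed=3, out_dir=tmp_path)
        loaded = load_geometries_csv(tmp_path / "geometries.csv")
        assert len(loaded) == 5
        for a, b in zip(cells, loaded):
            assert positioning_ratio(a) == pytest.approx(positioning_ratio(b), rel=1e-6)
            assert nucleoid_context(a) == nucleoid_context(b)

    def test_dose_response_round_trip(self, tmp_path):
        data, _ = synthetic.generate_dose_response(seed=4, out_dir=tmp_path)
        loaded = load_dose_response_csv(tmp_path / "dose_response.csv")
        assert np.allclose(loaded.concentrations, data.concentrations)
        assert np.array_equal(loaded.n_with_filaments, data.n_with_filaments)
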