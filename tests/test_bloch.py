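import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from mpcasl import bloch
from mpcasl.bloch import (
    GAMMA,
    FlowingSpin,
    LabelGeometry,
    MagnetisationState,
    PulseTrain,
    TransitWarning,
    bloch_step,
    efficiency_grid,
    gmax_to_thickness,
    hanning_envelope,
    resolve_peak_b1,
    saturation_vs_duration,
    simulate_passage,
    thickness_to_gmax,
)


class TestHanningEnvelope:
    def test_maximum_at_midpoint(self):
        assert hanning_envelope(300e-6, 600e-6, 5.0) == pytest.approx(5.0)

    def test_zero_outside_support(self):
        assert hanning_envelope(600e-6, 600e-6, 5.0) == 0.0
        assert hanning_envelope(1e-3, 600e-6, 5.0) == 0.0

    def test_integral_matches_quadrature(self):
        # independent quadrature oracle for the pulse area
        peak, dur = 5.0, 600e-6
        area, _ = quad(lambda t: hanning_envelope(t, dur, peak), 0.0, dur)
        assert area == pytest.approx(peak * dur / 2.0, rel=1e-6)

    @pytest.mark.parametrize("dur,peak", [(-1e-4, 5.0), (600e-6, -1.0), (0.0, 5.0)])
    def test_parameter_errors(self, dur, peak):
        with pytest.raises(ValueError):
            hanning_envelope(1e-4, dur, peak)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            hanning_envelope(-1e-6, 600e-6, 5.0)


class TestBlochStep:
    def test_zero_field_no_relaxation_is_identity(self):
        s = MagnetisationState(0.3, -0.2, 0.9)
        out = bloch_step(s, [0.0, 0.0, 0.0], 1e-3)
        assert (out.mx, out.my, out.mz) == (0.3, -0.2, 0.9)

    def test_on_resonance_rotation_matches_closed_form(self):
        # constant B1 along x: Mz(t) = cos(gamma * B1 * t)
        b1 = 5e-6
        t = 123e-6
        n = 1000
        s = MagnetisationState()
        for _ in range(n):
            s = bloch_step(s, [b1, 0.0, 0.0], t / n)
        assert s.mz == pytest.approx(math.cos(GAMMA * b1 * t), abs=1e-9)
        assert s.norm == pytest.approx(1.0, abs=1e-9)

    def test_t1_relaxation_closed_form(self):
        s = MagnetisationState(0.0, 0.0, -1.0)
        dt, t1 = 0.05, 2.1
        out = bloch_step(s, [0.0, 0.0, 0.0], dt, t1=t1)
        expected = 1.0 - (1.0 - (-1.0)) * math.exp(-dt / t1)
        assert out.mz == pytest.approx(expected, abs=1e-9)

    def test_t2_relaxation_closed_form(self):
        s = MagnetisationState(1.0, 0.0, 0.0)
        out = bloch_step(s, [0.0, 0.0, 0.0], 0.01, t2=0.033)
        assert out.mx == pytest.approx(math.exp(-0.01 / 0.033), abs=1e-12)

    def test_non_finite_field_raises(self):
        with pytest.raises(FloatingPointError):
            bloch_step(MagnetisationState(), [np.nan, 0.0, 0.0], 1e-6)

    def test_single_hard_pulse_180_inverts(self):
        # stationary spin, rectangular pulse with flip exactly pi
        dur = 600e-6
        b1 = math.pi / (GAMMA * dur)
        n = 1200
        s = MagnetisationState()
        for _ in range(n):
            s = bloch_step(s, [b1, 0.0, 0.0], dur / n)
        efficiency = (1.0 - s.mz) / 2.0
        assert efficiency == pytest.approx(1.0, abs=1e-6)

    def test_single_hanning_pulse_matches_rotation_oracle(self):
        # on-resonance shaped pulse: flip = gamma * integral(B1)
        dur, peak = 600e-6, 7.3
        n = 2400
        s = MagnetisationState()
        for i in range(n):
            t = (i + 0.5) * dur / n
            b1 = hanning_envelope(t, dur, peak) * 1e-6
            s = bloch_step(s, [b1, 0.0, 0.0], dur / n)
        flip = GAMMA * peak * 1e-6 * dur / 2.0
        assert s.mz == pytest.approx(math.cos(flip), abs=1e-6)


class TestThicknessGradient:
    def test_doubling_thickness_halves_gmax(self):
        g1 = thickness_to_gmax(2.0)
        g2 = thickness_to_gmax(4.0)
        assert g2 == pytest.approx(g1 / 2.0, rel=1e-12)

    def test_round_trip(self):
        g = thickness_to_gmax(2.0, 600e-6)
        assert gmax_to_thickness(g, 600e-6) == pytest.approx(2.0, rel=1e-9)

    def test_ratio_scale_invariance(self):
        assert thickness_to_gmax(1.0) / thickness_to_gmax(10.0) == pytest.approx(10.0)

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            thickness_to_gmax(0.0)


class TestPulseTrain:
    def test_invariants(self):
        with pytest.raises(ValueError):
            PulseTrain(pulse_duration=2e-3, inter_pulse_interval=1.2e-3)
        with pytest.raises(ValueError):
            PulseTrain(peak_b1=-1.0)

    def test_label_duration_pulse_count(self):
        train = PulseTrain(label_duration=0.9)
        assert train.n_pulses == 750

    def test_flip_angle_derived_from_peak(self):
        # 5 uT peak Hanning of 600 us is ~23 degrees, not the nominal 40
        assert PulseTrain(peak_b1=5.0).flip_angle == pytest.approx(23.0, abs=0.2)

    def test_b1_convention(self):
        assert resolve_peak_b1(5.0, "peak") == 5.0
        assert resolve_peak_b1(5.0, "pulse_mean") == 10.0
        with pytest.raises(ValueError):
            resolve_peak_b1(5.0, "train_mean")


class TestSimulatePassage:
    def test_no_rf_gives_zero_efficiency(self, fast_geom, fast_spin):
        eff = simulate_passage(PulseTrain(peak_b1=0.0), fast_geom, fast_spin)
        assert eff == pytest.approx(0.0, abs=1e-12)

    def test_efficiency_in_unit_interval(self, fast_geom):
        for v, b1 in [(50.0, 2.0), (100.0, 5.0), (200.0, 8.0)]:
            eff = simulate_passage(
                PulseTrain(peak_b1=b1), fast_geom, FlowingSpin(velocity=v)
            )
            assert 0.0 <= eff <= 1.0

    def test_norm_conserved_without_relaxation(self, fast_geom):
        # slow transit, long train, no relaxation: |M| must not drift
        spin = FlowingSpin(velocity=11.5, t1_blood=math.inf, t2_blood=math.inf)
        geom = fast_geom
        thickness_m = geom.label_thickness * 1e-3
        margin = 5.0 * thickness_m
        v = spin.velocity * 1e-3
        transit = 2 * margin / v  # ~0.87 s
        train = PulseTrain(peak_b1=5.0, label_duration=transit + 0.05)
        g_max = geom.g_max * 1e-3
        gap = train.inter_pulse_interval - train.pulse_duration
        g_ref = (geom.g_mean * 1e-3 * train.inter_pulse_interval - g_max * train.pulse_duration) / gap
        mx, my, mz, _ = bloch._passage_kernel(
            v, -margin, margin, thickness_m / 2, 5e-6, g_max, g_ref,
            train.pulse_duration, train.inter_pulse_interval, 0.0,
            train.n_pulses, 0.0, 0.0, False,
        )
        assert abs(math.sqrt(mx**2 + my**2 + mz**2) - 1.0) < 1e-8

    def test_control_phase_suppresses_labelling(self, operating_geom, operating_spin):
        label = simulate_passage(PulseTrain(peak_b1=5.0), operating_geom, operating_spin)
        control = simulate_passage(
            PulseTrain(peak_b1=5.0, phase_increment=180.0), operating_geom, operating_spin
        )
        assert control <= 0.1 * label

    def test_phase_increment_mirror_symmetry(self, fast_geom, fast_spin):
        # exact Bloch mirror: (theta, +G) == (-theta, -G)
        e_pos = simulate_passage(
            PulseTrain(peak_b1=5.0, phase_increment=45.0), fast_geom, fast_spin
        )
        e_mirror = simulate_passage(
            PulseTrain(peak_b1=5.0, phase_increment=-45.0),
            fast_geom,
            fast_spin,
            invert_gradient=True,
        )
        assert e_pos == pytest.approx(e_mirror, abs=1e-12)

    def test_phase_symmetry_without_gradient_flip_is_approximate(
        self, fast_geom, fast_spin
    ):
        e_pos = simulate_passage(
            PulseTrain(peak_b1=5.0, phase_increment=45.0), fast_geom, fast_spin
        )
        e_neg = simulate_passage(
            PulseTrain(peak_b1=5.0, phase_increment=-45.0), fast_geom, fast_spin
        )
        assert abs(e_pos - e_neg) < 0.01

    def test_short_train_warns(self, fast_geom, fast_spin):
        with pytest.warns(TransitWarning):
            simulate_passage(
                PulseTrain(peak_b1=5.0, label_duration=0.01), fast_geom, fast_spin
            )

    def test_spin_must_start_upstream(self, fast_geom):
        spin = FlowingSpin(velocity=100.0, start_position=1.0)
        with pytest.raises(ValueError):
            simulate_passage(PulseTrain(peak_b1=5.0), fast_geom, spin)

    def test_readout_conventions_ordering(self, operating_geom, operating_spin):
        frozen = simulate_passage(
            PulseTrain(peak_b1=5.0), operating_geom, operating_spin, readout="downstream"
        )
        relaxed = simulate_passage(
            PulseTrain(peak_b1=5.0), operating_geom, operating_spin, readout="relaxed"
        )
        # T1 recovery downstream can only reduce the apparent inversion
        assert relaxed < frozen


class TestEfficiencyGrid:
    def test_degenerate_grid_equals_single_call(self, fast_geom, fast_spin):
        df = efficiency_grid([1.0], [200.0], [5.0])
        single = simulate_passage(
            PulseTrain(peak_b1=5.0), LabelGeometry(label_thickness=1.0), FlowingSpin(velocity=200.0)
        )
        assert len(df) == 1
        assert df.efficiency.iloc[0] == pytest.approx(single, abs=1e-12)

    def test_cardinality(self):
        df = efficiency_grid([1.0, 2.0], [150.0, 200.0], [0.0, 5.0])
        assert len(df) == 8

    def test_b1_zero_column_is_zero(self):
        df = efficiency_grid([1.0], [100.0, 200.0], [0.0])
        assert np.allclose(df.efficiency, 0.0, atol=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            efficiency_grid([], [100.0], [5.0])


class TestSaturationVsDuration:
    def test_zero_duration_gives_zero(self, fast_geom, fast_spin):
        df = saturation_vs_duration([0.0], PulseTrain(peak_b1=5.0), fast_geom, fast_spin)
        assert df.saturation.iloc[0] == 0.0

    def test_monotone_over_paper_range(self, fast_geom, fast_spin):
        durations = [0.4, 0.9, 2.0, 3.5, 5.0]
        df = saturation_vs_duration(durations, PulseTrain(peak_b1=5.0), fast_geom, fast_spin)
        assert np.all(np.diff(df.saturation.to_numpy()) >= -1e-12)

    def test_plateau_for_long_durations(self, fast_geom, fast_spin):
        df = saturation_vs_duration([12.0], PulseTrain(peak_b1=5.0), fast_geom, fast_spin)
        asymptote = df.efficiency.iloc[0]  # alpha * 1 in the long-tau limit
        assert df.saturation.iloc[0] == pytest.approx(asymptote, rel=0.01)
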