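import numpy as np
import pytest

from fescycling import (
    CONTINUOUS,
    CircularInterval,
    ConfigurationError,
    MuscleModel,
    SimulationConfig,
    StimulationPattern,
    StimulatorModel,
    generate_active,
    generate_crank,
    generate_emg,
    generate_passive,
    raised_cosine_bump,
    segment_revolutions,
    to_angular_profile,
)
from fescycling.simulate import PassiveLoad


class TestCrank:
    def test_one_revolution_per_period(self):
        cfg = SimulationConfig(cadence=50.0, duration=1.2)
        t, angle = generate_crank(cfg)
        assert t[-1] == pytest.approx(1.2)
        assert len(segment_revolutions(angle)) == 1

    def test_cadence_control_error(self):
        """A 1.66% relative error at a 50 rpm target realizes 49.18 rpm
        (motor cadence-control accuracy at the top of the tested range)."""
        cfg = SimulationConfig(cadence=50.0, duration=2.0, cadence_error_fraction=0.0164)
        assert cfg.realized_cadence == pytest.approx(49.18)
        _, angle = generate_crank(cfg)
        # angular rate = 6 * realized cadence deg/s
        assert (angle[1] - angle[0]) * cfg.sample_rate == pytest.approx(6 * 49.18)

    def test_determinism(self):
        cfg = SimulationConfig(cadence=40.0, duration=1.0, noise_sd_force=2.0, seed=11)
        a = generate_passive(cfg, generate_crank(cfg))
        b = generate_passive(cfg, generate_crank(cfg))
        np.testing.assert_array_equal(a.pedals["left"].fx, b.pedals["left"].fx)
        np.testing.assert_array_equal(a.crank_angle, b.crank_angle)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(cadence=50.0, duration=-1.0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(cadence=120.0, duration=1.0)


class TestPassive:
    def test_zero_load_zero_noise_gives_zero_forces(self):
        cfg = SimulationConfig(cadence=50.0, duration=1.2)
        rec = generate_passive(cfg, generate_crank(cfg), load=PassiveLoad.zero())
        for side in ("left", "right"):
            np.testing.assert_array_equal(rec.pedals[side].fx, 0.0)
            np.testing.assert_array_equal(rec.pedals[side].fy, 0.0)

    def test_noiseless_revolutions_identical(self):
        cfg = SimulationConfig(cadence=50.0, duration=2.4)
        rec = generate_passive(cfg, generate_crank(cfg))
        (a0, a1), (b0, b1) = segment_revolutions(rec)
        np.testing.assert_allclose(
            rec.pedals["left"].fx[a0:a1], rec.pedals["left"].fx[b0:b1], atol=1e-9
        )

    def test_binned_noise_shrinks_with_support(self):
        """With white force noise of sd 5 N, the per-bin mean has sd about
        5 / sqrt(samples per bin) (Monte-Carlo against the bin counts)."""
        cfg = SimulationConfig(cadence=50.0, duration=12.0, noise_sd_force=5.0, seed=2)
        rec = generate_passive(cfg, generate_crank(cfg), load=PassiveLoad.zero())
        prof = to_angular_profile(rec, "left.fx")
        expected_sd = 5.0 / np.sqrt(np.mean(prof.counts))
        assert np.std(prof.values) == pytest.approx(expected_sd, rel=0.15)


class TestActive:
    def test_continuous_force_spans_exactly_the_active_arc(self, quad_right):
        """Under continuous stimulation the delays have no observable effect:
        force appears over exactly the muscle's active arc."""
        muscle = quad_right
        assert muscle.emd == 0.0
        delayed = MuscleModel(
            name=muscle.name,
            side=muscle.side,
            active_arc=muscle.active_arc,
            peak_force=muscle.peak_force,
            emd=0.123,  # arbitrary, must be irrelevant
        )
        cfg = SimulationConfig(cadence=50.0, duration=2.4)
        crank = generate_crank(cfg)
        rec = generate_active(
            cfg, crank, [delayed], StimulatorModel(), CONTINUOUS, load=PassiveLoad.zero()
        )
        f_t = rec.pedals["right"].fx
        inside = delayed.active_arc.contains(rec.crank_angle)
        # Skip the start-up transient (first delay's worth of samples).
        settle = int(0.2 * cfg.sample_rate)
        assert np.all(f_t[settle:][inside[settle:]] >= 0)
        assert np.all(f_t[settle:][~inside[settle:]] == 0)
        interior = inside[settle:] & (f_t[settle:] > 1e-9)
        assert interior.any()

    def test_zero_peak_equals_passive(self):
        muscle = MuscleModel(
            name="right_quadriceps",
            side="right",
            active_arc=CircularInterval(0, 120),
            peak_force=0.0,
        )
        cfg = SimulationConfig(cadence=50.0, duration=1.2, noise_sd_force=1.0, seed=5)
        crank = generate_crank(cfg)
        active = generate_active(cfg, crank, [muscle], StimulatorModel(), CONTINUOUS)
        passive = generate_passive(cfg, crank, channels=["right_quadriceps"])
        np.testing.assert_array_equal(active.pedals["right"].fx, passive.pedals["right"].fx)

    def test_superposition_is_exact(self, quad_right):
        """active - passive (noise 0) equals the injected bump pointwise."""
        cfg = SimulationConfig(cadence=50.0, duration=2.4)
        crank = generate_crank(cfg)
        active = generate_active(
            cfg, crank, [quad_right], StimulatorModel(internal_delay=0.0), CONTINUOUS
        )
        passive = generate_passive(cfg, crank, channels=[quad_right.name])
        injected = raised_cosine_bump(
            crank[1], quad_right.active_arc, quad_right.peak_force
        )
        np.testing.assert_allclose(
            active.pedals["right"].fx - passive.pedals["right"].fx, injected, atol=1e-9
        )

    def test_patterned_delay_shifts_force_onset(self):
        """A 53.3 ms total delay at 50 rpm lags the force onset 16 degrees of
        crank angle behind the commanded onset, within one sample of motion."""
        stim = StimulatorModel(internal_delay=0.0032)
        muscle = MuscleModel(
            name="right_quadriceps",
            side="right",
            active_arc=CircularInterval(0, 140),
            peak_force=50.0,
            emd=0.0501,
        )
        pattern = StimulationPattern(
            channels={"right_quadriceps": CircularInterval(20, 90)}, stim_params=stim
        )
        cfg = SimulationConfig(cadence=50.0, duration=2.4)
        crank = generate_crank(cfg)
        rec = generate_active(cfg, crank, [muscle], stim, pattern, load=PassiveLoad.zero())
        t, angle = crank
        i0, i1 = segment_revolutions(angle)[1]  # steady-state revolution
        f_t = rec.pedals["right"].fx[i0:i1]
        ang = angle[i0:i1]
        onset_angle = ang[np.flatnonzero(f_t > 0)[0]]
        expected = 20.0 + (0.0032 + 0.0501) * 6.0 * 50.0
        deg_per_sample = 6.0 * 50.0 / cfg.sample_rate
        assert onset_angle == pytest.approx(expected, abs=deg_per_sample)
        # stim_state records the commanded, not the delayed, activity
        commanded = rec.stim_state["right_quadriceps"][i0:i1]
        assert ang[np.flatnonzero(commanded)[0]] == pytest.approx(20.0, abs=deg_per_sample)

    def test_negative_arc_hinders(self):
        muscle = MuscleModel(
            name="right_quadriceps",
            side="right",
            active_arc=CircularInterval(0, 120),
            peak_force=30.0,
            emd=0.0,
            negative_arc=CircularInterval(200, 260),
            negative_force=10.0,
        )
        cfg = SimulationConfig(cadence=50.0, duration=1.2)
        crank = generate_crank(cfg)
        rec = generate_active(
            cfg, crank, [muscle], StimulatorModel(internal_delay=0.0), CONTINUOUS,
            load=PassiveLoad.zero(),
        )
        f_t = rec.pedals["right"].fx
        neg = muscle.negative_arc.contains(crank[1])
        assert np.min(f_t[neg]) < -9.0
        assert np.all(f_t[~neg] >= 0.0)

    def test_fatigue_decays_peak_per_revolution(self):
        muscle = MuscleModel(
            name="right_quadriceps",
            side="right",
            active_arc=CircularInterval(0, 120),
            peak_force=30.0,
            emd=0.0,
            fatigue_decay=0.1,
        )
        cfg = SimulationConfig(cadence=50.0, duration=3.6)
        crank = generate_crank(cfg)
        rec = generate_active(
            cfg, crank, [muscle], StimulatorModel(internal_delay=0.0), CONTINUOUS,
            load=PassiveLoad.zero(),
        )
        segs = segment_revolutions(crank[1])
        peaks = [np.max(rec.pedals["right"].fx[i0:i1]) for i0, i1 in segs]
        assert peaks[1] == pytest.approx(0.9 * peaks[0], rel=1e-6)
        assert peaks[2] == pytest.approx(0.81 * peaks[0], rel=1e-6)

    def test_unknown_channel_rejected(self, quad_right):
        pattern = StimulationPattern(channels={"left_hamstrings": CircularInterval(0, 90)})
        cfg = SimulationConfig(cadence=50.0, duration=1.2)
        with pytest.raises(ConfigurationError, match="unknown"):
            generate_active(
                cfg, generate_crank(cfg), [quad_right], StimulatorModel(), pattern
            )


class TestEmg:
    def test_determinism(self, quad_right):
        cfg = SimulationConfig(cadence=50.0, duration=2.4, seed=9)
        crank = generate_crank(cfg)
        a = generate_emg(cfg, crank, [quad_right])
        b = generate_emg(cfg, crank, [quad_right])
        np.testing.assert_array_equal(a[quad_right.name], b[quad_right.name])

    def test_zero_amplitude_is_pure_baseline(self, quad_right):
        cfg = SimulationConfig(cadence=50.0, duration=2.4, seed=9)
        crank = generate_crank(cfg)
        emg = generate_emg(cfg, crank, [quad_right], burst_amplitude=0.0, snr=10.0)
        x = emg[quad_right.name]
        inside = quad_right.active_arc.contains(crank[1])
        # No angle-locked modulation: comparable power inside and outside the arc.
        assert np.std(x[inside]) == pytest.approx(np.std(x[~inside]), rel=0.1)
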