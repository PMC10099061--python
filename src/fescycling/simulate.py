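"""Forward simulation of instrumented-ergometer FES-cycling sessions.

Emulates the recording streams of a cadence-controlled cycling ergometer
with force/torque pedals, an 8-channel stimulator and (for the volitional
sessions) surface EMG, so that every downstream analysis stage is testable
without hardware:

* crank kinematics at a constant realized cadence (target × (1 − error));
* passive pedal loads — the gravito-inertial forces of the strapped legs —
  as a two-harmonic circular function of each pedal's own angle, plus white
  measurement noise;
* stimulated-muscle contributions: a raised-cosine tangential-force bump
  over the muscle's active arc, gated by the stimulation command delayed by
  the stimulator's internal latency D_S plus the muscle's electromechanical
  delay EMD, with optional geometric fatigue decay per revolution and an
  optional hindering (negative-force) arc;
* per-muscle EMG: 10–30 Hz band-limited noise bursts amplitude-modulated by
  a Hann window over the muscle's activation arc, on top of baseline noise.

All randomness is seeded through :class:`~fescycling.models.SimulationConfig`;
identical configurations produce identical recordings.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal

from .forces import compose
from .intervals import CircularInterval
from .models import ConfigurationError, MuscleModel, SimulationConfig, StimulatorModel
from .patterns import StimulationPattern
from .recording import SIDES, PedalWrench, SessionRecording

#: Sentinel for continuous (un-patterned) stimulation of every muscle.
CONTINUOUS = "continuous"


@dataclass(frozen=True)
class PassiveLoad:
    """Two-harmonic model of the passive pedal load (legs' weight + inertia).

    Each pedal sees, as a function of its *own* crank position φ (left pedal:
    φ = θ; right pedal: φ = θ + 180°),

        F_t(φ) = t0 + t1·cos(φ − t1_phase) + t2·cos(2φ − t2_phase)
        F_n(φ) = n0 + n1·cos(φ − n1_phase) + n2·cos(2φ − n2_phase)

    Defaults give a ±~15 N tangential oscillation and a compressive normal
    load, the order of magnitude seen with strapped adult legs.
    """

    t0: float = -2.0
    t1: float = 14.0
    t1_phase: float = 90.0
    t2: float = 4.0
    t2_phase: float = 0.0
    n0: float = -15.0
    n1: float = 20.0
    n1_phase: float = 0.0
    n2: float = 5.0
    n2_phase: float = 0.0

    @classmethod
    def zero(cls) -> "PassiveLoad":
        return cls(0, 0, 0, 0, 0, 0, 0, 0, 0, 0)

    def tangential(self, phi_deg) -> np.ndarray:
        th = np.deg2rad(np.asarray(phi_deg, dtype=float))
        return (
            self.t0
            + self.t1 * np.cos(th - np.deg2rad(self.t1_phase))
            + self.t2 * np.cos(2 * th - np.deg2rad(self.t2_phase))
        )

    def normal(self, phi_deg) -> np.ndarray:
        th = np.deg2rad(np.asarray(phi_deg, dtype=float))
        return (
            self.n0
            + self.n1 * np.cos(th - np.deg2rad(self.n1_phase))
            + self.n2 * np.cos(2 * th - np.deg2rad(self.n2_phase))
        )


def generate_crank(
    config: SimulationConfig, start_angle_deg: float = 0.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Time base and wrapped crank-angle stream for one recording.

    The realized cadence is ``cadence × (1 − cadence_error_fraction)``,
    constant within the run. The sample at ``t = duration`` is included, so
    an exact number of periods closes its final revolution.
    """
    n = int(round(config.duration * config.sample_rate)) + 1
    t = np.arange(n) / config.sample_rate
    angle = (start_angle_deg + 6.0 * config.realized_cadence * t) % 360.0
    return t, angle


def _side_angle(crank_angle: np.ndarray, side: str) -> np.ndarray:
    """Pedal's own crank position: the right crank trails the left by 180°."""
    return crank_angle if side == "left" else (crank_angle + 180.0) % 360.0


def raised_cosine_bump(angle_deg, arc: CircularInterval, peak: float) -> np.ndarray:
    """Smooth unimodal force shape over ``arc``: zero at both arc ends,
    ``peak`` at the centre."""
    u = ((np.asarray(angle_deg, dtype=float) - arc.start) % 360.0) / arc.length
    inside = u <= 1.0
    return np.where(inside, peak * 0.5 * (1.0 - np.cos(2 * np.pi * u)), 0.0)


def generate_passive(
    config: SimulationConfig,
    crank: Tuple[np.ndarray, np.ndarray],
    load: Optional[PassiveLoad] = None,
    pedal_inclination_deg: float = 0.0,
    channels: Sequence[str] = (),
) -> SessionRecording:
    """Motor-driven cycling with no stimulation (the subtraction baseline)."""
    if load is None:
        load = PassiveLoad()
    time, angle = crank
    rng = np.random.default_rng(config.seed)
    n = len(time)
    pedals: Dict[str, PedalWrench] = {}
    inclination: Dict[str, np.ndarray] = {}
    for side in SIDES:
        phi = _side_angle(angle, side)
        beta = np.full(n, pedal_inclination_deg)
        fx, fy = compose(load.tangential(phi), load.normal(phi), beta)
        noise = config.noise_sd_force
        pedals[side] = PedalWrench(
            fx=fx + noise * rng.standard_normal(n),
            fy=fy + noise * rng.standard_normal(n),
            fz=noise * rng.standard_normal(n),
            tx=np.zeros(n),
            ty=np.zeros(n),
            tz=np.zeros(n),
        )
        inclination[side] = beta
    stim = {ch: np.zeros(n, dtype=bool) for ch in channels}
    return SessionRecording(
        time=time,
        crank_angle=angle,
        pedals=pedals,
        inclination=inclination,
        stim_state=stim,
        meta=config,
        phase="passive",
    )


def generate_active(
    config: SimulationConfig,
    crank: Tuple[np.ndarray, np.ndarray],
    muscles: Sequence[MuscleModel],
    stimulator: StimulatorModel,
    pattern: Union[StimulationPattern, str],
    load: Optional[PassiveLoad] = None,
    pedal_inclination_deg: float = 0.0,
) -> SessionRecording:
    """Cycling with stimulated muscles superimposed on the passive load.

    A muscle produces force only where stimulation was commanded
    ``stimulator.internal_delay + muscle.emd`` seconds earlier *and* the
    current crank angle lies inside its active (or hindering) arc. Under
    ``CONTINUOUS`` stimulation the command is always on, so the delays have
    no observable effect and force appears over exactly the active arc.
    ``stim_state`` records the commanded (not delayed) channel activity.
    """
    names = {m.name for m in muscles}
    if isinstance(pattern, StimulationPattern):
        unknown = set(pattern.channels) - names
        if unknown:
            raise ConfigurationError(f"pattern references unknown muscles: {sorted(unknown)}")
    elif pattern != CONTINUOUS:
        raise ConfigurationError(f"pattern must be a StimulationPattern or CONTINUOUS")

    rec = generate_passive(
        config, crank, load, pedal_inclination_deg, channels=[m.name for m in muscles]
    )
    time, angle = crank
    n = len(time)
    # Revolution index for fatigue decay (relative to the recording start).
    unwrapped = 6.0 * config.realized_cadence * time
    rev = np.floor(unwrapped / 360.0 + 1e-12).astype(int)

    for muscle in muscles:
        if isinstance(pattern, StimulationPattern):
            if muscle.name not in pattern.channels:
                continue
            commanded = pattern.channels[muscle.name].contains(angle)
        else:
            commanded = np.ones(n, dtype=bool)
        rec.stim_state[muscle.name] = commanded

        if isinstance(pattern, StimulationPattern):
            lag = int(round((stimulator.internal_delay + muscle.emd) * config.sample_rate))
            effective = np.zeros(n, dtype=bool)
            if lag < n:
                effective[lag:] = commanded[: n - lag] if lag else commanded
        else:
            # Continuous stimulation has been on since before the recording
            # window: the delays are unobservable.
            effective = commanded
        gain = (1.0 - muscle.fatigue_decay) ** rev
        f_t = raised_cosine_bump(angle, muscle.active_arc, muscle.peak_force)
        if muscle.negative_arc is not None:
            f_t = f_t - raised_cosine_bump(angle, muscle.negative_arc, muscle.negative_force)
        f_t = np.where(effective, f_t * gain, 0.0)

        fx_add, fy_add = compose(f_t, np.zeros(n), rec.inclination[muscle.side])
        rec.pedals[muscle.side].fx += fx_add
        rec.pedals[muscle.side].fy += fy_add

    rec.phase = "active"
    return rec


def generate_emg(
    config: SimulationConfig,
    crank: Tuple[np.ndarray, np.ndarray],
    muscles: Sequence[MuscleModel],
    burst_amplitude: float = 1.0,
    snr: float = 10.0,
    band: Tuple[float, float] = (10.0, 30.0),
) -> Dict[str, np.ndarray]:
    """Per-muscle surface-EMG streams for a volitional cycling session.

    Each muscle emits a band-limited noise carrier (unit RMS, energy in
    ``band``) amplitude-modulated by a Hann window over its activation arc
    (``muscle.active_arc``), on top of white baseline noise of standard
    deviation ``burst_amplitude / snr``.
    """
    time, angle = crank
    n = len(time)
    baseline_sd = burst_amplitude / snr if snr > 0 else 0.0
    sos = signal.butter(2, band, btype="bandpass", fs=config.sample_rate, output="sos")
    out: Dict[str, np.ndarray] = {}
    for k, muscle in enumerate(muscles):
        rng = np.random.default_rng([config.seed, 1000 + k])
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
        rms = np.sqrt(np.mean(carrier**2))
        if rms > 0:
            carrier = carrier / rms
        envelope = raised_cosine_bump(angle, muscle.active_arc, 1.0)
        out[muscle.name] = (
            burst_amplitude * envelope * carrier + baseline_sd * rng.standard_normal(n)
        )
    return out


# ---------------------------------------------------------------------------
# Study-condition defaults
# ---------------------------------------------------------------------------


def default_sci_muscles() -> list[MuscleModel]:
    """Ground-truth quadriceps models for the simulated SCI rider.

    Peak tangential forces (25 / 22 N) put the two-sided power of a wide
    pattern at 50 rpm near 10 W with 0.17 m cranks, the scale produced by
    trained paralyzed quadriceps. EMD 50.1 ms.
    """
    return [
        MuscleModel(
            name="right_quadriceps",
            side="right",
            active_arc=CircularInterval(0.0, 170.0),
            peak_force=25.0,
            emd=0.0501,
        ),
        MuscleModel(
            name="left_quadriceps",
            side="left",
            active_arc=CircularInterval(180.0, 350.0),
            peak_force=22.0,
            emd=0.0501,
        ),
    ]


def default_emg_muscles() -> list[MuscleModel]:
    """Activation arcs of the dominant-leg quadriceps heads for the
    simulated able-bodied EMG session (volitional cycling at 50 rpm).

    Volitional onsets sit earlier on the crank circle than the stimulated
    quadriceps' productive range (volitional cycling also recruits hip
    flexors unreachable by surface stimulation), so the EMG-derived pattern
    is deliberately offset from the force-optimal placement.
    """
    arcs = {
        "rectus_femoris": CircularInterval(335.0, 85.0),
        "vastus_lateralis": CircularInterval(355.0, 125.0),
        "vastus_medialis": CircularInterval(343.0, 100.0),
    }
    return [
        MuscleModel(name=name, side="right", active_arc=arc, peak_force=0.0, emd=0.0)
        for name, arc in arcs.items()
    ]
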