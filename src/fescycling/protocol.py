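"""End-to-end orchestration of the four-phase assessment protocol.

The protocol mirrors a single-session study design: after a passive warm-up,
four electro-stimulated phases are run, each beginning with 5-10 passive
cycles followed by 2 active cycles (and a rest period, which is metadata
only):

1. ``mfp``          — continuous stimulation of each muscle group at 30 rpm
                      to record its muscle force profile (MFP);
2. ``shift``        — patterned stimulation with a probe arc in the first
                      half of the MFP's positive range at 50 rpm, to measure
                      the total stimulation-to-force angular shift directly;
3. ``emg_pattern``  — cycling with the delay-compensated EMG-derived pattern;
4. ``mfp_pattern``  — cycling with the delay-compensated MFP-derived pattern
                      (same arc length as the EMG pattern, placed to maximize
                      the force integral).

The EMG pattern itself comes from a separate volitional-cycling EMG session
(:func:`simulate_emg_session` / :func:`derive_emg_pattern`): per-muscle 25%
threshold activation intervals, union over the quadriceps heads, opposite
leg by 180° rotation.

Everything is deterministic given the scenario seed; per-phase recordings
derive their seeds from it.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import emg as emg_mod
from .forces import MuscleForceProfile, net_force, tangential_profile
from .intervals import CircularInterval
from .models import DelayModel, MuscleModel, SimulationConfig, StimulatorModel
from .patterns import StimulationPattern, compensate, full_range_pattern, measure_shift, mfp_pattern
from .power import PowerResult, compare_patterns, mean_power
from .recording import SessionRecording, segment_revolutions, write_recording
from .simulate import (
    CONTINUOUS,
    PassiveLoad,
    default_emg_muscles,
    default_sci_muscles,
    generate_active,
    generate_crank,
    generate_emg,
    generate_passive,
)

VALID_KINDS = ("passive", "mfp", "shift", "emg_pattern", "mfp_pattern")


@dataclass(frozen=True)
class PhaseSpec:
    """One protocol phase: 5-10 passive cycles then ``n_active_revs`` active."""

    label: str
    kind: str
    cadence: float
    n_passive_revs: int = 8
    n_active_revs: int = 2

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.kind != "passive" and not (5 <= self.n_passive_revs <= 10):
            raise ValueError("each stimulated phase begins with 5 to 10 passive cycles")


@dataclass(frozen=True)
class ProtocolPlan:
    phases: Tuple[PhaseSpec, ...]
    stimulator: StimulatorModel = field(default_factory=StimulatorModel)
    crank_length: float = 0.17
    bin_width: float = 1.0


def default_plan() -> ProtocolPlan:
    """The study protocol: MFP determination at 30 rpm, then shift
    measurement and both pattern trials at 50 rpm."""
    return ProtocolPlan(
        phases=(
            PhaseSpec("phase1_mfp", "mfp", cadence=30.0),
            PhaseSpec("phase2_shift", "shift", cadence=50.0),
            PhaseSpec("phase3_emg_pattern", "emg_pattern", cadence=50.0),
            PhaseSpec("phase4_mfp_pattern", "mfp_pattern", cadence=50.0),
        )
    )


@dataclass(frozen=True)
class Scenario:
    """Simulator ground truth: who is riding and what the hardware does."""

    muscles: Tuple[MuscleModel, ...] = tuple(default_sci_muscles())
    emg_muscles: Tuple[MuscleModel, ...] = tuple(default_emg_muscles())
    load: PassiveLoad = field(default_factory=PassiveLoad)
    stimulator: StimulatorModel = field(default_factory=StimulatorModel)
    noise_sd_force: float = 3.0
    cadence_error_fraction: float = 0.0
    emg_snr: float = 10.0
    emg_revolutions: int = 20
    seed: int = 0


def _seed_stream(seed: int):
    for s in np.random.SeedSequence(seed).generate_state(64):
        yield int(s) >> 1  # keep below 2**31


def _config(scenario: Scenario, cadence: float, n_revs: int, seed: int) -> SimulationConfig:
    return SimulationConfig(
        cadence=cadence,
        duration=n_revs * 60.0 / (cadence * (1.0 - scenario.cadence_error_fraction)),
        cadence_error_fraction=scenario.cadence_error_fraction,
        noise_sd_force=scenario.noise_sd_force,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# EMG session → EMG pattern
# ---------------------------------------------------------------------------


def simulate_emg_session(
    scenario: Scenario, cadence: float = 50.0, seed: Optional[int] = None
) -> SessionRecording:
    """Volitional cycling of the able-bodied subject with surface EMG on the
    dominant-leg quadriceps heads."""
    cfg = _config(
        scenario, cadence, scenario.emg_revolutions, scenario.seed if seed is None else seed
    )
    crank = generate_crank(cfg)
    rec = generate_passive(cfg, crank, scenario.load)
    rec.emg = generate_emg(cfg, crank, scenario.emg_muscles, snr=scenario.emg_snr)
    rec.phase = "emg_session"
    return rec


def derive_emg_pattern(
    rec: SessionRecording,
    threshold_fraction: float = 0.25,
    bin_width: float = 1.0,
    stimulator: Optional[StimulatorModel] = None,
) -> Tuple[StimulationPattern, Dict[str, CircularInterval]]:
    """Per-muscle activation intervals and the resulting quadriceps pattern.

    The dominant (right) quadriceps interval is the union over the recorded
    heads; the left-leg interval is its 180° rotation (the legs' motion is
    antisymmetric on the crank circle). Returns the uncompensated pattern
    and the per-muscle intervals.
    """
    if not rec.emg:
        raise ValueError("recording carries no EMG channels")
    fs = rec.meta.sample_rate
    segments = segment_revolutions(rec)
    intervals: Dict[str, CircularInterval] = {}
    for muscle, raw in rec.emg.items():
        filtered = emg_mod.bandpass_emg(raw, fs)
        env = emg_mod.envelope(filtered, fs)
        prof = emg_mod.mean_emg_profile(env, rec.crank_angle, segments, muscle, bin_width)
        intervals[muscle] = emg_mod.activation_interval(prof, threshold_fraction)
    quad_right = emg_mod.union_intervals(list(intervals.values()))
    quad_left = quad_right.rotated(180.0)
    pattern = StimulationPattern(
        channels={"right_quadriceps": quad_right, "left_quadriceps": quad_left},
        stim_params=stimulator or StimulatorModel(),
    )
    return pattern, intervals


# ---------------------------------------------------------------------------
# Protocol phases
# ---------------------------------------------------------------------------


def _phase_recordings(
    scenario: Scenario,
    plan: ProtocolPlan,
    phase: PhaseSpec,
    pattern,
    muscles: Sequence[MuscleModel],
    seeds,
) -> Tuple[SessionRecording, Optional[SessionRecording]]:
    """Simulate the passive baseline and (unless passive-only) the active
    cycles of one phase."""
    cfg_p = _config(scenario, phase.cadence, phase.n_passive_revs, next(seeds))
    passive = generate_passive(
        cfg_p, generate_crank(cfg_p), scenario.load, channels=[m.name for m in muscles]
    )
    passive.phase = f"{phase.label}_passive"
    if phase.kind == "passive":
        return passive, None
    cfg_a = _config(scenario, phase.cadence, phase.n_active_revs, next(seeds))
    active = generate_active(
        cfg_a, generate_crank(cfg_a), muscles, plan.stimulator, pattern, scenario.load
    )
    active.phase = f"{phase.label}_active"
    return passive, active


def _side_nets(
    active: SessionRecording,
    passive: SessionRecording,
    cadence: float,
    bin_width: float,
) -> Dict[str, MuscleForceProfile]:
    nets = {}
    for side in active.pedals:
        ap = tangential_profile(active, side, bin_width=bin_width)
        pp = tangential_profile(passive, side, bin_width=bin_width)
        nets[side] = net_force(ap, pp, side=side, cadence=cadence)
    return nets


def _probe_pattern(
    mfps: Dict[str, MuscleForceProfile], stimulator: StimulatorModel
) -> StimulationPattern:
    """Probe arc inside the first half of each MFP's positive range, for the
    direct shift measurement."""
    channels = {}
    for name, profile in mfps.items():
        positive = full_range_pattern(profile)
        quarter = positive.length / 4.0
        channels[name] = CircularInterval(
            positive.start + quarter, positive.start + 2.0 * quarter
        )
    return StimulationPattern(channels=channels, stim_params=stimulator)


def simulate_shift_trial(
    total_delay_s: float,
    cadence: float = 50.0,
    noise_sd_force: float = 3.0,
    seed: int = 0,
    stimulator: Optional[StimulatorModel] = None,
    peak_force: float = 50.0,
    n_passive_revs: int = 8,
    n_active_revs: int = 2,
    bin_width: float = 1.0,
) -> float:
    """One direct shift-measurement trial on synthetic data.

    A muscle with the given total stimulation-to-force delay is stimulated
    over a probe arc in the first half of its productive range; the function
    returns the measured angular lag (degrees) between the commanded probe
    start and the net-force onset. At 50 rpm a 53.3 ms delay should measure
    near 16°.
    """
    stim = stimulator or StimulatorModel()
    emd = max(total_delay_s - stim.internal_delay, 0.0)
    muscle = MuscleModel(
        name="right_quadriceps",
        side="right",
        active_arc=CircularInterval(0.0, 140.0),
        peak_force=peak_force,
        emd=emd,
    )
    probe = StimulationPattern(
        channels={muscle.name: CircularInterval(20.0, 90.0)}, stim_params=stim
    )
    seeds = _seed_stream(seed)
    scenario = Scenario(noise_sd_force=noise_sd_force, seed=seed)
    cfg_p = _config(scenario, cadence, n_passive_revs, next(seeds))
    cfg_a = _config(scenario, cadence, n_active_revs, next(seeds))
    passive = generate_passive(cfg_p, generate_crank(cfg_p), scenario.load)
    active = generate_active(
        cfg_a, generate_crank(cfg_a), [muscle], stim, probe, scenario.load
    )
    net = net_force(
        tangential_profile(active, "right", bin_width=bin_width),
        tangential_profile(passive, "right", bin_width=bin_width),
        cadence=cadence,
    )
    return measure_shift(net, probe.channels[muscle.name].start)


def run_protocol(
    plan: ProtocolPlan,
    scenario: Scenario,
    emg_pattern: Optional[StimulationPattern] = None,
    out_dir: Optional[Path] = None,
) -> dict:
    """Execute the protocol phases in order, threading derived artifacts
    (MFPs → measured shift → compensated patterns → powers).

    ``emg_pattern`` is the uncompensated EMG-derived pattern; if omitted it
    is derived from a simulated volitional EMG session. Returns a bundle
    with every intermediate and a final comparison report; writes all
    intermediates under ``out_dir`` when given. Deterministic given the
    scenario seed.
    """
    seeds = _seed_stream(scenario.seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    needs_emg = any(p.kind == "emg_pattern" for p in plan.phases) or any(
        p.kind == "mfp_pattern" for p in plan.phases
    )
    emg_intervals: Dict[str, CircularInterval] = {}
    if emg_pattern is None and needs_emg:
        emg_rec = simulate_emg_session(scenario, seed=next(seeds))
        emg_pattern, emg_intervals = derive_emg_pattern(
            emg_rec, bin_width=plan.bin_width, stimulator=plan.stimulator
        )
        if out_dir is not None:
            write_recording(emg_rec, out_dir / "emg_session.txt")

    bundle: dict = {
        "emg_pattern": emg_pattern,
        "emg_intervals": emg_intervals,
        "mfps": {},
        "delay_model": None,
        "measured_shift_deg": None,
        "patterns": {},
        "powers": {},
        "passive_baseline": {},
    }
    muscles = list(scenario.muscles)
    entries = {}

    for phase in plan.phases:
        if phase.kind == "passive":
            passive, _ = _phase_recordings(scenario, plan, phase, None, muscles, seeds)
            prof = {
                side: tangential_profile(passive, side, bin_width=plan.bin_width)
                for side in passive.pedals
            }
            bundle["passive_baseline"][phase.label] = prof
            if out_dir is not None:
                write_recording(passive, out_dir / f"{phase.label}.txt")

        elif phase.kind == "mfp":
            for muscle in muscles:
                passive, active = _phase_recordings(
                    scenario, plan, phase, CONTINUOUS, [muscle], seeds
                )
                ap = tangential_profile(active, muscle.side, bin_width=plan.bin_width)
                pp = tangential_profile(passive, muscle.side, bin_width=plan.bin_width)
                bundle["mfps"][muscle.name] = net_force(
                    ap, pp, muscle=muscle.name, side=muscle.side, cadence=phase.cadence
                )
                if out_dir is not None:
                    write_recording(passive, out_dir / f"{phase.label}_{muscle.name}_passive.txt")
                    write_recording(active, out_dir / f"{phase.label}_{muscle.name}_active.txt")

        elif phase.kind == "shift":
            if not bundle["mfps"]:
                raise ValueError("shift phase requires MFPs from an earlier mfp phase")
            probe = _probe_pattern(bundle["mfps"], plan.stimulator)
            passive, active = _phase_recordings(scenario, plan, phase, probe, muscles, seeds)
            nets = _side_nets(active, passive, phase.cadence, plan.bin_width)
            shifts = []
            for muscle in muscles:
                net = nets[muscle.side]
                shifts.append(measure_shift(net, probe.channels[muscle.name].start))
            shift_deg = float(np.mean(shifts))
            total_delay_s = shift_deg / (6.0 * phase.cadence)
            d_s = plan.stimulator.internal_delay
            bundle["measured_shift_deg"] = shift_deg
            bundle["delay_model"] = DelayModel(d_s=d_s, emd=max(total_delay_s - d_s, 0.0))
            bundle["patterns"]["probe"] = probe

        elif phase.kind in ("emg_pattern", "mfp_pattern"):
            delays = bundle["delay_model"]
            if delays is None:
                raise ValueError(f"{phase.kind} phase requires a measured delay (shift phase)")
            if phase.kind == "emg_pattern":
                if emg_pattern is None:
                    raise ValueError("emg_pattern phase requires an EMG-derived pattern")
                uncompensated = emg_pattern
            else:
                if not bundle["mfps"]:
                    raise ValueError("mfp_pattern phase requires MFPs")
                if emg_pattern is None:
                    raise ValueError("mfp_pattern phase needs the EMG pattern's arc lengths")
                channels = {
                    name: mfp_pattern(profile, emg_pattern.channels[name].length)
                    for name, profile in bundle["mfps"].items()
                }
                uncompensated = StimulationPattern(channels=channels, stim_params=plan.stimulator)
            pattern = compensate(uncompensated, delays, phase.cadence, mode="start_only")
            passive, active = _phase_recordings(scenario, plan, phase, pattern, muscles, seeds)
            nets = _side_nets(active, passive, phase.cadence, plan.bin_width)
            per_side = {
                side: mean_power(net, phase.cadence, plan.crank_length)
                for side, net in nets.items()
            }
            result = PowerResult(
                per_side=per_side,
                cadence=phase.cadence,
                crank_length=plan.crank_length,
                pattern_id=phase.kind,
            )
            bundle["patterns"][phase.kind] = pattern
            bundle["powers"][phase.kind] = result
            entries[phase.kind] = (pattern, result)
            if out_dir is not None:
                write_recording(passive, out_dir / f"{phase.label}_passive.txt")
                write_recording(active, out_dir / f"{phase.label}_active.txt")
                for side, net in nets.items():
                    pd.DataFrame(
                        {
                            "angle_deg": net.grid,
                            "force_n": net.values,
                            "counts": net.profile.counts,
                        }
                    ).to_csv(out_dir / f"net_{phase.kind}_{side}.tsv", sep="\t", index=False)

    if entries:
        reference = "emg_pattern" if "emg_pattern" in entries else next(iter(entries))
        bundle["report"] = compare_patterns(entries, reference=reference)
    else:
        rows = []
        for label, profs in bundle["passive_baseline"].items():
            for side, prof in profs.items():
                rows.append(
                    {
                        "pattern": label,
                        "side": side,
                        "mean_tangential_force_n": round(float(np.mean(prof.values)), 3),
                    }
                )
        bundle["report"] = pd.DataFrame(rows)

    if out_dir is not None:
        _write_summary(bundle, plan, out_dir)
    return bundle


def _write_summary(bundle: dict, plan: ProtocolPlan, out_dir: Path) -> None:
    bundle["report"].to_csv(out_dir / "report.csv", index=False)
    summary = {
        "crank_length_m": plan.crank_length,
        "bin_width_deg": plan.bin_width,
        "measured_shift_deg": bundle["measured_shift_deg"],
        "delays_ms": None
        if bundle["delay_model"] is None
        else {"d_s": bundle["delay_model"].d_s * 1e3, "emd": bundle["delay_model"].emd * 1e3},
        "patterns": {
            label: {
                "cadence_rpm": pat.cadence_design,
                "compensated": pat.compensated,
                "channels": {
                    name: [iv.start, iv.stop] for name, iv in pat.channels.items()
                },
            }
            for label, pat in bundle["patterns"].items()
        },
        "powers_w": {
            label: {"per_side": res.per_side, "total": res.total, "cadence_rpm": res.cadence}
            for label, res in bundle["powers"].items()
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))


def recompute_report(out_dir: Path) -> pd.DataFrame:
    """Rebuild the comparison report from written intermediates (net-force
    tables + summary metadata), for checkpoint-consistency verification."""
    out_dir = Path(out_dir)
    summary = json.loads((out_dir / "summary.json").read_text())
    entries = {}
    from .recording import RevolutionProfile  # local import to avoid cycle noise

    for label, pat_meta in summary["patterns"].items():
        if label not in summary["powers_w"]:
            continue
        channels = {
            name: CircularInterval(*se) for name, se in pat_meta["channels"].items()
        }
        pattern = StimulationPattern(
            channels=channels,
            compensated=pat_meta["compensated"],
            cadence_design=pat_meta["cadence_rpm"],
        )
        per_side = {}
        for side in ("left", "right"):
            table = pd.read_csv(out_dir / f"net_{label}_{side}.tsv", sep="\t")
            prof = RevolutionProfile(
                grid=table["angle_deg"].to_numpy(),
                values=table["force_n"].to_numpy(),
                counts=table["counts"].to_numpy(),
                n_revolutions=1,
                bin_width=summary["bin_width_deg"],
            )
            per_side[side] = mean_power(
                prof, pat_meta["cadence_rpm"], summary["crank_length_m"]
            )
        entries[label] = (
            pattern,
            PowerResult(
                per_side=per_side,
                cadence=pat_meta["cadence_rpm"],
                crank_length=summary["crank_length_m"],
                pattern_id=label,
            ),
        )
    reference = "emg_pattern" if "emg_pattern" in entries else next(iter(entries))
    return compare_patterns(entries, reference=reference)
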