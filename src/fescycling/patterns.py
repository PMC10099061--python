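"""Stimulation-pattern derivation and delay compensation.

A stimulation pattern assigns each muscle-group channel a crank-angle arc
during which it is stimulated. Patterns are derived either from EMG
activation intervals (see :mod:`fescycling.emg`) or from muscle force
profiles, then shifted earlier to compensate the stimulator delay D_S and
the electromechanical delay EMD. At cadence ω (rpm) a delay of d seconds
sweeps d·360·ω/60 degrees of crank angle:

    Δθ_start = (D_S + EMD) · 360 · ω / 60        (start must pre-empt both)
    Δθ_stop  =  D_S · 360 · ω / 60               (force decay outlasts EMD)

The total shift can also be measured directly, as the angle between the
commanded stimulation onset and the first noticeable rise of the net-force.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .forces import MuscleForceProfile
from .intervals import CircularInterval
from .models import DelayModel, StimulatorModel
from .recording import RevolutionProfile


@dataclass(frozen=True)
class StimulationPattern:
    """Per-channel stimulation arcs plus the stimulator settings they assume.

    ``compensated`` marks a pattern whose start (and possibly stop) angles
    have already been shifted for the delays; the :class:`DelayModel` used
    is then recorded in ``delays``.
    """

    channels: Dict[str, CircularInterval]
    stim_params: StimulatorModel = field(default_factory=StimulatorModel)
    cadence_design: float = 50.0
    compensated: bool = False
    delays: Optional[DelayModel] = None


def _values_of(profile) -> tuple[np.ndarray, np.ndarray, float]:
    """(grid, values, bin_width) from an MFP, EmgProfile or RevolutionProfile."""
    if isinstance(profile, RevolutionProfile):
        p = profile
    else:
        p = profile.profile
    return p.grid, p.values, p.bin_width


def mfp_pattern(mfp: MuscleForceProfile, length_deg: float) -> CircularInterval:
    """Arc of a fixed length maximizing the integral of the force profile.

    Matching the arc length of a reference (EMG) pattern keeps the amount of
    stimulation — hence, approximately, the induced fatigue — equal while
    placing it where the muscle produces the most force. The search is an
    exhaustive scan over every grid start; ties go to the smallest start.
    """
    grid, values, bw = _values_of(mfp)
    if not (0 < length_deg <= 360):
        raise ValueError("length_deg must lie in (0, 360]")
    if np.max(values) <= 0:
        raise ValueError("no contributing range: force profile is nowhere positive")
    n = len(values)
    win = int(round(length_deg / bw))
    win = max(1, min(win, n))
    # Circular moving sum over `win` consecutive bins.
    ext = np.concatenate([values, values[: win - 1]])
    sums = np.convolve(ext, np.ones(win), mode="valid")
    best = int(np.argmax(sums + 0.0))
    # np.argmax already returns the first (smallest-start) maximizer.
    start = grid[best] - bw / 2.0
    return CircularInterval(start, start + length_deg)


def _interp_crossing(theta0, v0, theta1, v1, level) -> float:
    """Angle where the linear segment (theta0,v0)→(theta1,v1) crosses level."""
    if v1 == v0:
        return theta0
    return theta0 + (level - v0) / (v1 - v0) * ((theta1 - theta0) % 360.0)


def _run_around_argmax(values: np.ndarray, mask: np.ndarray) -> Tuple[int, int]:
    """Extent (first, last bin index, circular) of the True run containing
    the argmax of ``values``."""
    n = len(values)
    imax = int(np.argmax(values))
    lo = imax
    while mask[(lo - 1) % n] and ((imax - (lo - 1)) % n) < n - 1:
        lo = (lo - 1) % n
    hi = imax
    while mask[(hi + 1) % n] and (((hi + 1) - imax) % n) < n - 1:
        hi = (hi + 1) % n
    return lo, hi


def full_range_pattern(mfp: MuscleForceProfile) -> CircularInterval:
    """Arc from the last zero transition before the force maximum to the
    first zero transition after it (the widest useful stimulation range).

    Boundaries are refined by linear interpolation between the bracketing
    bins. A profile positive everywhere returns the full circle with a
    warning.
    """
    grid, values, bw = _values_of(mfp)
    if np.max(values) <= 0:
        raise ValueError("force profile attains no positive maximum")
    mask = values > 0
    if mask.all():
        warnings.warn("force profile positive everywhere; full-circle pattern")
        return CircularInterval.full()
    lo, hi = _run_around_argmax(values, mask)
    n = len(values)
    start = _interp_crossing(
        grid[(lo - 1) % n], values[(lo - 1) % n], grid[(lo - 1) % n] + bw, values[lo], 0.0
    )
    stop = _interp_crossing(grid[hi], values[hi], grid[hi] + bw, values[(hi + 1) % n], 0.0)
    return CircularInterval(start, stop)


def threshold_pattern(mfp: MuscleForceProfile, fraction: float) -> CircularInterval:
    """Contiguous arc around the force maximum where the profile stays at or
    above ``fraction`` × max — trades peak power for reduced fatigue."""
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    grid, values, bw = _values_of(mfp)
    vmax = np.max(values)
    if vmax <= 0:
        raise ValueError("force profile attains no positive maximum")
    level = fraction * vmax
    mask = values >= level if fraction > 0 else values > 0
    if mask.all():
        warnings.warn("whole profile above threshold; full-circle pattern")
        return CircularInterval.full()
    lo, hi = _run_around_argmax(values, mask)
    n = len(values)
    start = _interp_crossing(
        grid[(lo - 1) % n], values[(lo - 1) % n], grid[(lo - 1) % n] + bw, values[lo], level
    )
    stop = _interp_crossing(grid[hi], values[hi], grid[hi] + bw, values[(hi + 1) % n], level)
    return CircularInterval(start, stop)


def delay_to_shift(delays: DelayModel, cadence: float) -> Tuple[float, float]:
    """Angular shifts (Δθ_start, Δθ_stop) in degrees for the given delays at
    cadence ``cadence`` rpm."""
    if cadence <= 0:
        raise ValueError("cadence must be positive")
    factor = 360.0 * cadence / 60.0
    return (delays.d_s + delays.emd) * factor, delays.d_s * factor


def compensate(
    pattern: StimulationPattern,
    delays: DelayModel,
    cadence: float,
    mode: str = "start_only",
) -> StimulationPattern:
    """Shift every channel's start (and optionally stop) angle *earlier* so
    the muscle response lands on the designed arc.

    ``start_only`` (default) shifts only the start by Δθ_start, lengthening
    the arc; ``start_and_stop`` also pulls the stop earlier by Δθ_stop.
    Compensating twice is refused.
    """
    if pattern.compensated:
        raise ValueError("pattern is already delay-compensated")
    if mode not in ("start_only", "start_and_stop"):
        raise ValueError(f"unknown mode {mode!r}")
    d_start, d_stop = delay_to_shift(delays, cadence)
    if mode == "start_only":
        d_stop = 0.0
    channels = {
        name: iv.shifted(-d_start, -d_stop) for name, iv in pattern.channels.items()
    }
    return replace(
        pattern, channels=channels, compensated=True, delays=delays, cadence_design=cadence
    )


def measure_shift(
    net: MuscleForceProfile,
    commanded_start: float,
    onset_fraction: float = 0.05,
    baseline_k: float = 3.0,
    min_run_bins: int = 3,
) -> float:
    """Directly measure the total angular lag between the commanded
    stimulation onset and the first noticeable net-force response.

    "Noticeable" is the larger of ``onset_fraction`` × the peak net-force and
    ``baseline_k`` × the baseline standard deviation (estimated on the half
    circle preceding the commanded start); to reject isolated noise spikes
    the crossing must open a run of at least ``min_run_bins`` consecutive
    supra-threshold bins. Returns the lag in degrees; raises if no such
    crossing occurs within 180° of the commanded start.
    """
    grid, values, bw = _values_of(net)
    n = len(values)
    rel = (grid - commanded_start) % 360.0
    baseline = values[rel >= 180.0]
    base_sd = float(np.std(baseline)) if baseline.size else 0.0
    base_mean = float(np.mean(baseline)) if baseline.size else 0.0
    peak = float(np.max(values)) - base_mean
    if peak <= 0:
        raise ValueError("no measurable response: net-force never exceeds baseline")
    thr = base_mean + max(onset_fraction * peak, baseline_k * base_sd)

    order = np.argsort(rel)  # bins in scan order from the commanded start
    above = values[order] > thr
    within = np.sort(rel) < 180.0
    sustained = above.copy()
    for k in range(1, min_run_bins):
        sustained &= np.roll(above, -k)
    candidates = np.flatnonzero(sustained & within)
    if candidates.size == 0:
        raise ValueError("no measurable response within 180° of the commanded start")
    j = int(candidates[0])
    i = int(order[j])
    prev = int(order[j - 1]) if j > 0 else (i - 1) % n
    if j == 0 or values[prev] > thr:
        onset = grid[i] - net.profile.bin_width / 2.0
    else:
        onset = _interp_crossing(grid[prev], values[prev], grid[prev] + bw, values[i], thr)
    return (onset - commanded_start) % 360.0
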