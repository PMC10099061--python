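"""EMG processing: band-pass filtering, envelope extraction, per-revolution
normalized mean profiles, and threshold-based activation intervals.

The raw signal is band-pass filtered ([10, 30] Hz, 4th-order Butterworth,
applied zero-phase so no angular lag is introduced), rectified and smoothed
to a moving-RMS envelope, normalized to its maximum within each revolution,
and bin-averaged over revolutions onto the crank-angle grid. The activation
interval of a muscle is the crank-angle arc where this mean profile exceeds
25% of its peak; a muscle group's interval is the union of its heads'
intervals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .intervals import CircularInterval, union_intervals  # re-export union_intervals
from .recording import RevolutionProfile, angular_profile

__all__ = [
    "EmgProfile",
    "bandpass_emg",
    "envelope",
    "mean_emg_profile",
    "activation_interval",
    "union_intervals",
]


@dataclass
class EmgProfile:
    """Mean normalized EMG envelope of one muscle vs crank angle.

    Values are dimensionless: each revolution is scaled to unit maximum
    before averaging, so averaged values lie in [0, 1].
    """

    muscle: str
    profile: RevolutionProfile

    @property
    def grid(self) -> np.ndarray:
        return self.profile.grid

    @property
    def values(self) -> np.ndarray:
        return self.profile.values


def design_bandpass(sample_rate: float, band=(10.0, 30.0), order: int = 4):
    """Second-order sections of the band-pass filter (overall ``order``)."""
    if order % 2:
        raise ValueError("band-pass order must be even")
    return signal.butter(order // 2, band, btype="bandpass", fs=sample_rate, output="sos")


def bandpass_emg(
    raw: np.ndarray, sample_rate: float, band=(10.0, 30.0), order: int = 4
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass ([10, 30] Hz default)."""
    if sample_rate <= 60.0:
        raise ValueError("sample_rate must exceed 60 Hz for a 10-30 Hz band-pass")
    raw = np.asarray(raw, dtype=float)
    sos = design_bandpass(sample_rate, band, order)
    # sosfiltfilt pads with edge reflections; demand a few filter lengths.
    min_len = 3 * 6 * (sos.shape[0] + 1)
    if len(raw) <= min_len:
        raise ValueError(f"series too short to filter (need > {min_len} samples)")
    return signal.sosfiltfilt(sos, raw)


def envelope(filtered: np.ndarray, sample_rate: float, window_s: float = 0.1) -> np.ndarray:
    """Full-wave rectification followed by a moving-RMS window (default
    100 ms). The band-passed signal averages to ~zero, so thresholding is
    only meaningful on this nonnegative envelope."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = np.asarray(filtered, dtype=float)
    size = max(1, int(round(window_s * sample_rate)))
    return np.sqrt(uniform_filter1d(x * x, size=size, mode="nearest"))


def mean_emg_profile(
    env: np.ndarray,
    crank_angle: np.ndarray,
    segments: Sequence[Tuple[int, int]],
    muscle: str = "",
    bin_width: float = 1.0,
) -> EmgProfile:
    """Normalize the envelope to unit maximum within each revolution, then
    bin-average across revolutions.

    Per-revolution normalization makes the profile invariant to slow
    amplitude drift (e.g. electrode impedance changes). Revolutions with an
    all-zero envelope are excluded with a warning; fewer than two usable
    revolutions also warns.
    """
    env = np.asarray(env, dtype=float)
    normalized = np.full_like(env, np.nan)
    used = []
    for i0, i1 in segments:
        m = np.max(env[i0:i1])
        if m <= 0:
            warnings.warn(f"revolution [{i0}, {i1}) has all-zero envelope; excluded")
            continue
        normalized[i0:i1] = env[i0:i1] / m
        used.append((i0, i1))
    if not used:
        raise ValueError("no revolution with a positive envelope")
    if len(used) < 2:
        warnings.warn("fewer than 2 revolutions; mean EMG profile is a single pass")
    prof = angular_profile(crank_angle, normalized, used, bin_width)
    return EmgProfile(muscle=muscle, profile=prof)


def _circular_runs(mask: np.ndarray) -> list[Tuple[int, int]]:
    """(first, last) bin indices of each True run, treating the array as
    circular; a run crossing the wrap is reported once."""
    n = len(mask)
    if mask.all():
        return [(0, n - 1)]
    if not mask.any():
        return []
    # Start scanning from a False bin so no run is split by the wrap.
    start = int(np.argmin(mask))
    runs = []
    i = 0
    while i < n:
        j = (start + i) % n
        if mask[j]:
            k = i
            while k + 1 < n and mask[(start + k + 1) % n]:
                k += 1
            runs.append(((start + i) % n, (start + k) % n))
            i = k + 1
        else:
            i += 1
    return runs


def activation_interval(
    profile,
    threshold_fraction: float = 0.25,
    merge_gap_deg: float = 5.0,
) -> CircularInterval:
    """Crank-angle arc where the mean EMG profile exceeds a fraction of its
    peak (default 25%).

    Supra-threshold runs separated by gaps narrower than ``merge_gap_deg``
    are merged (small dropouts below threshold do not split the interval);
    the run containing the profile's maximum is returned, with boundaries
    refined by linear interpolation between adjacent bin centers. A profile
    entirely above threshold returns the full circle with a warning.
    """
    prof: RevolutionProfile = profile.profile if hasattr(profile, "profile") else profile
    values = prof.values
    grid = prof.grid
    bw = prof.bin_width
    vmax = float(np.max(values))
    if vmax <= 0:
        raise ValueError("profile has no strictly positive maximum")
    thr = threshold_fraction * vmax
    mask = values >= thr
    runs = _circular_runs(mask)
    if len(runs) == 1 and runs[0] == (0, len(values) - 1):
        warnings.warn("entire profile above threshold; full-circle activation interval")
        return CircularInterval.full()

    # Merge runs separated by sub-threshold gaps narrower than merge_gap_deg.
    n = len(values)
    merged = True
    while merged and len(runs) > 1:
        merged = False
        runs.sort(key=lambda r: r[0])
        for i in range(len(runs)):
            lo1, hi1 = runs[i]
            lo2, hi2 = runs[(i + 1) % len(runs)]
            gap_bins = (lo2 - hi1 - 1) % n
            if gap_bins * bw < merge_gap_deg:
                runs[i] = (lo1, hi2)
                del runs[(i + 1) % len(runs)]
                merged = True
                break

    imax = int(np.argmax(values))
    chosen = None
    for lo, hi in runs:
        if ((imax - lo) % n) <= ((hi - lo) % n):
            chosen = (lo, hi)
            break
    if chosen is None:  # numerical safety; argmax is supra-threshold by construction
        chosen = max(runs, key=lambda r: (r[1] - r[0]) % n)
    lo, hi = chosen
    span_bins = (hi - lo) % n
    if span_bins >= n - 1:
        warnings.warn("activation interval covers the full circle")
        return CircularInterval.full()

    prev = (lo - 1) % n
    nxt = (hi + 1) % n
    if values[prev] < thr:
        start = _interp(grid[prev], values[prev], grid[prev] + bw, values[lo], thr)
    else:  # merged-gap boundary: fall back to the bin edge
        start = grid[lo] - bw / 2.0
    if values[nxt] < thr:
        stop = _interp(grid[hi], values[hi], grid[hi] + bw, values[nxt], thr)
    else:
        stop = grid[hi] + bw / 2.0
    return CircularInterval(start, stop)


def _interp(theta0: float, v0: float, theta1: float, v1: float, level: float) -> float:
    if v1 == v0:
        return theta0
    return theta0 + (level - v0) / (v1 - v0) * (theta1 - theta0)
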