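"""Pedal-force decomposition and muscle force profiles.

A pedal sensor reports forces in its own (pedal-fixed) frame together with
the pedal's inclination relative to the crank arm. Rotating the in-plane
force by the inclination yields the component tangential to the pedal's
circular path (F_t, positive when it drives the cycling motion) and the
component along the crank arm (F_n, which produces no motion).

The muscle force profile (MFP) of a stimulated muscle group is the
tangential-force difference between active cycling (the group continuously
stimulated) and passive cycling (motor only), averaged over revolutions on
the crank-angle grid. Positive MFP means the contraction contributes to the
motion at that angle; negative means it hinders it. The "net-force" is the
same subtraction when stimulation follows an intermittent pattern instead
of being continuous.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .recording import RevolutionProfile, SessionRecording, angular_profile, segment_revolutions


@dataclass
class MuscleForceProfile:
    """Active-minus-passive tangential force (N) vs crank angle for one
    stimulated muscle group."""

    muscle: str
    side: str
    profile: RevolutionProfile
    cadence: float

    @property
    def grid(self) -> np.ndarray:
        return self.profile.grid

    @property
    def values(self) -> np.ndarray:
        return self.profile.values


def decompose(fx, fy, inclination_deg) -> Tuple[np.ndarray, np.ndarray]:
    """Rotate in-plane pedal-frame forces into the crank frame.

    ``fx``/``fy`` are the pedal-frame in-plane force components; the pedal
    frame is rotated by ``inclination_deg`` relative to the crank frame.
    Returns ``(F_t, F_n)``: tangential (drives rotation when positive) and
    normal (along the crank arm). A pure rotation, so F_t² + F_n² equals the
    in-plane squared magnitude exactly.
    """
    beta = np.deg2rad(np.asarray(inclination_deg, dtype=float))
    fx = np.asarray(fx, dtype=float)
    fy = np.asarray(fy, dtype=float)
    f_t = fx * np.cos(beta) - fy * np.sin(beta)
    f_n = fx * np.sin(beta) + fy * np.cos(beta)
    return f_t, f_n


def compose(f_t, f_n, inclination_deg) -> Tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`decompose`: crank-frame force into the pedal frame."""
    beta = np.deg2rad(np.asarray(inclination_deg, dtype=float))
    fx = np.asarray(f_t) * np.cos(beta) + np.asarray(f_n) * np.sin(beta)
    fy = -np.asarray(f_t) * np.sin(beta) + np.asarray(f_n) * np.cos(beta)
    return fx, fy


def tangential_profile(
    rec: SessionRecording,
    side: str,
    segments: Optional[Sequence[Tuple[int, int]]] = None,
    bin_width: float = 1.0,
) -> RevolutionProfile:
    """Per-sample tangential force of one pedal, bin-averaged over
    complete revolutions against the (global) crank angle."""
    if side not in rec.pedals:
        raise ValueError(f"recording has no {side!r} pedal")
    if segments is None:
        segments = segment_revolutions(rec)
    f_t, _ = decompose(rec.pedals[side].fx, rec.pedals[side].fy, rec.inclination[side])
    return angular_profile(rec.crank_angle, f_t, segments, bin_width)


def _check_compatible(active: RevolutionProfile, passive: RevolutionProfile) -> None:
    if active.n_bins != passive.n_bins or abs(active.bin_width - passive.bin_width) > 1e-12:
        raise ValueError("active and passive profiles are on different angular grids")


def mfp(
    active: RevolutionProfile,
    passive: RevolutionProfile,
    muscle: str = "",
    side: str = "",
    cadence: float = 0.0,
) -> MuscleForceProfile:
    """Muscle force profile: per-bin active − passive tangential force.

    Both profiles must come from the same conditions (same seating position
    and cadence) on the same angular grid.
    """
    _check_compatible(active, passive)
    diff = RevolutionProfile(
        grid=active.grid.copy(),
        values=active.values - passive.values,
        counts=np.minimum(active.counts, passive.counts),
        n_revolutions=active.n_revolutions,
        bin_width=active.bin_width,
    )
    return MuscleForceProfile(muscle=muscle, side=side, profile=diff, cadence=cadence)


def net_force(
    active_patterned: RevolutionProfile,
    passive: RevolutionProfile,
    muscle: str = "",
    side: str = "",
    cadence: float = 0.0,
) -> MuscleForceProfile:
    """Net-force: the same subtraction as :func:`mfp`, for a trial where the
    muscle group is stimulated only within a pattern's angular range."""
    return mfp(active_patterned, passive, muscle=muscle, side=side, cadence=cadence)
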