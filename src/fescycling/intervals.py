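"""Circular arcs of crank angle.

All angles are in degrees. Crank angle 0° means the left crank arm points
forward and horizontal; the angle increases in the pedaling direction and
the right crank arm sits at +180°. A :class:`CircularInterval` is the basic
unit of a stimulation pattern: the arc over which one channel is on.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

FULL_CIRCLE = 360.0


def wrap_angle(theta: float) -> float:
    """Wrap an angle to [0, 360)."""
    return float(theta) % FULL_CIRCLE


@dataclass(frozen=True)
class CircularInterval:
    """Arc from ``start`` to ``stop`` going in the pedaling direction.

    ``start == stop`` denotes the full circle (length 360°), not an empty
    arc; empty arcs are not representable, every pattern stimulates for a
    positive amount of angle.
    """

    start: float
    stop: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", wrap_angle(self.start))
        object.__setattr__(self, "stop", wrap_angle(self.stop))

    @classmethod
    def full(cls) -> "CircularInterval":
        return cls(0.0, 0.0)

    @property
    def length(self) -> float:
        """Arc length in degrees, in (0, 360]."""
        span = (self.stop - self.start) % FULL_CIRCLE
        return FULL_CIRCLE if span == 0.0 else span

    def contains(self, theta):
        """Membership test, vectorized over ``theta`` (degrees)."""
        rel = (np.asarray(theta, dtype=float) - self.start) % FULL_CIRCLE
        return rel <= self.length

    def shifted(self, dstart: float, dstop: float) -> "CircularInterval":
        """Move the endpoints by the given (signed) amounts, mod 360."""
        return CircularInterval(self.start + dstart, self.stop + dstop)

    def rotated(self, delta: float) -> "CircularInterval":
        """Rigidly rotate the arc by ``delta`` degrees."""
        return self.shifted(delta, delta)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.start:.1f}°, {self.stop:.1f}°]"


def merge_arcs(intervals: Sequence[CircularInterval]) -> list[CircularInterval]:
    """Merge overlapping or touching arcs into disjoint arcs.

    Returns the merged arcs sorted by start angle, or ``[CircularInterval.full()]``
    when the inputs cover the whole circle.
    """
    if not intervals:
        raise ValueError("need at least one interval")
    arcs = [(iv.start, iv.length) for iv in intervals]
    if any(ln >= FULL_CIRCLE for _, ln in arcs):
        return [CircularInterval.full()]

    # Find an uncovered base point: some arc's stop that lies in no arc's
    # interior. If none exists the union is the full circle.
    base = None
    for st, ln in arcs:
        p = (st + ln) % FULL_CIRCLE
        if not any(((p - st2) % FULL_CIRCLE) < ln2 for st2, ln2 in arcs):
            base = p
            break
    if base is None:
        return [CircularInterval.full()]

    # Unroll relative to the gap point and merge linearly.
    rel = sorted(((st - base) % FULL_CIRCLE, ln) for st, ln in arcs)
    merged: list[list[float]] = []
    for st, ln in rel:
        if merged and st <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], st + ln)
        else:
            merged.append([st, st + ln])
    return [
        CircularInterval(base + a, base + b)
        for a, b in sorted(merged)
    ]


def union_intervals(intervals: Iterable[CircularInterval]) -> CircularInterval:
    """Smallest single arc covering the union of the inputs.

    Overlapping or adjacent arcs merge exactly. When the merged pieces are
    disjoint, the covering arc that leaves out the largest gap (i.e. adds the
    least uncovered angle) is returned; ties go to the smaller start angle.
    A union covering the whole circle returns the full circle with a warning.
    """
    intervals = list(intervals)
    merged = merge_arcs(intervals)
    if len(merged) == 1:
        arc = merged[0]
        if arc.length >= FULL_CIRCLE:
            warnings.warn("interval union covers the full circle")
        return arc

    # Gap after each merged arc (to the next arc's start, going around).
    candidates = []
    for i, arc in enumerate(merged):
        nxt = merged[(i + 1) % len(merged)]
        gap = (nxt.start - arc.stop) % FULL_CIRCLE
        # Excluding this gap yields the covering arc [nxt.start, arc.stop].
        candidates.append((gap, nxt.start, CircularInterval(nxt.start, arc.stop)))
    best_gap = max(g for g, _, _ in candidates)
    winners = [c for g, s, c in sorted(candidates, key=lambda t: t[1]) if g == best_gap]
    return winners[0]
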