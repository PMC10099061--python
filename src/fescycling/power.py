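"""Power produced by a stimulated muscle group over a revolution.

With the motor holding the cadence ω (rpm) constant, the pedal moves at a
constant tangential speed v = r·ω·2π/60 (crank length r in metres). The
mean power of a muscle group over one cycle is the revolution-average of
its instantaneous tangential power:

    P = (1/360) · Σ_bins F_t(θ) · v · Δθ

where F_t is the net-force (active-minus-passive tangential force under the
pattern of interest).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .forces import MuscleForceProfile
from .patterns import StimulationPattern
from .recording import RevolutionProfile


@dataclass
class PowerResult:
    """Mean per-cycle power of one pattern, per side and total."""

    per_side: Dict[str, float]
    cadence: float
    crank_length: float
    pattern_id: str = ""

    @property
    def total(self) -> float:
        return float(sum(self.per_side.values()))


def mean_power(net, cadence: float, crank_length: float) -> float:
    """Mean power (W) over one cycle from a net-force profile.

    ``net`` is a :class:`MuscleForceProfile` or a raw
    :class:`RevolutionProfile` of tangential force (N). Bins without support
    are treated as zero force with a warning.
    """
    if cadence <= 0:
        raise ValueError("cadence must be positive")
    if crank_length <= 0:
        raise ValueError("crank_length must be positive")
    prof: RevolutionProfile = net.profile if isinstance(net, MuscleForceProfile) else net
    values = np.asarray(prof.values, dtype=float)
    undefined = (prof.counts == 0) | ~np.isfinite(values)
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} bins without support treated as 0 N")
        values = np.where(undefined, 0.0, values)
    v = crank_length * cadence * 2.0 * np.pi / 60.0  # tangential pedal speed, m/s
    return float(np.mean(values) * v)


def percent_increase(p_ref: float, p_new: float) -> float:
    """Relative power gain of ``p_new`` over ``p_ref``, in percent."""
    if p_ref <= 0:
        raise ValueError("reference power must be positive")
    return 100.0 * (p_new - p_ref) / p_ref


def compare_patterns(
    entries: Mapping[str, Tuple[Optional[StimulationPattern], PowerResult]],
    reference: Optional[str] = None,
) -> pd.DataFrame:
    """Tabulate per-pattern stimulation angles, per-side and total power,
    and the percent power difference vs a designated reference pattern.

    ``entries`` maps a pattern label to ``(pattern, power_result)``; the
    pattern may be None for rows without angles (e.g. a passive baseline).
    The table round-trips through CSV.
    """
    if not entries:
        raise ValueError("need at least one pattern to compare")
    if reference is None:
        reference = next(iter(entries))
    if reference not in entries:
        raise ValueError(f"reference {reference!r} not among entries")
    p_ref = entries[reference][1].total
    rows = []
    for label, (pattern, result) in entries.items():
        row: Dict[str, object] = {"pattern": label}
        for side in ("left", "right"):
            iv = None
            if pattern is not None:
                for ch, interval in pattern.channels.items():
                    if ch.startswith(side):
                        iv = interval
                        break
            row[f"{side}_start_deg"] = round(iv.start, 2) if iv else np.nan
            row[f"{side}_stop_deg"] = round(iv.stop, 2) if iv else np.nan
            row[f"{side}_power_w"] = round(result.per_side.get(side, 0.0), 3)
        row["total_power_w"] = round(result.total, 3)
        row["vs_reference_pct"] = (
            round(percent_increase(p_ref, result.total), 2) if p_ref > 0 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)
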