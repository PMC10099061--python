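"""Recording container, text-file dialect, revolution segmentation and
angular binning.

The platform logs synchronized 1 kHz streams (crank angle, per-pedal 3-axis
force/torque, pedal inclination, per-channel stimulation state, optionally
EMG) to a plain text file. The dialect used here is tab-delimited with a
``#``-prefixed header block declaring metadata and column names; parsing is
header-driven, so column order is free.

Every per-revolution computation downstream rests on two primitives defined
here: :func:`segment_revolutions` (complete 360° traversals starting at
crank angle 0°) and :func:`angular_profile` (binned averaging of a quantity
onto a uniform angular grid with per-bin support counts).
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .models import SimulationConfig

SIDES = ("left", "right")
WRENCH_AXES = ("fx", "fy", "fz", "tx", "ty", "tz")
_MAGIC = "# fescycling recording v1"


class RecordingParseError(ValueError):
    """Malformed recording file; the message names the offending line."""


@dataclass
class PedalWrench:
    """Force (N) and torque (N·m) streams measured by one pedal sensor."""

    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    tz: np.ndarray

    def __getitem__(self, axis: str) -> np.ndarray:
        return getattr(self, axis)


@dataclass
class SessionRecording:
    """Synchronized streams for one protocol phase.

    ``crank_angle`` is the encoder angle wrapped to [0, 360), 0° = left crank
    forward. ``stim_state`` records the *commanded* on/off state per channel
    (the physical response lags by the stimulator delay plus the EMD).
    """

    time: np.ndarray
    crank_angle: np.ndarray
    pedals: Dict[str, PedalWrench]
    inclination: Dict[str, np.ndarray]
    stim_state: Dict[str, np.ndarray] = field(default_factory=dict)
    emg: Optional[Dict[str, np.ndarray]] = None
    meta: Optional[SimulationConfig] = None
    phase: str = ""

    def __post_init__(self) -> None:
        n = len(self.time)
        arrays = [self.crank_angle]
        for side in self.pedals:
            arrays += [self.pedals[side][ax] for ax in WRENCH_AXES]
            arrays.append(self.inclination[side])
        arrays += list(self.stim_state.values())
        if self.emg:
            arrays += list(self.emg.values())
        if any(len(a) != n for a in arrays):
            raise ValueError("all recording streams must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass
class RevolutionProfile:
    """A quantity averaged onto a uniform crank-angle grid.

    ``grid`` holds bin centers covering [0, 360); ``values`` the per-bin mean
    across all contributing revolutions; ``counts`` the number of samples
    that fell in each bin.
    """

    grid: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    n_revolutions: int
    bin_width: float

    @property
    def n_bins(self) -> int:
        return len(self.grid)

    def argmax_angle(self) -> float:
        return float(self.grid[int(np.argmax(self.values))])


# ---------------------------------------------------------------------------
# Revolution segmentation and angular binning
# ---------------------------------------------------------------------------

_CROSSING_EPS = 1e-6  # deg; absorbs float rounding at exact multiples of 360


def unwrap_angle(angle_deg: np.ndarray) -> np.ndarray:
    """Unwrap a [0, 360)-wrapped monotone crank-angle stream to a
    cumulative angle."""
    return np.rad2deg(np.unwrap(np.deg2rad(np.asarray(angle_deg, dtype=float))))


def segment_revolutions(rec_or_angle) -> list[Tuple[int, int]]:
    """Index ranges ``[i0, i1)`` of complete revolutions starting at 0°.

    The crank angle is unwrapped; each segment spans one full 360° traversal
    between consecutive crossings of absolute crank angle 0°. Incomplete
    leading/trailing partial revolutions are discarded. Fewer than one
    complete aligned revolution yields an empty list.
    """
    angle = rec_or_angle.crank_angle if isinstance(rec_or_angle, SessionRecording) else rec_or_angle
    u = unwrap_angle(angle)
    if len(u) < 2:
        return []
    k0 = int(np.ceil((u[0] - _CROSSING_EPS) / 360.0))
    levels = []
    k = k0
    while k * 360.0 <= u[-1] + _CROSSING_EPS:
        levels.append(k * 360.0)
        k += 1
    if len(levels) < 2:
        return []
    idx = np.searchsorted(u, np.asarray(levels) - _CROSSING_EPS, side="left")
    return [(int(idx[i]), int(idx[i + 1])) for i in range(len(idx) - 1)]


def angular_profile(
    angle_deg: np.ndarray,
    values: np.ndarray,
    segments: Sequence[Tuple[int, int]],
    bin_width: float = 1.0,
) -> RevolutionProfile:
    """Bin-average ``values`` by crank angle across the given revolutions.

    Raises if any bin at the requested resolution receives no samples
    (use coarser bins or more revolutions).
    """
    if not segments:
        raise ValueError("need at least one complete revolution")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(round(360.0 / bin_width))
    if abs(n_bins * bin_width - 360.0) > 1e-6:
        raise ValueError("bin_width must divide 360")
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    angle_deg = np.asarray(angle_deg, dtype=float)
    values = np.asarray(values, dtype=float)
    for i0, i1 in segments:
        # Snap by 1 nano-degree so identical sample phases in different
        # revolutions cannot straddle a bin edge through float rounding.
        bins = (np.floor(((angle_deg[i0:i1] % 360.0) + 1e-9) / bin_width)).astype(int) % n_bins
        sums += np.bincount(bins, weights=values[i0:i1], minlength=n_bins)
        counts += np.bincount(bins, minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError(
            f"{int(np.sum(counts == 0))} empty bins at {bin_width}° resolution; "
            "use a coarser bin width"
        )
    grid = (np.arange(n_bins) + 0.5) * bin_width
    return RevolutionProfile(
        grid=grid,
        values=sums / counts,
        counts=counts,
        n_revolutions=len(segments),
        bin_width=bin_width,
    )


def to_angular_profile(
    rec: SessionRecording,
    quantity: Union[str, np.ndarray],
    segments: Optional[Sequence[Tuple[int, int]]] = None,
    bin_width: float = 1.0,
) -> RevolutionProfile:
    """Profile a named channel (e.g. ``"left.fx"``) or an explicit array."""
    if segments is None:
        segments = segment_revolutions(rec)
    if isinstance(quantity, str):
        side, _, axis = quantity.partition(".")
        values = rec.pedals[side][axis]
    else:
        values = quantity
    return angular_profile(rec.crank_angle, values, segments, bin_width)


# ---------------------------------------------------------------------------
# Text dialect
# ---------------------------------------------------------------------------

_FMT = {
    "time_s": "%.4f",
    "crank_angle_deg": "%.3f",
    "force": "%.3f",
    "incl": "%.3f",
    "stim": "%d",
    "emg": "%.6f",
}


def _columns_of(rec: SessionRecording) -> list[str]:
    cols = ["time_s", "crank_angle_deg"]
    for side in SIDES:
        if side in rec.pedals:
            cols += [f"{side}_{ax}" for ax in WRENCH_AXES]
            cols.append(f"{side}_inclination_deg")
    cols += [f"stim_{ch}" for ch in rec.stim_state]
    if rec.emg:
        cols += [f"emg_{m}" for m in rec.emg]
    return cols


def _column_array(rec: SessionRecording, col: str) -> np.ndarray:
    if col == "time_s":
        return rec.time
    if col == "crank_angle_deg":
        return rec.crank_angle
    if col.startswith("stim_"):
        return rec.stim_state[col[5:]].astype(int)
    if col.startswith("emg_"):
        return rec.emg[col[4:]]
    side, rest = col.split("_", 1)
    if rest == "inclination_deg":
        return rec.inclination[side]
    return rec.pedals[side][rest]


def _fmt_for(col: str) -> str:
    if col in _FMT:
        return _FMT[col]
    if col.startswith("stim_"):
        return _FMT["stim"]
    if col.startswith("emg_"):
        return _FMT["emg"]
    if col.endswith("_deg"):
        return _FMT["incl"]
    return _FMT["force"]


def write_recording(rec: SessionRecording, path: Union[str, Path]) -> None:
    """Write a recording in the text dialect (tab-delimited, '#' header)."""
    path = Path(path)
    cols = _columns_of(rec)
    lines = [_MAGIC]
    meta = rec.meta
    if meta is not None:
        lines += [
            f"# sample_rate_hz={meta.sample_rate!r}",
            f"# cadence_rpm={meta.cadence!r}",
            f"# cadence_error_fraction={meta.cadence_error_fraction!r}",
            f"# duration_s={meta.duration!r}",
            f"# crank_length_m={meta.crank_length!r}",
            f"# noise_sd_force_n={meta.noise_sd_force!r}",
            f"# seed={meta.seed}",
        ]
    lines.append(f"# phase={rec.phase}")
    lines.append("# columns=" + "\t".join(cols))
    data = np.column_stack([_column_array(rec, c) for c in cols])
    fmts = [_fmt_for(c) for c in cols]
    buf = io.StringIO()
    np.savetxt(buf, data, fmt=fmts, delimiter="\t")
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_recording(path: Union[str, Path]) -> SessionRecording:
    """Parse a recording file; round-trips :func:`write_recording` output
    to the declared precision (angles 0.01°, forces 0.01 N)."""
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    meta_kv: Dict[str, str] = {}
    cols: Optional[list[str]] = None
    body_start = 0
    for lineno, line in enumerate(raw_lines, start=1):
        if not line.startswith("#"):
            body_start = lineno
            break
        content = line[1:].strip()
        if "=" in content:
            key, _, val = content.partition("=")
            if key.strip() == "columns":
                cols = val.split("\t")
            else:
                meta_kv[key.strip()] = val.strip()
    else:
        raise RecordingParseError(f"{path}: no data rows found")
    if cols is None:
        raise RecordingParseError(f"{path}: header declares no 'columns' line")

    rows = []
    for lineno in range(body_start, len(raw_lines) + 1):
        line = raw_lines[lineno - 1]
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise RecordingParseError(
                f"{path}, line {lineno}: expected {len(cols)} fields, got {len(fields)}"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise RecordingParseError(f"{path}, line {lineno}: {exc}") from None
    if not rows:
        raise RecordingParseError(f"{path}: no data rows found")
    data = pd.DataFrame(np.asarray(rows), columns=cols)

    required = ("time_s", "crank_angle_deg")
    for col in required:
        if col not in data.columns:
            raise RecordingParseError(f"{path}: missing required column {col!r}")

    time = data["time_s"].to_numpy()
    if len(time) > 2:
        dt = np.diff(time)
        if np.ptp(dt) > 1e-3 * np.median(dt) + 1e-9:
            raise RecordingParseError(f"{path}: non-uniform timestamps")

    pedals: Dict[str, PedalWrench] = {}
    inclination: Dict[str, np.ndarray] = {}
    for side in SIDES:
        axes = {ax: f"{side}_{ax}" for ax in WRENCH_AXES}
        if all(c in data.columns for c in axes.values()):
            incl_col = f"{side}_inclination_deg"
            if incl_col not in data.columns:
                raise RecordingParseError(f"{path}: missing column {incl_col!r}")
            pedals[side] = PedalWrench(**{ax: data[c].to_numpy() for ax, c in axes.items()})
            inclination[side] = data[incl_col].to_numpy()

    stim = {
        c[5:]: data[c].to_numpy().astype(bool)
        for c in data.columns
        if c.startswith("stim_")
    }
    emg = {c[4:]: data[c].to_numpy() for c in data.columns if c.startswith("emg_")}

    meta = None
    if "sample_rate_hz" in meta_kv:
        meta = SimulationConfig(
            cadence=float(meta_kv.get("cadence_rpm", 50.0)),
            duration=float(meta_kv.get("duration_s", time[-1] - time[0])),
            cadence_error_fraction=float(meta_kv.get("cadence_error_fraction", 0.0)),
            sample_rate=float(meta_kv["sample_rate_hz"]),
            crank_length=float(meta_kv.get("crank_length_m", 0.17)),
            noise_sd_force=float(meta_kv.get("noise_sd_force_n", 0.0)),
            seed=int(meta_kv.get("seed", 0)),
        )
    return SessionRecording(
        time=time,
        crank_angle=data["crank_angle_deg"].to_numpy(),
        pedals=pedals,
        inclination=inclination,
        stim_state=stim,
        emg=emg or None,
        meta=meta,
        phase=meta_kv.get("phase", ""),
    )
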