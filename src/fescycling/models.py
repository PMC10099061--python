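"""Configuration and physiological model types shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .intervals import CircularInterval


class ConfigurationError(ValueError):
    """Invalid simulation or protocol configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated recording.

    cadence
        Target cadence in rpm; the platform's motor accepts 1-100 rpm.
    cadence_error_fraction
        Signed relative deviation of the realized cadence from the target
        (constant within a run); e.g. 0.0166 reproduces a measured
        49.18 rpm at a 50 rpm target.
    noise_sd_force
        Standard deviation (N) of white measurement noise added to every
        pedal force channel.
    """

    cadence: float
    duration: float
    cadence_error_fraction: float = 0.0
    sample_rate: float = 1000.0
    crank_length: float = 0.17
    noise_sd_force: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 <= self.cadence <= 100.0):
            raise ConfigurationError(
                f"cadence {self.cadence} rpm outside the platform range [1, 100]"
            )
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.crank_length <= 0:
            raise ConfigurationError("crank_length must be positive")
        if self.noise_sd_force < 0:
            raise ConfigurationError("noise_sd_force must be non-negative")

    @property
    def realized_cadence(self) -> float:
        """Cadence actually turned by the motor, rpm."""
        return self.cadence * (1.0 - self.cadence_error_fraction)


@dataclass(frozen=True)
class StimulatorModel:
    """Electrical stimulator settings and internal latency.

    ``internal_delay`` is D_S: the time from the command to generate a pulse
    until the pulse reaches the electrode. Defaults follow the study
    conditions: 40 Hz, 350 µs, 70 mA, D_S = 3.2 ms.
    """

    internal_delay: float = 0.0032
    frequency: float = 40.0
    pulse_width: float = 350.0
    amplitude: float = 70.0

    def __post_init__(self) -> None:
        if self.internal_delay < 0:
            raise ConfigurationError("internal_delay must be non-negative")
        if not (0 <= self.frequency <= 100):
            raise ConfigurationError("frequency outside stimulator range 0-100 Hz")
        if not (0 <= self.amplitude <= 170):
            raise ConfigurationError("amplitude outside stimulator range 0-170 mA")
        if not (0 <= self.pulse_width <= 1000):
            raise ConfigurationError("pulse_width outside stimulator range 0-1000 us")


@dataclass(frozen=True)
class MuscleModel:
    """Ground-truth force response of one stimulated muscle group.

    The muscle produces a raised-cosine tangential-force bump over
    ``active_arc`` (zero at both arc ends, ``peak_force`` at the centre)
    whenever stimulation *commanded* ``emd`` plus the stimulator delay
    earlier is on. An optional ``negative_arc`` models an angular range
    where the contraction hinders the motion (force sign flipped,
    magnitude ``negative_force``).
    """

    name: str
    side: str  # "left" | "right"
    active_arc: CircularInterval
    peak_force: float
    emd: float = 0.0501
    negative_arc: Optional[CircularInterval] = None
    negative_force: float = 0.0
    fatigue_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.peak_force < 0:
            raise ConfigurationError("peak_force must be non-negative")
        if self.emd < 0:
            raise ConfigurationError("emd must be non-negative")
        if not (0.0 <= self.fatigue_decay < 1.0):
            raise ConfigurationError("fatigue_decay must lie in [0, 1)")
        if self.negative_force < 0:
            raise ConfigurationError("negative_force is a magnitude, must be >= 0")


@dataclass(frozen=True)
class DelayModel:
    """Stimulator delay D_S and electromechanical delay EMD, both in seconds.

    Convertible to angular shifts at a given cadence: a delay of d seconds
    at cadence omega rpm corresponds to d * 360 * omega / 60 degrees of
    crank rotation.
    """

    d_s: float
    emd: float

    def __post_init__(self) -> None:
        if self.d_s < 0 or self.emd < 0:
            raise ValueError("delays must be non-negative")

    @property
    def total(self) -> float:
        return self.d_s + self.emd
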