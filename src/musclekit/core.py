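"""Shared domain containers: stimulation protocols and force/deflection traces.

An engineered muscle tissue (EMT) is paced with biphasic electrical pulses
while the deflection of a flexible, magnet-bearing post is recorded.  The
two stimulation protocols used throughout the package are

* ``twitch``: 10 single pulses separated by 5 s rest intervals (0.2 Hz);
* ``force_frequency``: 2 s pulse trains at 1, 2, 3, 5, 10, 15, 20, 30, 40,
  60, 80 and 100 Hz with 16 s rest between trains.

Both are sampled at 100 Hz.  Pulse width (5 ms) and current (100 mA) are
carried as metadata only; the electrical waveform itself is never modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["StimulationProtocol", "ForceTrace", "TWITCH_FREQUENCIES"]

#: Force-frequency protocol frequencies in Hz.
TWITCH_FREQUENCIES: tuple[float, ...] = (1, 2, 3, 5, 10, 15, 20, 30, 40, 60, 80, 100)


@dataclass(frozen=True)
class StimulationProtocol:
    """Electrical pacing schedule for an EMT measurement.

    Parameters
    ----------
    kind
        ``"twitch"`` (isolated pulses) or ``"force_frequency"`` (pulse
        trains of increasing rate).
    pulse_count
        Number of pulses (twitch protocol only).
    inter_pulse_interval
        Rest between single pulses, seconds (twitch protocol only).
    train_duration
        Duration of each pulse train, seconds (force-frequency only).
    frequencies
        Train frequencies in Hz (force-frequency only).
    inter_train_rest
        Rest between trains, seconds.
    sampling_rate
        Recording rate in Hz.
    lead_in
        Quiet time before the first stimulus, seconds.  Gives the baseline
        estimator a pre-stimulus window.
    pulse_width_ms, pulse_current_ma
        Stimulator settings, carried as metadata.
    """

    kind: str
    pulse_count: int = 0
    inter_pulse_interval: float = 0.0
    train_duration: float = 0.0
    frequencies: tuple[float, ...] = ()
    inter_train_rest: float = 0.0
    sampling_rate: float = 100.0
    lead_in: float = 2.0
    pulse_width_ms: float = 5.0
    pulse_current_ma: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("twitch", "force_frequency"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.kind == "force_frequency" and self.inter_train_rest < 0:
            raise ValueError("trains overlap: inter_train_rest < 0")
        object.__setattr__(self, "frequencies", tuple(self.frequencies))

    # ------------------------------------------------------------------
    @classmethod
    def twitch(cls, pulse_count: int = 10, inter_pulse_interval: float = 5.0,
               sampling_rate: float = 100.0, lead_in: float = 2.0) -> "StimulationProtocol":
        """The single-twitch preset: 10 pulses, 5 s apart."""
        return cls(kind="twitch", pulse_count=pulse_count,
                   inter_pulse_interval=inter_pulse_interval,
                   sampling_rate=sampling_rate, lead_in=lead_in)

    @classmethod
    def force_frequency(cls, frequencies: Sequence[float] = TWITCH_FREQUENCIES,
                        train_duration: float = 2.0, inter_train_rest: float = 16.0,
                        sampling_rate: float = 100.0, lead_in: float = 2.0) -> "StimulationProtocol":
        """The force-frequency preset: 2 s trains, 16 s rest, 1-100 Hz."""
        return cls(kind="force_frequency", frequencies=tuple(frequencies),
                   train_duration=train_duration, inter_train_rest=inter_train_rest,
                   sampling_rate=sampling_rate, lead_in=lead_in)

    # ------------------------------------------------------------------
    @property
    def stimulus_times(self) -> np.ndarray:
        """Start time of every pulse (twitch) or train (force-frequency), s."""
        if self.kind == "twitch":
            return self.lead_in + self.inter_pulse_interval * np.arange(self.pulse_count)
        n = len(self.frequencies)
        step = self.train_duration + self.inter_train_rest
        return self.lead_in + step * np.arange(n)

    @property
    def duration(self) -> float:
        """Total protocol duration in seconds (including lead-in)."""
        if self.kind == "twitch":
            return self.lead_in + self.pulse_count * self.inter_pulse_interval
        step = self.train_duration + self.inter_train_rest
        return self.lead_in + len(self.frequencies) * step

    @property
    def n_samples(self) -> int:
        """Sample count: duration x sampling_rate, exact integer contract."""
        n = self.duration * self.sampling_rate
        n_int = int(round(n))
        if abs(n - n_int) > 1e-9:
            raise ValueError("protocol duration is not an integer number of samples")
        return n_int

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "pulse_count": self.pulse_count,
            "inter_pulse_interval": self.inter_pulse_interval,
            "train_duration": self.train_duration,
            "frequencies": list(self.frequencies),
            "inter_train_rest": self.inter_train_rest,
            "sampling_rate": self.sampling_rate, "lead_in": self.lead_in,
            "pulse_width_ms": self.pulse_width_ms,
            "pulse_current_ma": self.pulse_current_ma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        return cls(**{k: (tuple(v) if k == "frequencies" else v) for k, v in d.items()})


@dataclass
class ForceTrace:
    """Uniformly sampled force (mN) or post-deflection (mm) series.

    ``units`` is ``"mN"`` for force or ``"mm"`` for deflection; conversion
    between the two is a linear spring model handled by
    :func:`musclekit.contractility.deflection_to_force`.
    """

    sampling_rate: float
    values: np.ndarray
    units: str = "mN"
    stimulus_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    protocol: StimulationProtocol | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.units not in ("mN", "mm"):
            raise ValueError("units must be 'mN' (force) or 'mm' (deflection)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.stimulus_times.size:
            if np.any(np.diff(self.stimulus_times) <= 0):
                raise ValueError("stimulus_times must be strictly increasing")
            if self.stimulus_times[0] < 0 or self.stimulus_times[-1] > self.duration:
                raise ValueError("stimulus_times fall outside the record")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate

    def with_values(self, values: np.ndarray, units: str | None = None,
                    **extra_meta) -> "ForceTrace":
        meta = dict(self.metadata)
        meta.update(extra_meta)
        return ForceTrace(sampling_rate=self.sampling_rate, values=values,
                          units=units or self.units,
                          stimulus_times=self.stimulus_times.copy(),
                          protocol=self.protocol, metadata=meta)
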