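"""Twitch, tetanus and relaxation analysis of EMT force traces.

The pipeline mirrors standard engineered-muscle contractility analysis:
deflection is converted to force through the linear stiffness of the
flexible post, a robust pre-stimulus baseline is subtracted, contraction
events are detected per stimulus window, and per-event/per-train metrics
(active force, time to peak, RT80% relaxation, force-frequency curve,
CSA-normalised specific force) are derived.

Conventions (configurable where noted):

* the standalone baseline estimator returns the 10th percentile of the
  2 s pre-stimulus window (robust to residual activity); per-event and
  per-train baselines inside detection default to the median (50th
  percentile) of the same window, which is equally robust to spikes but
  unbiased under symmetric noise;
* peaks are located on a 5-sample moving-median smoothed trace and their
  amplitude read from a Savitzky-Golay (window 7, order 2) local
  quadratic fit, which preserves the twitch crest to ~0.1% while
  averaging out sampling noise;
* an event is accepted when its prominence exceeds
  ``max(3 x robust noise SD, prominence_floor)``;
* RT80% is the time for force to fall by 80% of the active amplitude,
  measured from the twitch peak or from the end of a tetanic train, with
  linear interpolation between samples;
* tetanic plateau = mean force over the last half of the train window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .core import ForceTrace, StimulationProtocol

__all__ = [
    "ContractionEvent", "TrainMetrics", "ContractionMetrics",
    "deflection_to_force", "estimate_baseline", "detect_contractions",
    "twitch_summary", "tetanus_metrics", "relaxation_time", "specific_force",
    "robust_noise_sd",
]


@dataclass
class ContractionEvent:
    """A single detected twitch."""

    stimulus_time: float
    peak_time: float
    baseline_force: float
    peak_force: float
    rt80: float | None = None          # None when censored
    rt80_censored: bool = False

    @property
    def active_force(self) -> float:
        return self.peak_force - self.baseline_force

    @property
    def time_to_peak(self) -> float:
        return self.peak_time - self.stimulus_time


@dataclass
class TrainMetrics:
    """Per-train tetanic metrics of the force-frequency protocol."""

    frequency: float
    baseline_force: float
    plateau_force: float
    rt80: float | None = None
    rt80_censored: bool = False

    @property
    def active_force(self) -> float:
        return self.plateau_force - self.baseline_force


@dataclass
class ContractionMetrics:
    """Protocol-level summary of detected twitch events."""

    events: list[ContractionEvent] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def mean_active_force(self) -> float:
        if not self.events:
            return math.nan
        return float(np.mean([e.active_force for e in self.events]))

    @property
    def mean_time_to_peak(self) -> float:
        if not self.events:
            return math.nan
        return float(np.mean([e.time_to_peak for e in self.events]))

    @property
    def mean_rt80(self) -> float:
        vals = [e.rt80 for e in self.events if e.rt80 is not None]
        return float(np.mean(vals)) if vals else math.nan


# ----------------------------------------------------------------------
def deflection_to_force(trace: ForceTrace, stiffness: float) -> ForceTrace:
    """Convert a deflection trace (mm) to force (mN) via F = k * delta.

    Refuses traces already flagged as force to prevent double conversion.
    """
    if stiffness <= 0:
        raise ValueError("stiffness must be > 0")
    if trace.units != "mm":
        raise ValueError("trace is already in force units; refusing to convert")
    return trace.with_values(trace.values * stiffness, units="mN",
                             stiffness_mN_per_mm=stiffness)


def force_to_deflection(trace: ForceTrace, stiffness: float) -> ForceTrace:
    """Inverse of :func:`deflection_to_force` (delta = F / k)."""
    if stiffness <= 0:
        raise ValueError("stiffness must be > 0")
    if trace.units != "mN":
        raise ValueError("trace is not in force units")
    return trace.with_values(trace.values / stiffness, units="mm",
                             stiffness_mN_per_mm=stiffness)


def estimate_baseline(trace: ForceTrace, window_end: float,
                      window_length: float = 2.0,
                      percentile: float = 10.0) -> float:
    """Robust passive-tension estimate before a stimulus.

    Returns the ``percentile`` (default 10th) of the samples in
    ``[window_end - window_length, window_end)``.  The low percentile makes
    the estimate insensitive to residual activity or upward spikes inside
    the window.  Requires at least 10 samples.
    """
    fs = trace.sampling_rate
    i1 = int(round(window_end * fs))
    i0 = max(0, int(round((window_end - window_length) * fs)))
    i1 = min(i1, trace.n_samples)
    if i1 - i0 < 10:
        raise ValueError("baseline window shorter than 10 samples")
    return float(np.percentile(trace.values[i0:i1], percentile))


def robust_noise_sd(values: np.ndarray, smooth_samples: int = 5) -> float:
    """MAD-based noise SD of the residual around a moving-median smooth."""
    smoothed = median_filter(values, size=smooth_samples, mode="nearest")
    resid = values - smoothed
    return 1.4826 * float(np.median(np.abs(resid - np.median(resid))))


def _smooth(values: np.ndarray, smooth_samples: int) -> np.ndarray:
    if smooth_samples <= 1:
        return values
    return median_filter(values, size=smooth_samples, mode="nearest")


def detect_contractions(trace: ForceTrace,
                        protocol: StimulationProtocol | None = None,
                        smooth_samples: int = 5,
                        prominence_floor: float = 0.0,
                        relax_fraction: float = 0.8,
                        baseline_percentile: float = 50.0,
                        amplitude_window: int = 7) -> ContractionMetrics:
    """Detect one twitch per stimulus window and measure its kinetics.

    Each stimulus opens a candidate window ``[t_i, t_{i+1})`` (the last one
    runs to the end of the record).  The peak is located on the
    moving-median smoothed trace, refined within +-2 samples on a local
    quadratic (Savitzky-Golay) fit, and the amplitude is the quadratic-fit
    value at the refined peak — this recovers noise-free twitch amplitudes
    to ~0.1% and keeps the estimate unbiased under additive noise.  Events
    with prominence below ``max(3 x robust noise SD, prominence_floor)``
    are rejected.  Zero accepted events yields an empty
    :class:`ContractionMetrics`, not an exception.
    """
    if trace.units != "mN":
        raise ValueError("detect_contractions requires a force trace (mN); "
                         "convert deflection first")
    stim = trace.stimulus_times if trace.stimulus_times.size else (
        protocol.stimulus_times if protocol is not None else None)
    if stim is None or len(stim) == 0:
        raise ValueError("no stimulus times available")

    fs = trace.sampling_rate
    x = trace.values
    xs = _smooth(x, smooth_samples)
    win = min(amplitude_window, x.size if x.size % 2 else x.size - 1)
    sg = savgol_filter(x, win, 2, mode="nearest") if win >= 5 else x
    sigma = robust_noise_sd(x, smooth_samples)
    threshold = max(3.0 * sigma, prominence_floor)

    edges = list(stim) + [trace.duration]
    events: list[ContractionEvent] = []
    for ti, tnext in zip(edges[:-1], edges[1:]):
        i0 = int(round(ti * fs))
        i1 = min(int(round(tnext * fs)), trace.n_samples)
        if i1 - i0 < 3:
            continue
        baseline = estimate_baseline(trace, window_end=ti,
                                     percentile=baseline_percentile)
        j = i0 + int(np.argmax(xs[i0:i1]))
        lo = max(i0, j - 2)
        hi = min(i1, j + 3)
        j_raw = lo + int(np.argmax(sg[lo:hi]))
        peak = float(sg[j_raw])
        if peak - baseline <= threshold:
            continue
        ev = ContractionEvent(stimulus_time=float(ti),
                              peak_time=j_raw / fs,
                              baseline_force=baseline,
                              peak_force=peak)
        rt = relaxation_time(trace, reference_time=ev.peak_time,
                             baseline=baseline, active_force=ev.active_force,
                             fraction=relax_fraction,
                             search_end=tnext)
        ev.rt80, ev.rt80_censored = rt
        events.append(ev)
    return ContractionMetrics(events=events)


def twitch_summary(metrics: ContractionMetrics | list[ContractionEvent]) -> dict:
    """Average the detected twitches: the protocol-level twitch readout."""
    if isinstance(metrics, list):
        metrics = ContractionMetrics(events=metrics)
    return {
        "n_events": metrics.n_events,
        "mean_active_force_mN": metrics.mean_active_force,
        "mean_time_to_peak_s": metrics.mean_time_to_peak,
        "mean_rt80_s": metrics.mean_rt80,
    }


def tetanus_metrics(trace: ForceTrace,
                    protocol: StimulationProtocol,
                    plateau_window: float = 0.5,
                    relax_fraction: float = 0.8,
                    baseline_percentile: float = 50.0) -> list[TrainMetrics]:
    """Force-frequency analysis: per-train plateau, active force and RT80.

    The plateau is the mean force over the last ``plateau_window`` fraction
    (default 50%) of each train; the per-train baseline is the robust
    pre-train estimate; RT80 is anchored at the end of the train.  Returns
    trains ordered by frequency.
    """
    if trace.units != "mN":
        raise ValueError("tetanus_metrics requires a force trace (mN)")
    if protocol.kind != "force_frequency":
        raise ValueError("protocol must be the force-frequency kind")
    if protocol.inter_train_rest < 0:
        raise ValueError("trains overlap: inter_train_rest < 0")
    if not (0 < plateau_window <= 1):
        raise ValueError("plateau_window must be in (0, 1]")

    fs = trace.sampling_rate
    x = trace.values
    out: list[TrainMetrics] = []
    for start, freq in zip(protocol.stimulus_times, protocol.frequencies):
        end = start + protocol.train_duration
        p0 = int(round((end - plateau_window * protocol.train_duration) * fs))
        p1 = min(int(round(end * fs)), trace.n_samples)
        baseline = estimate_baseline(trace, window_end=start,
                                     percentile=baseline_percentile)
        plateau = float(np.mean(x[p0:p1]))
        tm = TrainMetrics(frequency=float(freq), baseline_force=baseline,
                          plateau_force=plateau)
        if tm.active_force > 0:
            rt = relaxation_time(trace, reference_time=end, baseline=baseline,
                                 active_force=tm.active_force,
                                 fraction=relax_fraction,
                                 search_end=end + protocol.inter_train_rest)
            tm.rt80, tm.rt80_censored = rt
        out.append(tm)
    return sorted(out, key=lambda m: m.frequency)


def relaxation_time(trace: ForceTrace, reference_time: float, baseline: float,
                    active_force: float, fraction: float = 0.8,
                    search_end: float | None = None) -> tuple[float | None, bool]:
    """Time from ``reference_time`` until force relaxes by ``fraction``.

    The threshold is ``baseline + (1 - fraction) * active_force``.  Returns
    ``(time, censored)``: the earliest crossing (linear interpolation
    between the bracketing samples), or ``(None, True)`` when the threshold
    is never reached before ``search_end`` / end of record.
    """
    if active_force <= 0:
        raise ValueError("active_force must be > 0")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    fs = trace.sampling_rate
    x = trace.values
    i0 = int(round(reference_time * fs))
    i1 = trace.n_samples if search_end is None else min(
        trace.n_samples, int(round(search_end * fs)))
    if i0 >= i1:
        return None, True
    target = baseline + (1.0 - fraction) * active_force
    seg = x[i0:i1]
    below = np.nonzero(seg <= target)[0]
    if below.size == 0:
        return None, True
    k = int(below[0])
    if k == 0:
        return 0.0, False
    # interpolate between samples k-1 (above) and k (at/below)
    y0, y1 = seg[k - 1], seg[k]
    frac = (y0 - target) / (y0 - y1) if y0 != y1 else 1.0
    return ((k - 1) + frac) / fs, False


def specific_force(active_force: float, effective_csa: float) -> float:
    """Specific force in mN/mm^2: active force normalised to effective CSA."""
    if effective_csa <= 0:
        raise ValueError("effective_csa must be > 0 mm^2")
    return active_force / effective_csa
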