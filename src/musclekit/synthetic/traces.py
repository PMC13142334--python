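"""Synthetic post-deflection traces with analytically known ground truth.

The single-twitch response is a difference-of-exponentials kernel

    f(t) = A * (exp(-t / tau_decay) - exp(-t / tau_rise)) / g_max,   t >= 0

scaled so its maximum equals ``peak_active_force`` (A, mN).  Train
responses are linear superpositions of kernels at the pulse times,
optionally passed through a soft saturation

    F_sat = F_max * (1 - exp(-F / F_max))

to produce a plateauing force-frequency curve.  The emitted trace is the
post *deflection* in mm — force divided by the linear post stiffness —
with additive i.i.d. Gaussian noise, mirroring what a magnetometric
platform hands to the analysis pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ..core import ForceTrace, StimulationProtocol

__all__ = ["TwitchModelParams", "gen_trace", "kernel_peak_time", "kernel_rt80"]


@dataclass(frozen=True)
class TwitchModelParams:
    """Parameters of the generative twitch model.

    Attributes
    ----------
    peak_active_force
        Active force of a single twitch above baseline, mN.
    tau_rise, tau_decay
        Rise and decay time constants of the kernel, s; requires
        ``0 < tau_rise < tau_decay``.
    latency
        Delay between the electrical pulse and force onset, s.
    passive_baseline
        Resting (passive) tension, mN.
    noise_sd
        Standard deviation of additive Gaussian noise, in force units (mN).
    post_stiffness
        Linear spring constant of the flexible post, mN/mm.
    saturation_force
        Soft tetanic ceiling F_max, mN; ``inf`` disables saturation.
    seed
        Seed for the noise generator.
    """

    peak_active_force: float = 1.2
    tau_rise: float = 0.03
    tau_decay: float = 0.15
    latency: float = 0.0
    passive_baseline: float = 0.5
    noise_sd: float = 0.0
    post_stiffness: float = 1.0
    saturation_force: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_rise <= 0:
            raise ValueError("tau_rise must be > 0")
        if self.tau_decay <= self.tau_rise:
            raise ValueError("tau_decay must exceed tau_rise")
        if self.peak_active_force < 0:
            raise ValueError("peak_active_force must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.post_stiffness <= 0:
            raise ValueError("post_stiffness must be > 0")
        if self.latency < 0:
            raise ValueError("latency must be >= 0")
        if self.saturation_force <= 0:
            raise ValueError("saturation_force must be > 0 (use inf to disable)")


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the kernel maximum: t* = (tr*td/(td-tr)) ln(td/tr)."""
    return tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)


def _kernel_shape(t: np.ndarray | float, tau_rise: float, tau_decay: float):
    """Unnormalised kernel exp(-t/td) - exp(-t/tr) for t >= 0, else 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    return out


def kernel_rt80(tau_rise: float, tau_decay: float, fraction: float = 0.8) -> float:
    """Time from the kernel peak until force has relaxed by ``fraction``.

    Solved by root-finding on the normalised kernel (no closed form for the
    difference of exponentials); accurate to ~1e-12 s.
    """
    t_pk = kernel_peak_time(tau_rise, tau_decay)
    g_pk = float(_kernel_shape(t_pk, tau_rise, tau_decay))
    target = (1.0 - fraction) * g_pk

    def f(s: float) -> float:
        return float(_kernel_shape(t_pk + s, tau_rise, tau_decay)) - target

    hi = tau_decay
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6 * tau_decay:  # pragma: no cover - defensive
            raise RuntimeError("relaxation target never reached")
    return brentq(f, 0.0, hi, xtol=1e-12)


def _pulse_times(protocol: StimulationProtocol) -> np.ndarray:
    """Every individual pulse time implied by the protocol, s."""
    if protocol.kind == "twitch":
        return protocol.stimulus_times
    pulses = []
    for start, freq in zip(protocol.stimulus_times, protocol.frequencies):
        n = int(math.floor(protocol.train_duration * freq))
        n = max(n, 1)
        pulses.append(start + np.arange(n) / freq)
    return np.concatenate(pulses)


def gen_trace(params: TwitchModelParams,
              protocol: StimulationProtocol) -> tuple[ForceTrace, dict]:
    """Simulate a deflection trace for ``protocol`` and return ground truth.

    Returns
    -------
    trace : ForceTrace
        Deflection in mm (force / post_stiffness) at the protocol's
        sampling rate, with the stimulus schedule attached.
    ground_truth : dict
        Per-event active force / time-to-peak / RT80 for twitch protocols,
        per-train noise-free plateau and active force for force-frequency
        protocols, plus the model parameters used.
    """
    fs = protocol.sampling_rate
    n = protocol.n_samples
    t = np.arange(n) / fs

    # kernel support: rise to peak plus ~9 decay constants
    t_pk = kernel_peak_time(params.tau_rise, params.tau_decay)
    support = params.latency + t_pk + 9.0 * params.tau_decay
    if protocol.duration < support:
        raise ValueError(
            f"protocol duration {protocol.duration:g} s is shorter than one "
            f"kernel support ({support:g} s)")

    g_pk = float(_kernel_shape(t_pk, params.tau_rise, params.tau_decay))
    scale = params.peak_active_force / g_pk if params.peak_active_force > 0 else 0.0

    pulses = _pulse_times(protocol)
    active = np.zeros(n)
    if scale > 0:
        for tp in pulses:
            onset = tp + params.latency
            # kernel is negligible beyond the support window
            i0 = max(0, int(math.floor(onset * fs)))
            i1 = min(n, int(math.ceil((onset + support) * fs)) + 1)
            if i0 >= n:
                continue
            active[i0:i1] += scale * _kernel_shape(t[i0:i1] - onset,
                                                   params.tau_rise, params.tau_decay)

    if math.isfinite(params.saturation_force):
        fmax = params.saturation_force
        active = fmax * (1.0 - np.exp(-active / fmax))

    force = params.passive_baseline + active
    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        force = force + rng.normal(0.0, params.noise_sd, size=n)
    deflection = force / params.post_stiffness

    gt: dict = {
        "params": {
            "peak_active_force": params.peak_active_force,
            "tau_rise": params.tau_rise, "tau_decay": params.tau_decay,
            "latency": params.latency,
            "passive_baseline": params.passive_baseline,
            "noise_sd": params.noise_sd,
            "post_stiffness": params.post_stiffness,
            "saturation_force": params.saturation_force, "seed": params.seed,
        },
        "protocol": protocol.to_dict(),
    }
    if protocol.kind == "twitch":
        rt80 = kernel_rt80(params.tau_rise, params.tau_decay) if scale > 0 else 0.0
        gt["events"] = [
            {"stimulus_time": float(ts),
             "active_force": params.peak_active_force,
             "time_to_peak": params.latency + t_pk,
             "rt80": rt80}
            for ts in protocol.stimulus_times
        ]
    else:
        noise_free = params.passive_baseline + active  # active already saturated
        trains = []
        for start, freq in zip(protocol.stimulus_times, protocol.frequencies):
            half = start + protocol.train_duration / 2.0
            end = start + protocol.train_duration
            sel = (t >= half) & (t < end)
            plateau = float(noise_free[sel].mean())
            trains.append({"frequency": float(freq),
                           "plateau_force": plateau,
                           "active_force": plateau - params.passive_baseline})
        gt["trains"] = trains

    trace = ForceTrace(
        sampling_rate=fs, values=deflection, units="mm",
        stimulus_times=protocol.stimulus_times, protocol=protocol,
        metadata={"generator": "musclekit.synthetic.traces.gen_trace",
                  "post_stiffness": params.post_stiffness,
                  "seed": params.seed})
    return trace, gt
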