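"""Synthetic paired LFP sessions with closed-form coherence.

Two channels (e.g. hippocampus and prefrontal cortex) share narrowband
oscillatory components realized as band-pass-filtered Gaussian noise — not
pure sinusoids, so Welch coherence has a well-defined expectation — plus
independent private white noise and common power-line contamination.  With
shared one-sided spectral density P_s(f) and private densities P_n1, P_n2,
the magnitude-squared coherence of the generative model is

    C(f) = P_s(f)^2 / ((P_s(f) + P_n1) (P_s(f) + P_n2))

computable per frequency from the designed filter responses.  A 50-Hz speed
trace and per-trial reward times accompany the signals so behavioral epoch
selection can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ..lfp import LFPSession

__all__ = [
    "SharedComponent",
    "LFPSessionSpec",
    "generate_lfp_session",
    "analytic_coherence",
    "coherence_quarter_spec",
]


@dataclass(frozen=True)
class SharedComponent:
    """A narrowband component common to both channels.

    ``amplitude`` is the standard deviation of the white noise driving the
    order-2 Butterworth band-pass of the stated center and bandwidth.
    """

    center_hz: float
    bandwidth_hz: float
    amplitude: float

    def sos(self, fs: float) -> np.ndarray:
        lo = self.center_hz - self.bandwidth_hz / 2.0
        hi = self.center_hz + self.bandwidth_hz / 2.0
        if lo <= 0 or hi >= fs / 2:
            raise ValueError("component band must lie inside (0, fs/2)")
        return sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")

    def gain_sq(self, freqs, fs: float) -> np.ndarray:
        """|H(f)|^2 of the shaping filter."""
        w, h = sps.sosfreqz(self.sos(fs), worN=np.atleast_1d(np.asarray(freqs, float)), fs=fs)
        return np.abs(h) ** 2


@dataclass(frozen=True)
class LFPSessionSpec:
    """Generative description of a two-channel LFP session."""

    fs_raw: float = 20000.0
    duration: float = 60.0
    shared: tuple[SharedComponent, ...] = (SharedComponent(8.0, 2.0, 1.0),)
    private_noise_sd: tuple[float, float] = (1.0, 1.0)
    line_amplitudes: tuple[tuple[float, float], ...] = (
        (50.0, 0.5), (100.0, 0.25), (150.0, 0.12), (200.0, 0.06),
    )
    speed_pieces: tuple[tuple[float, float, float], ...] | None = None  # (t0, t1, cm/s)
    speed_fs: float = 50.0
    reward_times: tuple[float, ...] = ()
    channel_names: tuple[str, str] = ("HPC", "PFC")
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.fs_raw <= 0:
            raise ValueError("duration and fs_raw must be positive")
        if min(self.private_noise_sd) < 0:
            raise ValueError("private noise SDs must be non-negative")
        for t in self.reward_times:
            if not (5.5 < t <= self.duration):
                raise ValueError(
                    f"reward time {t} s outside (5.5, duration]: no full 5-s "
                    "analysis window fits before it"
                )


def generate_lfp_session(spec: LFPSessionSpec) -> LFPSession:
    """Render the session (channels, speed trace, rewards) at fs_raw."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs_raw))
    t = np.arange(n) / spec.fs_raw

    shared_sum = np.zeros(n)
    for comp in spec.shared:
        drive = rng.normal(0.0, comp.amplitude, size=n)
        shared_sum += sps.sosfilt(comp.sos(spec.fs_raw), drive)

    line = np.zeros(n)
    for freq, amp in spec.line_amplitudes:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        line += amp * np.sin(2.0 * np.pi * freq * t + phase)

    channels = {}
    for name, sd in zip(spec.channel_names, spec.private_noise_sd):
        private = rng.normal(0.0, sd, size=n) if sd > 0 else 0.0
        channels[name] = shared_sum + private + line

    n_speed = int(round(spec.duration * spec.speed_fs))
    ts = np.arange(n_speed) / spec.speed_fs
    speed = np.full(n_speed, 7.5)
    if spec.speed_pieces is not None:
        for t0, t1, value in spec.speed_pieces:
            speed[(ts >= t0) & (ts < t1)] = value

    return LFPSession(
        channels=channels,
        fs=spec.fs_raw,
        speed=speed,
        speed_fs=spec.speed_fs,
        rewards=np.asarray(spec.reward_times, dtype=float),
    )


def analytic_coherence(spec: LFPSessionSpec, freqs) -> np.ndarray:
    """Closed-form magnitude-squared coherence of the generative model.

    Line noise (deterministic, common to both channels) is excluded: the
    formula describes the stochastic part of the model and is intended for
    frequencies away from the line harmonics.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    ps = np.zeros_like(freqs)
    for comp in spec.shared:
        ps += comp.amplitude**2 * comp.gain_sq(freqs, spec.fs_raw) * 2.0 / spec.fs_raw
    pn1 = 2.0 * spec.private_noise_sd[0] ** 2 / spec.fs_raw
    pn2 = 2.0 * spec.private_noise_sd[1] ** 2 / spec.fs_raw
    denom = (ps + pn1) * (ps + pn2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, ps**2 / np.where(denom > 0, denom, 1.0), 0.0)
    return coh


def coherence_quarter_spec(
    seed: int,
    duration: float = 60.0,
    center_hz: float = 8.0,
    bandwidth_hz: float = 2.0,
) -> LFPSessionSpec:
    """A session whose analytic coherence at ``center_hz`` is exactly 0.25.

    Sets the private-noise spectral density of both channels equal to the
    shared density at the center frequency, giving
    C = 1 / ((1+1)(1+1)) = 0.25 there.
    """
    comp = SharedComponent(center_hz, bandwidth_hz, 1.0)
    gain = float(np.sqrt(comp.gain_sq(np.array([center_hz]), 20000.0)[0]))
    sd = comp.amplitude * gain
    return LFPSessionSpec(
        duration=duration,
        shared=(comp,),
        private_noise_sd=(sd, sd),
        line_amplitudes=((50.0, 0.3), (100.0, 0.15), (150.0, 0.08), (200.0, 0.04)),
        seed=seed,
    )
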