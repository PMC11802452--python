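"""Awake-behavior LFP pipeline: conditioning, epoching, spectra, coherence.

The pipeline mirrors standard practice for chronic dual-site recordings
(e.g. hippocampus and medial prefrontal cortex during a rewarded virtual
linear-track task):

1. power-line harmonics (50/100/150/200 Hz) are removed with second-order
   band-stop filters, the signal is downsampled to 2 kHz behind an FIR
   anti-alias filter, then band-passed 0.5-500 Hz (second-order Butterworth);
   all filtering is zero-phase (forward-backward), preserving the cross-site
   phase relationships that coherence depends on;
2. analysis windows are 5-s segments ending 0.5 s before each reward,
   kept only when running speed lies in 5-10 cm/s and the hippocampal
   theta (6-10 Hz) : delta (2-4 Hz) mean-PSD ratio exceeds 4 (an awake
   locomotion/alertness gate);
3. power spectral density and magnitude-squared coherence are Welch
   estimates (2-s windows, 50% overlap) with segments pooled across the
   kept epochs, giving one averaged estimate per session;
4. band summaries report absolute power (integrated PSD), power relative to
   the total over the analysis range, and mean in-band coherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "LFPSession",
    "FilterSpec",
    "EpochRule",
    "Epoch",
    "EpochSet",
    "BandScheme",
    "SpectralEstimate",
    "BandSummary",
    "condition_signal",
    "select_epochs",
    "welch_psd",
    "ms_coherence",
    "summarize_bands",
    "full_session_epochs",
]


@dataclass(frozen=True)
class LFPSession:
    """A multi-channel LFP recording with behavior.

    ``channels`` maps site names to equal-length sample arrays at ``fs`` Hz;
    ``speed`` is the locomotion trace (cm/s) at ``speed_fs`` (50 Hz for an
    XY-motion sensor); ``rewards`` are trial reward-delivery times in
    seconds.
    """

    channels: dict
    fs: float
    speed: np.ndarray
    speed_fs: float = 50.0
    rewards: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        lengths = {len(x) for x in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        object.__setattr__(self, "speed", np.asarray(self.speed, dtype=float))
        object.__setattr__(self, "rewards", np.asarray(self.rewards, dtype=float))

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Signal-conditioning parameters."""

    line_frequencies: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0)
    bandstop_order: int = 2
    bandstop_halfwidth: float = 2.0
    bandpass: tuple[float, float] = (0.5, 500.0)
    bandpass_order: int = 2
    target_fs: float = 2000.0

    def __post_init__(self):
        if self.bandpass[1] >= self.target_fs / 2:
            raise ValueError("band-pass upper edge must lie below target Nyquist")
        if self.bandpass[0] <= 0 or self.bandpass[0] >= self.bandpass[1]:
            raise ValueError("invalid band-pass edges")


def condition_signal(session: LFPSession, spec: FilterSpec | None = None) -> LFPSession:
    """Notch line harmonics, downsample with FIR anti-aliasing, band-pass.

    Filtering is zero-phase (``sosfiltfilt``), so the stated order refers to
    the designed section and the effective attenuation is doubled.  If the
    raw rate is not an integer multiple of the target rate the signal is
    resampled by a rational factor with a warning.
    """
    spec = spec or FilterSpec()
    ratio = session.fs / spec.target_fs
    frac = Fraction(ratio).limit_denominator(1000)
    if frac.denominator != 1:
        warnings.warn(
            f"fs {session.fs} is not an integer multiple of {spec.target_fs}; "
            f"resampling by {frac.denominator}/{frac.numerator}", stacklevel=2,
        )

    stops = [
        sps.butter(
            spec.bandstop_order,
            [f - spec.bandstop_halfwidth, f + spec.bandstop_halfwidth],
            btype="bandstop", fs=session.fs, output="sos",
        )
        for f in spec.line_frequencies
    ]
    bp = sps.butter(
        spec.bandpass_order, list(spec.bandpass), btype="bandpass",
        fs=spec.target_fs, output="sos",
    )

    out = {}
    for name, x in session.channels.items():
        y = np.asarray(x, dtype=float)
        for sos in stops:
            y = sps.sosfiltfilt(sos, y)
        y = sps.resample_poly(y, frac.denominator, frac.numerator)
        y = sps.sosfiltfilt(bp, y)
        out[name] = y
    return LFPSession(
        channels=out, fs=spec.target_fs, speed=session.speed,
        speed_fs=session.speed_fs, rewards=session.rewards,
    )


@dataclass(frozen=True)
class EpochRule:
    """Behavioral gating of per-trial analysis windows."""

    speed_range: tuple[float, float] = (5.0, 10.0)
    window_length: float = 5.0
    window_end_offset: float = 0.5  # seconds before reward delivery
    gate_theta: tuple[float, float] = (6.0, 10.0)
    gate_delta: tuple[float, float] = (2.0, 4.0)
    gate_ratio_min: float = 4.0
    gate_channel: str = "HPC"

    def __post_init__(self):
        if self.gate_ratio_min <= 0:
            raise ValueError("gate_ratio_min must be positive")
        if self.window_length <= 0 or self.window_end_offset < 0:
            raise ValueError("invalid window geometry")


@dataclass(frozen=True)
class Epoch:
    start: float
    stop: float
    reward_time: float
    kept: bool
    reason: str  # "kept", "reward_too_early", "speed_out_of_range", "theta_delta_gate"


@dataclass(frozen=True)
class EpochSet:
    epochs: tuple[Epoch, ...]

    def kept(self) -> list[Epoch]:
        return [e for e in self.epochs if e.kept]

    @property
    def n_kept(self) -> int:
        return len(self.kept())


def select_epochs(session: LFPSession, rule: EpochRule | None = None) -> EpochSet:
    """Gate one candidate window per reward on speed and theta:delta ratio.

    For a reward at time t the candidate window is
    [t - window_end_offset - window_length, t - window_end_offset].
    The window is kept when the mean of the speed samples inside it lies in
    ``speed_range`` and the gate channel's mean Welch PSD over the theta band
    exceeds ``gate_ratio_min`` times the delta-band mean.  Rewards too early
    for a full window are skipped and logged.  The result is independent of
    the order of the reward list.
    """
    rule = rule or EpochRule()
    if rule.gate_channel not in session.channels:
        raise ValueError(f"gate channel {rule.gate_channel!r} not in session")
    x = session.channels[rule.gate_channel]
    epochs = []
    for t in sorted(float(t) for t in session.rewards):
        stop = t - rule.window_end_offset
        start = stop - rule.window_length
        if start < 0:
            epochs.append(Epoch(start, stop, t, False, "reward_too_early"))
            continue
        i0 = int(np.ceil(start * session.speed_fs - 1e-9))
        i1 = int(np.floor(stop * session.speed_fs - 1e-9)) + 1
        window_speed = session.speed[i0:i1]
        mean_speed = float(window_speed.mean()) if len(window_speed) else np.nan
        if not (rule.speed_range[0] <= mean_speed <= rule.speed_range[1]):
            epochs.append(Epoch(start, stop, t, False, "speed_out_of_range"))
            continue
        seg = x[int(round(start * session.fs)) : int(round(stop * session.fs))]
        f, pxx, _ = _pooled_csd([seg], [seg], session.fs, 2.0, 0.5)
        theta = _band_mean(f, pxx.real, rule.gate_theta)
        delta = _band_mean(f, pxx.real, rule.gate_delta)
        if delta <= 0 or theta / delta <= rule.gate_ratio_min:
            epochs.append(Epoch(start, stop, t, False, "theta_delta_gate"))
            continue
        epochs.append(Epoch(start, stop, t, True, "kept"))
    return EpochSet(tuple(epochs))


def _band_mean(f: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> float:
    sel = (f >= band[0]) & (f <= band[1])
    return float(p[sel].mean())


def full_session_epochs(session: LFPSession) -> EpochSet:
    """A single epoch spanning the whole session (for ungated analyses)."""
    e = Epoch(0.0, session.duration, float("nan"), True, "kept")
    return EpochSet((e,))


def _segments(session: LFPSession, epoch_set: EpochSet, channel: str) -> list[np.ndarray]:
    x = session.channels[channel]
    segs = []
    for e in epoch_set.kept():
        segs.append(x[int(round(e.start * session.fs)) : int(round(e.stop * session.fs))])
    return segs


def _pooled_csd(xs, ys, fs, window, overlap):
    """Average the cross-spectral density over 2-s Welch segments pooled
    across epochs; returns (f, csd, total segment count)."""
    nperseg = int(round(window * fs))
    noverlap = int(round(nperseg * overlap))
    step = nperseg - noverlap
    acc = None
    freqs = None
    total = 0
    for x, y in zip(xs, ys):
        if len(x) < nperseg:
            warnings.warn("epoch shorter than the Welch window; skipped", stacklevel=2)
            continue
        k = 1 + (len(x) - nperseg) // step
        f, pxy = sps.csd(
            x, y, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
            detrend="constant", scaling="density",
        )
        freqs = f
        acc = k * pxy if acc is None else acc + k * pxy
        total += k
    if acc is None:
        raise ValueError("no epoch is at least one Welch window long")
    return freqs, acc / total, total


@dataclass(frozen=True)
class SpectralEstimate:
    """Welch PSD per channel and magnitude-squared coherence per pair."""

    frequencies: np.ndarray
    psd: dict = field(default_factory=dict)  # channel -> density (units^2/Hz)
    coherence: dict = field(default_factory=dict)  # (ch_a, ch_b) -> [0, 1]
    n_segments: int = 0
    window: float = 2.0
    overlap: float = 0.5


def welch_psd(
    session: LFPSession,
    epoch_set: EpochSet,
    channel: str,
    window: float = 2.0,
    overlap: float = 0.5,
) -> SpectralEstimate:
    """Welch PSD pooled over all segments of all kept epochs (density units)."""
    segs = _segments(session, epoch_set, channel)
    if not segs:
        raise ValueError("no kept epochs to analyze")
    f, pxx, k = _pooled_csd(segs, segs, session.fs, window, overlap)
    return SpectralEstimate(
        frequencies=f, psd={channel: pxx.real}, n_segments=k,
        window=window, overlap=overlap,
    )


def ms_coherence(
    session: LFPSession,
    epoch_set: EpochSet,
    pair: tuple[str, str],
    window: float = 2.0,
    overlap: float = 0.5,
) -> SpectralEstimate:
    """Magnitude-squared coherence between two channels on pooled segments.

    At least two averaged segments are required: the coherence of a single
    segment is identically 1 and carries no information.
    """
    a, b = pair
    xs = _segments(session, epoch_set, a)
    ys = _segments(session, epoch_set, b)
    if not xs:
        raise ValueError("no kept epochs to analyze")
    f, pxy, k = _pooled_csd(xs, ys, session.fs, window, overlap)
    if k < 2:
        raise ValueError(
            "coherence needs at least 2 averaged segments (a single segment "
            "gives coherence identically 1)"
        )
    _, pxx, _ = _pooled_csd(xs, xs, session.fs, window, overlap)
    _, pyy, _ = _pooled_csd(ys, ys, session.fs, window, overlap)
    denom = pxx.real * pyy.real
    coh = np.zeros_like(denom)
    ok = denom > 0
    coh[ok] = np.abs(pxy[ok]) ** 2 / denom[ok]
    return SpectralEstimate(
        frequencies=f, psd={a: pxx.real, b: pyy.real}, coherence={pair: coh},
        n_segments=k, window=window, overlap=overlap,
    )


@dataclass(frozen=True)
class BandScheme:
    """Frequency bands for power and coherence summaries.

    The defaults follow the reporting convention of dual-site awake
    recordings: relative power over theta 4-12 Hz and gamma 30-80 Hz;
    coherence over theta 4-12, beta 15-25 and gamma 26-70 Hz.  Bands within
    one scheme must not overlap.
    """

    power_bands: tuple = (("theta", (4.0, 12.0)), ("gamma", (30.0, 80.0)))
    coherence_bands: tuple = (
        ("theta", (4.0, 12.0)), ("beta", (15.0, 25.0)), ("gamma", (26.0, 70.0)),
    )

    def __post_init__(self):
        for bands in (self.power_bands, self.coherence_bands):
            spans = sorted(b for _, b in bands)
            for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
                if l2 < h1:
                    raise ValueError("bands within a scheme must not overlap")


@dataclass(frozen=True)
class BandSummary:
    """Absolute/relative band power and mean band coherence."""

    absolute_power: dict = field(default_factory=dict)
    relative_power: dict = field(default_factory=dict)
    mean_coherence: dict = field(default_factory=dict)
    total_power: float = float("nan")


def summarize_bands(
    estimate: SpectralEstimate,
    scheme: BandScheme | None = None,
    channel: str | None = None,
    pair: tuple[str, str] | None = None,
    total_range: tuple[float, float] | None = None,
    power_mode: str = "integral",
) -> BandSummary:
    """Summarize a spectral estimate over the scheme's bands.

    Band power is the Riemann integral of the PSD over the in-band bins
    (sum x bin width), making results resolution-independent; the raw-sum
    convention (plain sum of PSD bins) is available as
    ``power_mode="sum"`` for strict replication of sum-of-PSD reports.
    Relative power is normalized by the total over ``total_range`` (the full
    estimated range by default).  Band coherence is the unweighted mean of
    the in-band coherence bins.
    """
    scheme = scheme or BandScheme()
    f = estimate.frequencies
    df = float(f[1] - f[0])
    bin_w = df if power_mode == "integral" else 1.0
    if power_mode not in ("integral", "sum"):
        raise ValueError("power_mode must be 'integral' or 'sum'")

    absolute, relative, coh_means = {}, {}, {}
    total = float("nan")
    if channel is not None:
        if channel not in estimate.psd:
            raise ValueError(f"channel {channel!r} not in the estimate")
        p = estimate.psd[channel]
        lo, hi = total_range if total_range else (float(f[0]), float(f[-1]))
        for name, (b_lo, b_hi) in scheme.power_bands:
            if b_lo < f[0] - df / 2 or b_hi > f[-1] + df / 2:
                raise ValueError(f"band {name!r} lies outside the frequency grid")
        total_sel = (f >= lo) & (f <= hi)
        total = float(p[total_sel].sum() * bin_w)
        for name, band in scheme.power_bands:
            sel = (f >= band[0]) & (f <= band[1])
            absolute[name] = float(p[sel].sum() * bin_w)
            relative[name] = absolute[name] / total if total > 0 else float("nan")
    if pair is not None:
        if pair not in estimate.coherence:
            raise ValueError(f"pair {pair!r} not in the estimate")
        c = estimate.coherence[pair]
        for name, band in scheme.coherence_bands:
            if band[0] < f[0] - df / 2 or band[1] > f[-1] + df / 2:
                raise ValueError(f"band {name!r} lies outside the frequency grid")
            sel = (f >= band[0]) & (f <= band[1])
            coh_means[name] = float(c[sel].mean())
    return BandSummary(
        absolute_power=absolute, relative_power=relative,
        mean_coherence=coh_means, total_power=total,
    )
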