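"""Radial-pulse waveform features at the Gwan position.

From a sampled pressure waveform, 20 named variables are extracted per
arm: eight time-domain features (heart rate, pulse pressure, time and
height of the dicrotic notch, and notch time plus three beat areas after
normalization to a 75 bpm heart rate), three tonometry features from an
applied-depth series (PDI, PVI, PPW_PVI) and nine spectral features from
a Welch power spectral density (fundamental power, harmonic-to-
fundamental ratios w2..w7, the 0-10 Hz integral and the 10-50 Hz to
0-10 Hz power ratio).

Algorithmic defaults fixed here: beat onsets are the local minimum (the
foot) preceding each systolic upstroke; beats whose onset-to-onset
length deviates more than 25% from the median are rejected; the dicrotic
notch is the deepest local minimum between 15% and 60% of the period
after the systolic peak of the ensemble-averaged beat; HR75
normalization rescales the averaged beat's time axis linearly so its
period equals 60/75 s; the PSD uses a Hann window, segments of four
beats and 50% overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

TIME_FEATURES = (
    "HR", "PP", "t4", "h4",
    "t4_HR75", "Asys_HR75", "Adias_HR75", "Aall_HR75",
)
TONOMETRY_FEATURES = ("PDI", "PVI", "PPW_PVI")
PSD_FEATURES = (
    "PSD_w1",
    "PSD_w2_w1", "PSD_w3_w1", "PSD_w4_w1",
    "PSD_w5_w1", "PSD_w6_w1", "PSD_w7_w1",
    "PSD_0_10Hz", "PSD_10_50Hz",
)
#: The 20 per-arm pulse variables (prefixed L_/R_ in feature tables).
PULSE_FEATURES = TIME_FEATURES + TONOMETRY_FEATURES + PSD_FEATURES


class SegmentationError(ValueError):
    """Fewer than three clean beats could be segmented."""


@dataclass
class PressureWaveform:
    """A uniformly sampled radial pressure signal.

    ``depth_series`` optionally holds (applied depth, waveform) pairs
    from a tonometry sweep at increasing hold-down pressures.
    """

    samples: np.ndarray
    fs: float
    arm: str = "L"
    depth_series: list[tuple[float, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.arm not in ("L", "R"):
            raise ValueError("arm must be 'L' or 'R'")


@dataclass
class Beats:
    """Segmented beats: foot-onset indices and accepted beat slices."""

    onsets: np.ndarray          # onset sample index per accepted beat
    beats: list[np.ndarray]     # samples from onset to next onset
    fs: float
    period: float               # median beat period, s
    n_rejected: int = 0


def _estimate_period(x: np.ndarray, fs: float) -> float:
    """Dominant period via the autocorrelation of the detrended signal."""
    y = x - x.mean()
    if np.allclose(y, 0.0):
        raise SegmentationError("constant signal, no beats")
    acf = np.correlate(y, y, mode="full")[len(y) - 1:]
    acf /= acf[0]
    # Physiological beat range 0.3-2.0 s (30-200 bpm).
    lo = max(int(0.3 * fs), 1)
    hi = min(int(2.0 * fs), len(acf) - 1)
    if hi <= lo:
        raise SegmentationError("signal too short for beat detection")
    lag = lo + int(np.argmax(acf[lo:hi]))
    if acf[lag] < 0.2:
        raise SegmentationError("no periodic beat structure detected")
    return lag / fs


def segment_beats(waveform: PressureWaveform) -> Beats:
    """Segment a pressure waveform into beats at the foot of the upstroke.

    Systolic peaks are located first; each beat onset is the minimum in
    the window preceding the upstroke.  Beats whose length deviates more
    than 25% from the median onset-to-onset interval are rejected.
    """
    x, fs = waveform.samples, waveform.fs
    period = _estimate_period(x, fs)
    min_dist = max(int(0.6 * period * fs), 1)
    prominence = 0.25 * (x.max() - x.min())
    peaks, _ = sps.find_peaks(x, distance=min_dist, prominence=prominence)
    if len(peaks) < 3:
        raise SegmentationError("fewer than 3 systolic peaks detected")
    onsets = []
    for pk in peaks:
        lo = max(pk - int(0.5 * period * fs), 0)
        if lo >= pk:
            continue
        onsets.append(lo + int(np.argmin(x[lo:pk])))
    onsets = np.unique(onsets)
    if len(onsets) < 3:
        raise SegmentationError("fewer than 3 beat onsets detected")
    lengths = np.diff(onsets)
    med = float(np.median(lengths))
    ok = np.abs(lengths - med) <= 0.25 * med
    beats = [
        x[onsets[i]: onsets[i + 1]]
        for i in range(len(lengths)) if ok[i]
    ]
    if len(beats) < 3:
        raise SegmentationError("fewer than 3 consistent beats retained")
    return Beats(
        onsets=onsets[:-1][ok],
        beats=beats,
        fs=fs,
        period=med / fs,
        n_rejected=int(np.sum(~ok)),
    )


def _ensemble_average(beats: Beats) -> np.ndarray:
    """Average the accepted beats on a common normalized time grid."""
    n = max(int(round(beats.period * beats.fs)), 8)
    grid = np.linspace(0.0, 1.0, n, endpoint=False)
    stack = [
        np.interp(grid, np.linspace(0.0, 1.0, len(b), endpoint=False), b)
        for b in beats.beats
    ]
    return np.mean(stack, axis=0)


def _find_notch(
    beat: np.ndarray, period: float, fs_eff: float,
    window: tuple[float, float] = (0.15, 0.60),
) -> int | None:
    """Deepest local minimum between ``window`` fractions of the period
    after the systolic peak; None when absent."""
    peak = int(np.argmax(beat))
    lo = peak + int(window[0] * period * fs_eff)
    hi = min(peak + int(window[1] * period * fs_eff) + 1, len(beat) - 1)
    if hi - lo < 3:
        return None
    seg = beat[lo:hi]
    minima, _ = sps.find_peaks(-seg)
    if len(minima) == 0:
        return None
    return lo + int(minima[np.argmin(seg[minima])])


def extract_time_features(
    beats: Beats, notch_window: tuple[float, float] = (0.15, 0.60)
) -> dict[str, float]:
    """Time-domain features from segmented beats.

    HR and PP are beat-to-beat medians; notch timing/height and the HR75
    areas come from the ensemble-averaged, foot-referenced beat with its
    time axis rescaled so the period equals 60/75 s.  Missing-notch
    features are NaN.
    """
    period = beats.period
    hr = 60.0 / period
    pp = float(np.median([b.max() - b[0] for b in beats.beats]))
    avg = _ensemble_average(beats)
    avg = avg - avg[0]                      # foot-referenced
    fs_eff = len(avg) / period              # samples per second on the grid
    scale = (60.0 / 75.0) / period          # HR75 time rescale factor
    out = {"HR": hr, "PP": pp}
    notch = _find_notch(avg, period, fs_eff, notch_window)
    t = np.arange(len(avg)) / fs_eff
    if notch is None:
        out.update(
            t4=math.nan, h4=math.nan, t4_HR75=math.nan,
            Asys_HR75=math.nan, Adias_HR75=math.nan,
            Aall_HR75=float(np.trapezoid(avg, t * scale)),
        )
        return out
    t4 = notch / fs_eff
    out["t4"] = t4
    out["h4"] = float(avg[notch])
    out["t4_HR75"] = t4 * scale
    t75 = t * scale
    asys = float(np.trapezoid(avg[: notch + 1], t75[: notch + 1]))
    adias = float(np.trapezoid(avg[notch:], t75[notch:]))
    out["Asys_HR75"] = asys
    out["Adias_HR75"] = adias
    out["Aall_HR75"] = asys + adias
    return out


@dataclass
class TonometryResult:
    PDI: float
    PVI: float
    PPW_PVI: float
    boundary_maximum: bool = False


def _pulse_amplitude(entry) -> float:
    """Pulse pressure of a depth-series entry (waveform or scalar)."""
    arr = np.asarray(entry, dtype=float)
    if arr.ndim == 0:
        return float(arr)
    return arr.max() - arr.min()


def extract_tonometry_features(
    depth_series: list[tuple[float, np.ndarray]]
) -> TonometryResult:
    """Tonometry indices from the amplitude-versus-applied-depth profile.

    PDI is the depth of maximal pulse amplitude normalized by the deepest
    applied depth; PVI is the width of the depth interval where the
    amplitude stays at or above half its maximum (crossings by linear
    interpolation), normalized by the span of applied depths; PPW_PVI is
    the mean amplitude over the sampled depths inside that interval.  A
    profile whose maximum sits on the boundary is flagged.
    """
    if len(depth_series) < 5:
        raise ValueError("need at least 5 applied depths")
    depths = np.array([d for d, _ in depth_series], dtype=float)
    amps = np.array([_pulse_amplitude(w) for _, w in depth_series])
    order = np.argsort(depths)
    depths, amps = depths[order], amps[order]
    imax = int(np.argmax(amps))
    pdi = depths[imax] / depths[-1]
    boundary = imax in (0, len(amps) - 1) and not np.allclose(amps, amps[0])
    half = amps[imax] / 2.0

    def cross(i0: int, i1: int) -> float:
        d0, d1, a0, a1 = depths[i0], depths[i1], amps[i0], amps[i1]
        return d0 + (half - a0) * (d1 - d0) / (a1 - a0)

    lo = depths[0]
    for i in range(imax, 0, -1):
        if amps[i - 1] < half <= amps[i]:
            lo = cross(i - 1, i)
            break
    hi = depths[-1]
    for i in range(imax, len(amps) - 1):
        if amps[i + 1] < half <= amps[i]:
            hi = cross(i + 1, i)
            break
    span = depths[-1] - depths[0]
    pvi = (hi - lo) / span if span > 0 else math.nan
    inside = (depths >= lo) & (depths <= hi)
    ppw = float(amps[inside].mean())
    return TonometryResult(
        PDI=float(pdi), PVI=float(pvi), PPW_PVI=ppw,
        boundary_maximum=bool(boundary),
    )


def extract_psd_features(
    waveform: PressureWaveform,
    hr: float | None = None,
    beats_per_segment: int = 4,
) -> dict[str, float]:
    """Spectral features from a Welch PSD of the pressure signal.

    The fundamental is the spectral peak nearest HR/60 Hz; harmonic
    powers are read at the nearest bins to k times the fundamental.
    PSD_0_10Hz integrates the density up to 10 Hz and PSD_10_50Hz is the
    ratio of the 10-50 Hz integral to it.
    """
    x, fs = waveform.samples, waveform.fs
    if fs < 100:
        raise ValueError("band features require fs >= 100 Hz")
    if len(x) / fs < 10.0:
        raise ValueError("need at least 10 s of signal")
    if hr is None:
        hr = extract_time_features(segment_beats(waveform))["HR"]
    f0 = hr / 60.0
    nperseg = min(int(round(beats_per_segment / f0 * fs)), len(x))
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    # Fundamental: local PSD maximum nearest the expected beat frequency.
    peaks, _ = sps.find_peaks(psd)
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(psd))])
    fund = peaks[np.argmin(np.abs(freqs[peaks] - f0))]
    f1 = freqs[fund]
    out = {"PSD_w1": float(psd[fund])}
    for k in range(2, 8):
        idx = int(np.argmin(np.abs(freqs - k * f1)))
        out[f"PSD_w{k}_w1"] = float(psd[idx] / psd[fund])
    low = freqs <= 10.0
    band_low = float(np.trapezoid(psd[low], freqs[low]))
    mid = (freqs >= 10.0) & (freqs <= 50.0)
    band_mid = float(np.trapezoid(psd[mid], freqs[mid]))
    out["PSD_0_10Hz"] = band_low
    out["PSD_10_50Hz"] = band_mid / band_low if band_low > 0 else math.nan
    return out


def extract_pulse_record(
    waveform: PressureWaveform,
    prefix_arm: bool = True,
) -> dict[str, float]:
    """All pulse features for one arm, optionally ``L_``/``R_`` prefixed.

    Tonometry features are NaN when the waveform carries no depth
    series.
    """
    beats = segment_beats(waveform)
    rec = dict(extract_time_features(beats))
    if waveform.depth_series is not None:
        tono = extract_tonometry_features(waveform.depth_series)
        rec.update(PDI=tono.PDI, PVI=tono.PVI, PPW_PVI=tono.PPW_PVI)
    else:
        rec.update(PDI=math.nan, PVI=math.nan, PPW_PVI=math.nan)
    rec.update(extract_psd_features(waveform, hr=rec["HR"]))
    if prefix_arm:
        rec = {f"{waveform.arm}_{k}": v for k, v in rec.items()}
    return rec
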