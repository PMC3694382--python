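"""Acoustic voice features: perturbation, formants, sentence pitch.

For each sustained vowel (a, e, i, o, u) the module measures the mean
fundamental frequency (F0), the MDVP-style perturbation measures --
jitter (JITT), relative average perturbation (RAP), pitch perturbation
quotient (PPQ), shimmer (SHIM) and amplitude perturbation quotient
(APQ) -- and the first three formant frequencies with the bandwidths of
the first two (linear-prediction analysis).  For the read sentence it
measures the voiced duration (sDT), the 10th/50th/90th percentiles of
the frame-wise F0 distribution (sF10/sF50/sF90) and their asymmetry
ratio sFHL = (sF90 - sF50) / (sF50 - sF10).

Perturbation formula sheet (cycle periods T_k, cycle peak amplitudes
A_k, N cycles, all reported in percent):

* JITT = mean_k |T_k - T_{k-1}| / mean(T) * 100
* RAP  = mean_k |T_k - (T_{k-1}+T_k+T_{k+1})/3| / mean(T) * 100
* PPQ  = as RAP with a centered 5-point window
* SHIM, APQ = the same with A_k in place of T_k (APQ 5-point)

Fixed analysis defaults: F0 search range 30-500 Hz, frame 40 ms, hop
10 ms, voicing threshold 0.45 on the normalized autocorrelation; LPC on
the pre-emphasized signal resampled to 10 kHz with order fs/1000 + 2.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

VOWELS = ("a", "e", "i", "o", "u")
VOWEL_FEATURES = (
    "F0", "JITT", "RAP", "PPQ", "SHIM", "APQ",
    "F1", "F2", "F3", "BW1", "BW2",
)
SENTENCE_FEATURES = ("sDT", "sF10", "sF50", "sF90", "sFHL")
#: All 60 vocal variable names: aF0 ... uBW2 plus the sentence features.
VOICE_VARIABLES = tuple(
    f"{v}{feat}" for v in VOWELS for feat in VOWEL_FEATURES
) + SENTENCE_FEATURES

F0_RANGE = (30.0, 500.0)
VOICING_THRESHOLD = 0.45


class VoicingError(ValueError):
    """Too few voiced cycles for a reliable measurement."""


class FormantError(ValueError):
    """Fewer than three resolvable formant poles."""


def _autocorr_f0(x: np.ndarray, fs: float) -> tuple[float, float]:
    """F0 and voicing strength from the normalized autocorrelation.

    Returns (f0_hz, peak_value); the peak lag is refined by parabolic
    interpolation.
    """
    y = x - x.mean()
    energy = float(np.dot(y, y))
    if energy <= 0:
        return math.nan, 0.0
    acf = np.correlate(y, y, mode="full")[len(y) - 1:] / energy
    lo = max(int(fs / F0_RANGE[1]), 2)
    hi = min(int(fs / F0_RANGE[0]), len(acf) - 2)
    if hi <= lo:
        return math.nan, 0.0
    # Shortest lag whose peak is close to the in-range maximum; taking
    # the global maximum would halve F0 whenever cycles alternate
    # (period doubling) or the signal repeats over several cycles.
    best = float(np.max(acf[lo:hi]))
    peaks, _ = sps.find_peaks(acf[lo:hi])
    candidates = [p + lo for p in peaks if acf[p + lo] >= 0.75 * best]
    lag = candidates[0] if candidates else lo + int(np.argmax(acf[lo:hi]))
    # Parabolic refinement of the peak lag.
    a, b, c = acf[lag - 1], acf[lag], acf[lag + 1]
    denom = a - 2 * b + c
    shift = 0.5 * (a - c) / denom if abs(denom) > 1e-12 else 0.0
    return fs / (lag + shift), float(b)


def extract_cycles(
    samples: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Glottal-cycle lengths (s) and per-cycle peak amplitudes.

    Cycle marks are waveform peaks picked at the autocorrelation period
    and refined to sub-sample precision by parabolic interpolation.
    The cycle amplitude is the root-mean-square level between
    consecutive (fractional) marks -- the energy of one period is
    phase-invariant, so a perfectly periodic signal yields exactly
    constant amplitudes.  The first and last cycles are dropped to
    avoid onset transients.
    """
    x = np.asarray(samples, dtype=float)
    f0, strength = _autocorr_f0(x, fs)
    if not math.isfinite(f0) or strength < VOICING_THRESHOLD:
        raise VoicingError("signal is unvoiced or aperiodic")
    t0 = fs / f0
    peaks, _ = sps.find_peaks(
        x, distance=max(int(0.7 * t0), 1), height=0.3 * x.max()
    )
    peaks = peaks[(peaks > 0) & (peaks < len(x) - 1)]
    if len(peaks) < 13:
        raise VoicingError("fewer than 10 usable cycles")
    # Sub-sample peak (cycle-mark) positions.
    a, b, c = x[peaks - 1], x[peaks], x[peaks + 1]
    denom = a - 2 * b + c
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (a - c) / denom, 0.0)
    marks = peaks + shift                  # fractional sample positions
    # Cycle RMS from the cumulative energy at fractional endpoints.
    cum = np.concatenate([[0.0], np.cumsum(x**2)])
    grid = np.arange(len(cum), dtype=float)
    energy = np.diff(np.interp(marks, grid, cum))
    lengths = np.diff(marks) / fs
    amps = np.sqrt(energy / np.maximum(np.diff(marks), 1e-12))
    lengths = lengths[1:-1]
    amps = amps[1:-1]
    if len(lengths) < 10:
        raise VoicingError("fewer than 10 usable cycles")
    return lengths, amps


def _window_perturbation(values: np.ndarray, width: int) -> float:
    """Mean absolute deviation from the centered moving average of
    ``width`` points, as a fraction of the overall mean."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean value")
    half = width // 2
    devs = [
        abs(v[k] - v[k - half: k + half + 1].mean())
        for k in range(half, len(v) - half)
    ]
    return float(np.mean(devs) / abs(mean))


def perturbation_measures(
    lengths: np.ndarray, amplitudes: np.ndarray
) -> dict[str, float]:
    """JITT, RAP, PPQ, SHIM and APQ (percent) from cycle data."""
    T = np.asarray(lengths, dtype=float)
    A = np.asarray(amplitudes, dtype=float)
    if len(T) < 10 or len(A) < 10:
        raise VoicingError("need at least 10 cycles")
    if T.mean() == 0:
        raise ValueError("zero mean period")
    jitt = np.mean(np.abs(np.diff(T))) / T.mean() * 100.0
    shim = np.mean(np.abs(np.diff(A))) / abs(A.mean()) * 100.0
    return {
        "JITT": float(jitt),
        "RAP": _window_perturbation(T, 3) * 100.0,
        "PPQ": _window_perturbation(T, 5) * 100.0,
        "SHIM": float(shim),
        "APQ": _window_perturbation(A, 5) * 100.0,
    }


def _lpc(x: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method linear prediction coefficients.

    Returns the polynomial [1, -a_1, ..., -a_p] of the inverse filter.
    """
    r = np.correlate(x, x, mode="full")[len(x) - 1: len(x) + order]
    a = sla.solve_toeplitz((r[:-1], r[:-1]), r[1:])
    return np.concatenate([[1.0], -a])


def formant_estimates(
    samples: np.ndarray,
    fs: float,
    max_bandwidth: float = 500.0,
) -> dict[str, float]:
    """First three formants (Hz) and the first two bandwidths via LPC.

    The signal is resampled to 10 kHz, Hamming-windowed and fitted
    with an order fs/1000 + 2 predictor; formants are pole angles and
    bandwidths follow from pole radii.  Two passes are run: frequencies
    come from a pre-emphasized analysis (tilt compensation separates
    the peaks), while bandwidths come from a plain analysis, because
    the pre-emphasis zero systematically sharpens the fitted poles.
    Poles below 90 Hz or broader than ``max_bandwidth`` are discarded.
    """
    x = np.asarray(samples, dtype=float)
    target_fs = 10_000
    if fs != target_fs:
        frac = Fraction(target_fs, int(round(fs))).limit_denominator(1000)
        x = sps.resample_poly(x, frac.numerator, frac.denominator)
    order = target_fs // 1000 + 2

    def poles(sig):
        roots = np.roots(_lpc(sig * np.hamming(len(sig)), order))
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * target_fs / (2 * np.pi)
        bws = -np.log(np.abs(roots)) * target_fs / np.pi
        keep = (freqs > 90.0) & (bws < max_bandwidth)
        ix = np.argsort(freqs[keep])
        return freqs[keep][ix], bws[keep][ix]

    emph = np.append(x[0], x[1:] - 0.97 * x[:-1])
    freqs, _ = poles(emph)
    plain_freqs, plain_bws = poles(x)
    if len(freqs) < 3 or len(plain_freqs) < 1:
        raise FormantError("fewer than 3 resolvable formants")
    f = freqs[:3]
    b = [
        float(plain_bws[np.argmin(np.abs(plain_freqs - fi))])
        for fi in f[:2]
    ]
    return {
        "F1": float(f[0]), "F2": float(f[1]), "F3": float(f[2]),
        "BW1": b[0], "BW2": b[1],
    }


def track_f0(
    samples: np.ndarray,
    fs: float,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    threshold: float = VOICING_THRESHOLD,
) -> np.ndarray:
    """Frame-wise F0 track; NaN for unvoiced frames."""
    x = np.asarray(samples, dtype=float)
    frame = int(frame_s * fs)
    hop = int(hop_s * fs)
    if len(x) < frame:
        raise VoicingError("signal shorter than one analysis frame")
    f0s = []
    for start in range(0, len(x) - frame + 1, hop):
        f0, strength = _autocorr_f0(x[start: start + frame], fs)
        f0s.append(f0 if strength >= threshold else math.nan)
    return np.array(f0s)


def vowel_features(samples: np.ndarray, fs: float) -> dict[str, float]:
    """All 11 per-vowel features (F0, perturbations, formants)."""
    lengths, amps = extract_cycles(samples, fs)
    out = {"F0": float(1.0 / lengths.mean())}
    out.update(perturbation_measures(lengths, amps))
    out.update(formant_estimates(samples, fs))
    return out


def sentence_features(samples: np.ndarray, fs: float) -> dict[str, float]:
    """Voiced duration and F0-distribution features of a sentence.

    sDT is the recording duration times the voiced-frame fraction;
    sF10/sF50/sF90 are linearly interpolated percentiles of the voiced
    frame-wise F0 values; sFHL is NaN when sF50 equals sF10.
    """
    track = track_f0(samples, fs)
    voiced = track[np.isfinite(track)]
    if len(voiced) == 0:
        raise VoicingError("no voiced frames in sentence")
    duration = len(samples) / fs
    sdt = duration * len(voiced) / len(track)
    f10, f50, f90 = np.percentile(voiced, [10, 50, 90])
    # A spread below the tracker's frequency resolution (~0.5 Hz) makes
    # the ratio meaningless: flag it undefined.
    sfhl = (f90 - f50) / (f50 - f10) if f50 - f10 > 0.5 else math.nan
    return {
        "sDT": float(sdt),
        "sF10": float(f10), "sF50": float(f50), "sF90": float(f90),
        "sFHL": float(sfhl),
    }
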