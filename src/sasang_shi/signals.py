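"""Raw-signal fixtures: pulse waveforms, face images, voice audio.

These generators produce simplified physical stand-ins for the device
recordings the extractors consume -- a smooth two-lobe pressure beat
with an analytically placed dicrotic notch, a flat-sector face with an
in-frame color chart, and a source-filter vowel (windowed-sinc glottal
impulse train through formant resonators).  They target extractor
correctness, not physiological realism: every construction parameter
maps to a known extractor output, which makes round-trip tests exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicHermiteSpline
from scipy.io import wavfile

from .complexion import SectorSet, ycrcb_to_rgb
from .pulse import PressureWaveform


# --------------------------------------------------------------------
# Pulse
# --------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSpec:
    """Parameters of the synthetic pressure beat.

    The beat rises from the foot to the systolic peak at
    ``peak_fraction`` of the period, falls to a local minimum (the
    dicrotic notch) of height ``notch_depth`` x amplitude at
    ``notch_fraction``, rebounds into a small diastolic lobe and decays
    to the foot.
    """

    period: float = 0.8          # s
    amplitude: float = 1.0       # systolic amplitude, arbitrary units
    peak_fraction: float = 0.18
    notch_fraction: float = 0.35
    notch_depth: float = 0.40    # notch height as fraction of amplitude
    dicrotic_bump: float = 0.15  # diastolic lobe above the notch
    n_beats: int = 16
    fs: float = 250.0            # Hz
    baseline: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        for name in ("peak_fraction", "notch_fraction", "notch_depth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.notch_fraction <= self.peak_fraction:
            raise ValueError("notch must come after the systolic peak")


def _beat_template(spec: PulseSpec):
    """Smooth beat as a clamped cubic Hermite spline; the knots at the
    peak, notch and dicrotic lobe have zero slope, so the notch is an
    exact local minimum."""
    T, A = spec.period, spec.amplitude
    knots_t = np.array([
        0.0,
        spec.peak_fraction * T,
        spec.notch_fraction * T,
        min(spec.notch_fraction + 0.12, 0.9) * T,
        T,
    ])
    knots_v = np.array([
        0.0,
        A,
        spec.notch_depth * A,
        (spec.notch_depth + spec.dicrotic_bump) * A,
        0.0,
    ])
    slopes = np.zeros_like(knots_t)
    return CubicHermiteSpline(knots_t, knots_v, slopes)


def generate_pulse_waveform(
    spec: PulseSpec | None = None,
    seed: int = 0,
    arm: str = "L",
) -> PressureWaveform:
    """Sampled periodic pressure waveform from a beat template."""
    spec = spec or PulseSpec()
    beat = _beat_template(spec)
    t = np.arange(int(spec.n_beats * spec.period * spec.fs)) / spec.fs
    x = beat(np.mod(t, spec.period)) + spec.baseline
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, spec.noise_sd, size=len(x))
    return PressureWaveform(samples=x, fs=spec.fs, arm=arm)


def generate_tonometry_series(
    spec: PulseSpec | None = None,
    depths: np.ndarray | None = None,
    peak_depth: float = 3.0,
    width: float = 1.2,
    seed: int = 0,
) -> list[tuple[float, np.ndarray]]:
    """Depth sweep whose pulse amplitude follows a Gaussian profile
    centered at ``peak_depth``."""
    spec = spec or PulseSpec()
    if depths is None:
        depths = np.arange(1.0, 6.0)
    out = []
    for i, d in enumerate(np.asarray(depths, dtype=float)):
        amp = np.exp(-0.5 * ((d - peak_depth) / width) ** 2)
        wf = generate_pulse_waveform(
            PulseSpec(**{
                **spec.__dict__, "amplitude": spec.amplitude * amp
            }),
            seed=seed + i,
        )
        out.append((float(d), wf.samples))
    return out


# --------------------------------------------------------------------
# Face
# --------------------------------------------------------------------

#: Reference chart: 18 distinct RGB patches spanning color space.
CHART_REFERENCE = np.array([
    [115, 82, 68], [194, 150, 130], [98, 122, 157], [87, 108, 67],
    [133, 128, 177], [103, 189, 170], [214, 126, 44], [80, 91, 166],
    [193, 90, 99], [94, 60, 108], [157, 188, 64], [224, 163, 46],
    [56, 61, 150], [70, 148, 73], [175, 54, 60], [231, 199, 31],
    [187, 86, 149], [8, 133, 161],
], dtype=float)

#: Default per-sector (Y, Cr, Cb) means of the seven atomic sectors.
DEFAULT_SECTOR_MEANS = {
    "FhL": (165.0, 145.0, 112.0),
    "FhR": (168.0, 143.0, 114.0),
    "ChLU": (158.0, 150.0, 110.0),
    "ChLD": (150.0, 152.0, 112.0),
    "ChRU": (160.0, 149.0, 109.0),
    "ChRD": (152.0, 151.0, 113.0),
    "Nose": (172.0, 147.0, 108.0),
}


@dataclass(frozen=True)
class FaceSpec:
    """Synthetic face: sector YCrCb means/SD and an optional global
    linear RGB distortion (matrix + offset) to exercise correction."""

    shape: tuple[int, int] = (360, 360)
    sector_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SECTOR_MEANS))
    sector_sd: float = 5.0
    distortion: np.ndarray | None = None      # 3x3 matrix
    distortion_offset: np.ndarray | None = None


@dataclass
class FaceImage:
    """A rendered face fixture and its ground truth."""

    image: np.ndarray                 # (H, W, 3) uint8 RGB
    sectors: SectorSet
    chart_boxes: list[tuple[slice, slice]]
    reference_patches: np.ndarray
    true_means: dict[str, tuple[float, float, float]]

    def observed_patches(self) -> np.ndarray:
        """Mean RGB of each rendered chart patch."""
        return np.array([
            self.image[box].reshape(-1, 3).mean(axis=0)
            for box in self.chart_boxes
        ])


def _face_layout(shape: tuple[int, int]) -> np.ndarray:
    """Label image of the seven atomic sectors on an H x W canvas."""
    h, w = shape
    labels = np.zeros(shape, dtype=np.uint8)
    r = lambda a, b: slice(int(a * h), int(b * h))
    c = lambda a, b: slice(int(a * w), int(b * w))
    labels[r(.06, .22), c(.12, .47)] = 1      # FhL
    labels[r(.06, .22), c(.53, .88)] = 2      # FhR
    labels[r(.40, .53), c(.10, .38)] = 3      # ChLU
    labels[r(.53, .66), c(.10, .38)] = 4      # ChLD
    labels[r(.40, .53), c(.62, .90)] = 5      # ChRU
    labels[r(.53, .66), c(.62, .90)] = 6      # ChRD
    labels[r(.40, .66), c(.42, .58)] = 7      # Nose
    return labels


def generate_face_image(
    spec: FaceSpec | None = None, seed: int = 0
) -> FaceImage:
    """Render the face fixture: Gaussian-perturbed sector colors, a
    chart strip of known patches, and the optional distortion applied
    to the whole frame (chart included)."""
    spec = spec or FaceSpec()
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    labels = _face_layout(spec.shape)
    ycrcb = np.empty((h, w, 3))
    ycrcb[...] = (200.0, 128.0, 128.0)        # neutral background
    atomic = {"FhL": 1, "FhR": 2, "ChLU": 3, "ChLD": 4,
              "ChRU": 5, "ChRD": 6, "Nose": 7}
    for name, lab in atomic.items():
        mask = labels == lab
        mean = np.asarray(spec.sector_means[name], dtype=float)
        vals = mean + spec.sector_sd * rng.standard_normal(
            (int(mask.sum()), 3))
        ycrcb[mask] = vals
    rgb = ycrcb_to_rgb(np.clip(ycrcb, 0.0, 255.0))

    # Chart strip along the bottom.
    n_patches = len(CHART_REFERENCE)
    strip = slice(int(0.88 * h), int(0.97 * h))
    boxes = []
    for i, color in enumerate(CHART_REFERENCE):
        cols = slice(
            int(i * w / n_patches) + 1, int((i + 1) * w / n_patches) - 1
        )
        rgb[strip, cols] = color
        boxes.append((strip, cols))

    if spec.distortion is not None:
        offset = (np.zeros(3) if spec.distortion_offset is None
                  else np.asarray(spec.distortion_offset, dtype=float))
        rgb = rgb.reshape(-1, 3) @ np.asarray(
            spec.distortion, dtype=float).T + offset
        rgb = rgb.reshape(h, w, 3)
    image = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return FaceImage(
        image=image,
        sectors=SectorSet.from_label_image(labels),
        chart_boxes=boxes,
        reference_patches=CHART_REFERENCE.copy(),
        true_means=dict(spec.sector_means),
    )


# --------------------------------------------------------------------
# Voice
# --------------------------------------------------------------------

@dataclass(frozen=True)
class VowelSpec:
    """Source-filter vowel: jittered/shimmered glottal impulse train
    through two-pole resonators at the formant frequencies."""

    f0: float = 200.0            # Hz
    jitter_pct: float = 0.0      # expected cycle-to-cycle jitter, %
    shimmer_pct: float = 0.0     # expected cycle-to-cycle shimmer, %
    formants: tuple[float, ...] = (730.0, 1200.0, 2600.0)
    bandwidths: tuple[float, ...] = (90.0, 110.0, 160.0)
    duration: float = 1.0        # s
    fs: int = 44100

    def __post_init__(self) -> None:
        if self.fs <= 2 * max(self.formants):
            raise ValueError("fs must exceed twice the highest formant")
        if self.duration <= 0 or self.f0 <= 0:
            raise ValueError("duration and f0 must be positive")


def _sinc_impulse(n: int, center: float, width: int = 64) -> np.ndarray:
    """Windowed-sinc unit impulse at a fractional sample position, so
    cycle marks are not quantized to the sample grid."""
    out = np.zeros(n)
    i0 = int(np.floor(center))
    idx = np.arange(max(i0 - width, 0), min(i0 + width, n))
    x = idx - center
    out[idx] = np.sinc(x) * np.hanning(2 * width + 1)[
        (idx - (i0 - width)).clip(0, 2 * width)
    ]
    return out


def generate_vowel_audio(
    spec: VowelSpec | None = None, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Synthesize a vowel; returns (float samples, fs).

    Cycle onsets follow T_k = T0 (1 + d_k) with d_k uniform on
    +-1.5 x jitter_pct/100 (so the expected measured jitter equals
    jitter_pct); cycle amplitudes analogously for shimmer.
    """
    spec = spec or VowelSpec()
    rng = np.random.default_rng(seed)
    n = int(spec.duration * spec.fs)
    t0 = spec.fs / spec.f0
    a_j = 1.5 * spec.jitter_pct / 100.0
    a_s = 1.5 * spec.shimmer_pct / 100.0
    source = np.zeros(n)
    pos = t0  # leave room for the first full cycle
    while pos < n - t0:
        amp = 1.0 + (rng.uniform(-a_s, a_s) if a_s > 0 else 0.0)
        source += amp * _sinc_impulse(n, pos)
        pos += t0 * (1.0 + (rng.uniform(-a_j, a_j) if a_j > 0 else 0.0))
    x = source
    for f, bw in zip(spec.formants, spec.bandwidths):
        r = np.exp(-np.pi * bw / spec.fs)
        theta = 2 * np.pi * f / spec.fs
        x = sps.lfilter([1.0], [1.0, -2 * r * np.cos(theta), r * r], x)
    x = 0.5 * x / np.max(np.abs(x))
    return x, spec.fs


def generate_sentence_audio(
    f0_contour: np.ndarray,
    duration: float = 3.0,
    fs: int = 44100,
    n_harmonics: int = 8,
) -> tuple[np.ndarray, int]:
    """Voiced 'sentence': a harmonic-rich tone whose instantaneous F0
    follows ``f0_contour`` (resampled to the signal length), so the
    frame-wise F0 distribution is controlled exactly."""
    n = int(duration * fs)
    contour = np.interp(
        np.linspace(0, 1, n),
        np.linspace(0, 1, len(f0_contour)),
        np.asarray(f0_contour, dtype=float),
    )
    phase = 2 * np.pi * np.cumsum(contour) / fs
    x = sum(np.sin(h * phase) / h for h in range(1, n_harmonics + 1))
    x = 0.5 * x / np.max(np.abs(x))
    return x, fs


def write_png(path, image: np.ndarray) -> None:
    """Write an image (grayscale or RGB uint8) as PNG."""
    from PIL import Image

    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_png(path) -> np.ndarray:
    """Read a PNG back as a uint8 array (label masks included)."""
    from PIL import Image

    return np.asarray(Image.open(path))


def write_wav(path, samples: np.ndarray, fs: int) -> None:
    """Write mono 16-bit PCM."""
    scaled = np.clip(samples, -1.0, 1.0)
    wavfile.write(path, fs, (scaled * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read mono 16-bit PCM back to float in [-1, 1]."""
    fs, data = wavfile.read(path)
    return data.astype(float) / 32768.0, int(fs)


# --------------------------------------------------------------------
# Skin
# --------------------------------------------------------------------

def generate_suction_series(
    immediate: tuple[float, ...] = (1.2, 1.05, 0.9),
    creep: tuple[float, ...] = (0.6, 0.55, 0.5),
    hold_s: float = 2.0,
    tau: float = 0.5,
    fs: float = 50.0,
):
    """Idealized suction cycles: elevation jumps to the immediate
    elastic value at onset and creeps exponentially toward
    immediate + creep over the hold."""
    from .skin import SuctionCycleSeries

    t = np.arange(int(hold_s * fs)) / fs
    cycles = []
    for e, c in zip(immediate, creep):
        # saturating exponential; scaled so the hold-end rise equals c
        rise = (1 - np.exp(-t / tau)) / (1 - np.exp(-hold_s / tau))
        cycles.append((t, e + c * rise))
    return SuctionCycleSeries(cycles)


def generate_wrinkle_image(
    shape: tuple[int, int] = (256, 256),
    n_lines: int = 12,
    line_width: int = 3,
    depth: float = 120.0,
    background: float = 180.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Skin close-up fixture: dark lines on a bright background.

    Returns (image, ground-truth line mask)."""
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, background)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_lines):
        x0, y0 = rng.uniform(0, w), rng.uniform(0, h)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.5, 1.0) * min(h, w)
        xs = x0 + np.cos(angle) * np.linspace(-length / 2, length / 2, 4 * int(length))
        ys = y0 + np.sin(angle) * np.linspace(-length / 2, length / 2, 4 * int(length))
        for x, y in zip(xs, ys):
            xi, yi = int(round(x)), int(round(y))
            half = line_width // 2
            lo_y, hi_y = max(yi - half, 0), min(yi + half + 1, h)
            lo_x, hi_x = max(xi - half, 0), min(xi + half + 1, w)
            if lo_y < hi_y and lo_x < hi_x:
                mask[lo_y:hi_y, lo_x:hi_x] = True
    img[mask] = background - depth
    return img, mask
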