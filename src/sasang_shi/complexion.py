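"""Facial complexion features in the YCrCb color space.

The face is partitioned into ten sectors -- left, right and whole
forehead (FhL, FhR, FhW), the four cheek quadrants with per-side wholes
(ChLU, ChLD, ChLW, ChRU, ChRD, ChRW) and the nose -- and for every
sector the mean and standard deviation of the Y (brightness), Cr (red)
and Cb (blue) channels are computed, giving 60 variables per face.
Images are color-corrected against a standard chart before extraction so
the statistics are robust to lighting.

Conventions fixed here: YCrCb is the full-range 8-bit BT.601 transform,
standard deviations use the population divisor ``n``, and color
correction is a per-channel affine map on RGB fitted by least squares
over the chart patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SECTORS = (
    "FhL", "FhR", "FhW",
    "ChLU", "ChLD", "ChLW",
    "ChRU", "ChRD", "ChRW",
    "Nose",
)
CHANNELS = ("Y", "Cr", "Cb")
STATS = ("avg", "std")

#: The 60 complexion variable names, FhL_Y_avg ... Nose_Cb_std.
COMPLEXION_VARIABLES = tuple(
    f"{sector}_{channel}_{stat}"
    for sector in SECTORS for channel in CHANNELS for stat in STATS
)

# Whole sectors and the parts they must contain.
_WHOLE_PARTS = {
    "FhW": ("FhL", "FhR"),
    "ChLW": ("ChLU", "ChLD"),
    "ChRW": ("ChRU", "ChRD"),
}

# Full-range BT.601: rows produce (Y, Cr, Cb) from (R, G, B).
_RGB_TO_YCRCB = np.array(
    [
        [0.299, 0.587, 0.114],
        [0.5, -0.418688, -0.081312],
        [-0.168736, -0.331264, 0.5],
    ]
)
_YCRCB_OFFSET = np.array([0.0, 128.0, 128.0])


class DegenerateChartError(ValueError):
    """The chart patches do not span color space (e.g. collinear)."""


@dataclass
class SectorSet:
    """Boolean pixel masks for the ten facial sectors.

    Whole sectors must contain the union of their parts and every mask
    must be non-empty.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in SECTORS if s not in self.masks]
        if missing:
            raise ValueError(f"missing sector masks: {missing}")
        for name, mask in self.masks.items():
            if not np.any(mask):
                raise ValueError(f"sector mask {name!r} is empty")
        for whole, parts in _WHOLE_PARTS.items():
            union = np.zeros_like(self.masks[whole], dtype=bool)
            for part in parts:
                union |= self.masks[part]
            if np.any(union & ~self.masks[whole]):
                raise ValueError(
                    f"sector {whole!r} must contain the union of {parts}"
                )

    @classmethod
    def from_label_image(cls, labels: np.ndarray) -> "SectorSet":
        """Build sectors from a label image of the seven atomic regions.

        Label ids: 1 FhL, 2 FhR, 3 ChLU, 4 ChLD, 5 ChRU, 6 ChRD, 7 Nose;
        0 is background.  Whole sectors are the unions of their parts,
        which satisfies the containment invariants by construction.
        """
        atomic = {
            "FhL": 1, "FhR": 2, "ChLU": 3, "ChLD": 4,
            "ChRU": 5, "ChRD": 6, "Nose": 7,
        }
        masks = {name: labels == lab for name, lab in atomic.items()}
        for whole, parts in _WHOLE_PARTS.items():
            masks[whole] = np.logical_or.reduce([masks[p] for p in parts])
        return cls(masks)


def rgb_to_ycrcb(rgb: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB values to full-range BT.601 (Y, Cr, Cb).

    Accepts any array whose last axis has length 3.  Output is float,
    with neutral chroma at 128.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("last axis must hold (R, G, B)")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB values must lie in [0, 255]")
    return arr @ _RGB_TO_YCRCB.T + _YCRCB_OFFSET


def ycrcb_to_rgb(ycrcb: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_ycrcb`; output clipped to [0, 255]."""
    arr = np.asarray(ycrcb, dtype=float) - _YCRCB_OFFSET
    rgb = arr @ np.linalg.inv(_RGB_TO_YCRCB).T
    return np.clip(rgb, 0.0, 255.0)


def fit_color_correction(
    observed: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Least-squares affine RGB map taking observed chart patches to the
    reference patches.

    Returns the 4x3 affine matrix (rows: R, G, B, offset) and the RMS
    patch residual after correction.
    """
    obs = np.asarray(observed, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.shape != ref.shape or obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observed/reference must be matching (n, 3) arrays")
    if obs.shape[0] < 4:
        raise DegenerateChartError("need at least 4 chart patches")
    design = np.column_stack([obs, np.ones(len(obs))])
    if np.linalg.matrix_rank(design, tol=1e-6 * np.abs(design).max()) < 4:
        raise DegenerateChartError(
            "chart patches are degenerate (affinely dependent)"
        )
    coef, *_ = np.linalg.lstsq(design, ref, rcond=None)
    residual = design @ coef - ref
    rms = float(np.sqrt(np.mean(residual**2)))
    return coef, rms


def apply_color_correction(image: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Apply an affine RGB correction to an image; output clipped."""
    arr = np.asarray(image, dtype=float)
    flat = arr.reshape(-1, 3)
    out = np.column_stack([flat, np.ones(len(flat))]) @ coef
    return np.clip(out, 0.0, 255.0).reshape(arr.shape)


def correct_color(
    image: np.ndarray,
    observed_chart_patches: np.ndarray,
    reference_chart_patches: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Color-correct ``image`` using a standard chart.

    The affine 3-channel map minimizing the summed squared patch error is
    fitted from the observed patch colors and applied to the image.
    Returns the corrected image (float RGB) and the RMS patch residual.
    """
    coef, rms = fit_color_correction(
        observed_chart_patches, reference_chart_patches
    )
    return apply_color_correction(image, coef), rms


def extract_complexion(
    image: np.ndarray, sectors: SectorSet
) -> dict[str, float]:
    """Extract the 60 complexion variables from a corrected RGB image.

    Per sector and YCrCb channel, the mean and population standard
    deviation over the mask pixels are returned under the
    ``Sector_Channel_stat`` names.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("image must be (H, W, 3)")
    ycrcb = rgb_to_ycrcb(arr)
    record: dict[str, float] = {}
    for sector in SECTORS:
        mask = sectors.masks[sector]
        if mask.shape != arr.shape[:2]:
            raise ValueError(f"mask {sector!r} does not match image shape")
        if not np.any(mask):
            raise ValueError(f"sector mask {sector!r} is empty")
        pix = ycrcb[mask]
        for ci, channel in enumerate(CHANNELS):
            record[f"{sector}_{channel}_avg"] = float(pix[:, ci].mean())
            record[f"{sector}_{channel}_std"] = float(pix[:, ci].std())
    return record
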