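"""Skin viscoelasticity and wrinkle-density features.

A suction device applies repeated fixed-pressure cycles to the skin and
records the elevation of the dome of skin over time.  Per cycle the
elevation jumps immediately (elastic response) and then creeps upward
during the hold (viscous response).  Features:

* ``E``      -- immediate elastic elevation of the first cycle (mm),
* ``E_hys``  -- elastic hysteresis, first-cycle minus third-cycle
  immediate elevation (may be negative),
* ``V_E``    -- viscoelasticity ratio, first-cycle creep over ``E``.

Wrinkle density is the fraction of pixels belonging to wrinkle lines in
a close-up image of the back of the hand (or the arm site), obtained
with a multi-scale second-derivative line filter followed by an Otsu
threshold on the filter response.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import filters


@dataclass
class SuctionCycleSeries:
    """Elevation-versus-time curves for consecutive suction cycles.

    Each cycle's curve spans the constant-pressure hold phase, starting
    at suction onset, in mm.
    """

    cycles: list[tuple[np.ndarray, np.ndarray]]  # (time_s, elevation_mm)

    def __post_init__(self) -> None:
        if len(self.cycles) < 3:
            raise ValueError("need at least 3 suction cycles")
        for t, e in self.cycles:
            if np.any(np.asarray(e) < 0):
                raise ValueError("elevations must be non-negative")


def viscoelastic_features(series: SuctionCycleSeries) -> dict[str, float]:
    """E, E_hys and V_E from a suction-cycle series.

    The first sample of each hold-phase curve is the immediate elastic
    elevation; the rise from there to the end of the hold is creep.
    ``V_E`` is NaN when the first cycle shows no elastic response.
    """
    imm, creep = [], []
    for t, e in series.cycles:
        e = np.asarray(e, dtype=float)
        imm.append(float(e[0]))
        creep.append(float(e[-1] - e[0]))
    e1 = imm[0]
    return {
        "E": e1,
        "E_hys": imm[0] - imm[2],
        "V_E": creep[0] / e1 if e1 > 0 else math.nan,
    }


def wrinkle_area(image: np.ndarray, sigmas=(1.0, 2.0)) -> float:
    """Wrinkle pixel-area fraction of a close-up skin image.

    Dark line structures are enhanced with a multi-scale ridge (second
    derivative) filter; the response is thresholded by Otsu's rule and
    the fraction of above-threshold pixels returned.  A blank image
    yields 0 with a low-contrast warning.  Brightness is normalized
    away, so the measure is invariant to global intensity shifts.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    span = arr.max() - arr.min()
    if span < 1e-6:
        warnings.warn("low-contrast image, no wrinkles detectable")
        return 0.0
    norm = (arr - arr.min()) / span
    response = filters.sato(norm, sigmas=sigmas, black_ridges=True)
    if response.max() <= 0:
        warnings.warn("low-contrast image, no wrinkles detectable")
        return 0.0
    thresh = filters.threshold_otsu(response)
    return float(np.mean(response > thresh))
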