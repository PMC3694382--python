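"""Published study constants for the Sasang Health Index (SHI) cohort.

The SHI study population was 298 Korean women aged 50-75, typed into the
three common Sasang constitutions: Tae-Eum (TE), So-Eum (SE) and So-Yang
(SY).  The constants below (group sizes, demographics, health-category
proportions, VAS score distributions, model accuracy) parameterize the
synthetic-cohort generator and serve as oracles for the evaluation
statistics.  The published regression models themselves are bundled as
JSON (see :func:`sasang_shi.model.load_published_models`).
"""

from __future__ import annotations

CONSTITUTIONS = ("TE", "SE", "SY")

COMPONENTS = ("face", "pulse", "skin", "voice", "questionnaire")

#: Subjects per constitution in the study cohort.
GROUP_SIZES = {"TE": 100, "SE": 72, "SY": 126}

#: Age in years, mean and SD per constitution.
AGE_MEAN_SD = {"TE": (57.4, 5.5), "SE": (56.7, 4.9), "SY": (55.2, 4.4)}

#: Body-mass index in kg/m^2, mean and SD per constitution.
BMI_MEAN_SD = {"TE": (26.8, 2.6), "SE": (21.4, 2.0), "SY": (23.2, 1.8)}

#: Health-category counts (healthy, subhealthy, diseased) per constitution.
CATEGORY_COUNTS = {
    "TE": (28, 38, 34),
    "SE": (29, 24, 19),
    "SY": (58, 45, 23),
}

#: Rater-averaged VAS score, mean and SD per constitution.
VAS_MEAN_SD = {"TE": (61.2, 23.2), "SE": (67.6, 23.7), "SY": (74.3, 19.9)}

#: Intraclass correlation between the two raters' VAS scores.
RATER_ICC = 0.95

#: Ten-fold cross-validated R-squared of the integrative model per
#: constitution (plain and adjusted).
INTEGRATIVE_R2 = {"TE": 0.58, "SE": 0.65, "SY": 0.38}
INTEGRATIVE_ADJ_R2 = {"TE": 0.51, "SE": 0.56, "SY": 0.30}

#: VAS category intervals: healthy is 80 or above, diseased below 40.
HEALTHY_THRESHOLD = 80.0
DISEASED_THRESHOLD = 40.0
CATEGORY_INTERVALS = {
    "healthy": (80.0, 100.0),
    "subhealthy": (40.0, 80.0),
    "diseased": (0.0, 40.0),
}
CATEGORIES = ("healthy", "subhealthy", "diseased")


def category_probs(constitution: str) -> tuple[float, float, float]:
    """Health-category probabilities implied by the published counts."""
    counts = CATEGORY_COUNTS[constitution]
    n = sum(counts)
    return tuple(c / n for c in counts)


def categorize_vas(vas: float) -> str:
    """Map a VAS score to its health category.

    80 and above is healthy, 40 (inclusive) to 80 subhealthy, below 40
    diseased.
    """
    if vas >= HEALTHY_THRESHOLD:
        return "healthy"
    if vas >= DISEASED_THRESHOLD:
        return "subhealthy"
    return "diseased"
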