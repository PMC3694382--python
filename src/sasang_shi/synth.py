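"""Synthetic cohorts with the statistical structure the analysis assumes.

The study cohort (298 women, constitutions TE/SE/SY of sizes
100/72/126) is not public, so this module generates feature-level
stand-ins:

* a health category per subject (healthy / subhealthy / diseased) drawn
  from the published per-constitution proportions;
* a true VAS score inside the category's interval ([80, 100], [40, 80),
  [0, 40)), by default from a truncated normal calibrated so the
  constitution's VAS mean and SD reproduce the published values
  (``vas_within_category="uniform"`` samples uniformly instead);
* two rater scores = true VAS plus independent Gaussian noise (default
  SD 5.2 points, the value implied by the published inter-rater ICC of
  0.95 and the cohort VAS variance), clipped to [0, 100];
* age and BMI from the published per-constitution normals;
* per-component feature tables generated by inverting the published
  component models: a standard-normal feature vector is shifted along
  the coefficient direction so that the published model evaluated on
  the (z-scale) features returns the centered true VAS plus a
  component-level noise term.  The noise SD is calibrated per
  constitution so the best linear read-out of the informative
  components attains the published integrative R^2 (0.58 TE, 0.65 SE,
  0.38 SY); ``feature_noise_sd`` overrides it (0 gives exact linear
  reconstruction).

Component residuals are drawn independently across components (no
joint covariance is published); one counter-based substream per subject
makes subject k independent of cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import published
from .complexion import COMPLEXION_VARIABLES
from .model import load_published_models
from .pulse import PULSE_FEATURES
from .questionnaire import (
    PHYSICAL_FACTORS,
    PSYCHOSOCIAL_FACTORS,
    QUESTIONNAIRE_VARIABLES,
    SELF_ESTIMATION,
    default_item_metadata,
)
from .voice import VOICE_VARIABLES

#: Column names of each component's feature table.
COMPONENT_VARIABLES = {
    "face": COMPLEXION_VARIABLES,
    "pulse": tuple(f"{arm}_{v}" for arm in ("L", "R")
                   for v in PULSE_FEATURES),
    "skin": ("E", "E_hys", "V_E", "Wrinkle_hand", "Wrinkle_arm_L"),
    "voice": VOICE_VARIABLES,
    "questionnaire": QUESTIONNAIRE_VARIABLES,
}

#: Default rater noise SD (VAS points), from the published ICC of 0.95
#: and the cohort VAS variance (~516): sd = sqrt(516 * 0.05 / 0.95).
DEFAULT_RATER_NOISE_SD = 5.2

_CATEGORY_BOUNDS = (
    published.CATEGORY_INTERVALS["healthy"],
    published.CATEGORY_INTERVALS["subhealthy"],
    published.CATEGORY_INTERVALS["diseased"],
)


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters; defaults are the published study
    conditions."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(published.GROUP_SIZES))
    category_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            c: published.category_probs(c) for c in published.CONSTITUTIONS
        })
    vas_within_category: str = "table7"     # or "uniform"
    rater_noise_sd: float = DEFAULT_RATER_NOISE_SD
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(published.AGE_MEAN_SD))
    bmi_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(published.BMI_MEAN_SD))
    component_r2: dict[str, float] = field(
        default_factory=lambda: dict(published.INTEGRATIVE_R2))
    feature_noise_sd: float | None = None   # overrides the calibration
    seed: int = 0

    def __post_init__(self) -> None:
        for const, probs in self.category_probs.items():
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ConfigError(f"invalid category probs for {const}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(
                    f"category probs for {const} must sum to 1"
                )
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be >= 0")
        if self.rater_noise_sd < 0:
            raise ConfigError("rater noise SD must be >= 0")
        if self.feature_noise_sd is not None and self.feature_noise_sd < 0:
            raise ConfigError("feature noise SD must be >= 0")
        if self.vas_within_category not in ("table7", "uniform"):
            raise ConfigError(
                "vas_within_category must be 'table7' or 'uniform'"
            )

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class Subject:
    """One synthetic participant."""

    id: str
    constitution: str
    age: float
    bmi: float
    vas_true: float
    vas_rater1: float
    vas_rater2: float
    category: str
    features: dict[str, dict[str, float]]

    @property
    def vas_mean(self) -> float:
        return (self.vas_rater1 + self.vas_rater2) / 2.0


def _mixture_moments(mu: float, sd: float,
                     probs: tuple[float, float, float]
                     ) -> tuple[float, float]:
    """Mean and SD of the category-weighted truncated-normal mixture."""
    mean = 0.0
    second = 0.0
    for p, (lo, hi) in zip(probs, _CATEGORY_BOUNDS):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sd, moments="mv")
        mean += p * m
        second += p * (v + m * m)
    return mean, math.sqrt(max(second - mean * mean, 0.0))


def _solve_vas_parent(constitution: str,
                      probs: tuple[float, float, float]
                      ) -> tuple[float, float]:
    """Parent-normal (mu, sd) whose truncated mixture reproduces the
    published VAS mean and SD for this constitution."""
    target_m, target_s = published.VAS_MEAN_SD[constitution]

    def equations(theta):
        mu, log_sd = theta
        m, s = _mixture_moments(mu, math.exp(log_sd), probs)
        return [m - target_m, s - target_s]

    sol = optimize.root(
        equations, x0=[target_m, math.log(target_s)], method="hybr"
    )
    if not sol.success:  # pragma: no cover - published targets converge
        raise RuntimeError(
            f"VAS calibration failed for {constitution}: {sol.message}"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


_PARENT_CACHE: dict[tuple, tuple[float, float]] = {}


def _vas_parent(constitution: str,
                probs: tuple[float, float, float]) -> tuple[float, float]:
    key = (constitution, tuple(np.round(probs, 12)))
    if key not in _PARENT_CACHE:
        _PARENT_CACHE[key] = _solve_vas_parent(constitution, probs)
    return _PARENT_CACHE[key]


def _draw_vas(rng: np.random.Generator, config: SyntheticConfig,
              constitution: str, category_idx: int) -> float:
    lo, hi = _CATEGORY_BOUNDS[category_idx]
    if config.vas_within_category == "uniform":
        return float(rng.uniform(lo, hi))
    mu, sd = _vas_parent(
        constitution, tuple(config.category_probs[constitution])
    )
    a, b = (lo - mu) / sd, (hi - mu) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b))
    return float(mu + sd * stats.norm.ppf(u))


def informative_components(constitution: str) -> list[str]:
    """Components whose published model selected at least one feature."""
    comps, _ = load_published_models()
    return [
        comp for comp in published.COMPONENTS
        if comps[(constitution, comp)].coefficients
    ]


def component_noise_sd(config: SyntheticConfig, constitution: str) -> float:
    """Per-component score noise SD (VAS points).

    Calibrated so the best linear read-out of the m informative
    component scores attains the configured integrative R^2:
    tau^2 = m * sigma_d^2 * (1 - R^2) / R^2 with sigma_d the published
    VAS SD of the constitution.
    """
    if config.feature_noise_sd is not None:
        return config.feature_noise_sd
    r2 = config.component_r2[constitution]
    m = len(informative_components(constitution))
    sigma_d = published.VAS_MEAN_SD[constitution][1]
    return math.sqrt(m * sigma_d**2 * (1.0 - r2) / r2)


def _generate_features(
    rng: np.random.Generator,
    constitution: str,
    centered_vas: float,
    tau: float,
    models,
) -> dict[str, dict[str, float]]:
    """Inverse-model feature generation for one subject.

    Features are on the z-scale the published models expect.  For each
    component with coefficient vector a, a standard-normal draw x0 is
    shifted along a so that a . x = centered_vas + noise.
    """
    features = {}
    for comp, variables in COMPONENT_VARIABLES.items():
        x = rng.standard_normal(len(variables))
        model = models[(constitution, comp)]
        if model.coefficients:
            a = np.array([
                model.coefficients.get(v, 0.0) for v in variables
            ])
            eps = rng.normal(0.0, tau) if tau > 0 else 0.0
            target = centered_vas + eps
            x = x + a * (target - a @ x) / (a @ a)
        features[comp] = dict(zip(variables, x))
    return features


def generate_cohort(config: SyntheticConfig | None = None) -> list[Subject]:
    """Generate a full synthetic cohort.

    Deterministic given the config seed; each subject draws from its
    own counter-based substream, so subject k of a constitution is
    unchanged when group sizes change.
    """
    config = config or SyntheticConfig()
    models, _ = load_published_models()
    subjects: list[Subject] = []
    for ci, const in enumerate(published.CONSTITUTIONS):
        n = config.group_sizes.get(const, 0)
        probs = np.asarray(config.category_probs[const], dtype=float)
        tau = component_noise_sd(config, const)
        age_m, age_s = config.age_mean_sd[const]
        bmi_m, bmi_s = config.bmi_mean_sd[const]
        center = published.VAS_MEAN_SD[const][0]
        for k in range(n):
            rng = np.random.default_rng((config.seed, ci, k))
            cat = int(rng.choice(3, p=probs))
            vas = _draw_vas(rng, config, const, cat)
            noise = rng.normal(0.0, config.rater_noise_sd, size=2)
            r1, r2 = np.clip(vas + noise, 0.0, 100.0)
            age = float(np.clip(rng.normal(age_m, age_s), 50.0, 75.0))
            bmi = float(np.clip(rng.normal(bmi_m, bmi_s), 15.0, 45.0))
            features = _generate_features(
                rng, const, vas - center, tau, models
            )
            subjects.append(Subject(
                id=f"{const}{k + 1:03d}",
                constitution=const,
                age=age,
                bmi=bmi,
                vas_true=float(vas),
                vas_rater1=float(r1),
                vas_rater2=float(r2),
                category=published.CATEGORIES[cat],
                features=features,
            ))
    return subjects


def cohort_frames(subjects: list[Subject]) -> dict[str, pd.DataFrame]:
    """Cohort as tables: a subjects table plus one feature table per
    component, indexed by subject id."""
    ids = [s.id for s in subjects]
    frames = {
        "subjects": pd.DataFrame(
            {
                "constitution": [s.constitution for s in subjects],
                "age": [s.age for s in subjects],
                "bmi": [s.bmi for s in subjects],
                "vas_rater1": [s.vas_rater1 for s in subjects],
                "vas_rater2": [s.vas_rater2 for s in subjects],
                "vas_mean": [s.vas_mean for s in subjects],
            },
            index=pd.Index(ids, name="id"),
        )
    }
    for comp, variables in COMPONENT_VARIABLES.items():
        frames[comp] = pd.DataFrame(
            [[s.features[comp][v] for v in variables] for s in subjects],
            index=pd.Index(ids, name="id"),
            columns=list(variables),
        )
    return frames


def write_cohort_csvs(subjects: list[Subject], outdir) -> None:
    """One CSV per table under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in cohort_frames(subjects).items():
        frame.to_csv(out / f"{name}.csv")


def generate_questionnaire_responses(
    n_subjects: int,
    seed: int = 0,
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Item-level ordinal responses with the published factor structure.

    Each factor is a latent standard normal; its items load equally so
    the block's expected Cronbach's alpha matches the published value
    (inter-item correlation r = alpha / (k - (k-1) alpha)).  Items with
    no factor are pure noise.  Latents are discretized onto the item's
    ordinal scale; reverse-coded items are flipped.  Returns
    (responses, metadata).
    """
    meta = metadata if metadata is not None else default_item_metadata()
    rng = np.random.default_rng(seed)
    alphas = {
        name: a for name, k, a in PHYSICAL_FACTORS + PSYCHOSOCIAL_FACTORS
    }
    alphas[SELF_ESTIMATION] = 0.85
    factor_latents = {
        label: rng.standard_normal(n_subjects)
        for label in list(alphas)
    }
    data = {}
    for _, row in meta.iterrows():
        label = row["factor"]
        if label and label in factor_latents:
            k = int((meta["factor"] == label).sum())
            a = alphas.get(label)
            if a is None or k < 2:
                r = 1.0  # single-item factor: the item is the latent
            else:
                r = a / (k - (k - 1) * a)
            latent = (
                math.sqrt(r) * factor_latents[label]
                + math.sqrt(1 - r) * rng.standard_normal(n_subjects)
            )
        else:
            latent = rng.standard_normal(n_subjects)
        lo, hi = int(row["scale_min"]), int(row["scale_max"])
        edges = stats.norm.ppf(np.linspace(0, 1, hi - lo + 2)[1:-1])
        vals = lo + np.searchsorted(edges, latent)
        if bool(row["reverse"]):
            vals = lo + hi - vals
        data[row["item"]] = vals
    responses = pd.DataFrame(
        data, index=[f"S{i + 1:04d}" for i in range(n_subjects)]
    )
    return responses, meta
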