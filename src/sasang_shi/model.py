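"""Two-stage LASSO health-index model.

Stage one fits, per constitution and diagnostic component, a sparse
linear model of the rater-averaged VAS score on the component's
z-scored features:

    SHI_comp = a0 + sum_j a_j * z_j

Candidate features are prefiltered by a two-sample Student's t-test
(healthy, VAS >= 80, versus unhealthy) at P < 0.2; the LASSO penalty is
chosen by 10-fold cross-validation at minimum mean squared error (a
one-standard-error rule is available).  Stage two fits the same LASSO
over the z-scored component scores plus age and BMI:

    SHI_sum = b0 + sum_i b_i * z(SHI_comp_i) + b_age*age + b_bmi*bmi

Coefficients are reported on the VAS scale per z-unit (features are
standardized, the response is not).  The published models ship with the
package; their age/BMI coefficients were never published, so the
bundled integrative models cannot evaluate SHI_sum absolutely --
scoring supports component-only evaluation or user-supplied age/BMI
coefficients.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

from .published import categorize_vas

logger = logging.getLogger(__name__)

_PUBLISHED_SHA256 = (
    "00fc65cbc5a783f74fb5554da1bd7f05ef257e5fe38e76c001c38bbfaf5fa88e"
)

PREFILTER_P = 0.2
N_FOLDS = 10
DEFAULT_CV_SEED = 20120301  # documented default fold seed


@dataclass
class ComponentModel:
    """Sparse linear model of VAS from one component's features."""

    constitution: str
    component: str
    intercept: float
    coefficients: dict[str, float]          # VAS points per z-unit
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_sds: dict[str, float] = field(default_factory=dict)
    published: bool = False

    def score(self, features: pd.DataFrame | dict) -> np.ndarray | float:
        """Evaluate SHI_comp.

        With stored training statistics the raw features are z-scored
        first; published models carry none, so their input must already
        be z-scored.  Unknown model variables raise, naming them.
        """
        scalar = isinstance(features, dict)
        frame = pd.DataFrame([features]) if scalar else features
        missing = [v for v in self.coefficients if v not in frame.columns]
        if missing:
            raise KeyError(
                f"features missing model variables: {missing}"
            )
        total = np.full(len(frame), self.intercept, dtype=float)
        for var, coef in self.coefficients.items():
            x = frame[var].to_numpy(dtype=float)
            if var in self.feature_means:
                x = (x - self.feature_means[var]) / self.feature_sds[var]
            total = total + coef * x
        return float(total[0]) if scalar else total


@dataclass
class IntegrativeModel:
    """Stage-two model over z-scored component scores, age and BMI."""

    constitution: str
    intercept: float
    coefficients: dict[str, float]          # per component
    beta_age: float | None = None
    beta_bmi: float | None = None
    score_means: dict[str, float] = field(default_factory=dict)
    score_sds: dict[str, float] = field(default_factory=dict)
    published: bool = False

    @property
    def age_bmi_available(self) -> bool:
        return self.beta_age is not None and self.beta_bmi is not None

    def score(
        self,
        component_scores: pd.DataFrame,
        age: np.ndarray | None = None,
        bmi: np.ndarray | None = None,
    ) -> np.ndarray:
        """Evaluate SHI_sum; raises if age/BMI terms are unavailable
        but required (published models), unless both arrays are omitted
        for a component-only evaluation."""
        total = np.full(len(component_scores), self.intercept, dtype=float)
        for comp, coef in self.coefficients.items():
            if comp not in component_scores.columns:
                raise KeyError(f"missing component score: {comp}")
            z = component_scores[comp].to_numpy(dtype=float)
            if comp in self.score_means:
                z = (z - self.score_means[comp]) / self.score_sds[comp]
            total = total + coef * z
        if age is not None or bmi is not None:
            if not self.age_bmi_available:
                raise ValueError(
                    "age/BMI coefficients are not available for this "
                    "model (unpublished); evaluate components only or "
                    "supply beta_age/beta_bmi"
                )
            total = total + self.beta_age * np.asarray(age, dtype=float)
            total = total + self.beta_bmi * np.asarray(bmi, dtype=float)
        return total


@dataclass
class FitReport:
    """Cross-validation accounting for one LASSO fit."""

    n: int
    selected: list[str]
    alpha: float
    alpha_grid: tuple[float, float]         # (max, min) of the path
    fold_r2: np.ndarray
    cv_r2: float                            # pooled out-of-fold R^2
    train_r2: float
    cv_adj_r2: float
    train_adj_r2: float
    fold_assignment: np.ndarray
    oof_prediction: np.ndarray | None = None


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1), p = retained predictors."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def prefilter_features(
    features: pd.DataFrame, healthy: np.ndarray, p_threshold: float = PREFILTER_P
) -> list[str]:
    """Columns whose two-sample Student's t-test P falls below 0.2.

    ``healthy`` is the boolean label (rater-averaged VAS >= 80).  Both
    groups must have at least two subjects.
    """
    healthy = np.asarray(healthy, dtype=bool)
    if healthy.sum() < 2 or (~healthy).sum() < 2:
        raise ValueError("each health group needs at least 2 subjects")
    keep = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        a, b = x[healthy], x[~healthy]
        if np.var(a) == 0 and np.var(b) == 0:
            continue  # identical groups: P = 1
        _, p = stats.ttest_ind(a, b, equal_var=True)
        if p < p_threshold:
            keep.append(col)
    return keep


class ZScorer:
    """Column-wise z-transform with stored training statistics.

    Uses the sample SD (divisor n-1); zero-variance columns are
    excluded with a warning.
    """

    def __init__(self) -> None:
        self.means: dict[str, float] = {}
        self.sds: dict[str, float] = {}
        self.columns: list[str] = []

    def fit(self, features: pd.DataFrame) -> "ZScorer":
        self.means, self.sds, self.columns = {}, {}, []
        for col in features.columns:
            x = features[col].to_numpy(dtype=float)
            sd = float(np.std(x, ddof=1))
            if sd == 0 or not np.isfinite(sd):
                warnings.warn(f"dropping zero-variance column {col!r}")
                continue
            self.means[col] = float(x.mean())
            self.sds[col] = sd
            self.columns.append(col)
        return self

    def apply(self, features: pd.DataFrame) -> pd.DataFrame:
        out = {
            col: (features[col].to_numpy(dtype=float) - self.means[col])
            / self.sds[col]
            for col in self.columns
        }
        return pd.DataFrame(out, index=features.index)

    def fit_apply(self, features: pd.DataFrame) -> pd.DataFrame:
        return self.fit(features).apply(features)


def _lasso_path_grid(X: np.ndarray, y: np.ndarray, n_alphas: int = 60,
                     eps: float = 1e-3) -> np.ndarray:
    n = len(y)
    alpha_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    alpha_max = max(alpha_max, 1e-12)
    return np.geomspace(alpha_max, alpha_max * eps, n_alphas)


def fit_lasso_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = DEFAULT_CV_SEED,
    rule: str = "min",
    n_folds: int = N_FOLDS,
    refit_ols: bool = False,
) -> tuple[float, dict[str, float], FitReport]:
    """LASSO over a geometric penalty grid with K-fold CV selection.

    ``rule`` is "min" (minimum mean CV squared error, the default) or
    "1se" (largest penalty within one standard error of the minimum).
    With ``refit_ols`` the LASSO only selects the support and the
    reported coefficients come from an unpenalized least-squares refit
    on it (relaxed LASSO; this is what permits the standard errors the
    integrative stage reports).  Returns (intercept, nonzero
    coefficients, fit report).
    """
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    alphas = _lasso_path_grid(Xa, ya)
    kf = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    folds = list(kf.split(Xa))
    cv_err = np.zeros((len(alphas), len(folds)))
    for j, (tr, te) in enumerate(folds):
        # Whole regularization path per fold; centering stands in for
        # the intercept.
        xm, ym = Xa[tr].mean(axis=0), ya[tr].mean()
        _, coefs, _ = lasso_path(
            Xa[tr] - xm, ya[tr] - ym, alphas=alphas, max_iter=50_000
        )
        pred = (Xa[te] - xm) @ coefs + ym          # (n_te, n_alphas)
        cv_err[:, j] = np.mean(
            (pred - ya[te][:, None]) ** 2, axis=0
        )
    mean_err = cv_err.mean(axis=1)
    i_min = int(np.argmin(mean_err))
    if rule == "1se":
        se = cv_err.std(axis=1, ddof=1) / np.sqrt(len(folds))
        within = np.where(mean_err <= mean_err[i_min] + se[i_min])[0]
        i_sel = int(within[0])  # grid is descending in alpha
    elif rule == "min":
        i_sel = i_min
    else:
        raise ValueError("rule must be 'min' or '1se'")
    alpha = float(alphas[i_sel])

    final = Lasso(alpha=alpha, max_iter=100_000)
    final.fit(Xa, ya)
    intercept = float(final.intercept_)
    coefs = {
        col: float(c)
        for col, c in zip(X.columns, final.coef_)
        if c != 0.0
    }
    train_pred = final.predict(Xa)
    if refit_ols and coefs:
        support = [i for i, c in enumerate(final.coef_) if c != 0.0]
        intercept, beta = ols_fit(Xa[:, support], ya)
        coefs = {
            X.columns[i]: float(b) for i, b in zip(support, beta)
        }
        train_pred = intercept + Xa[:, support] @ beta
    # Pooled out-of-fold predictions at the selected penalty.
    oof = np.empty(n)
    assignment = np.empty(n, dtype=int)
    for j, (tr, te) in enumerate(folds):
        m = Lasso(alpha=alpha, max_iter=50_000)
        m.fit(Xa[tr], ya[tr])
        if refit_ols and np.any(m.coef_ != 0.0):
            sup = np.flatnonzero(m.coef_)
            b0, b = ols_fit(Xa[tr][:, sup], ya[tr])
            oof[te] = b0 + Xa[te][:, sup] @ b
        else:
            oof[te] = m.predict(Xa[te])
        assignment[te] = j
    ss_tot = np.sum((ya - ya.mean()) ** 2)
    cv_r2 = 1.0 - np.sum((ya - oof) ** 2) / ss_tot
    train_r2 = 1.0 - np.sum((ya - train_pred) ** 2) / ss_tot
    fold_r2 = np.array([
        1.0 - np.sum((ya[te] - oof[te]) ** 2)
        / max(np.sum((ya[te] - ya[te].mean()) ** 2), 1e-12)
        for _, te in folds
    ])
    p = len(coefs)
    report = FitReport(
        n=n,
        selected=list(coefs),
        alpha=alpha,
        alpha_grid=(float(alphas[0]), float(alphas[-1])),
        fold_r2=fold_r2,
        cv_r2=float(cv_r2),
        train_r2=float(train_r2),
        cv_adj_r2=adjusted_r2(float(cv_r2), n, p),
        train_adj_r2=adjusted_r2(float(train_r2), n, p),
        fold_assignment=assignment,
        oof_prediction=oof,
    )
    return intercept, coefs, report


def ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Ordinary least squares (the zero-penalty limit of the LASSO)."""
    Xa = np.asarray(X, dtype=float)
    design = np.column_stack([np.ones(len(Xa)), Xa])
    beta, *_ = np.linalg.lstsq(design, np.asarray(y, dtype=float),
                               rcond=None)
    return float(beta[0]), beta[1:]


def fit_component_model(
    features: pd.DataFrame,
    vas_mean: np.ndarray,
    constitution: str,
    component: str,
    seed: int = DEFAULT_CV_SEED,
    rule: str = "min",
) -> tuple[ComponentModel, FitReport]:
    """Stage one: prefilter, z-score, LASSO-fit one component."""
    n = len(features)
    if n < 20:
        raise ValueError(f"need at least 20 subjects, got {n}")
    vas = np.asarray(vas_mean, dtype=float)
    candidates = prefilter_features(features, vas >= 80.0)
    if not candidates:
        logger.info(
            "%s/%s: no candidate features survived the prefilter",
            constitution, component,
        )
        model = ComponentModel(
            constitution, component, float(vas.mean()), {},
        )
        report = FitReport(
            n=n, selected=[], alpha=float("inf"),
            alpha_grid=(float("inf"), float("inf")),
            fold_r2=np.zeros(0), cv_r2=0.0, train_r2=0.0,
            cv_adj_r2=0.0, train_adj_r2=0.0,
            fold_assignment=np.zeros(n, dtype=int),
            oof_prediction=np.full(n, float(vas.mean())),
        )
        return model, report
    scaler = ZScorer()
    Z = scaler.fit_apply(features[candidates])
    intercept, coefs, report = fit_lasso_cv(Z, vas, seed=seed, rule=rule)
    model = ComponentModel(
        constitution=constitution,
        component=component,
        intercept=intercept,
        coefficients=coefs,
        feature_means={v: scaler.means[v] for v in coefs},
        feature_sds={v: scaler.sds[v] for v in coefs},
    )
    return model, report


def fit_integrative_model(
    component_scores: pd.DataFrame,
    age: np.ndarray,
    bmi: np.ndarray,
    vas_mean: np.ndarray,
    constitution: str,
    seed: int = DEFAULT_CV_SEED,
    rule: str = "min",
) -> tuple[IntegrativeModel, FitReport]:
    """Stage two: LASSO over z-scored component scores, age and BMI.

    Component columns with no variance (e.g. a stage-one model that
    selected nothing) are dropped with a log message.
    """
    scores = component_scores.copy()
    for col in list(scores.columns):
        if float(np.std(scores[col].to_numpy(dtype=float), ddof=1)) == 0:
            logger.info(
                "%s: dropping constant component score %r",
                constitution, col,
            )
            scores = scores.drop(columns=col)
    scaler = ZScorer()
    Z = scaler.fit_apply(scores)
    design = Z.copy()
    design["age"] = np.asarray(age, dtype=float)
    design["bmi"] = np.asarray(bmi, dtype=float)
    intercept, coefs, report = fit_lasso_cv(
        design, vas_mean, seed=seed, rule=rule, refit_ols=True
    )
    model = IntegrativeModel(
        constitution=constitution,
        intercept=intercept,
        coefficients={k: v for k, v in coefs.items()
                      if k not in ("age", "bmi")},
        beta_age=coefs.get("age", 0.0),
        beta_bmi=coefs.get("bmi", 0.0),
        score_means=dict(scaler.means),
        score_sds=dict(scaler.sds),
    )
    return model, report


def score_subject(
    component_models: dict[str, ComponentModel],
    features: dict[str, dict[str, float]],
    integrative: IntegrativeModel | None = None,
    age: float | None = None,
    bmi: float | None = None,
) -> dict:
    """Evaluate all component scores for one subject and, when an
    integrative model with age/BMI terms is supplied, SHI_sum and the
    health category."""
    comp_scores = {
        comp: model.score(features[comp])
        for comp, model in component_models.items()
    }
    out = {"components": comp_scores, "SHI_sum": None, "category": None}
    if integrative is not None and integrative.age_bmi_available:
        frame = pd.DataFrame([comp_scores])
        shi = float(integrative.score(
            frame,
            age=np.array([age], dtype=float),
            bmi=np.array([bmi], dtype=float),
        )[0])
        out["SHI_sum"] = shi
        out["category"] = categorize_vas(shi)
    return out


def fit_two_stage(
    frames: dict[str, pd.DataFrame],
    constitution: str,
    seed: int = DEFAULT_CV_SEED,
    rule: str = "min",
) -> dict:
    """Fit the full pipeline for one constitution from cohort tables.

    ``frames`` is the output of :func:`sasang_shi.synth.cohort_frames`
    (a subjects table plus one feature table per component).  Returns
    the component models/reports, the component scores and the
    integrative model/report.

    The integrative stage is fitted on the *out-of-fold* component
    scores (stacked generalization): each subject's component score is
    the prediction of the stage-one model trained without that
    subject's fold.  Fitting stage two on in-sample component scores
    would let stage-one overfitting leak into the stage-two
    cross-validation and overstate the pipeline's accuracy.
    """
    subjects = frames["subjects"]
    mask = subjects["constitution"] == constitution
    vas = subjects.loc[mask, "vas_mean"].to_numpy(dtype=float)
    comp_models, comp_reports, scores, oof_scores = {}, {}, {}, {}
    for comp in ("face", "pulse", "skin", "voice", "questionnaire"):
        feats = frames[comp].loc[mask.to_numpy()]
        m, rep = fit_component_model(
            feats, vas, constitution, comp, seed=seed, rule=rule
        )
        comp_models[comp] = m
        comp_reports[comp] = rep
        scores[comp] = np.asarray(m.score(feats), dtype=float)
        oof_scores[comp] = rep.oof_prediction
    idx = frames["face"].index[mask.to_numpy()]
    score_frame = pd.DataFrame(scores, index=idx)
    oof_frame = pd.DataFrame(oof_scores, index=idx)
    integ, integ_report = fit_integrative_model(
        oof_frame,
        subjects.loc[mask, "age"].to_numpy(dtype=float),
        subjects.loc[mask, "bmi"].to_numpy(dtype=float),
        vas,
        constitution,
        seed=seed,
        rule=rule,
    )
    return {
        "component_models": comp_models,
        "component_reports": comp_reports,
        "component_scores": score_frame,
        "oof_component_scores": oof_frame,
        "integrative_model": integ,
        "integrative_report": integ_report,
    }


def load_published_models() -> tuple[
    dict[tuple[str, str], ComponentModel], dict[str, IntegrativeModel]
]:
    """The bundled published models, keyed (constitution, component)
    and constitution.

    The JSON payload is checksum-verified.  Published component models
    carry no training normalization statistics (their inputs must be
    z-scored), and the integrative models' age/BMI coefficients are
    unavailable (never published), so they cannot evaluate SHI_sum
    absolutely.
    """
    raw = (
        resources.files("sasang_shi") / "data" / "published_models.json"
    ).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _PUBLISHED_SHA256:
        raise ValueError(
            "bundled model file failed its checksum: " + digest
        )
    payload = json.loads(raw)
    comps = {}
    for entry in payload["component_models"]:
        m = ComponentModel(
            constitution=entry["constitution"],
            component=entry["component"],
            intercept=float(entry["intercept"]),
            coefficients={k: float(v)
                          for k, v in entry["coefficients"].items()},
            published=True,
        )
        comps[(m.constitution, m.component)] = m
    integ = {}
    for entry in payload["integrative_models"]:
        m = IntegrativeModel(
            constitution=entry["constitution"],
            intercept=float(entry["intercept"]),
            coefficients={k: float(v)
                          for k, v in entry["coefficients"].items()},
            beta_age=entry["beta_age"],
            beta_bmi=entry["beta_bmi"],
            published=True,
        )
        integ[m.constitution] = m
    return comps, integ
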