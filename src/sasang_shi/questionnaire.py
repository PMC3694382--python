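"""Health-questionnaire scoring: factor analysis and reliability.

The 87-item instrument covers physical conditions/activities (52
items), psychosocial conditions/activities (33 items) and two
self-estimates of overall health.  Exploratory factor analysis
(principal-component extraction with promax rotation, power 4) reduces
the item pool to 11 physical and 5 psychosocial factors; items are
assigned to the factor carrying their largest absolute pattern loading
when it reaches 0.3 and dropped otherwise.  Cronbach's alpha screens
each factor's internal consistency (undefined for the single-item
"Unhealthy period" factor).  Factor scores are unit-weighted means of
the assigned items after reverse-coding, z-scored across subjects; the
two self-estimate items form the "Self-estimation of health state"
variable.

The concrete item texts are not part of this package: items are
abstract ordinal columns described by a metadata table (domain, scale,
reverse flag, factor label).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Published factor structure: (label, n_items, Cronbach's alpha).
PHYSICAL_FACTORS = (
    ("Physical discomfort", 9, 0.772),
    ("Exercise capability", 2, 0.752),
    ("Defecation", 3, 0.734),
    ("Perspiration", 3, 0.743),
    ("Digestion", 2, 0.600),
    ("Discomfort after eating, defecation, and urination", 3, 0.509),
    ("Sleep habits", 6, 0.779),
    ("Exercise habits", 2, 0.799),
    ("Body warming habits", 2, 0.673),
    ("Eating habits", 2, 0.727),
    ("Unhealthy period", 1, None),
)
PSYCHOSOCIAL_FACTORS = (
    ("Sociability", 14, 0.846),
    ("Emotional stability", 7, 0.819),
    ("Extroversion and broad-mindedness", 3, 0.691),
    ("Introspection and preparation", 4, 0.772),
    ("Addiction", 2, 0.843),
)
FACTOR_LABELS = tuple(
    name for name, _, _ in PHYSICAL_FACTORS + PSYCHOSOCIAL_FACTORS
)
SELF_ESTIMATION = "Self-estimation of health state"
#: The 17 questionnaire variables entering the health-index models.
QUESTIONNAIRE_VARIABLES = FACTOR_LABELS + (SELF_ESTIMATION,)

N_PHYSICAL_ITEMS = 52
N_PSYCHOSOCIAL_ITEMS = 33
N_SELF_ITEMS = 2
LOADING_THRESHOLD = 0.3
PROMAX_POWER = 4


def default_item_metadata(scale_max: int = 5) -> pd.DataFrame:
    """Metadata for the 87 abstract items.

    Factor-assigned items come first within each domain, the remaining
    items (dropped during the published factor screening) carry an
    empty factor label.  Every fourth assigned item is reverse-coded so
    the coding path is exercised.
    """
    rows = []

    def add_domain(domain, factors, total):
        start = len(rows)
        for label, n_items, _ in factors:
            for _ in range(n_items):
                rows.append({"domain": domain, "factor": label})
        while len(rows) - start < total:
            rows.append({"domain": domain, "factor": ""})

    add_domain("physical", PHYSICAL_FACTORS, N_PHYSICAL_ITEMS)
    add_domain("psychosocial", PSYCHOSOCIAL_FACTORS, N_PSYCHOSOCIAL_ITEMS)
    for _ in range(N_SELF_ITEMS):
        rows.append({"domain": "self", "factor": SELF_ESTIMATION})
    meta = pd.DataFrame(rows)
    meta.insert(0, "item", [f"Q{i + 1:03d}" for i in range(len(meta))])
    meta["scale_min"] = 1
    meta["scale_max"] = scale_max
    assigned = meta["factor"] != ""
    meta["reverse"] = assigned & (np.arange(len(meta)) % 4 == 3)
    return meta


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha of an item block (columns = items).

    alpha = k/(k-1) * (1 - sum of item variances / total-score
    variance), sample variances.  Raises on fewer than two items or a
    degenerate total score.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 items")
    return cronbach_alpha_from_cov(np.cov(X, rowvar=False, ddof=1))


def cronbach_alpha_from_cov(cov: np.ndarray) -> float:
    """Cronbach's alpha from an item covariance matrix."""
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    total_var = S.sum()
    if total_var <= 0:
        raise ValueError("zero total-score variance, alpha undefined")
    return float(k / (k - 1) * (1.0 - np.trace(S) / total_var))


def varimax(loadings: np.ndarray, tol: float = 1e-8,
            max_iter: int = 500) -> np.ndarray:
    """Orthogonal varimax rotation with Kaiser row normalization."""
    L = np.asarray(loadings, dtype=float)
    p, m = L.shape
    if m < 2:
        return L.copy()
    comm = np.sqrt((L**2).sum(axis=1))
    comm[comm == 0] = 1.0
    X = L / comm[:, None]
    R = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        A = X @ R
        B = A**3 - A @ np.diag((A**2).sum(axis=0)) / p
        U, s, Vt = np.linalg.svd(X.T @ B)
        R = U @ Vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return (X @ R) * comm[:, None]


def promax(loadings: np.ndarray, power: int = PROMAX_POWER
           ) -> tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation (Hendrickson-White).

    A varimax solution is raised element-wise to ``power`` (signs kept)
    as an ideal simple-structure target, and the varimax loadings are
    regressed onto it.  Returns the pattern matrix and the factor
    correlation matrix.
    """
    V = varimax(loadings)
    if V.shape[1] < 2:
        return V.copy(), np.eye(V.shape[1])
    target = V * np.abs(V) ** (power - 1)
    coef = np.linalg.lstsq(V, target, rcond=None)[0]
    d = np.sqrt(np.diag(np.linalg.inv(coef.T @ coef)))
    coef = coef * d
    pattern = V @ coef
    inv = np.linalg.inv(coef)
    phi = inv @ inv.T
    return pattern, phi


@dataclass
class FactorSolution:
    """An exploratory factor solution over one item domain."""

    loadings: pd.DataFrame            # items x factors pattern matrix
    factor_correlations: np.ndarray
    variance_explained: np.ndarray    # per extracted component
    assignment: dict[str, int]        # item -> factor column
    dropped: list[str] = field(default_factory=list)
    alphas: dict[int, float] = field(default_factory=dict)


def run_efa(responses: pd.DataFrame, n_factors: int) -> FactorSolution:
    """Principal-component extraction with promax rotation.

    Items are assigned to the factor with the largest absolute pattern
    loading when it reaches 0.3, otherwise dropped; Cronbach's alpha is
    reported per assigned block (NaN for single-item blocks).
    """
    X = responses.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        warnings.warn(
            f"only {n} subjects for {p} items; factor solution may be "
            "unstable"
        )
    corr = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise np.linalg.LinAlgError(
            "singular correlation matrix (constant item?)"
        )
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() <= 1e-10:
        raise np.linalg.LinAlgError("correlation matrix is singular")
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    L = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    pattern, phi = promax(L)
    items = list(responses.columns)
    loadings = pd.DataFrame(pattern, index=items)
    assignment, dropped = {}, []
    for item in items:
        row = loadings.loc[item].to_numpy()
        j = int(np.argmax(np.abs(row)))
        if abs(row[j]) >= LOADING_THRESHOLD:
            assignment[item] = j
        else:
            dropped.append(item)
    alphas = {}
    for j in sorted(set(assignment.values())):
        block = [it for it, jj in assignment.items() if jj == j]
        alphas[j] = (
            cronbach_alpha(responses[block]) if len(block) > 1 else math.nan
        )
    return FactorSolution(
        loadings=loadings,
        factor_correlations=phi,
        variance_explained=eigval[:n_factors] / p,
        assignment=assignment,
        dropped=dropped,
        alphas=alphas,
    )


def reverse_code(responses: pd.DataFrame, metadata: pd.DataFrame
                 ) -> pd.DataFrame:
    """Flip reverse-coded items back onto the common direction."""
    out = responses.copy().astype(float)
    meta = metadata.set_index("item")
    for item in out.columns:
        if bool(meta.loc[item, "reverse"]):
            lo = float(meta.loc[item, "scale_min"])
            hi = float(meta.loc[item, "scale_max"])
            out[item] = lo + hi - out[item]
    return out


def factor_scores(responses: pd.DataFrame, metadata: pd.DataFrame
                  ) -> pd.DataFrame:
    """Per-subject scores for the 16 factors plus self-estimation.

    Score = mean of the factor's items after reverse-coding, z-scored
    across subjects (sample SD).  Subjects missing all items of a
    factor get NaN.
    """
    coded = reverse_code(responses, metadata)
    meta = metadata.set_index("item")
    out = {}
    for label in QUESTIONNAIRE_VARIABLES:
        items = [
            it for it in coded.columns
            if it in meta.index and meta.loc[it, "factor"] == label
        ]
        if not items:
            out[label] = np.full(len(coded), np.nan)
            continue
        raw = coded[items].mean(axis=1, skipna=True)
        sd = raw.std(ddof=1)
        out[label] = (raw - raw.mean()) / sd if sd > 0 else raw * 0.0
    return pd.DataFrame(out, index=responses.index)
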