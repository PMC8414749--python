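"""Condition-effect statistics for the assistance study design.

Peak corrected elevation per analysed trial is modelled with a
random-intercept linear mixed model

    peak_theta ~ support * direction + (1 | participant) + error

where ``support`` has levels None / Therapist / Orthosis and
``direction`` flexion / abduction. The model is fitted by restricted
maximum likelihood, profiling the single variance ratio
``lambda = sigma_b^2 / sigma_e^2`` via 1-D optimisation. Post-hoc Wald
contrasts {Therapist - None, Orthosis - None} x {flexion, abduction}
form the Holm-corrected family; confidence intervals are normal-quantile
(+/- 1.96 SE) by default with a t-quantile option.

The module also provides the study's normalized effect measures:
improvement relative to baseline ability, orthosis improvement relative
to the therapist's, trunk compensation normalized by arm elevation, and
the Borg perceived-exertion mean difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

SUPPORT_LEVELS = ("none", "therapist", "orthosis")
DIRECTION_LEVELS = ("abduction", "flexion")  # reference level first

#: fixed-effect design columns, treatment coding with none/abduction reference
DESIGN_COLUMNS = (
    "intercept",
    "therapist",
    "orthosis",
    "flexion",
    "therapist:flexion",
    "orthosis:flexion",
)


@dataclass
class EffectEstimate:
    """One condition contrast: mean, CI95 and raw/Holm-adjusted p."""

    contrast: str
    direction: str
    mean: float
    se: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_holm: float = float("nan")

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError("CI must bracket the mean")
        if np.isfinite(self.p_holm) and self.p_holm < self.p_raw:
            raise ValueError("Holm-adjusted p cannot undercut the raw p")


@dataclass
class LMMFit:
    """Random-intercept LMM fit (REML) for the support x direction design."""

    beta: pd.Series  # fixed effects, indexed by DESIGN_COLUMNS
    cov_beta: pd.DataFrame
    sigma_e2: float  # residual variance
    sigma_b2: float  # between-participant intercept variance
    lam: float  # sigma_b2 / sigma_e2
    n_obs: int
    n_params: int
    reml_criterion: float
    single_group_fallback: bool = False


def build_design(df: pd.DataFrame, support_col: str = "support", direction_col: str = "direction") -> np.ndarray:
    """Treatment-coded support*direction design matrix (reference none/abduction)."""
    sup = df[support_col].astype(str).str.lower()
    dirn = df[direction_col].astype(str).str.lower()
    bad = set(sup) - set(SUPPORT_LEVELS)
    if bad:
        raise ValueError(f"unknown support levels {bad}")
    bad = set(dirn) - set(DIRECTION_LEVELS)
    if bad:
        raise ValueError(f"unknown direction levels {bad}")
    ther = (sup == "therapist").to_numpy(float)
    orth = (sup == "orthosis").to_numpy(float)
    flex = (dirn == "flexion").to_numpy(float)
    X = np.column_stack(
        [np.ones(len(df)), ther, orth, flex, ther * flex, orth * flex]
    )
    return X


def reml_criterion(y: np.ndarray, X: np.ndarray, groups: np.ndarray, lam: float) -> float:
    """-2 x (profiled restricted log-likelihood), up to an additive constant.

    For the random-intercept model, each participant's covariance is
    ``sigma_e^2 (I + lam J)``; the residual variance is profiled out, so
    the criterion depends on ``lam`` alone:

        f(lam) = (n - p) log(r' V^-1 r) + sum_i log|I + lam J_i|
                 + log|X' V^-1 X|
    """
    if lam < 0:
        raise ValueError("variance ratio must be non-negative")
    y = np.asarray(y, float)
    n, p = X.shape
    A = np.zeros((p, p))
    b = np.zeros(p)
    logdet_v = 0.0
    codes, _ = pd.factorize(groups)
    for gi in np.unique(codes):
        idx = codes == gi
        Xi, yi = X[idx], y[idx]
        ni = int(idx.sum())
        c = lam / (1.0 + lam * ni)
        # V_i^-1 = I - c * J
        A += Xi.T @ Xi - c * np.outer(Xi.sum(0), Xi.sum(0))
        b += Xi.T @ yi - c * Xi.sum(0) * yi.sum()
        logdet_v += np.log1p(lam * ni)
    beta = np.linalg.solve(A, b)
    q = 0.0
    for gi in np.unique(codes):
        idx = codes == gi
        ri = y[idx] - X[idx] @ beta
        ni = int(idx.sum())
        c = lam / (1.0 + lam * ni)
        q += ri @ ri - c * ri.sum() ** 2
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular design in REML criterion")
    return float((n - p) * np.log(q) + logdet_v + logdet_a)


def fit_random_intercept_lmm(
    df: pd.DataFrame,
    response: str = "peak_theta",
    support_col: str = "support",
    direction_col: str = "direction",
    participant_col: str = "participant",
    max_lambda: float = 1e4,
) -> LMMFit:
    """REML fit of ``response ~ support*direction + (1 | participant)``.

    The variance ratio is profiled by bounded 1-D minimisation of the
    REML criterion; given the data the fit is deterministic. With a
    single participant the random intercept is unidentifiable and the
    fit falls back to ordinary least squares with a warning.
    """
    y = df[response].to_numpy(float)
    X = build_design(df, support_col, direction_col)
    groups = df[participant_col].to_numpy()
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough observations to estimate the fixed effects")

    if len(np.unique(groups)) < 2:
        warnings.warn(
            "single participant: random intercept unidentifiable, "
            "falling back to a fixed-effects (OLS) fit",
            stacklevel=2,
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma_e2 = float(resid @ resid / (n - p))
        cov = sigma_e2 * np.linalg.inv(X.T @ X)
        return LMMFit(
            beta=pd.Series(beta, index=DESIGN_COLUMNS),
            cov_beta=pd.DataFrame(cov, index=DESIGN_COLUMNS, columns=DESIGN_COLUMNS),
            sigma_e2=sigma_e2,
            sigma_b2=0.0,
            lam=0.0,
            n_obs=n,
            n_params=p,
            reml_criterion=float("nan"),
            single_group_fallback=True,
        )

    crit = lambda lam: reml_criterion(y, X, groups, lam)
    res = optimize.minimize_scalar(crit, bounds=(0.0, max_lambda), method="bounded")
    lam = float(res.x)
    if crit(0.0) <= res.fun:  # boundary solution: no between-participant variance
        lam = 0.0

    codes, _ = pd.factorize(groups)
    A = np.zeros((p, p))
    b = np.zeros(p)
    for gi in np.unique(codes):
        idx = codes == gi
        Xi, yi = X[idx], y[idx]
        ni = int(idx.sum())
        c = lam / (1.0 + lam * ni)
        A += Xi.T @ Xi - c * np.outer(Xi.sum(0), Xi.sum(0))
        b += Xi.T @ yi - c * Xi.sum(0) * yi.sum()
    beta = np.linalg.solve(A, b)
    q = 0.0
    for gi in np.unique(codes):
        idx = codes == gi
        ri = y[idx] - X[idx] @ beta
        ni = int(idx.sum())
        c = lam / (1.0 + lam * ni)
        q += ri @ ri - c * ri.sum() ** 2
    sigma_e2 = float(q / (n - p))
    cov = sigma_e2 * np.linalg.inv(A)
    return LMMFit(
        beta=pd.Series(beta, index=DESIGN_COLUMNS),
        cov_beta=pd.DataFrame(cov, index=DESIGN_COLUMNS, columns=DESIGN_COLUMNS),
        sigma_e2=sigma_e2,
        sigma_b2=float(lam * sigma_e2),
        lam=lam,
        n_obs=n,
        n_params=p,
        reml_criterion=float(crit(lam)),
    )


_CONTRASTS = {
    ("therapist", "abduction"): {"therapist": 1.0},
    ("therapist", "flexion"): {"therapist": 1.0, "therapist:flexion": 1.0},
    ("orthosis", "abduction"): {"orthosis": 1.0},
    ("orthosis", "flexion"): {"orthosis": 1.0, "orthosis:flexion": 1.0},
}


def wald_contrast(fit: LMMFit, coeffs: dict[str, float], use_t: bool = False) -> tuple[float, float, float]:
    """Wald estimate, SE and two-sided p for a fixed-effect combination."""
    c = pd.Series(0.0, index=DESIGN_COLUMNS)
    for name, w in coeffs.items():
        if name not in c.index:
            raise ValueError(f"non-estimable contrast: unknown coefficient {name!r}")
        c[name] = w
    est = float(c @ fit.beta)
    var = float(c @ fit.cov_beta.to_numpy() @ c)
    se = np.sqrt(var)
    if se == 0:
        return est, 0.0, 1.0
    stat = est / se
    if use_t:
        dof = fit.n_obs - fit.n_params
        p = 2 * stats.t.sf(abs(stat), dof)
    else:
        p = 2 * stats.norm.sf(abs(stat))
    return est, se, float(p)


def posthoc_contrasts(fit: LMMFit, use_t: bool = False, ci_level: float = 0.95) -> list[EffectEstimate]:
    """Support-vs-baseline contrasts within each direction, Holm-corrected.

    Family: {Therapist - None, Orthosis - None} x {flexion, abduction}.
    CI is mean +/- z * SE with the normal quantile by default
    (``use_t=True`` switches both p and CI to the t reference with
    n - p degrees of freedom).
    """
    if use_t:
        zq = stats.t.ppf(0.5 + ci_level / 2, fit.n_obs - fit.n_params)
    else:
        zq = stats.norm.ppf(0.5 + ci_level / 2)
    rows = []
    for (support, direction), coeffs in _CONTRASTS.items():
        est, se, p = wald_contrast(fit, coeffs, use_t=use_t)
        rows.append(
            EffectEstimate(
                contrast=f"{support}-none",
                direction=direction,
                mean=est,
                se=se,
                ci_low=est - zq * se,
                ci_high=est + zq * se,
                p_raw=p,
            )
        )
    adjusted = holm_adjust([r.p_raw for r in rows])
    for row, p_adj in zip(rows, adjusted):
        row.p_holm = p_adj
    return rows


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, original order preserved.

    Sort ascending, multiply the i-th smallest by (m - i), enforce
    monotonicity along the sorted order, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(np.maximum.accumulate((m - np.arange(m)) * p[order]), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# normalized effect measures


def normalize_by_baseline(theta_cond: float, theta_none: float) -> float:
    """Improvement relative to baseline ability: (cond - none) / none."""
    if theta_none <= 0:
        raise ValueError("baseline peak elevation must be positive")
    return (theta_cond - theta_none) / theta_none


def relative_effect_vs_therapist(
    orthosis_improvement: float, therapist_improvement: float
) -> Optional[float]:
    """Orthosis improvement as a fraction of the therapist's.

    Participants whose therapist improvement is not positive are
    excluded (returns None with a logged reason) rather than failing;
    the ratio may exceed 1 or be negative.
    """
    if therapist_improvement <= 0:
        logger.info(
            "excluded from relative-effect computation: non-positive therapist "
            "improvement (%.2f deg)",
            therapist_improvement,
        )
        return None
    return orthosis_improvement / therapist_improvement


def normalized_trunk_compensation(kappa_peak: float, theta_g_peak: float) -> float:
    """Trunk compensation per degree of elevation: kappa / theta_g (deg/deg)."""
    if theta_g_peak <= 0:
        raise ValueError("peak elevation must be positive to normalize by it")
    return kappa_peak / theta_g_peak


def compensation_percent_change(baseline_ratio: float, condition_ratio: float) -> float:
    """Percent reduction of normalized trunk compensation vs baseline."""
    if baseline_ratio == 0:
        raise ValueError("baseline compensation ratio is zero; change undefined")
    return (baseline_ratio - condition_ratio) / baseline_ratio * 100.0


def borg_mean_difference(
    ratings_none: Sequence[float], ratings_orthosis: Sequence[float]
) -> float:
    """Mean Borg-scale reduction: mean(none) - mean(orthosis), in points."""
    for r in list(ratings_none) + list(ratings_orthosis):
        if not 6 <= r <= 20:
            raise ValueError(f"Borg rating {r} outside the 6-20 scale")
    return float(np.mean(ratings_none) - np.mean(ratings_orthosis))
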