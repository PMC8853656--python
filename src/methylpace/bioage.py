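"""Physiology-based biological-age comparators and validation statistics.

Implements the three classical biological-age constructions used to
benchmark methylation pace measures — Klemera-Doubal biological age,
the Phenotypic Age functional form (Gompertz mortality-risk inversion), and
homeostatic dysregulation (log Mahalanobis distance from a healthy
reference) — plus age-acceleration residuals, Pearson r with Fisher-z CI,
and Cohen's d with CI. All algorithms are panel-agnostic; references are fit
to whatever training table is supplied (synthetic or user data). A named
default biomarker metadata set mirrors the classical 8-marker panel
(albumin, log alkaline phosphatase, blood urea nitrogen, log creatinine,
log CRP, HbA1c, systolic blood pressure, FEV1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateDataError,
    NumericalError,
)

#: Classical 8-biomarker panel: marker -> (log-transform flag, display name).
DEFAULT_BIOMARKER_PANEL = {
    "albumin": (False, "serum albumin"),
    "alp": (True, "alkaline phosphatase (log)"),
    "bun": (False, "blood urea nitrogen"),
    "creatinine": (True, "creatinine (log)"),
    "crp": (True, "C-reactive protein (log)"),
    "hba1c": (False, "glycated hemoglobin"),
    "sbp": (False, "systolic blood pressure"),
    "fev1": (False, "forced expiratory volume in 1 s"),
}

_MIN_RESIDUAL_SD = 1e-8


@dataclass(frozen=True)
class GompertzConstants:
    """Constants for the Phenotypic Age construction.

    ``coefficients`` weight the (transformed) markers and chronological age
    into the mortality linear predictor xb. Mortality risk over ``horizon``
    years is the Gompertz CDF 1 - exp(-exp(xb) * (exp(g*t) - 1) / g) with
    shape ``gamma_markers``; the risk is then mapped back to an age through
    the age-only Gompertz model with shape ``gamma_age`` and linear
    predictor ``age_intercept + age_slope * age``.
    """

    coefficients: dict[str, float]  # marker name (and optionally "age") -> weight
    intercept: float
    gamma_markers: float
    gamma_age: float
    age_intercept: float
    age_slope: float
    horizon: float = 10.0

    def validate(self) -> None:
        vals = [self.intercept, self.gamma_markers, self.gamma_age,
                self.age_intercept, self.age_slope, self.horizon]
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("Gompertz constants must be finite")
        if self.age_slope == 0:
            raise ConfigurationError("age_slope must be nonzero")


@dataclass
class BiomarkerReference:
    """Reference-population parameters for the comparator algorithms.

    Per marker j: OLS regression of the marker on age (intercept ``q``,
    slope ``k``, residual SD ``s``); for homeostatic dysregulation, the mean
    vector and covariance of the markers in the healthy subset; Phenotypic
    Age constants are attached when supplied.
    """

    markers: list[str]
    q: pd.Series
    k: pd.Series
    s: pd.Series
    hd_mean: pd.Series | None = None
    hd_cov: pd.DataFrame | None = None
    pheno: GompertzConstants | None = None
    meta: dict = field(default_factory=dict)


def fit_reference(
    training: pd.DataFrame,
    markers: list[str] | None = None,
    age_col: str = "age",
    healthy_rule: str = "youngest_tertile",
    pheno: GompertzConstants | None = None,
) -> BiomarkerReference:
    """Fit reference regressions and the healthy centroid from a table.

    ``training`` has one row per subject with an age column and one column
    per marker. The healthy subset for dysregulation defaults to the
    youngest age tertile ("all" uses every subject). Residual SDs are
    floored at a tiny positive value so exactly collinear synthetic inputs
    do not produce zero-precision weights.
    """
    if age_col not in training.columns:
        raise DataError(f"training table needs an {age_col!r} column")
    markers = markers or [c for c in training.columns if c != age_col]
    age = training[age_col].to_numpy(float)
    if np.var(age) == 0:
        raise DataError("training ages have zero variance")

    q, k, s = {}, {}, {}
    for mkr in markers:
        yv = training[mkr].to_numpy(float)
        slope, intercept = np.polyfit(age, yv, 1)
        resid = yv - (intercept + slope * age)
        dof = max(len(yv) - 2, 1)
        q[mkr] = float(intercept)
        k[mkr] = float(slope)
        s[mkr] = float(max(np.sqrt(resid @ resid / dof), _MIN_RESIDUAL_SD))

    if healthy_rule == "youngest_tertile":
        cutoff = np.quantile(age, 1 / 3)
        healthy = training[age <= cutoff]
    elif healthy_rule == "all":
        healthy = training
    else:
        raise ConfigurationError(f"unknown healthy_rule {healthy_rule!r}")
    hd_mean = healthy[markers].mean()
    hd_cov = healthy[markers].cov()
    cond = np.linalg.cond(hd_cov.to_numpy())
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(
            "healthy-subset covariance is numerically singular; remove "
            "collinear markers"
        )
    if pheno is not None:
        pheno.validate()
    return BiomarkerReference(
        markers=list(markers),
        q=pd.Series(q),
        k=pd.Series(k),
        s=pd.Series(s),
        hd_mean=hd_mean,
        hd_cov=hd_cov,
        pheno=pheno,
        meta={"healthy_rule": healthy_rule, "n_training": len(training)},
    )


def _marker_frame(x, markers: list[str]) -> pd.DataFrame:
    if isinstance(x, pd.Series):
        x = x.to_frame().T
    x = pd.DataFrame(x)
    missing = [m for m in markers if m not in x.columns]
    if missing:
        raise DataError(f"missing markers: {missing}")
    return x[markers]


def kdm_biological_age(
    x, ref: BiomarkerReference, age=None, s_ba: float | None = None
) -> pd.Series:
    """Klemera-Doubal biological age: precision-weighted inverse regression.

    BA = sum_j[(x_j - q_j) k_j / s_j^2] / sum_j[k_j^2 / s_j^2]. When ``age``
    and ``s_ba`` are given, the chronological age enters as an extra term
    with variance s_ba^2 (the augmented variant).
    """
    X = _marker_frame(x, ref.markers)
    k = ref.k[ref.markers].to_numpy(float)
    q = ref.q[ref.markers].to_numpy(float)
    s2 = ref.s[ref.markers].to_numpy(float) ** 2
    denom = float(np.sum(k**2 / s2))
    if denom == 0:
        raise NumericalError("all reference slopes are zero; biological age undefined")
    num = (X.to_numpy(float) - q) @ (k / s2)
    if age is not None and s_ba is not None:
        a = np.asarray(age, float)
        num = num + a / s_ba**2
        denom = denom + 1.0 / s_ba**2
    return pd.Series(num / denom, index=X.index, name="kdm_ba")


def _gompertz_risk(xb: np.ndarray, gamma: float, horizon: float) -> np.ndarray:
    return 1.0 - np.exp(-np.exp(xb) * (np.exp(gamma * horizon) - 1.0) / gamma)


def phenotypic_age_from_xb(xb, constants: GompertzConstants, eps: float = 1e-15):
    """Invert mortality risk through the age-only Gompertz model.

    Risk over the horizon is computed from the marker linear predictor xb
    via the Gompertz CDF, clamped away from {0, 1} (flagged via the
    returned mask), and mapped back to the age whose age-only model yields
    the same risk. Strictly increasing in xb.
    """
    constants.validate()
    xb = np.asarray(xb, float)
    risk = _gompertz_risk(xb, constants.gamma_markers, constants.horizon)
    clamped = (risk <= eps) | (risk >= 1 - eps)
    risk = np.clip(risk, eps, 1 - eps)
    xb_age = np.log(
        -np.log1p(-risk) * constants.gamma_age / (np.exp(constants.gamma_age * constants.horizon) - 1.0)
    )
    age = (xb_age - constants.age_intercept) / constants.age_slope
    return age, clamped


def phenotypic_age(x, ref: BiomarkerReference, age=None) -> pd.Series:
    """Phenotypic Age of each subject from markers (+ chronological age).

    The linear predictor is the configured intercept plus the weighted sum
    of markers, plus an "age" coefficient times chronological age when
    present in the coefficient set.
    """
    if ref.pheno is None:
        raise DataError("reference has no Phenotypic Age constants configured")
    c = ref.pheno
    marker_names = [m for m in c.coefficients if m != "age"]
    X = _marker_frame(x, marker_names)
    xb = c.intercept + X.to_numpy(float) @ np.array(
        [c.coefficients[m] for m in marker_names]
    )
    if "age" in c.coefficients:
        if age is None:
            raise DataError("constants include an age term; pass chronological ages")
        xb = xb + c.coefficients["age"] * np.asarray(age, float)
    years, _ = phenotypic_age_from_xb(xb, c)
    return pd.Series(years, index=X.index, name="phenotypic_age")


def homeostatic_dysregulation(x, ref: BiomarkerReference) -> pd.Series:
    """log(1 + Mahalanobis distance) from the healthy reference centroid."""
    if ref.hd_mean is None or ref.hd_cov is None:
        raise DataError("reference has no healthy centroid/covariance")
    X = _marker_frame(x, ref.markers)
    if list(X.columns) != list(ref.hd_cov.columns):
        X = X[list(ref.hd_cov.columns)]
    diff = X.to_numpy(float) - ref.hd_mean[ref.hd_cov.columns].to_numpy(float)
    cov = ref.hd_cov.to_numpy(float)
    try:
        sol = np.linalg.solve(cov, diff.T)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"covariance not invertible: {exc}") from exc
    d = np.sqrt(np.einsum("ij,ji->i", diff, sol))
    return pd.Series(np.log1p(d), index=X.index, name="homeostatic_dysregulation")


def age_acceleration(measure, age) -> pd.Series:
    """OLS residuals of a biological-age measure on chronological age."""
    m = np.asarray(measure, float)
    a = np.asarray(age, float)
    if len(m) < 3:
        raise DataError("need >= 3 subjects")
    if np.var(a) == 0:
        raise DataError("age variance is zero; residualization undefined")
    slope, intercept = np.polyfit(a, m, 1)
    resid = m - (intercept + slope * a)
    index = measure.index if isinstance(measure, pd.Series) else pd.RangeIndex(len(m))
    return pd.Series(resid, index=index, name="age_acceleration")


@dataclass
class EffectSize:
    estimate: float
    ci_low: float
    ci_high: float
    kind: str  # "cohens_d" or "pearson_r"
    n: int


def cohens_d(group1, group2, alpha: float = 0.05) -> EffectSize:
    """Cohen's d (pooled SD) with a normal-approximation CI."""
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise DataError("need >= 2 observations per group")
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise DegenerateDataError("pooled SD is zero; d undefined")
    d = (g1.mean() - g2.mean()) / np.sqrt(sp2)
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2 - 2)))
    z = stats.norm.ppf(1 - alpha / 2)
    return EffectSize(float(d), float(d - z * se), float(d + z * se), "cohens_d", n1 + n2)


def pearson_r(x, y, alpha: float = 0.05) -> EffectSize:
    """Pearson correlation with the Fisher-z confidence interval."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need >= 3 paired observations")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return EffectSize(float(res.statistic), float(ci.low), float(ci.high), "pearson_r", len(x))
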