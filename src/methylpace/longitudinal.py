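"""Pace of Aging from longitudinal biomarker panels.

The phenotype is built in three steps: (1) each biomarker is standardized
against its baseline-visit distribution and sign-oriented so that a positive
slope always means deterioration; (2) a linear mixed-effects growth model with
a random intercept and random slope per subject is fitted to every biomarker,
yielding per-subject best linear unbiased predictors (BLUPs) of the annual
rate of change; (3) the per-subject slopes are summed across biomarkers and
the composite is divided by its cohort mean, so the result reads as
"biological years per chronological year" with a cohort mean of exactly 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import DataError, DegenerateDataError, ScalingError

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ("subject_id", "visit_age", "biomarker_id", "value")

#: Pooled per-subject residual variance below which trajectories are treated
#: as exactly linear and the maximum-likelihood fit is skipped (it is singular
#: in that limit; the shrinkage weight is then 1 and BLUP = per-subject OLS).
_RESIDUAL_DEGENERACY_TOL = 1e-12


@dataclass
class LongBiomarkerPanel:
    """Tidy longitudinal biomarker observations plus per-biomarker metadata.

    ``data`` holds one row per (subject, visit age, biomarker) measurement;
    ``meta`` is indexed by ``biomarker_id`` with an ``orientation`` column
    (+1 if an increase indicates deterioration, -1 otherwise) and a display
    ``name``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise DataError(f"panel is missing columns {missing}")
        if "orientation" not in self.meta.columns:
            raise DataError("biomarker metadata is missing an 'orientation' column")

    def validate(self) -> None:
        dup = self.data.duplicated(subset=["subject_id", "visit_age", "biomarker_id"])
        if dup.any():
            raise DataError(
                f"{int(dup.sum())} duplicate (subject, visit_age, biomarker) rows"
            )
        if self.data["visit_age"].nunique() < 2:
            raise DataError("panel needs at least 2 distinct visit ages")
        bad = ~self.meta["orientation"].isin([1, -1])
        if bad.any():
            raise DataError(
                f"orientation must be +1 or -1 for: {list(self.meta.index[bad])}"
            )
        unknown = set(self.data["biomarker_id"]) - set(self.meta.index)
        if unknown:
            raise DataError(f"biomarkers without metadata: {sorted(unknown)}")

    @property
    def biomarkers(self) -> list[str]:
        return list(self.meta.index)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())


@dataclass
class GrowthModelFit:
    """Mixed-model growth fit for one biomarker.

    ``random_slopes`` holds the per-subject BLUP of the annual rate of change
    (fixed slope + random deviation), in standardized units per year.
    """

    biomarker_id: str
    fixed_intercept: float
    fixed_slope: float
    random_slopes: pd.Series
    var_intercept: float
    var_slope: float
    var_resid: float
    n_subjects: int
    method: str  # "mle" or "twostage"
    converged: bool


@dataclass
class PaceOfAgingScores:
    """Per-subject Pace of Aging, scaled so the cohort mean is 1."""

    pace: pd.Series
    raw_composite: pd.Series
    scaling_constant: float
    n_biomarkers: int
    n_imputed: int = 0
    excluded_subjects: list = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.pace.to_numpy()


def standardize_panel(panel: LongBiomarkerPanel) -> LongBiomarkerPanel:
    """Z-score each biomarker against its baseline visit and orient its sign.

    The anchor is the earliest visit age at which the biomarker is observed:
    values are centered and scaled by the baseline mean and SD, then
    multiplied by the biomarker's orientation so a positive slope means
    deterioration for every biomarker. Output metadata carries orientation +1
    throughout.
    """
    panel.validate()
    out = panel.data.copy()
    meta = panel.meta.copy()
    for bid, grp in out.groupby("biomarker_id", sort=False):
        baseline_age = grp["visit_age"].min()
        base = grp.loc[grp["visit_age"] == baseline_age, "value"]
        mu, sd = base.mean(), base.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateDataError(
                f"biomarker {bid!r} has zero variance at its baseline visit"
            )
        orient = meta.loc[bid, "orientation"]
        out.loc[grp.index, "value"] = orient * (grp["value"] - mu) / sd
    meta["orientation"] = 1
    return LongBiomarkerPanel(out, meta)


def _subject_arrays(sub: pd.DataFrame):
    ca = sub["visit_age"] - sub["visit_age"].mean()
    return sub["subject_id"].to_numpy(), ca.to_numpy(float), sub["value"].to_numpy(float)


def _per_subject_ols(subjects, ca, y):
    """Per-subject OLS intercepts/slopes on centered age.

    Returns (ids, slopes, sxx, pooled residual variance). Subjects with a
    single distinct age get a NaN slope.
    """
    ids, slopes, sxx_list = [], [], []
    rss, rdf = 0.0, 0
    order = np.argsort(subjects, kind="stable")
    subjects, ca, y = subjects[order], ca[order], y[order]
    bounds = np.flatnonzero(np.r_[True, subjects[1:] != subjects[:-1], True])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        x_i, y_i = ca[lo:hi], y[lo:hi]
        xc = x_i - x_i.mean()
        sxx = float(xc @ xc)
        ids.append(subjects[lo])
        if sxx == 0:
            slopes.append(np.nan)
            sxx_list.append(np.nan)
            continue
        b = float(xc @ y_i) / sxx
        slopes.append(b)
        sxx_list.append(sxx)
        resid = y_i - y_i.mean() - b * xc
        rss += float(resid @ resid)
        rdf += len(y_i) - 2
    sigma2 = rss / rdf if rdf > 0 else 0.0
    return np.asarray(ids), np.asarray(slopes), np.asarray(sxx_list), sigma2


def _twostage_fit(biomarker_id, subjects, ca, y, converged=True) -> GrowthModelFit:
    """Two-stage estimator: per-subject OLS, moment variance components,
    closed-form shrinkage of slopes toward the fixed (mean) slope."""
    ids, ols, sxx, sigma2 = _per_subject_ols(subjects, ca, y)
    have = np.isfinite(ols)
    if have.sum() < 2:
        raise DataError(
            f"biomarker {biomarker_id!r}: fewer than 2 subjects with >=2 visits"
        )
    mean_slope = float(ols[have].mean())
    # moment estimate: var(OLS slopes) = tau^2 + mean(sigma^2 / Sxx_i)
    tau2 = max(0.0, float(np.var(ols[have], ddof=1)) - sigma2 * float(np.mean(1.0 / sxx[have])))
    lam = np.zeros(len(ids))
    denom = tau2 + np.where(have, sigma2 / np.where(have, sxx, 1.0), np.inf)
    with np.errstate(invalid="ignore"):
        lam = np.where(denom > 0, tau2 / denom, 1.0)
    lam = np.where(have, lam, 0.0)  # single-visit subjects: fully shrunk
    blup = lam * np.where(have, ols, 0.0) + (1 - lam) * mean_slope
    # intercept: grand mean at centered age 0
    fixed_intercept = float(np.mean(y))
    return GrowthModelFit(
        biomarker_id=biomarker_id,
        fixed_intercept=fixed_intercept,
        fixed_slope=mean_slope,
        random_slopes=pd.Series(blup, index=ids, name="slope"),
        var_intercept=float("nan"),
        var_slope=tau2,
        var_resid=sigma2,
        n_subjects=len(ids),
        method="twostage",
        converged=converged,
    )


def fit_growth_model(
    panel: LongBiomarkerPanel,
    biomarker_id: str,
    method: str = "mle",
    min_subjects: int = 10,
) -> GrowthModelFit:
    """Fit ``value ~ 1 + centered_age`` with a random intercept and slope.

    The maximum-likelihood fit constrains the intercept-slope covariance of
    the random effects to zero (age is centered, which decorrelates them by
    design), so in balanced designs the slope BLUP has the closed shrinkage
    form lambda*OLS_i + (1-lambda)*fixed_slope with
    lambda = tau^2 / (tau^2 + sigma^2/Sxx). On non-convergence, or when the
    trajectories are exactly linear (zero residual variance, where the
    likelihood is singular), the two-stage moment estimator is used instead
    and flagged via ``method``/``converged``.
    """
    sub = panel.data[panel.data["biomarker_id"] == biomarker_id]
    if sub.empty:
        raise DataError(f"biomarker {biomarker_id!r} not present in panel")
    counts = sub.groupby("subject_id")["visit_age"].nunique()
    if (counts >= 2).sum() < min_subjects:
        raise DataError(
            f"biomarker {biomarker_id!r}: needs >= {min_subjects} subjects with "
            f">= 2 visits, found {(counts >= 2).sum()}"
        )
    subjects, ca, y = _subject_arrays(sub)

    if method == "twostage":
        return _twostage_fit(biomarker_id, subjects, ca, y)
    if method not in ("mle", "auto"):
        raise DataError(f"unknown growth-model method {method!r}")

    _, _, _, sigma2 = _per_subject_ols(subjects, ca, y)
    if sigma2 <= _RESIDUAL_DEGENERACY_TOL:
        return _twostage_fit(biomarker_id, subjects, ca, y)

    # Random intercept via re_formula, random slope as a variance component:
    # this encodes an independent intercept/slope structure exactly (the
    # covariance is structurally zero, not merely estimated near zero).
    frame = pd.DataFrame({"y": y, "ca": ca, "subject": subjects})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM.from_formula(
                "y ~ ca", groups="subject", re_formula="1",
                vc_formula={"slope": "0 + ca"}, data=frame,
            )
            res = model.fit(reml=False, method="powell", maxiter=500)
        converged = bool(res.converged)
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("mixed-model fit failed for %s (%s); using two-stage", biomarker_id, exc)
        return _twostage_fit(biomarker_id, subjects, ca, y, converged=False)
    if not converged:
        logger.warning("mixed-model fit did not converge for %s; using two-stage", biomarker_id)
        return _twostage_fit(biomarker_id, subjects, ca, y, converged=False)

    fixed_intercept = float(res.fe_params["Intercept"])
    fixed_slope = float(res.fe_params["ca"])
    re = res.random_effects
    ids = list(re.keys())
    blup = pd.Series(
        [fixed_slope + float(re[g]["slope[ca]"]) for g in ids], index=ids, name="slope"
    )
    return GrowthModelFit(
        biomarker_id=biomarker_id,
        fixed_intercept=fixed_intercept,
        fixed_slope=fixed_slope,
        random_slopes=blup,
        var_intercept=float(np.asarray(res.cov_re)[0, 0]),
        var_slope=float(res.vcomp[0]),
        var_resid=float(res.scale),
        n_subjects=len(ids),
        method="mle",
        converged=True,
    )


def compute_pace(
    fits: list[GrowthModelFit],
    max_missing_frac: float = 0.5,
) -> PaceOfAgingScores:
    """Composite the per-subject slopes into a mean-1 Pace of Aging.

    The raw composite is the sum over biomarkers of each subject's slope
    BLUP; slopes missing for a biomarker are imputed with that biomarker's
    cohort mean slope (counted in ``n_imputed``). Subjects missing more than
    ``max_missing_frac`` of biomarkers are excluded and flagged. The
    composite is divided by its cohort mean; a non-positive mean raises
    :class:`ScalingError` (the usual cause is mis-set orientations).
    """
    if not fits:
        raise DataError("compute_pace needs at least one growth-model fit")
    slope_mat = pd.DataFrame({f.biomarker_id: f.random_slopes for f in fits})
    n_bio = slope_mat.shape[1]
    missing = slope_mat.isna()
    n_imputed = int(missing.to_numpy().sum())
    excluded = list(slope_mat.index[missing.mean(axis=1) > max_missing_frac])
    kept = slope_mat.drop(index=excluded)
    if kept.empty:
        raise DataError("no subjects with enough biomarkers to composite")
    filled = kept.fillna(kept.mean())
    raw = filled.sum(axis=1)
    mean_raw = float(raw.mean())
    if mean_raw <= 0:
        raise ScalingError(
            f"cohort mean raw composite is {mean_raw:.4g} <= 0; check biomarker "
            "orientations"
        )
    pace = raw / mean_raw
    logger.info(
        "pace_composite n_subjects=%d n_biomarkers=%d n_imputed=%d n_excluded=%d",
        len(pace), n_bio, n_imputed, len(excluded),
    )
    return PaceOfAgingScores(
        pace=pace,
        raw_composite=raw,
        scaling_constant=mean_raw,
        n_biomarkers=n_bio,
        n_imputed=n_imputed,
        excluded_subjects=excluded,
    )


def compute_pace_from_panel(
    panel: LongBiomarkerPanel,
    method: str = "mle",
    standardize: bool = True,
) -> tuple[PaceOfAgingScores, list[GrowthModelFit]]:
    """Standardize, fit every biomarker's growth model, and composite."""
    std = standardize_panel(panel) if standardize else panel
    fits = [fit_growth_model(std, b, method=method) for b in std.biomarkers]
    return compute_pace(fits), fits
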