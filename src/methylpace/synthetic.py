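"""Synthetic cohorts, methylation matrices, replicates, and distortions.

Everything downstream of this module can be exercised without external data.
The generators emulate the study design the toolkit targets: a single-age
birth cohort re-measured at four visit ages (26, 32, 38, 45) on 19 organ-
system biomarkers whose subject-specific slopes are driven by a latent pace
factor (mean 1, SD 0.29); methylation beta matrices in which a sparse causal
probe subset carries linear signal of that latent pace on the logit scale;
technical replicate pairs with a controllable per-probe intraclass
correlation; and strictly increasing per-sample batch distortions used to
probe the rank invariance of reference-quantile scoring.

All generators are pure functions of their configuration including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError, DataError, DomainError
from .longitudinal import LongBiomarkerPanel


@dataclass(frozen=True)
class SimCohortConfig:
    """Design constants for the longitudinal cohort generator.

    ``pace_sd`` is the dispersion of the latent pace factor around its mean
    of 1. ``slope_loading_range`` scales how strongly each biomarker's slope
    loads on the latent pace, relative to that biomarker's mean slope.
    ``mean_slope_range`` is in baseline-SD units per year: the default
    0.03-0.08 makes a typical biomarker deteriorate by about one baseline SD
    over the two-decade follow-up. ``residual_sd`` is visit-level measurement
    noise, ``slope_dev_sd`` subject-by-biomarker slope heterogeneity not
    explained by the latent factor, both in baseline-SD units.
    """

    n_subjects: int = 500
    visit_ages: tuple[float, ...] = (26.0, 32.0, 38.0, 45.0)
    n_biomarkers: int = 19
    pace_sd: float = 0.29
    slope_loading_range: tuple[float, float] = (0.5, 1.5)
    mean_slope_range: tuple[float, float] = (0.03, 0.08)
    intercept_sd: float = 1.0
    slope_dev_sd: float = 0.01
    residual_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        ages = np.asarray(self.visit_ages, float)
        if len(ages) < 2 or not np.all(np.diff(ages) > 0):
            raise ConfigurationError("visit_ages must be >= 2 strictly increasing ages")
        if self.n_biomarkers < 1:
            raise ConfigurationError("n_biomarkers must be >= 1")
        if not self.pace_sd > 0:
            raise ConfigurationError("pace_sd must be > 0")
        for name in ("intercept_sd", "slope_dev_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of a simulation, for parameter-recovery tests."""

    latent_pace: pd.Series | None = None
    true_slopes: pd.DataFrame | None = None  # subjects x biomarkers
    causal_effects: pd.Series | None = None  # probe_id -> effect size
    clip_fraction: float = 0.0
    extras: dict = field(default_factory=dict)


def _latent_pace(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    z = rng.normal(0.0, sd, n)
    return 1.0 + (z - z.mean())  # mean exactly 1 by centering


def simulate_longitudinal_cohort(
    config: SimCohortConfig,
) -> tuple[LongBiomarkerPanel, SimTruth]:
    """Generate a tidy longitudinal biomarker panel with known latent pace.

    For subject i, biomarker B, visit age a:

        value = b0_iB + mu_iB * (a - mean(ages)) + eps,
        mu_iB = mean_slope_B + loading_B * (pace_i - 1) + dev_iB,

    with per-biomarker loadings proportional to the mean slope so the latent
    factor moves all biomarkers coherently. Values are emitted on the
    deterioration-positive scale (orientation +1 for every biomarker).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, nb = config.n_subjects, config.n_biomarkers
    ages = np.asarray(config.visit_ages, float)
    ca = ages - ages.mean()

    subjects = np.array([f"S{i:05d}" for i in range(1, n + 1)])
    biomarkers = np.array([f"bm{j:02d}" for j in range(1, nb + 1)])

    pace = _latent_pace(rng, n, config.pace_sd)
    mean_slope = rng.uniform(*config.mean_slope_range, nb)
    loading = mean_slope * rng.uniform(*config.slope_loading_range, nb)
    dev = rng.normal(0.0, config.slope_dev_sd, (n, nb))
    b0 = rng.normal(0.0, config.intercept_sd, (n, nb))
    slopes = mean_slope[None, :] + loading[None, :] * (pace - 1.0)[:, None] + dev

    noise = rng.normal(0.0, config.residual_sd, (n, nb, len(ages)))
    values = b0[:, :, None] + slopes[:, :, None] * ca[None, None, :] + noise

    data = pd.DataFrame(
        {
            "subject_id": np.repeat(subjects, nb * len(ages)),
            "visit_age": np.tile(ages, n * nb),
            "biomarker_id": np.tile(np.repeat(biomarkers, len(ages)), n),
            "value": values.ravel(),
        }
    )
    meta = pd.DataFrame(
        {"orientation": 1, "name": [f"biomarker {b}" for b in biomarkers]},
        index=pd.Index(biomarkers, name="biomarker_id"),
    )
    truth = SimTruth(
        latent_pace=pd.Series(pace, index=subjects, name="latent_pace"),
        true_slopes=pd.DataFrame(slopes, index=subjects, columns=biomarkers),
        extras={"mean_slope": pd.Series(mean_slope, index=biomarkers),
                "loading": pd.Series(loading, index=biomarkers)},
    )
    return LongBiomarkerPanel(data, meta), truth


def probe_ids(n_probes: int, start: int = 0) -> pd.Index:
    """Illumina-style probe identifiers cg00000000, cg00000001, ..."""
    if start + n_probes > 10**8:
        raise ConfigurationError("probe id space exhausted")
    return pd.Index([f"cg{i:08d}" for i in range(start, start + n_probes)], name="probe_id")


def simulate_methylation(
    pace,
    n_probes: int = 2000,
    n_causal: int = 50,
    effect_sd: float = 0.3,
    noise_sd: float = 0.04,
    seed: int = 0,
    architecture: SimTruth | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Beta matrix (probes x samples) with a sparse causal subset.

    Signal lives on an unbounded logit scale: causal probes are linear in the
    latent pace with effect sizes of magnitude ~``effect_sd`` and random
    sign; all probes get N(0, ``noise_sd``) measurement noise; the logistic
    squashing 1/(1+exp(-z)) maps into (0, 1), so values never touch the
    boundary.

    Passing the ``SimTruth`` of a previous call as ``architecture`` reuses
    its probe universe, per-probe baselines and causal effects, so held-out
    samples can be generated from the same generative model as a training
    matrix (only the measurement noise is redrawn, under ``seed``).
    """
    if n_causal > n_probes:
        raise ConfigurationError("n_causal must be <= n_probes")
    pace = pd.Series(pace) if not isinstance(pace, pd.Series) else pace
    vals = pace.to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise DataError("pace vector must be finite")
    rng = np.random.default_rng(seed)
    if architecture is not None:
        baseline = architecture.extras["baseline"].to_numpy(float)
        probes = architecture.extras["baseline"].index
        effects = np.zeros(len(probes))
        causal_pos = probes.get_indexer(architecture.causal_effects.index)
        effects[causal_pos] = architecture.causal_effects.to_numpy(float)
        n_probes = len(probes)
    else:
        probes = probe_ids(n_probes)
        baseline = rng.uniform(-3.0, 3.0, n_probes)
        causal_idx = rng.choice(n_probes, size=n_causal, replace=False)
        effects = np.zeros(n_probes)
        effects[causal_idx] = (
            rng.choice([-1.0, 1.0], n_causal) * rng.uniform(0.5, 1.5, n_causal) * effect_sd
        )
    z = (
        baseline[:, None]
        + effects[:, None] * (vals - 1.0)[None, :]
        + rng.normal(0.0, noise_sd, (n_probes, len(vals)))
    )
    betas = pd.DataFrame(expit(z), index=probes, columns=pace.index)
    truth = SimTruth(
        latent_pace=pace.copy(),
        causal_effects=pd.Series(effects[effects != 0.0], index=probes[effects != 0.0]),
        extras={"baseline": pd.Series(baseline, index=probes)},
    )
    return betas, truth


def simulate_replicates(
    base: pd.DataFrame,
    target_icc,
    n_reps: int = 2,
    seed: int = 0,
    max_clip_frac: float = 0.01,
) -> tuple[list[pd.DataFrame], float]:
    """Technical replicates of ``base`` with a planted per-probe ICC.

    Each replicate is the shared sample-level value plus probe-specific
    technical error whose variance solves
    sigma_b^2 / (sigma_b^2 + sigma_e^2) = target_icc, where sigma_b^2 is the
    between-sample variance of the probe in ``base``. Values are clipped to
    [0, 1]; the clip fraction is returned and the generator refuses to emit
    a replicate set where more than ``max_clip_frac`` of values clipped,
    since silent clipping corrupts the planted ICC.
    """
    if n_reps < 2:
        raise ConfigurationError("n_reps must be >= 2")
    icc = np.asarray(target_icc, float)
    if icc.ndim == 0:
        icc = np.full(base.shape[0], float(icc))
    elif isinstance(target_icc, pd.Series):
        icc = target_icc.reindex(base.index).to_numpy(float)
    if icc.shape[0] != base.shape[0]:
        raise ConfigurationError("target_icc length must match the probe count")
    if np.any(~np.isfinite(icc)) or np.any(icc <= 0) or np.any(icc > 1):
        raise DomainError("target_icc must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    arr = base.to_numpy(float)
    sigma_b = arr.std(axis=1, ddof=1)
    sigma_e = sigma_b * np.sqrt((1.0 - icc) / icc)
    reps, n_clip = [], 0
    for _ in range(n_reps):
        noisy = arr + rng.normal(0.0, 1.0, arr.shape) * sigma_e[:, None]
        clipped = np.clip(noisy, 0.0, 1.0)
        n_clip += int(np.sum(clipped != noisy))
        reps.append(pd.DataFrame(clipped, index=base.index, columns=base.columns))
    clip_frac = n_clip / (arr.size * n_reps)
    if clip_frac > max_clip_frac:
        raise DataError(
            f"{clip_frac:.2%} of replicate values clipped to [0, 1] "
            f"(limit {max_clip_frac:.2%}); lower target error variance"
        )
    return reps, clip_frac


DISTORTIONS = ("identity", "affine-compress", "logit-shift", "power")


def apply_monotone_distortion(
    m: pd.DataFrame, distortion_id: str, seed: int = 0
) -> pd.DataFrame:
    """Apply a strictly increasing per-sample transform mapping [0,1]->[0,1].

    Each sample (column) draws its own parameters, emulating per-sample batch
    shifts; within-sample rank order is preserved exactly, which is the
    property reference-quantile scoring is invariant to.
    """
    if distortion_id not in DISTORTIONS:
        raise ConfigurationError(
            f"unknown distortion {distortion_id!r}; choose from {DISTORTIONS}"
        )
    if distortion_id == "identity":
        return m.copy()
    rng = np.random.default_rng(seed)
    arr = m.to_numpy(float)
    n_samples = arr.shape[1]
    if distortion_id == "affine-compress":
        a = rng.uniform(0.0, 0.2, n_samples)
        b = rng.uniform(0.5, 1.0 - a)  # a + b <= 1 keeps the range inside [0,1]
        out = a[None, :] + b[None, :] * arr
    elif distortion_id == "logit-shift":
        delta = rng.uniform(-1.0, 1.0, n_samples)
        eps = 1e-12
        out = expit(logit(np.clip(arr, eps, 1 - eps)) + delta[None, :])
    else:  # power
        gamma = rng.uniform(0.5, 2.0, n_samples)
        out = arr ** gamma[None, :]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def synthetic_published_weights(
    n_probes: int = 173, seed: int = 20000, scale: float = 0.05
) -> pd.Series:
    """Synthetic stand-in for a published CpG weight table.

    Produces a weight vector with the published algorithm's *structure*
    (probe count and cg-style naming) but randomly drawn weights; useful for
    exercising model I/O and panel construction without the real
    supplementary table, which this package does not redistribute.
    """
    rng = np.random.default_rng(seed)
    ids = probe_ids(n_probes, start=int(rng.integers(0, 10**8 - n_probes)))
    return pd.Series(rng.normal(0.0, scale, n_probes), index=ids, name="weight")
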