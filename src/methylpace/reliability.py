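"""Test-retest reliability via one-way random-effects ICC.

Technical replicates are interchangeable aliquots, so the appropriate
intraclass correlation is the one-way random-effects, single-measurement
(absolute agreement) form: sample identity is the random effect and

    ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2),

estimated by ANOVA moments with the mean-replicate-count correction for
unbalanced designs and an F-distribution confidence interval (Searle's
one-way interval). Negative moment estimates are truncated to 0 and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import AlignmentError, ConfigurationError, DataError, DegenerateDataError

logger = logging.getLogger(__name__)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_samples: int
    n_replicates: float  # mean replicates per sample (k0 for unbalanced)
    truncated: bool = False
    ms_between: float = float("nan")
    ms_within: float = float("nan")


@dataclass
class ReplicateDesign:
    """Maps each biological sample to its replicate measurement columns."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for sample, cols in self.groups.items():
            for c in cols:
                if c in seen:
                    raise DataError(f"replicate column {c!r} assigned to two samples")
                seen.add(c)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReplicateDesign":
        if not {"sample_id", "replicate_column"} <= set(df.columns):
            raise DataError("design needs columns sample_id, replicate_column")
        return cls(
            {
                s: list(g["replicate_column"])
                for s, g in df.groupby("sample_id", sort=False)
            }
        )

    def to_matrix(self, wide: pd.DataFrame) -> np.ndarray:
        """Rearrange a (probe x column) frame row into samples x replicates
        (NaN-padded) for a single probe, or samples x replicates for a 1-D
        series of per-column values."""
        k = max(len(c) for c in self.groups.values())
        out = np.full((len(self.groups), k), np.nan)
        for i, cols in enumerate(self.groups.values()):
            out[i, : len(cols)] = wide[cols].to_numpy(float)
        return out


def estimate_icc(values, alpha: float = 0.05) -> ICCResult:
    """One-way random-effects ICC from a samples x replicates matrix.

    ``values`` is a 2-D array with one row per biological sample and one
    column per replicate; NaN marks absent replicates (unbalanced designs
    are handled with the mean-replicate-count correction
    k0 = (N - sum n_i^2 / N) / (a - 1)).
    """
    arr = np.asarray(values, float)
    if arr.ndim != 2:
        raise DataError("values must be a 2-D samples x replicates array")
    n_i = np.sum(np.isfinite(arr), axis=1)
    arr = arr[n_i >= 1]
    n_i = n_i[n_i >= 1]
    a = arr.shape[0]
    if a < 2 or np.sum(n_i >= 2) < 2:
        raise DataError("need >= 2 samples, >= 2 of them with >= 2 replicates")
    if not np.all(np.isfinite(arr[np.isfinite(arr)])):
        raise DataError("values must be finite")

    N = int(n_i.sum())
    grand = np.nansum(arr) / N
    means = np.nanmean(arr, axis=1)
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(np.nansum((arr - means[:, None]) ** 2))
    if ssb + ssw == 0:
        raise DegenerateDataError("all values identical; ICC undefined")
    k0 = (N - float(np.sum(n_i**2)) / N) / (a - 1)
    msb = ssb / (a - 1)
    msw = ssw / (N - a)

    if msw == 0:
        return ICCResult(1.0, 1.0, 1.0, a, k0, False, msb, msw)

    sigma_b = (msb - msw) / k0
    icc = sigma_b / (sigma_b + msw)
    truncated = icc < 0
    icc = max(icc, 0.0)

    fcrit_hi = f_dist.ppf(1 - alpha / 2, a - 1, N - a)
    fcrit_lo = f_dist.ppf(1 - alpha / 2, N - a, a - 1)
    F = msb / msw
    fl = F / fcrit_hi
    fu = F * fcrit_lo
    lo = max(0.0, (fl - 1) / (fl + k0 - 1))
    hi = min(1.0, (fu - 1) / (fu + k0 - 1))
    return ICCResult(float(icc), float(lo), float(hi), a, float(k0), truncated, msb, msw)


def split_by_design(matrix: pd.DataFrame, design: ReplicateDesign) -> list[pd.DataFrame]:
    """Split a wide probes x measurement-columns matrix into replicate
    matrices (probes x samples) according to a replicate design.

    Requires a balanced design (equal replicate counts); replicate r of the
    output is the r-th measurement column of every sample.
    """
    counts = {len(cols) for cols in design.groups.values()}
    if len(counts) != 1:
        raise DataError("design must be balanced (equal replicates per sample)")
    k = counts.pop()
    if k < 2:
        raise DataError("design needs >= 2 replicates per sample")
    missing = [c for cols in design.groups.values() for c in cols if c not in matrix.columns]
    if missing:
        raise AlignmentError(f"design columns absent from matrix: {missing[:5]}")
    samples = list(design.groups)
    out = []
    for r in range(k):
        cols = [design.groups[s][r] for s in samples]
        rep = matrix[cols].copy()
        rep.columns = samples
        out.append(rep)
    return out


def _stack_replicates(rep_matrices: list[pd.DataFrame]) -> np.ndarray:
    first = rep_matrices[0]
    for m in rep_matrices[1:]:
        if not m.index.equals(first.index):
            n_mismatch = len(first.index.symmetric_difference(m.index))
            raise AlignmentError(
                f"replicate matrices disagree on {n_mismatch} probes"
            )
        if not m.columns.equals(first.columns):
            raise AlignmentError("replicate matrices disagree on sample columns")
    return np.stack([m.to_numpy(float) for m in rep_matrices], axis=2)


def probe_icc_table(rep_matrices: list[pd.DataFrame], alpha: float = 0.05) -> pd.DataFrame:
    """Per-probe one-way ICC across a balanced set of replicate matrices.

    Each matrix is probes x samples; replicate r of sample s is the (s)
    column of matrix r. Returns a frame indexed by probe with columns
    ``icc``, ``icc_lo``, ``icc_hi``, ``n_samples``, ``n_replicates``,
    ``truncated``; probes with zero total variance get NaN ICC and are
    counted in the log.
    """
    if len(rep_matrices) < 2:
        raise DataError("need >= 2 replicate matrices")
    arr = _stack_replicates(rep_matrices)  # probes x samples x reps
    n_probes, a, k = arr.shape
    if a < 2:
        raise DataError("need >= 2 samples")
    N = a * k
    grand = arr.mean(axis=(1, 2))
    means = arr.mean(axis=2)  # probes x samples
    ssb = k * ((means - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((arr - means[:, :, None]) ** 2).sum(axis=(1, 2))
    msb = ssb / (a - 1)
    msw = ssw / (N - a)

    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (msb - msw) / k
        icc = sigma_b / (sigma_b + msw)
        F = msb / msw
    degenerate = (ssb + ssw) == 0
    perfect = (msw == 0) & ~degenerate
    truncated = (icc < 0) & ~degenerate
    icc = np.clip(icc, 0.0, None)
    icc[perfect] = 1.0
    icc[degenerate] = np.nan

    fcrit_hi = f_dist.ppf(1 - alpha / 2, a - 1, N - a)
    fcrit_lo = f_dist.ppf(1 - alpha / 2, N - a, a - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fl = F / fcrit_hi
        fu = F * fcrit_lo
        lo = np.clip((fl - 1) / (fl + k - 1), 0.0, 1.0)
        hi = np.clip((fu - 1) / (fu + k - 1), 0.0, 1.0)
    lo[perfect] = 1.0
    hi[perfect] = 1.0
    lo[degenerate] = np.nan
    hi[degenerate] = np.nan

    if degenerate.any():
        logger.warning("probe_icc degenerate_probes=%d", int(degenerate.sum()))
    logger.info(
        "probe_icc n_probes=%d n_samples=%d n_replicates=%d truncated=%d",
        n_probes, a, k, int(truncated.sum()),
    )
    return pd.DataFrame(
        {
            "icc": icc,
            "icc_lo": lo,
            "icc_hi": hi,
            "n_samples": a,
            "n_replicates": k,
            "truncated": truncated,
        },
        index=rep_matrices[0].index,
    )


@dataclass
class ProbeFilterResult:
    probes: pd.Index
    n_retained: int
    n_total: int


def filter_probes(table: pd.DataFrame, threshold: float = 0.4) -> ProbeFilterResult:
    """Probes whose ICC is strictly greater than ``threshold``.

    The comparison is strict (ICC > threshold, not >=); input order is
    preserved. ``table`` is the output of :func:`probe_icc_table` or any
    frame with an ``icc`` column indexed by probe.
    """
    if not (0 <= threshold < 1):
        raise ConfigurationError("threshold must lie in [0, 1)")
    if "icc" not in table.columns:
        raise DataError("reliability table needs an 'icc' column")
    keep = table.index[table["icc"] > threshold]
    logger.info(
        "filter_probes threshold=%s retained=%d total=%d",
        threshold, len(keep), len(table),
    )
    return ProbeFilterResult(probes=keep, n_retained=len(keep), n_total=len(table))
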