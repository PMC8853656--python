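"""Apply a trained CpG scoring model to new beta matrices.

Scoring is deterministic and per-sample: the target matrix is aligned to the
model's frozen probe panel, each sample is quantile-normalized against the
reference distribution (the sorted vector of panel reference means), and the
score is the intercept plus the weighted sum of normalized betas at the
algorithm probes. Because the normalization replaces values by reference
values at matching within-sample ranks, any strictly increasing per-sample
distortion of the input leaves the scores bit-identical — the property that
makes the score portable across batches and array generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .reliability import ICCResult, estimate_icc
from .trainer import ReferencePanel, TrainedModel

logger = logging.getLogger(__name__)


@dataclass
class ScoreResult:
    """Per-sample scores with missingness diagnostics.

    ``scores`` is NaN for refused samples; ``diagnostics`` has one row per
    sample with ``frac_algo_probes``, ``frac_panel_probes``, ``n_imputed``
    and a ``flag`` string ("ok" or the refusal reason).
    """

    scores: pd.Series
    diagnostics: pd.DataFrame
    model_version: str = ""

    @property
    def ok(self) -> pd.Series:
        return self.scores[self.diagnostics["flag"] == "ok"]


def align_to_panel(m: pd.DataFrame, panel: ReferencePanel) -> pd.DataFrame:
    """Subset and order a beta matrix to the panel's probe list.

    Probes absent from ``m`` appear as missing rows; extra probes are
    dropped. Column (sample) order is preserved.
    """
    aligned = m.reindex(panel.probes)
    n_absent = int(aligned.isna().all(axis=1).sum())
    if n_absent:
        logger.info("align_to_panel absent_probes=%d of %d", n_absent, len(panel))
    return aligned


def quantile_normalize_to_reference(
    m: pd.DataFrame, panel: ReferencePanel
) -> pd.DataFrame:
    """Per-sample quantile normalization onto the reference distribution.

    For each sample independently: missing values are first imputed with the
    probe's reference mean (so the rank vector is complete), then every
    value is replaced by the reference target value at its within-sample
    rank, where the target is the sorted vector of panel reference means.
    Tied values receive the mean of the tied target positions. Output values
    therefore lie within [min, max] of the reference means, and the map
    depends on the input only through within-sample ranks.
    """
    if not m.index.equals(panel.probes):
        m = align_to_panel(m, panel)
    target = np.sort(panel.reference_means.to_numpy(float))
    ref = panel.reference_means.to_numpy(float)
    arr = m.to_numpy(float, copy=True)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        nan = np.isnan(col)
        if nan.all():
            out[:, j] = np.nan
            continue
        col = np.where(nan, ref, col)
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        # positions of each tie group in the sorted target vector; reduceat
        # sums each group, so untied values map to their target exactly
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        group_means = np.add.reduceat(target, starts) / counts
        out[:, j] = group_means[inv]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def score(
    m: pd.DataFrame,
    model: TrainedModel,
    min_algo_frac: float = 0.8,
    min_panel_frac: float = 0.8,
) -> ScoreResult:
    """Score samples: align -> missingness gate -> normalize -> weighted sum.

    Samples with fewer than ``min_algo_frac`` of algorithm probes or
    ``min_panel_frac`` of panel probes present are refused (score NaN, flag
    set); missing values on surviving samples are imputed with reference
    means inside the normalization step and counted per sample. No
    randomness is involved at scoring time.
    """
    model.validate()
    panel = model.panel
    aligned = align_to_panel(m, panel)
    if aligned.isna().all(axis=None):
        raise DataError("no overlap between target probes and the model panel")

    present = aligned.notna()
    algo_mask = panel.is_algorithm.astype(bool).to_numpy()
    if algo_mask.any():
        frac_algo = present.to_numpy()[algo_mask].mean(axis=0)
    else:  # null model: the gate is vacuously satisfied
        frac_algo = np.ones(aligned.shape[1])
    frac_panel = present.to_numpy().mean(axis=0)
    n_imputed = (~present).to_numpy().sum(axis=0)

    flags = np.full(aligned.shape[1], "ok", dtype=object)
    flags[frac_panel < min_panel_frac] = "refused: panel probe fraction below threshold"
    flags[frac_algo < min_algo_frac] = "refused: algorithm probe fraction below threshold"

    normalized = quantile_normalize_to_reference(aligned, panel)
    w = model.weights.weights.reindex(panel.probes).fillna(0.0).to_numpy(float)
    raw = model.weights.intercept + normalized.to_numpy(float).T @ w

    scores = pd.Series(raw, index=aligned.columns, name="score")
    refused = flags != "ok"
    scores[refused] = np.nan
    diagnostics = pd.DataFrame(
        {
            "frac_algo_probes": frac_algo,
            "frac_panel_probes": frac_panel,
            "n_imputed": n_imputed.astype(int),
            "flag": flags,
        },
        index=aligned.columns,
    )
    if refused.any():
        logger.warning("score refused_samples=%d of %d", int(refused.sum()), len(flags))
    logger.info("score n_samples=%d n_scored=%d", len(flags), int((~refused).sum()))
    return ScoreResult(scores=scores, diagnostics=diagnostics, model_version=model.version)


def score_replicate_reliability(*score_sets) -> ICCResult:
    """ICC of scores across replicate datasets of the same samples.

    Each argument is a :class:`ScoreResult` or a per-sample Series from one
    replicate dataset; samples are matched by id.
    """
    series = [
        s.scores if isinstance(s, ScoreResult) else pd.Series(s) for s in score_sets
    ]
    if len(series) < 2:
        raise DataError("need scores from >= 2 replicate datasets")
    common = series[0].index
    for s in series[1:]:
        common = common.intersection(s.index)
    if len(common) < 2:
        raise DataError("need >= 2 paired samples")
    mat = np.column_stack([s.reindex(common).to_numpy(float) for s in series])
    return estimate_icc(mat)
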