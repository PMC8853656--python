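"""Distill a pace phenotype into a CpG scoring algorithm.

Training restricts predictors to reliability-filtered probes, fits an
elastic net (mixing parameter alpha, penalty lambda chosen by k-fold
cross-validation at minimum mean squared error), and freezes a reference
normalization panel: the algorithm's probes plus background probes sampled
to represent the training set's beta distribution, each carrying its
training-set mean beta. The weight table and panel together are the entire
deployable artifact — scoring needs nothing else.

Note on conventions: the elastic-net mixing parameter called alpha here (and
in glmnet) is scikit-learn's ``l1_ratio``; the penalty strength lambda is
scikit-learn's ``alpha``. Coefficients are fitted on internally standardized
predictors and returned on the original beta scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .errors import (
    AlignmentError,
    ConfigurationError,
    DataError,
    FormatError,
    IntegrityError,
)

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1"


@dataclass(frozen=True)
class TrainerConfig:
    alpha: float = 0.5  # elastic-net mixing (L1 fraction)
    lambda_grid: tuple[float, ...] | None = None  # None: data-driven log grid
    n_lambdas: int = 40
    lambda_min_ratio: float = 1e-2  # glmnet convention for n < p
    cv_folds: int = 10
    panel_size: int = 20000
    reliability_threshold: float = 0.4
    seed: int = 0
    tol: float = 1e-5
    max_iter: int = 3000

    def validate(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")
        if self.panel_size < 1:
            raise ConfigurationError("panel_size must be >= 1")


@dataclass
class WeightTable:
    """Intercept plus nonzero probe weights on the beta scale."""

    intercept: float
    weights: pd.Series  # probe_id -> weight, zero weights never stored
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = self.weights[self.weights != 0.0]
        if self.weights.index.has_duplicates:
            raise IntegrityError("duplicate probe ids in weight table")

    @property
    def probes(self) -> pd.Index:
        return self.weights.index

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class ReferencePanel:
    """Frozen probe panel with per-probe reference means.

    Algorithm probes come first, then the background probes drawn at panel
    construction time; the order is part of the artifact and is never
    redrawn at scoring time.
    """

    probes: pd.Index
    reference_means: pd.Series
    is_algorithm: pd.Series
    seed: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.probes.has_duplicates:
            raise IntegrityError("duplicate probe ids in reference panel")
        self.reference_means = self.reference_means.reindex(self.probes)
        self.is_algorithm = self.is_algorithm.reindex(self.probes)
        if self.reference_means.isna().any():
            raise IntegrityError("reference mean missing for some panel probes")
        vals = self.reference_means.to_numpy(float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise IntegrityError("reference means must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def n_background(self) -> int:
        return int((~self.is_algorithm.astype(bool)).sum())


@dataclass
class TrainedModel:
    weights: WeightTable
    panel: ReferencePanel
    version: str = FORMAT_VERSION

    def validate(self) -> None:
        missing = self.weights.probes.difference(self.panel.probes)
        if len(missing):
            raise IntegrityError(
                f"{len(missing)} weighted probes absent from the reference panel"
            )


def _default_lambda_grid(Xs: np.ndarray, y: np.ndarray, config: TrainerConfig) -> np.ndarray:
    n = len(y)
    l1 = max(config.alpha, 1e-3)
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / (n * l1)
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * config.lambda_min_ratio), config.n_lambdas
    )


def train_elastic_net(
    betas: pd.DataFrame,
    pace,
    reliable: pd.Index | list[str],
    config: TrainerConfig = TrainerConfig(),
) -> WeightTable:
    """Fit the CpG scoring weights by cross-validated elastic net.

    ``betas`` is probes x samples; ``pace`` is the per-sample phenotype
    (Series indexed by sample id). Predictors are restricted to ``reliable``
    probes, standardized internally, and the penalty is chosen at minimum
    mean cross-validated squared error with fold assignment deterministic
    given ``config.seed``. Returned weights are on the original beta scale
    and only nonzero weights are stored.
    """
    config.validate()
    pace = pd.Series(pace) if not isinstance(pace, pd.Series) else pace
    if set(betas.columns) != set(pace.index):
        raise AlignmentError("beta-matrix samples and pace samples differ")
    reliable = pd.Index(reliable)
    if len(reliable) == 0:
        raise DataError("reliable probe set is empty")
    extra = reliable.difference(betas.index)
    if len(extra):
        raise AlignmentError(f"{len(extra)} reliable probes absent from beta matrix")
    if len(pace) < config.cv_folds:
        raise DataError("need at least cv_folds samples")

    y = pace.to_numpy(float)
    X = betas.loc[reliable, pace.index].to_numpy(float).T  # samples x probes

    if np.allclose(y, y[0]):
        return WeightTable(
            intercept=float(y[0]),
            weights=pd.Series(dtype=float),
            provenance={"alpha": config.alpha, "lambda": None, "n_samples": len(y),
                        "note": "constant phenotype; null model"},
        )

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    probes_kept = reliable[keep]

    grid = (
        np.asarray(config.lambda_grid, float)
        if config.lambda_grid is not None
        else _default_lambda_grid(Xs, y, config)
    )
    cv = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    model = ElasticNetCV(
        l1_ratio=config.alpha,
        alphas=np.sort(grid)[::-1],
        cv=cv,
        fit_intercept=True,
        max_iter=config.max_iter,
        tol=config.tol,
    )
    model.fit(Xs, y)
    lam = float(model.alpha_)

    w_std = model.coef_
    nz = w_std != 0.0
    w_beta = w_std[nz] / sd[keep][nz]
    intercept = float(model.intercept_ - np.sum(w_std[nz] * mu[keep][nz] / sd[keep][nz]))
    weights = pd.Series(w_beta, index=probes_kept[nz], name="weight")
    logger.info(
        "train_elastic_net alpha=%s lambda=%.6g n_samples=%d n_predictors=%d n_selected=%d",
        config.alpha, lam, len(y), int(keep.sum()), int(nz.sum()),
    )
    return WeightTable(
        intercept=intercept,
        weights=weights,
        provenance={
            "alpha": config.alpha,
            "lambda": lam,
            "cv_folds": config.cv_folds,
            "seed": config.seed,
            "n_samples": len(y),
            "n_predictors": int(keep.sum()),
        },
    )


def build_reference_panel(
    weights: WeightTable,
    betas: pd.DataFrame,
    universe: pd.Index | None = None,
    panel_size: int = 20000,
    seed: int = 0,
    stratified: bool = True,
) -> ReferencePanel:
    """Freeze the normalization panel: algorithm probes + background probes.

    Background probes are drawn without replacement from
    ``universe \\ weighted``; by default the draw is stratified across
    deciles of training-set mean beta so the panel represents the underlying
    beta distribution (set ``stratified=False`` for a simple random draw).
    Reference means are training-set mean betas. Sampling happens exactly
    once, here; scorers must never redraw it.
    """
    universe = betas.index if universe is None else pd.Index(universe)
    if len(weights.probes.difference(universe)):
        raise DataError("universe must contain every weighted probe")
    if len(weights.probes.difference(betas.index)):
        raise DataError("beta matrix must contain every weighted probe")
    if len(universe) < panel_size:
        raise DataError(
            f"universe has {len(universe)} probes < panel_size {panel_size}"
        )
    missing_means = universe.difference(betas.index)
    if len(missing_means):
        raise DataError(
            f"{len(missing_means)} universe probes lack training betas for reference means"
        )

    algo = weights.probes
    n_bg = panel_size - len(algo)
    if n_bg < 0:
        raise ConfigurationError("panel_size smaller than the number of weighted probes")
    pool = universe.difference(algo, sort=False)
    rng = np.random.default_rng(seed)
    if n_bg == 0:
        background = pd.Index([], name="probe_id")
    elif not stratified:
        background = pd.Index(rng.choice(pool, size=n_bg, replace=False))
    else:
        pool_means = betas.loc[pool].mean(axis=1).to_numpy(float)
        edges = np.quantile(pool_means, np.linspace(0, 1, 11))
        bins = np.clip(np.searchsorted(edges, pool_means, side="right") - 1, 0, 9)
        counts = np.bincount(bins, minlength=10)
        quota = counts * n_bg / len(pool)
        alloc = np.floor(quota).astype(int)
        remainder = quota - alloc
        short = n_bg - alloc.sum()
        for b in np.argsort(remainder)[::-1][:short]:
            alloc[b] += 1
        picks = []
        pool_arr = np.asarray(pool)
        for b in range(10):
            members = pool_arr[bins == b]
            take = min(alloc[b], len(members))
            if take:
                picks.append(rng.choice(members, size=take, replace=False))
        background = pd.Index(np.concatenate(picks) if picks else [])
        # rounding versus bin-size clashes can leave a shortfall; top up randomly
        if len(background) < n_bg:
            left = pool.difference(background, sort=False)
            background = background.append(
                pd.Index(rng.choice(left, size=n_bg - len(background), replace=False))
            )

    probes = algo.append(background)
    ref_means = betas.loc[probes].mean(axis=1)
    is_algo = pd.Series(False, index=probes)
    is_algo.loc[algo] = True
    logger.info(
        "build_reference_panel panel_size=%d n_algorithm=%d n_background=%d stratified=%s",
        len(probes), len(algo), len(background), stratified,
    )
    return ReferencePanel(
        probes=probes,
        reference_means=ref_means,
        is_algorithm=is_algo,
        seed=seed,
        source=f"training betas ({betas.shape[1]} samples)",
    )


# ---------------------------------------------------------------------------
# Model serialization: a directory with weights.csv, panel.csv, model.json.
# Floats are written with repr() so the round trip is bit-exact.
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> Path:
    model.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "weights.csv", "w") as fh:
        fh.write("probe_id,weight\n")
        fh.write(f"intercept,{float(model.weights.intercept)!r}\n")
        for probe, w in model.weights.weights.items():
            fh.write(f"{probe},{float(w)!r}\n")
    with open(path / "panel.csv", "w") as fh:
        fh.write("probe_id,reference_mean,is_algorithm_probe\n")
        for probe in model.panel.probes:
            fh.write(
                f"{probe},{float(model.panel.reference_means[probe])!r},"
                f"{int(bool(model.panel.is_algorithm[probe]))}\n"
            )
    meta = {
        "format_version": model.version,
        "panel_seed": model.panel.seed,
        "panel_source": model.panel.source,
        "provenance": model.weights.provenance,
    }
    with open(path / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return path


def load_weights_csv(path) -> WeightTable:
    """Load a weights-only CSV (``probe_id,weight`` with an intercept row).

    Accepts both this package's weight files and externally published weight
    tables in the same two-column layout.
    """
    df = pd.read_csv(path, comment="#", dtype={"probe_id": str}, float_precision="round_trip")
    if not {"probe_id", "weight"} <= set(df.columns):
        raise FormatError("weights file needs columns probe_id, weight")
    inter = df[df["probe_id"] == "intercept"]
    intercept = float(inter["weight"].iloc[0]) if len(inter) else 0.0
    rest = df[df["probe_id"] != "intercept"]
    weights = pd.Series(
        rest["weight"].to_numpy(float),
        index=pd.Index(rest["probe_id"], name="probe_id"),
        name="weight",
    )
    if weights.index.has_duplicates:
        raise FormatError("duplicate probe ids in weights file")
    return WeightTable(intercept=intercept, weights=weights, provenance={"path": str(path)})


def load_panel_csv(path, seed=None, source="") -> ReferencePanel:
    df = pd.read_csv(path, comment="#", dtype={"probe_id": str}, float_precision="round_trip")
    need = {"probe_id", "reference_mean", "is_algorithm_probe"}
    if not need <= set(df.columns):
        raise FormatError(f"panel file needs columns {sorted(need)}")
    probes = pd.Index(df["probe_id"], name="probe_id")
    return ReferencePanel(
        probes=probes,
        reference_means=pd.Series(df["reference_mean"].to_numpy(float), index=probes),
        is_algorithm=pd.Series(df["is_algorithm_probe"].astype(bool).to_numpy(), index=probes),
        seed=seed,
        source=source,
    )


def load_model(path) -> TrainedModel:
    path = Path(path)
    meta_path = path / "model.json"
    if not meta_path.exists():
        raise FormatError(f"{path} is not a model directory (no model.json)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    version = str(meta.get("format_version", ""))
    if version != FORMAT_VERSION:
        raise FormatError(
            f"model format version {version!r} not supported (expected {FORMAT_VERSION!r})"
        )
    weights = load_weights_csv(path / "weights.csv")
    weights.provenance = meta.get("provenance", {})
    panel = load_panel_csv(
        path / "panel.csv", seed=meta.get("panel_seed"), source=meta.get("panel_source", "")
    )
    model = TrainedModel(weights=weights, panel=panel, version=version)
    model.validate()
    return model
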