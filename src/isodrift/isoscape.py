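"""Quantile-forest δ³⁴S isoscape: fitting, variable selection, prediction.

The isoscape is a random-forest regression of site δ³⁴S on environmental
covariates. Per-pixel uncertainty comes from the quantile-random-forest
convention: for a query point, pool the training responses found in the
leaf that each tree routes the point to, and read empirical quantiles off
that pooled distribution (type-7 interpolation). The default uncertainty
raster is the 68.27% prediction-interval **full width**,
``σ ≈ q(0.841) − q(0.159)`` (≈ 2s for Gaussian residual noise of SD s);
``sigma_mode="halfwidth"`` divides by two.

Predictions are masked wherever any selected covariate falls outside its
training range, so the isoscape never extrapolates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, RepeatedKFold

from ._rng import child_seed
from .covariates import CovariateStack
from .raster import Raster

__all__ = [
    "IsoscapeConfig", "IsoscapeModel", "Isoscape", "CVResult",
    "fit_isoscape", "select_variables", "predict_isoscape", "crossvalidate",
    "regression_metrics", "save_model", "load_model",
]

QUANTILE_LEVELS = (0.159, 0.841)


@dataclass
class IsoscapeConfig:
    """Fitting configuration.

    ``n_trees`` is the forest size of the final model; the tuning grid
    sweeps predictors-per-split over 1..p and minimum leaf size over
    ``min_leaf_grid``, scored by k-fold CV RMSE. ``cv_reps=0`` skips the
    (reported) cross-validation metrics at fit time.
    """

    n_trees: int = 1000
    min_leaf_grid: tuple[int, ...] = (3, 5)
    tune: bool = True
    tune_folds: int = 5
    cv_folds: int = 10
    cv_reps: int = 5
    sigma_mode: str = "fullwidth"      # or "halfwidth"
    sigma_quantiles: tuple[float, float] = QUANTILE_LEVELS
    select_tol: float = 0.01           # relative CV-RMSE gain to keep a predictor
    select_n_fits: int = 3             # repeated fits for permutation importance
    n_trees_select: int = 200          # forest size during selection/tuning
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_mode not in ("fullwidth", "halfwidth"):
            raise ValueError("sigma_mode must be 'fullwidth' or 'halfwidth'")


@dataclass
class CVResult:
    r2: float
    rmse: float
    fold_rmse: np.ndarray
    fold_r2: np.ndarray


@dataclass
class IsoscapeModel:
    """A fitted quantile forest plus everything needed to predict safely."""

    forest: RandomForestRegressor
    predictors: tuple[str, ...]
    train_ranges: dict                    # name -> (min, max)
    y_train: np.ndarray
    train_leaves: np.ndarray              # (n_train, n_trees) leaf ids
    cfg: IsoscapeConfig
    cv: CVResult | None = None
    tuned: dict = field(default_factory=dict)


@dataclass
class Isoscape:
    """Mean and uncertainty rasters with the no-extrapolation mask."""

    mean: Raster
    sigma: Raster
    valid_mask: Raster    # 1.0 valid / 0.0 masked

    def __post_init__(self) -> None:
        self.mean.require_congruent(self.sigma, "sigma")
        self.mean.require_congruent(self.valid_mask, "valid_mask")
        valid = self.valid
        if np.any(self.sigma.values[valid] < 0):
            raise ValueError("sigma must be non-negative on valid cells")

    @property
    def valid(self) -> np.ndarray:
        return self.valid_mask.values > 0.5


# -- small numeric helpers -------------------------------------------------


def regression_metrics(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """(R², RMSE): R² is the squared Pearson correlation, RMSE in ‰.

    R² is 0 when either vector is constant (no linear association).
    """
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.std(obs) == 0 or np.std(pred) == 0:
        return 0.0, rmse
    r = float(stats.pearsonr(obs, pred).statistic)
    return r * r, rmse


def _seed_int(cfg_seed: int, *names: str) -> int:
    return int(child_seed(cfg_seed, *names).generate_state(1)[0] % (2**31 - 1))


def _forest(n_trees, max_features, min_leaf, seed) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees, max_features=max_features,
        min_samples_leaf=min_leaf, random_state=seed, n_jobs=1,
    )


def _extract_xy(samples: pd.DataFrame, covs: CovariateStack, predictors):
    """Covariate values of the containing cell for every sample row.

    Uses the ``row``/``col`` columns when present, otherwise locates the
    cell from lat/lon. Raises naming the site_id of any off-grid or
    masked sample.
    """
    grid = covs.grid
    if {"row", "col"}.issubset(samples.columns):
        rows = samples["row"].to_numpy(int)
        cols = samples["col"].to_numpy(int)
    else:
        rows, cols = [], []
        for _, rec in samples.iterrows():
            try:
                r, c = grid.cell_of(rec["lat"], rec["lon"])
            except ValueError as exc:
                raise ValueError(f"sample site {rec['site_id']!r} is off-grid") from exc
            rows.append(r)
            cols.append(c)
        rows, cols = np.asarray(rows), np.asarray(cols)
    on_mask = covs.mask[rows, cols]
    if not on_mask.all():
        bad = samples["site_id"].to_numpy()[~on_mask]
        raise ValueError(f"sample site(s) on masked covariate cells: {list(bad[:5])}")
    X = covs.matrix(predictors, rows, cols)
    y = samples["d34S"].to_numpy(float)
    return X, y


def _cv_rmse(X, y, n_trees, max_features, min_leaf, folds, seed) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.empty_like(y)
    for i, (tr, te) in enumerate(kf.split(X)):
        f = _forest(n_trees, max_features, min_leaf, seed + i + 1)
        f.fit(X[tr], y[tr])
        oof[te] = f.predict(X[te])
    return float(np.sqrt(np.mean((y - oof) ** 2)))


# -- operations ------------------------------------------------------------


def fit_isoscape(samples: pd.DataFrame, covs: CovariateStack,
                 cfg: IsoscapeConfig | None = None,
                 predictors=None) -> IsoscapeModel:
    """Fit the quantile forest on covariates extracted at sample cells.

    Hyperparameters (predictors-per-split, minimum leaf size) are tuned by
    minimizing CV RMSE over a small grid; the reported CV metrics use the
    configured repeated k-fold (``cv_reps=0`` to skip).
    """
    cfg = cfg or IsoscapeConfig()
    predictors = tuple(predictors) if predictors is not None else covs.names
    if len(samples) < 20:
        raise ValueError("need at least 20 samples to fit an isoscape")
    X, y = _extract_xy(samples, covs, predictors)
    if np.ptp(y) == 0:
        raise ValueError("constant response: cannot fit an isoscape")

    p = X.shape[1]
    best = (max(1, p // 3), cfg.min_leaf_grid[0])
    tuned = {}
    if cfg.tune:
        scores = {}
        for mtry in range(1, p + 1):
            for leaf in cfg.min_leaf_grid:
                scores[(mtry, leaf)] = _cv_rmse(
                    X, y, cfg.n_trees_select, mtry, leaf,
                    min(cfg.tune_folds, len(y)), _seed_int(cfg.seed, "tune"))
        best = min(scores, key=lambda k: (round(scores[k], 12), k))
        tuned = {"grid_rmse": {f"{m}/{l}": v for (m, l), v in scores.items()},
                 "max_features": best[0], "min_samples_leaf": best[1]}

    forest = _forest(cfg.n_trees, best[0], best[1], _seed_int(cfg.seed, "forest"))
    forest.fit(X, y)
    model = IsoscapeModel(
        forest=forest, predictors=predictors,
        train_ranges={n: (float(X[:, j].min()), float(X[:, j].max()))
                      for j, n in enumerate(predictors)},
        y_train=y, train_leaves=forest.apply(X), cfg=cfg, tuned=tuned,
    )
    if cfg.cv_reps > 0:
        model.cv = crossvalidate(model, samples, covs,
                                 k=cfg.cv_folds, reps=cfg.cv_reps, seed=cfg.seed)
    return model


def crossvalidate(model: IsoscapeModel, samples: pd.DataFrame, covs: CovariateStack,
                  k: int = 10, reps: int = 5, seed: int = 0) -> CVResult:
    """Repeated k-fold CV with the model's hyperparameters.

    Out-of-fold predictions are pooled; R² is the squared Pearson
    correlation of observed vs predicted, RMSE is in ‰.
    """
    X, y = _extract_xy(samples, covs, model.predictors)
    if k > len(y):
        raise ValueError(f"k={k} exceeds the number of samples ({len(y)})")
    mtry = model.forest.max_features
    leaf = model.forest.min_samples_leaf
    rkf = RepeatedKFold(n_splits=k, n_repeats=reps, random_state=_seed_int(seed, "cv"))
    oof = np.zeros((reps, len(y)))
    fold_rmse, fold_r2 = [], []
    for i, (tr, te) in enumerate(rkf.split(X)):
        f = _forest(model.cfg.n_trees_select, mtry, leaf, _seed_int(seed, "cv", str(i)))
        f.fit(X[tr], y[tr])
        pred = f.predict(X[te])
        oof[i // k, te] = pred
        r2_i, rmse_i = regression_metrics(y[te], pred)
        fold_rmse.append(rmse_i)
        fold_r2.append(r2_i)
    r2, rmse = regression_metrics(np.tile(y, reps), oof.ravel())
    return CVResult(r2=r2, rmse=rmse,
                    fold_rmse=np.asarray(fold_rmse), fold_r2=np.asarray(fold_r2))


def select_variables(samples: pd.DataFrame, covs: CovariateStack,
                     cfg: IsoscapeConfig | None = None) -> list[str]:
    """Two-stage predictor selection (importance screen + greedy forward).

    Stage 1 ranks predictors by permutation importance averaged over
    repeated forest fits and drops those whose importance does not exceed
    that of a seeded pure-noise probe column. Stage 2 adds survivors in
    rank order, keeping an addition only if it lowers 5-fold CV RMSE by
    more than ``select_tol`` (relative). The first-ranked predictor is
    always kept.
    """
    cfg = cfg or IsoscapeConfig()
    names = list(covs.names)
    if len(names) < 2:
        return names
    X, y = _extract_xy(samples, covs, names)
    rng = np.random.default_rng(child_seed(cfg.seed, "select", "probe"))
    probe = rng.standard_normal(len(y))
    Xp = np.column_stack([X, probe])

    imp = np.zeros(Xp.shape[1])
    for r in range(cfg.select_n_fits):
        f = _forest(cfg.n_trees_select, max(1, Xp.shape[1] // 3), 5,
                    _seed_int(cfg.seed, "select", str(r)))
        f.fit(Xp, y)
        pi = permutation_importance(f, Xp, y, n_repeats=5,
                                    random_state=_seed_int(cfg.seed, "select-pi", str(r)))
        imp += pi.importances_mean
    imp /= cfg.select_n_fits
    probe_imp = imp[-1]
    survivors = [(names[j], imp[j]) for j in range(len(names)) if imp[j] > probe_imp]
    survivors.sort(key=lambda t: -t[1])
    ranked = [n for n, _ in survivors]
    if not ranked:
        # nothing beats noise; fall back to the single best-ranked predictor
        ranked = [names[int(np.argmax(imp[:-1]))]]

    selected: list[str] = []
    best_rmse = np.inf
    folds = min(5, len(y))
    for name in ranked:
        cand = selected + [name]
        idx = [names.index(n) for n in cand]
        rmse = _cv_rmse(X[:, idx], y, cfg.n_trees_select,
                        max(1, len(idx) // 3), 5, folds, _seed_int(cfg.seed, "forward"))
        if not selected or rmse < best_rmse * (1 - cfg.select_tol):
            selected = cand
            best_rmse = rmse
    return selected


def _pooled_quantiles(model: IsoscapeModel, X: np.ndarray, qs,
                      chunk: int = 2048) -> np.ndarray:
    """Quantiles of the pooled per-tree leaf training responses (type 7)."""
    order = np.argsort(model.y_train, kind="stable")
    ys = model.y_train[order]
    TL = model.train_leaves[order]            # (n_train, n_trees)
    n_trees = TL.shape[1]
    out = np.empty((X.shape[0], len(qs)))
    for s in range(0, X.shape[0], chunk):
        Q = model.forest.apply(X[s:s + chunk])     # (m, n_trees)
        m = Q.shape[0]
        W = np.zeros((m, len(ys)), dtype=np.int32)
        for t in range(n_trees):
            W += Q[:, t:t + 1] == TL[None, :, t]
        cum = np.cumsum(W, axis=1)
        N = cum[:, -1].astype(float)
        for qi, q in enumerate(qs):
            h = (N - 1.0) * q
            lo = np.floor(h).astype(np.int64)
            frac = h - lo
            v = np.empty(m)
            for i in range(m):
                k_lo = int(np.searchsorted(cum[i], lo[i] + 1))
                k_hi = int(np.searchsorted(cum[i], min(lo[i] + 2, int(N[i]))))
                v[i] = ys[k_lo] + frac[i] * (ys[k_hi] - ys[k_lo])
            out[s + np.arange(m), qi] = v
    return out


def predict_isoscape(model: IsoscapeModel, covs: CovariateStack) -> Isoscape:
    """Predict mean and σ rasters, masking outside the training range."""
    for name in model.predictors:
        if name not in covs.names:
            raise ValueError(f"missing predictor layer: {name!r}")
    grid = covs.grid
    valid = covs.mask.copy()
    rows, cols = np.nonzero(valid)
    X = covs.matrix(model.predictors, rows, cols)
    in_range = np.ones(len(rows), dtype=bool)
    for j, name in enumerate(model.predictors):
        lo, hi = model.train_ranges[name]
        in_range &= (X[:, j] >= lo) & (X[:, j] <= hi)
    valid[rows[~in_range], cols[~in_range]] = False

    mean = np.full(grid.shape, np.nan)
    sigma = np.full(grid.shape, np.nan)
    if in_range.any():
        Xv = X[in_range]
        rv, cv = rows[in_range], cols[in_range]
        mean[rv, cv] = model.forest.predict(Xv)
        qlo, qhi = model.cfg.sigma_quantiles
        qq = _pooled_quantiles(model, Xv, (qlo, qhi))
        width = qq[:, 1] - qq[:, 0]
        if model.cfg.sigma_mode == "halfwidth":
            width = width / 2.0
        sigma[rv, cv] = width
    return Isoscape(
        mean=grid.like(mean, units="permil VCDT"),
        sigma=grid.like(sigma, units="permil"),
        valid_mask=grid.like(valid.astype(float), units="valid"),
    )


# -- persistence -----------------------------------------------------------


def save_model(model: IsoscapeModel, path: str | Path) -> Path:
    """Persist a model as a directory: forest.joblib + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump({"forest": model.forest, "y_train": model.y_train,
                 "train_leaves": model.train_leaves}, path / "forest.joblib")
    meta = {
        "predictors": list(model.predictors),
        "train_ranges": {k: list(v) for k, v in model.train_ranges.items()},
        "cfg": {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(model.cfg).items()},
        "cv": None if model.cv is None else {"r2": model.cv.r2, "rmse": model.cv.rmse},
        "tuned": model.tuned,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def load_model(path: str | Path) -> IsoscapeModel:
    path = Path(path)
    blob = joblib.load(path / "forest.joblib")
    meta = json.loads((path / "meta.json").read_text())
    cfg_d = meta["cfg"]
    for key in ("min_leaf_grid", "sigma_quantiles"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = IsoscapeConfig(**cfg_d)
    model = IsoscapeModel(
        forest=blob["forest"], predictors=tuple(meta["predictors"]),
        train_ranges={k: tuple(v) for k, v in meta["train_ranges"].items()},
        y_train=blob["y_train"], train_leaves=blob["train_leaves"],
        cfg=cfg, tuned=meta.get("tuned", {}),
    )
    if meta.get("cv"):
        model.cv = CVResult(r2=meta["cv"]["r2"], rmse=meta["cv"]["rmse"],
                            fold_rmse=np.array([]), fold_r2=np.array([]))
    return model
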