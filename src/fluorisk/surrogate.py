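"""Feed-forward neural-network surrogate for the hazard quotient.

The HQ is a smooth deterministic function of six exposure features
(C, EF, IR, ED, BW, AT), so a small multilayer perceptron can learn it to
near machine accuracy from under a hundred rows. The training protocol:

1. :func:`build_dataset` — one row per water replicate; each row is assigned
   one cohort at random (seeded), which makes all cohort-dependent features
   vary; the target is the analytic HQ. Rows are split 80/10/10 into
   train/validation/test (69/8/8 for the default 85-row study).
2. :func:`standardize` — per-feature z-scoring fitted on the training rows
   only; constant features (EF under the default cohorts) are centred and
   flagged, not rescaled.
3. :func:`grid_search` — every (architecture, L2, learning-rate) candidate is
   scored by k-fold cross-validation *inside the training split*; candidates
   are ranked by mean fold MSE, ties broken by fewer parameters.
4. :func:`train_final` — the winning candidate is retrained on the full
   training split with ReLU hidden layers, a linear output, L2 penalty and
   early stopping driven by the held-out validation split; the best-epoch
   weights are restored and per-epoch history is kept.

Models serialize to JSON (architecture, scaler statistics, weight matrices);
:func:`predict_hq` runs the forward pass from the stored weights and warns
when queried outside the training hull (+/-20% of each feature's range).

The optimizer is Adam with full-batch updates (the in-memory fitting is
delegated to scikit-learn's ``MLPRegressor``; epoch-level control, early
stopping against the explicit validation split and serialization are
implemented here).
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning as _SkConvergenceWarning
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .errors import ConfigurationError, ExtrapolationWarning, TrainingWarning, UsageError
from .exposure import AgeGroupParams, DEFAULT_COHORTS, SiteRecord, compute_hq

__all__ = [
    "FEATURES",
    "FeatureScaler",
    "SurrogateDataset",
    "SurrogateConfig",
    "CandidateResult",
    "SurrogateModel",
    "build_dataset",
    "standardize",
    "grid_search",
    "train_final",
    "evaluate",
    "regression_metrics",
    "predict_hq",
]

#: Feature order fed to the network.
FEATURES = ("C", "EF", "IR", "ED", "BW", "AT")

_SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature z-scoring with pass-through for constant features."""

    names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray           # 1.0 where constant
    constant: np.ndarray        # bool mask of constant (sd == 0) features
    lo: np.ndarray              # training-split minima (raw units)
    hi: np.ndarray              # training-split maxima (raw units)

    @classmethod
    def fit(cls, X: np.ndarray, names: Sequence[str]) -> "FeatureScaler":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = sd == 0
        scale = np.where(constant, 1.0, sd)
        return cls(tuple(names), mean, scale, constant, X.min(axis=0), X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale + self.mean

    def hull_violations(self, X: np.ndarray, margin: float = 0.2) -> np.ndarray:
        """Boolean mask of rows outside the training hull, widened by
        ``margin`` times each feature's range."""
        span = np.maximum(self.hi - self.lo, np.maximum(np.abs(self.hi), 1e-12))
        lo = self.lo - margin * span
        hi = self.hi + margin * span
        X = np.asarray(X, dtype=float)
        return ((X < lo) | (X > hi)).any(axis=1)


@dataclass(frozen=True)
class SurrogateDataset:
    """Feature matrix, analytic HQ target and train/val/test split labels.

    ``features`` stays in raw units; the fitted :class:`FeatureScaler`
    (training rows only) is attached by :func:`standardize`.
    """

    features: pd.DataFrame
    target: np.ndarray
    split: np.ndarray
    cohort: np.ndarray
    site_id: np.ndarray
    seed: int
    scaler: FeatureScaler | None = None

    def __post_init__(self) -> None:
        n = len(self.features)
        if not (len(self.target) == len(self.split) == n):
            raise ConfigurationError("dataset arrays must share one length")
        if np.isnan(self.features.to_numpy()).any() or np.isnan(self.target).any():
            raise ConfigurationError("dataset contains missing values")

    def rows(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        """(X_raw, y) for one split."""
        if split not in _SPLITS:
            raise UsageError(f"unknown split {split!r}")
        mask = self.split == split
        return self.features.to_numpy(dtype=float)[mask], self.target[mask]

    def n_rows(self, split: str) -> int:
        return int((self.split == split).sum())


def _split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    if min(fractions) < 0:
        raise ConfigurationError("split fractions must be non-negative")
    # The two small splits truncate and training takes the remainder, so the
    # canonical 85-row study lands on 69/8/8.
    n_val = int(np.floor(n * f_val))
    n_test = int(np.floor(n * f_test))
    n_train = n - n_val - n_test
    if n_train <= 0 or (f_val > 0 and n_val == 0) or (f_test > 0 and n_test == 0):
        raise ConfigurationError(f"fractions {fractions} degenerate for n={n}")
    return n_train, n_val, n_test


def build_dataset(
    sites: Sequence[SiteRecord],
    cohorts: Sequence[AgeGroupParams] = DEFAULT_COHORTS,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SurrogateDataset:
    """One row per water replicate with a randomly assigned cohort.

    The six features are the replicate concentration plus the assigned
    cohort's EF, IR, ED, BW, AT; the target is the analytic HQ. Splitting is
    a seeded permutation into the requested fractions.
    """
    rows: list[dict[str, float]] = []
    meta_cohort: list[str] = []
    meta_site: list[str] = []
    rng = np.random.default_rng(seed)
    for site in sites:
        samples = site.samples if site.samples is not None else (site.summary.mean,)
        for c in samples:
            cohort = cohorts[int(rng.integers(len(cohorts)))]
            rows.append(
                {"C": c, "EF": cohort.EF, "IR": cohort.IR,
                 "ED": cohort.ED, "BW": cohort.BW, "AT": cohort.AT,
                 "_hq": compute_hq(c, cohort)}
            )
            meta_cohort.append(cohort.name)
            meta_site.append(site.site_id)
    n = len(rows)
    if n < 20:
        raise UsageError(f"need at least 20 rows to build a dataset, have {n}")
    frame = pd.DataFrame(rows)
    target = frame.pop("_hq").to_numpy(dtype=float)
    frame = frame[list(FEATURES)]
    n_train, n_val, n_test = _split_counts(n, tuple(fractions))
    labels = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    perm = rng.permutation(n)
    split = np.empty(n, dtype=labels.dtype)
    split[perm] = labels
    return SurrogateDataset(
        features=frame,
        target=target,
        split=split,
        cohort=np.array(meta_cohort),
        site_id=np.array(meta_site),
        seed=seed,
    )


def standardize(dataset: SurrogateDataset) -> SurrogateDataset:
    """Attach a z-scorer fitted on the training rows only.

    Constant features are centred but not rescaled (and flagged in
    ``scaler.constant``), so a zero-variance column cannot blow up the
    transform.
    """
    X_train, _ = dataset.rows("train")
    if len(X_train) == 0:
        raise UsageError("cannot standardize without training rows")
    scaler = FeatureScaler.fit(X_train, dataset.features.columns)
    return replace(dataset, scaler=scaler)


@dataclass(frozen=True)
class SurrogateConfig:
    """Hyperparameter search space and training protocol."""

    architectures: tuple[tuple[int, ...], ...] = (
        (64, 32, 16),
        (128, 64, 32),
        (64, 32),
        (128, 64),
    )
    l2: tuple[float, ...] = (0.01, 0.1)
    learning_rates: tuple[float, ...] = (0.01, 0.001)
    k_folds: int = 5
    patience: int = 100
    max_epochs: int = 2000
    cv_max_epochs: int = 800
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.architectures) == 0:
            raise ConfigurationError("architecture candidate list is empty")
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")
        if self.patience < 1 or self.max_epochs < 1:
            raise ConfigurationError("patience and max_epochs must be >= 1")


@dataclass(frozen=True)
class CandidateResult:
    architecture: tuple[int, ...]
    l2: float
    learning_rate: float
    mean_cv_mse: float
    fold_mse: tuple[float, ...]
    n_params: int
    failed: bool = False


def _n_params(architecture: tuple[int, ...], n_features: int = len(FEATURES)) -> int:
    sizes = (n_features, *architecture, 1)
    return sum(a * b + b for a, b in zip(sizes, sizes[1:]))


def _make_estimator(
    architecture: tuple[int, ...],
    l2: float,
    lr: float,
    batch: int,
    seed: int,
    max_iter: int,
    warm: bool = False,
) -> MLPRegressor:
    return MLPRegressor(
        hidden_layer_sizes=architecture,
        activation="relu",
        solver="adam",
        alpha=l2,
        learning_rate_init=lr,
        batch_size=max(1, batch),
        max_iter=max_iter,
        warm_start=warm,
        shuffle=False,
        tol=1e-8,
        n_iter_no_change=50,
        random_state=seed,
    )


def grid_search(dataset: SurrogateDataset, config: SurrogateConfig) -> list[CandidateResult]:
    """Rank every (architecture, L2, learning-rate) candidate by k-fold CV MSE.

    Folds live entirely inside the training split. A candidate whose fit
    diverges (non-finite loss) in any fold is marked failed and ranked last
    rather than aborting the search.
    """
    if dataset.scaler is None:
        dataset = standardize(dataset)
    X_raw, y = dataset.rows("train")
    X = dataset.scaler.transform(X_raw)
    if len(X) < config.k_folds:
        raise UsageError(
            f"{config.k_folds}-fold CV infeasible on {len(X)} training rows"
        )
    kf = KFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
    folds = list(kf.split(X))
    results: list[CandidateResult] = []
    for arch, l2, lr in product(config.architectures, config.l2, config.learning_rates):
        fold_mse: list[float] = []
        failed = False
        for fit_idx, val_idx in folds:
            est = _make_estimator(
                arch, l2, lr, batch=len(fit_idx), seed=config.seed,
                max_iter=config.cv_max_epochs,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", _SkConvergenceWarning)
                    est.fit(X[fit_idx], y[fit_idx])
                mse = mean_squared_error(y[val_idx], est.predict(X[val_idx]))
            except Exception:
                failed = True
                break
            if not np.isfinite(mse):
                failed = True
                break
            fold_mse.append(float(mse))
        results.append(
            CandidateResult(
                architecture=tuple(arch),
                l2=float(l2),
                learning_rate=float(lr),
                mean_cv_mse=float(np.mean(fold_mse)) if not failed else float("inf"),
                fold_mse=tuple(fold_mse),
                n_params=_n_params(tuple(arch)),
                failed=failed,
            )
        )
    results.sort(key=lambda r: (r.failed, r.mean_cv_mse, r.n_params))
    return results


@dataclass(frozen=True)
class SurrogateModel:
    """A trained surrogate: weights, scaler, history and metrics."""

    architecture: tuple[int, ...]
    l2: float
    learning_rate: float
    seed: int
    coefs: tuple[np.ndarray, ...]
    intercepts: tuple[np.ndarray, ...]
    scaler: FeatureScaler
    history: pd.DataFrame          # columns: epoch, train_mse, val_mse
    metrics: Mapping[str, Mapping[str, float]]
    best_epoch: int
    converged: bool

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "architecture": list(self.architecture),
            "l2": self.l2,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "coefs": [w.tolist() for w in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "scaler": {
                "names": list(self.scaler.names),
                "mean": self.scaler.mean.tolist(),
                "scale": self.scaler.scale.tolist(),
                "constant": self.scaler.constant.astype(bool).tolist(),
                "lo": self.scaler.lo.tolist(),
                "hi": self.scaler.hi.tolist(),
            },
            "history": self.history.to_dict(orient="list"),
            "metrics": {k: dict(v) for k, v in self.metrics.items()},
            "best_epoch": self.best_epoch,
            "converged": self.converged,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModel":
        d = json.loads(text)
        sc = d["scaler"]
        scaler = FeatureScaler(
            names=tuple(sc["names"]),
            mean=np.asarray(sc["mean"], dtype=float),
            scale=np.asarray(sc["scale"], dtype=float),
            constant=np.asarray(sc["constant"], dtype=bool),
            lo=np.asarray(sc["lo"], dtype=float),
            hi=np.asarray(sc["hi"], dtype=float),
        )
        return cls(
            architecture=tuple(d["architecture"]),
            l2=float(d["l2"]),
            learning_rate=float(d["learning_rate"]),
            seed=int(d["seed"]),
            coefs=tuple(np.asarray(w, dtype=float) for w in d["coefs"]),
            intercepts=tuple(np.asarray(b, dtype=float) for b in d["intercepts"]),
            scaler=scaler,
            history=pd.DataFrame(d["history"]),
            metrics=d["metrics"],
            best_epoch=int(d["best_epoch"]),
            converged=bool(d["converged"]),
        )


def _forward(X_std: np.ndarray, coefs, intercepts) -> np.ndarray:
    a = np.asarray(X_std, dtype=float)
    for W, b in zip(coefs[:-1], intercepts[:-1]):
        a = np.maximum(a @ W + b, 0.0)
    return (a @ coefs[-1] + intercepts[-1]).ravel()


def train_final(
    dataset: SurrogateDataset,
    candidate: CandidateResult,
    config: SurrogateConfig = SurrogateConfig(),
    seed: int | None = None,
) -> SurrogateModel:
    """Train the selected candidate with explicit-validation early stopping.

    One Adam epoch at a time (full batch); validation MSE is tracked on the
    held-out 10% split, and training stops once it has not improved for
    ``config.patience`` epochs. The best-epoch weights are restored. If the
    epoch cap is reached without the validation plateau, the model is still
    returned but flagged unconverged with a :class:`TrainingWarning`.
    """
    if candidate.failed:
        raise UsageError("cannot train a candidate marked failed")
    if dataset.scaler is None:
        dataset = standardize(dataset)
    seed = config.seed if seed is None else seed
    X_train_raw, y_train = dataset.rows("train")
    X_val_raw, y_val = dataset.rows("val")
    X_train = dataset.scaler.transform(X_train_raw)
    have_val = len(X_val_raw) > 0
    X_val = dataset.scaler.transform(X_val_raw) if have_val else X_train
    y_watch = y_val if have_val else y_train
    est = _make_estimator(
        candidate.architecture, candidate.l2, candidate.learning_rate,
        batch=len(X_train), seed=seed, max_iter=1,
    )
    history: list[tuple[int, float, float]] = []
    best_val = np.inf
    best_epoch = -1
    best_weights: tuple | None = None
    stale = 0
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", _SkConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for epoch in range(1, config.max_epochs + 1):
            # One optimizer epoch; partial_fit keeps the Adam state alive
            # across calls (warm_start would reset the moment estimates).
            est.partial_fit(X_train, y_train)
            train_mse = float(mean_squared_error(y_train, est.predict(X_train)))
            val_mse = float(mean_squared_error(y_watch, est.predict(X_val)))
            history.append((epoch, train_mse, val_mse))
            if not np.isfinite(val_mse):
                break
            if val_mse < best_val - 1e-15:
                best_val = val_mse
                best_epoch = epoch
                best_weights = (
                    copy.deepcopy(est.coefs_), copy.deepcopy(est.intercepts_)
                )
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    converged = True
                    break
    if best_weights is None:
        raise UsageError("training never produced finite validation loss")
    if not converged:
        warnings.warn(
            f"validation loss still improving after {config.max_epochs} epochs; "
            "returning best weights so far",
            TrainingWarning,
            stacklevel=2,
        )
    coefs = tuple(np.asarray(w, dtype=float) for w in best_weights[0])
    intercepts = tuple(np.asarray(b, dtype=float).ravel() for b in best_weights[1])
    model = SurrogateModel(
        architecture=candidate.architecture,
        l2=candidate.l2,
        learning_rate=candidate.learning_rate,
        seed=seed,
        coefs=coefs,
        intercepts=intercepts,
        scaler=dataset.scaler,
        history=pd.DataFrame(history, columns=["epoch", "train_mse", "val_mse"]),
        metrics={},
        best_epoch=best_epoch,
        converged=converged,
    )
    metrics = {
        split: evaluate(model, dataset, split)
        for split in _SPLITS
        if dataset.n_rows(split) > 0
    }
    return replace(model, metrics=metrics)


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """R2 (= 1 - SS_res/SS_tot), RMSE and MSE."""
    mse = float(mean_squared_error(y, yhat))
    return {"R2": float(r2_score(y, yhat)), "RMSE": float(np.sqrt(mse)), "MSE": mse}


def evaluate(
    model: SurrogateModel, dataset: SurrogateDataset, split: str
) -> dict[str, float]:
    """R2, RMSE and MSE on the raw HQ scale for one split."""
    X_raw, y = dataset.rows(split)
    if len(y) == 0:
        raise UsageError(f"split {split!r} is empty")
    return regression_metrics(y, predict_hq(model, X_raw, warn=False))


def predict_hq(
    model: SurrogateModel,
    features: pd.DataFrame | np.ndarray | Mapping[str, float],
    warn: bool = True,
) -> np.ndarray:
    """Forward pass on raw-unit features (column order C, EF, IR, ED, BW, AT).

    Emits an :class:`ExtrapolationWarning` when any row lies outside the
    training hull widened by 20% per feature; the value is still returned.
    """
    if isinstance(features, Mapping):
        features = pd.DataFrame([features])
    if isinstance(features, pd.DataFrame):
        missing = set(model.scaler.names) - set(features.columns)
        if missing:
            raise UsageError(f"missing feature columns {sorted(missing)}")
        X = features[list(model.scaler.names)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != len(model.scaler.names):
        raise UsageError(
            f"expected {len(model.scaler.names)} features, got {X.shape[1]}"
        )
    if warn and model.scaler.hull_violations(X).any():
        warnings.warn(
            "some rows lie outside the training hull (+/-20%); "
            "surrogate output is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return _forward(model.scaler.transform(X), model.coefs, model.intercepts)
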