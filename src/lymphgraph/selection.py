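"""Feature selection: standardize, drop redundant features, then RFECV.

The 2048 deep features are first z-scored with statistics fitted on the
training cohort only. Redundancy is then removed with a pairwise Spearman
rank-correlation filter: whenever |rho| exceeds the cutoff (0.85), the
later-indexed member of the pair is dropped — a deterministic, order-stable
rule. The survivors go through recursive feature elimination with
cross-validation (RFECV): a linear SVM (C = 1) is fitted, the features with
the smallest |weight| are removed, and mean accuracy under 10-fold
stratified cross-validation is recorded at each feature count; the returned
subset is the one at the accuracy-optimal count (ties resolved toward fewer
features), never below ``min_features`` (3).

Elimination uses a two-phase step schedule — blocks of ``rfe_step`` (64)
columns at a time until 256 features remain, then one column per step —
since single-column elimination from 2048 features is needlessly slow and
the optimum sits well below 256. ``rfe_step=1`` recovers the pure schedule.

Estimator classes (`SpearmanRedundancyFilter`, `RfecvSelector`,
`FeatureSelector`) follow the scikit-learn fit/transform protocol; the
module-level functions are thin wrappers.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from ._utils import as_binary_labels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    spearman_cutoff: float = 0.85
    svm_C: float = 1.0
    cv_folds: int = 10
    min_features: int = 3
    rfe_step: int = 64
    rfe_fine_below: int = 256   # switch to single-column elimination here
    scoring: str = "accuracy"
    seed: int = 0
    n_features: int | str = "auto"  # "auto" = CV optimum; int = fixed count

    def __post_init__(self) -> None:
        if not 0.0 < self.spearman_cutoff < 1.0:
            raise ValueError("spearman_cutoff must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")
        if self.rfe_step < 1:
            raise ValueError("rfe_step must be >= 1")
        if isinstance(self.n_features, str) and self.n_features != "auto":
            raise ValueError("n_features must be 'auto' or an integer")


@dataclass
class SelectionResult:
    """Frozen output of the training-cohort selection, applicable to any
    cohort without refitting (no validation leakage)."""

    mean_: np.ndarray
    scale_: np.ndarray
    kept_after_spearman: np.ndarray   # indices into the original columns
    selected: np.ndarray              # indices into the original columns
    cv_curve: list[tuple[int, float]]

    def __post_init__(self) -> None:
        if not set(map(int, self.selected)) <= set(map(int, self.kept_after_spearman)):
            raise ValueError("selected features must survive the Spearman filter")
        if not self.cv_curve:
            raise ValueError("cv_curve must be non-empty")

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Standardize with training statistics, then keep selected columns."""
        X = np.asarray(X, dtype=float)
        Xs = (X - self.mean_[None, :]) / self.scale_[None, :]
        return Xs[:, self.selected]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "kept_after_spearman": [int(i) for i in self.kept_after_spearman],
            "selected": [int(i) for i in self.selected],
            "cv_curve": [[int(k), float(a)] for k, a in self.cv_curve],
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean_=np.asarray(payload["mean"], dtype=float),
            scale_=np.asarray(payload["scale"], dtype=float),
            kept_after_spearman=np.asarray(payload["kept_after_spearman"], dtype=int),
            selected=np.asarray(payload["selected"], dtype=int),
            cv_curve=[(int(k), float(a)) for k, a in payload["cv_curve"]],
        )


def fit_standardizer(X_train: np.ndarray) -> StandardScaler:
    """Fit a per-column z-scorer on the training matrix.

    Zero-variance columns get scale 1 (a warning is logged), so they pass
    through as mean-centred constants.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit the standardizer")
    scaler = StandardScaler().fit(X_train)
    zero_var = np.flatnonzero(scaler.var_ == 0)
    if zero_var.size:
        logger.warning("standardizer: %d zero-variance columns, scale set to 1", zero_var.size)
    return scaler


def apply_standardizer(scaler: StandardScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(np.asarray(X, dtype=float))


def spearman_filter(X: np.ndarray, cutoff: float = 0.85) -> np.ndarray:
    """Indices of columns surviving the pairwise |Spearman rho| <= cutoff rule.

    When a pair violates the cutoff the later-indexed column is dropped, so
    the result is deterministic and stable under column reordering of the
    survivors. Rank correlation makes the filter invariant to strictly
    monotone transformations of any column.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows for rank correlations")
    ranks = np.apply_along_axis(rankdata, 0, X)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.nan_to_num(rho, nan=0.0)  # constant columns correlate with nothing
    d = X.shape[1]
    keep = np.ones(d, dtype=bool)
    for j in range(d):
        if not keep[j]:
            continue
        earlier = np.flatnonzero(keep[:j])
        if earlier.size and np.any(np.abs(rho[earlier, j]) > cutoff):
            keep[j] = False
    return np.flatnonzero(keep)


def rfecv_select(
    X: np.ndarray, y: np.ndarray, cfg: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """RFECV on an already standardized, Spearman-filtered matrix.

    Note the returned ``SelectionResult`` from this low-level function has
    identity scaler statistics; use :class:`FeatureSelector` for the full
    standardize -> filter -> RFECV chain.
    """
    X = np.asarray(X, dtype=float)
    y = as_binary_labels(y)
    n, d = X.shape
    if n < cfg.cv_folds:
        raise ValueError(f"n_rows={n} < cv_folds={cfg.cv_folds}")

    fixed_k = None if cfg.n_features == "auto" else int(cfg.n_features)
    if fixed_k is not None and not (cfg.min_features <= fixed_k <= d):
        raise ValueError(f"fixed n_features={fixed_k} outside [{cfg.min_features}, {d}]")

    cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    svm = LinearSVC(C=cfg.svm_C, random_state=cfg.seed)

    current = np.arange(d)
    subsets: dict[int, np.ndarray] = {}
    cv_curve: list[tuple[int, float]] = []
    target = fixed_k if fixed_k is not None else cfg.min_features

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        while True:
            k = current.size
            subsets[k] = current.copy()
            if fixed_k is None:
                score = cross_val_score(svm, X[:, current], y, cv=cv, scoring=cfg.scoring).mean()
                cv_curve.append((k, float(score)))
            if k <= target:
                break
            if k > cfg.rfe_fine_below:
                next_k = max(target, cfg.rfe_fine_below, k - cfg.rfe_step)
            else:
                next_k = k - 1
            drop = k - next_k
            svm.fit(X[:, current], y)
            importance = np.abs(svm.coef_.ravel())
            order = np.argsort(importance, kind="stable")  # ascending |w|
            current = np.sort(current[order[drop:]])

        if fixed_k is None:
            best_acc = max(a for _, a in cv_curve)
            best_k = min(k for k, a in cv_curve if a == best_acc)  # ties -> fewer features
            selected = subsets[best_k]
        else:
            selected = subsets[fixed_k]
            score = cross_val_score(svm, X[:, selected], y, cv=cv, scoring=cfg.scoring).mean()
            cv_curve.append((fixed_k, float(score)))

    return SelectionResult(
        mean_=np.zeros(d),
        scale_=np.ones(d),
        kept_after_spearman=np.arange(d),
        selected=selected,
        cv_curve=cv_curve,
    )


class SpearmanRedundancyFilter(BaseEstimator, TransformerMixin):
    """Drops the later member of every feature pair with |Spearman rho| > cutoff."""

    def __init__(self, cutoff: float = 0.85):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        self.kept_indices_ = spearman_filter(np.asarray(X, dtype=float), self.cutoff)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from fit")
        return X[:, self.kept_indices_]


class RfecvSelector(BaseEstimator, TransformerMixin):
    """Recursive feature elimination with stratified CV under a linear SVM."""

    def __init__(self, config: SelectionConfig = SelectionConfig()):
        self.config = config

    def fit(self, X, y):
        res = rfecv_select(X, y, self.config)
        self.selected_indices_ = res.selected
        self.cv_curve_ = res.cv_curve
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from fit")
        return X[:, self.selected_indices_]


class FeatureSelector(BaseEstimator, TransformerMixin):
    """Full chain: standardize -> Spearman redundancy filter -> RFECV.

    Fitted on the training cohort only; ``transform`` applies the frozen
    training statistics and column choices to any cohort.
    """

    def __init__(self, config: SelectionConfig = SelectionConfig()):
        self.config = config

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = as_binary_labels(y)
        scaler = fit_standardizer(X)
        Xs = apply_standardizer(scaler, X)
        kept = spearman_filter(Xs, self.config.spearman_cutoff)
        inner = rfecv_select(Xs[:, kept], y, self.config)
        self.result_ = SelectionResult(
            mean_=scaler.mean_,
            scale_=scaler.scale_,
            kept_after_spearman=kept,
            selected=kept[inner.selected],
            cv_curve=inner.cv_curve,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from fit")
        return self.result_.transform(X)
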