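"""Classic tabular-ML comparison harness.

Feature tables concatenate normalised taxon abundances, normalised function
abundances, alpha-diversity metrics and environmental features.  Features are
min-max scaled to [0, 1] with parameters learned on the training portion
only, ranked by the univariate F statistic of a simple linear regression
against the target (F = r^2 / (1 - r^2) * (n - 2)), and reduced along a
coarse-to-fine schedule of feature counts, re-fitting the regressor with
5-fold cross-validation at each step.  Regressors themselves are delegated
to scikit-learn; the harness owns the protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR

from .dgcnn import split_data

logger = logging.getLogger(__name__)

__all__ = [
    "univariate_f",
    "select_k_best",
    "minmax01",
    "schedule_search",
    "mae_percent_of_range",
    "make_estimator",
    "tune_estimator",
    "pca_reduce",
    "assemble_features",
    "ScheduleResult",
    "PCA_VARIANCE_PRESETS",
]

#: Variance fractions offered for PCA-based feature reduction.
PCA_VARIANCE_PRESETS = (0.75, 0.80, 0.90, 0.95, 0.99, 0.995, 0.999, 0.9999)

ESTIMATOR_FAMILIES = {
    "svm": SVR,
    "random_forest": RandomForestRegressor,
    "gradient_boosting": GradientBoostingRegressor,
    "knn": KNeighborsRegressor,
    "gaussian_process": GaussianProcessRegressor,
}


def make_estimator(spec: dict):
    """Instantiate a scikit-learn regressor from ``{"name": ..., "params": {...}}``."""
    name = spec.get("name")
    if name not in ESTIMATOR_FAMILIES:
        raise ValueError(f"unknown estimator family {name!r}; choose from {sorted(ESTIMATOR_FAMILIES)}")
    params = dict(spec.get("params", {}))
    if name in ("random_forest", "gradient_boosting") and "random_state" not in params:
        params["random_state"] = 0
    return ESTIMATOR_FAMILIES[name](**params)


def univariate_f(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(F statistic, Pearson r) of the single-feature linear regression of y on x.

    A constant feature carries no information: returns (0, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0:
        logger.debug("constant feature; F set to 0")
        return 0.0, 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = min(r * r, 1.0 - 1e-15)
    f = r2 / (1.0 - r2) * (n - 2)
    return float(f), r


def _f_scores(table: pd.DataFrame, y: np.ndarray) -> pd.Series:
    scores = {c: univariate_f(table[c].to_numpy(), y)[0] for c in table.columns}
    return pd.Series(scores)


def select_k_best(table: pd.DataFrame, y: np.ndarray, k: int, signed: bool = False) -> pd.DataFrame:
    """Keep the k features with the largest F (ties broken by feature name).

    ``signed=True`` ranks by signed Pearson r instead (most positively
    correlated first).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > table.shape[1]:
        raise ValueError(f"k={k} exceeds feature count {table.shape[1]}")
    if signed:
        scores = pd.Series({c: univariate_f(table[c].to_numpy(), y)[1] for c in table.columns})
    else:
        scores = _f_scores(table, y)
    order = sorted(table.columns, key=lambda c: (-scores[c], c))
    return table[order[:k]]


def minmax01(train: pd.DataFrame, test: pd.DataFrame | None = None):
    """Scale columns to [0, 1] using training extrema only; no clipping of test."""
    scaler = MinMaxScaler()
    train_scaled = pd.DataFrame(
        scaler.fit_transform(train), index=train.index, columns=train.columns
    )
    if test is None:
        return train_scaled, None
    test_scaled = pd.DataFrame(
        scaler.transform(test), index=test.index, columns=test.columns
    )
    return train_scaled, test_scaled


@dataclass
class ScheduleResult:
    curve: pd.DataFrame  # k, train_mae, test_mae, cv_mean_mae, cv_sd_mae
    chosen_k: int
    selected_features: list[str]
    skipped: list[tuple[int, str]] = field(default_factory=list)


def schedule_search(
    table: pd.DataFrame,
    y: pd.Series,
    schedule: list[int],
    estimator_spec: dict,
    split_fraction: float = 0.85,
    split_seed: int = 40,
    folds: int = 5,
) -> ScheduleResult:
    """Feature-reduction curve over the schedule; chosen k minimises CV MAE.

    The schedule must be strictly decreasing and end at >= 1.  Selection and
    scaling are learned on the training split only.  Ties between k values go
    to the smaller k.  A k exceeding the feature count (or an estimator
    failure) is recorded and skipped.
    """
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("schedule must be strictly decreasing")
    if schedule[-1] < 1:
        raise ValueError("final schedule value must be >= 1")
    train_ids, test_ids = split_data(list(table.index), split_fraction, split_seed)
    X_tr, X_te = table.loc[train_ids], table.loc[test_ids]
    y_tr, y_te = y.loc[train_ids].to_numpy(), y.loc[test_ids].to_numpy()

    rows, skipped = [], []
    kf = KFold(n_splits=folds, shuffle=True, random_state=split_seed)
    features_by_k: dict[int, list[str]] = {}
    for k in schedule:
        if k > table.shape[1]:
            skipped.append((k, f"schedule exceeds feature count ({table.shape[1]})"))
            logger.warning("k=%d exceeds feature count %d; skipped", k, table.shape[1])
            continue
        try:
            sel = select_k_best(X_tr, y_tr, k)
            features_by_k[k] = list(sel.columns)
            tr_s, te_s = minmax01(sel, X_te[sel.columns])
            cv_maes = []
            for tr_i, va_i in kf.split(tr_s):
                est = make_estimator(estimator_spec)
                a_tr, a_va = minmax01(sel.iloc[tr_i], sel.iloc[va_i])
                est.fit(a_tr, y_tr[tr_i])
                cv_maes.append(float(np.mean(np.abs(est.predict(a_va) - y_tr[va_i]))))
            est = make_estimator(estimator_spec)
            est.fit(tr_s, y_tr)
            train_mae = float(np.mean(np.abs(est.predict(tr_s) - y_tr)))
            test_mae = float(np.mean(np.abs(est.predict(te_s) - y_te)))
            rows.append(
                {
                    "k": k,
                    "train_mae": train_mae,
                    "test_mae": test_mae,
                    "cv_mean_mae": float(np.mean(cv_maes)),
                    "cv_sd_mae": float(np.std(cv_maes)),
                }
            )
        except Exception as exc:  # estimator failure: record, continue
            skipped.append((k, str(exc)))
            logger.warning("estimator failed at k=%d: %s", k, exc)
    if not rows:
        raise ValueError("no schedule step succeeded")
    curve = pd.DataFrame(rows)
    best = curve.sort_values(["cv_mean_mae", "k"]).iloc[0]
    chosen_k = int(best["k"])
    return ScheduleResult(
        curve=curve,
        chosen_k=chosen_k,
        selected_features=features_by_k[chosen_k],
        skipped=skipped,
    )


def pca_reduce(train: pd.DataFrame, variance_fraction: float, test: pd.DataFrame | None = None):
    """Alternative reduction mode: project onto the fewest principal
    components explaining *variance_fraction* of the training variance.

    Returns component-score tables (columns ``PC1..PCk``); the decomposition
    is fitted on the training portion only.
    """
    if not (0 < variance_fraction < 1):
        raise ValueError("variance_fraction must be in (0, 1)")
    pca = PCA(n_components=variance_fraction, svd_solver="full")
    tr = pca.fit_transform(train)
    cols = [f"PC{i + 1}" for i in range(tr.shape[1])]
    tr = pd.DataFrame(tr, index=train.index, columns=cols)
    if test is None:
        return tr, None
    te = pd.DataFrame(pca.transform(test), index=test.index, columns=cols)
    return tr, te


def tune_estimator(
    table: pd.DataFrame,
    y: pd.Series | np.ndarray,
    spec: dict,
    grid: dict,
    folds: int = 5,
    split_seed: int = 40,
):
    """Grid-search an estimator family over *grid*, scored by CV MAE.

    A thin wrapper over the established grid-search implementation; returns
    ``(best_estimator, best_params, best_cv_mae)``.
    """
    base = make_estimator(spec)
    search = GridSearchCV(
        base,
        grid,
        scoring="neg_mean_absolute_error",
        cv=KFold(n_splits=folds, shuffle=True, random_state=split_seed),
    )
    search.fit(table, np.asarray(y))
    return search.best_estimator_, search.best_params_, -float(search.best_score_)


def mae_percent_of_range(mae: float, target_range: tuple[float, float]) -> float:
    """MAE expressed as a percentage of the target range, at one decimal."""
    low, high = target_range
    if high <= low:
        raise ValueError("target range must satisfy high > low")
    if mae < 0:
        raise ValueError("mae must be >= 0")
    return round(100.0 * mae / (high - low), 1)


def assemble_features(
    taxa: pd.DataFrame | None = None,
    functions: pd.DataFrame | None = None,
    diversity: pd.DataFrame | None = None,
    environment: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Column-wise concatenation of the available feature blocks.

    Blocks must share the same sample index; column names are prefixed by
    block to keep feature provenance visible and names unique.
    """
    blocks = {
        "taxon": taxa,
        "function": functions,
        "diversity": diversity,
        "env": environment,
    }
    parts = []
    index = None
    for prefix, block in blocks.items():
        if block is None:
            continue
        if index is None:
            index = block.index
        elif not block.index.equals(index):
            raise ValueError(f"feature block {prefix!r} has a mismatched sample index")
        parts.append(block.add_prefix(f"{prefix}:"))
    if not parts:
        raise ValueError("no feature blocks provided")
    return pd.concat(parts, axis=1)
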