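"""Host-gene prediction of community states and microbial loads.

A randomized-forest learner (bagged decision trees with per-split
feature subsetting of size ``mtry``) predicts either the categorical
community state (classification) or a log-scale bacterial/viral load
(regression) from the host-gene expression panel.  Around that standard
learner sit the bespoke pieces:

* repeated k-fold cross-validated tuning of ``mtry`` and ``ntrees``;
* Boruta all-relevant feature selection against shadow (column-shuffled)
  copies of every gene, with a binomial hit test and a rough fix for
  tentative genes;
* percentile confidence intervals of importance over repeated refits;
* stepwise-AIC additive linear models relating selected genes to loads.

Importance is the per-tree out-of-bag permutation importance normalized
by its standard deviation across trees (a Z score); mean-decrease-impurity
is exposed as an alternative but is not the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import BaggingClassifier, BaggingRegressor
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor
import statsmodels.api as sm

from .core_io import ValidationError


@dataclass
class ForestSpec:
    task: str = "classification"  # or "regression"
    ntrees: int = 500
    mtry: int | None = None  # None -> sqrt(p) / p/3 heuristic
    cv_folds: int = 10
    cv_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValidationError(f"unknown task {self.task!r}")
        if self.ntrees < 100:
            raise ValidationError("ntrees must be >= 100")
        if self.mtry is not None and self.mtry < 1:
            raise ValidationError("mtry must be >= 1")


@dataclass
class BorutaReport:
    decisions: dict[str, str]  # feature -> Confirmed/Rejected (after rough fix)
    raw_decisions: dict[str, str]  # incl. Tentative, pre rough fix
    hits: dict[str, int]
    n_iter: int
    alpha: float
    max_iter: int
    z_history: pd.DataFrame  # iterations x features
    shadow_max: list[float]
    shadow_mean: list[float]
    shadow_min: list[float]

    def confirmed(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == "Confirmed"]


@dataclass
class ImportanceInterval:
    feature: str
    median: float
    lower: float
    upper: float
    level: float


@dataclass
class LinearModelReport:
    selected: list[str]
    coefficients: dict[str, float]
    aic: float
    t_values: dict[str, float]
    p_values: dict[str, float]
    visited_aic: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# forest learner wrapper
# ---------------------------------------------------------------------------


def _default_mtry(p: int, task: str) -> int:
    return max(1, int(np.sqrt(p)) if task == "classification" else p // 3)


def fit_forest(X: np.ndarray, y: np.ndarray, spec: ForestSpec, oob: bool = False):
    """Bagged trees with per-split random feature subsetting of size mtry."""
    p = X.shape[1]
    mtry = min(spec.mtry or _default_mtry(p, spec.task), p)
    if spec.task == "classification":
        base = DecisionTreeClassifier(max_features=mtry)
        model = BaggingClassifier(
            estimator=base,
            n_estimators=spec.ntrees,
            bootstrap=True,
            oob_score=oob,
            random_state=spec.seed,
            n_jobs=1,
        )
    else:
        base = DecisionTreeRegressor(max_features=mtry)
        model = BaggingRegressor(
            estimator=base,
            n_estimators=spec.ntrees,
            bootstrap=True,
            oob_score=oob,
            random_state=spec.seed,
            n_jobs=1,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse-OOB warnings at small ntrees
        model.fit(X, y)
    return model


def per_tree_importance(model, X: np.ndarray, y: np.ndarray, seed: int = 0) -> np.ndarray:
    """(ntrees, p) out-of-bag permutation importances.

    For every tree: score its OOB samples (accuracy for classification,
    negative MSE for regression), permute one feature at a time, and
    record the score drop.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    is_clf = hasattr(model, "classes_")
    if is_clf:
        # base estimators see label-encoded classes
        y = np.searchsorted(model.classes_, y)
    out = np.zeros((len(model.estimators_), p))
    for t, (est, samp) in enumerate(zip(model.estimators_, model.estimators_samples_)):
        oob = np.setdiff1d(np.arange(n), samp)
        if len(oob) < 2:
            continue
        Xo, yo = X[oob], y[oob]
        pred = est.predict(Xo)
        base = (pred == yo).mean() if is_clf else -((pred - yo) ** 2).mean()
        m = len(oob)
        stacked = np.tile(Xo, (p, 1))
        for f in range(p):
            perm = rng.permutation(m)
            stacked[f * m:(f + 1) * m, f] = Xo[perm, f]
        preds = est.predict(stacked).reshape(p, m)
        if is_clf:
            scores = (preds == yo).mean(axis=1)
        else:
            scores = -((preds - yo) ** 2).mean(axis=1)
        out[t] = base - scores
    return out


def z_importance(imp: np.ndarray) -> np.ndarray:
    """Boruta-style Z: mean per-tree importance over its SD across trees."""
    mean = imp.mean(axis=0)
    sd = imp.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.inf)
    z = mean / sd
    return np.where(np.isfinite(z), z, 0.0)


def mdi_importance(model) -> np.ndarray:
    """Mean-decrease-impurity alternative (mean over trees)."""
    return np.mean([est.feature_importances_ for est in model.estimators_], axis=0)


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------


def tune_forest(
    X,
    y,
    spec: ForestSpec,
    mtry_grid=None,
    ntrees_grid=None,
) -> tuple[ForestSpec, pd.DataFrame]:
    """Repeated k-fold CV over an (mtry, ntrees) grid.

    Classification is scored by accuracy, regression by RMSE and R^2;
    the best spec (max accuracy / min RMSE) is returned with the full
    trace.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValidationError("X contains missing values; impute or drop first")
    n, p = X.shape
    mtry_grid = list(mtry_grid or sorted({_default_mtry(p, spec.task), max(1, p // 2), p}))
    ntrees_grid = list(ntrees_grid or [spec.ntrees])
    if spec.task == "classification":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < spec.cv_folds:
            raise ValidationError(
                f"smallest class has {counts.min()} members; use cv_folds <= that "
                "or merge rare classes"
            )
    rows = []
    for mtry, ntrees in product(mtry_grid, ntrees_grid):
        metrics = []
        for rep in range(spec.cv_repeats):
            if spec.task == "classification":
                cv = StratifiedKFold(
                    spec.cv_folds, shuffle=True, random_state=spec.seed + rep
                )
            else:
                cv = KFold(spec.cv_folds, shuffle=True, random_state=spec.seed + rep)
            for tr, te in cv.split(X, y):
                sub = replace(spec, mtry=mtry, ntrees=ntrees, seed=spec.seed + rep)
                model = fit_forest(X[tr], y[tr], sub)
                pred = model.predict(X[te])
                if spec.task == "classification":
                    metrics.append({"accuracy": float((pred == y[te]).mean())})
                else:
                    resid = y[te].astype(float) - pred
                    ss_tot = ((y[te].astype(float) - y[tr].astype(float).mean()) ** 2).sum()
                    metrics.append(
                        {
                            "rmse": float(np.sqrt((resid**2).mean())),
                            "r2": float(1 - (resid**2).sum() / ss_tot)
                            if ss_tot > 0
                            else 0.0,
                        }
                    )
        agg = pd.DataFrame(metrics).mean().to_dict()
        rows.append({"mtry": mtry, "ntrees": ntrees, **agg})
    trace = pd.DataFrame(rows)
    if spec.task == "classification":
        best = trace.loc[trace["accuracy"].idxmax()]
    else:
        best = trace.loc[trace["rmse"].idxmin()]
    best_spec = replace(spec, mtry=int(best["mtry"]), ntrees=int(best["ntrees"]))
    return best_spec, trace


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------


def boruta_select(
    X,
    y,
    spec: ForestSpec,
    alpha: float = 0.01,
    max_iter: int = 100,
    seed: int = 0,
) -> BorutaReport:
    """All-relevant feature selection against shadow features.

    Each iteration appends a column-shuffled shadow copy of every
    feature, fits the forest on the doubled matrix, and scores a "hit"
    for any real feature whose importance Z exceeds the iteration's
    shadowMax.  Accumulated hits are tested against Binomial(iters, 0.5)
    two-sided at ``alpha``: significantly many -> Confirmed,
    significantly few -> Rejected.  Features still undecided after
    ``max_iter`` are Tentative and resolved by comparing their median Z
    to the median shadowMax (rough fix).
    """
    if max_iter < 10:
        raise ValidationError("max_iter < 10 leaves the hit test under-powered")
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    if not np.isfinite(X).all():
        raise ValidationError("X contains missing values; impute or drop first")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    hits = np.zeros(p, dtype=int)
    decided = np.array([""] * p, dtype=object)
    z_rows, smax, smean, smin = [], [], [], []
    it = 0
    for it in range(1, max_iter + 1):
        shadow = X.copy()
        for f in range(p):
            shadow[:, f] = X[rng.permutation(n), f]
        Xall = np.hstack([X, shadow])
        sub = replace(spec, seed=int(rng.integers(2**31 - 1)))
        model = fit_forest(Xall, y, sub)
        imp = per_tree_importance(model, Xall, y, seed=int(rng.integers(2**31 - 1)))
        z = z_importance(imp)
        z_real, z_shadow = z[:p], z[p:]
        z_rows.append(z_real)
        smax.append(float(z_shadow.max()))
        smean.append(float(z_shadow.mean()))
        smin.append(float(z_shadow.min()))
        hits += z_real > z_shadow.max()
        if it >= 5:
            for f in range(p):
                if decided[f]:
                    continue
                test = stats.binomtest(int(hits[f]), it, 0.5)
                if test.pvalue < alpha:
                    decided[f] = "Confirmed" if hits[f] > it / 2 else "Rejected"
            if all(decided):
                break
    z_history = pd.DataFrame(z_rows, columns=names)
    raw = {
        names[f]: (decided[f] or "Tentative") for f in range(p)
    }
    median_shadow_max = float(np.median(smax))
    final = dict(raw)
    for f in range(p):
        if raw[names[f]] == "Tentative":
            final[names[f]] = (
                "Confirmed"
                if float(z_history[names[f]].median()) > median_shadow_max
                else "Rejected"
            )
    return BorutaReport(
        decisions=final,
        raw_decisions=raw,
        hits={names[f]: int(hits[f]) for f in range(p)},
        n_iter=it,
        alpha=alpha,
        max_iter=max_iter,
        z_history=z_history,
        shadow_max=smax,
        shadow_mean=smean,
        shadow_min=smin,
    )


# ---------------------------------------------------------------------------
# importance intervals
# ---------------------------------------------------------------------------


def importance_intervals(
    X,
    y,
    spec: ForestSpec,
    n_refits: int = 100,
    level: float = 0.99,
    seed: int = 0,
) -> tuple[list[ImportanceInterval], dict[str, float]]:
    """Percentile CIs of importance Z over repeated refits.

    Also summarizes out-of-bag performance across refits: mean OOB
    accuracy with per-class recall for classification, or mean OOB
    percent variance explained for regression.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    zs, oob_scores = [], []
    per_class: dict[str, list[float]] = {}
    for _ in range(n_refits):
        sub = replace(spec, seed=int(rng.integers(2**31 - 1)))
        model = fit_forest(X, y, sub, oob=True)
        imp = per_tree_importance(model, X, y, seed=int(rng.integers(2**31 - 1)))
        zs.append(z_importance(imp))
        oob_scores.append(float(model.oob_score_))
        if spec.task == "classification":
            oob_pred = model.classes_[model.oob_decision_function_.argmax(axis=1)]
            for cls in model.classes_:
                m = y == cls
                per_class.setdefault(str(cls), []).append(
                    float((oob_pred[m] == y[m]).mean())
                )
    Z = np.asarray(zs)
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    intervals = [
        ImportanceInterval(
            feature=names[f],
            median=float(np.median(Z[:, f])),
            lower=float(np.percentile(Z[:, f], lo)),
            upper=float(np.percentile(Z[:, f], hi)),
            level=level,
        )
        for f in range(len(names))
    ]
    summary: dict[str, float] = {}
    if spec.task == "classification":
        summary["oob_accuracy"] = float(np.mean(oob_scores))
        for cls, vals in per_class.items():
            summary[f"oob_recall_{cls}"] = float(np.mean(vals))
    else:
        summary["oob_pct_variance_explained"] = float(np.mean(oob_scores)) * 100.0
    return intervals, summary


# ---------------------------------------------------------------------------
# radar-style median normalization and stepwise AIC
# ---------------------------------------------------------------------------


def median_normalize_expression(medians: pd.DataFrame) -> pd.DataFrame:
    """Normalize gene x state medians so each gene's largest median is 1.

    Genes whose maximum median is <= 0 cannot be scaled this way and are
    emitted as missing with a warning.
    """
    out = medians.astype(float).copy()
    for gene, row in out.iterrows():
        m = row.max()
        if not np.isfinite(m) or m <= 0:
            warnings.warn(f"gene {gene!r} has non-positive max median", stacklevel=2)
            out.loc[gene] = np.nan
        else:
            out.loc[gene] = row / m
    return out


def linear_aic(rss: float, n: int, k: int) -> float:
    """AIC = n ln(RSS/n) + 2 (k + 1), k = number of predictor terms."""
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2.0 * (k + 1)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    return float(((y - X @ coef) ** 2).sum())


def stepwise_aic_fit(X, y, candidates=None) -> LinearModelReport:
    """Bidirectional stepwise selection of additive terms by AIC.

    Starting from the intercept-only model, each step evaluates adding
    any excluded term and dropping any included term, taking the move
    with the lowest AIC until no move improves.  The final model is
    refit by OLS to report coefficients and t statistics.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if candidates is not None:
        keep = [names.index(c) for c in candidates]
        X, names = X[:, keep], [names[i] for i in keep]
        p = len(names)
    if n <= p + 2:
        raise ValidationError(f"n={n} too small for {p} candidate terms")

    def aic_of(idx: tuple[int, ...]) -> float:
        design = np.hstack([np.ones((n, 1)), X[:, list(idx)]]) if idx else np.ones((n, 1))
        return linear_aic(_ols_rss(design, y), n, len(idx))

    current: tuple[int, ...] = ()
    current_aic = aic_of(current)
    visited = [current_aic]
    while p > 0:
        moves = []
        for j in range(p):
            if j in current:
                moves.append(tuple(i for i in current if i != j))
            else:
                moves.append(tuple(sorted(current + (j,))))
        scored = [(aic_of(m), m) for m in set(moves)]
        best_aic, best_move = min(scored, key=lambda t: (t[0], t[1]))
        visited.extend(a for a, _ in scored)
        if best_aic < current_aic - 1e-10:
            current, current_aic = best_move, best_aic
        else:
            break

    sel = [names[i] for i in current]
    design = sm.add_constant(
        pd.DataFrame(X[:, list(current)], columns=sel), has_constant="add"
    )
    fit = sm.OLS(y, design).fit()
    return LinearModelReport(
        selected=sel,
        coefficients={k: float(v) for k, v in fit.params.items()},
        aic=float(current_aic),
        t_values={k: float(v) for k, v in fit.tvalues.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        visited_aic=visited,
    )


__all__ = [
    "BorutaReport",
    "ForestSpec",
    "ImportanceInterval",
    "LinearModelReport",
    "boruta_select",
    "fit_forest",
    "importance_intervals",
    "linear_aic",
    "mdi_importance",
    "median_normalize_expression",
    "per_tree_importance",
    "stepwise_aic_fit",
    "tune_forest",
    "z_importance",
]
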