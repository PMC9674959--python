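"""Penalized classification/regression with repeated random-subsampling evaluation.

The classifier is an L1 (lasso) penalized logistic regression minimizing

    (1/n) * sum_i -log P(y_i | x_i, beta) + lambda * sum_j |beta_j|

with the intercept unpenalized; the regression analogue minimizes mean squared
error plus the same penalty.  Because features are min-max scaled to [0, 1]
before fitting, coefficient magnitudes are directly comparable and serve as
feature importances.

Evaluation follows a repeated random-subsampling protocol: many independent
stratified train/test splits; per split the scaling is fitted on the training
rows only, the penalty weight is tuned by inner cross-validation on the
training rows, a probability cutoff is chosen on the training scores by
maximizing sensitivity + specificity, and the metric suite (AUC, accuracy,
sensitivity, specificity, PPV, NPV, MCC) is computed on the held-out rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix

POSITIVE_CLASS_DOC = "the positive class is LOF (function below threshold)"

#: Default penalty-weight grid (log-spaced); tuned by inner CV.
DEFAULT_LAMBDA_GRID: np.ndarray = np.logspace(-4, 0.5, 50)


class DegenerateLabelsError(ValueError):
    """Only one class present where two are required."""


# ---------------------------------------------------------------------------
# Core fits

def _check_X_y(X: pd.DataFrame, y: np.ndarray, need_both_classes: bool = True):
    Xv = np.asarray(X, dtype=float)
    if not np.isfinite(Xv).all():
        raise ValueError("feature matrix contains non-finite values")
    y = np.asarray(y)
    if need_both_classes and len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels contain a single class")
    return Xv, y


@dataclass
class PenalizedModel:
    """A fitted sparse linear model (classification or regression)."""

    task: str  # "classification" | "regression"
    intercept: float
    coefficients: dict[str, float]
    lam: float
    cutoff: float | None = None  # probability threshold, classification only
    scaling: dict | None = None  # per-feature {"min","max","impute_mean"}

    def _linear(self, X: pd.DataFrame) -> np.ndarray:
        cols = list(self.coefficients)
        beta = np.array([self.coefficients[c] for c in cols])
        if list(X.columns) == cols:
            Xv = X.to_numpy(dtype=float)
        else:
            missing = [c for c in cols if c not in X.columns]
            if missing:
                raise ValueError(f"feature columns missing from input: {missing}")
            Xv = X[cols].to_numpy(dtype=float)
        return self.intercept + Xv @ beta

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """P(positive class) for scaled feature rows; classification only."""
        if self.task != "classification":
            raise ValueError("predict_proba is for classification models")
        from scipy.special import expit

        return expit(self._linear(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.task == "classification":
            if self.cutoff is None:
                raise ValueError("no cutoff set on this classifier")
            return self.predict_proba(X) >= self.cutoff
        return self._linear(X)

    def nonzero_features(self, tol: float = 0.0) -> list[str]:
        return [k for k, v in self.coefficients.items() if abs(v) > tol]

    def to_json(self, path: str | Path | None = None, **extra) -> str:
        payload = {
            "task": self.task,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "lambda": self.lam,
            "cutoff": self.cutoff,
            "scaling": self.scaling,
            **extra,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PenalizedModel":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            task=payload["task"],
            intercept=payload["intercept"],
            coefficients=payload["coefficients"],
            lam=payload["lambda"],
            cutoff=payload.get("cutoff"),
            scaling=payload.get("scaling"),
        )


def fit_penalized_logistic(
    X: pd.DataFrame, y: Sequence[bool], lam: float, *, tol: float = 1e-7
) -> PenalizedModel:
    """L1-penalized logistic regression (intercept unpenalized).

    ``lam`` weights the penalty against the *mean* negative log-likelihood,
    so results are comparable across sample sizes.  ``lam == 0`` gives the
    unpenalized maximum-likelihood fit.  Deterministic given (X, y, lam).
    """
    from sklearn.linear_model import LogisticRegression

    Xv, y = _check_X_y(X, np.asarray(y, dtype=bool))
    n = len(y)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000, tol=tol)
    else:
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (n * lam),
            solver="liblinear",
            # liblinear penalizes the intercept via an augmented column; a large
            # scaling makes that contribution negligible (intercept unpenalized)
            intercept_scaling=1000.0,
            max_iter=10000,
            tol=tol,
            random_state=0,
        )
    clf.fit(Xv, y)
    beta = clf.coef_[0]
    intercept = _refine_intercept(Xv, y, beta, float(clf.intercept_[0]))
    return PenalizedModel(
        task="classification",
        intercept=intercept,
        coefficients=dict(zip(X.columns, beta.tolist())),
        lam=float(lam),
    )


def _refine_intercept(Xv: np.ndarray, y: np.ndarray, beta: np.ndarray, b0: float) -> float:
    """Exact unpenalized intercept given fixed coefficients (1-D Newton).

    liblinear only approximates an unpenalized intercept (augmented-column
    trick); this final coordinate pass removes the residual shrinkage.
    """
    from scipy.special import expit

    eta = Xv @ beta
    yf = y.astype(float)
    b = b0
    for _ in range(100):
        p = expit(eta + b)
        grad = float(np.mean(p - yf))
        hess = float(np.mean(p * (1 - p)))
        if hess < 1e-12:
            break
        step = grad / hess
        b -= step
        if abs(step) < 1e-12:
            break
    return float(b)


def fit_penalized_linear(
    X: pd.DataFrame, y: Sequence[float], lam: float, *, tol: float = 1e-10
) -> PenalizedModel:
    """L1-penalized linear regression minimizing MSE + lam * ||beta||_1."""
    from sklearn.linear_model import Lasso, LinearRegression

    Xv, y = _check_X_y(X, np.asarray(y, dtype=float), need_both_classes=False)
    if len(y) < 2:
        raise ValueError("need n >= 2 observations")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        reg = LinearRegression()
    else:
        # sklearn's Lasso objective is (1/2n)*RSS + alpha*||beta||_1;
        # ours is (1/n)*RSS + lam*||beta||_1, hence alpha = lam / 2.
        reg = Lasso(alpha=lam / 2.0, max_iter=100000, tol=tol)
    reg.fit(Xv, y)
    return PenalizedModel(
        task="regression",
        intercept=float(reg.intercept_),
        coefficients=dict(zip(X.columns, np.ravel(reg.coef_).tolist())),
        lam=float(lam),
    )


def r_squared(pred: Sequence[float], y: Sequence[float]) -> float:
    """Proportion of variance in measured values explained by predictions."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant observations")
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# Cutoff and metrics

def select_cutoff(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Probability cutoff maximizing sensitivity + specificity.

    All midpoints between adjacent sorted unique scores are evaluated, plus
    -inf/+inf sentinels; a row is predicted positive when score >= cutoff.
    Ties go to the smallest such cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("cutoff selection needs both classes")
    uniq = np.unique(s)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    n_pos, n_neg = y.sum(), (~y).sum()
    best_c, best_j = None, -np.inf
    for c in candidates:
        pred = s >= c
        sens = (pred & y).sum() / n_pos
        spec = (~pred & ~y).sum() / n_neg
        j = sens + spec
        if j > best_j + 1e-12:
            best_j, best_c = j, float(c)
    return best_c


@dataclass
class MetricSet:
    """Binary-classification metric suite; LOF is the positive class.

    Undefined ratios (zero denominator) are NaN, never silently 0.
    """

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "mcc": self.mcc,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float
) -> MetricSet:
    """Confusion-matrix metrics at ``cutoff`` plus rank-statistic AUC.

    AUC is the Mann-Whitney statistic with midrank ties (equivalently the
    area under the empirical ROC curve).
    """
    from sklearn.metrics import roc_auc_score

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("metrics need both classes present")
    pred = s >= cutoff
    tp = int((pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    n = tp + tn + fp + fn
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")
    return MetricSet(
        auc=float(roc_auc_score(y, s)),
        accuracy=(tp + tn) / n,
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        mcc=float(mcc),
    )


# ---------------------------------------------------------------------------
# Lambda tuning

@dataclass(frozen=True)
class TuneConfig:
    """Inner cross-validation shape for penalty-weight tuning."""

    grid: tuple[float, ...] = tuple(DEFAULT_LAMBDA_GRID)
    folds: int = 5
    repeats: int = 5


def tune_lambda(
    X: pd.DataFrame,
    y: Sequence[bool],
    grid: Sequence[float] | None = None,
    *,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    task: str = "classification",
) -> float:
    """Penalty weight maximizing mean cross-validated AUC (classification) or
    minimizing mean CV squared error (regression); AUC ties break toward the
    larger (sparser) lambda."""
    from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold

    if grid is None:
        grid = DEFAULT_LAMBDA_GRID
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("empty lambda grid")
    if len(grid) == 1:
        return grid[0]
    y_arr = np.asarray(y)
    if task == "classification":
        cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    else:
        cv = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(np.zeros(len(y_arr)), y_arr))
    scores_per_lam: dict[float, list[float]] = {g: [] for g in grid}
    from sklearn.metrics import roc_auc_score

    for tr, va in splits:
        X_tr, X_va = X.iloc[tr], X.iloc[va]
        y_tr, y_va = y_arr[tr], y_arr[va]
        if task == "classification" and (
            len(np.unique(y_tr)) < 2 or len(np.unique(y_va)) < 2
        ):
            continue
        for g in grid:
            if task == "classification":
                m = fit_penalized_logistic(X_tr, y_tr, g)
                scores_per_lam[g].append(
                    float(roc_auc_score(y_va, m.predict_proba(X_va)))
                )
            else:
                m = fit_penalized_linear(X_tr, y_tr, g)
                scores_per_lam[g].append(
                    -float(np.mean((m.predict(X_va) - y_va) ** 2))
                )
    means = {g: np.mean(v) for g, v in scores_per_lam.items() if v}
    if not means:
        raise RuntimeError("all inner folds degenerate; cannot tune lambda")
    best = max(means.values())
    # ties toward larger lambda -> sparser model
    return max(g for g, m in means.items() if m >= best - 1e-12)


# ---------------------------------------------------------------------------
# Repeated random-subsampling evaluation

@dataclass
class EvaluationReport:
    """Per-split metrics and coefficients from repeated subsampling."""

    metrics: pd.DataFrame  # one row per split
    coefficients: pd.DataFrame | None  # one row per split (sparse models only)
    cutoffs: list[float]
    lambdas: list[float]
    n_train: int
    n_test: int
    seed: int

    def aggregate(self) -> pd.DataFrame:
        """Mean and SD of each metric across splits (NaN-aware)."""
        return pd.DataFrame(
            {"mean": self.metrics.mean(), "sd": self.metrics.std(ddof=1)}
        )

    def metrics_tsv(self, path: str | Path) -> None:
        self.metrics.to_csv(path, sep="\t", index_label="split")

    def summary_json(self, path: str | Path | None = None) -> str:
        agg = self.aggregate()
        payload = {
            "n_splits": len(self.metrics),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
            "metrics": {
                m: {"mean": float(agg.loc[m, "mean"]), "sd": float(agg.loc[m, "sd"])}
                for m in agg.index
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _penalized_factory(tune: TuneConfig | None, lam: float | None):
    """Fit function for the sparse logistic path (optionally tuned)."""

    def fit(X_tr: pd.DataFrame, y_tr: np.ndarray, seed: int) -> PenalizedModel:
        g = lam
        if tune is not None:
            g = tune_lambda(
                X_tr, y_tr, tune.grid, folds=tune.folds, repeats=tune.repeats, seed=seed
            )
        elif g is None:
            g = 0.01
        return fit_penalized_logistic(X_tr, y_tr, g)

    return fit


def make_sklearn_factory(estimator_cls, **params):
    """Adapter letting tree ensembles (or any probabilistic scikit-learn
    classifier) run under the same evaluation protocol."""

    class _Wrapped:
        def __init__(self, est):
            self.est = est
            self.lam = float("nan")
            self.coefficients = None

        def predict_proba(self, X):
            return self.est.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def fit(X_tr: pd.DataFrame, y_tr: np.ndarray, seed: int):
        est = estimator_cls(random_state=seed, **params)
        est.fit(np.asarray(X_tr, dtype=float), y_tr)
        return _Wrapped(est)

    return fit


def repeated_evaluation(
    X_raw: pd.DataFrame,
    y: Sequence[bool],
    *,
    iterations: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
    tune: TuneConfig | None = TuneConfig(),
    lam: float | None = None,
    fit_fn: Callable | None = None,
    stratify: bool = True,
    cutoff_on_test: bool = False,
    max_resplits: int = 25,
) -> EvaluationReport:
    """Repeated stratified random train/test subsampling.

    Per split: min-max scaling fitted on the training rows only; the penalty
    weight tuned on the training rows (inner CV); the cutoff chosen on
    training scores (``cutoff_on_test=True`` reproduces the leaky variant
    that chooses it on test scores); the metric suite computed on held-out
    rows.  Bit-reproducible for a fixed seed.
    """
    from sklearn.model_selection import StratifiedShuffleSplit, ShuffleSplit

    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    y_arr = np.asarray(y, dtype=bool)
    if len(np.unique(y_arr)) < 2:
        raise DegenerateLabelsError("labels contain a single class")
    if fit_fn is None:
        fit_fn = _penalized_factory(tune, lam)

    rng = np.random.default_rng(seed)
    metric_rows, coef_rows, cutoffs, lambdas = [], [], [], []
    n_train = n_test = 0
    for it in range(iterations):
        sub_seed = int(rng.integers(2**31 - 1))
        splitter_cls = StratifiedShuffleSplit if stratify else ShuffleSplit
        ok = False
        for attempt in range(max_resplits):
            sp = splitter_cls(
                n_splits=1, test_size=test_fraction, random_state=sub_seed + attempt
            )
            tr, te = next(sp.split(np.zeros(len(y_arr)), y_arr))
            if len(np.unique(y_arr[tr])) == 2 and len(np.unique(y_arr[te])) == 2:
                ok = True
                break
        if not ok:
            raise RuntimeError("could not produce a split with both classes on each side")
        n_train, n_test = len(tr), len(te)
        fm = FeatureMatrix(X_raw.iloc[tr]).fit_scaling()
        Xs_tr = fm.transform()
        Xs_te = fm.transform(X_raw.iloc[te])
        model = fit_fn(Xs_tr, y_arr[tr], sub_seed)
        s_tr = model.predict_proba(Xs_tr)
        s_te = model.predict_proba(Xs_te)
        cutoff = select_cutoff(
            s_te if cutoff_on_test else s_tr, y_arr[te] if cutoff_on_test else y_arr[tr]
        )
        ms = compute_metrics(s_te, y_arr[te], cutoff)
        metric_rows.append(ms.as_dict())
        cutoffs.append(cutoff)
        lambdas.append(getattr(model, "lam", float("nan")))
        coefs = getattr(model, "coefficients", None)
        if coefs is not None:
            coef_rows.append(coefs)
    coefficients = pd.DataFrame(coef_rows) if coef_rows else None
    return EvaluationReport(
        metrics=pd.DataFrame(metric_rows),
        coefficients=coefficients,
        cutoffs=cutoffs,
        lambdas=lambdas,
        n_train=n_train,
        n_test=n_test,
        seed=seed,
    )


def train_final_classifier(
    X_raw: pd.DataFrame,
    y: Sequence[bool],
    *,
    tune: TuneConfig | None = TuneConfig(),
    lam: float | None = None,
    seed: int = 0,
) -> tuple[PenalizedModel, FeatureMatrix]:
    """Fit the deployable classifier on all rows: scale on everything, tune
    the penalty, fit, and choose the cutoff on the full-sample scores."""
    y_arr = np.asarray(y, dtype=bool)
    fm = FeatureMatrix(X_raw).fit_scaling()
    Xs = fm.transform()
    g = lam
    if tune is not None:
        g = tune_lambda(Xs, y_arr, tune.grid, folds=tune.folds, repeats=tune.repeats, seed=seed)
    elif g is None:
        g = 0.01
    model = fit_penalized_logistic(Xs, y_arr, g)
    model.cutoff = select_cutoff(model.predict_proba(Xs), y_arr)
    model.scaling = fm.scaling_params()
    return model, fm


# ---------------------------------------------------------------------------
# Model-selection grid, importance, localization

def model_selection(
    feature_tables: Mapping[str, pd.DataFrame],
    y: Sequence[bool],
    *,
    model_types: Sequence[str] = ("penalized", "random_forest", "gradient_boosting"),
    iterations: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
    tune: TuneConfig | None = TuneConfig(),
) -> pd.DataFrame:
    """Evaluate every (model type, feature set) cell and rank by mean test AUC.

    ``feature_tables`` maps feature-set name -> raw feature table; a missing
    table marks the cell unavailable (NaN AUC) rather than skipping it.
    """
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

    factories = {
        "penalized": None,  # handled by the sparse-logistic path
        "random_forest": make_sklearn_factory(RandomForestClassifier, n_estimators=300),
        "gradient_boosting": make_sklearn_factory(GradientBoostingClassifier),
    }
    rows = []
    for mt in model_types:
        if mt not in factories:
            raise ValueError(f"unknown model type {mt!r}")
        for fs_name in sorted(feature_tables):
            X_raw = feature_tables[fs_name]
            if X_raw is None:
                rows.append(
                    {"model": mt, "feature_set": fs_name, "mean_auc": float("nan"),
                     "sd_auc": float("nan"), "available": False}
                )
                continue
            rep = repeated_evaluation(
                X_raw,
                y,
                iterations=iterations,
                test_fraction=test_fraction,
                seed=seed,
                tune=tune if mt == "penalized" else None,
                fit_fn=None if mt == "penalized" else factories[mt],
            )
            agg = rep.aggregate()
            rows.append(
                {
                    "model": mt,
                    "feature_set": fs_name,
                    "mean_auc": float(agg.loc["auc", "mean"]),
                    "sd_auc": float(agg.loc["auc", "sd"]),
                    "available": True,
                }
            )
    out = pd.DataFrame(rows).sort_values("mean_auc", ascending=False, kind="mergesort")
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)


def feature_importance(report: EvaluationReport) -> pd.DataFrame:
    """Coefficient-distribution summary across splits, per feature.

    Whiskers extend to the most extreme coefficient no more than 1.5 * IQR
    beyond the quartiles (Tukey box-plot convention); ``frac_nonzero`` is the
    fraction of splits in which the feature survived the L1 penalty.
    Features sort by |median| descending.
    """
    if report.coefficients is None:
        raise ValueError("report holds no per-split coefficients")
    C = report.coefficients
    rows = []
    for feat in C.columns:
        v = C[feat].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        in_lo = v[v >= lo_lim]
        in_hi = v[v <= hi_lim]
        rows.append(
            {
                "feature": feat,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": float(in_lo.min()) if len(in_lo) else med,
                "whisker_high": float(in_hi.max()) if len(in_hi) else med,
                "frac_nonzero": float((v != 0).mean()),
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    return out.reindex(out["median"].abs().sort_values(ascending=False).index)


def fit_localization_models(
    X_raw: pd.DataFrame,
    localization: Sequence[str],
    *,
    iterations: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
    tune: TuneConfig | None = TuneConfig(),
) -> dict[str, EvaluationReport]:
    """Two one-vs-rest localization classifiers under the same protocol.

    ``membrane``: full membrane localization vs {mixed, intracellular};
    ``intracellular``: full intracellular retention vs {membrane, mixed}.
    """
    loc = pd.Series(list(localization))
    classes = set(loc.unique())
    for needed in ("membrane", "intracellular"):
        if needed not in classes:
            raise DegenerateLabelsError(f"no {needed!r} examples in localization labels")
    out = {}
    for name, positive in (("membrane", "membrane"), ("intracellular", "intracellular")):
        y = (loc == positive).to_numpy()
        out[name] = repeated_evaluation(
            X_raw,
            y,
            iterations=iterations,
            test_fraction=test_fraction,
            seed=seed,
            tune=tune,
        )
    return out
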