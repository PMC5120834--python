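"""The five suitability-model algorithms behind one fit/predict contract.

* GLM — weighted binomial regression with logit link.
* GAM — binomial model with a B-spline smooth per covariate.
* GBM — gradient-boosted trees with logistic loss.
* RF — classification forest; suitability is the class-1 vote fraction.
* MAXENT — penalised logistic regression on an expanded feature basis
  (linear + quadratic + pairwise products), the maxnet-style equivalent
  of maximum-entropy modelling, avoiding the Java implementation.

All models honour row weights, are frozen after fit (same rows in, same
predictions out) and predict in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .grids import EnvStack, Grid
from .preprocess import ModelTable

__all__ = ["ALGORITHMS", "FittedModel", "fit", "predict_map", "DEFAULT_SETTINGS"]

ALGORITHMS = ("GLM", "GAM", "GBM", "RF", "MAXENT")

#: fixed default hyperparameters (none are tuned per species)
DEFAULT_SETTINGS: dict[str, dict] = {
    "GLM": {},
    "GAM": {"df": 5, "degree": 3},
    "GBM": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
    "RF": {"n_estimators": 300, "min_samples_leaf": 2},
    "MAXENT": {"C": 1.0},
}


@dataclass
class FittedModel:
    """A frozen fitted suitability model."""

    algorithm: str
    covariates: list[str]
    predict_fn: Callable[[np.ndarray], np.ndarray]
    fit_meta: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        """Suitability in [0, 1] for rows of covariate values (in order)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.covariates):
            raise ValueError(
                f"expected {len(self.covariates)} covariate columns, got {X.shape[1]}"
            )
        p = np.asarray(self.predict_fn(X), dtype=float)
        return np.clip(p, 0.0, 1.0)

    def predict_table(self, table: ModelTable) -> np.ndarray:
        return self.predict(table.covariates[self.covariates].to_numpy())


def _near_constant_columns(X: np.ndarray) -> np.ndarray:
    return X.std(axis=0) <= 1e-12


# ----------------------------------------------------------------------
# individual algorithms: each returns predict_fn(X)->p
def _fit_glm(X, y, w, settings, seed):
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1e6, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lr.fit(X, y, sample_weight=w)
    return lambda Z: lr.predict_proba(Z)[:, 1]


def _fit_gam(X, y, w, settings, seed):
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    usable = ~_near_constant_columns(X)
    if not usable.any():
        return _fit_prevalence(y, w)
    Xs = X[:, usable]
    k = Xs.shape[1]
    df = int(settings.get("df", 5))
    degree = int(settings.get("degree", 3))
    bs = BSplines(Xs, df=[df] * k, degree=[degree] * k, include_intercept=False)
    exog = np.ones((len(y), 1))
    # escalate the smoothness penalty if perfect separation breaks IRLS
    res = None
    last_exc: Exception | None = None
    for alpha in (0.0, 1.0, 100.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = GLMGam(
                    y, exog=exog, smoother=bs, alpha=[alpha] * k,
                    family=sm.families.Binomial(), var_weights=w,
                )
                res = model.fit(maxiter=100)
            break
        except Exception as exc:  # noqa: BLE001 - separation raises various types
            last_exc = exc
            res = None
    if res is None:
        raise RuntimeError(f"GAM fit failed even with penalisation: {last_exc}")

    def predict(Z):
        Zs = np.clip(Z[:, usable], Xs.min(axis=0), Xs.max(axis=0))
        return res.predict(exog=np.ones((len(Z), 1)), exog_smooth=Zs)

    return predict


def _fit_gbm(X, y, w, settings, seed):
    from sklearn.ensemble import GradientBoostingClassifier

    gbm = GradientBoostingClassifier(
        n_estimators=int(settings.get("n_estimators", 100)),
        learning_rate=float(settings.get("learning_rate", 0.1)),
        max_depth=int(settings.get("max_depth", 3)),
        random_state=seed,
    )
    gbm.fit(X, y, sample_weight=w)
    return lambda Z: gbm.predict_proba(Z)[:, 1]


def _fit_rf(X, y, w, settings, seed):
    from sklearn.ensemble import RandomForestClassifier

    rf = RandomForestClassifier(
        n_estimators=int(settings.get("n_estimators", 300)),
        min_samples_leaf=int(settings.get("min_samples_leaf", 2)),
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y, sample_weight=w)
    return lambda Z: rf.predict_proba(Z)[:, 1]


def _maxent_features(Z: np.ndarray) -> np.ndarray:
    """Linear + quadratic + pairwise-product basis expansion."""
    cols = [Z, Z**2]
    k = Z.shape[1]
    for i in range(k):
        for j in range(i + 1, k):
            cols.append((Z[:, i] * Z[:, j])[:, None])
    return np.hstack(cols)


def _fit_maxent(X, y, w, settings, seed):
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    F = _maxent_features(X)
    usable = ~_near_constant_columns(F)
    if not usable.any():
        return _fit_prevalence(y, w)
    scaler = StandardScaler().fit(F[:, usable])
    lr = LogisticRegression(
        l1_ratio=1.0, C=float(settings.get("C", 1.0)), solver="liblinear", random_state=seed
    )
    lr.fit(scaler.transform(F[:, usable]), y, sample_weight=w)

    def predict(Z):
        Fz = _maxent_features(Z)
        return lr.predict_proba(scaler.transform(Fz[:, usable]))[:, 1]

    return predict


def _fit_prevalence(y, w):
    p = float(np.average(y, weights=w)) if w.sum() > 0 else float(np.mean(y))
    return lambda Z: np.full(len(Z), p)


_FITTERS = {
    "GLM": _fit_glm,
    "GAM": _fit_gam,
    "GBM": _fit_gbm,
    "RF": _fit_rf,
    "MAXENT": _fit_maxent,
}


# ----------------------------------------------------------------------
def fit(algorithm: str, table: ModelTable, settings: dict | None = None, seed: int = 0) -> FittedModel:
    """Fit one algorithm on a model table and freeze it.

    With all-constant covariates every algorithm degenerates to
    predicting the weighted prevalence.
    """
    algorithm = algorithm.upper()
    if algorithm not in _FITTERS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if table.n == 0 or not table.columns:
        raise ValueError("model table must have rows and at least one covariate")
    y = table.label
    if len(np.unique(y)) < 2:
        raise ValueError("model table contains a single class; cannot fit")
    merged = dict(DEFAULT_SETTINGS[algorithm])
    merged.update(settings or {})
    X = table.covariates.to_numpy(dtype=float)
    w = table.weight
    if _near_constant_columns(X).all():
        predict_fn = _fit_prevalence(y, w)
    else:
        predict_fn = _FITTERS[algorithm](X, y, w, merged, seed)
    return FittedModel(
        algorithm=algorithm,
        covariates=table.columns,
        predict_fn=predict_fn,
        fit_meta={"settings": merged, "seed": seed, "n": table.n,
                  "n_presence": table.n_presence, "species": table.species},
    )


def predict_map(model: FittedModel, env: EnvStack) -> Grid:
    """Predict suitability for every land cell of a stack.

    Returns a grid of probabilities in [0, 1]; cells that are nodata in
    any model covariate stay nodata.
    """
    missing = [n for n in model.covariates if n not in env]
    if missing:
        raise KeyError(f"covariate layers missing from stack: {missing}")
    template = env.template
    stack = np.stack([env[n].values for n in model.covariates], axis=-1)
    ok = np.isfinite(stack).all(axis=-1)
    out = np.full(template.shape, np.nan)
    if ok.any():
        out[ok] = model.predict(stack[ok])
    return template.copy_with(out)
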