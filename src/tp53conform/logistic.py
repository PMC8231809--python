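"""Logistic phenotype models for LFS-vs-HBC prediction.

The outcome is binary (LFS coded 1, HBC coded 0) and is modelled as a
logistic function of the Buried/Surface/unknown status of the variant
residue plus continuous variant-minus-wild-type conformational difference
scores.  Fitting is maximum likelihood by Newton-Raphson on the
log-likelihood.  The ``unknown`` burial level typically contains a handful
of observations of a single class; the resulting quasi-separation drives its
coefficient to a large negative value with an enormous Wald interval, which
is reported (flagged) rather than raised — the published models show exactly
this behaviour.

The estimators follow the scikit-learn protocol (``fit`` / ``predict_proba``
/ ``get_params``) and operate on the feature table produced by
:mod:`tp53conform.features`; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

try:  # sklearn is optional at run time; the protocol is duck-typed
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        def get_params(self, deep=True):
            return {k: v for k, v in self.__dict__.items() if not k.endswith("_")}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self

__all__ = [
    "BUR_LEVELS",
    "LogisticModel",
    "PhenotypeLogit",
    "design_matrix",
    "fit_logistic",
    "summarize",
    "predict_probability",
    "published_model",
    "PUBLISHED_MODELS",
    "model_to_json",
    "model_from_json",
    "SeparationWarning",
]

BUR_LEVELS = ("Buried", "Surface", "unknown")  # Buried is the reference level

INTERCEPT = "Intercept"
BUR_SURFACE = "Bur[Surface]"
BUR_UNKNOWN = "Bur[unknown]"


class SeparationWarning(UserWarning):
    """Raised as a warning when (quasi-)separation inflates coefficients."""


@dataclass
class LogisticModel:
    """Named coefficients of a fitted (or fixed published) logistic model."""

    terms: tuple[str, ...]          # model terms, e.g. ("Bur", "comp_dif")
    names: tuple[str, ...]          # design columns incl. Intercept and Bur contrasts
    beta: np.ndarray
    covariance: np.ndarray | None = None
    n_obs: int | None = None
    converged: bool = True
    separation: bool = False
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.names):
            raise ValueError("beta length does not match design names")
        if self.covariance is not None:
            self.covariance = np.asarray(self.covariance, dtype=float)
            if self.covariance.shape != (len(self.names),) * 2:
                raise ValueError("covariance shape mismatch")
            if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
                raise ValueError("covariance not symmetric")

    @property
    def se(self) -> np.ndarray:
        if self.covariance is None:
            raise ValueError("model has no covariance (fixed published coefficients)")
        return np.sqrt(np.clip(np.diag(self.covariance), 0, None))

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta

    def predict_proba_design(self, X: np.ndarray) -> np.ndarray:
        return _expit(self.linear_predictor(X))


def _expit(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=float)))


def design_matrix(
    features: pd.DataFrame,
    terms: Sequence[str],
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix with intercept; Bur expands to two dummies vs Buried.

    ``terms`` lists model terms by feature-table column ("Bur" plus any of
    the continuous ``_dif`` columns).  The returned column names align with
    published coefficient tables (Surface-vs-Buried, unknown-vs-Buried).
    """
    cols: list[np.ndarray] = [np.ones(len(features))]
    names: list[str] = [INTERCEPT]
    for term in terms:
        if term == "Bur":
            bur = features["Bur"].astype(str)
            bad = set(bur) - set(BUR_LEVELS)
            if bad:
                raise ValueError(f"unknown Bur levels: {sorted(bad)}")
            cols.append((bur == "Surface").to_numpy(float))
            names.append(BUR_SURFACE)
            cols.append((bur == "unknown").to_numpy(float))
            names.append(BUR_UNKNOWN)
        else:
            if term not in features.columns:
                raise KeyError(f"feature column {term!r} missing")
            cols.append(features[term].to_numpy(float))
            names.append(term)
    return np.column_stack(cols), tuple(names)


def encode_outcome(outcome: Sequence[str] | np.ndarray | pd.Series) -> np.ndarray:
    """LFS -> 1, HBC -> 0; already-binary input passes through."""
    arr = np.asarray(outcome)
    if arr.dtype.kind in "OUS":
        vals = set(np.unique(arr).tolist())
        if not vals <= {"LFS", "HBC"}:
            raise ValueError(f"outcome labels must be LFS/HBC, got {sorted(vals)}")
        return (arr == "LFS").astype(float)
    y = arr.astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("numeric outcome must be 0/1")
    return y


def _newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    max_step: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, bool, float]:
    """Newton-Raphson MLE with step capping and a tiny ridge fallback.

    Convergence is a change in log-likelihood below ``tol``.  Under
    separation the likelihood keeps creeping; the iteration cap then leaves
    large finite coefficients (flagged by the caller), mirroring what
    standard IRLS fitters report in that situation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -n * np.log(2.0)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = _expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(hess + 1e-8 * np.eye(p), grad)
        norm = np.linalg.norm(step)
        if norm > max_step:
            step *= max_step / norm
        beta = beta + step
        with np.errstate(divide="ignore"):
            eta = X @ beta
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = X @ beta
    mu = _expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    hess = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(hess + 1e-8 * np.eye(p))
    cov = 0.5 * (cov + cov.T)
    return beta, cov, converged, ll_old


class PhenotypeLogit(BaseEstimator):
    """Scikit-learn style logistic classifier on the variant feature table.

    Parameters
    ----------
    terms:
        Feature-table columns to use ("Bur" and/or continuous ``_dif``
        columns).  ``None`` means Bur plus all eleven difference scores
        (the full model).
    tol, max_iter:
        Newton-Raphson stopping rule (log-likelihood change / iteration cap).

    Attributes
    ----------
    model_ : LogisticModel
        Named coefficients, covariance and convergence flags.
    classes_ : ndarray
        ``[0, 1]`` (HBC, LFS).
    """

    def __init__(self, terms: Sequence[str] | None = None,
                 tol: float = 1e-8, max_iter: int = 50):
        self.terms = terms
        self.max_iter = max_iter
        self.tol = tol

    def _resolved_terms(self, features: pd.DataFrame) -> tuple[str, ...]:
        if self.terms is not None:
            return tuple(self.terms)
        from .features import DIF_VARIABLES
        return ("Bur", *DIF_VARIABLES)

    def fit(self, X: pd.DataFrame, y: Sequence) -> "PhenotypeLogit":
        terms = self._resolved_terms(X)
        yv = encode_outcome(y)
        if len(np.unique(yv)) < 2:
            raise ValueError("outcome has a single class; cannot fit")
        design, names = design_matrix(X, terms)
        # factor levels absent from this sample leave all-zero dummy columns;
        # fit without them and pin their coefficients at zero (reference-like)
        keep = [0] + [j for j in range(1, design.shape[1]) if np.any(design[:, j])]
        if design[:, keep].shape[0] <= len(keep):
            raise ValueError(
                f"{design.shape[0]} observations for {len(keep)} coefficients"
            )
        beta_k, cov_k, converged, ll = _newton_logistic(
            design[:, keep], yv, tol=self.tol, max_iter=self.max_iter
        )
        beta = np.zeros(design.shape[1])
        cov = np.zeros((design.shape[1],) * 2)
        beta[keep] = beta_k
        cov[np.ix_(keep, keep)] = cov_k
        separation = bool(np.abs(beta).max() > 8.0) or not converged
        if separation:
            warnings.warn(
                "large coefficients suggest (quasi-)separation; Wald intervals "
                "for the affected terms are unreliable",
                SeparationWarning,
                stacklevel=2,
            )
        self.model_ = LogisticModel(
            terms=tuple(terms), names=names, beta=beta, covariance=cov,
            n_obs=len(yv), converged=converged, separation=separation,
            log_likelihood=ll,
        )
        self.classes_ = np.array([0.0, 1.0])
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        design, _ = design_matrix(X, self.model_.terms)
        p1 = self.model_.predict_proba_design(design)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(float)

    def summary(self) -> pd.DataFrame:
        return summarize(self.model_)


def fit_logistic(
    features: pd.DataFrame,
    outcome: Sequence,
    terms: Sequence[str],
    **kwargs,
) -> LogisticModel:
    """Functional wrapper: fit and return the named-coefficient model."""
    return PhenotypeLogit(terms=terms, **kwargs).fit(features, outcome).model_


def summarize(model: LogisticModel) -> pd.DataFrame:
    """Per-coefficient beta, odds ratio, Wald 95% CI and Wald p-value."""
    if model.covariance is None:
        raise ValueError("published fixed models carry no covariance to summarize")
    se = model.se
    z = np.divide(model.beta, se, out=np.zeros_like(se), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(se > 0, p, 1.0)
    with np.errstate(over="ignore"):
        out = pd.DataFrame(
            {
                "beta": model.beta,
                "se": se,
                "odds_ratio": np.exp(model.beta),
                "ci_low": np.exp(model.beta - 1.96 * se),
                "ci_high": np.exp(model.beta + 1.96 * se),
                "wald_p": p,
            },
            index=list(model.names),
        )
    return out


def predict_probability(model: LogisticModel, x: Mapping[str, object]) -> float:
    """Probability of the LFS outcome for one feature mapping.

    ``x`` supplies ``Bur`` (level name) when the model contains it, and a
    value for every continuous term; a missing term raises ``KeyError``.
    """
    row = {}
    for term in model.terms:
        if term not in x:
            raise KeyError(f"missing value for model term {term!r}")
        row[term] = x[term]
    frame = pd.DataFrame([row])
    design, names = design_matrix(frame, model.terms)
    assert names == model.names
    return float(model.predict_proba_design(design)[0])


# -- published fixed-coefficient models ------------------------------------

#: Reduced-model coefficients exactly as published for the 48-variant cohort.
PUBLISHED_MODELS: dict[str, dict[str, float]] = {
    "mod_2v": {
        INTERCEPT: 0.914,
        BUR_SURFACE: -1.886,
        BUR_UNKNOWN: -8.804,
        "comp_dif": 0.014,
    },
    "mod_3v": {
        INTERCEPT: 1.094,
        BUR_SURFACE: -2.229,
        BUR_UNKNOWN: -9.03,
        "comp_dif": 0.015,
        "PPI6_dif": 0.0006,
    },
    "mod_4v": {
        INTERCEPT: 1.282,
        BUR_SURFACE: -2.465,
        BUR_UNKNOWN: -9.897,
        "comp_dif": 0.023,
        "PPI6_dif": 0.001,
        "nmr_dif": 10.461,
    },
}


def published_model(name: str) -> LogisticModel:
    """Fixed-coefficient reduced model (``mod_2v``, ``mod_3v`` or ``mod_4v``)."""
    if name not in PUBLISHED_MODELS:
        raise KeyError(f"unknown model {name!r}; options: {sorted(PUBLISHED_MODELS)}")
    coefs = PUBLISHED_MODELS[name]
    names = tuple(coefs)
    terms = ["Bur"] + [n for n in names if n not in (INTERCEPT, BUR_SURFACE, BUR_UNKNOWN)]
    return LogisticModel(
        terms=tuple(terms),
        names=names,
        beta=np.array(list(coefs.values())),
        covariance=None,
        n_obs=48,
        converged=True,
        separation=True,  # the unknown-vs-Buried contrast is quasi-separated
    )


# -- serialization ---------------------------------------------------------

def model_to_json(model: LogisticModel) -> str:
    payload = {
        "terms": list(model.terms),
        "names": list(model.names),
        "beta": model.beta.tolist(),
        "covariance": None if model.covariance is None else model.covariance.tolist(),
        "n_obs": model.n_obs,
        "converged": model.converged,
        "separation": model.separation,
        "log_likelihood": model.log_likelihood,
    }
    return json.dumps(payload, indent=2)


def model_from_json(text: str) -> LogisticModel:
    d = json.loads(text)
    return LogisticModel(
        terms=tuple(d["terms"]),
        names=tuple(d["names"]),
        beta=np.array(d["beta"], dtype=float),
        covariance=None if d["covariance"] is None else np.array(d["covariance"]),
        n_obs=d["n_obs"],
        converged=d["converged"],
        separation=d["separation"],
        log_likelihood=d["log_likelihood"],
    )
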