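"""Model reduction and internal validation.

Implements the discrimination and over-fitting diagnostics around the
logistic phenotype models: the concordance statistic (identical to the area
under the ROC curve), backward step-down variable selection on Wald tests,
Harrell-style bootstrap optimism correction of the C-statistic, bootstrap
calibration curves, and leave-one-out cross-validated predictions.

Multi-column terms (the three-level burial factor) are dropped or kept as a
block.  The block's significance is its joint Wald chi-square over its
contrasts, which reduces to the individual Wald test for single-column
terms; step-down repeatedly removes the least significant block while its
p-value exceeds the significance-to-stay threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .logistic import (
    LogisticModel,
    PhenotypeLogit,
    design_matrix,
    encode_outcome,
    fit_logistic,
)

__all__ = [
    "ValidationReport",
    "CalibrationCurve",
    "LooPrediction",
    "concordance_statistic",
    "roc_curve",
    "term_pvalues",
    "backward_stepdown",
    "StepdownPhenotypeLogit",
    "manual_reduce",
    "bootstrap_validate",
    "bootstrap_calibrate",
    "loo_cross_validate",
]


@dataclass(frozen=True)
class ValidationReport:
    """Bootstrap optimism correction of the concordance statistic."""

    apparent_C: float
    optimism: float
    corrected_C: float
    n_boot: int
    selected_terms_per_replicate: list[tuple[str, ...]]
    n_redrawn: int = 0
    seed: int | None = None


@dataclass(frozen=True)
class CalibrationCurve:
    bin_midpoints: np.ndarray
    apparent: np.ndarray
    corrected: np.ndarray
    n_per_bin: np.ndarray


@dataclass(frozen=True)
class LooPrediction:
    variant_id: str
    probability_LFS: float
    terms_used: tuple[str, ...]


def concordance_statistic(probs: Sequence[float], outcome: Sequence) -> float:
    """Concordance probability (C-statistic / AUROC) with ties scored 0.5.

    Rank-based: C = (R1 - n1(n1+1)/2) / (n1 n0), with R1 the rank sum of the
    positive class using midranks, which is exactly the all-pairs count with
    half credit for tied scores.
    """
    y = encode_outcome(outcome)
    p = np.asarray(probs, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required for concordance")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(probs: Sequence[float], outcome: Sequence) -> pd.DataFrame:
    """Threshold sweep ROC: ordered (threshold, FPR, TPR) points.

    The trapezoidal area under the returned curve equals
    :func:`concordance_statistic` identically (ties handled by midpoints).
    """
    y = encode_outcome(outcome)
    p = np.asarray(probs, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required for a ROC curve")
    order = np.argsort(-p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    # collapse tied scores into single operating points
    distinct = np.r_[np.diff(p_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    thresholds = p_sorted[distinct]
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, thresholds],
            "fpr": np.r_[0.0, fp / n0],
            "tpr": np.r_[0.0, tp / n1],
        }
    )


def auc(curve: pd.DataFrame) -> float:
    return float(np.trapezoid(curve["tpr"], curve["fpr"]))


def term_pvalues(model: LogisticModel) -> dict[str, float]:
    """Joint Wald p-value per model term (block test for multi-column terms)."""
    if model.covariance is None:
        raise ValueError("model has no covariance")
    out: dict[str, float] = {}
    for term in model.terms:
        if term == "Bur":
            idx = [i for i, n in enumerate(model.names) if n.startswith("Bur[")]
        else:
            idx = [model.names.index(term)]
        # contrasts pinned at zero (factor level absent from the sample)
        # carry no information and would make the block covariance singular
        diag = np.diag(model.covariance)
        idx = [i for i in idx if diag[i] > 0]
        if not idx:
            out[term] = 1.0
            continue
        b = model.beta[idx]
        cov = model.covariance[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(cov, b))
        except np.linalg.LinAlgError:
            chi2 = 0.0
        out[term] = float(stats.chi2.sf(max(chi2, 0.0), df=len(idx)))
    return out


def backward_stepdown(
    features: pd.DataFrame,
    outcome: Sequence,
    terms: Sequence[str],
    sls: float = 0.13,
) -> LogisticModel:
    """Backward step-down: drop the least significant term while p > sls.

    ``sls`` is the significance level to stay.  One term (block) is removed
    per iteration and the model refitted; the burial factor moves as a block.
    """
    current = list(terms)
    model = fit_logistic(features, outcome, current)
    while len(current) > 1:
        pvals = term_pvalues(model)
        worst = max(current, key=lambda t: pvals[t])
        if pvals[worst] <= sls:
            break
        current.remove(worst)
        model = fit_logistic(features, outcome, current)
    # a single remaining term may still be non-significant; drop to report?
    # Keep at least one term: an intercept-only model has no discrimination.
    return model


class StepdownPhenotypeLogit(PhenotypeLogit):
    """Logistic classifier with backward step-down selection inside ``fit``.

    Starting from ``terms`` (default: Bur plus all difference scores), the
    least significant term is dropped while its joint Wald p exceeds ``sls``;
    the surviving model is exposed as ``model_`` and ``terms_``.
    """

    def __init__(self, terms: Sequence[str] | None = None, sls: float = 0.13,
                 tol: float = 1e-8, max_iter: int = 50):
        super().__init__(terms=terms, tol=tol, max_iter=max_iter)
        self.sls = sls

    def fit(self, X: pd.DataFrame, y: Sequence) -> "StepdownPhenotypeLogit":
        terms = self._resolved_terms(X)
        self.model_ = backward_stepdown(X, y, terms, sls=self.sls)
        self.terms_ = self.model_.terms
        self.classes_ = np.array([0.0, 1.0])
        return self


def manual_reduce(
    model: LogisticModel,
    features: pd.DataFrame,
    outcome: Sequence,
) -> LogisticModel:
    """Remove exactly the least significant term and refit."""
    if len(model.terms) < 2:
        raise ValueError("model must keep at least one non-intercept term")
    pvals = term_pvalues(model)
    worst = max(model.terms, key=lambda t: pvals[t])
    remaining = [t for t in model.terms if t != worst]
    return fit_logistic(features, outcome, remaining)


def _resample_indices(
    rng: np.random.Generator, y: np.ndarray, max_redraw: int = 100
) -> tuple[np.ndarray, int]:
    """Simple resample with replacement; redraw if one class vanishes."""
    n = len(y)
    redraws = 0
    while True:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) == 2:
            return idx, redraws
        redraws += 1
        if redraws > max_redraw:
            raise RuntimeError("could not draw a two-class bootstrap resample")


def bootstrap_validate(
    features: pd.DataFrame,
    outcome: Sequence,
    terms: Sequence[str],
    n_boot: int = 1000,
    sls: float = 0.13,
    seed: int | None = None,
    stepdown: bool = True,
) -> ValidationReport:
    """Harrell bootstrap optimism correction of the C-statistic.

    The apparent model is selected (step-down from ``terms`` at ``sls``) and
    scored on the full data.  Each bootstrap replicate repeats the entire
    selection on the resample, scores the resampled model on the resample
    (training C) and on the original data (test C); optimism is the mean
    train-minus-test difference and corrected_C = apparent_C - optimism.
    Resamples that lose an outcome class are redrawn and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y = encode_outcome(outcome)
    rng = np.random.default_rng(seed)

    def select_and_fit(df: pd.DataFrame, yv: np.ndarray) -> LogisticModel:
        if stepdown:
            return backward_stepdown(df, yv, terms, sls=sls)
        return fit_logistic(df, yv, terms)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        apparent_model = select_and_fit(features, y)
        design_full, _ = design_matrix(features, apparent_model.terms)
        apparent_C = concordance_statistic(
            apparent_model.predict_proba_design(design_full), y
        )

        optimisms = []
        selected: list[tuple[str, ...]] = []
        total_redraws = 0
        for _ in range(n_boot):
            idx, redraws = _resample_indices(rng, y)
            total_redraws += redraws
            boot_df = features.iloc[idx]
            boot_y = y[idx]
            try:
                model = select_and_fit(boot_df, boot_y)
            except ValueError:
                # e.g. a resampled factor level degenerates; skip replicate
                continue
            selected.append(model.terms)
            Xb, _ = design_matrix(boot_df, model.terms)
            Xo, _ = design_matrix(features, model.terms)
            c_train = concordance_statistic(model.predict_proba_design(Xb), boot_y)
            c_test = concordance_statistic(model.predict_proba_design(Xo), y)
            optimisms.append(c_train - c_test)

    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return ValidationReport(
        apparent_C=apparent_C,
        optimism=optimism,
        corrected_C=apparent_C - optimism,
        n_boot=len(optimisms),
        selected_terms_per_replicate=selected,
        n_redrawn=total_redraws,
        seed=seed,
    )


def _binned_calibration(
    probs: np.ndarray, y: np.ndarray, edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Observed outcome frequency per predicted-probability bin."""
    which = np.clip(np.digitize(probs, edges) - 1, 0, len(edges) - 2)
    obs = np.full(len(edges) - 1, np.nan)
    n = np.zeros(len(edges) - 1, dtype=int)
    for b in range(len(edges) - 1):
        mask = which == b
        n[b] = mask.sum()
        if n[b]:
            obs[b] = y[mask].mean()
    return obs, n


def bootstrap_calibrate(
    features: pd.DataFrame,
    outcome: Sequence,
    terms: Sequence[str],
    n_boot: int = 1000,
    seed: int | None = None,
    n_bins: int = 10,
) -> CalibrationCurve:
    """Optimism-corrected calibration curve over predicted-probability bins.

    The apparent curve is the observed LFS frequency per bin of predicted
    probability from the model fitted on the full data.  Each bootstrap
    refit contributes (training-curve minus original-data-curve) to a
    per-bin optimism that is subtracted from the apparent curve; corrected
    values are clipped to [0, 1].
    """
    y = encode_outcome(outcome)
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_logistic(features, y, terms)
        X_full, _ = design_matrix(features, model.terms)
        p_full = model.predict_proba_design(X_full)
        apparent, n_per_bin = _binned_calibration(p_full, y, edges)

        diffs = []
        for _ in range(n_boot):
            idx, _ = _resample_indices(rng, y)
            boot_df, boot_y = features.iloc[idx], y[idx]
            try:
                m = fit_logistic(boot_df, boot_y, terms)
            except ValueError:
                continue
            Xb, _ = design_matrix(boot_df, m.terms)
            Xo, _ = design_matrix(features, m.terms)
            train, _n = _binned_calibration(m.predict_proba_design(Xb), boot_y, edges)
            test, _n = _binned_calibration(m.predict_proba_design(Xo), y, edges)
            diffs.append(train - test)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        optimism = np.nanmean(np.array(diffs), axis=0) if diffs else np.zeros_like(mids)
    corrected = np.clip(apparent - optimism, 0.0, 1.0)
    return CalibrationCurve(mids, apparent, corrected, n_per_bin)


def loo_cross_validate(
    features: pd.DataFrame,
    outcome: Sequence,
    terms: Sequence[str],
    sls: float = 0.16,
    stepdown: bool = True,
) -> list[LooPrediction]:
    """Leave-one-out predictions with per-fold step-down selection.

    Each observation is predicted by a model selected and fitted on the
    other n-1 rows only.  Folds whose training outcome degenerates to one
    class are skipped with a warning.
    """
    y = encode_outcome(outcome)
    if len(y) < 3:
        raise ValueError("need at least 3 observations for leave-one-out")
    preds: list[LooPrediction] = []
    for i in range(len(y)):
        mask = np.arange(len(y)) != i
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {i}: single-class training set; skipped", stacklevel=2)
            continue
        df_train = features.iloc[mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stepdown:
                model = backward_stepdown(df_train, y_train, terms, sls=sls)
            else:
                model = fit_logistic(df_train, y_train, terms)
            X_i, _ = design_matrix(features.iloc[[i]], model.terms)
            prob = float(model.predict_proba_design(X_i)[0])
        preds.append(LooPrediction(str(features.index[i]), prob, model.terms))
    return preds
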