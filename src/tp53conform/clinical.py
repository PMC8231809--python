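"""Decision-curve analysis and nomogram rendering of a phenotype model.

Decision curves report the net benefit of calling LFS when the predicted
probability reaches a risk threshold, against the treat-all and treat-none
policies.  The nomogram re-expresses the additive linear predictor on a
0-100 points scale per variable so the LFS probability can be read off by
hand; the ``unknown`` burial level is excluded from the nomogram because its
coefficient is an artefact of quasi-separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .logistic import (
    BUR_SURFACE,
    INTERCEPT,
    LogisticModel,
    _expit,
    encode_outcome,
)

__all__ = [
    "NetBenefitCurve",
    "Nomogram",
    "decision_curve",
    "build_nomogram",
    "evaluate_nomogram",
    "render_nomogram_text",
]


@dataclass(frozen=True)
class NetBenefitCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_all": self.nb_all,
                "nb_none": self.nb_none,
            }
        )


@dataclass(frozen=True)
class NomogramVariable:
    """Linear map from one variable's value to nomogram points."""

    name: str                     # "Bur" or a continuous term
    lo: float                     # value (or 0/1 dummy) at the 0-point anchor
    hi: float
    beta: float
    points_per_unit: float
    anchor_contribution: float    # beta * value at the 0-point end

    def points(self, value: float) -> float:
        return (value - self.lo) * self.points_per_unit if self.hi != self.lo else 0.0


@dataclass(frozen=True)
class Nomogram:
    variables: tuple[NomogramVariable, ...]
    intercept: float
    scale: float                  # linear-predictor units per point
    base_lp: float                # lp when every variable sits at 0 points

    def probability_from_points(self, total_points: float) -> float:
        return float(_expit(self.base_lp + total_points * self.scale))


def decision_curve(
    probs: Sequence[float],
    outcome: Sequence,
    thresholds: Sequence[float] | None = None,
) -> NetBenefitCurve:
    """Net benefit of the model vs treat-all / treat-none across thresholds.

    nb_model(pt) = TP/N - FP/N * pt/(1-pt) calling LFS when prob >= pt;
    nb_all(pt) = prevalence - (1-prevalence) * pt/(1-pt); nb_none = 0.
    The default grid is 0.01..0.99 in steps of 0.01.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.0, 0.01), 10)
    pt = np.asarray(thresholds, dtype=float)
    if pt.size == 0:
        raise ValueError("empty threshold grid")
    if (pt <= 0).any() or (pt >= 1).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    y = encode_outcome(outcome)
    p = np.asarray(probs, dtype=float)
    n = len(y)
    prevalence = float(y.mean())
    odds = pt / (1.0 - pt)

    call = p[None, :] >= pt[:, None]             # (threshold, obs)
    tp = (call & (y == 1)[None, :]).sum(axis=1)
    fp = (call & (y == 0)[None, :]).sum(axis=1)
    nb_model = tp / n - fp / n * odds
    nb_all = prevalence - (1.0 - prevalence) * odds
    return NetBenefitCurve(pt, nb_model, nb_all, np.zeros_like(pt), prevalence)


def build_nomogram(
    model: LogisticModel,
    ranges: Mapping[str, tuple[float, float]],
) -> Nomogram:
    """Points-scale rendering of a fitted or published logistic model.

    Each variable's contribution beta*(value) over its observed range is
    mapped affinely to points, anchored so the minimum-contribution end is 0
    points, and scaled so the variable with the widest contribution span runs
     0-100.  For the burial factor the range is Buried vs Surface (the
    ``unknown`` contrast is omitted).  Total points convert back to an LFS
    probability through the inverse logit.
    """
    intercept = model.coef(INTERCEPT)
    specs: list[tuple[str, float, float, float]] = []  # name, beta, lo_val, hi_val
    for term in model.terms:
        if term == "Bur":
            specs.append(("Bur", model.coef(BUR_SURFACE), 0.0, 1.0))
            continue
        if term not in ranges:
            raise KeyError(f"no observed range for model variable {term!r}")
        lo, hi = ranges[term]
        if hi < lo:
            raise ValueError(f"range for {term!r} has hi < lo")
        if hi == lo:
            warnings.warn(f"zero-span range for {term!r}; fixed at 0 points", stacklevel=2)
        beta = model.coef(term)
        if not np.isfinite(beta):
            raise ValueError(f"non-finite coefficient for {term!r}")
        specs.append((term, beta, lo, hi))

    spans = [abs(beta) * (hi - lo) for _, beta, lo, hi in specs]
    max_span = max(spans) if spans else 0.0
    if max_span <= 0:
        raise ValueError("model has no variable with a non-zero contribution span")
    scale = max_span / 100.0  # lp units per point

    variables = []
    base_lp = intercept
    for (name, beta, lo, hi) in specs:
        # 0-point anchor at the end with the smaller contribution
        if beta >= 0:
            anchor_val, far_val = lo, hi
        else:
            anchor_val, far_val = hi, lo
        anchor_contribution = beta * anchor_val
        base_lp += anchor_contribution
        ppu = beta / scale  # signed; points() uses value - anchor
        variables.append(
            NomogramVariable(
                name=name,
                lo=anchor_val,
                hi=far_val,
                beta=beta,
                points_per_unit=ppu,
                anchor_contribution=anchor_contribution,
            )
        )
    return Nomogram(tuple(variables), intercept, scale, base_lp)


def evaluate_nomogram(
    nomogram: Nomogram,
    values: Mapping[str, object],
) -> tuple[dict[str, float], float, float]:
    """Per-variable points, total points and LFS probability for one input.

    ``values`` maps each nomogram variable to its value; ``Bur`` takes the
    level name ("Buried"/"Surface").  Values outside the declared range are
    clamped with a warning.
    """
    per_var: dict[str, float] = {}
    for var in nomogram.variables:
        if var.name not in values:
            raise KeyError(f"missing value for nomogram variable {var.name!r}")
        raw = values[var.name]
        if var.name == "Bur":
            if raw not in ("Buried", "Surface"):
                raise ValueError(
                    f"Bur must be 'Buried' or 'Surface' on the nomogram, got {raw!r}"
                )
            val = 1.0 if raw == "Surface" else 0.0
        else:
            val = float(raw)  # type: ignore[arg-type]
            lo, hi = sorted((var.lo, var.hi))
            if not lo <= val <= hi:
                warnings.warn(
                    f"{var.name} = {val} outside declared range [{lo}, {hi}]; clamped",
                    stacklevel=2,
                )
                val = min(max(val, lo), hi)
        per_var[var.name] = var.points(val)
    total = float(sum(per_var.values()))
    return per_var, total, nomogram.probability_from_points(total)


def render_nomogram_text(nomogram: Nomogram, width: int = 60) -> str:
    """Plain-text sketch of the points scales and the probability axis."""
    lines = ["Nomogram (0-100 points per variable)", "=" * 40]
    for var in nomogram.variables:
        span = abs(var.beta * (var.hi - var.lo)) / nomogram.scale
        if var.name == "Bur":
            lines.append(
                f"  Bur:        Buried = {var.points(0.0):6.1f} pts | "
                f"Surface = {var.points(1.0):6.1f} pts"
            )
        else:
            lines.append(
                f"  {var.name:<11s} {var.lo:>10.3g} -> 0.0 pts | "
                f"{var.hi:>10.3g} -> {span:6.1f} pts"
            )
    lines.append("-" * 40)
    lines.append("  Total points -> probability of LFS:")
    max_total = sum(abs(v.beta * (v.hi - v.lo)) / nomogram.scale for v in nomogram.variables)
    for frac in np.linspace(0.0, 1.0, 6):
        pts = frac * max_total
        lines.append(f"    {pts:7.1f} pts -> {nomogram.probability_from_points(pts):0.3f}")
    return "\n".join(lines)
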