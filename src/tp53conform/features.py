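"""Per-variant explanatory variables from predictor score profiles.

External predictors (disorder, flexibility, secondary structure, compactness,
protein-interaction propensity) score every residue of wild-type TP53 and of
each missense variant.  The explanatory variable for a variant is the
variant-minus-wild-type score difference at the substituted position (the
``_dif`` variables), plus the categorical Buried/Surface/unknown status of the
residue in the tetramer structure.  The predictors themselves are external
published tools; this module only defines their file contract and assembles
the feature table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import BurialCall

__all__ = [
    "CONTINUOUS_PREDICTORS",
    "DIF_VARIABLES",
    "ScoreProfile",
    "MissenseVariant",
    "PPIRegion",
    "diff_at_position",
    "build_feature_table",
    "call_ppi_regions",
    "read_profiles",
    "write_profiles",
    "read_variants",
    "write_variants",
    "WILDTYPE",
]

#: Continuous per-residue predictors whose differences enter the models.
#: PPI10 (less sensitive interaction-region settings) is read alongside them
#: but used only for region calling/plotting, never as a model variable.
CONTINUOUS_PREDICTORS: tuple[str, ...] = (
    "disprot", "nmr", "xray", "iupl", "iups", "iupstr", "anc", "dyn",
    "Sec", "comp", "PPI6",
)
DIF_VARIABLES: tuple[str, ...] = tuple(p + "_dif" for p in CONTINUOUS_PREDICTORS)
KNOWN_PREDICTORS: tuple[str, ...] = CONTINUOUS_PREDICTORS + ("PPI10",)

WILDTYPE = "wildtype"

TP53_LENGTH = 393


@dataclass(frozen=True)
class ScoreProfile:
    """Per-residue scores of one predictor for one entity (wild-type or variant)."""

    predictor: str
    entity: str
    scores: tuple[float, ...]  # 1-based positions map to scores[pos - 1]

    @property
    def length(self) -> int:
        return len(self.scores)

    def score_at(self, position: int) -> float:
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside 1..{self.length} for "
                f"{self.predictor}/{self.entity}"
            )
        return self.scores[position - 1]


@dataclass(frozen=True)
class MissenseVariant:
    """A single amino-acid substitution with its phenotype label."""

    variant_id: str
    position: int
    wt_aa: str
    var_aa: str
    outcome: str | None = None  # "LFS" | "HBC" | None
    source: str = ""

    def __post_init__(self) -> None:
        if self.wt_aa == self.var_aa:
            raise ValueError(f"{self.variant_id}: synonymous substitution")
        if not 1 <= self.position <= TP53_LENGTH:
            raise ValueError(f"{self.variant_id}: position {self.position} outside protein")


@dataclass(frozen=True)
class PPIRegion:
    start: int
    end: int  # inclusive, 1-based
    min_segment: int
    peak_score: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < self.min_segment:
            raise ValueError("region shorter than min_segment")


def diff_at_position(wt: ScoreProfile, var: ScoreProfile, position: int) -> float:
    """Variant score minus wild-type score at one position."""
    if wt.predictor != var.predictor:
        raise ValueError(f"predictor mismatch: {wt.predictor} vs {var.predictor}")
    if wt.length != var.length:
        raise ValueError("profile length mismatch")
    return var.score_at(position) - wt.score_at(position)


def build_feature_table(
    variants: Sequence[MissenseVariant],
    profiles: Mapping[tuple[str, str], ScoreProfile],
    burial: Iterable[BurialCall],
) -> pd.DataFrame:
    """One row per variant: Bur category plus the eleven ``_dif`` variables.

    ``profiles`` is keyed by (predictor, entity) where entity is either a
    variant_id or :data:`WILDTYPE`.  The burial call at the variant's position
    supplies Bur; positions not covered by the structure are ``unknown``.
    """
    burial_by_pos = {call.canonical_position: call.status for call in burial}

    missing: list[tuple[str, str]] = []
    for v in variants:
        for pred in CONTINUOUS_PREDICTORS:
            if (pred, WILDTYPE) not in profiles or (pred, v.variant_id) not in profiles:
                missing.append((v.variant_id, pred))
    if missing:
        raise KeyError(f"missing predictor profiles for (variant, predictor): {missing}")

    rows = []
    for v in variants:
        row: dict[str, object] = {
            "variant_id": v.variant_id,
            "position": v.position,
            "Bur": burial_by_pos.get(v.position, "unknown"),
            "outcome": v.outcome,
        }
        for pred in CONTINUOUS_PREDICTORS:
            row[pred + "_dif"] = diff_at_position(
                profiles[(pred, WILDTYPE)], profiles[(pred, v.variant_id)], v.position
            )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("variant_id")
    return df[["position", "Bur", *DIF_VARIABLES, "outcome"]]


def call_ppi_regions(
    profile: ScoreProfile,
    min_segment: int = 10,
    rel_threshold: float = 0.05,
    trim: tuple[int, int] = (4, 3),
) -> list[PPIRegion]:
    """Contiguous high-propensity protein-interaction regions.

    The first ``trim[0]`` and last ``trim[1]`` positions are zeroed first
    (terminal scores of the propensity profile are artefactual); maximal runs
    with score >= rel_threshold * max(score) and length >= min_segment are
    returned.  Trimming applies only here, never to ``_dif`` computation.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    head, tail = trim
    scores = np.asarray(profile.scores, dtype=float).copy()
    if head:
        scores[:head] = 0.0
    if tail:
        scores[len(scores) - tail:] = 0.0
    peak = scores.max()
    if peak <= 0:
        return []
    mask = scores >= rel_threshold * peak
    regions: list[PPIRegion] = []
    start = None
    for i, flag in enumerate(np.append(mask, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_segment:
                regions.append(
                    PPIRegion(start + 1, i, min_segment, float(scores[start:i].max()))
                )
            start = None
    return regions


# -- file contracts --------------------------------------------------------

def read_profiles(path: str) -> dict[tuple[str, str], ScoreProfile]:
    """Read the TSV profile contract (predictor, entity, position, score)."""
    df = pd.read_csv(path, sep="\t")
    required = {"predictor", "entity", "position", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"profile file must have columns {sorted(required)}")
    out: dict[tuple[str, str], ScoreProfile] = {}
    for (pred, entity), grp in df.groupby(["predictor", "entity"], sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        if positions[0] != 1 or not np.array_equal(positions, np.arange(1, len(grp) + 1)):
            raise ValueError(f"profile {pred}/{entity} positions are not contiguous from 1")
        out[(str(pred), str(entity))] = ScoreProfile(
            str(pred), str(entity), tuple(float(s) for s in grp["score"])
        )
    return out


def write_profiles(profiles: Mapping[tuple[str, str], ScoreProfile], path: str) -> None:
    rows = [
        {"predictor": p.predictor, "entity": p.entity, "position": i + 1, "score": s}
        for p in profiles.values()
        for i, s in enumerate(p.scores)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variants(path: str) -> list[MissenseVariant]:
    """Read the CSV variant contract (variant_id, position, wt_aa, var_aa, outcome, source)."""
    df = pd.read_csv(path)
    out = []
    for rec in df.to_dict("records"):
        outcome = rec.get("outcome")
        if pd.isna(outcome):
            outcome = None
        source = rec.get("source", "")
        if pd.isna(source):
            source = ""
        out.append(
            MissenseVariant(
                str(rec["variant_id"]), int(rec["position"]),
                str(rec["wt_aa"]), str(rec["var_aa"]),
                outcome, str(source),
            )
        )
    return out


def write_variants(variants: Sequence[MissenseVariant], path: str) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": v.variant_id, "position": v.position,
                "wt_aa": v.wt_aa, "var_aa": v.var_aa,
                "outcome": v.outcome, "source": v.source,
            }
            for v in variants
        ]
    ).to_csv(path, index=False)
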