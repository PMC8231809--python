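"""Synthetic cohorts, score profiles and toy structures.

The study cohort is 48 germline TP53 missense variants, 24 per phenotype
class, each characterized by a burial category and eleven conformational
difference scores.  The generator reproduces that statistical shape: burial
probability differs by class (LFS variants sit in buried residues far more
often), two of the continuous scores (compactness and protein-interaction
propensity differences) carry class-conditional location shifts with
positive LFS-minus-HBC direction, and the remaining scores are pure noise.
Default shift sizes are calibration constants chosen to give roughly the
discriminability of the real cohort (apparent C around 0.8 for the
three-variable model); they are not estimates of the real score
distributions.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import (
    CONTINUOUS_PREDICTORS,
    DIF_VARIABLES,
    WILDTYPE,
    MissenseVariant,
    ScoreProfile,
)
from .logistic import _expit
from .structure import AtomRecord, StructureModel, structure_from_atoms

__all__ = [
    "SimulationConfig",
    "ToyStructureSpec",
    "simulate_cohort",
    "simulate_profiles",
    "make_toy_structure",
]

#: Class-conditional means/sds for the informative difference scores.
#: comp_dif is on the compactness scale (differences of order tens), PPI6_dif
#: on the interaction-propensity scale (differences of order hundreds).
DEFAULT_SIGNAL = {
    "comp_dif": {"mean_lfs": 12.0, "mean_hbc": -12.0, "sd": 40.0},
    "PPI6_dif": {"mean_lfs": 80.0, "mean_hbc": -80.0, "sd": 400.0},
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings; defaults emulate the 24+24 study cohort."""

    n_lfs: int = 24
    n_hbc: int = 24
    p_buried_lfs: float = 0.55
    p_buried_hbc: float = 0.15
    p_unknown: float = 0.04
    signal: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SIGNAL.items()}
    )
    noise_sd: float = 1.0
    generator_betas: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_buried_lfs, self.p_buried_hbc, self.p_unknown):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for var, spec in self.signal.items():
            if var not in DIF_VARIABLES:
                raise ValueError(f"unknown signal variable {var!r}")
            if spec["sd"] <= 0:
                raise ValueError(f"sd for {var} must be positive")
        if self.n_lfs + self.n_hbc < 4:
            raise ValueError("cohort must contain at least 4 variants")


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[MissenseVariant], pd.DataFrame, np.ndarray]:
    """Draw a synthetic variant cohort with its feature table.

    Returns (variants, features, outcome) where ``features`` has the same
    columns as :func:`tp53conform.features.build_feature_table` and
    ``outcome`` is the 0/1 (HBC/LFS) vector.  With ``generator_betas`` set,
    features are drawn class-free (pooled mixtures) and the outcome is drawn
    from the logistic model on the simulated features instead of by design.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lfs + config.n_hbc

    if config.generator_betas is None:
        y = np.r_[np.ones(config.n_lfs), np.zeros(config.n_hbc)]
    else:
        y = np.full(n, np.nan)  # drawn after the features below

    # burial category
    bur = np.empty(n, dtype=object)
    for i in range(n):
        if rng.random() < config.p_unknown:
            bur[i] = "unknown"
            continue
        if config.generator_betas is None:
            p_b = config.p_buried_lfs if y[i] == 1 else config.p_buried_hbc
        else:
            p_b = 0.5 * (config.p_buried_lfs + config.p_buried_hbc)
        bur[i] = "Buried" if rng.random() < p_b else "Surface"

    difs: dict[str, np.ndarray] = {}
    for var in DIF_VARIABLES:
        spec = config.signal.get(var)
        if spec is None:
            difs[var] = rng.normal(0.0, config.noise_sd, size=n)
        elif config.generator_betas is None:
            means = np.where(y == 1, spec["mean_lfs"], spec["mean_hbc"])
            difs[var] = rng.normal(means, spec["sd"])
        else:
            pooled = 0.5 * (spec["mean_lfs"] + spec["mean_hbc"])
            difs[var] = rng.normal(pooled, spec["sd"], size=n)

    if config.generator_betas is not None:
        lp = np.full(n, config.generator_betas.get("Intercept", 0.0))
        lp += np.where(bur == "Surface", config.generator_betas.get("Bur[Surface]", 0.0), 0.0)
        lp += np.where(bur == "unknown", config.generator_betas.get("Bur[unknown]", 0.0), 0.0)
        for var, b in config.generator_betas.items():
            if var in DIF_VARIABLES:
                lp += b * difs[var]
        y = (rng.random(n) < _expit(lp)).astype(float)

    pool = np.arange(94, 293)
    positions = rng.choice(pool, size=n, replace=n > len(pool))
    variants = []
    seen: dict[str, int] = {}
    for i in range(n):
        wt, var_aa = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
        outcome = "LFS" if y[i] == 1 else "HBC"
        vid = f"{wt}{positions[i]}{var_aa}"
        if vid in seen:  # same substitution drawn twice in a large cohort
            seen[vid] += 1
            vid = f"{vid}.{seen[vid]}"
        else:
            seen[vid] = 0
        variants.append(
            MissenseVariant(
                variant_id=vid,
                position=int(positions[i]),
                wt_aa=str(wt),
                var_aa=str(var_aa),
                outcome=outcome,
                source="simulated",
            )
        )

    features = pd.DataFrame(
        {
            "position": positions,
            "Bur": bur,
            **difs,
            "outcome": [v.outcome for v in variants],
        },
        index=pd.Index([v.variant_id for v in variants], name="variant_id"),
    )
    features = features[["position", "Bur", *DIF_VARIABLES, "outcome"]]
    return variants, features, y


def simulate_profiles(
    protein_length: int,
    variants: Sequence[MissenseVariant],
    effect_spec: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> dict[tuple[str, str], ScoreProfile]:
    """Wild-type profiles plus per-variant profiles with point effects.

    ``effect_spec`` maps variant_id -> predictor -> score shift applied at
    the variant's substituted position (all other positions identical to the
    wild-type profile), so the downstream difference construction recovers
    the shifts exactly.  A ``None``/missing entry means zero effect.
    """
    rng = np.random.default_rng(seed)
    for v in variants:
        if v.position > protein_length:
            raise ValueError(f"{v.variant_id}: position beyond protein length")

    profiles: dict[tuple[str, str], ScoreProfile] = {}
    wt_scores = {
        pred: rng.uniform(0.0, 1.0, size=protein_length) for pred in CONTINUOUS_PREDICTORS
    }
    for pred, scores in wt_scores.items():
        profiles[(pred, WILDTYPE)] = ScoreProfile(pred, WILDTYPE, tuple(scores))
    for v in variants:
        effects = (effect_spec or {}).get(v.variant_id, {})
        for pred in CONTINUOUS_PREDICTORS:
            scores = wt_scores[pred].copy()
            scores[v.position - 1] += effects.get(pred, 0.0)
            profiles[(pred, v.variant_id)] = ScoreProfile(pred, v.variant_id, tuple(scores))
    return profiles


@dataclass(frozen=True)
class ToyStructureSpec:
    """Deterministic small structures for geometry testing."""

    geometry: str = "isolated"  # isolated | pair | compact_cluster | two_chain_contact
    n_atoms: int = 1
    spacing: float = 20.0  # Angstrom, pair separation
    seed: int = 0


def make_toy_structure(spec: ToyStructureSpec) -> StructureModel:
    """Construct the geometry fixtures.

    * ``isolated``: one carbon atom (analytic sphere SASA).
    * ``pair``: two atoms ``spacing`` apart (no mutual occlusion when the
      spacing exceeds the expanded-sphere sum).
    * ``compact_cluster``: ``n_atoms`` carbons jittered on a dense cubic grid
      so central residues end up buried.
    * ``two_chain_contact``: two 6-atom chains in van-der-Waals contact
      (interface fixture).
    """
    rng = np.random.default_rng(spec.seed)

    def atom(chain: str, resnum: int, name: str, pos: Sequence[float]) -> AtomRecord:
        return AtomRecord(
            chain_id=chain, residue_number=resnum, residue_name="ALA",
            atom_name=name, element="C",
            position=(float(pos[0]), float(pos[1]), float(pos[2])),
            vdw_radius=1.70,
        )

    if spec.geometry == "isolated":
        atoms = [atom("A", 100, "C1", (0.0, 0.0, 0.0))]
    elif spec.geometry == "pair":
        atoms = [
            atom("A", 100, "C1", (0.0, 0.0, 0.0)),
            atom("A", 101, "C1", (spec.spacing, 0.0, 0.0)),
        ]
    elif spec.geometry == "compact_cluster":
        n = max(spec.n_atoms, 8)
        side = int(np.ceil(n ** (1 / 3)))
        grid = [
            (i, j, k) for i in range(side) for j in range(side) for k in range(side)
        ][:n]
        # 2.0 A grid packs tighter than van-der-Waals contact so that the
        # central residues of a ~30-atom cluster drop below the 11 A^2 cutoff
        coords = 2.0 * np.array(grid, dtype=float)
        coords += rng.uniform(-0.2, 0.2, size=coords.shape)
        # centre-out ordering so low residue numbers sit in the middle
        centre = coords.mean(axis=0)
        order = np.argsort(np.linalg.norm(coords - centre, axis=1))
        atoms = []
        for rank, idx in enumerate(order):
            atoms.append(atom("A", 100 + rank // 3, f"C{rank % 3 + 1}", coords[idx]))
    elif spec.geometry == "two_chain_contact":
        base = 2.8 * np.array(
            [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0), (0, 0, 1), (1, 0, 1)],
            dtype=float,
        )
        atoms = []
        for i, pos in enumerate(base):
            atoms.append(atom("A", 100 + i // 3, f"C{i % 3 + 1}", pos))
        shifted = base + np.array([0.0, 0.0, 2.8 * 1.6])
        for i, pos in enumerate(shifted):
            atoms.append(atom("B", 100 + i // 3, f"C{i % 3 + 1}", pos))
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")

    return structure_from_atoms(atoms)
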