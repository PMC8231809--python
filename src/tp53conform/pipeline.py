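"""End-to-end orchestration: structure -> features -> statistics -> clinic.

A single config (YAML/JSON or dict) drives the whole analysis.  Inputs are
either real files (structure, profile TSV, variant CSV) or a simulation
block; every stochastic stage draws its seed from one root seed through
named substreams, so a completed run is byte-identical on rerun.  Each stage
writes its outputs and marks itself done in ``manifest.json``; a rerun over
an existing run directory resumes after the last completed stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import build_nomogram, decision_curve, render_nomogram_text
from .enrichment import dedupe_residue_set, enrichment_scan
from .features import (
    DIF_VARIABLES,
    build_feature_table,
    read_profiles,
    read_variants,
    write_variants,
)
from .logistic import (
    design_matrix,
    fit_logistic,
    model_to_json,
    published_model,
    summarize,
)
from .simulate import SimulationConfig, simulate_cohort
from .structure import (
    assign_secondary_structure,
    burial_from_structure,
    find_interface_residues,
    load_structure,
)
from .validation import (
    backward_stepdown,
    bootstrap_calibrate,
    bootstrap_validate,
    loo_cross_validate,
    roc_curve,
)

__all__ = ["RunConfig", "run_full_analysis", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "cutoffs": {
        "sasa_cutoff": 11.0,        # A^2, burial threshold
        "interface_cutoff": 1.0,    # A^2, buried-area threshold
        "probe_radius": 1.4,        # A, water probe
        "n_sphere_points": 960,
    },
    "statistics": {
        "sls_main": 0.13,           # significance-to-stay, main step-down
        "sls_loo": 0.16,            # significance-to-stay inside LOO folds
        "n_boot": 1000,
        "call_threshold": 0.5,
        "threshold_grid": [0.01, 0.99, 0.01],  # start, stop, step for DCA
    },
    "seed": 0,
}


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: Path
    seed: int = 0
    cutoffs: dict[str, float] = dataclasses.field(default_factory=dict)
    statistics: dict[str, Any] = dataclasses.field(default_factory=dict)
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None      # structure / profiles / variants paths
    published: str | None = None              # use a fixed published model, no refit
    resume: bool = True

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.cutoffs = {**DEFAULTS["cutoffs"], **self.cutoffs}
        self.statistics = {**DEFAULTS["statistics"], **self.statistics}
        for key, val in self.cutoffs.items():
            if val <= 0:
                raise ValueError(f"cutoff {key} must be positive, got {val}")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' block or 'inputs' paths")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))  # type: ignore[arg-type]

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def fingerprint(self) -> str:
        payload = {
            "seed": self.seed,
            "cutoffs": self.cutoffs,
            "statistics": self.statistics,
            "simulate": self.simulate,
            "inputs": self.inputs,
            "published": self.published,
            "version": __version__,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path, fingerprint: str, resume: bool):
        self.path = path
        self.data: dict[str, Any] = {
            "fingerprint": fingerprint,
            "version": __version__,
            "stages": {},
            "warnings": [],
            "overrides": [],
        }
        if resume and path.exists():
            old = json.loads(path.read_text())
            if old.get("fingerprint") == fingerprint:
                self.data = old

    def done(self, stage: str) -> bool:
        return self.data["stages"].get(stage, {}).get("status") == "done"

    def mark(self, stage: str, outputs: list[str], seed: int | None = None) -> None:
        self.data["stages"][stage] = {"status": "done", "outputs": outputs, "seed": seed}
        self.write()

    def warn(self, message: str) -> None:
        self.data["warnings"].append(message)

    def write(self) -> None:
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _record_overrides(config: RunConfig, manifest: _Manifest) -> None:
    for block in ("cutoffs", "statistics"):
        for key, default in DEFAULTS[block].items():
            actual = getattr(config, block)[key]
            if actual != default:
                manifest.data["overrides"].append(
                    {"parameter": f"{block}.{key}", "default": default, "value": actual}
                )


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Execute every stage in order and return a run report dict.

    Stages: features (simulated or structure-derived), enrichment, model
    fitting and reduction, bootstrap validation/calibration, leave-one-out
    predictions, ROC, decision curve, nomogram.  With ``config.published``
    set, fitting/validation are skipped and the fixed published model drives
    predictions and clinical outputs only.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", config.fingerprint(), config.resume)
    _record_overrides(config, manifest)
    report: dict[str, Any] = {"out_dir": str(out), "stages": manifest.data["stages"]}
    cut = config.cutoffs
    stat = config.statistics

    def stage(name: str):
        def decorator(fn):
            if manifest.done(name):
                return
            try:
                outputs = fn()
            except Exception as exc:
                manifest.warn(f"stage {name} failed: {exc}")
                manifest.write()
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest.mark(name, outputs, config.stage_seed(name))
        return decorator

    # ------------------------------------------------------------- features
    features_only = config.inputs is not None and "features" in config.inputs

    @stage("features")
    def _features() -> list[str]:
        if config.simulate is not None:
            sim = SimulationConfig(seed=config.stage_seed("features"), **config.simulate)
            variants, features, _y = simulate_cohort(sim)
            write_variants(variants, str(out / "variants.csv"))
        elif features_only:
            features = pd.read_csv(
                (config.inputs or {})["features"], sep="\t", index_col="variant_id"
            )
        else:
            paths = config.inputs or {}
            structure = load_structure(paths["structure"])
            variants = read_variants(paths["variants"])
            profiles = read_profiles(paths["profiles"])
            burial = burial_from_structure(
                structure, cut["sasa_cutoff"], cut["probe_radius"],
                int(cut["n_sphere_points"]),
            )
            features = build_feature_table(variants, profiles, burial)
        features.to_csv(out / "features.tsv", sep="\t")
        return ["features.tsv"]

    features = pd.read_csv(out / "features.tsv", sep="\t", index_col="variant_id")
    if "outcome" not in features.columns:
        features["outcome"] = np.nan
    outcome = features["outcome"]

    # ----------------------------------------------------------- enrichment
    @stage("enrichment")
    def _enrichment() -> list[str]:
        if features_only:
            return []  # no variant/structure inputs to test against
        variants = read_variants(str(out / "variants.csv")) if config.simulate is not None \
            else read_variants((config.inputs or {})["variants"])
        if config.simulate is not None:
            # simulation carries burial as a feature column; no geometry scan
            universe = set(features["position"])
            buried = set(features.loc[features["Bur"] == "Buried", "position"])
            known = set(features.loc[features["Bur"] != "unknown", "position"])
            groups = {
                g: {v.position for v in variants if v.outcome == g} & known
                for g in ("LFS", "HBC")
            }
            results = enrichment_scan(groups, {"Buried": buried}, universe & known)
        else:
            structure = load_structure((config.inputs or {})["structure"])
            universe = structure.canonical_positions()
            burial = burial_from_structure(
                structure, cut["sasa_cutoff"], cut["probe_radius"],
                int(cut["n_sphere_points"]),
            )
            buried = {b.canonical_position for b in burial if b.status == "Buried"}
            ss = assign_secondary_structure(structure)
            cats: dict[str, set[int]] = {"Buried": buried}
            for kind in ("helix", "sheet", "loop"):
                cats[kind] = {
                    structure.canonical_map[key]
                    for key, k in ss.items()
                    if k == kind and structure.canonical_map.get(key) is not None
                }
            prot = structure.protein_chains()
            nuc = structure.nucleic_chains()
            if nuc:
                dna_calls = find_interface_residues(
                    structure, prot, nuc, cut["interface_cutoff"],
                    cut["probe_radius"], int(cut["n_sphere_points"]),
                )
                cats["DNA-interface"] = {
                    structure.canonical_map[(c.chain_id, c.residue_number)]
                    for c in dna_calls
                    if structure.canonical_map.get((c.chain_id, c.residue_number))
                }
            groups = {}
            for g in ("LFS", "HBC"):
                grp = [v for v in variants if v.outcome == g]
                testable, excluded = dedupe_residue_set(grp, universe)
                if excluded:
                    manifest.warn(f"{g}: positions outside structure excluded: {sorted(excluded)}")
                groups[g] = testable
            results = enrichment_scan(groups, cats, universe)
        rows = [
            {
                "group": r.group, "category": r.category, "chain": r.chain,
                "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
                "odds_ratio": r.odds_ratio, "p": r.p, "p_adj": r.p_adjusted,
            }
            for r in results
        ]
        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return ["enrichment.tsv"]

    # --------------------------------------------------------------- models
    terms_full = ["Bur", *DIF_VARIABLES]

    if config.published is not None:
        model = published_model(config.published)
        model_files = []
    else:
        @stage("models")
        def _models() -> list[str]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = fit_logistic(features, outcome, terms_full)
                reduced = backward_stepdown(features, outcome, terms_full, sls=stat["sls_main"])
            (out / "model_full.json").write_text(model_to_json(full))
            (out / "model_reduced.json").write_text(model_to_json(reduced))
            summarize(full).to_csv(out / "model_full_summary.tsv", sep="\t")
            summarize(reduced).to_csv(out / "model_reduced_summary.tsv", sep="\t")
            return ["model_full.json", "model_reduced.json",
                    "model_full_summary.tsv", "model_reduced_summary.tsv"]

        from .logistic import model_from_json
        model = model_from_json((out / "model_reduced.json").read_text())
        model_files = ["model_reduced.json"]

        @stage("validation")
        def _validation() -> list[str]:
            rep = bootstrap_validate(
                features, outcome, terms_full,
                n_boot=int(stat["n_boot"]), sls=stat["sls_main"],
                seed=config.stage_seed("validation"),
            )
            cal = bootstrap_calibrate(
                features, outcome, list(model.terms),
                n_boot=int(stat["n_boot"]), seed=config.stage_seed("calibration"),
            )
            payload = {
                "apparent_C": rep.apparent_C,
                "optimism": rep.optimism,
                "corrected_C": rep.corrected_C,
                "n_boot": rep.n_boot,
                "n_redrawn": rep.n_redrawn,
                "seed": rep.seed,
                "selected_terms_counts": {
                    " + ".join(t): sum(1 for s in rep.selected_terms_per_replicate if s == t)
                    for t in set(rep.selected_terms_per_replicate)
                },
            }
            (out / "validation.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
            pd.DataFrame(
                {
                    "bin_midpoint": cal.bin_midpoints,
                    "apparent": cal.apparent,
                    "corrected": cal.corrected,
                    "n": cal.n_per_bin,
                }
            ).to_csv(out / "calibration.tsv", sep="\t", index=False)
            return ["validation.json", "calibration.tsv"]

        @stage("loo")
        def _loo() -> list[str]:
            preds = loo_cross_validate(
                features, outcome, terms_full, sls=stat["sls_loo"]
            )
            pd.DataFrame(
                {
                    "variant_id": [p.variant_id for p in preds],
                    "p_LFS": [p.probability_LFS for p in preds],
                    "terms": [" + ".join(p.terms_used) for p in preds],
                }
            ).to_csv(out / "loo_predictions.tsv", sep="\t", index=False)
            return ["loo_predictions.tsv"]

    # ---------------------------------------------------------- predictions
    X, _ = design_matrix(features, model.terms)
    probs = model.predict_proba_design(X)
    thr = stat["call_threshold"]
    has_labels = bool(outcome.notna().all()) and outcome.nunique() == 2

    @stage("predictions")
    def _predictions() -> list[str]:
        pd.DataFrame(
            {
                "variant_id": features.index,
                "p_LFS": probs,
                f"call_at_{thr}": np.where(probs > thr, "LFS", "HBC"),
            }
        ).to_csv(out / "predictions.tsv", sep="\t", index=False)
        written = ["predictions.tsv"]
        if has_labels:
            curve = roc_curve(probs, outcome)
            curve.to_csv(out / "roc.tsv", sep="\t", index=False)
            written.append("roc.tsv")
        return written

    # ------------------------------------------------------ clinical utility
    @stage("clinical")
    def _clinical() -> list[str]:
        written = []
        if has_labels:
            start, stop, step = stat["threshold_grid"]
            grid = np.round(np.arange(start, stop + step / 2, step), 10)
            curve = decision_curve(probs, outcome, grid)
            curve.to_frame().to_csv(out / "decision_curve.tsv", sep="\t", index=False)
            written.append("decision_curve.tsv")
        ranges = {
            t: (float(features[t].min()), float(features[t].max()))
            for t in model.terms if t != "Bur"
        }
        nomo = build_nomogram(model, ranges)
        (out / "nomogram.txt").write_text(render_nomogram_text(nomo) + "\n")
        nomo_json = {
            "scale_lp_per_point": nomo.scale,
            "base_lp": nomo.base_lp,
            "variables": [
                {
                    "name": v.name, "anchor_value": v.lo, "far_value": v.hi,
                    "beta": v.beta, "points_per_unit": v.points_per_unit,
                }
                for v in nomo.variables
            ],
        }
        (out / "nomogram.json").write_text(json.dumps(nomo_json, indent=2, sort_keys=True))
        return written + ["nomogram.txt", "nomogram.json"]

    manifest.write()
    report["warnings"] = manifest.data["warnings"]
    report["fingerprint"] = manifest.data["fingerprint"]
    return report
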