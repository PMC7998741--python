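"""End-to-end orchestration: synth → accelerometry → cognition → stats.

``run_study`` executes the whole chain under a single :class:`RunConfig`,
writes per-stage CSV artifacts plus a JSON results bundle, and records a
provenance manifest (config hash, seed, per-stage row counts, exclusion
accounting) so that a second run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accelerometry, cognition, stats, synthdata


@dataclass
class RunConfig:
    """All knobs of a study run; the defaults are the study constants."""

    seed: int = 0
    n_per_track: dict[str, int] = field(
        default_factory=lambda: {"Hairdresser": 26, "Admin": 24, "Sports": 34, "Nursing": 19}
    )
    n_days: int = 7
    bout_cutoff_min: float = 30.0
    cadence_threshold: float = 100.0
    rt_low_ms: float = 170.0
    rt_high_ms: float = 5000.0
    sd_multiplier: float = 3.0
    alpha: float = 0.05
    alpha_borderline: float = 0.1
    sb_ratio_per_day: bool = False
    sd_pooled_rounds: bool = False
    vif_threshold: float = 10.0
    #: cognitive ground truth (independent of activity: the null preset)
    cognitive_profile: dict = field(default_factory=dict)

    DEFAULTS = None  # populated below for override reporting

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def overrides(self) -> dict:
        """Settings that differ from the defaults (echoed in the manifest)."""
        default = dataclasses.asdict(RunConfig())
        mine = self.to_dict()
        return {k: v for k, v in mine.items() if default[k] != v}

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _comparison_to_dict(gc: stats.GroupComparison) -> dict:
    return {
        "outcome": gc.outcome_name,
        "F": gc.F,
        "df_between": gc.df_between,
        "df_error": gc.df_error,
        "p": gc.p,
        "significance_tier": gc.significance_tier,
        "n_complete": gc.n_complete,
        "n_dropped": gc.n_dropped,
        "emm": {g: {"mean": m, "se": s} for g, (m, s) in gc.emm.items()},
        "group_n": gc.group_n,
        "pairwise": [dataclasses.asdict(p) for p in gc.pairwise],
    }


def run_study(config: RunConfig, out_dir) -> dict:
    """Run every stage and write artifacts under ``out_dir``.

    Returns the results bundle (also written to ``results.json``).
    Any stage validation error aborts with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("cohort", "events", "cognition"), ss.generate_state(3) >> np.uint32(1)
    )}
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "overrides": config.overrides(),
        "seed": config.seed,
        "stages": {},
    }

    profiles = synthdata.default_profiles()
    cog_profile = synthdata.CognitiveProfile(**config.cognitive_profile)

    # -- synth ------------------------------------------------------------
    try:
        cohort = synthdata.generate_cohort(config.n_per_track, profiles, int(seeds["cohort"]))
        events = synthdata.generate_cohort_streams(
            cohort, profiles, config.n_days, int(seeds["events"])
        )
        cst, lmt = synthdata.generate_cohort_sessions(cohort, cog_profile, int(seeds["cognition"]))
    except synthdata.ConfigurationError as e:
        raise StageError("synth", str(e)) from e
    cohort.to_csv(out / "cohort.csv", index=False, float_format="%.6f")
    synthdata.write_events_csv(events, out / "events.csv")
    cst.to_csv(out / "cst_trials.csv", index=False, float_format="%.6f")
    lmt.to_csv(out / "lmt_trials.csv", index=False)
    manifest["stages"]["synth"] = {
        "participants": int(len(cohort)),
        "events": int(len(events)),
        "cst_trials": int(len(cst)),
        "lmt_trials": int(len(lmt)),
    }

    # -- accelerometry ----------------------------------------------------
    try:
        pab = accelerometry.summarize_cohort(
            events, config.bout_cutoff_min, config.cadence_threshold, config.sb_ratio_per_day
        )
    except accelerometry.StreamValidationError as e:
        raise StageError("accelerometry", str(e)) from e
    pab.to_csv(out / "pab.csv", index=False, float_format="%.6f")
    manifest["stages"]["accelerometry"] = {
        "participants": int(len(pab)),
        "valid": int(pab["valid"].sum()),
        "invalid": int((~pab["valid"]).sum()),
    }

    # -- cognition --------------------------------------------------------
    try:
        scores, excl = cognition.score_sessions(
            cst, lmt,
            rt_low_ms=config.rt_low_ms,
            rt_high_ms=config.rt_high_ms,
            sd_multiplier=config.sd_multiplier,
            sd_pooled_rounds=config.sd_pooled_rounds,
        )
    except cognition.SessionValidationError as e:
        raise StageError("cognition", str(e)) from e
    scores.to_csv(out / "scores.csv", index=False, float_format="%.6f")
    excl.to_csv(out / "exclusions.csv", index=False)
    manifest["stages"]["cognition"] = {
        "participants": int(len(scores)),
        "chance_excluded": int((excl["chance_excluded"] > 0).sum()),
        "exclusion_totals": {
            rule: int(excl[rule].sum()) for rule in cognition.FILTER_RULES
        },
    }

    # -- stats ------------------------------------------------------------
    results = analyze(cohort, pab, scores, config)
    manifest["stages"]["stats"] = {
        "ancova_outcomes": list(results["ancova"]),
        "association_cells": int(len(results["associations"]["correlations"])),
    }

    bundle = {"manifest": manifest, "results": results}
    serializable = _jsonable(bundle)
    (out / "results.json").write_text(json.dumps(serializable, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
    return bundle


def analyze(
    cohort: pd.DataFrame, pab: pd.DataFrame, scores: pd.DataFrame, config: RunConfig
) -> dict:
    """The statistical stage on already-materialised summary tables."""
    data = cohort.merge(pab, on="participant_id", how="inner")
    valid = data[data["valid"]].reset_index(drop=True)

    # covariate screen: fat % and muscle % are collinear by construction
    vifs = stats.vif_screen(valid[["age", "fat_pct", "muscle_pct"]])
    dropped = stats.flag_high_vif(vifs, config.vif_threshold)
    # of a collinear pair keep fat %, the study's adjustment variable
    cov_names = [c for c in ("age", "female", "fat_pct") if c not in dropped]
    covariates = valid[cov_names]

    outcomes = {
        "sitting": "sitting_hours",
        "standing": "standing_hours",
        "stepping": "stepping_hours",
        "time_in_bed": "time_in_bed_hours",
        "sb_ratio": "sb_ratio",
    }
    ancova_results = {}
    for name, col in outcomes.items():
        gc = stats.ancova(
            valid[col], valid["track"], covariates,
            outcome_name=name, alpha=config.alpha,
            alpha_borderline=config.alpha_borderline,
        )
        ancova_results[name] = _comparison_to_dict(gc)

    adherent = valid.groupby("track")["adheres_youth"].sum().astype(int).to_dict()
    sizes = valid.groupby("track").size().to_dict()
    adh = stats.adherence_test(adherent, sizes)
    adherence = {
        "observed": adh.observed.to_dict(),
        "chi2": adh.chi2,
        "df": adh.df,
        "p": adh.p,
        "posthoc": adh.posthoc.to_dict(orient="records"),
    }

    assoc_pab = valid[["participant_id", "sitting_hours", "standing_hours", "stepping_hours"]]
    assoc_pab = assoc_pab.rename(columns=lambda c: c.replace("_hours", ""))
    assoc_scores = scores.rename(
        columns={
            "inhibition_cost_ms": "inhibition",
            "shifting_cost_ms": "shifting",
            "updating_accuracy": "updating",
        }
    )
    associations = stats.association_suite(assoc_pab, assoc_scores, alpha=config.alpha)

    return {
        "vif": vifs,
        "vif_dropped": dropped,
        "covariates_used": cov_names,
        "ancova": ancova_results,
        "adherence": adherence,
        "associations": {
            "correlations": associations["correlations"].to_dict(orient="records"),
            "regressions": associations["regressions"],
        },
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj
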