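"""End-to-end orchestration: simulate → score → reliability → associate.

The pipeline reproduces a complete synthetic observer-reliability and
association study from one YAML/JSON config and one master seed, writing
every stage artifact (measurement CSVs, reliability JSON, Bland-Altman
coordinate CSVs, association tables) plus a consolidated run report.
Identical config + seed reproduces an identical report payload.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import run_association_suite
from .cohort import CohortParams, generate_cohort
from .observers import ObserverProfile, simulate_reliability_study
from .phantom import PhantomParams
from .reliability import (
    assemble_complete_cases,
    bland_altman,
    gwet_ac1,
    icc_absolute_agreement,
)
from .scoring import select_cohort_values, summarize_mfi_by_grade

logger = logging.getLogger("parafat.pipeline")

_KNOWN_SECTIONS = {
    "n_patients", "n_observers", "n_sessions", "levels", "alpha", "seed",
    "phantom", "observers", "cohort", "stages", "measurements_path",
    "cohort_path",
}
_STAGES = ("simulate", "score", "reliability", "associate")


@dataclass
class PipelineConfig:
    n_patients: int = 102
    n_observers: int = 3
    n_sessions: int = 2
    levels: tuple = ("L2L3",)
    alpha: float = 0.05
    seed: int = 0
    phantom: PhantomParams = field(default_factory=PhantomParams)
    observers: list = field(default_factory=list)   # ObserverProfile per observer
    cohort: CohortParams = field(default_factory=CohortParams)
    stages: tuple = _STAGES
    measurements_path: str | None = None            # analysis-only mode input
    cohort_path: str | None = None

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        payload = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(source) -> PipelineConfig:
    """Parse and validate a pipeline config.

    ``source`` may be a dict, a YAML/JSON file path, or an existing
    PipelineConfig (returned unchanged).  All problems are collected and
    reported in one itemised error.
    """
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text)   # YAML is a superset of JSON
    else:
        raw = dict(source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")

    errors: list[str] = []
    unknown = set(raw) - _KNOWN_SECTIONS
    for key in sorted(unknown):
        errors.append(f"unknown config key: {key!r}")

    def build(cls, section, name):
        try:
            return cls(**section) if isinstance(section, dict) else section
        except (TypeError, ValueError) as exc:
            errors.append(f"{name}: {exc}")
            return cls()

    phantom = build(PhantomParams, raw.get("phantom", {}), "phantom")
    cohort = build(CohortParams, raw.get("cohort", {}), "cohort")
    observers = []
    for i, obs in enumerate(raw.get("observers", []), start=1):
        observers.append(build(ObserverProfile, obs, f"observers[{i}]"))

    cfg = PipelineConfig(
        n_patients=int(raw.get("n_patients", 102)),
        n_observers=int(raw.get("n_observers", max(len(observers), 3))),
        n_sessions=int(raw.get("n_sessions", 2)),
        levels=tuple(raw.get("levels", ("L2L3",))),
        alpha=float(raw.get("alpha", 0.05)),
        seed=int(raw.get("seed", 0)),
        phantom=phantom,
        observers=observers,
        cohort=cohort,
        stages=tuple(raw.get("stages", _STAGES)),
        measurements_path=raw.get("measurements_path"),
        cohort_path=raw.get("cohort_path"),
    )

    if cfg.n_patients < 1:
        errors.append("n_patients must be >= 1")
    if cfg.n_observers < 2:
        errors.append("n_observers must be >= 2 for interobserver analysis")
    if cfg.n_sessions < 1:
        errors.append("n_sessions must be >= 1")
    if not 0 < cfg.alpha < 1:
        errors.append("alpha must lie in (0, 1)")
    for stage in cfg.stages:
        if stage not in _STAGES:
            errors.append(f"unknown stage {stage!r}")
    if cfg.observers and len(cfg.observers) != cfg.n_observers:
        errors.append(
            f"{len(cfg.observers)} observer profiles given for "
            f"{cfg.n_observers} observers"
        )
    if "simulate" not in cfg.stages:
        if ("reliability" in cfg.stages or "score" in cfg.stages) and not cfg.measurements_path:
            errors.append("analysis-only mode requires measurements_path")
        if cfg.measurements_path and not Path(cfg.measurements_path).exists():
            errors.append(f"measurements_path not found: {cfg.measurements_path}")
        if cfg.cohort_path and not Path(cfg.cohort_path).exists():
            errors.append(f"cohort_path not found: {cfg.cohort_path}")

    if errors:
        raise ValueError("invalid pipeline config:\n  - " + "\n  - ".join(errors))
    if not cfg.observers:
        cfg.observers = [
            ObserverProfile(roi_jitter_px=1, epimuscular_inclusion_prob=0.05,
                            grade_misclass_prob=0.10)
            for _ in range(cfg.n_observers)
        ]
    return cfg


def _reliability_stage(measurements: pd.DataFrame, outdir: Path | None) -> dict:
    out: dict = {"interobserver": {}, "intraobserver": {}, "bland_altman": {}}

    def pack(r):
        return {
            "statistic": r.statistic, "estimate": r.estimate,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "band": r.band,
            "n_subjects": r.n_subjects, "k_raters": r.k_raters,
            "ci_method": r.ci_method,
        }

    inter_mfi = assemble_complete_cases(measurements, "mfi", "interobserver")
    inter_gcs = assemble_complete_cases(measurements, "gcs", "interobserver")
    out["interobserver"]["mfi_icc"] = pack(icc_absolute_agreement(inter_mfi))
    out["interobserver"]["gcs_ac1"] = pack(gwet_ac1(inter_gcs))
    out["interobserver"]["n_dropped"] = int(inter_mfi.n_dropped)

    observers = sorted(measurements["observer"].unique())
    sessions = sorted(measurements["session"].unique())

    for obs in observers:
        if len(sessions) >= 2:
            intra_mfi = assemble_complete_cases(measurements, "mfi", "intraobserver", obs)
            intra_gcs = assemble_complete_cases(measurements, "gcs", "intraobserver", obs)
            out["intraobserver"][f"observer_{obs}"] = {
                "mfi_icc": pack(icc_absolute_agreement(intra_mfi)),
                "gcs_ac1": pack(gwet_ac1(intra_gcs)),
                "n_dropped": int(intra_mfi.n_dropped),
            }
            ba = bland_altman(intra_mfi.values[:, 0], intra_mfi.values[:, 1])
            out["bland_altman"][f"observer_{obs}_test_retest"] = {
                "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                "n_pairs": ba.n_pairs,
            }
            if outdir is not None:
                ba.coordinates.to_csv(
                    outdir / f"bland_altman_observer_{obs}_retest.csv", index=False
                )

    for i, a in enumerate(observers):
        for b in observers[i + 1 :]:
            cols = list(inter_mfi.columns)
            ba = bland_altman(
                inter_mfi.values[:, cols.index(a)], inter_mfi.values[:, cols.index(b)]
            )
            out["bland_altman"][f"observers_{a}_vs_{b}"] = {
                "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                "n_pairs": ba.n_pairs,
            }
            if outdir is not None:
                ba.coordinates.to_csv(
                    outdir / f"bland_altman_observers_{a}_vs_{b}.csv", index=False
                )
    return out


def run_pipeline(config, outdir=None) -> dict:
    """Execute the configured stages and return the consolidated run report.

    When ``outdir`` is given all stage artifacts (CSV/JSON) are written
    there; the report itself goes to ``report.json``.  The report payload is
    deterministic for a fixed config + seed.
    """
    cfg = validate_config(config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(cfg.seed)
    study_seed, cohort_seed = (int(s.generate_state(1)[0] % (2**31 - 1))
                               for s in master.spawn(2))
    report: dict = {
        "provenance": {"config_hash": cfg.config_hash(), "version": __version__,
                       "seed": cfg.seed},
        "counts": {},
        "stages": {},
    }

    measurements = None
    if "simulate" in cfg.stages:
        logger.info("simulate: %d patients, %d observers, %d sessions",
                    cfg.n_patients, cfg.n_observers, cfg.n_sessions)
        measurements = simulate_reliability_study(
            n_patients=cfg.n_patients,
            observer_profiles=list(cfg.observers),
            n_sessions=cfg.n_sessions,
            levels=tuple(cfg.levels),
            phantom_params=cfg.phantom,
            seed=study_seed,
        )
        if outdir is not None:
            measurements.to_csv(outdir / "measurements.csv", index=False)
    elif cfg.measurements_path:
        measurements = pd.read_csv(cfg.measurements_path)

    if measurements is not None:
        report["counts"]["measurements"] = int(len(measurements))
        report["counts"]["clipped_mfi"] = int(measurements.get(
            "was_clipped", pd.Series(dtype=bool)).sum())

    try:
        if "score" in cfg.stages and measurements is not None:
            level = cfg.levels[0]
            obs1 = measurements[
                (measurements["observer"] == measurements["observer"].min())
                & (measurements["session"] == 1)
            ]
            selected = select_cohort_values(obs1, level=level)
            grade_summary = summarize_mfi_by_grade(obs1)
            report["stages"]["score"] = {
                "level": level,
                "n_patients_selected": int(len(selected)),
                "grade_summary": grade_summary.to_dict(orient="records"),
            }
            if outdir is not None:
                selected.to_csv(outdir / "selected_values.csv", index=False)
                grade_summary.to_csv(outdir / "mfi_by_grade.csv", index=False)

        if "reliability" in cfg.stages and measurements is not None:
            logger.info("reliability: ICC / AC1 / Bland-Altman")
            rel = _reliability_stage(measurements, outdir)
            report["stages"]["reliability"] = rel
            report["counts"]["reliability_dropped"] = rel["interobserver"]["n_dropped"]
            if outdir is not None:
                (outdir / "reliability.json").write_text(json.dumps(rel, indent=2))

        if "associate" in cfg.stages:
            if cfg.cohort_path:
                cohort = pd.read_csv(cfg.cohort_path)
            else:
                params = dataclasses.replace(cfg.cohort, seed=cohort_seed)
                cohort = generate_cohort(params)
            if outdir is not None and not cfg.cohort_path:
                cohort.to_csv(outdir / "cohort.csv", index=False)
            suite = run_association_suite(cohort, alpha=cfg.alpha)
            report["counts"]["cohort_patients"] = int(len(cohort))
            report["stages"]["association"] = {
                "table": suite["table"].to_dict(orient="records"),
                "aic_comparisons": [
                    {
                        "outcome": c["outcome"],
                        "adjusted": c["adjusted"],
                        "aic_mfi": c["comparison"].aic_a,
                        "aic_gcs": c["comparison"].aic_b,
                        "delta": c["comparison"].delta,
                        "verdict": c["comparison"].verdict,
                        "better": c["comparison"].better,
                    }
                    for c in suite["comparisons"]
                ],
            }
            if outdir is not None:
                suite["table"].to_csv(outdir / "association_table.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
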