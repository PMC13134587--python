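"""Pipeline configuration, cohort file I/O and stage orchestration.

``run_pipeline`` executes the full chain — generate, impute, split,
calibrate twins, score, GAN synthesis + fidelity, virtual trial, window
sweep, metric evaluation — writing one artifact per stage into the
output directory.  Every stochastic stage receives an explicit seed
derived from the global seed, and every artifact records the
configuration hash and seed, so a rerun with the same configuration
reproduces the same numbers (GAN training is deterministic for fixed
numpy versions).
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

from .evaluation import metrics_report
from .gan_cohort import (
    FidelityThresholds,
    GanConfig,
    copula_baseline,
    fidelity_report,
    fit_generator,
)
from .risk_models import StsCoefficients, TwinRiskCoefficients, score_panel
from .synth_cohort import (
    BOOLEAN_COLUMNS,
    COHORT_COLUMNS,
    GroundTruthConfig,
    draw_outcomes,
    generate_cohort,
    inject_and_impute,
    split_cohort,
)
from .twin_builder import CalibrationConfig, VulnerabilityWeights, build_twins
from .virtual_trial import (
    InterventionPolicy,
    TrialConfig,
    simulate_trial,
    window_sweep,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "load_cohort_csv",
    "save_cohort_csv",
    "SchemaError",
]


class SchemaError(ValueError):
    """Cohort file header does not match the cohort schema."""


@dataclass
class PipelineConfig:
    ground_truth: GroundTruthConfig = field(default_factory=GroundTruthConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    weights: VulnerabilityWeights = field(default_factory=VulnerabilityWeights)
    gan: GanConfig = field(default_factory=GanConfig)
    trial: TrialConfig = field(default_factory=TrialConfig)
    policy: InterventionPolicy = field(default_factory=InterventionPolicy)
    sts: StsCoefficients = field(default_factory=StsCoefficients)
    twin_risk: TwinRiskCoefficients = field(default_factory=TwinRiskCoefficients)
    fidelity: FidelityThresholds = field(default_factory=FidelityThresholds)
    n_cohort: int = 10_000
    gan_train_n: int = 5_000
    run_gan: bool = True
    run_sweep: bool = True
    sweep_lead_times_h: tuple[float, ...] = (12, 24, 48, 60, 72, 96, 120)
    seed: int = 0
    out_dir: str = "artifacts"

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the global seed (< 2^31)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        blob = json.dumps(enc(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(cfg: PipelineConfig, extra: dict | None = None) -> dict:
    d = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    if extra:
        d.update(extra)
    return d


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the artifact directory.

    On a stage failure the exception is re-raised with the stage name;
    artifacts of completed stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, **_stamp(config)}
    stage = "generate"
    try:
        cohort = generate_cohort(config.ground_truth, config.n_cohort,
                                 seed=config.stage_seed("generate"))
        stage = "impute"
        cohort, imp_report = inject_and_impute(
            cohort, config.ground_truth, seed=config.stage_seed("missing"))
        save_cohort_csv(cohort, out / "cohort.csv")
        summary["stages"]["impute"] = {
            k: imp_report[k] for k in ("n_missing", "iterations", "converged")}

        stage = "split"
        train, val, test = split_cohort(cohort, seed=config.stage_seed("split"))
        for name, part in (("train", train), ("val", val), ("test", test)):
            save_cohort_csv(part, out / f"cohort_{name}.csv")

        stage = "calibrate"
        twins = build_twins(cohort, config.calibration, config.weights)
        twins.to_csv(out / "twins.csv", index=False)
        summary["stages"]["calibrate"] = {
            "n": len(twins),
            "converged_fraction": float(twins["converged"].mean()),
            "median_residual_ms": float(twins["calibration_residual_ms"].median()),
        }

        stage = "score"
        panel = score_panel(cohort, twins, config.sts, config.twin_risk)
        panel.to_csv(out / "score_panel.csv", index=False)

        if config.run_gan:
            stage = "gan"
            gan_train = cohort.iloc[:config.gan_train_n]
            gen = fit_generator(gan_train, config.gan)
            gen.save(out / "gan_checkpoint")
            synth = gen.sample(config.n_cohort, seed=config.stage_seed("gan-sample"))
            synth = draw_outcomes(synth, config.ground_truth,
                                  config.stage_seed("gan-outcomes"))
            save_cohort_csv(synth, out / "cohort_gan.csv")
            fid = fidelity_report(gan_train, synth, config.fidelity)
            fid.save_json(out / "fidelity_gan.json")
            cop = copula_baseline(gan_train, seed=config.stage_seed("copula"))
            fid_cop = fidelity_report(
                gan_train,
                cop.sample(config.n_cohort, seed=config.stage_seed("copula-sample")),
                config.fidelity)
            fid_cop.save_json(out / "fidelity_copula.json")
            summary["stages"]["gan"] = {
                "fidelity_pass": fid.passed,
                "correlation_gap": fid.correlation_gap,
                "copula_correlation_gap": fid_cop.correlation_gap,
            }

        stage = "trial"
        trial_cfg = dataclasses.replace(
            config.trial, seed=config.stage_seed("trial"))
        report = simulate_trial(cohort, panel["twin_prob"],
                                config.ground_truth, trial_cfg, config.policy)
        report.save_json(out / "trial_report.json")
        (out / "trial_report.txt").write_text(report.text_table() + "\n")
        report.km_intervention.to_csv(out / "km_intervention.csv", index=False)
        report.km_control.to_csv(out / "km_control.csv", index=False)
        summary["stages"]["trial"] = report.to_dict()

        if config.run_sweep:
            stage = "sweep"
            sweep = window_sweep(cohort, panel["twin_prob"],
                                 config.ground_truth, trial_cfg, config.policy,
                                 config.sweep_lead_times_h)
            sweep.to_csv(out / "window_sweep.csv", index=False)
            best = sweep.loc[sweep["argmin"], "lead_time_h"].iloc[0]
            summary["stages"]["sweep"] = {"optimal_lead_time_h": float(best)}

        stage = "evaluate"
        y = cohort["poaf_event"].to_numpy()
        rows = {}
        for name in ("twin_prob", "chads_vasc", "has_bled", "sts_surrogate"):
            rep = metrics_report(panel[name], y,
                                 seed=config.stage_seed(f"boot-{name}"))
            rows[name] = rep.to_dict()
        pd.DataFrame(rows).T.to_csv(out / "metrics.csv")
        (out / "metrics.json").write_text(json.dumps(rows, indent=2))
        summary["stages"]["evaluate"] = {
            name: {"auc": rows[name]["auc"], "auc_ci": rows[name]["auc_ci"]}
            for name in rows
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return out


# ---------------------------------------------------------------------------
# cohort CSV I/O

_BOOL_LIKE = BOOLEAN_COLUMNS + ["poaf_event", "censored"]


def save_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort table; missing values as empty cells."""
    cohort.to_csv(path, index=False)


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table, enforcing the exact schema.

    Raises :class:`SchemaError` listing unknown or missing columns.
    Round-trips :func:`save_cohort_csv` exactly, including missing cells.
    """
    df = pd.read_csv(path, dtype={"id": str})
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if extra or missing:
        parts = []
        if extra:
            parts.append(f"unknown column(s): {extra}")
        if missing:
            parts.append(f"missing column(s): {missing}")
        raise SchemaError("; ".join(parts))
    for c in _BOOL_LIKE:
        if df[c].dtype != bool:
            df[c] = df[c].map({"True": True, "False": False, True: True,
                               False: False})
            if df[c].isna().any():
                raise SchemaError(f"non-boolean values in column {c!r}")
            df[c] = df[c].astype(bool)
    df["poaf_day"] = pd.array(df["poaf_day"], dtype="Int64")
    return df[COHORT_COLUMNS]
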