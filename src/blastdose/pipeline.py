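"""End-to-end session orchestration: dosimetry -> behavior -> dose response.

A *session* is one experiment: several injury groups, each with replicate
weight-drop recordings on the rig plus per-larva behavioral exports and
phenotype tables.  The manifest (flat ``key = value`` file, dotted keys
for nesting, commas for lists) names every input file and parameter;
:func:`run_pipeline` executes the stages in dependency order, joins the
per-group mean maximal pressure onto each larva's phenotype record
(larvae in one syringe share the group-level dose — individual pressure
is not observable), and writes wave tables, behavior metrics, fit
reports and a structured run log.  Synthetic sessions declare a seed and
generator settings instead of files and exercise the identical path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import behavior, dose_response, dosimetry, synthetic_data, trace_io

__all__ = [
    "SessionManifest",
    "PipelineError",
    "parse_manifest",
    "validate_manifest",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class SessionManifest:
    """Parsed session description.

    ``groups`` maps group label -> dict with keys ``traces`` (list of raw
    trace CSV paths) and ``device`` (DeviceConfig), or the marker
    ``no_tbi: True`` for the uninjured control.  File-path fields may be
    None when the corresponding stage is skipped.
    """

    session_id: str
    groups: dict = field(default_factory=dict)
    control_group: str = "control"
    activity_csv: str | None = None
    phenotype_csv: str | None = None
    scores_csv: str | None = None
    fin_poke_csv: str | None = None
    params: dict = field(default_factory=dict)
    synthetic: dict | None = None
    seed: int | None = None
    base_dir: Path = field(default_factory=Path)

    def resolve(self, p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else self.base_dir / path


def _coerce(value: str):
    value = value.strip()
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


def parse_manifest(path: Union[str, Path]) -> SessionManifest:
    """Parse a flat ``key = value`` manifest file.

    Dotted keys nest (``g100.device.drop_mass_g = 100``); commas split
    lists (``g100.traces = d1.csv, d2.csv``).  Unparseable lines raise.
    """
    path = Path(path)
    flat: dict[str, object] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path.name}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if "," in value:
                flat[key] = [_coerce(v) for v in value.split(",") if v.strip()]
            else:
                flat[key] = _coerce(value)

    nested: dict = {}
    for key, value in flat.items():
        parts = key.split(".")
        node = nested
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value

    groups = {}
    for label, spec in nested.pop("group", {}).items():
        if not isinstance(spec, dict):
            raise ValueError(f"group.{label}: expected dotted sub-keys")
        entry: dict = {"no_tbi": bool(spec.get("no_tbi", False))}
        if "traces" in spec:
            traces = spec["traces"]
            entry["traces"] = traces if isinstance(traces, list) else [traces]
        if "device" in spec:
            entry["device"] = trace_io.DeviceConfig.from_dict(spec["device"])
        groups[label] = entry

    return SessionManifest(
        session_id=str(nested.pop("session_id", path.stem)),
        groups=groups,
        control_group=str(nested.pop("control_group", "control")),
        activity_csv=nested.pop("activity_csv", None),
        phenotype_csv=nested.pop("phenotype_csv", None),
        scores_csv=nested.pop("scores_csv", None),
        fin_poke_csv=nested.pop("fin_poke_csv", None),
        params=nested.pop("params", {}),
        synthetic=nested.pop("synthetic", None),
        seed=nested.pop("seed", None),
        base_dir=path.parent,
    )


def validate_manifest(manifest: SessionManifest) -> list[str]:
    """Schema and cross-reference checks; returns human-readable findings.

    Findings include missing trace files, phenotype groups with no
    dosimetry entry and no ``no_tbi`` marker, duplicated larva IDs, and a
    note whenever the shared control group is reused across comparisons.
    """
    findings: list[str] = []
    if manifest.synthetic is not None and manifest.seed is None:
        findings.append("synthetic session without a seed")
    for label, entry in manifest.groups.items():
        for trace_path in entry.get("traces", []):
            if not manifest.resolve(str(trace_path)).exists():
                findings.append(f"group {label}: missing trace file {trace_path}")
        if entry.get("traces") and "device" not in entry:
            findings.append(f"group {label}: traces listed but no device config")
    if manifest.phenotype_csv is not None:
        pheno_path = manifest.resolve(manifest.phenotype_csv)
        if not pheno_path.exists():
            findings.append(f"missing phenotype file {manifest.phenotype_csv}")
        else:
            df = pd.read_csv(pheno_path, comment="#")
            if df["larva_id"].duplicated().any():
                dupes = sorted(df.loc[df["larva_id"].duplicated(), "larva_id"].unique())
                findings.append(f"duplicated larva_id in phenotype table: {dupes}")
            for label in df["group"].unique():
                entry = manifest.groups.get(str(label))
                if entry is None:
                    findings.append(f"phenotype group {label!r} not in manifest")
                elif not entry.get("traces") and not entry.get("no_tbi"):
                    findings.append(
                        f"phenotype group {label!r} has no dosimetry and no no_tbi marker"
                    )
    if manifest.activity_csv is not None and not manifest.resolve(
        manifest.activity_csv
    ).exists():
        findings.append(f"missing activity file {manifest.activity_csv}")
    return findings


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def log(self, stage: str, message: str, **params) -> None:
        rendered = " ".join(f"{k}={v}" for k, v in params.items())
        self.lines.append(f"[{stage}] {message}" + (f" | {rendered}" if rendered else ""))
        self.path.write_text("\n".join(self.lines) + "\n", encoding="utf-8")


def _dosimetry_stage(manifest, out_dir, log) -> dict[str, float]:
    """Convert and segment every group's traces; return group mean doses."""
    seg = dosimetry.SegmentationParams(
        exceedance_kpa=manifest.params.get("exceedance_kpa"),
        min_duration_ms=manifest.params.get("min_duration_ms", 1.0),
        baseline_window_ms=manifest.params.get("baseline_window_ms", 100.0),
        baseline_mode=manifest.params.get("baseline_mode", "trailing"),
    )
    wave_rows, rep_rows = [], []
    group_dose: dict[str, float] = {}
    for label, entry in manifest.groups.items():
        if entry.get("no_tbi"):
            group_dose[label] = 0.0
            continue
        drops = []
        for i, trace_path in enumerate(entry.get("traces", []), start=1):
            resolved = manifest.resolve(str(trace_path))
            if not resolved.exists():
                raise PipelineError("dosimetry", f"missing trace file {trace_path}")
            raw = trace_io.read_raw_trace(resolved, entry.get("device"), drop_index=i)
            summary = dosimetry.summarize_drop(trace_io.convert_trace(raw), seg)
            drops.append(summary)
            for w in summary.waves:
                wave_rows.append(
                    {
                        "group": label,
                        "drop_index": i,
                        "wave_index": w.index,
                        "start_ms": w.start_ms,
                        "end_ms": w.end_ms,
                        "peak_kpa": w.peak_kpa,
                        "mean_kpa": w.mean_kpa,
                        "duration_ms": w.duration_ms,
                    }
                )
        if not drops:
            continue
        if len(drops) >= 2:
            rep = dosimetry.summarize_replicates(drops)
            group_dose[label] = rep.mean_max_pressure_kpa
            rep_rows.append(
                {
                    "group": label,
                    "n_drops": rep.n_drops,
                    "mean_max_pressure_kpa": rep.mean_max_pressure_kpa,
                    "sem_max_pressure_kpa": rep.sem_max_pressure_kpa,
                    "rsd_percent": rep.rsd_percent,
                }
            )
        else:
            group_dose[label] = drops[0].maximal_pressure_kpa
        log.log(
            "dosimetry",
            f"group {label}",
            n_drops=len(drops),
            mean_max_kpa=round(group_dose[label], 3),
        )
    if wave_rows:
        pd.DataFrame(wave_rows).to_csv(out_dir / "wave_table.csv", index=False)
    if rep_rows:
        pd.DataFrame(rep_rows).to_csv(out_dir / "replicate_summary.csv", index=False)
    return group_dose


def _behavior_stage(manifest, out_dir, log) -> pd.DataFrame | None:
    if manifest.activity_csv is None:
        return None
    path = manifest.resolve(manifest.activity_csv)
    if not path.exists():
        raise PipelineError("behavior", f"missing activity file {manifest.activity_csv}")
    traces = behavior.read_activity_csv(path)
    metrics = behavior.larva_metrics(
        traces,
        control_group=manifest.control_group,
        threshold=manifest.params.get("high_activity_threshold"),
        inactivity_min_s=manifest.params.get("inactivity_min_s", 60.0),
        epsilon=manifest.params.get("epsilon", 0.0),
    )
    metrics.to_csv(out_dir / "behavior_metrics.csv", index=False)
    n_dead = int(metrics["candidate_dead"].sum())
    log.log(
        "behavior",
        "per-larva metrics",
        n_larvae=len(metrics),
        candidate_dead=n_dead,
    )
    return metrics


def _dose_response_stage(manifest, group_dose, out_dir, log) -> dict | None:
    if manifest.phenotype_csv is None:
        return None
    path = manifest.resolve(manifest.phenotype_csv)
    if not path.exists():
        raise PipelineError(
            "dose_response", f"missing phenotype file {manifest.phenotype_csv}"
        )
    df = pd.read_csv(path, comment="#")
    if "max_pressure_kpa" not in df.columns or df["max_pressure_kpa"].isna().any():
        # larvae within a syringe share the group-level dose
        missing = [g for g in df["group"].unique() if str(g) not in group_dose]
        if missing:
            raise PipelineError(
                "dose_response", f"no dosimetry for phenotype group(s) {missing}"
            )
        df["max_pressure_kpa"] = [group_dose[str(g)] for g in df["group"]]
    records = [
        dose_response.PhenotypeRecord(
            larva_id=str(row.larva_id),
            group=str(row.group),
            outcome=int(row.outcome),
            max_pressure_kpa=float(row.max_pressure_kpa),
            n_drops=int(getattr(row, "n_drops", 1)),
        )
        for row in df.itertuples(index=False)
    ]
    covariates = manifest.params.get("covariates", "max_pressure_kpa")
    if isinstance(covariates, str):
        covariates = [c.strip() for c in covariates.split("+")]
    try:
        fit = dose_response.fit_logistic(records, covariates=covariates)
    except (dose_response.SeparationError, ValueError) as exc:
        raise PipelineError("dose_response", str(exc)) from exc
    report = {
        "model": fit.model_spec,
        "n": fit.n,
        "auc": fit.auc,
        "intercept": fit.intercept,
        "effects": {
            name: {
                "odds_ratio": eff.odds_ratio,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "p_value": eff.p_value,
                "percent_change_per_100_units": round(
                    dose_response.scale_odds_ratio(eff.odds_ratio, 100)[1], 1
                ),
            }
            for name, eff in fit.effects.items()
        },
    }
    with (out_dir / "dose_response_fit.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    pd.DataFrame(
        [
            {
                "covariate": name,
                "odds_ratio": eff.odds_ratio,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "p_value": eff.p_value,
                "auc": fit.auc,
                "n": fit.n,
            }
            for name, eff in fit.effects.items()
        ]
    ).to_csv(out_dir / "dose_response_fit.csv", index=False)
    log.log("dose_response", fit.model_spec, n=fit.n, auc=round(fit.auc, 4))
    return report


def _materialize_synthetic(manifest: SessionManifest, out_dir: Path, log) -> None:
    """Generate input files for a synthetic session, then treat them as data."""
    spec = manifest.synthetic or {}
    seed = int(manifest.seed or 0)
    data_dir = (out_dir / "synthetic_inputs").resolve()
    data_dir.mkdir(exist_ok=True)

    doses = spec.get("doses_kpa", [0.0, 150.0, 300.0, 600.0])
    if not isinstance(doses, list):
        doses = [doses]
    n_drops = int(spec.get("n_drops", 1))
    heights = spec.get("heights_cm", [27.0, 54.0, 108.0])
    if not isinstance(heights, list):
        heights = [heights]

    # pressure traces: one group per drop height, 3 replicate drops each
    manifest.groups = {}
    for gi, height in enumerate(heights):
        label = f"h{height:g}cm"
        device = synthetic_data.default_device(drop_height_cm=float(height))
        paths = []
        for rep in range(int(spec.get("replicates", 3))):
            cfg = synthetic_data.ImpactSimConfig(
                device=device,
                noise_sd_kpa=float(spec.get("noise_sd_kpa", 0.5)),
                seed=seed + 101 * gi + rep,
            )
            raw = synthetic_data.simulate_drop_trace(cfg)
            p = data_dir / f"trace_{label}_drop{rep + 1}.csv"
            trace_io.write_raw_trace(raw, p)
            paths.append(str(p))
        manifest.groups[label] = {"no_tbi": False, "traces": paths, "device": device}
    log.log("synthetic", "trace files generated", groups=len(heights))

    # activity traces across the dose range
    bcfg_base = synthetic_data.BehaviorSimConfig(
        n_per_group=int(spec.get("n_per_group", 24)),
        recording_s=float(spec.get("recording_s", 1800.0)),
        seed=seed,
    )
    traces = []
    for di, dose in enumerate(doses):
        cfg = synthetic_data.BehaviorSimConfig(
            n_per_group=bcfg_base.n_per_group,
            recording_s=bcfg_base.recording_s,
            seed=seed + 1000 + di,
        )
        label = manifest.control_group if dose == 0 else f"{dose:g}kPa"
        traces.extend(synthetic_data.simulate_activity(cfg, float(dose), group=label))
    activity_path = data_dir / "activity.csv"
    behavior.write_activity_csv(traces, activity_path)
    manifest.activity_csv = str(activity_path)
    log.log("synthetic", "activity file generated", n_larvae=len(traces))

    # phenotype table from the stated logistic model
    pcfg = synthetic_data.PhenotypeSimConfig(
        b0=float(spec.get("b0", -2.0)),
        b1_per_kpa=float(spec.get("b1_per_kpa", np.log(1.005))),
        b2_per_drop=float(spec.get("b2_per_drop", 0.0)),
        doses=tuple((float(d), n_drops) for d in doses if d > 0) or ((150.0, 1),),
        n_per_dose=int(spec.get("n_per_dose", 100)),
        seed=seed + 5000,
    )
    records = synthetic_data.simulate_phenotypes(pcfg)
    pheno_path = data_dir / "phenotypes.csv"
    pd.DataFrame(
        [
            {
                "larva_id": r.larva_id,
                "group": r.group,
                "outcome": r.outcome,
                "max_pressure_kpa": r.max_pressure_kpa,
                "n_drops": r.n_drops,
            }
            for r in records
        ]
    ).to_csv(pheno_path, index=False)
    manifest.phenotype_csv = str(pheno_path)
    # synthetic phenotype groups carry their own dose column; register markers
    for r in records:
        manifest.groups.setdefault(r.group, {"no_tbi": True})
    log.log("synthetic", "phenotype table generated", n_records=len(records))


def run_pipeline(
    manifest: Union[SessionManifest, str, Path],
    out_dir: Union[str, Path],
) -> dict:
    """Run all applicable stages; returns the session report dict.

    Stages run in dependency order (synthesize -> dosimetry -> behavior ->
    dose response); a stage failure raises :class:`PipelineError` naming
    the stage, with earlier partial outputs preserved on disk.  Output is
    a pure function of (input files, parameters, seed).
    """
    if not isinstance(manifest, SessionManifest):
        manifest = parse_manifest(manifest)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out_dir / "run_log.txt")
    log.log("session", manifest.session_id, seed=manifest.seed)

    if manifest.synthetic is not None:
        _materialize_synthetic(manifest, out_dir, log)

    findings = validate_manifest(manifest)
    for finding in findings:
        log.log("validate", finding)
    fatal = [f for f in findings if "missing" in f or "duplicated" in f]
    if fatal:
        raise PipelineError("validate", "; ".join(fatal))

    group_dose = _dosimetry_stage(manifest, out_dir, log)
    _behavior_stage(manifest, out_dir, log)
    fit_report = _dose_response_stage(manifest, group_dose, out_dir, log)

    report = {
        "session_id": manifest.session_id,
        "seed": manifest.seed,
        "group_mean_max_pressure_kpa": group_dose,
        "dose_response": fit_report,
        "findings": findings,
    }
    with (out_dir / "session_report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.log("session", "complete")
    return report
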