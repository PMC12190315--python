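"""Config-driven orchestration: simulate -> process -> analyze -> report.

A single YAML config drives every stage; unknown keys are rejected so typos
fail loudly before any processing.  Each processing run writes a
run-manifest JSON recording the resolved config hash, package version and
per-stage record counts (licks read = licks kept + licks filtered).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bout_segmentation import SegmentationParams, label_licks, segment
from .errors import LickstructError, ValidationError
from .event_io import (
    EVENTS_DIALECT,
    NONBOUT,
    SAMPLES_DIALECT,
    LogDialect,
    SessionRecord,
    read_event_log,
    read_lick_table,
    read_sample_log,
    read_session_manifest,
    write_tables,
)
from .intake_pk import FLUID_SPECS, FluidSpec, compute_intake, fit_accumulation, slope_ratio
from .lick_processing import (
    DetectionParams,
    Lick,
    build_licks,
    dedupe_onsets,
    detect_transitions,
    filter_licks,
)
from .microstructure import (
    TemporalParams,
    pooled_time_distribution,
    summarize_session,
)
from .stats import (
    MixedModelSpec,
    fit_mixed_model,
    ks_two_sample,
    location_test,
    mixed_anova,
)

_log = logging.getLogger(__name__)

_DEFAULT_CONFIG: dict = {
    "paths": {"logs_dir": "logs", "manifest": "manifest.csv", "out_dir": "out"},
    "dialect": {"kind": "events", "delimiter": ",", "timestamp": "seconds",
                "has_header": True},
    "detection": {"delta": 12, "sample_period": None},
    "licks": {"min_duration_s": 0.005, "max_duration_s": 10.0, "channel": 0},
    "bout": {"init_n": 3, "init_ili_max_s": 1.0, "term_gap_s": 3.0},
    "temporal": {"frontload_window_s": 1800.0, "kde_grid_points": 256,
                 "kde_bandwidth_rule": "scott"},
    "fluid": {"ethanol_vol_fraction": 0.20, "ethanol_density": 0.789,
              "solution_density": 0.97, "additive": "none"},
    "pk": {"include_intercept": True, "bootstrap_reps": 2000, "seed": 0},
    "stats": {"location_method": "auto"},
    "simulate": {"n_per_group": 12, "session_length_s": 7200.0,
                 "fluid": "ethanol20", "dialect": "events",
                 "sample_period_s": 0.005},
    "seed": 0,
    "log_level": "INFO",
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ValidationError(f"unknown config key {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValidationError(f"config key {here!r} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


@dataclass
class PipelineConfig:
    raw: dict
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def load(cls, path: str | Path | None = None, overrides: dict | None = None
             ) -> "PipelineConfig":
        raw = {}
        base_dir = Path(".")
        if path is not None:
            with open(path, encoding="utf-8") as fh:
                raw = yaml.safe_load(fh) or {}
            base_dir = Path(path).parent
        merged = _merge(_DEFAULT_CONFIG, raw)
        if overrides:
            merged = _merge(merged, overrides)
        cfg = cls(merged, base_dir)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        # constructing the parameter objects runs all their invariant checks
        self.segmentation()
        self.detection()
        self.temporal()
        self.fluid()
        licks = self.raw["licks"]
        if not (0 <= licks["min_duration_s"] < licks["max_duration_s"]):
            raise ValidationError("licks: need 0 <= min_duration_s < max_duration_s")

    # -- typed accessors -----------------------------------------------------
    def path(self, key: str) -> Path:
        p = Path(self.raw["paths"][key])
        return p if p.is_absolute() else self.base_dir / p

    def dialect(self) -> LogDialect:
        d = self.raw["dialect"]
        return LogDialect(
            kind=d["kind"], delimiter=d["delimiter"],
            timestamp=d["timestamp"], has_header=d["has_header"],
        )

    def detection(self) -> DetectionParams:
        d = self.raw["detection"]
        return DetectionParams(delta=d["delta"], sample_period=d["sample_period"])

    def segmentation(self) -> SegmentationParams:
        b = self.raw["bout"]
        return SegmentationParams(
            init_n=b["init_n"], init_ili_max=b["init_ili_max_s"],
            term_gap=b["term_gap_s"],
        )

    def temporal(self) -> TemporalParams:
        t = self.raw["temporal"]
        return TemporalParams(
            frontload_window=t["frontload_window_s"],
            kde_grid_points=t["kde_grid_points"],
            kde_bandwidth_rule=t["kde_bandwidth_rule"],
        )

    def fluid(self) -> FluidSpec:
        f = self.raw["fluid"]
        return FluidSpec(
            ethanol_vol_fraction=f["ethanol_vol_fraction"],
            ethanol_density=f["ethanol_density"],
            solution_density=f["solution_density"],
            additive=f["additive"],
        )

    def hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _fluid_spec_for(record: SessionRecord, cfg: PipelineConfig) -> FluidSpec:
    if record.fluid in FLUID_SPECS and record.fluid != "ethanol20":
        return FLUID_SPECS[record.fluid]
    return cfg.fluid()


def process_session(
    record: SessionRecord, licks: list[Lick], cfg: PipelineConfig
) -> tuple[list[Lick], list, list[str], dict]:
    """Filter, segment, label and summarize one session's lick train."""
    n_read = len(licks)
    kept = filter_licks(
        licks,
        cfg.raw["licks"]["min_duration_s"],
        cfg.raw["licks"]["max_duration_s"],
    )
    lk = dedupe_onsets(kept)
    bouts, _ = segment([l.onset for l in lk], cfg.segmentation())
    labels = label_licks(lk, bouts)
    summary = summarize_session(lk, bouts, labels, record, cfg.temporal())
    summary.intake = compute_intake(record, _fluid_spec_for(record, cfg))
    row = summary.to_dict()
    row.update(
        animal_id=record.animal_id,
        genotype=record.genotype,
        sex=record.sex,
        fluid=record.fluid,
        day_index=record.day_index,
        bec=record.bec if record.bec is not None else math.nan,
        licks_read=n_read,
        licks_filtered=n_read - len(kept),
    )
    return lk, bouts, labels, row


def run_process(cfg: PipelineConfig) -> dict:
    """Read logs and manifest, process every session, write all tables.

    Returns a dict with the lick/bout/summary DataFrames and written paths.
    Any stage error is re-raised with the stage name and session_id.
    """
    manifest = read_session_manifest(cfg.path("manifest"))
    dialect = cfg.dialect()
    logs_dir = cfg.path("logs_dir")
    channel = cfg.raw["licks"]["channel"]
    lick_rows, bout_rows, summary_rows = [], [], []
    counts = {"licks_read": 0, "licks_kept": 0, "licks_filtered": 0}
    for record in manifest:
        try:
            log_path = logs_dir / f"{record.session_id}.csv"
            if dialect.kind == "samples":
                df = read_sample_log(log_path, dialect)
                df = df[df["channel"] == channel]
                events = detect_transitions(
                    df["t"].to_numpy(), df["value"].to_numpy(), cfg.detection()
                )
            else:
                events = [
                    ev for ev in read_event_log(log_path, dialect)
                    if ev.channel == channel
                ]
            raw_licks = build_licks(events, record.session_id, channel)
            licks, bouts, labels, row = process_session(record, raw_licks, cfg)
            counts["licks_read"] += len(raw_licks)
            counts["licks_kept"] += len(licks)
            counts["licks_filtered"] += row["licks_filtered"]
            _log.info(
                "session %s: %d licks, %d bouts", record.session_id,
                len(licks), len(bouts),
            )
        except LickstructError as exc:
            raise type(exc)(
                f"[process/{record.session_id}] {exc}"
            ) from exc
        for lk, lab in zip(licks, labels):
            lick_rows.append(
                dict(session_id=record.session_id, channel=lk.channel,
                     onset_s=lk.onset, duration_s=lk.duration,
                     bout_id=lab if lab == NONBOUT else lab.lstrip("b"))
            )
        for bout in bouts:
            bout_rows.append(
                dict(session_id=record.session_id, bout_id=bout.bout_id,
                     start_s=bout.start, end_s=bout.end, n_licks=bout.n_licks,
                     total_lick_duration_s=bout.total_lick_duration)
            )
        summary_rows.append(row)
    lick_df = pd.DataFrame(
        lick_rows,
        columns=["session_id", "channel", "onset_s", "duration_s", "bout_id"],
    )
    bout_df = pd.DataFrame(
        bout_rows,
        columns=["session_id", "bout_id", "start_s", "end_s", "n_licks",
                 "total_lick_duration_s"],
    )
    summary_df = pd.DataFrame(summary_rows)
    out_dir = cfg.path("out_dir")
    paths = write_tables(
        lick_df, bout_df, summary_rows, out_dir
    )
    summary_df.to_csv(out_dir / "summary.csv", index=False, float_format="%.6f")
    paths["summary_csv"] = out_dir / "summary.csv"
    run_manifest = {
        "config_hash": cfg.hash(),
        "version": __version__,
        "n_sessions": len(manifest),
        **counts,
    }
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(run_manifest, fh, indent=2)
        fh.write("\n")
    paths["run_manifest"] = out_dir / "run_manifest.json"
    return {
        "licks": lick_df, "bouts": bout_df, "summary": summary_df,
        "paths": paths, "run_manifest": run_manifest,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def run_analyze(
    cfg: PipelineConfig, summary_df: pd.DataFrame, lick_df: pd.DataFrame
) -> dict:
    """Run the group-level statistics and return a JSON-ready report.

    Blocks: intake~behavior mixed models, group intake test, pooled
    time/cumulative KS comparisons, frontloading tests, bout/non-bout
    duration mixed ANOVA, and BEC accumulation slopes with their ratio.
    Blocks whose preconditions fail are skipped with a warning entry.
    """
    report: dict = {"blocks": {}, "warnings": []}
    method = cfg.raw["stats"]["location_method"]
    genos = sorted(summary_df["genotype"].unique())
    if len(genos) < 2:
        report["warnings"].append(
            "single genotype in summary; group comparisons skipped"
        )
        return report
    g_ref, g_alt = "wild_type", "adh1_ko"
    if set(genos) != {g_ref, g_alt}:
        g_ref, g_alt = genos[0], genos[1]

    # 1. intake ~ behavior * genotype mixed models -----------------------
    models = {}
    for predictor in ("total_licks", "total_lick_duration", "n_bouts"):
        spec = MixedModelSpec(
            response="intake",
            fixed_effects=(predictor, "genotype", f"{predictor}:genotype"),
            grouping="animal_id",
        )
        try:
            models[predictor] = fit_mixed_model(summary_df, spec)
        except LickstructError as exc:
            report["warnings"].append(f"intake~{predictor} model skipped: {exc}")
    report["blocks"]["intake_models"] = models

    # 2. group intake location test --------------------------------------
    per_animal = summary_df.groupby(["animal_id", "genotype"], as_index=False)[
        "intake"
    ].mean()
    a = per_animal.loc[per_animal["genotype"] == g_ref, "intake"]
    b = per_animal.loc[per_animal["genotype"] == g_alt, "intake"]
    report["blocks"]["intake_group_test"] = location_test(a, b, method)

    # 3. pooled time / cumulative-lick distributions ----------------------
    sess_geno = summary_df.set_index("session_id")["genotype"]
    group_sessions: dict[str, list] = {g: [] for g in (g_ref, g_alt)}
    for session_id, sub in lick_df.groupby("session_id"):
        g = sess_geno.get(session_id)
        if g in group_sessions:
            group_sessions[g].append(sub["onset_s"].to_numpy())
    try:
        pooled = pooled_time_distribution(group_sessions)
        report["blocks"]["distributions_ks"] = {
            "times": ks_two_sample(
                pooled[g_ref]["times"], pooled[g_alt]["times"]
            ),
            "cumulative": ks_two_sample(
                pooled[g_ref]["cumulative"], pooled[g_alt]["cumulative"]
            ),
        }
    except LickstructError as exc:
        report["warnings"].append(f"distribution block skipped: {exc}")

    # 4. frontloading ------------------------------------------------------
    front = {}
    for col, name in (
        ("licks_frontload", "frontload"),
        ("licks_postfrontload", "postfrontload"),
    ):
        pa = summary_df.groupby(["animal_id", "genotype"], as_index=False)[col].sum()
        a = pa.loc[pa["genotype"] == g_ref, col]
        b = pa.loc[pa["genotype"] == g_alt, col]
        front[name] = location_test(a, b, method)
    report["blocks"]["frontloading"] = front

    # 5. bout vs non-bout duration mixed ANOVA ----------------------------
    merged = lick_df.merge(
        summary_df[["session_id", "animal_id", "genotype"]], on="session_id"
    )
    merged["bout_type"] = np.where(merged["bout_id"] == NONBOUT, "nonbout", "bout")
    cell = merged.groupby(
        ["animal_id", "genotype", "bout_type"], as_index=False
    )["duration_s"].mean()
    complete = cell.groupby("animal_id")["bout_type"].nunique()
    keep = complete[complete == 2].index
    dropped = sorted(set(cell["animal_id"]) - set(keep))
    if dropped:
        report["warnings"].append(
            f"animals without both bout types dropped from ANOVA: {dropped}"
        )
    cell = cell[cell["animal_id"].isin(keep)]
    try:
        report["blocks"]["bout_structure_anova"] = mixed_anova(
            cell, dv="duration_s", within="bout_type", between="genotype",
            subject="animal_id",
        )
    except Exception as exc:  # pingouin failures included
        report["warnings"].append(f"bout-structure ANOVA skipped: {exc}")

    # 6. BEC accumulation --------------------------------------------------
    has_bec = summary_df["bec"].notna() if "bec" in summary_df else pd.Series(False)
    if has_bec.sum() >= 6:
        sub = summary_df[has_bec]
        try:
            fits = fit_accumulation(
                sub["intake"], sub["bec"], sub["genotype"],
                include_intercept=cfg.raw["pk"]["include_intercept"],
            )
            pts = {
                g: (
                    sub.loc[sub["genotype"] == g, "intake"].to_numpy(),
                    sub.loc[sub["genotype"] == g, "bec"].to_numpy(),
                )
                for g in (g_ref, g_alt)
            }
            ratio = slope_ratio(
                fits[g_ref], fits[g_alt],
                points_a=pts[g_ref], points_b=pts[g_alt],
                n_boot=cfg.raw["pk"]["bootstrap_reps"],
                seed=cfg.raw["pk"]["seed"],
                include_intercept=cfg.raw["pk"]["include_intercept"],
            )
            report["blocks"]["accumulation"] = {
                "fits": fits, "slope_ratio": ratio,
                "ratio_direction": f"{g_alt}/{g_ref}",
            }
        except LickstructError as exc:
            report["warnings"].append(f"accumulation block skipped: {exc}")
    else:
        report["warnings"].append(
            "missing bec column or too few measurements; accumulation skipped"
        )
    return report


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2)
        fh.write("\n")
    return path


def render_report(report: dict) -> str:
    """Human-readable rendering of an analysis report."""
    lines = ["lickstruct analysis report", "=" * 26]
    blocks = report.get("blocks", {})
    models = blocks.get("intake_models", {})
    for name, fit in models.items():
        f, (d1, d2), p = (
            fit["interaction_test"] if isinstance(fit, dict)
            else fit.interaction_test
        )
        lines.append(
            f"intake ~ {name} * genotype: interaction "
            f"F({d1:.0f},{d2:.0f}) = {f:.3f}, p = {p:.3g}"
        )
    ks = blocks.get("distributions_ks")
    if ks:
        for key, res in ks.items():
            stat = res["statistic"] if isinstance(res, dict) else res.statistic
            p = res["p_value"] if isinstance(res, dict) else res.p_value
            lines.append(f"KS ({key} by genotype): D = {stat:.4f}, p = {p:.3g}")
    front = blocks.get("frontloading")
    if front:
        for key, res in front.items():
            m = res["method"] if isinstance(res, dict) else res.method
            s = res["statistic"] if isinstance(res, dict) else res.statistic
            p = res["p_value"] if isinstance(res, dict) else res.p_value
            lines.append(f"{key} licks ({m}): stat = {s:.3f}, p = {p:.3g}")
    acc = blocks.get("accumulation")
    if acc:
        ratio = acc["slope_ratio"]
        r = ratio["ratio"] if isinstance(ratio, dict) else ratio.ratio
        lines.append(f"BEC accumulation slope ratio ({acc['ratio_direction']}): "
                     f"{r:.3f}")
    for w in report.get("warnings", []):
        lines.append(f"warning: {w}")
    return "\n".join(lines)
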