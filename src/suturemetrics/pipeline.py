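"""End-to-end pipeline: annotations -> calibration -> metrics -> statistics
-> strength model -> reports.

Every run is a pure function of (input files, config, master seed): stage
seeds are derived from the master seed by fixed labels, reports carry the
config echo, seeds, library versions and input content hashes, and no
artifact embeds a timestamp — two runs with identical inputs are
byte-identical.  Malformed or non-compliant annotations are excluded and
logged (the run manifest lists them); ``strict=True`` turns any exclusion
into a hard failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import strength as strength_mod
from .errors import ConfigError, InputError, SutureMetricsError
from .geometry import read_annotation_json, calibrate_from_checkerboard, extract_distances
from .metrics import METRIC_NAMES, compute_metrics
from .questionnaires import TLX_DIMENSIONS, categorize_tlx, score_sus
from .util import derive_seed

log = logging.getLogger("suturemetrics")

ALL_STAGES = ("metrics", "stats", "questionnaires", "model")


@dataclass
class PipelineConfig:
    """Paths and knobs for one pipeline run."""

    annotations_dir: str
    cohort_csv: str
    out_dir: str
    questionnaire_csv: str | None = None
    alpha: float = 0.05
    iqr_k: float = 1.5
    dunn_adjustment: str = "none"
    kfold_k: int = 5
    kfold_repeats: int = 10
    hyperparams: dict = field(default_factory=dict)
    gold_mm: float = 5.0
    unit_mode: str = "mm"
    px_per_mm: float | None = None  # explicit scale when no checkerboard is present
    expected_stitches: int = 7
    power_n_sims: int = 400
    power_n_max: int = 300
    power_test: str = "kruskal"
    seed: int = 0
    strict: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.kfold_k < 2:
            raise ConfigError("kfold_k must be >= 2")
        if self.unit_mode not in ("mm", "px"):
            raise ConfigError(f"unit_mode must be 'mm' or 'px', got {self.unit_mode!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict:
    import scipy, sklearn, statsmodels, xgboost
    from . import __version__

    return {
        "suturemetrics": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
        "xgboost": xgboost.__version__,
    }


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, allow_nan=True) + "\n")


def _stage_metrics(cfg: PipelineConfig, manifest: dict, out: Path) -> pd.DataFrame:
    ann_dir = Path(cfg.annotations_dir)
    files = sorted(ann_dir.glob("*.json"))
    if not files:
        raise InputError(f"no annotation JSON files under {ann_dir}")
    rows, exclusions = [], []

    def exclude(name: str, reason: str) -> None:
        if cfg.strict:
            raise InputError(f"{name}: {reason}")
        exclusions.append({"file": name, "reason": reason})
        log.warning("excluding %s: %s", name, reason)

    for f in files:
        try:
            ann = read_annotation_json(f)
        except SutureMetricsError as e:
            exclude(f.name, str(e))
            continue
        if len(ann.entry_points) != len(ann.exit_points):
            exclude(f.name, f"non-compliant: {len(ann.entry_points)} entry vs "
                            f"{len(ann.exit_points)} exit points")
            continue
        if not ann.is_compliant(cfg.expected_stitches):
            exclude(f.name, f"non-compliant: expected {cfg.expected_stitches} stitches "
                            f"per side, got {len(ann.entry_points)}")
            continue
        try:
            if cfg.unit_mode == "mm":
                if ann.checkerboard_corners is not None and ann.checkerboard_square_mm:
                    cal = calibrate_from_checkerboard(ann.checkerboard_corners,
                                                      ann.checkerboard_square_mm)
                    d = extract_distances(ann, cal)
                elif cfg.px_per_mm:
                    d = extract_distances(ann, None)
                    d.pm, d.pp, d.units = d.pm / cfg.px_per_mm, d.pp / cfg.px_per_mm, "mm"
                else:
                    exclude(f.name, "mm mode but no checkerboard and no px_per_mm override")
                    continue
                gold = cfg.gold_mm
            else:
                if not cfg.px_per_mm:
                    raise InputError("px mode needs px_per_mm to express the 5 mm "
                                     "gold standard in pixels")
                d = extract_distances(ann, None)
                gold = cfg.gold_mm * cfg.px_per_mm
            mv = compute_metrics(d, gold=gold)
        except SutureMetricsError as e:
            exclude(f.name, str(e))
            continue
        rows.append({"trial_id": ann.trial_id, **mv.as_dict(),
                     "units": mv.units, "gold": mv.gold_mm})
    if not rows:
        raise InputError("every annotation was excluded; nothing to analyse")
    table = pd.DataFrame(rows)
    manifest["exclusions"] = exclusions
    path = out / "metrics.csv"
    table.to_csv(path, index=False)
    manifest["artifacts"]["metrics"] = {"path": path.name, "sha256": _sha256(path)}
    return table


def _stage_stats(cfg: PipelineConfig, manifest: dict, out: Path,
                 merged: pd.DataFrame) -> None:
    summaries, comparisons, power = [], [], []
    for variable in ("burst_pressure_mmHg", "time_s"):
        for grouping in ("device", "experience", ["device", "experience"]):
            desc = cohort_mod.describe_by(merged, grouping, variable)
            desc.insert(0, "variable", variable)
            desc.insert(1, "grouping", "x".join(grouping) if isinstance(grouping, list) else grouping)
            if isinstance(grouping, list):
                desc["group"] = desc[grouping[0]].astype(str) + "/" + desc[grouping[1]].astype(str)
                desc = desc.drop(columns=grouping)
            else:
                desc = desc.rename(columns={grouping: "group"})
            summaries.append(desc[["variable", "grouping", "group", "mean", "sd", "n"]])
        for grouping in ("device", "experience"):
            comp = cohort_mod.compare_groups(
                merged, variable, grouping,
                iqr_k=cfg.iqr_k, adjustment=cfg.dunn_adjustment)
            d = comp.as_dict()
            d["variable"] = variable
            comparisons.append(d)
            desc = cohort_mod.describe_by(merged, grouping, variable)
            ok = desc["sd"].notna() & (desc["sd"] > 0) & (desc["n"] >= 2)
            if ok.sum() >= 2:
                est = cohort_mod.required_n_simulation(
                    desc.loc[ok, "mean"], desc.loc[ok, "sd"],
                    test=cfg.power_test, alpha=cfg.alpha,
                    n_sims=cfg.power_n_sims, n_max=cfg.power_n_max,
                    seed=derive_seed(cfg.seed, f"power:{variable}:{grouping}"),
                    observed_n=int(desc.loc[ok, "n"].min()),
                    variable=f"{variable} by {grouping}",
                    n_unit="trials per group",
                )
                power.append(est.as_dict())

    summary = pd.concat(summaries, ignore_index=True)
    spath = out / "group_summary.csv"
    summary.to_csv(spath, index=False)
    cpath = out / "comparisons.json"
    _write_json(cpath, comparisons)
    ppath = out / "power.json"
    _write_json(ppath, power)
    for name, p in (("group_summary", spath), ("comparisons", cpath), ("power", ppath)):
        manifest["artifacts"][name] = {"path": p.name, "sha256": _sha256(p)}


def _stage_questionnaires(cfg: PipelineConfig, manifest: dict, out: Path,
                          merged: pd.DataFrame) -> None:
    q = pd.read_csv(cfg.questionnaire_csv)
    need = {"trial_id", "instrument", "item_index", "value"}
    if not need <= set(q.columns):
        raise InputError(f"questionnaire CSV missing columns {sorted(need - set(q.columns))}")
    sus_rows, tlx_rows = [], []
    for trial_id, sub in q.groupby("trial_id", sort=True):
        sus = sub[sub["instrument"] == "SUS"].sort_values("item_index")
        if len(sus):
            score, band = score_sus([int(v) for v in sus["value"]])
            sus_rows.append({"trial_id": trial_id, "sus_score": score, "band": band})
        tlx = sub[sub["instrument"] == "TLX"].sort_values("item_index")
        if len(tlx):
            bands = categorize_tlx([int(v) for v in tlx["value"]])
            tlx_rows.append({"trial_id": trial_id, **bands})
    sus_df = pd.DataFrame(sus_rows)
    tlx_df = pd.DataFrame(tlx_rows, columns=["trial_id", *TLX_DIMENSIONS])
    spath = out / "sus_scores.csv"
    sus_df.to_csv(spath, index=False)
    tpath = out / "tlx_bands.csv"
    tlx_df.to_csv(tpath, index=False)
    artifacts = {"sus_scores": spath, "tlx_bands": tpath}

    if len(sus_df) >= 4:
        with_dev = sus_df.merge(merged[["trial_id", "device"]], on="trial_id")
        if with_dev["device"].nunique() >= 2:
            comp = cohort_mod.compare_groups(with_dev, "sus_score", "device",
                                             iqr_k=None, adjustment=cfg.dunn_adjustment)
            qpath = out / "sus_comparison.json"
            _write_json(qpath, comp.as_dict())
            artifacts["sus_comparison"] = qpath
    for name, p in artifacts.items():
        manifest["artifacts"][name] = {"path": p.name, "sha256": _sha256(p)}


def _stage_model(cfg: PipelineConfig, manifest: dict, out: Path,
                 merged: pd.DataFrame) -> None:
    # the screen covers the 18 spacing metrics plus task time, all against pressure
    candidates = [*METRIC_NAMES, "time_s"]
    screen = strength_mod.spearman_screen(
        merged[candidates], merged["burst_pressure_mmHg"], alpha=cfg.alpha)
    cpath = out / "correlation_table.csv"
    screen.to_csv(cpath, index=False)
    manifest["artifacts"]["correlation_table"] = {"path": cpath.name, "sha256": _sha256(cpath)}

    selected = [m for m, s in zip(screen["metric"], screen["selected"]) if s]
    manifest["selected_features"] = selected
    if len(selected) < 1:
        log.info("no features passed the screen at alpha=%s; regression skipped", cfg.alpha)
        manifest["model_skipped"] = f"no features selected at alpha={cfg.alpha}"
        return

    if len(selected) >= 2 and len(merged) > len(selected):
        vif = strength_mod.vif_table(merged[selected])
        vpath = out / "vif.csv"
        vif.to_csv(vpath, index=False)
        manifest["artifacts"]["vif"] = {"path": vpath.name, "sha256": _sha256(vpath)}

    report = strength_mod.repeated_kfold_regression(
        merged[selected], merged["burst_pressure_mmHg"],
        k=cfg.kfold_k, repeats=cfg.kfold_repeats,
        seed=derive_seed(cfg.seed, "regression"),
        hyperparams=cfg.hyperparams or None,
    )
    extremes = strength_mod.residual_analysis(report)
    shap = strength_mod.shap_attribution(report.model, merged[selected])

    rpath = out / "residuals.csv"
    report.residuals.to_csv(rpath, index=False)
    apath = out / "shap_attributions.csv"
    shap["attributions"].to_csv(apath, index=False)
    payload = report.as_dict()
    payload["residual_extremes"] = extremes
    payload["shap"] = {
        "mode": "full-data refit",
        "base_value": shap["base_value"],
        "mean_abs": {k: float(v) for k, v in shap["mean_abs"].items()},
    }
    mpath = out / "regression_report.json"
    _write_json(mpath, payload)
    for name, p in (("residuals", rpath), ("shap_attributions", apath),
                    ("regression_report", mpath)):
        manifest["artifacts"][name] = {"path": p.name, "sha256": _sha256(p)}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages in order and write the manifest.

    Returns the manifest dict.  A failing stage stops the run; the manifest
    (with the completed-stage list and the error) is still written.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s) {sorted(unknown)}; available: {ALL_STAGES}")
    stages = tuple(s for s in ALL_STAGES if s in stages)

    manifest: dict = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "versions": _versions(),
        "input_hashes": {},
        "stages_completed": [],
        "artifacts": {},
    }
    for f in sorted(Path(cfg.annotations_dir).glob("*.json")):
        manifest["input_hashes"][f"annotations/{f.name}"] = _sha256(f)
    for key in ("cohort_csv", "questionnaire_csv"):
        val = getattr(cfg, key)
        if val and Path(val).exists():
            manifest["input_hashes"][key] = _sha256(Path(val))

    try:
        metrics_table = _stage_metrics(cfg, manifest, out)
        manifest["stages_completed"].append("metrics")

        outcomes = cohort_mod.validate_cohort_frame(pd.read_csv(cfg.cohort_csv))
        merged = outcomes.merge(metrics_table, on="trial_id", how="inner", validate="1:1")
        dropped = sorted(set(outcomes["trial_id"]) - set(merged["trial_id"]))
        if dropped:
            log.warning("%d outcome record(s) without usable annotation: %s",
                        len(dropped), dropped)
            manifest["outcomes_without_annotation"] = dropped
        if merged.empty:
            raise InputError("no trial_id overlap between annotations and cohort CSV")

        if "stats" in stages:
            _stage_stats(cfg, manifest, out, merged)
            manifest["stages_completed"].append("stats")
        if "questionnaires" in stages and cfg.questionnaire_csv:
            _stage_questionnaires(cfg, manifest, out, merged)
            manifest["stages_completed"].append("questionnaires")
        if "model" in stages:
            _stage_model(cfg, manifest, out, merged)
            manifest["stages_completed"].append("model")
    except Exception as e:
        manifest["error"] = f"{type(e).__name__}: {e}"
        _write_json(out / "manifest.json", manifest)
        raise
    _write_json(out / "manifest.json", manifest)
    return manifest
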