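"""Synthetic cohort generator: annotations, outcomes and questionnaires.

Emulates the study design the analysis assumes — 15 operators stratified
into three experience levels, each suturing once on each of three platforms
(45 trials), 7-stitch running sutures targeting 5 mm spacing and 5 mm
margins, with platform order counterbalanced across three rotation groups.

The generative model, stage by stage:

* **Spacing geometry.**  Along a straight incision, entry-side x-positions
  accumulate advances drawn from a positive-truncated Normal(g, sigma_pp);
  the exit side gets independent advances.  Margin offsets on each side are
  drawn from a positive-truncated Normal(g + bias_pm, sigma_pm).  Because
  consecutive points also differ in margin offset, the *true PP distance*
  recorded as ground truth is the realized Euclidean gap between consecutive
  points (slightly larger than the drawn advance), exactly what landmark
  extraction recovers from the rendered annotation.  Dispersion
  defaults are anchored to the aggregate mean-error magnitudes reported for
  this task family (mean |distance - 5| of roughly 1.4-2.2).  By default the
  dispersion is common to all strata, so the *only* pathway linking spacing
  metrics to burst pressure is the explicit coupling below — the no-coupling
  configuration is then an exact null for the correlation screen.
  Per-device / per-experience dispersion overrides are available in config.
* **Burst pressure.**  ``max(0, mu0 + device_offset + experience_offset
  - gamma * (true_pp_std - pp_std_ref) + Normal(0, noise_sd))`` in mmHg.
  The irregularity driver is the *true* (pre-measurement) spread of the PP
  gaps, so annotation and calibration noise attenuate the observable
  correlation realistically.  Offsets are anchored to the reported
  per-platform and per-experience means; ``gamma`` defaults to the value at
  which the pooled sample Spearman between measured pp_std and pressure at
  n = 45 averages the reported effect size of -0.375 (calibrated by
  simulation; see docs/methods.md).  Centering on ``pp_std_ref`` keeps the
  stratum means at their anchors for any gamma.
* **Task time.**  Lognormal per device at the reported mean/SD, with a mild
  multiplicative experience effect (masters faster).
* **Questionnaires.**  SUS item contributions and TLX ratings are shifted
  binomials with device-specific success probabilities, set so the flexible
  endoscope scores worst on usability and on mental demand / frustration.
* **Rendering.**  All landmarks are scaled to pixels, rigidly rotated and
  translated per trial, and a jittered checkerboard corner lattice is added,
  so the full image-calibration path can be exercised end to end.
"""

from __future__ import annotations

import copy
import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DEVICES, EXPERIENCE_LEVELS
from .errors import ConfigError
from .geometry import (
    SutureAnnotation,
    calibrate_from_checkerboard,
    extract_distances,
    write_annotation_json,
    DistanceSet,
)
from .metrics import METRIC_NAMES, compute_metrics
from .questionnaires import TLX_DIMENSIONS
from .util import derive_seed

__all__ = ["CohortConfig", "SyntheticTrial", "generate_cohort", "cohort_frame",
           "render_annotation", "write_cohort"]


def _default_pressure() -> dict:
    # mmHg anchors: per-platform means 17.38 / 15.99 / 13.60 and per-experience
    # means 15.13 / 13.89 / 17.95 around a grand mean of 15.66
    return {
        "mu0": 15.66,
        "device_offsets": {"laparoscopy": 1.72, "dvrk": 0.33, "flex": -2.06},
        "experience_offsets": {"beginner": -0.53, "advanced": -1.77, "master": 2.29},
        "gamma": 7.8,          # mmHg per mm of true pp-std (simulation-calibrated)
        "pp_std_ref": 1.90,    # expected true pp-std at default dispersion (centering)
        "noise_sd": 7.0,
    }


def _default_time() -> dict:
    # lognormal anchored at reported per-platform mean/SD seconds;
    # multiplicative experience factor (mean ~1) makes masters faster
    return {
        "lognormal": {
            "laparoscopy": {"mean_s": 1341.13, "sd_s": 643.89},
            "dvrk": {"mean_s": 1594.53, "sd_s": 696.52},
            "flex": {"mean_s": 3141.13, "sd_s": 1043.83},
        },
        "experience_factor": {"beginner": 1.04, "advanced": 1.08, "master": 0.88},
    }


def _default_sus() -> dict:
    # mean SUS score is ~100 p: laparoscopy/dVRK "good", Flex clearly lower
    return {"laparoscopy": 0.72, "dvrk": 0.70, "flex": 0.45}


def _default_tlx() -> dict:
    base = {dim: 0.40 for dim in TLX_DIMENSIONS}
    flex = dict(base, mental=0.65, frustration=0.68, effort=0.55,
                physical=0.45, temporal=0.45, performance=0.45)
    return {"laparoscopy": dict(base), "dvrk": dict(base), "flex": flex}


@dataclass
class CohortConfig:
    """Full parameterisation of one synthetic cohort.

    Spacing dispersions are in mm; pressures in mmHg; times in s.  The
    per-stratum dispersion multipliers default to 1 (homogeneous dispersion),
    which makes ``gamma = 0`` an exact null for metric-pressure association.
    """

    n_operators: int = 15
    devices: tuple[str, ...] = DEVICES
    experience_split: dict = field(
        default_factory=lambda: {"beginner": 5, "advanced": 5, "master": 5})
    stitches: int = 7
    gold_mm: float = 5.0
    sigma_pp_mm: float = 2.10
    sigma_pm_mm: float = 2.25
    bias_pm_mm: float = 0.0
    device_sigma_factor: dict = field(
        default_factory=lambda: {d: 1.0 for d in DEVICES})
    experience_sigma_factor: dict = field(
        default_factory=lambda: {e: 1.0 for e in EXPERIENCE_LEVELS})
    pressure: dict = field(default_factory=_default_pressure)
    time: dict = field(default_factory=_default_time)
    sus_p: dict = field(default_factory=_default_sus)
    tlx_q: dict = field(default_factory=_default_tlx)
    checkerboard_square_mm: float = 5.0
    px_per_mm: float = 10.0
    corner_grid: int = 2           # 2x2 interior corners (a 3x3-square board)
    corner_jitter_px: float = 0.2
    rotation_max_deg: float = 10.0
    incision_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.n_operators < 1:
            raise ConfigError("n_operators must be >= 1")
        if self.stitches < 2:
            raise ConfigError("need at least 2 stitches per side")
        if not self.gold_mm > 0:
            raise ConfigError("gold_mm must be positive (truncation infeasible otherwise)")
        if self.sigma_pp_mm < 0 or self.sigma_pm_mm < 0:
            raise ConfigError("dispersion sds must be nonnegative")
        if not self.px_per_mm > 0:
            raise ConfigError("px_per_mm must be positive")
        if self.corner_grid < 1:
            raise ConfigError("corner_grid must be >= 1")
        if sum(self.experience_split.values()) != self.n_operators:
            raise ConfigError("experience_split must sum to n_operators")
        if self.gold_mm + self.bias_pm_mm <= 0:
            raise ConfigError("gold_mm + bias_pm_mm must be positive (truncation infeasible)")
        if self.pressure["noise_sd"] < 0:
            raise ConfigError("pressure noise_sd must be nonnegative")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = copy.deepcopy(d)
        if "devices" in d:
            d["devices"] = tuple(d["devices"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["devices"] = list(self.devices)
        return d


@dataclass
class SyntheticTrial:
    """One generated procedure with its ground truth attached.

    ``true_pm``/``true_pp`` are the mm distances the annotation was rendered
    from; passing the annotation back through calibration and extraction
    recovers them up to checkerboard jitter.  ``latent_pressure`` is the
    pressure before flooring at 0 mmHg.
    """

    trial_id: str
    operator_id: str
    device: str
    experience: str
    platform_order: int
    annotation: SutureAnnotation
    burst_pressure_mmHg: float
    time_s: float
    sus_items: tuple[int, ...]
    tlx_items: tuple[int, ...]
    true_pm: np.ndarray
    true_pp: np.ndarray
    true_pp_std: float
    latent_pressure: float


def _truncated_normal(rng, mean, sd, size) -> np.ndarray:
    """Normal(mean, sd) truncated to (0, inf); degenerate sd gives the mean."""
    sd = np.broadcast_to(np.asarray(sd, dtype=float), size)
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    out = np.where(sd > 0, 0.0, mean).astype(float)
    pos = sd > 0
    if np.any(pos):
        a = (0.0 - mean[pos]) / sd[pos]
        out[pos] = stats.truncnorm.rvs(a, np.inf, loc=mean[pos], scale=sd[pos],
                                       size=int(pos.sum()), random_state=rng)
    return out


def _rotation(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])


def generate_cohort(cfg: CohortConfig, seed: int = 0) -> list[SyntheticTrial]:
    """Generate the full cohort of trials for one seeded replicate."""
    rng = np.random.default_rng(derive_seed(seed, "cohort"))
    S = cfg.stitches
    g = cfg.gold_mm
    n_dev = len(cfg.devices)

    operators, experiences = [], []
    i = 0
    for level in EXPERIENCE_LEVELS:
        for _ in range(cfg.experience_split.get(level, 0)):
            i += 1
            operators.append(f"op{i:02d}")
            experiences.append(level)

    plan = []  # (operator, experience, device, order position 1-based)
    for idx, (op, exp) in enumerate(zip(operators, experiences)):
        rot = idx % n_dev  # counterbalanced platform order: three rotation groups
        order = cfg.devices[rot:] + cfg.devices[:rot]
        for pos, dev in enumerate(order, start=1):
            plan.append((op, exp, dev, pos))
    n_trials = len(plan)

    s_pp = np.array([cfg.sigma_pp_mm
                     * cfg.device_sigma_factor[dev] * cfg.experience_sigma_factor[exp]
                     for _, exp, dev, _ in plan])
    s_pm = np.array([cfg.sigma_pm_mm
                     * cfg.device_sigma_factor[dev] * cfg.experience_sigma_factor[exp]
                     for _, exp, dev, _ in plan])

    n_gaps, n_pm = 2 * (S - 1), 2 * S
    gaps = _truncated_normal(rng, g, s_pp[:, None], (n_trials, n_gaps))
    pms = _truncated_normal(rng, g + cfg.bias_pm_mm, s_pm[:, None], (n_trials, n_pm))

    # realized geometry: consecutive points differ in margin offset too, so the
    # true PP distance is the Euclidean gap, not the drawn x-advance
    entry_xs = 2.0 + np.concatenate(
        [np.zeros((n_trials, 1)), np.cumsum(gaps[:, : S - 1], axis=1)], axis=1)
    exit_xs = 2.0 + np.concatenate(
        [np.zeros((n_trials, 1)), np.cumsum(gaps[:, S - 1 :], axis=1)], axis=1)
    entry_pp = np.hypot(np.diff(entry_xs, axis=1), np.diff(pms[:, :S], axis=1))
    exit_pp = np.hypot(np.diff(exit_xs, axis=1), np.diff(-pms[:, S:], axis=1))
    true_pp = np.concatenate([entry_pp, exit_pp], axis=1)

    pr = cfg.pressure
    true_pp_std = true_pp.std(axis=1, ddof=0)
    noise = rng.normal(0.0, pr["noise_sd"], size=n_trials)
    latent = np.array([
        pr["mu0"] + pr["device_offsets"][dev] + pr["experience_offsets"][exp]
        for _, exp, dev, _ in plan
    ]) - pr["gamma"] * (true_pp_std - pr["pp_std_ref"]) + noise
    pressure = np.maximum(0.0, latent)

    tm = cfg.time
    t_mu, t_sig = [], []
    for _, exp, dev, _ in plan:
        m, s = tm["lognormal"][dev]["mean_s"], tm["lognormal"][dev]["sd_s"]
        sig2 = math.log1p((s / m) ** 2)
        t_mu.append(math.log(m) - sig2 / 2 + math.log(tm["experience_factor"][exp]))
        t_sig.append(math.sqrt(sig2))
    time_s = rng.lognormal(np.array(t_mu), np.array(t_sig))

    sus_p = np.array([cfg.sus_p[dev] for _, _, dev, _ in plan])
    sus_adj = rng.binomial(4, sus_p[:, None], size=(n_trials, 10))
    # odd items score raw-1, even items 5-raw: invert the adjusted draw back to raws
    sus_items = np.empty_like(sus_adj)
    sus_items[:, 0::2] = sus_adj[:, 0::2] + 1
    sus_items[:, 1::2] = 5 - sus_adj[:, 1::2]
    tlx_q = np.array([[cfg.tlx_q[dev][dim] for dim in TLX_DIMENSIONS]
                      for _, _, dev, _ in plan])
    tlx_items = 1 + rng.binomial(9, tlx_q, size=(n_trials, len(TLX_DIMENSIONS)))

    # pixel rendering
    angles = rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg, size=n_trials)
    shifts = rng.uniform(100.0, 400.0, size=(n_trials, 2))
    square_px = cfg.checkerboard_square_mm * cfg.px_per_mm
    grid = np.array([[cfg.px_per_mm * (-15.0) + square_px * j,
                      cfg.px_per_mm * (-20.0) + square_px * i]
                     for i in range(cfg.corner_grid) for j in range(cfg.corner_grid)])
    corner_jitter = rng.normal(0.0, cfg.corner_jitter_px,
                               size=(n_trials, len(grid), 2))

    trials: list[SyntheticTrial] = []
    for t, (op, exp, dev, pos) in enumerate(plan):
        entry_x, exit_x = entry_xs[t], exit_xs[t]
        entry = np.column_stack([entry_x, pms[t, :S]])
        exit_ = np.column_stack([exit_x, -pms[t, S:]])
        x_lo = min(entry_x.min(), exit_x.min()) - cfg.incision_margin_mm
        x_hi = max(entry_x.max(), exit_x.max()) + cfg.incision_margin_mm
        incision = np.array([[x_lo, 0.0], [x_hi, 0.0]])

        R = _rotation(angles[t])

        def px(a):
            return (cfg.px_per_mm * a) @ R.T + shifts[t]

        corners = grid @ R.T + shifts[t] + corner_jitter[t]
        ann = SutureAnnotation(
            trial_id=f"{op}_{dev}",
            entry_points=px(entry),
            exit_points=px(exit_),
            incision=px(incision),
            checkerboard_corners=corners,
            checkerboard_square_mm=cfg.checkerboard_square_mm,
        )
        trials.append(SyntheticTrial(
            trial_id=f"{op}_{dev}",
            operator_id=op,
            device=dev,
            experience=exp,
            platform_order=pos,
            annotation=ann,
            burst_pressure_mmHg=float(pressure[t]),
            time_s=float(time_s[t]),
            sus_items=tuple(int(v) for v in sus_items[t]),
            tlx_items=tuple(int(v) for v in tlx_items[t]),
            true_pm=pms[t].copy(),
            true_pp=true_pp[t].copy(),
            true_pp_std=float(true_pp_std[t]),
            latent_pressure=float(latent[t]),
        ))
    return trials


def cohort_frame(trials: list[SyntheticTrial], cfg: CohortConfig,
                 measure: str = "annotation") -> pd.DataFrame:
    """Tidy analysis table: outcomes plus the 18 metrics per trial.

    ``measure='annotation'`` runs the full measurement path (checkerboard
    calibration, landmark extraction); ``measure='truth'`` computes metrics
    directly from the generated mm distances, bypassing rendering — useful
    for fast Monte-Carlo studies, and identical up to checkerboard jitter.
    """
    if measure not in ("annotation", "truth"):
        raise ConfigError(f"measure must be 'annotation' or 'truth', got {measure!r}")
    rows = []
    for tr in trials:
        if measure == "annotation":
            cal = calibrate_from_checkerboard(tr.annotation.checkerboard_corners,
                                              tr.annotation.checkerboard_square_mm)
            d = extract_distances(tr.annotation, cal)
        else:
            d = DistanceSet(tr.trial_id, tr.true_pm, tr.true_pp, units="mm")
        mv = compute_metrics(d, gold=cfg.gold_mm)
        row = {
            "trial_id": tr.trial_id,
            "operator_id": tr.operator_id,
            "device": tr.device,
            "experience": tr.experience,
            "platform_order": tr.platform_order,
            "burst_pressure_mmHg": tr.burst_pressure_mmHg,
            "time_s": tr.time_s,
        }
        row.update(mv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["trial_id", "operator_id", "device",
                                       "experience", "platform_order",
                                       "burst_pressure_mmHg", "time_s", *METRIC_NAMES])


def render_annotation(trial: SyntheticTrial, out_dir: str | Path) -> Path:
    """Write the trial's annotation JSON; returns the file path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{trial.trial_id}.json"
    write_annotation_json(trial.annotation, path)
    return path


def write_cohort(trials: list[SyntheticTrial], cfg: CohortConfig,
                 out_dir: str | Path) -> dict[str, Path]:
    """Emit the full cohort file set.

    ``annotations/*.json`` (pixel landmarks), ``cohort.csv`` (outcomes only —
    metrics are recomputed by the analysis pipeline), ``questionnaires.csv``
    (tidy SUS/TLX item table) and ``ground_truth_synthetic.csv`` (generator
    internals for validation only; never read by any analysis stage).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann_dir = out_dir / "annotations"
    for tr in trials:
        render_annotation(tr, ann_dir)

    cohort_path = out_dir / "cohort.csv"
    with open(cohort_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "operator_id", "device", "experience",
                    "platform_order", "burst_pressure_mmHg", "time_s"])
        for tr in trials:
            w.writerow([tr.trial_id, tr.operator_id, tr.device, tr.experience,
                        tr.platform_order, repr(tr.burst_pressure_mmHg), repr(tr.time_s)])

    q_path = out_dir / "questionnaires.csv"
    with open(q_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "instrument", "item_index", "value"])
        for tr in trials:
            for idx, v in enumerate(tr.sus_items, start=1):
                w.writerow([tr.trial_id, "SUS", idx, v])
            for idx, v in enumerate(tr.tlx_items, start=1):
                w.writerow([tr.trial_id, "TLX", idx, v])

    gt_path = out_dir / "ground_truth_synthetic.csv"
    with open(gt_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "true_pp_std_mm", "latent_pressure_mmHg",
                    "true_pm_mm", "true_pp_mm"])
        for tr in trials:
            w.writerow([tr.trial_id, repr(tr.true_pp_std), repr(tr.latent_pressure),
                        ";".join(repr(v) for v in tr.true_pm),
                        ";".join(repr(v) for v in tr.true_pp)])
    return {"annotations": ann_dir, "cohort": cohort_path,
            "questionnaires": q_path, "ground_truth": gt_path}
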