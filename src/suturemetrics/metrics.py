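"""The 18 spacing metrics derived from PM and PP distance lists.

Each trial yields three metric families: PM (point-to-margin), PP
(point-to-point) and "P all" (both families pooled).  For every family six
statistics are computed: max, max error, mean, mean error, std and std error,
where "error" means the absolute deviation of each distance from the
instructed gold standard g (5 mm under the small-bites protocol).

Conventions, chosen to match the metric definitions as printed in the source
protocol and kept configurable where the printed form is ambiguous:

* standard deviations use the population divisor ``n`` (``sample_std=True``
  switches to ``n - 1``);
* the pooled "P all mean error" is the *unweighted* average of the two family
  mean errors, even when the families differ in length;
* the pooled "P all std" is, as printed, a variance-like quantity without a
  square root; the default here applies the root for unit consistency, and
  ``p_all_std_as_printed=True`` reproduces the rootless form.  All downstream
  rank-based analyses are invariant to this monotone choice;
* absolute values are applied to every distance before any operation
  (harmless for true distances, which are nonnegative by construction).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import InputError, UnitError
from .geometry import DistanceSet

__all__ = ["MetricVector", "METRIC_NAMES", "compute_metrics", "write_metrics_csv"]

#: Canonical column order for the 18 metrics.
METRIC_NAMES = [
    "pm_max", "pm_max_error", "pm_mean", "pm_mean_error", "pm_std", "pm_std_error",
    "pp_max", "pp_max_error", "pp_mean", "pp_mean_error", "pp_std", "pp_std_error",
    "p_all_max", "p_all_max_error", "p_all_mean", "p_all_mean_error",
    "p_all_std", "p_all_std_error",
]

#: Target spacing of the small-bites technique: 5 mm between stitches and
#: 5 mm from the incision edge.
DEFAULT_GOLD_MM = 5.0


@dataclass(frozen=True)
class MetricVector:
    """The 18 spacing metrics for one trial, in the units of its DistanceSet."""

    trial_id: str
    pm_max: float
    pm_max_error: float
    pm_mean: float
    pm_mean_error: float
    pm_std: float
    pm_std_error: float
    pp_max: float
    pp_max_error: float
    pp_mean: float
    pp_mean_error: float
    pp_std: float
    pp_std_error: float
    p_all_max: float
    p_all_max_error: float
    p_all_mean: float
    p_all_mean_error: float
    p_all_std: float
    p_all_std_error: float
    gold_mm: float = DEFAULT_GOLD_MM
    units: str = "mm"

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _family_stats(x: np.ndarray, gold: float, ddof: int) -> dict[str, float]:
    """max/mean/std of |x| and of the errors ||x| - g| for one family."""
    ax = np.abs(x)
    err = np.abs(ax - gold)
    return {
        "max": float(ax.max()),
        "max_error": float(err.max()),
        "mean": float(ax.mean()),
        "mean_error": float(err.mean()),
        "std": float(ax.std(ddof=ddof)),
        "std_error": float(err.std(ddof=ddof)),
    }


def compute_metrics(
    d: DistanceSet,
    gold: float = DEFAULT_GOLD_MM,
    *,
    gold_units: str | None = None,
    sample_std: bool = False,
    p_all_std_as_printed: bool = False,
) -> MetricVector:
    """Compute the full 18-metric vector from a DistanceSet.

    Parameters
    ----------
    d:
        The PM/PP distances of one trial; both lists must be nonempty.
    gold:
        Target spacing g in the same units as ``d`` (default 5 mm).
    gold_units:
        Optional explicit unit of ``gold``; if given and different from
        ``d.units`` a :class:`UnitError` is raised rather than silently
        mixing mm and px.
    sample_std:
        Use divisor ``n - 1`` instead of the default population ``n``.
    p_all_std_as_printed:
        Report the pooled std as the rootless (variance-like) quantity.
    """
    if not gold > 0:
        raise InputError(f"gold standard must be positive, got {gold}")
    if gold_units is not None and gold_units != d.units:
        raise UnitError(f"gold is in {gold_units!r} but distances are in {d.units!r}")
    for name, arr in (("pm", d.pm), ("pp", d.pp)):
        if arr.size == 0:
            raise InputError(
                f"trial {d.trial_id!r}: {name} list is empty; {name} metrics are undefined"
            )

    ddof = 1 if sample_std else 0
    pm = _family_stats(d.pm, gold, ddof)
    pp = _family_stats(d.pp, gold, ddof)

    apm, app = np.abs(d.pm), np.abs(d.pp)
    n_pool = apm.size + app.size
    # pooled deviations are taken from each family's own mean (resp. mean error)
    pooled_ss = np.sum((apm - pm["mean"]) ** 2) + np.sum((app - pp["mean"]) ** 2)
    p_all_var = float(pooled_ss / (n_pool - ddof))
    err_pm = np.abs(apm - gold)
    err_pp = np.abs(app - gold)
    pooled_err_ss = np.sum((err_pm - pm["mean_error"]) ** 2) + np.sum((err_pp - pp["mean_error"]) ** 2)

    return MetricVector(
        trial_id=d.trial_id,
        pm_max=pm["max"], pm_max_error=pm["max_error"],
        pm_mean=pm["mean"], pm_mean_error=pm["mean_error"],
        pm_std=pm["std"], pm_std_error=pm["std_error"],
        pp_max=pp["max"], pp_max_error=pp["max_error"],
        pp_mean=pp["mean"], pp_mean_error=pp["mean_error"],
        pp_std=pp["std"], pp_std_error=pp["std_error"],
        p_all_max=max(pm["max"], pp["max"]),
        p_all_max_error=max(pm["max_error"], pp["max_error"]),
        p_all_mean=float((apm.sum() + app.sum()) / n_pool),
        p_all_mean_error=0.5 * (pm["mean_error"] + pp["mean_error"]),
        p_all_std=p_all_var if p_all_std_as_printed else float(np.sqrt(p_all_var)),
        p_all_std_error=float(np.sqrt(pooled_err_ss / (n_pool - ddof))),
        gold_mm=gold,
        units=d.units,
    )


def write_metrics_csv(vectors: Iterable[MetricVector], path: str | Path) -> None:
    """Tidy metrics table: one row per trial, the 18 metric columns plus ids."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", *METRIC_NAMES, "units", "gold_mm"])
        for v in vectors:
            w.writerow(
                [v.trial_id, *(repr(getattr(v, m)) for m in METRIC_NAMES), v.units, repr(v.gold_mm)]
            )
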