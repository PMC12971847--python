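"""Pixel-space suture annotations and their conversion to millimetre distances.

A sutured specimen is photographed with a checkerboard of known square size in
frame; needle entry/exit points, the incision line and the checkerboard's
interior corners are annotated as pixel coordinates.  This module estimates an
isotropic pixel-to-millimetre scale from the checkerboard and turns the
landmarks into the two primitive distance families of quantitative suture
assessment:

* **PM** (point-to-margin): distance from each entry/exit point to the
  incision polyline — target 5 mm under the small-bites protocol.
* **PP** (point-to-point): distance between consecutive entry (or exit)
  points along the suture run — target 5 mm.

Only distances are ever used downstream, so all geometry here is invariant to
rigid motion of the image and, once calibrated, to uniform rescaling.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Point

from .errors import CalibrationError, InputError

__all__ = [
    "SutureAnnotation",
    "CalibrationModel",
    "DistanceSet",
    "calibrate_from_checkerboard",
    "point_to_margin_distance",
    "extract_distances",
    "read_annotation_json",
    "write_annotation_json",
    "read_annotation_csv",
    "write_annotation_csv",
]

#: Default number of stitches per side under the small-bites running-suture
#: protocol (7 stitches, closing knot excluded from annotation).
PROTOCOL_STITCHES = 7

_COLLINEARITY_TOL = 1e-8


def _as_points(arr: Sequence, name: str, min_len: int = 1) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise InputError(f"{name} must be an (n, 2) array of xy coordinates, got shape {a.shape}")
    if len(a) < min_len:
        raise InputError(f"{name} needs at least {min_len} point(s), got {len(a)}")
    if not np.all(np.isfinite(a)):
        raise InputError(f"{name} contains non-finite coordinates")
    return a


@dataclass
class SutureAnnotation:
    """Pixel-space landmark set for one sutured specimen.

    Coordinates follow the image convention (origin top-left, y downward),
    but nothing downstream depends on it: only distances are consumed.

    Parameters
    ----------
    trial_id:
        Opaque identifier tying the annotation to its outcome record.
    entry_points, exit_points:
        Needle entry/exit coordinates in proximal-to-distal order, one per
        stitch and side.
    incision:
        Polyline (>= 2 vertices) tracing the incision reference; the supplied
        polyline *defines* the margin (cut edge or fitted midline — the
        caller's choice).
    checkerboard_corners:
        Interior corner coordinates of the reference grid, any count >= 2;
        ``None`` if the image carries no reference (pixel-mode pipeline).
    checkerboard_square_mm:
        Physical side length of one checkerboard square, in mm.
    """

    trial_id: str
    entry_points: np.ndarray
    exit_points: np.ndarray
    incision: np.ndarray
    checkerboard_corners: np.ndarray | None = None
    checkerboard_square_mm: float | None = None

    def __post_init__(self) -> None:
        self.entry_points = _as_points(self.entry_points, "entry_points")
        self.exit_points = _as_points(self.exit_points, "exit_points")
        self.incision = _as_points(self.incision, "incision", min_len=2)
        if self.checkerboard_corners is not None:
            self.checkerboard_corners = _as_points(self.checkerboard_corners, "checkerboard_corners", min_len=2)
        self.validate()

    def validate(self) -> None:
        seg = np.diff(self.incision, axis=0)
        if not np.any(np.linalg.norm(seg, axis=1) > 0):
            raise InputError(f"trial {self.trial_id!r}: incision polyline has zero length")
        if self.checkerboard_corners is not None and self.checkerboard_square_mm is not None:
            if not self.checkerboard_square_mm > 0:
                raise InputError(f"trial {self.trial_id!r}: checkerboard_square_mm must be > 0")

    def is_compliant(self, stitches: int = PROTOCOL_STITCHES) -> bool:
        """True if both sides carry exactly the protocol stitch count."""
        return len(self.entry_points) == stitches and len(self.exit_points) == stitches


@dataclass(frozen=True)
class CalibrationModel:
    """Isotropic pixel-to-millimetre scale estimated from the checkerboard.

    A single scalar scale (no homography): the capture protocol fixes the
    camera distance and orientation, so perspective correction is out of
    scope; lattice-fit deviation is surfaced via ``residual_rms_px`` instead.
    """

    mm_per_px: float
    residual_rms_px: float
    n_corners_used: int

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise InputError("mm_per_px must be positive")
        if self.residual_rms_px < 0:
            raise InputError("residual_rms_px must be nonnegative")


@dataclass
class DistanceSet:
    """PM and PP distance lists for one trial, in mm or px.

    For S stitches per side the contract is ``len(pm) == 2*S`` (entries then
    exits) and ``len(pp) == 2*(S-1)`` (entry-side gaps then exit-side gaps).
    """

    trial_id: str
    pm: np.ndarray
    pp: np.ndarray
    units: str = "px"

    def __post_init__(self) -> None:
        self.pm = np.asarray(self.pm, dtype=float)
        self.pp = np.asarray(self.pp, dtype=float)
        if self.units not in ("mm", "px"):
            raise InputError(f"units must be 'mm' or 'px', got {self.units!r}")
        for name, a in (("pm", self.pm), ("pp", self.pp)):
            if a.size and (not np.all(np.isfinite(a)) or np.any(a < 0)):
                raise InputError(f"{name} distances must be finite and nonnegative")


def calibrate_from_checkerboard(corners: Sequence, square_mm: float) -> CalibrationModel:
    """Estimate the mm-per-pixel scale from checkerboard interior corners.

    The inter-corner pixel spacing is taken as the median of each corner's
    nearest-neighbour distance — on a square lattice every corner's nearest
    neighbour is an adjacent corner one square away, and the median is robust
    to annotation jitter and to stray corners.  ``residual_rms_px`` is the RMS
    deviation of those adjacency distances from the fitted spacing.

    The estimate depends only on pairwise distances, hence is exactly
    invariant to rigid rotation and translation of the corner set.
    """
    pts = _as_points(corners, "corners", min_len=2)
    if not square_mm > 0:
        raise InputError(f"square_mm must be positive, got {square_mm}")

    centered = pts - pts.mean(axis=0)
    scale = float(np.abs(centered).max())
    if scale == 0.0:
        raise CalibrationError("all checkerboard corners coincide")
    if len(pts) >= 3:
        # collinear corners give no 2-D lattice; reject via smallest singular value
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[-1] <= _COLLINEARITY_TOL * sv[0]:
            raise CalibrationError("checkerboard corners are collinear; cannot fit a lattice")

    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    nn = dist.min(axis=1)
    if np.any(nn == 0.0):
        raise CalibrationError("duplicate checkerboard corners")
    spacing_px = float(np.median(nn))
    residual = float(np.sqrt(np.mean((nn - spacing_px) ** 2)))
    return CalibrationModel(
        mm_per_px=square_mm / spacing_px,
        residual_rms_px=residual,
        n_corners_used=len(pts),
    )


def point_to_margin_distance(point: Sequence[float], incision: Sequence) -> float:
    """Minimum Euclidean distance from a point to the incision polyline.

    The perpendicular foot is used where it falls inside a segment, else the
    nearest vertex — i.e. true distance to the polyline as a point set.
    """
    p = np.asarray(point, dtype=float)
    if p.shape != (2,) or not np.all(np.isfinite(p)):
        raise InputError(f"point must be a finite xy pair, got {point!r}")
    poly = _as_points(incision, "incision", min_len=2)
    line = LineString(poly)
    if line.length == 0:
        raise InputError("incision polyline has zero length")
    return float(Point(p).distance(line))


def _side_gaps(points: np.ndarray) -> np.ndarray:
    """Consecutive Euclidean gaps along one side; a single point yields none."""
    if len(points) < 2:
        return np.empty(0)
    return np.linalg.norm(np.diff(points, axis=0), axis=1)


def extract_distances(ann: SutureAnnotation, cal: CalibrationModel | None = None) -> DistanceSet:
    """Compute the PM and PP distance lists for one annotation.

    PM: distance from every entry point, then every exit point, to the
    incision polyline, in listed (proximal-to-distal) order.  PP: gaps
    between consecutive entry points followed by gaps between consecutive
    exit points.  With a calibration the result is in mm, otherwise px.
    """
    line = LineString(ann.incision)
    if line.length == 0:
        raise InputError(f"trial {ann.trial_id!r}: incision polyline has zero length")
    all_points = np.vstack([ann.entry_points, ann.exit_points])
    pm = np.array([Point(p).distance(line) for p in all_points])
    pp = np.concatenate([_side_gaps(ann.entry_points), _side_gaps(ann.exit_points)])
    if cal is not None:
        return DistanceSet(ann.trial_id, pm * cal.mm_per_px, pp * cal.mm_per_px, units="mm")
    return DistanceSet(ann.trial_id, pm, pp, units="px")


# ---------------------------------------------------------------------------
# Annotation file I/O (JSON canonical, CSV alternative)
# ---------------------------------------------------------------------------

def write_annotation_json(ann: SutureAnnotation, path: str | Path) -> None:
    payload = {
        "trial_id": ann.trial_id,
        "entry_points": ann.entry_points.tolist(),
        "exit_points": ann.exit_points.tolist(),
        "incision": ann.incision.tolist(),
        "checkerboard_corners": None
        if ann.checkerboard_corners is None
        else ann.checkerboard_corners.tolist(),
        "checkerboard_square_mm": ann.checkerboard_square_mm,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_annotation_json(path: str | Path) -> SutureAnnotation:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise InputError(f"{path}: not valid JSON ({e})") from e
    required = {"trial_id", "entry_points", "exit_points", "incision"}
    missing = required - payload.keys()
    if missing:
        raise InputError(f"{path}: missing keys {sorted(missing)}")
    return SutureAnnotation(
        trial_id=str(payload["trial_id"]),
        entry_points=payload["entry_points"],
        exit_points=payload["exit_points"],
        incision=payload["incision"],
        checkerboard_corners=payload.get("checkerboard_corners"),
        checkerboard_square_mm=payload.get("checkerboard_square_mm"),
    )


_CSV_ROLES = ("entry", "exit", "incision", "corner")


def write_annotation_csv(ann: SutureAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial_id", "role", "order_index", "x_px", "y_px"])
        groups = [("entry", ann.entry_points), ("exit", ann.exit_points), ("incision", ann.incision)]
        if ann.checkerboard_corners is not None:
            groups.append(("corner", ann.checkerboard_corners))
        for role, pts in groups:
            for i, (x, y) in enumerate(pts):
                w.writerow([ann.trial_id, role, i, repr(float(x)), repr(float(y))])


def read_annotation_csv(path: str | Path, checkerboard_square_mm: float | None = None) -> SutureAnnotation:
    rows: dict[str, list[tuple[int, float, float]]] = {r: [] for r in _CSV_ROLES}
    trial_id = None
    with open(path, newline="") as fh:
        for lineno, rec in enumerate(csv.DictReader(fh), start=2):
            role = rec.get("role", "")
            if role not in _CSV_ROLES:
                raise InputError(f"{path} row {lineno}: role {role!r} not in {_CSV_ROLES}")
            trial_id = rec["trial_id"]
            try:
                rows[role].append((int(rec["order_index"]), float(rec["x_px"]), float(rec["y_px"])))
            except (KeyError, ValueError) as e:
                raise InputError(f"{path} row {lineno}: {e}") from e
    if trial_id is None:
        raise InputError(f"{path}: empty annotation CSV")

    def ordered(role: str) -> list[list[float]]:
        return [[x, y] for _, x, y in sorted(rows[role])]

    corners = ordered("corner") or None
    return SutureAnnotation(
        trial_id=trial_id,
        entry_points=ordered("entry"),
        exit_points=ordered("exit"),
        incision=ordered("incision"),
        checkerboard_corners=corners,
        checkerboard_square_mm=checkerboard_square_mm,
    )
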