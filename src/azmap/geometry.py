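"""Functional active-zone geometry and normalized radial distances.

The functional AZ of a bouton is the convex hull of its synchronous release
event positions; the AZ center is the arithmetic mean of those positions
(which is guaranteed to lie strictly inside the hull).  An event's radial
position is normalized by the distance from the center to the hull border
along the ray through the event, plus a rim (approximating the vesicle
radius) that absorbs localization uncertainty of the hull-defining events:

    d_norm = d_center / (d_border + rim)

Events with d_norm <= 1 are inside the AZ, events with d_norm > 1 are
ectopic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .errors import DegenerateGeometryError, InsufficientPointsError
from .model import ECTOPIC, IN_AZ, SYNCHRONOUS, UNDEFINED, Dataset


@dataclass
class ActiveZone:
    """Functional active zone of one bouton.

    ``hull_vertices`` are in counter-clockwise order; ``center_nm`` is the
    mean position of all synchronous events (not the polygon centroid),
    ``area_nm2`` the shoelace area of the hull.
    """

    bouton_id: object
    hull_vertices: np.ndarray
    center_nm: np.ndarray
    area_nm2: float
    n_sync_events: int

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.hull_vertices)


@dataclass
class RadialMeasure:
    """Radial position of one event relative to an active zone."""

    event_id: object
    d_center_nm: float
    d_border_nm: float
    d_norm: float
    location_class: str


def shoelace_area(vertices: np.ndarray) -> float:
    """Polygon area by the shoelace formula (positive for CCW order)."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def build_az(positions: np.ndarray, bouton_id=None, center: str = "mean") -> ActiveZone:
    """Build the functional AZ from one bouton's synchronous event positions.

    Parameters
    ----------
    positions
        (n, 2) array of synchronous event coordinates in nm, n >= 3 and not
        all collinear.
    center
        ``"mean"`` (default): mean of all synchronous events;
        ``"centroid"``: area centroid of the hull polygon.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be an (n, 2) array")
    if len(positions) < 3:
        raise InsufficientPointsError(
            f"need >= 3 synchronous events to build an AZ, got {len(positions)}"
        )
    try:
        hull = ConvexHull(positions)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate hull: {exc}") from None
    vertices = positions[hull.vertices]  # CCW in 2-D
    if shoelace_area(vertices) <= 0:
        raise DegenerateGeometryError("hull has non-positive area")
    if center == "mean":
        c = positions.mean(axis=0)
    elif center == "centroid":
        c = np.asarray(Polygon(vertices).centroid.coords[0])
    else:
        raise ValueError("center must be 'mean' or 'centroid'")
    return ActiveZone(
        bouton_id=bouton_id,
        hull_vertices=vertices,
        center_nm=c,
        area_nm2=shoelace_area(vertices),
        n_sync_events=len(positions),
    )


def ray_border_distance(az: ActiveZone, directions: np.ndarray) -> np.ndarray:
    """Distance from the AZ center to the hull border along given rays.

    *directions* is an (n, 2) array of (not necessarily unit) ray direction
    vectors anchored at the center.  For a convex polygon with the center
    strictly inside there is exactly one boundary crossing per ray; the
    distance to it is returned for each ray.  Computed by exact
    ray-segment intersection against every hull edge.
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-length ray direction")
    d = directions / norms
    a = az.hull_vertices
    b = np.roll(a, -1, axis=0)
    e = b - a  # (m, 2) edge vectors
    ac = a - az.center_nm  # (m, 2)
    # cross products, broadcast rays (n, 1, 2) against edges (m, 2)
    denom = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ac[None, :, 0] * e[None, :, 1] - ac[None, :, 1] * e[None, :, 0]) / denom
        s = (ac[None, :, 0] * d[:, None, 1] - ac[None, :, 1] * d[:, None, 0]) / denom
    eps = 1e-9
    valid = (denom != 0) & (s >= -eps) & (s <= 1 + eps) & (t > 0)
    t = np.where(valid, t, -np.inf)
    out = t.max(axis=1)
    if np.any(~np.isfinite(out)):
        raise DegenerateGeometryError("ray does not cross the hull boundary")
    return out


def normalized_distance(xy: np.ndarray, az: ActiveZone, rim_nm: float) -> RadialMeasure:
    """Radial measure of a single event (see module docstring).

    An event exactly at the AZ center has d_norm = 0 and is in the AZ; its
    border distance is reported along the +x ray by convention.
    """
    xy = np.asarray(xy, dtype=float)
    vec = xy - az.center_nm
    d_center = float(np.linalg.norm(vec))
    direction = vec if d_center > 0 else np.array([1.0, 0.0])
    d_border = float(ray_border_distance(az, direction[None, :])[0])
    d_norm = d_center / (d_border + rim_nm)
    return RadialMeasure(
        event_id=None,
        d_center_nm=d_center,
        d_border_nm=d_border,
        d_norm=d_norm,
        location_class=IN_AZ if d_norm <= 1 else ECTOPIC,
    )


def build_az_map(dataset: Dataset, center: str = "mean") -> dict:
    """Functional AZ per bouton (from labeled synchronous events).

    Boutons whose synchronous events cannot define a hull (fewer than three,
    or collinear) are omitted from the map.
    """
    az_map: dict = {}
    ev = dataset.events
    for bouton_id, sub in ev[ev["release_class"] == SYNCHRONOUS].groupby(
        "bouton_id", sort=False
    ):
        pos = sub[["x_nm", "y_nm"]].to_numpy()
        try:
            az_map[bouton_id] = build_az(pos, bouton_id=bouton_id, center=center)
        except (InsufficientPointsError, DegenerateGeometryError):
            continue
    return az_map


def radial_profile(dataset: Dataset, az_map: dict | None = None) -> pd.DataFrame:
    """Per-event radial measures relative to each bouton's functional AZ.

    Returns one row per event with columns ``event_id, bouton_id,
    release_class, d_center_nm, d_border_nm, d_norm, location_class``.
    Events in boutons without a valid AZ are flagged ``undefined``.
    Synchronous events always come out with d_norm < 1: they define the
    hull, and the rim keeps the border ratio strictly below one.
    """
    if az_map is None:
        az_map = build_az_map(dataset)
    rim = dataset.config.rim_nm
    ev = dataset.events
    rows = []
    for bouton_id, sub in ev.groupby("bouton_id", sort=False):
        az = az_map.get(bouton_id)
        if az is None:
            for eid, rc in zip(sub["event_id"], sub.get("release_class", "")):
                rows.append((eid, bouton_id, rc, np.nan, np.nan, np.nan, UNDEFINED))
            continue
        xy = sub[["x_nm", "y_nm"]].to_numpy()
        vec = xy - az.center_nm
        d_center = np.linalg.norm(vec, axis=1)
        directions = np.where(
            d_center[:, None] > 0, vec, np.array([1.0, 0.0])
        )
        d_border = ray_border_distance(az, directions)
        d_norm = d_center / (d_border + rim)
        loc = np.where(d_norm <= 1, IN_AZ, ECTOPIC)
        for i, (eid, rc) in enumerate(zip(sub["event_id"], sub["release_class"])):
            rows.append(
                (eid, bouton_id, rc, d_center[i], d_border[i], d_norm[i], loc[i])
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "event_id", "bouton_id", "release_class",
            "d_center_nm", "d_border_nm", "d_norm", "location_class",
        ],
    )
    return out


def attach_location(dataset: Dataset, radial: pd.DataFrame) -> Dataset:
    """Copy location_class (and d_norm, d_center_nm) onto the event table."""
    merged = dataset.events.merge(
        radial[["event_id", "d_center_nm", "d_norm", "location_class"]],
        on="event_id",
        how="left",
        suffixes=("_old", ""),
    )
    for c in ("d_center_nm_old", "d_norm_old", "location_class_old"):
        if c in merged.columns:
            merged = merged.drop(columns=c)
    merged["location_class"] = merged["location_class"].fillna(UNDEFINED)
    dataset.events = merged
    return dataset
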