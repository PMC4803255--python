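"""Track I/O, burst segmentation and annotation export.

CSV is the canonical interchange format (Movebank-style columns by
default); KML and GeoJSON are export-only.  Annotated sequences can be
run-length encoded into *bursts* — maximal runs of consecutive locations
sharing a label — for segment-wise visualization.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .core import ClusteringResult
from .features import FeatureMatrix, Trajectory

logger = logging.getLogger("embc")

#: Conventional colours of the bivariate behavioural modes.
LABEL_COLORS = {"LL": "orange", "LH": "red", "HL": "cyan", "HH": "blue"}
_KML_COLORS = {  # KML is aabbggrr
    "orange": "ff00a5ff", "red": "ff0000ff", "cyan": "ffffff00",
    "blue": "ffff0000",
}
_FALLBACK_COLOR = "gray"


@dataclass
class Burst:
    """A maximal run of equal labels: [start, stop) half-open indices."""

    label: str
    start: int
    stop: int
    t_start: float | None = None
    t_end: float | None = None
    duration: float | None = None
    mean_position: tuple[float, float] | None = None

    @property
    def length(self) -> int:
        return self.stop - self.start


def bursts(labels: np.ndarray, traj: Trajectory | None = None) -> list[Burst]:
    """Run-length encode a label sequence; with a trajectory, attach the
    per-burst time span, duration and mean position."""
    labels = np.asarray(labels)
    if traj is not None and len(traj) != labels.shape[0]:
        raise ValueError("labels not aligned to trajectory points")
    if labels.size == 0:
        return []
    breaks = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], breaks])
    stops = np.concatenate([breaks, [labels.size]])
    out = []
    for a, b in zip(starts, stops):
        burst = Burst(label=str(labels[a]), start=int(a), stop=int(b))
        if traj is not None:
            burst.t_start = float(traj.t[a])
            burst.t_end = float(traj.t[b - 1])
            burst.duration = burst.t_end - burst.t_start
            burst.mean_position = tuple(traj.xy[a:b].mean(axis=0))
        out.append(burst)
    return out


# ---------------------------------------------------------------------------
# CSV


def read_trajectory_csv(
    path,
    time_col: str | None = None,
    x_col: str | None = None,
    y_col: str | None = None,
    geometry: str | None = None,
    id: str | None = None,
) -> Trajectory:
    """Read a track from CSV.

    Column defaults follow the Movebank dialect
    (``timestamp, location-long, location-lat``, geodesic) with a planar
    fallback (``t, x, y``).  Timestamps may be ISO-8601 or epoch seconds.
    Rows with missing coordinates are dropped with a logged index.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if x_col is None:
        if {"location-long", "location-lat"} <= cols:
            x_col, y_col = "location-long", "location-lat"
            geometry = geometry or "geodesic"
        elif {"x", "y"} <= cols:
            x_col, y_col = "x", "y"
            geometry = geometry or "planar"
        else:
            raise ValueError("no recognizable coordinate columns")
    if time_col is None:
        time_col = "timestamp" if "timestamp" in cols else "t"
    geometry = geometry or "geodesic"

    t_raw = df[time_col]
    try:
        t = t_raw.astype(float).to_numpy()
    except (TypeError, ValueError):
        t = pd.to_datetime(t_raw).astype("int64").to_numpy() / 1e9
    xy = df[[x_col, y_col]].to_numpy(dtype=float)
    drop = ~np.all(np.isfinite(xy), axis=1) | ~np.isfinite(t)
    if np.any(drop):
        logger.warning("dropping %d row(s) with missing coordinates: %s",
                       int(drop.sum()), np.flatnonzero(drop).tolist()[:20])
    keep = ~drop
    return Trajectory(t=t[keep], xy=xy[keep], geometry=geometry,
                      id=id or str(path))


def features_frame(fm: FeatureMatrix, traj: Trajectory | None = None
                   ) -> pd.DataFrame:
    """Feature table with id/t/tau, variables, reliabilities and validity."""
    data = {}
    if traj is not None:
        data["id"] = traj.id
        data["t"] = traj.t
    if fm.tau is not None:
        data["tau"] = fm.tau
    for l, name in enumerate(fm.variable_names):
        data[name] = fm.X[:, l]
    for l, name in enumerate(fm.variable_names):
        data[f"u_{name}"] = fm.U[:, l]
    data["valid"] = fm.valid
    return pd.DataFrame(data)


def annotation_frame(result: ClusteringResult, fm: FeatureMatrix,
                     traj: Trajectory | None = None) -> pd.DataFrame:
    """Annotated table: features plus label, posterior weights, active_k."""
    df = features_frame(fm, traj)
    df["label"] = result.labels
    for j, code in enumerate(result.codes):
        df[f"w_{code}"] = result.W[:, j]
    df["active_k"] = result.n_active
    return df


def write_annotation_csv(result: ClusteringResult, fm: FeatureMatrix,
                         path, traj: Trajectory | None = None) -> None:
    annotation_frame(result, fm, traj).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# KML / GeoJSON export


def _color_of(label: str) -> str:
    return LABEL_COLORS.get(label, _FALLBACK_COLOR)


def _kml_color(label: str) -> str:
    return _KML_COLORS.get(_color_of(label), "ff888888")


def _geojson_features(traj, labels, W, codes, mode):
    feats = []
    if mode == "point":
        for i in range(len(traj)):
            props = {"label": str(labels[i]), "t": float(traj.t[i]),
                     "color": _color_of(str(labels[i]))}
            if W is not None:
                for j, c in enumerate(codes):
                    w = W[i, j]
                    props[f"w_{c}"] = None if not np.isfinite(w) else float(w)
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [float(traj.xy[i, 0]),
                                             float(traj.xy[i, 1])]},
                "properties": props,
            })
    else:
        for b in bursts(labels, traj):
            stop = min(b.stop + 1, len(traj))  # connect to the next burst
            coords = [[float(x), float(y)] for x, y in traj.xy[b.start:stop]]
            feats.append({
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {"label": b.label, "duration": b.duration,
                               "n_points": b.length,
                               "color": _color_of(b.label)},
            })
    return feats


def export_annotation(
    result: ClusteringResult,
    traj: Trajectory,
    path,
    fm: FeatureMatrix | None = None,
    format: str = "csv",
    mode: str = "point",
) -> None:
    """Write the annotated track as CSV, KML or GeoJSON.

    ``mode='point'`` emits one feature per location (label + posterior
    weights); ``mode='burst'`` emits one line segment per burst with its
    label and duration.  Colour map: LL orange, LH red, HL cyan, HH blue.
    """
    if mode not in ("point", "burst"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = result.labels
    if format == "csv":
        if fm is None:
            raise ValueError("csv export needs the feature matrix")
        write_annotation_csv(result, fm, path, traj)
        return
    if format == "geojson":
        doc = {"type": "FeatureCollection",
               "features": _geojson_features(traj, labels, result.W,
                                             result.codes, mode)}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
        return
    if format == "kml":
        parts = ['<?xml version="1.0" encoding="UTF-8"?>',
                 '<kml xmlns="http://www.opengis.net/kml/2.2">',
                 f"<Document><name>{escape(traj.id)}</name>"]
        seen = sorted(set(np.asarray(labels).tolist()))
        for lab in seen:
            parts.append(
                f'<Style id="s_{escape(lab)}">'
                f"<IconStyle><color>{_kml_color(lab)}</color></IconStyle>"
                f"<LineStyle><color>{_kml_color(lab)}</color>"
                "<width>3</width></LineStyle></Style>")
        if mode == "point":
            for i in range(len(traj)):
                lab = str(labels[i])
                parts.append(
                    f"<Placemark><name>{escape(lab)}</name>"
                    f"<styleUrl>#s_{escape(lab)}</styleUrl>"
                    "<Point><coordinates>"
                    f"{traj.xy[i, 0]:.8f},{traj.xy[i, 1]:.8f}"
                    "</coordinates></Point></Placemark>")
        else:
            for b in bursts(labels, traj):
                stop = min(b.stop + 1, len(traj))
                coords = " ".join(f"{x:.8f},{y:.8f}"
                                  for x, y in traj.xy[b.start:stop])
                parts.append(
                    f"<Placemark><name>{escape(b.label)}</name>"
                    f"<styleUrl>#s_{escape(b.label)}</styleUrl>"
                    f"<LineString><coordinates>{coords}</coordinates>"
                    "</LineString></Placemark>")
        parts.append("</Document></kml>")
        with open(path, "w") as fh:
            fh.write("\n".join(parts))
        return
    raise ValueError(f"unknown format {format!r}")
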