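"""Movement features: velocity/turn estimation, reliability weights, windowed summaries.

Raw tracks are sequences of time-stamped positions, either geographic
(lon/lat, WGS84 degrees) or planar (metres).  Behavioural annotation
consumes *local* movement features attributed to each interior location:
the speed of the outgoing step and the absolute turning angle between the
incoming and outgoing headings.  Because empirical tracks are sampled at
irregular intervals, each feature value carries a per-point reliability
weight in [0, 1] that discounts values estimated across long time gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("embc")

#: Mean Earth radius (m), spherical model used for geodesic distance/bearing.
EARTH_RADIUS_M = 6371008.8


@dataclass
class Trajectory:
    """An ordered track of time-stamped positions.

    Parameters
    ----------
    t : array of float
        Timestamps in seconds (e.g. seconds since epoch); strictly increasing.
    xy : (n, 2) array
        Positions: columns (lon, lat) in degrees if ``geometry='geodesic'``,
        or (x, y) in metres if ``geometry='planar'``.
    geometry : {'geodesic', 'planar'}
    id : str
        Track identifier.
    """

    t: np.ndarray
    xy: np.ndarray
    geometry: str = "geodesic"
    id: str = "track"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        if self.t.shape[0] != self.xy.shape[0]:
            raise ValueError("t and xy lengths differ")
        if self.geometry not in ("geodesic", "planar"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        dt = np.diff(self.t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise ValueError(
                f"timestamps not strictly increasing at index {int(bad[0]) + 1}"
            )
        if self.geometry == "geodesic":
            lon, lat = self.xy[:, 0], self.xy[:, 1]
            if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
                raise ValueError("lon/lat outside valid ranges")

    def __len__(self) -> int:
        return self.xy.shape[0]


@dataclass
class FeatureMatrix:
    """n x m feature values with per-point, per-variable reliability weights.

    ``valid`` marks rows usable for model fitting; invalid rows (e.g. track
    end-points where a turn is undefined) are kept so labels can be
    back-filled onto every location.
    """

    X: np.ndarray
    variable_names: list[str]
    units: list[str]
    U: np.ndarray = None
    tau: np.ndarray = None
    tau_mode: float = None
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, m = self.X.shape
        if len(self.variable_names) != m or len(self.units) != m:
            raise ValueError("variable_names/units length mismatch")
        if self.U is None:
            self.U = np.ones((n, m))
        self.U = np.asarray(self.U, dtype=float)
        if self.U.shape != (n, m):
            raise ValueError("U shape mismatch")
        if np.any((self.U < 0) | (self.U > 1)):
            raise ValueError("reliability weights must lie in [0, 1]")
        if self.valid is None:
            self.valid = np.all(np.isfinite(self.X), axis=1)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.tau is not None:
            self.tau = np.asarray(self.tau, dtype=float)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_array(cls, X, variable_names=None, units=None) -> "FeatureMatrix":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = X.shape[1]
        names = list(variable_names) if variable_names else [f"x{l + 1}" for l in range(m)]
        units_ = list(units) if units else [""] * m
        return cls(X=X, variable_names=names, units=units_)


# ---------------------------------------------------------------------------
# geometry primitives


def _haversine(lonlat_a: np.ndarray, lonlat_b: np.ndarray) -> np.ndarray:
    la1, la2 = np.radians(lonlat_a[..., 1]), np.radians(lonlat_b[..., 1])
    dlon = np.radians(lonlat_b[..., 0] - lonlat_a[..., 0])
    dlat = la2 - la1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _initial_bearing(lonlat_a: np.ndarray, lonlat_b: np.ndarray) -> np.ndarray:
    la1, la2 = np.radians(lonlat_a[..., 1]), np.radians(lonlat_b[..., 1])
    dlon = np.radians(lonlat_b[..., 0] - lonlat_a[..., 0])
    y = np.sin(dlon) * np.cos(la2)
    x = np.cos(la1) * np.sin(la2) - np.sin(la1) * np.cos(la2) * np.cos(dlon)
    return np.arctan2(y, x)


def step_lengths_headings(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Length (m) and heading (rad) of each consecutive step p_i -> p_{i+1}."""
    a, b = traj.xy[:-1], traj.xy[1:]
    if traj.geometry == "planar":
        d = b - a
        return np.hypot(d[:, 0], d[:, 1]), np.arctan2(d[:, 1], d[:, 0])
    return _haversine(a, b), _initial_bearing(a, b)


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), 2.0 * np.pi)


# ---------------------------------------------------------------------------
# reliability


def reliability_from_tau(tau: np.ndarray, tau_mode: float) -> np.ndarray:
    """Default reliability u_i = min(1, tau_mode / tau_i).

    A location estimated over the nominal sampling interval (the mode of the
    interval distribution) is fully reliable; reliability decays inversely
    with longer gaps and is clipped at 1 for shorter ones.
    """
    tau = np.asarray(tau, dtype=float)
    if tau_mode <= 0:
        raise ValueError("tau_mode must be positive")
    if np.any(tau[np.isfinite(tau)] <= 0):
        raise ValueError("sampling intervals must be positive")
    return np.minimum(1.0, tau_mode / tau)


def pair_reliability(u_r, u_s):
    """Combined reliability of a variable pair: normalized Euclidean length
    sqrt((u_r^2 + u_s^2) / 2), anchored so (1, 1) -> 1 and (0, 0) -> 0."""
    u_r = np.asarray(u_r, dtype=float)
    u_s = np.asarray(u_s, dtype=float)
    if np.any((u_r < 0) | (u_r > 1)) or np.any((u_s < 0) | (u_s > 1)):
        raise ValueError("reliability weights must lie in [0, 1]")
    return np.sqrt((u_r**2 + u_s**2) / 2.0)


def tau_mode_estimate(tau: np.ndarray) -> float:
    """Mode of the sampling-interval distribution, 1-second histogram bins.

    Falls back to the median when no bin holds at least two intervals.
    """
    tau = np.asarray(tau, dtype=float)
    tau = tau[np.isfinite(tau)]
    if tau.size == 0:
        raise ValueError("no finite sampling intervals")
    bins = np.floor(tau).astype(np.int64)
    idx, counts = np.unique(bins, return_counts=True)
    if counts.max() < 2:
        return float(np.median(tau))
    mode_bin = idx[np.argmax(counts)]
    return float(np.median(tau[bins == mode_bin]))


# ---------------------------------------------------------------------------
# feature construction


def compute_velocity_turn(
    traj: Trajectory,
    reliability: str | Callable | None = "tau",
) -> FeatureMatrix:
    """Bivariate (velocity, turn) features attributed to interior locations.

    velocity_i = distance(p_i, p_{i+1}) / tau_i  (m/s, outgoing step)
    turn_i     = |wrap(heading_i - heading_{i-1})|  in [0, pi]

    The first point has no turn and the last point has neither feature;
    both are flagged invalid, leaving n - 2 valid rows.

    Parameters
    ----------
    reliability : 'tau', None, or callable
        'tau' applies the default interval-based weight min(1, tau~/tau_i)
        to both variables; None disables weighting (U = 1); a callable
        ``f(tau, tau_mode) -> (n,) weights`` supplies a custom scheme.
    """
    n = len(traj)
    if n < 3:
        raise ValueError("at least 3 points required for velocity/turn features")
    tau_step = np.diff(traj.t)
    if np.any(tau_step == 0):
        raise ValueError(f"zero sampling interval at index {int(np.argmin(tau_step))}")
    lengths, headings = step_lengths_headings(traj)

    velocity = np.full(n, np.nan)
    velocity[:-1] = lengths / tau_step
    turn = np.full(n, np.nan)
    turn[1:-1] = np.abs(wrap_angle(headings[1:] - headings[:-1]))

    tau = np.full(n, np.nan)
    tau[:-1] = tau_step
    tau_mode = tau_mode_estimate(tau_step)

    valid = np.zeros(n, dtype=bool)
    valid[1:-1] = True

    U = np.ones((n, 2))
    if reliability is not None:
        fn = reliability_from_tau if reliability == "tau" else reliability
        u = np.ones(n)
        u[:-1] = fn(tau_step, tau_mode)
        U = np.column_stack([u, u])

    return FeatureMatrix(
        X=np.column_stack([velocity, turn]),
        variable_names=["velocity", "turn"],
        units=["m/s", "rad"],
        U=U,
        tau=tau,
        tau_mode=tau_mode,
        valid=valid,
    )


def windowed_features(traj: Trajectory, window: float) -> FeatureMatrix:
    """Per-window summary features: mean speed, net displacement, straightness.

    The track is cut into consecutive windows of ``window`` seconds starting
    at the first timestamp.  Within each window holding at least two points:

    - mean speed = gross path length / elapsed time (m/s),
    - net displacement = distance(first, last) (m),
    - straightness = net displacement / gross path length in [0, 1]
      (1 for a zero-length path).

    Windows with fewer than two points are skipped with a log notice.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n = len(traj)
    span = traj.t[-1] - traj.t[0]
    if span < window:
        raise ValueError("trajectory shorter than one window")
    lengths, _ = step_lengths_headings(traj)
    w_idx = np.floor((traj.t - traj.t[0]) / window).astype(int)

    rows, skipped = [], 0
    for w in range(w_idx.max() + 1):
        sel = np.flatnonzero(w_idx == w)
        if sel.size < 2:
            skipped += 1
            continue
        first, last = sel[0], sel[-1]
        gross = float(np.sum(lengths[first:last]))
        if traj.geometry == "planar":
            net = float(np.hypot(*(traj.xy[last] - traj.xy[first])))
        else:
            net = float(_haversine(traj.xy[first], traj.xy[last]))
        elapsed = traj.t[last] - traj.t[first]
        speed = gross / elapsed if elapsed > 0 else 0.0
        straight = 1.0 if gross == 0 else min(1.0, net / gross)
        rows.append([speed, net, straight])
    if skipped:
        logger.info("windowed_features: skipped %d window(s) with < 2 points", skipped)
    X = np.asarray(rows, dtype=float).reshape(-1, 3)
    return FeatureMatrix(
        X=X,
        variable_names=["mean_speed", "net_displacement", "straightness"],
        units=["m/s", "m", ""],
        tau=np.full(X.shape[0], float(window)),
        tau_mode=float(window),
    )


def running_mean_presmooth(features: FeatureMatrix, span: int) -> FeatureMatrix:
    """Centred running mean over valid rows; truncated windows at the edges.

    A pre-clustering smoother: averaging local measures over a window sets
    the behavioural scale of interest.  Reliability weights and the validity
    mask are propagated unchanged.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be an odd integer >= 1")
    n = features.n
    if span > n:
        logger.warning("running_mean_presmooth: span %d > series length %d; "
                       "using the global mean", span, n)
    half = span // 2
    Xs = features.X.copy()
    vi = np.flatnonzero(features.valid)
    if vi.size:
        V = features.X[vi]  # smooth along the sequence of valid rows
        for out_pos, _ in enumerate(vi):
            lo = max(0, out_pos - half)
            hi = min(vi.size, out_pos + half + 1)
            Xs[vi[out_pos]] = V[lo:hi].mean(axis=0)
    return FeatureMatrix(
        X=Xs,
        variable_names=list(features.variable_names),
        units=list(features.units),
        U=features.U.copy(),
        tau=None if features.tau is None else features.tau.copy(),
        tau_mode=features.tau_mode,
        valid=features.valid.copy(),
    )
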