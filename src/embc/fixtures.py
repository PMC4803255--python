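"""Small deterministic datasets for tests, demos and CLI smoke runs.

Everything is generated programmatically; the 12-point planar track is
constructed *inversely* from chosen step lengths and turning angles, so
its expected features are known exactly and written beside the fixture.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SyntheticConfig, simulate

#: Step speeds (m/s at 10 s intervals) and absolute turns (rad) used to
#: build the hand-checkable planar track; feature row i of the generated
#: trajectory must reproduce these values exactly on interior points.
PLANAR12_SPEEDS = np.array(
    [1.0, 1.0, 2.0, 2.0, 0.5, 0.5, 3.0, 3.0, 1.5, 1.5, 2.5])
PLANAR12_TURNS = np.array(
    [0.0, np.pi / 2, 0.0, np.pi / 4, np.pi / 4, 0.0, np.pi / 2,
     np.pi / 6, 0.0, np.pi / 3])


def planar12_trajectory():
    """12 planar points integrated from the frozen speed/turn table."""
    from .features import Trajectory

    dt = 10.0
    headings = np.concatenate([[0.0], np.cumsum(PLANAR12_TURNS)])
    steps = (PLANAR12_SPEEDS * dt)[:, None] * np.column_stack(
        [np.cos(headings), np.sin(headings)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Trajectory(t=np.arange(12) * dt, xy=xy, geometry="planar",
                      id="planar12")


def four_blobs(n_per: int = 100, seed: int = 7, spread: float = 0.03):
    """Well-separated blobs at the LL/LH/HL/HH unit-square corners.

    Returns (X, codes) with the generating code of each row.
    """
    rng = np.random.default_rng([seed, 11])
    centers = np.array([[0.2, 0.2], [0.2, 0.8], [0.8, 0.2], [0.8, 0.8]])
    codes = np.array(["LL", "LH", "HL", "HH"])
    X = np.vstack([c + rng.normal(scale=spread, size=(n_per, 2))
                   for c in centers])
    labels = np.repeat(codes, n_per)
    return X, labels


def make_fixtures(outdir, seed: int = 7) -> dict[str, Path]:
    """Write the fixture bundle; byte-identical for a given seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    traj = planar12_trajectory()
    paths["planar12"] = outdir / "planar12.csv"
    pd.DataFrame({"t": traj.t, "x": traj.xy[:, 0], "y": traj.xy[:, 1]}
                 ).to_csv(paths["planar12"], index=False, float_format="%.10f")
    paths["planar12_expected"] = outdir / "planar12_expected.csv"
    pd.DataFrame({
        "velocity": PLANAR12_SPEEDS[1:],          # interior points 1..10
        "turn": PLANAR12_TURNS,
    }).to_csv(paths["planar12_expected"], index=False, float_format="%.10f")

    X, labels = four_blobs(seed=seed)
    paths["blobs4"] = outdir / "blobs4.csv"
    pd.DataFrame({"velocity": X[:, 0], "turn": X[:, 1], "code": labels}
                 ).to_csv(paths["blobs4"], index=False, float_format="%.10f")

    # delimiter-overlap instance: two configurations of the bivariate
    # delimiters whose middle rectangle is claimed by two regions at once
    paths["delimiters"] = outdir / "delimiters_overlap.json"
    paths["delimiters"].write_text(
        '{"overlapping": {".L": 0.6, ".H": 0.4, "L.": 0.6, "H.": 0.4},\n'
        ' "non_overlapping": {".L": 0.4, ".H": 0.6, "L.": 0.4, "H.": 0.6}}\n')

    ds = simulate(SyntheticConfig(n=400, gamma=0.05, scheme="markov",
                                  seed=seed))
    paths["synth400"] = outdir / "synth400.csv"
    pd.DataFrame({
        "state": ds.state_labels,
        "velocity": ds.features.X[:, 0],
        "turn": ds.features.X[:, 1],
        "tau": ds.features.tau,
    }).to_csv(paths["synth400"], index=False, float_format="%.10f")
    return paths
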