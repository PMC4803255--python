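"""Posterior-margin smoothing of label sequences.

Labels are assigned per location without temporal context.  The smoother
accounts for temporal correlation after the fact, in its most basic form:
it looks for *singles* — interior locations whose label differs from the
identical labels of both neighbours — and relabels a single to its
neighbours' cluster when the posterior margin in favour of its current
cluster is at most delta_w.  delta_w expresses the user's willingness to
accept the change and is deliberately kept apart from the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SmoothConfig:
    delta_w: float = 0.0
    passes: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_w <= 1.0:
            raise ValueError("delta_w must lie in [0, 1]")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


def find_singles(labels: np.ndarray) -> np.ndarray:
    """Indices i (interior) with labels[i-1] == labels[i+1] != labels[i]."""
    labels = np.asarray(labels)
    if labels.shape[0] < 3:
        raise ValueError("need at least 3 labels")
    prev, cur, nxt = labels[:-2], labels[1:-1], labels[2:]
    return np.flatnonzero((prev == nxt) & (prev != cur)) + 1


def smooth_labels(
    labels: np.ndarray,
    W: np.ndarray,
    codes: list[str],
    config: SmoothConfig | None = None,
) -> np.ndarray:
    """Relabel singles whose margin w_ic - w_in <= delta_w.

    ``W`` columns follow ``codes``.  Each pass scans left to right on the
    labels as they stood at the start of the pass (changes applied after
    the scan), re-detecting singles between passes.  Non-single labels are
    never modified, so smoothing cannot increase the number of label
    transitions.
    """
    config = config or SmoothConfig()
    labels = np.asarray(labels, dtype=object).astype(str)
    col = {c: j for j, c in enumerate(codes)}
    out = labels.copy()
    for _ in range(config.passes):
        singles = find_singles(out)
        if singles.size == 0:
            break
        new = out.copy()
        changed = False
        for i in singles:
            c, nb = col[out[i]], col[out[i - 1]]
            margin = W[i, c] - W[i, nb]
            if np.isfinite(margin) and margin <= config.delta_w:
                new[i] = out[i - 1]
                changed = True
        out = new
        if not changed:
            break
    return out
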