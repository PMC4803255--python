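"""Classic unconstrained Gaussian-mixture EM clustering (EMC baseline).

The comparison baseline: a standard k-component Gaussian mixture fitted by
EM from multiple random starts, with the best final likelihood kept.  It
shares the Gaussian E-step and the weighted-moment M-step kernels with the
constrained algorithm, of which it is the unconstrained limit (reliability
weights and region membership switched off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import binary
from .core import (ClusteringResult, EMbCConfig, MixtureModel, estep, loglik,
                   mstep_embc, resolve_sigma_min)
from .features import FeatureMatrix

logger = logging.getLogger("embc")


@dataclass
class EMCConfig:
    k: int = 4
    n_starts: int = 10
    seed: int = 0
    sigma_min: object = None
    max_iter: int = 200
    delta: float = 1e-6


def _seed_means(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding: means drawn from the data points with
    probability proportional to the squared distance to the nearest seed."""
    n = X.shape[0]
    means = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [np.sum((X - mu) ** 2, axis=1) for mu in means], axis=0)
        total = d2.sum()
        if total <= 0:
            means.append(X[rng.integers(n)])
            continue
        means.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(means)


def _run_em(X: np.ndarray, k: int, sigma_min: np.ndarray,
            rng: np.random.Generator, max_iter: int, delta: float
            ) -> tuple[MixtureModel, list[float]]:
    n, m = X.shape
    var = np.maximum(X.var(axis=0), sigma_min**2)
    model = MixtureModel(
        mus=_seed_means(X, k, rng),
        sigmas=np.tile(np.diag(var), (k, 1, 1)),
        pis=np.full(k, 1.0 / k),
        active=np.ones(k, dtype=bool),
        codes=[str(j) for j in range(k)],
    )
    U = np.ones((n, m))
    memb = np.ones((n, k), dtype=bool)
    reseeded = np.zeros(k, dtype=bool)
    trace: list[float] = []
    prev = None
    for _ in range(max_iter):
        W = estep(X, model)
        # one re-seed for a collapsing component before dropping it
        soft = W.sum(axis=0)
        for j in range(k):
            if model.active[j] and soft[j] < 1e-8 * n and not reseeded[j]:
                model.mus[j] = X[rng.integers(n)]
                model.sigmas[j] = np.diag(var)
                reseeded[j] = True
                logger.warning("emc: component %d re-seeded", j)
                W = estep(X, model)
        model = mstep_embc(X, W, U, memb, model, sigma_min,
                           delimiters=None, absorb_tol=1e-8)
        ll = loglik(X, model)
        trace.append(ll)
        if prev is not None and abs(ll - prev) < delta:
            break
        prev = ll
    return model, trace


def fit_emc(fm: FeatureMatrix | np.ndarray, config: EMCConfig | None = None
            ) -> ClusteringResult:
    """Best-of-n_starts EM fit; reproducible under ``config.seed``.

    Labels are component indices (as strings); unlike the binary-constrained
    clustering these carry no intrinsic semantics and must be matched to a
    reference before scoring.
    """
    if not isinstance(fm, FeatureMatrix):
        fm = FeatureMatrix.from_array(fm)
    config = config or EMCConfig()
    if config.k < 1 or config.n_starts < 1:
        raise ValueError("k and n_starts must be >= 1")
    sigma_min = resolve_sigma_min(fm, config.sigma_min)
    Xv = fm.X[fm.valid]
    if Xv.shape[0] < config.k:
        raise ValueError("fewer valid points than components")

    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=config.n_starts)
    best = None
    for s in seeds:
        model, trace = _run_em(Xv, config.k, sigma_min,
                               np.random.default_rng(int(s)),
                               config.max_iter, config.delta)
        if best is None or trace[-1] > best[1][-1]:
            best = (model, trace)
    model, trace = best

    Wv = estep(Xv, model)
    Wa = np.where(model.active, Wv, -np.inf)
    labels_valid = np.asarray(model.codes, dtype=object)[
        np.argmax(Wa, axis=1)].astype(str)
    from .core import backfill_labels
    labels = backfill_labels(labels_valid, fm.valid)
    W = np.full((fm.n, config.k), np.nan)
    W[fm.valid] = Wv
    status = "converged" if len(trace) < config.max_iter else "max_iter"
    return ClusteringResult(model, None, W, labels, trace, status,
                            model.n_active)
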