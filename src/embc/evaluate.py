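"""Confusion-matrix metrics and benchmark/robustness experiment drivers."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EMbCConfig, fit
from .emc import EMCConfig, fit_emc
from .features import FeatureMatrix, reliability_from_tau
from .simulate import (SyntheticConfig, SyntheticDataset, degrade_jitter,
                       degrade_loss, simulate)

logger = logging.getLogger("embc")


@dataclass
class ConfusionMatrix:
    """Reference (rows) vs predicted (columns) label counts."""

    counts: np.ndarray
    ref_labels: list
    pred_labels: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class recall/precision/F and the marginal-weighted overall F."""

    labels: list
    recall: np.ndarray
    precision: np.ndarray
    f: np.ndarray
    marginals: np.ndarray
    overall_f: float


def confusion(ref, pred, labels=None) -> ConfusionMatrix:
    """Count matrix counts[a, b] = #{i : ref_i = a, pred_i = b}.

    ``labels`` fixes the class order for both axes (useful so absorbed or
    unused clusters keep a row/column); by default the sorted union of the
    observed labels is used.
    """
    ref = np.asarray(ref)
    pred = np.asarray(pred)
    if ref.shape != pred.shape:
        raise ValueError("ref and pred lengths differ")
    if labels is None:
        labels = sorted(set(ref.tolist()) | set(pred.tolist()))
    labels = list(labels)
    idx = {c: j for j, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in zip(ref.tolist(), pred.tolist()):
        counts[idx[a], idx[b]] += 1
    return ConfusionMatrix(counts=counts, ref_labels=labels,
                           pred_labels=labels)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """recall = diag/rowsum, precision = diag/colsum, F = 2PR/(P+R); the
    overall F is the reference-marginal-weighted mean of the per-class F
    (classes absent from the reference carry zero weight)."""
    counts = cm.counts.astype(float)
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(rows > 0, diag / rows, 0.0)
        precision = np.where(cols > 0, diag / cols, 0.0)
        pr = precision + recall
        f = np.where(pr > 0, 2.0 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    marginals = rows / rows.sum()
    return MetricsReport(labels=list(cm.ref_labels), recall=recall,
                         precision=precision, f=f, marginals=marginals,
                         overall_f=float(marginals @ f))


def match_clusters(cm: ConfusionMatrix) -> tuple[int, ...]:
    """Column permutation maximizing the overall F-measure (exhaustive for
    up to 8 classes).  Needed to score methods whose cluster indices are
    arbitrary; binary-coded labels are semantically anchored and skip this.

    Returns ``perm`` such that ``counts[:, perm]`` aligns predicted column
    ``perm[a]`` with reference class ``a``.
    """
    c = cm.counts.shape[0]
    if cm.counts.shape[0] != cm.counts.shape[1]:
        raise ValueError("match_clusters needs a square matrix")
    if c > 8:
        raise ValueError("exhaustive matching limited to 8 classes")
    best_perm, best_f = None, -1.0
    for perm in itertools.permutations(range(c)):
        f = metrics(ConfusionMatrix(cm.counts[:, perm], cm.ref_labels,
                                    cm.pred_labels)).overall_f
        if f > best_f:
            best_perm, best_f = perm, f
    return best_perm


def f_score(ref, pred, labels=None, match: bool = False) -> float:
    """Overall F-measure of ``pred`` against ``ref``; with ``match=True``
    predicted classes are first optimally matched to reference classes."""
    cm = confusion(ref, pred, labels=labels)
    if match:
        perm = match_clusters(cm)
        cm = ConfusionMatrix(cm.counts[:, perm], cm.ref_labels, cm.pred_labels)
    return metrics(cm).overall_f


# ---------------------------------------------------------------------------
# experiment drivers


def _cell_seed(seed: int, *parts: int) -> list[int]:
    return [int(seed)] + [int(p) for p in parts]


def score_method(dataset: SyntheticDataset, method: str, seed: int = 0,
                 emc_starts: int = 5) -> float:
    """F-measure of one method's labelling of one synthetic dataset."""
    ref = dataset.state_labels
    if method == "embc":
        res = fit(dataset.features, EMbCConfig())
        return f_score(ref, res.labels, labels=dataset.codes)
    if method == "emc":
        res = fit_emc(dataset.features,
                      EMCConfig(k=len(dataset.codes), n_starts=emc_starts,
                                seed=seed))
        # arbitrary indices: map reference codes and predicted indices onto
        # a common axis, then optimally match
        classes = dataset.codes + res.model.codes
        cm = confusion(ref, res.labels, labels=classes)
        k = len(dataset.codes)
        sub = ConfusionMatrix(cm.counts[:k, k:], dataset.codes,
                              res.model.codes)
        perm = match_clusters(sub)
        aligned = ConfusionMatrix(sub.counts[:, perm], sub.ref_labels,
                                  sub.pred_labels)
        return metrics(aligned).overall_f
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    ns=(50, 100, 200, 400, 800, 1600),
    gammas=(0.01, 0.05, 0.1),
    schemes=("markov",),
    reps: int = 100,
    methods=("embc",),
    seed: int = 1,
    emc_starts: int = 5,
) -> pd.DataFrame:
    """Synthetic benchmark grid: mean F-measure and its root-mean-square
    spread across replicates, per (method, scheme, n, gamma).

    Replicate r of each cell uses an independent generator seed derived
    from ``seed``; failed fits are recorded and excluded from the means.
    """
    rows = []
    for method in methods:
        for scheme in schemes:
            for n in ns:
                for gamma in gammas:
                    fs, failures = [], 0
                    for r in range(1, reps + 1):
                        ds = simulate(SyntheticConfig(
                            n=n, gamma=gamma, scheme=scheme,
                            seed=0), seed=_cell_seed(seed, n, round(gamma * 1000), r))
                        try:
                            fs.append(score_method(ds, method, seed=r,
                                                   emc_starts=emc_starts))
                        except Exception:
                            logger.exception("fit failed (%s n=%d gamma=%.2f rep=%d)",
                                             method, n, gamma, r)
                            failures += 1
                    fs = np.asarray(fs)
                    mean_f = float(fs.mean()) if fs.size else np.nan
                    rmse = float(np.sqrt(np.mean((fs - mean_f) ** 2))) if fs.size else np.nan
                    rows.append(dict(method=method, scheme=scheme, n=n,
                                     gamma=gamma, reps=len(fs),
                                     failures=failures, mean_f=mean_f,
                                     rmse_f=rmse))
    return pd.DataFrame(rows)


def run_robustness(
    fm: FeatureMatrix,
    kind: str,
    factors,
    reps: int = 10,
    reliability: bool = True,
    seed: int = 1,
    config: EMbCConfig | None = None,
) -> pd.DataFrame:
    """Degrade-and-refit robustness experiment.

    The full-data labelling is the reference.  For each degradation factor
    and replicate: degrade the feature set (``kind='loss'`` removes points,
    ``kind='jitter'`` perturbs values in proportion to the sampling gap),
    refit, and score the new labels against the reference labels on the
    surviving points.  ``reliability`` toggles the interval-based weights
    in the refits.
    """
    if kind not in ("loss", "jitter"):
        raise ValueError("kind must be 'loss' or 'jitter'")
    base_cfg = config or EMbCConfig()
    ref = fit(fm, base_cfg)
    refit_cfg = EMbCConfig(
        sigma_min=base_cfg.sigma_min, max_iter=base_cfg.max_iter,
        delta=base_cfg.delta, use_reliability=reliability)
    n = fm.n
    k_min = 2**fm.m
    rows = []
    for factor in factors:
        fs, invalid = [], 0
        for r in range(1, reps + 1):
            rep_seed = _cell_seed(seed, kind == "jitter",
                                  round(float(factor) * 1000), r)
            if kind == "loss":
                _, kept = degrade_loss(fm.X, float(factor), seed=rep_seed)
                if kept.size < k_min or fm.valid[kept].sum() < k_min:
                    invalid += 1
                    continue
                sub = FeatureMatrix(
                    X=fm.X[kept], variable_names=list(fm.variable_names),
                    units=list(fm.units), U=fm.U[kept],
                    tau=None if fm.tau is None else fm.tau[kept],
                    tau_mode=fm.tau_mode, valid=fm.valid[kept])
                res = fit(sub, refit_cfg)
                fs.append(f_score(ref.labels[kept], res.labels,
                                  labels=ref.codes))
            else:
                if fm.tau is None or fm.tau_mode is None:
                    raise ValueError("jitter requires sampling intervals")
                tau = np.where(np.isfinite(fm.tau), fm.tau, fm.tau_mode)
                if float(factor) == 0.0:
                    Xj = fm.X.copy()
                else:
                    Xj = degrade_jitter(fm.X, tau, fm.tau_mode,
                                        float(factor), seed=rep_seed)
                sub = FeatureMatrix(
                    X=Xj, variable_names=list(fm.variable_names),
                    units=list(fm.units), U=fm.U.copy(), tau=fm.tau,
                    tau_mode=fm.tau_mode, valid=fm.valid)
                res = fit(sub, refit_cfg)
                fs.append(f_score(ref.labels, res.labels, labels=ref.codes))
        fs = np.asarray(fs)
        rows.append(dict(kind=kind, factor=float(factor),
                         reliability=reliability, reps=len(fs),
                         invalid=invalid,
                         mean_f=float(fs.mean()) if fs.size else np.nan))
    return pd.DataFrame(rows)
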