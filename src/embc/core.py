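"""The EMbC algorithm: constrained Gaussian-mixture EM with binary delimiters.

The model is a k = 2^m component Gaussian mixture whose component means are
constrained to axis-aligned binary regions (low/high per variable), so each
cluster keeps a fixed semantic identity (e.g. LL = slow, straight = resting).
At each iteration:

1. E-step: posterior weights w_ij under the current parameters.
2. Delimiters: for every adjacent cluster pair, data points are projected
   onto the segment joining the two means and the delimiter is placed at
   the projected point where the pair-restricted posteriors are closest
   to equiprobable.
3. Region membership: points are assigned (possibly multiply) to the binary
   regions the delimiters define.
4. M-step: mixing weights from all points; means restricted to region
   members, weighted by per-point reliability; covariances unbounded (over
   all points) so the correlation structure of the whole variable space is
   retained.  Variances are floored at sigma_min^2 per variable.

Because the bounded mean update is not an exact maximizer, the likelihood
trace is predominantly increasing but may drop sporadically; a persistent
oscillation between the binary and the unconstrained optimum is detected
as a cycle and the best state seen is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from . import binary
from .binary import DelimiterSet
from .features import FeatureMatrix

logger = logging.getLogger("embc")

#: Generic variance floor (standard deviation): sqrt of double precision eps.
GENERIC_SIGMA_MIN = 1.49e-8
#: Conventional floors for movement variables, by variable name.
NAMED_SIGMA_MIN = {"velocity": 0.01, "turn": 0.087}


@dataclass
class GaussianComponent:
    """One mixture component: mean, covariance, mixing weight, activity flag."""

    mu: np.ndarray
    sigma: np.ndarray
    pi: float
    active: bool = True
    code: str = ""


@dataclass
class MixtureModel:
    """Vectorized container for up to k = 2^m Gaussian components."""

    mus: np.ndarray       # (k, m)
    sigmas: np.ndarray    # (k, m, m)
    pis: np.ndarray       # (k,)
    active: np.ndarray    # (k,) bool
    codes: list[str]

    @property
    def k(self) -> int:
        return self.mus.shape[0]

    @property
    def m(self) -> int:
        return self.mus.shape[1]

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def components(self) -> list[GaussianComponent]:
        return [
            GaussianComponent(self.mus[j].copy(), self.sigmas[j].copy(),
                              float(self.pis[j]), bool(self.active[j]),
                              self.codes[j])
            for j in range(self.k)
        ]

    def copy(self) -> "MixtureModel":
        return MixtureModel(self.mus.copy(), self.sigmas.copy(),
                            self.pis.copy(), self.active.copy(),
                            list(self.codes))


@dataclass
class EMbCConfig:
    """Fit configuration.

    sigma_min : per-variable standard-deviation floor.  Defaults: 0.01 m/s
        for a variable named 'velocity', 0.087 rad (5 degrees) for 'turn',
        sqrt(machine eps) otherwise.  Sets the resolution of the analysis
        rather than acting as a free parameter.
    delta : convergence threshold on the mean per-point log-likelihood.
    """

    sigma_min: Sequence[float] | None = None
    max_iter: int = 200
    delta: float = 1e-6
    use_reliability: bool = True
    cycle_window: int = 20
    cycle_tol: float = 1e-9
    absorb_tol: float = 1e-8


@dataclass
class ClusteringResult:
    """Output of a fit: model, delimiters, posteriors, labels, diagnostics."""

    model: MixtureModel
    delimiters: DelimiterSet | None
    W: np.ndarray                 # (n, k); NaN rows for invalid points
    labels: np.ndarray            # (n,) label per point (codes, back-filled)
    loglik_trace: list[float]
    status: str                   # converged | max_iter | cycle_stop
    n_active: int

    @property
    def components(self) -> list[GaussianComponent]:
        return self.model.components

    @property
    def codes(self) -> list[str]:
        return self.model.codes


# ---------------------------------------------------------------------------
# Gaussian math


def log_gauss(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log density of N(mu, sigma) at the rows of X, via Cholesky."""
    m = mu.shape[0]
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        # floor guarantees PD in the fit loop; guard stray inputs anyway
        w, V = np.linalg.eigh((sigma + sigma.T) / 2.0)
        w = np.maximum(w, 1e-12 * max(w.max(), 1.0))
        chol = np.linalg.cholesky((V * w) @ V.T)
    z = solve_triangular(chol, (np.atleast_2d(X) - mu).T, lower=True)
    maha = np.sum(z * z, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (m * np.log(2.0 * np.pi) + logdet + maha)


def _floor_and_fix(sigma: np.ndarray, sigma_min: np.ndarray) -> np.ndarray:
    """Symmetrize, clip negative eigenvalues, floor diagonal at sigma_min^2."""
    s = (sigma + sigma.T) / 2.0
    w = np.linalg.eigvalsh(s)
    if w[0] < 0:
        wc, V = np.linalg.eigh(s)
        wc = np.maximum(wc, 1e-12 * max(abs(wc[-1]), 1.0))
        s = (V * wc) @ V.T
        s = (s + s.T) / 2.0
    d = np.maximum(np.diag(s), sigma_min**2)
    s[np.diag_indices_from(s)] = d
    return s


def resolve_sigma_min(fm: FeatureMatrix, sigma_min=None) -> np.ndarray:
    """Per-variable sigma floor from config, variable names, or the generic
    machine-precision default."""
    if sigma_min is not None:
        out = np.asarray(sigma_min, dtype=float)
        if out.ndim == 0:
            out = np.full(fm.m, float(out))
        if out.shape != (fm.m,):
            raise ValueError("sigma_min length mismatch")
        return out
    return np.array([
        NAMED_SIGMA_MIN.get(name, GENERIC_SIGMA_MIN)
        for name in fm.variable_names
    ])


# ---------------------------------------------------------------------------
# E-step and likelihood


def estep(X: np.ndarray, model: MixtureModel) -> np.ndarray:
    """Posterior weights w_ij; rows sum to 1 over active components.

    Computed in log-space; rows where every density underflows fall back
    to uniform weights over the active components (with a warning).
    """
    n = X.shape[0]
    k = model.k
    logw = np.full((n, k), -np.inf)
    for j in range(k):
        if model.active[j] and model.pis[j] > 0:
            logw[:, j] = np.log(model.pis[j]) + log_gauss(X, model.mus[j],
                                                          model.sigmas[j])
    norm = logsumexp(logw, axis=1)
    bad = ~np.isfinite(norm)
    W = np.exp(logw - norm[:, None])
    if np.any(bad):
        logger.warning("estep: %d row(s) underflowed; uniform weights used",
                       int(bad.sum()))
        W[bad] = model.active / max(model.n_active, 1)
    return W


def loglik(X: np.ndarray, model: MixtureModel,
           valid: np.ndarray | None = None) -> float:
    """Mean per-point mixture log-likelihood over valid rows."""
    if valid is not None:
        X = X[valid]
    n = X.shape[0]
    logw = np.full((n, model.k), -np.inf)
    for j in range(model.k):
        if model.active[j] and model.pis[j] > 0:
            logw[:, j] = np.log(model.pis[j]) + log_gauss(X, model.mus[j],
                                                          model.sigmas[j])
    return float(np.mean(logsumexp(logw, axis=1)))


# ---------------------------------------------------------------------------
# initialization


def _split_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


def init_max_entropy(
    X: np.ndarray, sigma_min: np.ndarray
) -> tuple[DelimiterSet, MixtureModel]:
    """Maximum-entropy starting point: recursive median splits.

    At each node of a binary split tree, among the variables not yet split
    on the path, the one whose median split of the node's data has maximum
    entropy is chosen (ties to the lowest variable index); the within-subset
    median becomes the initial delimiter for every context consistent with
    the path.  Components are estimated from the resulting cells with
    uniform per-point weights and a uniform prior pi = 1/k, conveying the
    least information possible.
    """
    n, m = X.shape
    k = 2**m
    if n < k:
        raise ValueError(f"need at least {k} valid points, got {n}")
    code_list = binary.codes(m)
    delims = DelimiterSet(m)
    cell = np.zeros(n, dtype=int)

    def recurse(idx: np.ndarray, remaining: list[int], path: dict[int, str]):
        if not remaining:
            j = binary.code_index(
                "".join(path[l] for l in range(m)))
            cell[idx] = j
            return
        best_l, best_h, best_med = None, -1.0, None
        for l in remaining:
            if idx.size == 0:
                med, h = float(np.median(X[:, l])), 0.0
            else:
                med = float(np.median(X[idx, l]))
                h = _split_entropy(float(np.mean(X[idx, l] <= med)))
            if h > best_h:
                best_l, best_h, best_med = l, h, med
        if best_h == 0.0 and idx.size:
            logger.warning("init: degenerate split of variable %d "
                           "(all values equal side)", best_l)
        # the delimiter applies to every context consistent with the path
        for code in code_list:
            if all(code[v] == b for v, b in path.items()):
                delims[binary.delimiter_key(code, best_l)] = best_med
        low = idx[X[idx, best_l] <= best_med] if idx.size else idx
        high = idx[X[idx, best_l] > best_med] if idx.size else idx
        rest = [v for v in remaining if v != best_l]
        recurse(low, rest, {**path, best_l: binary.L})
        recurse(high, rest, {**path, best_l: binary.H})

    recurse(np.arange(n), list(range(m)), {})

    mus = np.zeros((k, m))
    sigmas = np.zeros((k, m, m))
    g_mu = X.mean(axis=0)
    g_sig = _floor_and_fix(np.cov(X.T, ddof=0).reshape(m, m), sigma_min)
    for j in range(k):
        sel = cell == j
        if sel.sum() >= 2:
            mus[j] = X[sel].mean(axis=0)
            sigmas[j] = _floor_and_fix(
                np.cov(X[sel].T, ddof=0).reshape(m, m), sigma_min)
        elif sel.sum() == 1:
            mus[j] = X[sel][0]
            sigmas[j] = np.diag(np.diag(g_sig))
        else:
            mus[j] = g_mu
            sigmas[j] = g_sig.copy()
    model = MixtureModel(
        mus=mus, sigmas=sigmas, pis=np.full(k, 1.0 / k),
        active=np.ones(k, dtype=bool), codes=code_list,
    )
    return delims, model


# ---------------------------------------------------------------------------
# delimiters


def compute_delimiter(
    X: np.ndarray,
    model: MixtureModel,
    a: int,
    b: int,
    split_var: int,
) -> float:
    """Delimiter between adjacent clusters a (low) and b (high).

    Data points are projected orthogonally onto the segment joining the two
    means; among projections falling inside the segment (all points if none
    do), the delimiter is the split-variable coordinate of the projected
    point whose pair-restricted posteriors are closest to equiprobable
    (minimum |w_a - w_b|, equivalently minimum pair log-odds).  Ties go to
    the projection nearest the segment midpoint.
    """
    mu_a, mu_b = model.mus[a], model.mus[b]
    d = mu_b - mu_a
    denom = float(d @ d)
    if denom <= 0.0:
        logger.warning("compute_delimiter: coincident means for %s/%s",
                       model.codes[a], model.codes[b])
        return float(mu_a[split_var])
    tproj = (X - mu_a) @ d / denom
    sel = (tproj >= 0.0) & (tproj <= 1.0)
    if not np.any(sel):
        sel = np.ones(X.shape[0], dtype=bool)
    tz = tproj[sel]
    Z = mu_a + tz[:, None] * d
    la = np.log(model.pis[a]) + log_gauss(Z, mu_a, model.sigmas[a])
    lb = np.log(model.pis[b]) + log_gauss(Z, mu_b, model.sigmas[b])
    diff = np.abs(la - lb)  # |w_a - w_b| is monotone in the pair log-odds
    dmin = diff.min()
    cand = np.flatnonzero(diff <= dmin + 1e-12)
    best = cand[np.argmin(np.abs(tz[cand] - 0.5))]
    return float(Z[best, split_var])


def compute_delimiters(X: np.ndarray, model: MixtureModel) -> DelimiterSet:
    """All delimiters for the active clusters; pairs touching an absorbed
    cluster are left undefined."""
    delims = DelimiterSet(model.m)
    index = {c: j for j, c in enumerate(model.codes)}
    for key, ca, cb, l in delims.pairs():
        a, b = index[ca], index[cb]
        if model.active[a] and model.active[b]:
            delims[key] = compute_delimiter(X, model, a, b, l)
    return delims


# ---------------------------------------------------------------------------
# M-step


def mstep_embc(
    X: np.ndarray,
    W: np.ndarray,
    U: np.ndarray,
    membership: np.ndarray,
    model: MixtureModel,
    sigma_min: np.ndarray,
    delimiters: DelimiterSet | None = None,
    absorb_tol: float = 1e-8,
) -> MixtureModel:
    """Reliability-weighted, region-bounded parameter update.

    - pi_j: mean posterior over all points.
    - mu_j: weighted mean over the members of R_j with weights u_i^(l) w_ij,
      then clipped to R_j (the members of a convex region keep the weighted
      mean inside it; clipping only acts on fallback-assigned points).
    - sigma_j: weighted second moments over *all* points with pair weights
      u_i^(r,s) w_ij around the new mean; diagonal floored at sigma_min^2.

    Clusters whose region is empty or whose posterior mass vanishes are
    absorbed: deactivated, pi renormalized, and skipped from then on.
    With U = 1 and all-true membership this reduces exactly to the
    unconstrained EMC update.
    """
    n, m = X.shape
    new = model.copy()
    u_pair = np.empty((m, m, n))
    for r in range(m):
        for s in range(m):
            u_pair[r, s] = np.sqrt((U[:, r] ** 2 + U[:, s] ** 2) / 2.0)

    for j in range(model.k):
        if not model.active[j]:
            continue
        wj = W[:, j]
        soft = float(wj.sum())
        memb = membership[:, j]
        if soft < absorb_tol * n or not memb.any():
            logger.warning("cluster %s absorbed (mass %.3g, members %d)",
                           model.codes[j], soft, int(memb.sum()))
            new.active[j] = False
            new.pis[j] = 0.0
            continue
        new.pis[j] = soft / n
        mu = np.empty(m)
        degenerate = False
        for l in range(m):
            wl = U[memb, l] * wj[memb]
            den = float(wl.sum())
            if den <= 0.0:
                degenerate = True
                break
            mu[l] = float(wl @ X[memb, l]) / den
        if degenerate:
            logger.warning("cluster %s absorbed (zero reliability mass)",
                           model.codes[j])
            new.active[j] = False
            new.pis[j] = 0.0
            continue
        if delimiters is not None:
            lo, hi = delimiters.bounds(model.codes[j])
            mu = np.clip(mu, lo, hi)
        sig = np.empty((m, m))
        for r in range(m):
            dr = X[:, r] - mu[r]
            for s in range(r, m):
                w = u_pair[r, s] * wj
                ds = X[:, s] - mu[s]
                sig[r, s] = sig[s, r] = float(w @ (dr * ds)) / float(w.sum())
        new.mus[j] = mu
        new.sigmas[j] = _floor_and_fix(sig, sigma_min)

    total = new.pis[new.active].sum()
    if total > 0:
        new.pis[new.active] /= total
    return new


# ---------------------------------------------------------------------------
# labelling helpers


def assign_labels(
    W: np.ndarray,
    model: MixtureModel,
    membership: np.ndarray | None = None,
) -> np.ndarray:
    """Most-probable cluster per point; posterior ties are broken first by
    region membership, then by the lexicographic code order."""
    Wa = np.where(model.active, W, -np.inf)
    top = Wa.max(axis=1, keepdims=True)
    tied = Wa >= top - 1e-12
    if membership is not None:
        pref = tied & membership
        use = pref.any(axis=1)
        tied[use] = pref[use]
    idx = np.argmax(tied, axis=1)  # first True = lowest code index
    return np.asarray(model.codes, dtype=object)[idx].astype(str)


def backfill_labels(labels_valid: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Spread labels onto invalid rows from the nearest preceding valid row
    (leading invalid rows take the first valid label)."""
    n = valid.shape[0]
    out = np.empty(n, dtype=object)
    out[valid] = labels_valid
    vi = np.flatnonzero(valid)
    if vi.size == 0:
        raise ValueError("no valid rows to label")
    pos = np.clip(np.searchsorted(vi, np.arange(n), side="right") - 1, 0, None)
    fill = ~valid
    out[fill] = out[vi[pos[fill]]]
    return out.astype(str)


# ---------------------------------------------------------------------------
# the fit loop


def _detect_cycle(trace: list[float], window: int, tol: float) -> bool:
    """Cycle: the current log-likelihood matches a value seen at least two
    iterations earlier within the window, with a decrease in between."""
    t = len(trace) - 1
    for j in range(max(0, t - window), t - 1):
        if abs(trace[t] - trace[j]) <= tol:
            seg = np.asarray(trace[j:t + 1])
            if np.any(np.diff(seg) < -tol):
                return True
    return False


def fit(fm: FeatureMatrix | np.ndarray, config: EMbCConfig | None = None
        ) -> ClusteringResult:
    """Run the EMbC on a feature matrix.

    Deterministic: the fit involves no random state, so identical inputs
    give identical outputs.
    """
    if not isinstance(fm, FeatureMatrix):
        fm = FeatureMatrix.from_array(fm)
    config = config or EMbCConfig()
    sigma_min = resolve_sigma_min(fm, config.sigma_min)

    valid = fm.valid
    Xv = fm.X[valid]
    Uv = fm.U[valid] if config.use_reliability else np.ones_like(fm.U[valid])
    n, m = Xv.shape
    k = 2**m
    if n < k:
        raise ValueError(f"need at least {k} valid points, got {n}")

    if np.all(np.ptp(Xv, axis=0) == 0.0):
        logger.warning("all points identical: single active cluster")
        code_list = binary.codes(m)
        model = MixtureModel(
            mus=np.tile(Xv[0], (k, 1)),
            sigmas=np.tile(np.diag(sigma_min**2), (k, 1, 1)),
            pis=np.r_[1.0, np.zeros(k - 1)],
            active=np.r_[True, np.zeros(k - 1, dtype=bool)],
            codes=code_list,
        )
        W = np.full((fm.n, k), np.nan)
        W[valid] = np.r_[1.0, np.zeros(k - 1)]
        labels = backfill_labels(
            np.full(n, code_list[0], dtype=object), valid)
        return ClusteringResult(model, DelimiterSet(m), W, labels,
                                [loglik(Xv, model)], "converged", 1)

    delims, model = init_max_entropy(Xv, sigma_min)
    trace: list[float] = []
    best_ll = -np.inf
    best_state: tuple[MixtureModel, DelimiterSet] | None = None
    status = "max_iter"
    prev_ll = None

    for _ in range(config.max_iter):
        W = estep(Xv, model)
        delims = compute_delimiters(Xv, model)
        memb = binary.region_membership(Xv, delims, model.codes,
                                        model.active, W)
        model = mstep_embc(Xv, W, Uv, memb, model, sigma_min,
                           delimiters=delims, absorb_tol=config.absorb_tol)
        ll = loglik(Xv, model)
        trace.append(ll)
        if ll > best_ll:
            best_ll = ll
            best_state = (model.copy(), DelimiterSet(m, dict(delims)))
        if prev_ll is not None and abs(ll - prev_ll) < config.delta:
            status = "converged"
            break
        if len(trace) >= 3 and _detect_cycle(trace, config.cycle_window,
                                             config.cycle_tol):
            logger.warning("cycle detected at iteration %d; returning the "
                           "best state seen", len(trace))
            status = "cycle_stop"
            model, delims = best_state
            break
        prev_ll = ll

    Wv = estep(Xv, model)
    delims = compute_delimiters(Xv, model)
    memb = binary.region_membership(Xv, delims, model.codes, model.active, Wv)
    labels_valid = assign_labels(Wv, model, memb)
    labels = backfill_labels(labels_valid, valid)
    W = np.full((fm.n, k), np.nan)
    W[valid] = Wv
    return ClusteringResult(model, delims, W, labels, trace, status,
                            model.n_active)


def fit_pooled(
    feature_sets: Sequence[FeatureMatrix],
    config: EMbCConfig | None = None,
) -> tuple[ClusteringResult, list[np.ndarray]]:
    """Population-level fit: one clustering on the stacked sets, labels
    split back per individual.  Per-individual tracks typically use only a
    subset of the population-level clusters."""
    if not feature_sets:
        raise ValueError("no feature sets given")
    names = feature_sets[0].variable_names
    for fm in feature_sets[1:]:
        if fm.variable_names != names:
            raise ValueError("feature sets have mismatched variables")
    stacked = FeatureMatrix(
        X=np.vstack([fm.X for fm in feature_sets]),
        variable_names=list(names),
        units=list(feature_sets[0].units),
        U=np.vstack([fm.U for fm in feature_sets]),
        tau=None,
        tau_mode=feature_sets[0].tau_mode,
        valid=np.concatenate([fm.valid for fm in feature_sets]),
    )
    result = fit(stacked, config)
    slices, start = [], 0
    for fm in feature_sets:
        slices.append(result.labels[start:start + fm.n])
        start += fm.n
    for i, lab in enumerate(slices):
        used = sorted(set(lab.tolist()))
        logger.info("individual %d uses clusters: %s", i, ",".join(used))
    return result, slices
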