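"""Synthetic labelled trajectories and degradation protocols.

The generator emulates the evaluation design used for the clustering
benchmarks: a 4-component bivariate Gaussian mixture on the unit square
with a tunable overlap parameter gamma (lower gamma = more blurred
clusters), a state sequence drawn either from a Markov transition matrix
or i.i.d. from the mixture prior, plus the two degradation operators used
in the robustness experiments (uniform data loss and gap-proportional
jittering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import binary
from .core import MixtureModel
from .features import FeatureMatrix, Trajectory, wrap_angle

logger = logging.getLogger("embc")


def _salted(seed, salt: int) -> list[int]:
    """Flatten an int or int-sequence seed and append a stream salt."""
    if np.isscalar(seed):
        return [int(seed), salt]
    return [int(s) for s in seed] + [salt]


@dataclass
class SyntheticConfig:
    """Generation parameters.

    gamma in (0, 0.25): cluster overlap; the component standard deviation
    is 0.8 * (0.25 - gamma), so gamma -> 0.25 is the perfectly separated
    limit.  scheme 'markov' draws states from ``transition`` (default:
    self-transition 0.85, uniform off-diagonal); 'prior' draws i.i.d. from
    ``prior`` (default uniform).
    """

    n: int = 400
    gamma: float = 0.05
    scheme: str = "markov"
    transition: np.ndarray | None = None
    prior: np.ndarray | None = None
    seed: int = 0
    m: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 0.25:
            raise ValueError("gamma must lie in (0, 0.25)")
        if self.scheme not in ("markov", "prior"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        k = 2**self.m
        if self.transition is not None:
            self.transition = np.asarray(self.transition, dtype=float)
            if self.transition.shape != (k, k) or np.any(self.transition < 0) \
                    or not np.allclose(self.transition.sum(axis=1), 1.0):
                raise ValueError("transition must be a row-stochastic k x k matrix")
        if self.prior is not None:
            self.prior = np.asarray(self.prior, dtype=float)
            if self.prior.shape != (k,) or np.any(self.prior < 0) \
                    or not np.isclose(self.prior.sum(), 1.0):
                raise ValueError("prior must be a length-k distribution")


@dataclass
class SyntheticDataset:
    """Feature matrix plus the generating ground truth."""

    features: FeatureMatrix
    states: np.ndarray            # (n,) component indices
    model: MixtureModel           # generating mixture
    config: SyntheticConfig

    @property
    def codes(self) -> list[str]:
        return self.model.codes

    @property
    def state_labels(self) -> np.ndarray:
        """Ground-truth states as binary codes."""
        return np.asarray(self.codes, dtype=object)[self.states].astype(str)


def default_transition(k: int = 4, self_prob: float = 0.85) -> np.ndarray:
    """Self-transition ``self_prob``, remaining mass uniform off-diagonal."""
    off = (1.0 - self_prob) / (k - 1)
    T = np.full((k, k), off)
    np.fill_diagonal(T, self_prob)
    return T


def gmm_layout(gamma: float, m: int = 2) -> MixtureModel:
    """2^m components on the unit hypercube: per variable the L mean is
    0.25 and the H mean 0.75, isotropic sigma = 0.8 * (0.25 - gamma),
    uniform mixing weights."""
    if not 0.0 < gamma < 0.25:
        raise ValueError("gamma must lie in (0, 0.25)")
    code_list = binary.codes(m)
    k = len(code_list)
    mus = np.array([[0.25 if c == binary.L else 0.75 for c in code]
                    for code in code_list])
    sigma = 0.8 * (0.25 - gamma)
    return MixtureModel(
        mus=mus,
        sigmas=np.tile(np.eye(m) * sigma**2, (k, 1, 1)),
        pis=np.full(k, 1.0 / k),
        active=np.ones(k, dtype=bool),
        codes=code_list,
    )


def sample_states(config: SyntheticConfig) -> np.ndarray:
    """State sequence under the configured scheme; reproducible under seed."""
    k = 2**config.m
    rng = np.random.default_rng(_salted(config.seed, 0))
    if config.scheme == "prior":
        prior = config.prior if config.prior is not None else np.full(k, 1.0 / k)
        return rng.choice(k, size=config.n, p=prior)
    T = config.transition if config.transition is not None else default_transition(k)
    states = np.empty(config.n, dtype=int)
    states[0] = rng.integers(k)
    for i in range(1, config.n):
        states[i] = rng.choice(k, p=T[states[i - 1]])
    return states


def emit_features(states: np.ndarray, model: MixtureModel,
                  seed: int | list = 0) -> FeatureMatrix:
    """Draw row i from component states[i]; values clipped to [0, 1]."""
    rng = np.random.default_rng(seed)
    n = states.shape[0]
    m = model.m
    chol = np.linalg.cholesky(model.sigmas)
    eps = rng.standard_normal((n, m))
    X = model.mus[states] + np.einsum("nij,nj->ni", chol[states], eps)
    np.clip(X, 0.0, 1.0, out=X)
    return FeatureMatrix(
        X=X,
        variable_names=["velocity", "turn"][:m] if m == 2
        else [f"x{l + 1}" for l in range(m)],
        units=[""] * m,
        tau=np.ones(n),
        tau_mode=1.0,
    )


def simulate(config: SyntheticConfig | None = None, **kwargs) -> SyntheticDataset:
    """Generate a labelled synthetic dataset; ``kwargs`` override config
    fields (e.g. ``simulate(n=400, gamma=0.05, seed=7)``)."""
    config = replace(config or SyntheticConfig(), **kwargs)
    model = gmm_layout(config.gamma, config.m)
    states = sample_states(config)
    fm = emit_features(states, model, seed=_salted(config.seed, 1))
    return SyntheticDataset(features=fm, states=states, model=model,
                            config=config)


def to_trajectory(dataset: SyntheticDataset, dt: float = 1.0,
                  v_scale: float = 1.0, seed: int | None = None) -> Trajectory:
    """Integrate the (velocity, turn) feature rows into a planar track.

    Step i has length velocity_i * v_scale * dt; the heading turns by
    +/- turn_i (random sign per step).  Re-deriving features from the
    trajectory recovers the inputs on interior points.
    """
    if dataset.features.m != 2:
        raise ValueError("trajectory integration needs (velocity, turn) features")
    v = dataset.features.X[:, 0] * v_scale
    turn = dataset.features.X[:, 1]
    n = v.shape[0]
    rng = np.random.default_rng(
        _salted(dataset.config.seed, 2) if seed is None else seed)
    signs = rng.choice([-1.0, 1.0], size=n)
    headings = np.concatenate([[0.0], np.cumsum(signs[1:] * turn[1:])])
    steps = (v * dt)[:, None] * np.column_stack(
        [np.cos(headings), np.sin(headings)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    t = np.arange(n + 1) * dt
    return Trajectory(t=t, xy=xy, geometry="planar",
                      id=f"synthetic-{dataset.config.seed}")


def degrade_loss(X: np.ndarray, k_dl: float, seed: int | list = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random data loss: point i kept iff p_i >= k_dl with
    p_i ~ U(0, 1), so the kept count is Binomial(n, 1 - k_dl)."""
    if not 0.0 <= k_dl <= 1.0:
        raise ValueError("k_dl must lie in [0, 1]")
    X = np.asarray(X)
    rng = np.random.default_rng(seed)
    kept = np.flatnonzero(rng.uniform(size=X.shape[0]) >= k_dl)
    return X[kept], kept


def degrade_jitter(X: np.ndarray, tau: np.ndarray, tau_mode: float,
                   k_di: float, seed: int | list = 0) -> np.ndarray:
    """Gap-proportional jitter emulating estimation inaccuracy.

    Each value is redrawn uniformly on x_i +/- Delta_i clamped to the
    variable's global range, with per-variable radius
    Delta_i^(l) = k_di * max(X^(l)) * max(0, (tau_i - tau~) / tau~);
    points at the nominal interval (tau_i <= tau~) are left untouched.
    """
    if not 0.0 < k_di < 1.0:
        raise ValueError("k_di must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if tau_mode <= 0 or np.any(tau <= 0):
        raise ValueError("intervals must be positive")
    rng = np.random.default_rng(seed)
    rel = np.maximum(0.0, (tau - tau_mode) / tau_mode)
    delta = k_di * X.max(axis=0) * rel[:, None]
    lo = np.maximum(X.min(axis=0), X - delta)
    hi = np.minimum(X.max(axis=0), X + delta)
    out = lo + rng.uniform(size=X.shape) * (hi - lo)
    return np.where(delta > 0, out, X)
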