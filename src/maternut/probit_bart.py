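"""Probit Bayesian Additive Regression Trees, implemented from scratch.

The model for a binary outcome is

    P(Y = 1 | x) = Phi( sum_{j=1}^{m} g(x; T_j, M_j) )

where each ``g`` is a shallow decision tree with structure ``T_j`` and
leaf values ``M_j``, and ``Phi`` is the standard normal CDF.  Fitting
uses Albert-Chib latent augmentation: a latent z_i ~ Normal(eta_i, 1)
truncated to the positive half-line when y_i = 1 and the non-positive
half-line otherwise, which makes every leaf conditional conjugate
normal.  Tree structures move by Metropolis-Hastings grow / prune /
change proposals under the canonical regularisation prior
``p(split at depth d) = alpha (1 + d)^(-beta)``; leaf values carry a
Normal(0, (3 / (k sqrt(m)))^2) prior on the probit scale.

Each sweep performs Bayesian backfitting: every tree is updated against
the partial residuals of the latents with the other m - 1 trees held
fixed, its leaf values are redrawn from their conjugate conditionals,
and finally all latents are redrawn.  Prediction matrices supplied at
fit time are tracked incrementally during sampling, so posterior
predictive draws for counterfactual designs cost almost nothing extra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

_EPS = 1e-12


@dataclass
class BartConfig:
    """Sampler configuration with the canonical regularisation defaults."""

    num_trees: int = 200
    burn_in: int = 1000
    num_draws: int = 1000
    alpha: float = 0.95          # depth prior: p_split(d) = alpha (1+d)^-beta
    beta: float = 2.0
    k: float = 2.0               # leaf prior sd = 3 / (k sqrt(m))
    p_grow: float = 0.28
    p_prune: float = 0.28
    p_change: float = 0.44
    seed: int = 0
    keep_states: bool = True     # retain tree states for post-hoc prediction

    def __post_init__(self) -> None:
        if self.num_trees < 1:
            raise ValueError("num_trees must be >= 1")
        if self.burn_in < 0 or self.num_draws < 1:
            raise ValueError("burn_in must be >= 0 and num_draws >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        total = self.p_grow + self.p_prune + self.p_change
        if total <= 0:
            raise ValueError("proposal probabilities must sum to > 0")


def tree_traverse(tree: dict[str, np.ndarray], x: Sequence[float]) -> float:
    """Leaf value reached by one covariate vector (``x[var] < c`` goes left).

    A tree is a dict of parallel node arrays ``var``, ``thresh``,
    ``left``, ``right``, ``mu``; ``left[i] < 0`` marks node ``i`` as a
    leaf.  This flat format is exactly what retained posterior states
    store.
    """
    x = np.asarray(x, dtype=float)
    i = 0
    while tree["left"][i] >= 0:
        v = tree["var"][i]
        if np.isnan(x[v]):
            raise ValueError(f"missing value at split variable {v}")
        i = tree["left"][i] if x[v] < tree["thresh"][i] else tree["right"][i]
    return float(tree["mu"][i])


def _tree_predict(tree: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    """Vectorised leaf values for every row of ``X``."""
    n = X.shape[0]
    out = np.empty(n)
    stack = [(0, np.arange(n))]
    left, right, var, thresh, mu = (tree["left"], tree["right"], tree["var"],
                                    tree["thresh"], tree["mu"])
    while stack:
        i, rows = stack.pop()
        if left[i] < 0:
            out[rows] = mu[i]
            continue
        go_left = X[rows, var[i]] < thresh[i]
        stack.append((left[i], rows[go_left]))
        stack.append((right[i], rows[~go_left]))
    return out


def validate_tree(tree: dict[str, np.ndarray], n_vars: int) -> None:
    """Structural audit of one flat tree; raises on an invalid state.

    Checks reachable-node structure: every internal node has two
    children, every reachable leaf has a finite value, and decision
    rules reference valid variable indices.  (Pruned slots are allowed
    to linger in the arrays; they must simply be unreachable.)
    """
    left, right, var, mu = (tree["left"], tree["right"], tree["var"],
                            tree["mu"])
    stack = [0]
    while stack:
        i = stack.pop()
        if left[i] < 0:
            if right[i] >= 0:
                raise ValueError(f"leaf {i} has a right child")
            if not np.isfinite(mu[i]):
                raise ValueError(f"leaf {i} has non-finite value")
        else:
            if right[i] < 0:
                raise ValueError(f"internal node {i} lacks a right child")
            if not 0 <= var[i] < n_vars:
                raise ValueError(f"node {i} splits on invalid variable "
                                 f"{var[i]}")
            stack.append(int(left[i]))
            stack.append(int(right[i]))


def sample_latent(y: np.ndarray, eta: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Albert-Chib latent draw: Normal(eta, 1) truncated by the outcome sign.

    ``z > 0`` when ``y = 1`` and ``z <= 0`` when ``y = 0``, drawn by
    inverse-CDF so a single uniform stream drives the whole vector.
    """
    y = np.asarray(y)
    eta = np.asarray(eta, dtype=float)
    u = rng.random(eta.shape)
    tail = ndtr(-eta)                       # P(standard normal > -(-eta)) etc.
    # y=1: eps | eps > -eta ; y=0: eps | eps <= -eta
    q = np.where(y == 1, tail + u * (1.0 - tail), u * tail)
    q = np.clip(q, _EPS, 1.0 - _EPS)
    return eta + ndtri(q)


@dataclass
class BartPosterior:
    """Retained post-burn-in states of the probit sum-of-trees model.

    ``states`` is empty when the sampler ran with ``keep_states=False``;
    tracked prediction matrices supplied at fit time are then the only
    source of posterior draws.
    """

    config: BartConfig
    columns: list[str] | None
    offset: float
    states: list[list[dict[str, np.ndarray]]]
    tracked_draws: dict[str, np.ndarray] = field(default_factory=dict)
    train_draws: np.ndarray | None = None


class _Sampler:
    """Driver for the compiled backfitting kernel.

    Holds the ensemble in flat arrays (one row per tree), calls the
    kernel one sweep at a time, and snapshots retained states between
    calls.  A single internal PRNG stream is seeded once per fit from
    the master seed, so a fixed seed reproduces the chain exactly.
    """

    MAX_NODES_CAP = 4096

    def __init__(self, X: np.ndarray, y: np.ndarray, config: BartConfig,
                 tracked: dict[str, np.ndarray]):
        from maternut import _bart_kernel as K
        self.K = K
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.ascontiguousarray(y, dtype=np.int8)
        self.cfg = config
        n, p = X.shape
        self.n = n
        m = config.num_trees
        self.sigma_mu2 = (3.0 / (config.k * math.sqrt(m))) ** 2
        # split candidates: distinct observed values, minimum dropped
        # (a cut at the minimum can never send anything left)
        cand = [np.unique(self.X[:, j])[1:] for j in range(p)]
        self.usable_vars = np.array([j for j in range(p) if len(cand[j])],
                                    dtype=np.int64)
        self.candvals = (np.concatenate([c for c in cand if len(c)])
                         if len(self.usable_vars) else np.zeros(0))
        starts = np.zeros(p + 1, dtype=np.int64)
        for j in range(p):
            starts[j + 1] = starts[j] + len(cand[j])
        self.candstart = starts
        prevalence = float(np.clip(y.mean(), 1.0 / (n + 1), n / (n + 1.0)))
        self.offset = float(ndtri(prevalence))
        # ensemble arrays; each sweep can add at most 2 nodes per tree
        sweeps = config.burn_in + config.num_draws
        self.maxn = int(min(self.MAX_NODES_CAP, 2 * sweeps + 8))
        self.var = np.full((m, self.maxn), -1, dtype=np.int64)
        self.thresh = np.zeros((m, self.maxn))
        self.left = np.full((m, self.maxn), -1, dtype=np.int64)
        self.right = np.full((m, self.maxn), -1, dtype=np.int64)
        self.depth = np.zeros((m, self.maxn), dtype=np.int64)
        self.mu = np.zeros((m, self.maxn))
        self.n_nodes = np.ones(m, dtype=np.int64)
        self.assign = np.zeros((m, n), dtype=np.int32)
        # tracked matrices are stacked into one block; per-name slices
        # recover the individual draw matrices afterwards
        self.tracked_slices: dict[str, slice] = {}
        mats = []
        offset_rows = 0
        for name, M in tracked.items():
            mats.append(np.ascontiguousarray(M, dtype=float))
            self.tracked_slices[name] = slice(offset_rows,
                                              offset_rows + len(M))
            offset_rows += len(M)
        self.Xt = (np.concatenate(mats, axis=0) if mats
                   else np.zeros((0, p)))
        nt = self.Xt.shape[0]
        self.t_assign = np.zeros((m, nt), dtype=np.int32)
        self.t_old = np.zeros((m, nt))
        self.t_fit = np.full(nt, self.offset)
        self.total_fit = np.full(n, self.offset)
        self.z = np.zeros(n)
        K.set_seed(config.seed % (2 ** 32))
        # initial latents from the prior fit (offset only)
        self.step(latents_only=True)

    def step(self, latents_only: bool = False) -> None:
        """One backfitting sweep (or just a latent redraw)."""
        if latents_only:
            # run the kernel with zero trees by passing empty ensemble
            self.K.one_sweep(
                self.X, self.y, self.z, self.total_fit,
                self.var[:0], self.thresh[:0], self.left[:0],
                self.right[:0], self.depth[:0], self.mu[:0],
                self.n_nodes[:0], self.assign[:0], self.Xt,
                self.t_assign[:0], self.t_old[:0], self.t_fit,
                self.candvals, self.candstart, self.usable_vars,
                self.sigma_mu2, self.cfg.alpha, self.cfg.beta,
                self.p_grow, self.p_prune)
            return
        self.K.one_sweep(
            self.X, self.y, self.z, self.total_fit,
            self.var, self.thresh, self.left, self.right, self.depth,
            self.mu, self.n_nodes, self.assign, self.Xt,
            self.t_assign, self.t_old, self.t_fit,
            self.candvals, self.candstart, self.usable_vars,
            self.sigma_mu2, self.cfg.alpha, self.cfg.beta,
            self.p_grow, self.p_prune)

    @property
    def p_grow(self) -> float:
        c = self.cfg
        return c.p_grow / (c.p_grow + c.p_prune + c.p_change)

    @property
    def p_prune(self) -> float:
        c = self.cfg
        return c.p_prune / (c.p_grow + c.p_prune + c.p_change)

    def snapshot(self) -> list[dict[str, np.ndarray]]:
        out = []
        for j in range(self.cfg.num_trees):
            nn = self.n_nodes[j]
            out.append({"var": self.var[j, :nn].copy(),
                        "thresh": self.thresh[j, :nn].copy(),
                        "left": self.left[j, :nn].copy(),
                        "right": self.right[j, :nn].copy(),
                        "mu": self.mu[j, :nn].copy()})
        return out

    def run(self) -> BartPosterior:
        cfg = self.cfg
        states: list[list[dict[str, np.ndarray]]] = []
        tracked_draws = {name: np.empty((cfg.num_draws, sl.stop - sl.start))
                         for name, sl in self.tracked_slices.items()}
        train_draws = np.empty((cfg.num_draws, self.n))
        for it in range(cfg.burn_in + cfg.num_draws):
            self.step()
            s = it - cfg.burn_in
            if s >= 0:
                if cfg.keep_states:
                    states.append(self.snapshot())
                for name, sl in self.tracked_slices.items():
                    tracked_draws[name][s] = self.t_fit[sl]
                train_draws[s] = self.total_fit
        return BartPosterior(config=cfg, columns=None, offset=self.offset,
                             states=states, tracked_draws=tracked_draws,
                             train_draws=train_draws)


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def fit_probit_bart(X, y, config: BartConfig | None = None,
                    tracked: dict[str, "pd.DataFrame | np.ndarray"] | None = None
                    ) -> BartPosterior:
    """Fit the probit sum-of-trees model by MCMC.

    Parameters
    ----------
    X : DataFrame or array, shape (N, K)
        Covariates including the treatment column; no missing values,
        categoricals pre-encoded.
    y : binary vector of length N.
    config : sampler settings; canonical defaults when omitted.
    tracked : optional named prediction matrices (same column schema as
        ``X``).  Their probit-scale posterior draws are accumulated during
        sampling and stored in ``BartPosterior.tracked_draws`` — exactly
        what :func:`predict_probit_draws` would return, at a fraction of
        the cost.

    Deterministic for a fixed ``config.seed``.
    """
    config = config or BartConfig()
    Xm, columns = _as_matrix(X)
    yv = np.asarray(y)
    if Xm.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(yv) != Xm.shape[0]:
        raise ValueError("X and y lengths differ")
    if Xm.shape[0] < 10:
        raise ValueError("need at least 10 observations")
    if not np.isin(yv, (0, 1)).all():
        raise ValueError("y must be binary 0/1")
    if np.isnan(Xm).any():
        raise ValueError("X contains missing values")
    tracked_mats: dict[str, np.ndarray] = {}
    for name, M in (tracked or {}).items():
        Mm, cols = _as_matrix(M)
        if cols is not None and columns is not None and cols != columns:
            raise ValueError(f"tracked matrix {name!r} schema mismatch")
        if Mm.shape[1] != Xm.shape[1]:
            raise ValueError(f"tracked matrix {name!r} has wrong width")
        tracked_mats[name] = Mm
    sampler = _Sampler(Xm, yv.astype(np.int8), config, tracked_mats)
    post = sampler.run()
    post.columns = columns
    return post


def predict_probit_draws(post: BartPosterior, X_new) -> np.ndarray:
    """Posterior predictive draws on the probit scale, (num_draws, n_new).

    Entry (s, i) is offset + sum over trees of the leaf value row i
    reaches in retained state s.  Requires ``keep_states=True`` at fit
    time.
    """
    if not post.states:
        raise ValueError("posterior was fitted with keep_states=False; "
                         "supply the matrix via `tracked` at fit time instead")
    Xm, cols = _as_matrix(X_new)
    if post.columns is not None and cols is not None and cols != post.columns:
        raise ValueError("X_new schema does not match training schema")
    draws = np.empty((len(post.states), Xm.shape[0]))
    for s, trees in enumerate(post.states):
        acc = np.full(Xm.shape[0], post.offset)
        for tree in trees:
            acc += _tree_predict(tree, Xm)
        draws[s] = acc
    return draws


def posterior_mean_probability(draws: np.ndarray) -> np.ndarray:
    """Per-observation mean of Phi(draw) over posterior draws."""
    return ndtr(draws).mean(axis=0)
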