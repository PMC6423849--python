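"""Maximum-likelihood estimation of the CHMM by EM (Baum-Welch style).

The E-step is the forward-backward decoding from :mod:`replis.model`; the
M-step has closed forms for the initial law, the transition matrix and the
two alternative-emission moments:

* ``pi  <- gamma[0]``
* ``A_uv <- sum_j xi_j(u,v) / sum_j gamma_j(u)``   (j = 1..m-1)
* ``mu_i    <- sum_j z_ij p_ij / sum_j p_ij``
* ``sigma_i^2 <- sum_j (z_ij - mu_i)^2 p_ij / sum_j p_ij``

where ``p_ij = P(H_ij = 1 | Z)`` is the posterior mass of the states with
bit ``i`` set.  Null emissions stay fixed at N(0,1); only the alternative
components are estimated.

An independence-restricted variant (all rows of A constrained equal to the
state frequencies) is available via ``em_fit(..., independence=True)``; it
is the exact EM for the site-wise i.i.d. four-group mixture model and serves
as a chain-free baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    ChmmParams,
    JointStateSpace,
    ZMatrix,
    _estep_kernel,
    emission_matrix,
)

__all__ = ["EmConfig", "EmTrace", "initialize_params", "em_update", "em_fit"]

logger = logging.getLogger(__name__)


@dataclass
class EmConfig:
    """EM controls.

    tol is the relative change of the log-likelihood between successive
    iterations below which the fit is declared converged.  With
    ``mean_sign_constraint`` the alternative means are clipped at zero,
    which pins the alternative component to the right of the null (the
    one-sided p-to-z transform makes true signals right-shifted) and
    prevents null/alternative label switching.  ``n_restarts`` is the total
    number of EM runs: the first uses ``init_strategy``, the rest use
    seed-jittered random starts, and the run with the best final
    log-likelihood wins.
    """

    max_iter: int = 500
    tol: float = 1e-6
    init_strategy: str = "fixed"
    n_restarts: int = 1
    seed: int = 0
    min_sigma: float = 1e-3
    mean_sign_constraint: bool = True

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.min_sigma <= 0:
            raise ValueError("min_sigma must be positive")
        if self.init_strategy not in ("fixed", "moment", "random"):
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")
        if self.n_restarts < 0:
            raise ValueError("n_restarts must be non-negative")


@dataclass
class EmTrace:
    """Fit trace: per-iteration log-likelihoods and the final parameters."""

    loglik_per_iter: np.ndarray
    n_iter: int
    converged: bool
    final_params: ChmmParams

    @property
    def loglik(self) -> float:
        return float(self.loglik_per_iter[-1])


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _fixed_init(D: int) -> ChmmParams:
    S = 2 ** D
    pi = np.full(S, 1.0 / S)
    A = np.full((S, S), 0.3 / (S - 1))
    np.fill_diagonal(A, 0.7)
    return ChmmParams(pi, A, np.full(D, 2.0), np.ones(D))


def initialize_params(zmat: ZMatrix, config: EmConfig) -> ChmmParams:
    """Starting parameters for EM.

    fixed:  pi uniform, A with 0.7 diagonal / uniform off-diagonal,
            mu_i = 2, sigma_i = 1.
    moment: as fixed, but mu_i = mean of the upper quartile of study-i
            z-values (a crude location estimate of the alternative).
    random: the fixed values jittered deterministically from ``seed``.
    """
    if zmat.m < 2:
        raise ValueError("at least two sites are required to initialise EM")
    D = zmat.num_studies
    params = _fixed_init(D)
    if config.init_strategy == "moment":
        q3 = np.quantile(zmat.z, 0.75, axis=0)
        mu = np.array(
            [zmat.z[zmat.z[:, i] >= q3[i], i].mean() for i in range(D)]
        )
        params.alt_means = mu
    elif config.init_strategy == "random":
        rng = np.random.default_rng(config.seed)
        S = params.n_states
        pi = params.pi * np.exp(rng.uniform(-0.3, 0.3, S))
        params.pi = pi / pi.sum()
        A = params.A * np.exp(rng.uniform(-0.3, 0.3, (S, S)))
        params.A = A / A.sum(axis=1, keepdims=True)
        params.alt_means = params.alt_means + rng.uniform(-0.5, 0.5, D)
        params.alt_sds = params.alt_sds * np.exp(rng.uniform(-0.2, 0.2, D))
    params.validate()
    return params


# ---------------------------------------------------------------------------
# one EM step
# ---------------------------------------------------------------------------

def _mstep(
    z: np.ndarray,
    bits: np.ndarray,
    gamma: np.ndarray,
    xi_sum: np.ndarray,
    min_sigma: float,
    mean_sign_constraint: bool,
    independence: bool,
) -> ChmmParams:
    S = gamma.shape[1]
    D = bits.shape[1]
    if independence:
        w = gamma.mean(axis=0)
        pi = w / w.sum()
        A = np.tile(pi, (S, 1))
    else:
        pi = gamma[0] / gamma[0].sum()
        denom = gamma[:-1].sum(axis=0)
        A = np.empty((S, S))
        for u in range(S):
            if denom[u] <= 0:
                logger.warning(
                    "state %d has zero posterior mass; transition row set uniform", u
                )
                A[u] = 1.0 / S
            else:
                A[u] = xi_sum[u] / denom[u]
        A = np.clip(A, 0.0, None)
        A /= A.sum(axis=1, keepdims=True)
    mu = np.empty(D)
    sd = np.empty(D)
    for i in range(D):
        p_i = gamma[:, bits[:, i] == 1].sum(axis=1)
        tot = p_i.sum()
        if tot <= 0:
            logger.warning("study %d has zero alternative mass; keeping mu=0", i)
            mu[i], sd[i] = 0.0, 1.0
            continue
        mu[i] = float(np.dot(z[:, i], p_i) / tot)
        if mean_sign_constraint and mu[i] < 0:
            mu[i] = 0.0
        sd[i] = float(np.sqrt(np.dot((z[:, i] - mu[i]) ** 2, p_i) / tot))
        if sd[i] < min_sigma:
            sd[i] = min_sigma
    return ChmmParams(pi, A, mu, sd)


def em_update(
    zmat: ZMatrix,
    params: ChmmParams,
    min_sigma: float = 1e-3,
    mean_sign_constraint: bool = True,
    independence: bool = False,
) -> ChmmParams:
    """One full E+M step from ``params``; EM guarantees the observed-data
    log-likelihood does not decrease."""
    space = JointStateSpace(params.num_studies)
    B = emission_matrix(zmat, params, space)
    gamma, xi_sum, _, bad = _estep_kernel(B, params.pi, params.A)
    if bad >= 0:
        raise FloatingPointError(f"E-step underflow at site {bad}")
    return _mstep(
        zmat.z, space.bits, gamma, xi_sum, min_sigma, mean_sign_constraint, independence
    )


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------

def _em_run(
    zmat: ZMatrix, init: ChmmParams, config: EmConfig, independence: bool
) -> EmTrace:
    space = JointStateSpace(init.num_studies)
    bits = space.bits
    params = init.copy()
    logliks = []
    converged = False
    prev_ll = None
    n_iter = 0
    for t in range(config.max_iter + 1):
        B = emission_matrix(zmat, params, space)
        gamma, xi_sum, ll, bad = _estep_kernel(B, params.pi, params.A)
        if bad >= 0 or not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite log-likelihood at EM iteration {t}"
            )
        logliks.append(ll)
        if prev_ll is not None:
            rel = abs(ll - prev_ll) / max(1.0, abs(prev_ll))
            if rel < config.tol:
                converged = True
                break
        prev_ll = ll
        if t == config.max_iter:
            break
        params = _mstep(
            zmat.z,
            bits,
            gamma,
            xi_sum,
            config.min_sigma,
            config.mean_sign_constraint,
            independence,
        )
        n_iter = t + 1
    return EmTrace(
        loglik_per_iter=np.array(logliks),
        n_iter=n_iter,
        converged=converged,
        final_params=params,
    )


def em_fit(
    zmat: ZMatrix, config: Optional[EmConfig] = None, independence: bool = False
) -> EmTrace:
    """Fit the CHMM by EM, with optional random restarts.

    With ``independence=True`` every transition row is constrained equal to
    the state frequencies, i.e. the joint states are fitted as i.i.d.
    draws from a four-group mixture (the chain-free baseline).
    """
    if config is None:
        config = EmConfig()
    if zmat.m < 2:
        raise ValueError("EM requires at least two sites")
    n_runs = max(1, config.n_restarts)
    best: Optional[EmTrace] = None
    for k in range(n_runs):
        if k == 0:
            init = initialize_params(zmat, config)
        else:
            jitter_cfg = EmConfig(
                max_iter=config.max_iter,
                tol=config.tol,
                init_strategy="random",
                n_restarts=1,
                seed=config.seed + k,
                min_sigma=config.min_sigma,
                mean_sign_constraint=config.mean_sign_constraint,
            )
            init = initialize_params(zmat, jitter_cfg)
        trace = _em_run(zmat, init, config, independence)
        if best is None or trace.loglik > best.loglik:
            best = trace
    assert best is not None
    return best
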