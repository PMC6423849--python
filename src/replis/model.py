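"""Cartesian hidden Markov model (CHMM) for replicability analysis.

Two (or more) association studies test the same ``m`` genomic sites.  The
latent state of site ``j`` is the joint hypothesis vector
``(H_1j, ..., H_Dj)`` where ``H_ij = 1`` means site ``j`` carries a signal in
study ``i``.  The joint states follow a stationary Markov chain over the
Cartesian product state space (``2**D`` states), capturing the local
dependence of neighbouring SNPs, while the observed z-values are
conditionally independent across studies given the states:

* null emission:        ``z_ij | H_ij = 0  ~  N(0, 1)``
* alternative emission: ``z_ij | H_ij = 1  ~  N(mu_i, sigma_i**2)``

The *no-replicability null* at site ``j`` holds when the signal is present in
at most one study; for two studies that is the state set
``{(0,0), (1,0), (0,1)}``.  The repLIS statistic is the posterior
probability of this null given all z-values in all studies, computed exactly
by the (scaled) forward-backward algorithm.

The module also ships a brute-force enumeration oracle
(:func:`brute_force_posteriors`) that sums the joint distribution over all
``(2**D)**m`` state sequences; it exists to validate the recursions and is
only usable for small ``m``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.stats import norm

__all__ = [
    "JointStateSpace",
    "ChmmParams",
    "ZMatrix",
    "PosteriorResult",
    "UnderflowError",
    "emission_density",
    "emission_matrix",
    "forward_pass",
    "backward_pass",
    "posteriors",
    "brute_force_posteriors",
]


class UnderflowError(FloatingPointError):
    """All state probabilities vanished at some site during a recursion."""

    def __init__(self, site: int):
        self.site = site
        super().__init__(f"forward-backward underflow at site index {site}")


# ---------------------------------------------------------------------------
# state space
# ---------------------------------------------------------------------------

def _canonical_states(num_studies: int) -> tuple:
    """Binary D-tuples in canonical order: study 1 varies fastest.

    For D=2 this is (0,0), (1,0), (0,1), (1,1); the integer index of a state
    is ``sum_i bit_i * 2**i`` with ``i`` the zero-based study index.
    """
    states = []
    for u in range(2 ** num_studies):
        states.append(tuple((u >> i) & 1 for i in range(num_studies)))
    return tuple(states)


@dataclass(frozen=True)
class JointStateSpace:
    """Ordered joint hypothesis states for D studies and the null subset.

    The default null subset is every state except the all-ones state, i.e.
    "signal in at most D-1 studies".  For D=2 this is exactly the
    no-replicability null {(0,0),(1,0),(0,1)}.  For D>2 other partial
    conjunction nulls can be supplied explicitly via ``null_states``.
    """

    num_studies: int = 2
    states: tuple = field(default=None)  # type: ignore[assignment]
    null_states: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.num_studies < 2:
            raise ValueError("at least two studies are required")
        if self.states is None:
            object.__setattr__(self, "states", _canonical_states(self.num_studies))
        if self.null_states is None:
            full = tuple([1] * self.num_studies)
            object.__setattr__(
                self, "null_states", frozenset(s for s in self.states if s != full)
            )
        expected = set(_canonical_states(self.num_studies))
        if set(self.states) != expected or len(self.states) != len(expected):
            raise ValueError("states must contain every binary D-tuple exactly once")
        if not self.null_states:
            raise ValueError("null_states must be non-empty")
        if tuple([1] * self.num_studies) in self.null_states:
            raise ValueError("the all-ones state cannot belong to the null")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def bits(self) -> np.ndarray:
        """(n_states, D) 0/1 array, row u = state u."""
        return np.array(self.states, dtype=np.int64)

    @property
    def null_indices(self) -> np.ndarray:
        return np.array(
            [k for k, s in enumerate(self.states) if s in self.null_states],
            dtype=np.int64,
        )

    @property
    def full_index(self) -> int:
        """Index of the all-ones (replicated-signal) state."""
        return self.states.index(tuple([1] * self.num_studies))


# ---------------------------------------------------------------------------
# parameters and data containers
# ---------------------------------------------------------------------------

_PROB_ATOL = 1e-12


@dataclass
class ChmmParams:
    """CHMM parameters: initial law pi, transition matrix A, alternative
    emission moments per study.  Null emissions are fixed at N(0,1)."""

    pi: np.ndarray
    A: np.ndarray
    alt_means: np.ndarray
    alt_sds: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.alt_means = np.atleast_1d(np.asarray(self.alt_means, dtype=float))
        self.alt_sds = np.atleast_1d(np.asarray(self.alt_sds, dtype=float))
        self.validate()

    @property
    def num_studies(self) -> int:
        return self.alt_means.size

    @property
    def n_states(self) -> int:
        return self.pi.size

    def validate(self) -> None:
        S = self.pi.size
        D = self.alt_means.size
        if S != 2 ** D:
            raise ValueError(f"pi has length {S}, expected 2**{D}")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > _PROB_ATOL:
            raise ValueError("pi must be a probability vector (sum 1 within 1e-12)")
        if self.A.shape != (S, S):
            raise ValueError(f"A must be {S}x{S}")
        if np.any(self.A < 0) or np.any(np.abs(self.A.sum(axis=1) - 1.0) > _PROB_ATOL):
            raise ValueError("every row of A must be a probability vector")
        if self.alt_sds.size != D:
            raise ValueError("alt_means and alt_sds must have equal length")
        if np.any(self.alt_sds <= 0):
            raise ValueError("alt_sds must be strictly positive")

    def copy(self) -> "ChmmParams":
        return ChmmParams(
            self.pi.copy(), self.A.copy(), self.alt_means.copy(), self.alt_sds.copy()
        )


@dataclass
class ZMatrix:
    """m x D matrix of z-values with optional site annotations."""

    z: np.ndarray
    site_ids: Optional[np.ndarray] = None
    chrom: Optional[np.ndarray] = None
    pos: Optional[np.ndarray] = None

    def __post_init__(self):
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.z.ndim != 2:
            raise ValueError("z must be a 2-d array (sites x studies)")
        if self.z.shape[0] < 1:
            raise ValueError("at least one site is required")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z-values must be finite; transform p-values first")
        for name in ("site_ids", "chrom", "pos"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if val.shape[0] != self.z.shape[0]:
                    raise ValueError(f"{name} must have one entry per site")
                setattr(self, name, val)

    @property
    def m(self) -> int:
        return self.z.shape[0]

    @property
    def num_studies(self) -> int:
        return self.z.shape[1]


@dataclass
class PosteriorResult:
    """Forward-backward output: scaled alpha/beta, marginal and pairwise
    posteriors, log-likelihood and the repLIS vector.

    ``forward[j]`` is alpha_j normalised to sum to 1; ``scale[j]`` holds the
    per-site normalisers so that ``loglik = sum(log(scale))`` and the
    unscaled alpha_j is ``forward[j] * prod(scale[:j+1])``.  ``backward``
    shares the same convention (``backward[j] * prod(scale[j+1:])`` is the
    unscaled beta_j).
    """

    forward: np.ndarray
    backward: np.ndarray
    scale: np.ndarray
    gamma: np.ndarray
    xi: np.ndarray
    loglik: float
    replis: np.ndarray
    space: JointStateSpace


# ---------------------------------------------------------------------------
# emission densities
# ---------------------------------------------------------------------------

def emission_density(z, study: int, state_bit: int, params: ChmmParams):
    """Density of z in ``study`` under the null (state_bit=0, standard
    normal) or the alternative (state_bit=1, N(mu_i, sigma_i^2))."""
    if not 0 <= study < params.num_studies:
        raise ValueError(f"study index {study} out of range")
    if state_bit == 0:
        return norm.pdf(z)
    if state_bit == 1:
        return norm.pdf(z, loc=params.alt_means[study], scale=params.alt_sds[study])
    raise ValueError("state_bit must be 0 or 1")


_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _normal_pdf(z: np.ndarray, mu: float, sd: float) -> np.ndarray:
    t = (z - mu) / sd
    return _INV_SQRT_2PI / sd * np.exp(-0.5 * t * t)


def emission_matrix(
    zmat: ZMatrix, params: ChmmParams, space: Optional[JointStateSpace] = None
) -> np.ndarray:
    """(m, n_states) matrix B with B[j,u] = prod_i f_{i, u_i}(z_ij)."""
    if space is None:
        space = JointStateSpace(params.num_studies)
    z = zmat.z
    if z.shape[1] != params.num_studies:
        raise ValueError("z-matrix and parameters disagree on the number of studies")
    f0 = _normal_pdf(z, 0.0, 1.0)  # (m, D)
    f1 = np.column_stack(
        [
            _normal_pdf(z[:, i], params.alt_means[i], params.alt_sds[i])
            for i in range(params.num_studies)
        ]
    )
    bits = space.bits
    B = np.ones((zmat.m, space.n_states))
    for u in range(space.n_states):
        for i in range(params.num_studies):
            B[:, u] *= f1[:, i] if bits[u, i] else f0[:, i]
    return B


# ---------------------------------------------------------------------------
# scaled forward-backward (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_kernel(B, pi, A):  # pragma: no cover - exercised via wrappers
    m, S = B.shape
    alpha = np.zeros((m, S))
    scale = np.zeros(m)
    c = 0.0
    for u in range(S):
        alpha[0, u] = pi[u] * B[0, u]
        c += alpha[0, u]
    scale[0] = c
    if c <= 0.0:
        return alpha, scale, 0
    for u in range(S):
        alpha[0, u] /= c
    for j in range(1, m):
        c = 0.0
        for v in range(S):
            s = 0.0
            for u in range(S):
                s += alpha[j - 1, u] * A[u, v]
            s *= B[j, v]
            alpha[j, v] = s
            c += s
        scale[j] = c
        if c <= 0.0:
            return alpha, scale, j
        for v in range(S):
            alpha[j, v] /= c
    return alpha, scale, -1


@njit(cache=True)
def _backward_kernel(B, A, scale):  # pragma: no cover - exercised via wrappers
    m, S = B.shape
    beta = np.zeros((m, S))
    for u in range(S):
        beta[m - 1, u] = 1.0
    for j in range(m - 2, -1, -1):
        for u in range(S):
            s = 0.0
            for v in range(S):
                s += A[u, v] * B[j + 1, v] * beta[j + 1, v]
            beta[j, u] = s / scale[j + 1]
    return beta


@njit(cache=True)
def _estep_kernel(B, pi, A):  # pragma: no cover - exercised via wrappers
    """Forward-backward sufficient statistics without materialising xi.

    Returns (gamma, xi_sum, first gamma row is gamma[0], loglik, bad_site).
    xi_sum[u,v] = sum_j P(state_j=u, state_{j+1}=v | Z).
    """
    m, S = B.shape
    alpha, scale, bad = _forward_kernel(B, pi, A)
    gamma = np.zeros((m, S))
    xi_sum = np.zeros((S, S))
    if bad >= 0:
        return gamma, xi_sum, 0.0, bad
    beta = _backward_kernel(B, A, scale)
    for j in range(m):
        c = 0.0
        for u in range(S):
            g = alpha[j, u] * beta[j, u]
            gamma[j, u] = g
            c += g
        for u in range(S):
            gamma[j, u] /= c
    for j in range(m - 1):
        c = 0.0
        tmp = np.empty((S, S))
        for u in range(S):
            au = alpha[j, u]
            for v in range(S):
                w = au * A[u, v] * B[j + 1, v] * beta[j + 1, v]
                tmp[u, v] = w
                c += w
        for u in range(S):
            for v in range(S):
                xi_sum[u, v] += tmp[u, v] / c
    ll = 0.0
    for j in range(m):
        ll += np.log(scale[j])
    return gamma, xi_sum, ll, -1


def forward_pass(zmat: ZMatrix, params: ChmmParams, space=None):
    """Scaled forward recursion.

    Returns ``(forward, scale, loglik)`` where each row of ``forward`` sums
    to one and ``loglik = sum(log(scale))``; the unscaled forward variable
    alpha_j(u) = P(state_j=u, z_{1:j}) is ``forward[j,u]*prod(scale[:j+1])``.
    """
    B = emission_matrix(zmat, params, space)
    alpha, scale, bad = _forward_kernel(B, params.pi, params.A)
    if bad >= 0:
        raise UnderflowError(bad)
    return alpha, scale, float(np.sum(np.log(scale)))


def backward_pass(zmat: ZMatrix, params: ChmmParams, space=None) -> np.ndarray:
    """Scaled backward recursion, sharing the forward scaling constants so
    that gamma[j] = forward[j]*backward[j] (up to normalisation)."""
    B = emission_matrix(zmat, params, space)
    _, scale, bad = _forward_kernel(B, params.pi, params.A)
    if bad >= 0:
        raise UnderflowError(bad)
    return _backward_kernel(B, params.A, scale)


def posteriors(
    zmat: ZMatrix, params: ChmmParams, space: Optional[JointStateSpace] = None
) -> PosteriorResult:
    """Full forward-backward decoding: marginal posteriors gamma, pairwise
    posteriors xi, log-likelihood, and the repLIS statistic

    ``replis[j] = P(null joint state at j | all z) = 1 - gamma[j, (1,..,1)]``
    (equality holds when the null set is the complement of the all-ones
    state, as it is for two studies)."""
    if space is None:
        space = JointStateSpace(params.num_studies)
    B = emission_matrix(zmat, params, space)
    alpha, scale, bad = _forward_kernel(B, params.pi, params.A)
    if bad >= 0:
        raise UnderflowError(bad)
    beta = _backward_kernel(B, params.A, scale)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # xi[j] ∝ alpha_j(u) A_uv f(z_{j+1}|v) beta_{j+1}(v)
    xi = (
        alpha[:-1, :, None]
        * params.A[None, :, :]
        * (B[1:] * beta[1:])[:, None, :]
        / scale[1:, None, None]
    )
    xi /= xi.sum(axis=(1, 2), keepdims=True)
    # roundoff can leave sums a few ulp outside [0,1]
    replis = np.clip(gamma[:, space.null_indices].sum(axis=1), 0.0, 1.0)
    return PosteriorResult(
        forward=alpha,
        backward=beta,
        scale=scale,
        gamma=gamma,
        xi=xi,
        loglik=float(np.sum(np.log(scale))),
        replis=replis,
        space=space,
    )


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_posteriors(
    zmat: ZMatrix,
    params: ChmmParams,
    space: Optional[JointStateSpace] = None,
    max_sites: int = 10,
    return_pairwise: bool = False,
):
    """Exact posteriors by summing the joint over all state sequences.

    Independent of the forward-backward code path: the joint probability of
    every one of the ``n_states**m`` sequences is evaluated explicitly.
    Refuses ``m > max_sites`` to bound the enumeration.

    Returns ``(gamma, loglik)``, or ``(gamma, loglik, xi)`` with
    ``return_pairwise=True``.
    """
    if space is None:
        space = JointStateSpace(params.num_studies)
    m, S = zmat.m, space.n_states
    if m > max_sites:
        raise ValueError(
            f"enumeration over {S}**{m} sequences refused (max_sites={max_sites})"
        )
    B = emission_matrix(zmat, params, space)
    seqs = np.array(list(itertools.product(range(S), repeat=m)), dtype=np.int64)
    p = params.pi[seqs[:, 0]].copy()
    for j in range(1, m):
        p *= params.A[seqs[:, j - 1], seqs[:, j]]
    for j in range(m):
        p *= B[j, seqs[:, j]]
    total = p.sum()
    if total <= 0:
        raise UnderflowError(0)
    gamma = np.zeros((m, S))
    for j in range(m):
        for u in range(S):
            gamma[j, u] = p[seqs[:, j] == u].sum()
    gamma /= total
    loglik = float(np.log(total))
    if not return_pairwise:
        return gamma, loglik
    xi = np.zeros((m - 1, S, S))
    for j in range(m - 1):
        for u in range(S):
            for v in range(S):
                mask = (seqs[:, j] == u) & (seqs[:, j + 1] == v)
                xi[j, u, v] = p[mask].sum()
    xi /= total
    return gamma, loglik, xi
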