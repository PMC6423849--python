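"""Decision rules: the repLIS step-up procedure, the max-p BH baseline, the
p-to-z transform and the pooled multi-chromosome analysis.

The repLIS procedure sorts the posterior null probabilities ascending and
rejects the ``l`` smallest, where ``l`` is the largest ``t`` whose running
mean stays at or below the nominal level::

    l = max { t : (1/t) * sum_{j<=t} repLIS_(j) <= alpha }

Rejecting site j claims the signal is present in *both* studies.  The
running-mean cutoff makes the expected false-discovery proportion of the
rejected set at most alpha when the statistics are the true posterior null
probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .estimation import EmConfig, EmTrace, em_fit
from .model import ChmmParams, JointStateSpace, ZMatrix, posteriors

__all__ = [
    "DecisionResult",
    "PooledResult",
    "pvalues_to_z",
    "replis_stepup",
    "bh_max_p",
    "pooled_analysis",
]

logger = logging.getLogger(__name__)

#: p-values below this floor are clamped before the quantile transform so the
#: resulting z stays finite (the recorded-as-1 clamp is 0.99; this is the
#: symmetric guard at the small end).
P_FLOOR = 1e-15


@dataclass
class DecisionResult:
    """Rejection decisions of a step-up rule.

    ``order`` ranks sites by the statistic (ascending, ties broken by the
    original site index via a stable sort); ``delta[j] = 1`` iff site j is
    rejected; ``n_rejected = delta.sum()``.
    """

    delta: np.ndarray
    n_rejected: int
    alpha: float
    order: np.ndarray
    statistic: np.ndarray


def pvalues_to_z(p: Sequence[float], p_floor: float = P_FLOOR) -> np.ndarray:
    """One-sided transform z = Phi^{-1}(1 - p).

    p-values recorded as exactly 1 are set to 0.99 first (so z stays
    finite), and p-values below ``p_floor`` are clamped to the floor.
    Values outside (0, 1] are rejected with the offending indices.
    """
    p = np.asarray(p, dtype=float)
    bad = np.nonzero(~((p > 0) & (p <= 1)))[0]
    if bad.size:
        shown = ", ".join(str(i) for i in bad[:10])
        more = "" if bad.size <= 10 else f" (+{bad.size - 10} more)"
        raise ValueError(
            f"{bad.size} p-value(s) outside (0, 1] at indices {shown}{more}"
        )
    p = np.where(p == 1.0, 0.99, p)
    p = np.maximum(p, p_floor)
    return norm.isf(p)


def replis_stepup(replis: Sequence[float], alpha: float) -> DecisionResult:
    """Step-up rule on posterior null probabilities (smaller = stronger)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    replis = np.asarray(replis, dtype=float)
    if replis.ndim != 1 or replis.size < 1:
        raise ValueError("replis must be a non-empty 1-d vector")
    if np.any((replis < 0) | (replis > 1)) or not np.all(np.isfinite(replis)):
        raise ValueError("repLIS values must lie in [0, 1]")
    m = replis.size
    order = np.argsort(replis, kind="stable")
    running_mean = np.cumsum(replis[order]) / np.arange(1, m + 1)
    passing = np.nonzero(running_mean <= alpha)[0]
    l = int(passing[-1] + 1) if passing.size else 0
    delta = np.zeros(m, dtype=np.int64)
    delta[order[:l]] = 1
    return DecisionResult(
        delta=delta, n_rejected=l, alpha=alpha, order=order, statistic=replis
    )


def bh_max_p(
    p1: Sequence[float], p2: Sequence[float], alpha: float
) -> DecisionResult:
    """Benjamini-Hochberg on the per-site maximum of the two studies'
    p-values (the partial-conjunction baseline)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError("p1 and p2 must be 1-d vectors of equal length")
    for name, p in (("p1", p1), ("p2", p2)):
        bad = np.nonzero(~((p > 0) & (p <= 1)))[0]
        if bad.size:
            raise ValueError(f"{name} has {bad.size} value(s) outside (0, 1]")
    joint = np.maximum(p1, p2)
    m = joint.size
    order = np.argsort(joint, kind="stable")
    thresh = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(joint[order] <= thresh)[0]
    l = int(passing[-1] + 1) if passing.size else 0
    delta = np.zeros(m, dtype=np.int64)
    delta[order[:l]] = 1
    return DecisionResult(
        delta=delta, n_rejected=l, alpha=alpha, order=order, statistic=joint
    )


# ---------------------------------------------------------------------------
# pooled per-chromosome analysis
# ---------------------------------------------------------------------------

@dataclass
class PooledResult:
    """Pooled decision over several chromosome groups.

    The model is fitted and repLIS computed within each group; the step-up
    cutoff is applied once to the pooled statistic vector, so the ranking
    spans all groups.  ``group_index``/``site_index`` map each pooled site
    back to its group and within-group position.
    """

    decision: DecisionResult
    group_params: List[ChmmParams]
    traces: List[EmTrace]
    replis: np.ndarray
    group_index: np.ndarray
    site_index: np.ndarray
    failed_groups: List[int] = field(default_factory=list)


def pooled_analysis(
    groups: Sequence[ZMatrix],
    alpha: float,
    em_config: Optional[EmConfig] = None,
    permissive: bool = False,
) -> PooledResult:
    """Fit per group, rank and threshold over the pool.

    With ``permissive=True`` a group whose EM fit fails is dropped (and
    recorded in ``failed_groups``) instead of aborting the whole run.
    """
    if len(groups) < 1:
        raise ValueError("at least one group is required")
    if em_config is None:
        em_config = EmConfig()
    replis_parts, params_list, traces = [], [], []
    group_idx, site_idx = [], []
    failed: List[int] = []
    for g, zmat in enumerate(groups):
        try:
            trace = em_fit(zmat, em_config)
        except (FloatingPointError, ValueError):
            if not permissive:
                raise
            logger.warning("EM failed on group %d; excluded from the pool", g)
            failed.append(g)
            continue
        post = posteriors(zmat, trace.final_params)
        replis_parts.append(post.replis)
        params_list.append(trace.final_params)
        traces.append(trace)
        group_idx.append(np.full(zmat.m, g, dtype=np.int64))
        site_idx.append(np.arange(zmat.m, dtype=np.int64))
        logger.info(
            "group %d: m=%d loglik=%.3f mu=%s sigma=%s",
            g,
            zmat.m,
            trace.loglik,
            np.round(trace.final_params.alt_means, 4),
            np.round(trace.final_params.alt_sds, 4),
        )
    if not replis_parts:
        raise ValueError("every group failed; nothing to pool")
    pooled = np.concatenate(replis_parts)
    decision = replis_stepup(pooled, alpha)
    return PooledResult(
        decision=decision,
        group_params=params_list,
        traces=traces,
        replis=pooled,
        group_index=np.concatenate(group_idx),
        site_index=np.concatenate(site_idx),
        failed_groups=failed,
    )


def top_k_selection(statistic: Sequence[float], k: int) -> np.ndarray:
    """Indices of the k best-ranked (smallest-statistic) sites, ties broken
    by original index.  The real-data alternative to an alpha cutoff."""
    statistic = np.asarray(statistic, dtype=float)
    if k < 0:
        raise ValueError("k must be non-negative")
    order = np.argsort(statistic, kind="stable")
    return order[: min(k, statistic.size)]
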