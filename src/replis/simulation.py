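"""Synthetic data generators and the replicated-experiment harness.

Two generative designs for paired association studies over m sites:

* ``iid_multinomial`` - joint hypothesis states drawn i.i.d. from a
  multinomial over the four joint states (independent tests; default cell
  probabilities (0.4, 0.2, 0.2, 0.2));
* ``markov`` - joint states follow a four-state stationary Markov chain
  (locally dependent tests; default transition matrix with 0.7 diagonal and
  0.1 off-diagonal, uniform initial law).

Given the states, z-values are conditionally independent Gaussians: null
N(0,1), alternative N(mu_i, sigma_i^2) in study i.  Defaults follow the
validated operating points: m = 10000 sites, 200 replications, nominal FDR
level 0.1, study-2 mean 4 (i.i.d. design) or 2 (Markov design).

The harness runs four procedures per replication - oracle repLIS (true
parameters), data-driven repLIS (EM plug-in), BH on the max p-value, and an
independence-restricted mixture fit - and averages FDR/FNR/ATP over
replications.

A genotype-level generator (:func:`simulate_gwas_pair`) emulates a pair of
case-control studies with locally correlated SNPs for sensitivity-at-top-k
evaluation: haplotypes copy the previous allele with a configurable
neighbour correlation, disease status follows a logistic model on a few
causal SNPs, and each SNP is tested with a Cochran-Armitage trend test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimation import EmConfig, em_fit
from .model import ChmmParams, JointStateSpace, ZMatrix, posteriors
from .multitest import bh_max_p, replis_stepup

__all__ = [
    "SimDesign",
    "TruthMatrix",
    "Metrics",
    "ExperimentResult",
    "scenario1_design",
    "scenario2_design",
    "simulate_iid",
    "simulate_markov",
    "simulate_states",
    "evaluate_decisions",
    "ranking_curves",
    "roc_points",
    "sensitivity_at_top_k",
    "run_experiment",
    "simulate_gwas_pair",
    "trend_test",
]

PROCEDURES = ("replis_oracle", "replis_datadriven", "bh_maxp", "indep_eb")


@dataclass
class SimDesign:
    """One simulation design point.

    ``state_probs`` drives the i.i.d. design; ``pi``/``A`` drive the Markov
    design (``A2``, a (S,S,S) tensor of P(next | prev2, prev), optionally
    makes the chain second-order while the analysis model stays first-order,
    for misspecification studies).
    """

    m: int = 10000
    mode: str = "markov"
    mu: Sequence[float] = (3.0, 2.0)
    sigma: Sequence[float] = (1.0, 1.0)
    state_probs: Optional[np.ndarray] = None
    A: Optional[np.ndarray] = None
    pi: Optional[np.ndarray] = None
    A2: Optional[np.ndarray] = None
    n_reps: int = 200
    alpha: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.m < 1 or self.n_reps < 1:
            raise ValueError("m and n_reps must be positive")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")
        if self.mode not in ("iid_multinomial", "markov"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        S = 2 ** self.mu.size
        if self.mode == "iid_multinomial":
            if self.state_probs is None:
                raise ValueError("iid design requires state_probs")
            self.state_probs = np.asarray(self.state_probs, dtype=float)
            if (
                self.state_probs.size != S
                or np.any(self.state_probs < 0)
                or abs(self.state_probs.sum() - 1.0) > 1e-9
            ):
                raise ValueError("state_probs must be a length-2**D probability vector")
        else:
            if self.A is None or self.pi is None:
                raise ValueError("markov design requires A and pi")
            self.A = np.asarray(self.A, dtype=float)
            self.pi = np.asarray(self.pi, dtype=float)
            if self.A.shape != (S, S) or np.any(self.A < 0) or np.any(
                np.abs(self.A.sum(axis=1) - 1.0) > 1e-9
            ):
                raise ValueError("A must be row-stochastic over 2**D states")
            if self.pi.size != S or abs(self.pi.sum() - 1.0) > 1e-9:
                raise ValueError("pi must be a length-2**D probability vector")

    @property
    def num_studies(self) -> int:
        return self.mu.size

    def generating_params(self) -> ChmmParams:
        """The true CHMM corresponding to this design (for the i.i.d.
        design the chain with every row equal to the cell probabilities)."""
        if self.mode == "iid_multinomial":
            S = self.state_probs.size
            return ChmmParams(
                self.state_probs,
                np.tile(self.state_probs, (S, 1)),
                self.mu,
                self.sigma,
            )
        return ChmmParams(self.pi, self.A, self.mu, self.sigma)


def scenario1_design(mu1: float = 2.0, mu2: float = 4.0, **kw) -> SimDesign:
    """Independent tests: states i.i.d. Multi(m, (0.4, 0.2, 0.2, 0.2))."""
    kw.setdefault("state_probs", np.array([0.4, 0.2, 0.2, 0.2]))
    kw.setdefault("sigma", (1.0, 1.0))
    return SimDesign(mode="iid_multinomial", mu=(mu1, mu2), **kw)


def scenario2_design(
    mu1: float = 3.0, mu2: float = 2.0, a_rr: float = 0.7, **kw
) -> SimDesign:
    """Locally dependent tests: four-state chain, 0.7 diagonal, uniform
    initial law.  ``a_rr`` is the self-transition of the replicated-signal
    state (1,1); its row is (0.1, 0.1, 0.8 - a_rr, a_rr)."""
    A = np.array(
        [
            [0.7, 0.1, 0.1, 0.1],
            [0.1, 0.7, 0.1, 0.1],
            [0.1, 0.1, 0.7, 0.1],
            [0.1, 0.1, 0.8 - a_rr, a_rr],
        ]
    )
    kw.setdefault("pi", np.full(4, 0.25))
    kw.setdefault("sigma", (1.0, 1.0))
    return SimDesign(mode="markov", mu=(mu1, mu2), A=A, **kw)


@dataclass
class TruthMatrix:
    """m x D binary matrix of true hypothesis states."""

    H: np.ndarray

    def __post_init__(self):
        self.H = np.atleast_2d(np.asarray(self.H, dtype=np.int64))
        if not np.isin(self.H, (0, 1)).all():
            raise ValueError("H entries must be 0/1")

    @property
    def replicated(self) -> np.ndarray:
        """Boolean mask of sites with a signal in every study."""
        return self.H.all(axis=1)


@dataclass
class Metrics:
    """Operating characteristics of a decision rule (averaged over
    replications where applicable)."""

    fdr: float
    fnr: float
    atp: float
    n_rejected: float

    def __post_init__(self):
        if not (0 <= self.fdr <= 1 and 0 <= self.fnr <= 1 and self.atp >= 0):
            raise ValueError("metrics out of range")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _emit_z(
    states: np.ndarray, bits: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    H = bits[states]  # (m, D)
    loc = H * mu[None, :]
    scale = np.where(H == 1, sigma[None, :], 1.0)
    return rng.standard_normal(H.shape) * scale + loc


def simulate_states(design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    """Integer state sequence (canonical state indices) for the design."""
    S = 2 ** design.num_studies
    if design.mode == "iid_multinomial":
        return rng.choice(S, size=design.m, p=design.state_probs)
    states = np.empty(design.m, dtype=np.int64)
    u = rng.random(design.m)
    cum_pi = np.cumsum(design.pi)
    states[0] = np.searchsorted(cum_pi, u[0])
    cum_A = np.cumsum(design.A, axis=1)
    if design.A2 is None:
        for j in range(1, design.m):
            states[j] = np.searchsorted(cum_A[states[j - 1]], u[j])
    else:
        cum_A2 = np.cumsum(design.A2, axis=2)
        if design.m > 1:
            states[1] = np.searchsorted(cum_A[states[0]], u[1])
        for j in range(2, design.m):
            states[j] = np.searchsorted(cum_A2[states[j - 2], states[j - 1]], u[j])
    return states


def _finish(
    design: SimDesign, states: np.ndarray, rng: np.random.Generator
) -> Tuple[TruthMatrix, ZMatrix]:
    bits = JointStateSpace(design.num_studies).bits
    z = _emit_z(states, bits, design.mu, design.sigma, rng)
    return TruthMatrix(bits[states]), ZMatrix(z)


def simulate_iid(
    design: SimDesign, rng: Optional[np.random.Generator] = None
) -> Tuple[TruthMatrix, ZMatrix]:
    """Draw one replicate of the i.i.d.-states design."""
    if design.mode != "iid_multinomial":
        raise ValueError("design.mode must be 'iid_multinomial'")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    return _finish(design, simulate_states(design, rng), rng)


def simulate_markov(
    design: SimDesign, rng: Optional[np.random.Generator] = None
) -> Tuple[TruthMatrix, ZMatrix]:
    """Draw one replicate of the Markov-states design."""
    if design.mode != "markov":
        raise ValueError("design.mode must be 'markov'")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    return _finish(design, simulate_states(design, rng), rng)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate_decisions(truth: TruthMatrix, delta: Sequence[int]) -> Metrics:
    """FDR/FNR/ATP of one decision vector against the truth.

    Conventions: with zero rejections the false-discovery proportion is 0;
    with zero non-rejections the false-nondiscovery proportion is 0.  ATP
    is the count of correctly rejected replicated-signal sites.
    """
    delta = np.asarray(delta).astype(bool)
    pos = truth.replicated
    if delta.size != pos.size:
        raise ValueError("truth and delta must have equal length")
    n_rej = int(delta.sum())
    false_rej = int((delta & ~pos).sum())
    true_rej = int((delta & pos).sum())
    missed = int((~delta & pos).sum())
    n_acc = delta.size - n_rej
    return Metrics(
        fdr=false_rej / n_rej if n_rej else 0.0,
        fnr=missed / n_acc if n_acc else 0.0,
        atp=float(true_rej),
        n_rejected=float(n_rej),
    )


def roc_points(positive: np.ndarray, statistic: np.ndarray) -> pd.DataFrame:
    """ROC of a ranking statistic where *smaller* means stronger evidence.

    Sweeps the threshold "reject iff statistic <= c" over the sorted unique
    statistic values (sites tied at a threshold enter together); returns the
    (fpr, tpr, threshold) table including the (0,0) origin.
    """
    positive = np.asarray(positive, dtype=bool)
    statistic = np.asarray(statistic, dtype=float)
    if not np.all(np.isfinite(statistic)):
        raise ValueError("statistic must be finite")
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0:
        raise ValueError("ROC undefined: no positive sites")
    order = np.argsort(statistic, kind="stable")
    s = statistic[order]
    tp = np.cumsum(positive[order])
    fp = np.cumsum(~positive[order])
    last_of_tie = np.nonzero(np.append(np.diff(s) > 0, True))[0]
    tpr = tp[last_of_tie] / n_pos
    fpr = fp[last_of_tie] / max(n_neg, 1)
    return pd.DataFrame(
        {
            "threshold": np.concatenate(([-np.inf], s[last_of_tie])),
            "fpr": np.concatenate(([0.0], fpr)),
            "tpr": np.concatenate(([0.0], tpr)),
        }
    )


def roc_auc(positive: np.ndarray, statistic: np.ndarray) -> float:
    """Area under :func:`roc_points` by trapezoidal integration."""
    curve = roc_points(positive, statistic)
    return float(np.trapezoid(curve["tpr"], curve["fpr"]))


def sensitivity_at_top_k(
    relevant: np.ndarray, statistic: np.ndarray, k_grid: Iterable[int]
) -> pd.DataFrame:
    """Fraction of the relevant site set captured among the k best-ranked
    sites (ranking ascending in the statistic, ties by site index)."""
    statistic = np.asarray(statistic, dtype=float)
    relevant = np.asarray(relevant)
    if relevant.dtype == bool:
        relevant = np.nonzero(relevant)[0]
    rel = set(int(i) for i in relevant)
    if not rel:
        raise ValueError("relevant set is empty")
    order = np.argsort(statistic, kind="stable")
    in_rel = np.isin(order, list(rel)).cumsum()
    rows = []
    for k in k_grid:
        k = int(k)
        if k < 0 or k > statistic.size:
            raise ValueError(f"k={k} outside [0, m]")
        hits = int(in_rel[k - 1]) if k > 0 else 0
        rows.append({"k": k, "sensitivity": hits / len(rel)})
    return pd.DataFrame(rows)


def ranking_curves(
    truth: TruthMatrix,
    statistic: Sequence[float],
    relevant: Optional[np.ndarray] = None,
    k_grid: Optional[Iterable[int]] = None,
) -> Dict[str, pd.DataFrame]:
    """ROC (positives = replicated-signal sites) plus, when ``relevant``
    and ``k_grid`` are given, the sensitivity-at-top-k table."""
    statistic = np.asarray(statistic, dtype=float)
    out = {"roc": roc_points(truth.replicated, statistic)}
    if relevant is not None:
        if k_grid is None:
            k_grid = [10, 50, 100, 200, 500]
        out["sensitivity"] = sensitivity_at_top_k(relevant, statistic, k_grid)
    return out


# ---------------------------------------------------------------------------
# replicated-experiment harness
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Averaged operating characteristics per procedure, with per-rep
    arrays and Monte-Carlo standard errors retained for error bars."""

    summary: Dict[str, Metrics]
    se: Dict[str, Metrics]
    per_rep: Dict[str, pd.DataFrame]
    auc: Dict[str, float] = field(default_factory=dict)
    n_failures: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for proc, met in self.summary.items():
            row = {
                "procedure": proc,
                "fdr": met.fdr,
                "fnr": met.fnr,
                "atp": met.atp,
                "n_rejected": met.n_rejected,
                "fdr_se": self.se[proc].fdr,
                "fnr_se": self.se[proc].fnr,
            }
            if proc in self.auc:
                row["auc"] = self.auc[proc]
            rows.append(row)
        return pd.DataFrame(rows)


def _decide(
    proc: str,
    truth: TruthMatrix,
    zmat: ZMatrix,
    design: SimDesign,
    em_config: EmConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """Decision vector and ranking statistic for one procedure."""
    if design.alpha == 0.0:
        # degenerate level: nothing is rejectable, but rankings still exist
        if proc == "bh_maxp":
            p = norm.sf(zmat.z)
            stat = np.maximum(p[:, 0], p[:, 1:].max(axis=1))
        elif proc == "replis_oracle":
            stat = posteriors(zmat, design.generating_params()).replis
        else:
            fit = em_fit(zmat, em_config, independence=(proc == "indep_eb"))
            stat = posteriors(zmat, fit.final_params).replis
        return np.zeros(zmat.m, dtype=np.int64), stat
    if proc == "replis_oracle":
        stat = posteriors(zmat, design.generating_params()).replis
        return replis_stepup(stat, design.alpha).delta, stat
    if proc == "replis_datadriven":
        fit = em_fit(zmat, em_config)
        stat = posteriors(zmat, fit.final_params).replis
        return replis_stepup(stat, design.alpha).delta, stat
    if proc == "indep_eb":
        fit = em_fit(zmat, em_config, independence=True)
        stat = posteriors(zmat, fit.final_params).replis
        return replis_stepup(stat, design.alpha).delta, stat
    if proc == "bh_maxp":
        p = norm.sf(zmat.z)
        stat = np.maximum(p[:, 0], p[:, 1:].max(axis=1))
        return bh_max_p(p[:, 0], p[:, 1:].max(axis=1), design.alpha).delta, stat
    raise ValueError(f"unknown procedure {proc!r}")


def run_experiment(
    design: SimDesign,
    procedures: Sequence[str] = PROCEDURES,
    em_config: Optional[EmConfig] = None,
    compute_roc: bool = False,
) -> ExperimentResult:
    """Replicate the design ``n_reps`` times and average each procedure's
    FDR, FNR, ATP and rejection count (optionally per-rep ROC AUCs).

    Replication r uses the child stream ``SeedSequence([seed, r])`` so runs
    are reproducible and procedures see identical data within a rep.  A
    replication whose model fit fails is skipped and counted.
    """
    unknown = set(procedures) - set(PROCEDURES)
    if unknown:
        raise ValueError(f"unknown procedures: {sorted(unknown)}")
    if em_config is None:
        em_config = EmConfig()
    records: Dict[str, list] = {p: [] for p in procedures}
    aucs: Dict[str, list] = {p: [] for p in procedures}
    simulate = simulate_iid if design.mode == "iid_multinomial" else simulate_markov
    n_failures = 0
    for rep in range(design.n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([design.seed, rep]))
        truth, zmat = simulate(design, rng)
        try:
            for proc in procedures:
                delta, stat = _decide(proc, truth, zmat, design, em_config)
                met = evaluate_decisions(truth, delta)
                records[proc].append(
                    {
                        "rep": rep,
                        "fdr": met.fdr,
                        "fnr": met.fnr,
                        "atp": met.atp,
                        "n_rejected": met.n_rejected,
                    }
                )
                if compute_roc:
                    aucs[proc].append(roc_auc(truth.replicated, stat))
        except FloatingPointError:
            n_failures += 1
            for proc in procedures:
                records[proc] = [r for r in records[proc] if r["rep"] != rep]
            continue
    per_rep = {p: pd.DataFrame(records[p]) for p in procedures}
    summary, se = {}, {}
    for p in procedures:
        df = per_rep[p]
        n = len(df)
        summary[p] = Metrics(
            fdr=df["fdr"].mean(),
            fnr=df["fnr"].mean(),
            atp=df["atp"].mean(),
            n_rejected=df["n_rejected"].mean(),
        )
        se[p] = Metrics(
            fdr=df["fdr"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            fnr=df["fnr"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            atp=df["atp"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            n_rejected=df["n_rejected"].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
        )
    mean_auc = {p: float(np.mean(aucs[p])) for p in procedures if aucs[p]}
    return ExperimentResult(
        summary=summary, se=se, per_rep=per_rep, auc=mean_auc, n_failures=n_failures
    )


# ---------------------------------------------------------------------------
# genotype-level generator (sensitivity-at-top-k evaluation)
# ---------------------------------------------------------------------------

def _haplotypes(
    n: int, freqs: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """n binary haplotypes over len(freqs) SNPs; each allele copies its left
    neighbour with probability rho, else is a fresh Bernoulli(freq) draw."""
    m = freqs.size
    fresh = rng.random((n, m)) < freqs[None, :]
    h = np.empty((n, m), dtype=np.int8)
    h[:, 0] = fresh[:, 0]
    copy = rng.random((n, m)) < rho
    for j in range(1, m):
        h[:, j] = np.where(copy[:, j], h[:, j - 1], fresh[:, j])
    return h


def trend_test(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cochran-Armitage trend test p-values (two-sided) per SNP column of
    the genotype matrix G (0/1/2 coding) against case status y."""
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    num = gc.T @ yc
    den = np.sqrt((gc ** 2).sum(axis=0) * (yc ** 2).sum()) + 1e-300
    r = num / den
    z = r * np.sqrt(n)
    return 2.0 * norm.sf(np.abs(z))


def simulate_gwas_pair(
    n_snps: int = 10000,
    causal: Sequence[int] = (1200, 1500, 1800, 6500, 6504, 6508),
    n_cases: int = 500,
    n_controls: int = 500,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    neighbor_rho: float = 0.9,
    beta0: float = -8.0,
    beta: float = np.log(2.0),
    batch: int = 20000,
    max_batches: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, np.ndarray]:
    """Two synthetic case-control studies sharing the same causal SNPs.

    Each study has its own genotype pool (allele frequencies drawn from
    ``maf_range``, neighbour-correlated haplotypes), disease status follows
    logit P(Y=1|G) = beta0 + sum_i beta * G_i over the causal genotypes, and
    cases/controls are accumulated by rejection sampling from the
    population.  Returns per-study trend-test p-value vectors plus the
    causal index set (keys ``p1``, ``p2``, ``causal``).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    causal = np.asarray(causal, dtype=np.int64)
    if np.any((causal < 0) | (causal >= n_snps)):
        raise ValueError("causal indices out of range")
    out: Dict[str, np.ndarray] = {"causal": causal}
    for study in (1, 2):
        freqs = rng.uniform(*maf_range, size=n_snps)
        G_cases, G_controls = [], []
        n_ca = n_co = 0
        for _ in range(max_batches):
            G = (
                _haplotypes(batch, freqs, neighbor_rho, rng)
                + _haplotypes(batch, freqs, neighbor_rho, rng)
            ).astype(np.int8)
            eta = beta0 + beta * G[:, causal].sum(axis=1)
            y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
            if n_ca < n_cases:
                take = G[y][: n_cases - n_ca]
                G_cases.append(take)
                n_ca += take.shape[0]
            if n_co < n_controls:
                take = G[~y][: n_controls - n_co]
                G_controls.append(take)
                n_co += take.shape[0]
            if n_ca >= n_cases and n_co >= n_controls:
                break
        else:
            raise RuntimeError(
                "could not accumulate the requested cases/controls; "
                "raise max_batches or the disease prevalence"
            )
        G_all = np.vstack(G_cases + G_controls)
        y_all = np.concatenate(
            [np.ones(n_cases, dtype=np.int64), np.zeros(n_controls, dtype=np.int64)]
        )
        out[f"p{study}"] = trend_test(G_all, y_all)
    return out
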