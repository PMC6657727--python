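"""Hidden Markov model with zero-inflated-Poisson regression emissions.

The genome is modelled position-by-position: the hidden state is the degree
of functional importance, the observation is the (rounded log2) insertion
count, and each state's emission is a zero-inflated Poisson regression of
that observation on normalised nucleosome density and the insertion motif
similarity score (IMSS):

    y_t | S_t = s  ~  omega_s * delta_0 + (1 - omega_s) * Poisson(lambda_st)
    log lambda_st  =  beta0_s + beta1_s * nuc_t + beta2_s * imss_t

States are pretrained on annotation- or insertion-quantile-defined subsets,
then the full model (initial distribution, transition matrix, emission
parameters) is fitted by EM and decoded with Viterbi. State 1 is the most
insertion-depleted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import brentq, minimize
from scipy.special import expit, gammaln
from scipy.stats import norm, rankdata

from .genome import ANNOTATION_CLASSES, Track

log = logging.getLogger("tnscape")

#: EM stopping rule: relative log-likelihood tolerance and iteration cap.
EM_TOL = 1e-8
EM_MAX_ITER = 150
#: Initial transition self-probability.
INIT_SELF_PROB = 0.95
#: Bounds for the emission optimiser (log-rate intercept, slopes, logit omega).
_B0_BOUNDS = (-12.0, 12.0)
_SLOPE_BOUNDS = (-10.0, 10.0)
_ETA_BOUNDS = (-12.0, 12.0)


class EMError(RuntimeError):
    """EM aborted: likelihood decreased beyond tolerance or went non-finite."""


# ---------------------------------------------------------------- observed data

def observed_states(
    counts: np.ndarray, rounding: str = "half_even", plus_one: bool = False
) -> np.ndarray:
    """Transform raw insertion counts to the HMM's observed variable.

    Default: y = 0 for counts of 0 or 1, otherwise the rounded log2 count
    (so one and zero insertions share an observed state). ``plus_one``
    switches to rounded log2(count + 1), a non-default variant that fitted
    the data worse. Rounding is half-to-even by default, ``half_up`` floors
    x + 0.5.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("insertion counts must be non-negative")
    counts = counts.astype(float)
    with np.errstate(divide="ignore"):
        x = np.log2(counts + 1.0) if plus_one else np.log2(np.maximum(counts, 1.0))
    if rounding == "half_even":
        y = np.rint(x)
    elif rounding == "half_up":
        y = np.floor(x + 0.5)
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return y.astype(np.int64)


def normalize_nucleosome(raw: Track) -> Track:
    """Rank-based inverse-normal (Blom) transform of a nucleosome track.

    Non-missing values are mapped to normal scores Phi^-1((r - 3/8)/(m + 1/4))
    with average ranks for ties, pooled over chromosomes; missing values are
    set to the median of the transformed series (approximately 0).
    """
    chroms = list(raw.data)
    pooled = np.concatenate([raw.data[c] for c in chroms])
    ok = np.isfinite(pooled)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing nucleosome values")
    values = pooled[ok]
    if np.ptp(values) == 0:
        log.warning("constant nucleosome track; normal scores are all zero")
        z = np.zeros(len(values))
    else:
        ranks = rankdata(values, method="average")
        z = norm.ppf((ranks - 3.0 / 8.0) / (len(values) + 0.25))
    out = np.empty(len(pooled))
    out[ok] = z
    out[~ok] = np.median(z)
    result, off = {}, 0
    for c in chroms:
        n = len(raw.data[c])
        result[c] = out[off : off + n]
        off += n
    return Track(result, "nucleosome_norm")


@dataclass
class ObservedSeries:
    """Per-position observations and covariates over mappable positions."""

    chrom: str
    positions: np.ndarray  # genomic coordinates, strictly increasing
    y: np.ndarray          # observed state (rounded log2 count)
    nuc: np.ndarray        # normal-score nucleosome density
    imss: np.ndarray       # insertion motif similarity score
    unique: np.ndarray | None = None   # unique strand-resolved sites per base
    classes: np.ndarray | None = None  # annotation class codes per position

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if (self.y < 0).any():
            raise ValueError("observed states must be non-negative")
        self.nuc = np.asarray(self.nuc, dtype=float)
        self.imss = np.asarray(self.imss, dtype=float)
        if not (np.isfinite(self.nuc).all() and np.isfinite(self.imss).all()):
            raise ValueError("covariates must be finite after imputation")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def X(self) -> np.ndarray:
        """Design matrix [1, nuc, imss]."""
        return np.column_stack([np.ones(len(self)), self.nuc, self.imss])

    def slice_positions(self, start: int, end: int) -> "ObservedSeries":
        """Sub-series of genomic positions in [start, end)."""
        lo = np.searchsorted(self.positions, start, side="left")
        hi = np.searchsorted(self.positions, end, side="left")
        sub = slice(lo, hi)
        return ObservedSeries(
            self.chrom,
            self.positions[sub],
            self.y[sub],
            self.nuc[sub],
            self.imss[sub],
            None if self.unique is None else self.unique[sub],
            None if self.classes is None else self.classes[sub],
        )


def make_series(
    chrom: str,
    count_per_base: np.ndarray,
    nuc_norm: np.ndarray,
    imss: np.ndarray,
    mask: np.ndarray | None = None,
    unique_per_base: np.ndarray | None = None,
    class_codes: np.ndarray | None = None,
    rounding: str = "half_even",
    plus_one: bool = False,
) -> ObservedSeries:
    """Assemble an ObservedSeries for one chromosome.

    Unmappable positions are excised (the analysis universe is the mappable
    genome); missing IMSS values (chromosome ends) are imputed with 0, the
    background score.
    """
    length = len(count_per_base)
    keep = np.ones(length, dtype=bool) if mask is None else np.asarray(mask, bool)
    positions = np.flatnonzero(keep)
    y = observed_states(count_per_base[positions], rounding, plus_one)
    nuc = np.nan_to_num(np.asarray(nuc_norm, float)[positions], nan=0.0)
    im = np.nan_to_num(np.asarray(imss, float)[positions], nan=0.0)
    return ObservedSeries(
        chrom,
        positions,
        y,
        nuc,
        im,
        None if unique_per_base is None else np.asarray(unique_per_base)[positions],
        None if class_codes is None else np.asarray(class_codes)[positions],
    )


# ---------------------------------------------------------------- emissions

@dataclass
class ZIPEmission:
    """One state's zero-inflated Poisson regression."""

    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0
    omega: float = 0.0
    family: str = "zip"  # "zip" or "poisson"
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("zip", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "poisson":
            self.omega = 0.0
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])

    def rates(self, X: np.ndarray) -> np.ndarray:
        return np.exp(np.clip(X @ self.beta, -30.0, 30.0))

    def n_params(self) -> int:
        return 4 if self.family == "zip" else 3


def zip_logpmf(y: np.ndarray, lam: np.ndarray, omega: float) -> np.ndarray:
    """log[ omega*1{y=0} + (1-omega) * e^-lam lam^y / y! ], elementwise."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    pois = y * np.log(lam) - lam - gammaln(y + 1.0)
    if omega == 0.0:
        return pois
    with np.errstate(divide="ignore"):
        log_om = np.log(omega)
        log_1m = np.log1p(-omega)
    zero_term = np.logaddexp(log_om, log_1m - lam)
    return np.where(y == 0, zero_term, log_1m + pois)


def _zip_negloglik_grad(theta, y, X, w, family):
    """Weighted negative ZIP log-likelihood and gradient.

    theta = (beta0, beta1, beta2[, eta]) with omega = expit(eta).
    """
    beta = theta[:3]
    z = np.clip(X @ beta, -30.0, 30.0)
    lam = np.exp(z)
    pos = y > 0
    if family == "poisson":
        omega = 0.0
    else:
        eta = float(np.clip(theta[3], -30.0, 30.0))
        omega = expit(eta)
    ll_pos = y[pos] * z[pos] - lam[pos] - gammaln(y[pos] + 1.0)
    grad_beta = (w[pos] * (y[pos] - lam[pos])) @ X[pos]
    if family == "poisson":
        f = -(w[pos] * ll_pos).sum() - (w[~pos] * (-lam[~pos])).sum()
        grad_beta += (w[~pos] * (-lam[~pos])) @ X[~pos]
        return f, -grad_beta
    e = np.exp(-lam[~pos])
    p0 = omega + (1.0 - omega) * e
    f = (w[pos] * (np.log1p(-omega) + ll_pos)).sum() + (w[~pos] * np.log(p0)).sum()
    grad_beta += (w[~pos] * (-(1.0 - omega) * e * lam[~pos] / p0)) @ X[~pos]
    grad_eta = (
        -(w[pos].sum()) * omega
        + (w[~pos] * ((1.0 - e) / p0)).sum() * omega * (1.0 - omega)
    )
    return -f, -np.append(grad_beta, grad_eta)


def fit_weighted_zip(
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    family: str = "zip",
    init: ZIPEmission | None = None,
    maxiter: int = 200,
) -> ZIPEmission:
    """Maximise the weighted ZIP log-likelihood by L-BFGS-B.

    Falls back to moment estimates (flagged) on optimiser failure; an
    effectively all-zero subset returns omega=1 with beta0 at its lower
    bound, flagged as degenerate.
    """
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    w_pos = float(w[y > 0].sum())
    w_tot = float(w.sum())
    if w_tot <= 0:
        raise ValueError("weights sum to zero")
    if family == "zip" and w_pos / w_tot < 1e-12:
        return ZIPEmission(_B0_BOUNDS[0], 0.0, 0.0, 1.0, "zip", flagged=True)
    theta0 = _moment_init(y, w, family) if init is None else _emission_theta(init, family)
    bounds = [_B0_BOUNDS, _SLOPE_BOUNDS, _SLOPE_BOUNDS]
    if family == "zip":
        bounds.append(_ETA_BOUNDS)
    res = minimize(
        _zip_negloglik_grad,
        theta0,
        args=(y, X, w, family),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter},
    )
    theta = res.x if np.isfinite(res.fun) else theta0
    omega = float(expit(theta[3])) if family == "zip" else 0.0
    return ZIPEmission(
        float(theta[0]), float(theta[1]), float(theta[2]), omega, family,
        flagged=not res.success and not np.isfinite(res.fun),
    )


def _moment_init(y, w, family):
    p0 = float(w[y == 0].sum() / w.sum())
    pos = y > 0
    m_pos = float((w[pos] * y[pos]).sum() / w[pos].sum()) if pos.any() else 0.5
    lam0 = max(m_pos, 0.05)
    theta = [math.log(lam0), 0.0, 0.0]
    if family == "zip":
        om0 = min(max((p0 - math.exp(-lam0)) / max(1 - math.exp(-lam0), 1e-9), 0.01), 0.99)
        theta.append(math.log(om0 / (1 - om0)))
    return np.array(theta)


def _emission_theta(em: ZIPEmission, family: str) -> np.ndarray:
    theta = [em.beta0, em.beta1, em.beta2]
    if family == "zip":
        om = min(max(em.omega, 1e-5), 1 - 1e-5)
        theta.append(math.log(om / (1 - om)))
    return np.array(theta)


def zero_truncated_rate(mean_positive: float) -> float:
    """Solve m+ = lambda / (1 - exp(-lambda)) for lambda (ZIP MLE identity)."""
    if mean_positive <= 1.0:
        return 1e-8
    return brentq(
        lambda lam: lam / (1.0 - math.exp(-lam)) - mean_positive, 1e-10, 1e6
    )


def emission_standard_errors(
    series: ObservedSeries, emission: ZIPEmission, w: np.ndarray | None = None
) -> np.ndarray:
    """Standard errors of (beta0, beta1, beta2[, eta]) from the observed
    information (finite differences of the analytic gradient)."""
    family = emission.family
    theta = _emission_theta(emission, family)
    y, X = series.y.astype(float), series.X
    w = np.ones(len(series)) if w is None else w
    k = len(theta)
    hess = np.zeros((k, k))
    h = 1e-5
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _zip_negloglik_grad(tp, y, X, w, family)
        _, gm = _zip_negloglik_grad(tm, y, X, w, family)
        hess[:, j] = (gp - gm) / (2 * h)
    hess = (hess + hess.T) / 2
    cov = np.linalg.pinv(hess)
    return np.sqrt(np.maximum(np.diag(cov), 0.0))


# ---------------------------------------------------------------- the HMM

@dataclass
class CovariateHMM:
    """n-state HMM with ZIP-regression emissions."""

    n: int
    pi_init: np.ndarray
    A: np.ndarray
    emissions: list[ZIPEmission]
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def __post_init__(self) -> None:
        self.pi_init = np.asarray(self.pi_init, float)
        self.A = np.asarray(self.A, float)
        if self.n < 1:
            raise ValueError("need at least one state")
        if len(self.emissions) != self.n or self.A.shape != (self.n, self.n):
            raise ValueError("inconsistent state count")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.pi_init.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    def log_emission_matrix(self, series: ObservedSeries) -> np.ndarray:
        X = series.X
        logB = np.empty((len(series), self.n))
        for s, em in enumerate(self.emissions):
            logB[:, s] = zip_logpmf(series.y, em.rates(X), em.omega)
        return logB

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pi_init": self.pi_init.tolist(),
            "A": self.A.tolist(),
            "emissions": [
                {
                    "beta0": e.beta0, "beta1": e.beta1, "beta2": e.beta2,
                    "omega": e.omega, "family": e.family,
                }
                for e in self.emissions
            ],
            "loglik_trace": list(self.loglik_trace),
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateHMM":
        return cls(
            d["n"],
            np.array(d["pi_init"]),
            np.array(d["A"]),
            [ZIPEmission(**e) for e in d["emissions"]],
            list(d.get("loglik_trace", [])),
            d.get("converged", False),
        )


def initial_model(emissions: list[ZIPEmission], self_prob: float = INIT_SELF_PROB) -> CovariateHMM:
    """Uniform initial distribution; self-transition ``self_prob`` with the
    remainder spread evenly."""
    n = len(emissions)
    pi = np.full(n, 1.0 / n)
    if n == 1:
        A = np.ones((1, 1))
    else:
        A = np.full((n, n), (1.0 - self_prob) / (n - 1))
        np.fill_diagonal(A, self_prob)
    return CovariateHMM(n, pi, A, emissions)


@njit(cache=True)
def _fb_kernel(pi, A, Bs):  # pragma: no cover - exercised via wrappers
    T, n = Bs.shape
    alpha = np.empty((T, n))
    c = np.empty(T)
    a = pi * Bs[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * Bs[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, n))
    beta[T - 1] = 1.0
    xi = np.zeros((n, n))
    for t in range(T - 2, -1, -1):
        scale = c[t + 1]
        for i in range(n):
            acc = 0.0
            for j in range(n):
                term = A[i, j] * Bs[t + 1, j] * beta[t + 1, j]
                xi[i, j] += alpha[t, i] * term / scale
                acc += term
            beta[t, i] = acc / scale
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    return gamma, xi, np.log(c).sum()


@njit(cache=True)
def _viterbi_kernel(logpi, logA, logB):  # pragma: no cover
    T, n = logB.shape
    delta = logpi + logB[0]
    psi = np.zeros((T, n), np.int64)
    for t in range(1, T):
        new = np.empty(n)
        for j in range(n):
            best = -1e308
            arg = 0
            for i in range(n):
                v = delta[i] + logA[i, j]
                if v > best:  # strict: ties keep the lower state index
                    best = v
                    arg = i
            new[j] = best + logB[t, j]
            psi[t, j] = arg
        delta = new
    last = 0
    best = -1e308
    for j in range(n):
        if delta[j] > best:
            best = delta[j]
            last = j
    path = np.empty(T, np.int64)
    path[T - 1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path


def _forward_backward(model: CovariateHMM, series: ObservedSeries):
    logB = model.log_emission_matrix(series)
    m = logB.max(axis=1)
    Bs = np.exp(logB - m[:, None])
    gamma, xi, logc = _fb_kernel(model.pi_init, model.A, Bs)
    return gamma, xi, float(logc + m.sum())


def loglikelihood(model: CovariateHMM, series: ObservedSeries) -> float:
    return _forward_backward(model, series)[2]


def posterior_probabilities(model: CovariateHMM, series: ObservedSeries) -> np.ndarray:
    """Smoothed per-position state distribution (rows sum to 1)."""
    return _forward_backward(model, series)[0]


def viterbi_decode(model: CovariateHMM, series: ObservedSeries) -> np.ndarray:
    """Most probable state path, as 1-based state labels."""
    with np.errstate(divide="ignore"):
        logpi = np.log(model.pi_init)
        logA = np.log(model.A)
    logB = model.log_emission_matrix(series)
    return _viterbi_kernel(logpi, logA, logB) + 1


def em_fit(
    series: ObservedSeries,
    init: CovariateHMM,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> CovariateHMM:
    """Baum-Welch/EM fit from a pretrained initial model.

    E-step by scaled forward-backward; M-step updates the initial
    distribution and transitions in closed form and each state's regression
    by warm-started L-BFGS-B (a generalised EM step, so the log-likelihood
    trace is non-decreasing). Stops when the relative log-likelihood change
    drops below ``tol`` or after ``max_iter`` iterations.
    """
    if len(series) < init.n:
        raise ValueError("series shorter than the number of states")
    model = CovariateHMM(
        init.n, init.pi_init.copy(), init.A.copy(),
        [replace(e) for e in init.emissions],
    )
    trace: list[float] = []
    converged = False
    X = series.X
    yf = series.y.astype(float)
    while True:
        gamma, xi, ll = _forward_backward(model, series)
        if not np.isfinite(ll) or np.isnan(gamma).any():
            raise EMError(f"non-finite E-step at iteration {len(trace)}")
        if trace and ll < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            raise EMError(
                f"log-likelihood decreased from {trace[-1]:.6f} to {ll:.6f}"
            )
        trace.append(ll)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(ll - prev) <= tol * abs(prev):
                converged = True
                break
        if len(trace) > max_iter:
            break
        # M-step
        model.pi_init = gamma[0] / gamma[0].sum()
        rowsum = xi.sum(axis=1, keepdims=True)
        if model.n > 1 and (rowsum > 0).all():
            model.A = xi / rowsum
        for s, em in enumerate(model.emissions):
            w = gamma[:, s]
            if w.sum() < 1e-8:
                em.flagged = True
                continue
            # warm-started partial maximisation: a generalised EM step
            model.emissions[s] = fit_weighted_zip(
                yf, X, w, em.family, init=em, maxiter=15
            )
    model.loglik_trace = trace
    model.converged = converged
    return model


def expected_counts(model: CovariateHMM, series: ObservedSeries) -> np.ndarray:
    """Per-state expected observation at the central covariate values.

    Evaluated at the series' median covariates rather than averaged over
    positions: averaging exp(X beta) lets one extreme slope dominate the
    ordering, whereas the median profile ranks states by their typical rate.
    """
    x_med = np.array([1.0, float(np.median(series.nuc)), float(np.median(series.imss))])
    return np.array(
        [(1.0 - e.omega) * float(e.rates(x_med[None, :])[0]) for e in model.emissions]
    )


def relabel_by_depletion(
    model: CovariateHMM, series: ObservedSeries
) -> tuple[CovariateHMM, np.ndarray]:
    """Reorder states by ascending expected count so S1 is most depleted.

    Returns the relabelled model and the permutation (old index of each new
    state)."""
    order = np.argsort(expected_counts(model, series), kind="stable")
    if (order == np.arange(model.n)).all():
        return model, order
    relabelled = CovariateHMM(
        model.n,
        model.pi_init[order],
        model.A[np.ix_(order, order)],
        [model.emissions[i] for i in order],
        model.loglik_trace,
        model.converged,
    )
    return relabelled, order


def bic_score(model: CovariateHMM, series: ObservedSeries) -> float:
    """BIC = -2L + k ln T with k = (n-1) + n(n-1) + sum of emission params."""
    L = model.loglik_trace[-1] if model.loglik_trace else loglikelihood(model, series)
    n = model.n
    k = (n - 1) + n * (n - 1) + sum(e.n_params() for e in model.emissions)
    return -2.0 * L + k * math.log(len(series))


# ---------------------------------------------------------------- pretraining

@dataclass
class TrainingPartition:
    """Disjoint per-state position-index sets used for pretraining."""

    scheme: str  # "annotation" or "quantile"
    sets: dict[int, np.ndarray]  # state (1-based) -> indices into the series
    families: dict[int, str]

    def __post_init__(self) -> None:
        for state, idx in self.sets.items():
            if len(idx) == 0:
                raise ValueError(f"empty training set for state {state}")
        all_idx = np.concatenate([v for v in self.sets.values()])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("training sets must be disjoint")


def _window_density(series: ObservedSeries, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Unique-insertion count per ``window``-nt genomic window.

    Returns (window id per position, density per distinct window)."""
    if series.unique is None:
        raise ValueError("series lacks unique-site counts")
    win = series.positions // window
    uniq_wins, inverse = np.unique(win, return_inverse=True)
    dens = np.bincount(inverse, weights=series.unique.astype(float))
    return inverse, dens


def _rank_tiers(values: np.ndarray, n_tiers: int) -> np.ndarray:
    """Split items into ``n_tiers`` near-equal groups by ascending value.

    Rank-based (stable on ties) so every tier is non-empty whenever
    len(values) >= n_tiers."""
    order = np.argsort(values, kind="stable")
    tiers = np.empty(len(values), dtype=np.int64)
    for t, chunk in enumerate(np.array_split(order, n_tiers)):
        tiers[chunk] = t
    return tiers


def _top_decile_windows(values: np.ndarray) -> np.ndarray:
    """Boolean mask of the highest 10% of windows by value (at least one)."""
    k = max(1, int(math.ceil(0.1 * len(values))))
    order = np.argsort(values, kind="stable")
    mask = np.zeros(len(values), dtype=bool)
    mask[order[-k:]] = True
    return mask


_CLS = {name: i for i, name in enumerate(ANNOTATION_CLASSES)}

#: State -> annotation-class codes for each annotation-scheme size.
_ANNOTATION_SCHEMES = {
    2: {1: ("eCDS", "nCDS"), 2: ("UTR_intron", "ncRNA", "unannotated")},
    3: {1: ("eCDS",), 2: ("nCDS",), 3: ("UTR_intron", "unannotated")},
    4: {1: ("eCDS",), 2: ("nCDS",), 3: ("UTR_intron",), 4: ("unannotated",)},
    5: {1: ("eCDS",), 2: ("nCDS",), 3: ("UTR_intron",), 4: ("unannotated",)},
}


def build_training_partition(
    series: ObservedSeries,
    scheme: str,
    n: int,
    window: int = 100,
    s5_poisson: bool = True,
) -> TrainingPartition:
    """Assign pretraining positions to states.

    ``annotation``: S1 = essential CDS, S2 = nonessential CDS, S3 =
    introns+UTRs, S4 = unannotated (for n=5, S5 = positions in the top decile
    of unique-insertion density per 100-nt window, taking precedence; its
    family is plain Poisson). ``quantile``: positions split into n
    near-equal tiers of window insertion density, S1 = sparsest.
    """
    families: dict[int, str]
    if scheme == "annotation":
        if n not in _ANNOTATION_SCHEMES:
            raise ValueError("annotation scheme supports 2-5 states")
        if series.classes is None:
            raise ValueError("series lacks annotation class codes")
        in_s5 = np.zeros(len(series), dtype=bool)
        if n == 5:
            inverse, dens = _window_density(series, window)
            in_s5 = _top_decile_windows(dens)[inverse]
        sets = {}
        for state, class_names in _ANNOTATION_SCHEMES[n].items():
            codes = [_CLS[c] for c in class_names]
            member = np.isin(series.classes, codes) & ~in_s5
            sets[state] = np.flatnonzero(member)
        if n == 5:
            sets[5] = np.flatnonzero(in_s5)
        families = {s: "zip" for s in sets}
        if n == 5 and s5_poisson:
            families[5] = "poisson"
    elif scheme == "quantile":
        if not 2 <= n <= 10:
            raise ValueError("quantile scheme supports 2-10 states")
        inverse, dens = _window_density(series, window)
        if len(dens) < n:
            raise ValueError(f"only {len(dens)} windows for {n} quantile states")
        tiers = _rank_tiers(dens, n)[inverse]
        sets = {s: np.flatnonzero(tiers == s - 1) for s in range(1, n + 1)}
        families = {s: "zip" for s in sets}
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    for state, idx in sets.items():
        if len(idx) == 0:
            raise ValueError(f"empty training set for state {state} ({scheme}, n={n})")
    return TrainingPartition(scheme, sets, families)


def pretrain_emissions(
    series: ObservedSeries, partition: TrainingPartition
) -> list[ZIPEmission]:
    """Fit each state's regression on its training subset (unit weights)."""
    emissions = []
    yf = series.y.astype(float)
    X = series.X
    for state in sorted(partition.sets):
        idx = partition.sets[state]
        fam = partition.families[state]
        emissions.append(fit_weighted_zip(yf[idx], X[idx], np.ones(len(idx)), fam))
    return emissions


def fit_hmm(
    series: ObservedSeries,
    scheme: str = "annotation",
    n: int = 5,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    window: int = 100,
    relabel: bool = True,
    s5_poisson: bool = True,
) -> CovariateHMM:
    """Pretrain, EM-fit and (optionally) relabel by depletion."""
    partition = build_training_partition(series, scheme, n, window, s5_poisson)
    init = initial_model(pretrain_emissions(series, partition))
    model = em_fit(series, init, tol=tol, max_iter=max_iter)
    if relabel:
        model, _ = relabel_by_depletion(model, series)
    return model


# ---------------------------------------------------------------- selection

def select_model(
    series: ObservedSeries,
    test_subsets: list[tuple[int, int]],
    candidates: list[tuple[str, int]] | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> pd.DataFrame:
    """Fit each candidate (scheme, n) on each genomic test subset.

    Returns one row per (candidate, subset) with BIC, convergence status,
    per-state Viterbi occupancy fractions, and a flag for failed runs or
    empty decoded states. Subsets are genomic [start, end) intervals and
    must lie within the series.
    """
    if candidates is None:
        candidates = [("quantile", k) for k in range(2, 11)] + [
            ("annotation", k) for k in range(2, 6)
        ]
    lo = int(series.positions[0])
    hi = int(series.positions[-1]) + 1
    rows = []
    n_ok = 0
    for start, end in test_subsets:
        if not (lo <= start < end <= hi):
            raise ValueError(f"subset [{start}, {end}) outside series [{lo}, {hi})")
        sub = series.slice_positions(start, end)
        for scheme, n in candidates:
            row = {
                "scheme": scheme, "n": n, "start": start, "end": end,
                "bic": np.nan, "loglik": np.nan, "converged": False,
                "flagged": False, "occupancy": None,
            }
            try:
                model = fit_hmm(sub, scheme, n, tol=tol, max_iter=max_iter)
                path = viterbi_decode(model, sub)
                occ = np.bincount(path - 1, minlength=n) / len(sub)
                row.update(
                    bic=bic_score(model, sub),
                    loglik=model.loglik_trace[-1],
                    converged=model.converged,
                    occupancy=occ.tolist(),
                    flagged=bool((occ == 0).any()),
                )
                n_ok += 1
            except (ValueError, EMError) as exc:
                row["flagged"] = True
                row["error"] = str(exc)
                log.warning("candidate %s-%d on [%d,%d) failed: %s",
                            scheme, n, start, end, exc)
            rows.append(row)
    if n_ok == 0:
        raise RuntimeError("all model-selection candidates failed")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- chunked fits

def fit_chunked(
    series: ObservedSeries,
    chunks: list[tuple[int, int]],
    scheme: str = "annotation",
    n: int = 5,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    s5_poisson: bool = True,
) -> tuple[np.ndarray, list[CovariateHMM]]:
    """Independent pretrain+EM+decode per genomic chunk.

    Chunks must tile [first, last] of the series without gaps or overlap;
    each chunk needs at least 10*n mappable positions. Returns the
    concatenated Viterbi path (aligned with ``series.positions``) and the
    per-chunk models.
    """
    chunks = sorted(chunks)
    lo = int(series.positions[0])
    hi = int(series.positions[-1]) + 1
    if chunks[0][0] > lo or chunks[-1][1] < hi:
        raise ValueError("chunks do not cover the series")
    for (s1, e1), (s2, e2) in zip(chunks, chunks[1:]):
        if e1 != s2:
            raise ValueError(f"chunks must tile without gaps: {e1} != {s2}")
    path = np.zeros(len(series), dtype=np.int64)
    models = []
    for start, end in chunks:
        sub = series.slice_positions(start, end)
        if len(sub) < 10 * n:
            raise ValueError(
                f"chunk [{start}, {end}) has only {len(sub)} mappable positions "
                f"(need >= {10 * n})"
            )
        model = fit_hmm(sub, scheme, n, tol=tol, max_iter=max_iter,
                        s5_poisson=s5_poisson)
        sub_path = viterbi_decode(model, sub)
        sel = (series.positions >= start) & (series.positions < end)
        path[sel] = sub_path
        models.append(model)
    if (path == 0).any():
        raise AssertionError("some mappable positions were not decoded")
    return path, models


def state_agreement(
    path_a: np.ndarray,
    path_b: np.ndarray,
    positions_a: np.ndarray | None = None,
    positions_b: np.ndarray | None = None,
    interval: tuple[int, int] | None = None,
) -> tuple[float, dict[int, float]]:
    """Fraction of overlap positions assigned the same state.

    With explicit position vectors the two paths are aligned on their common
    positions (optionally restricted to ``interval``); otherwise they must
    already be defined on the same positions. Also returns the per-state
    agreement breakdown (keyed by path_a's state)."""
    if positions_a is not None and positions_b is not None:
        common, ia, ib = np.intersect1d(positions_a, positions_b, return_indices=True)
        if interval is not None:
            keep = (common >= interval[0]) & (common < interval[1])
            ia, ib = ia[keep], ib[keep]
        a, b = np.asarray(path_a)[ia], np.asarray(path_b)[ib]
    else:
        a, b = np.asarray(path_a), np.asarray(path_b)
        if len(a) != len(b):
            raise ValueError("paths differ in length and no positions were given")
    if len(a) == 0:
        raise ValueError("empty overlap")
    same = a == b
    per_state = {
        int(s): float(same[a == s].mean()) for s in np.unique(a)
    }
    return float(same.mean()), per_state
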