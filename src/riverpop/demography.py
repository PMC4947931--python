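"""Mismatch distributions, sudden-expansion fitting, neutrality and dating.

The sudden-expansion expectation follows the Rogers-Harpending model: the
distribution of pairwise differences for a population that changed scaled
size from ``theta0`` to ``theta1`` at ``tau`` mutational time units before
present is a mixture of the new-size equilibrium geometric term and a
Poisson(tau) convolution of the old-size equilibrium.

The dating chain converts a fitted ``tau`` to calendar time with
``u = 2 * mu * k * T_gen`` (per-sequence per-generation rate), ``t = tau/(2u)``
generations and ``T = t * T_gen`` years; algebraically ``T = tau / (4 mu k)``.
Substitution rates are supplied in percent per site per million years, the
unit in which fish mtDNA clocks are conventionally quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .seqcore import Alignment, pairwise_differences
from .simulate import (
    simulate_haplotype_counts,
    simulate_pair_differences,
)

__all__ = [
    "MismatchDistribution",
    "ExpansionFit",
    "NeutralityResult",
    "ExpansionTiming",
    "mismatch_observed",
    "equilibrium_mismatch",
    "expected_mismatch",
    "fit_sudden_expansion",
    "raggedness",
    "expansion_gof",
    "ewens_log_pmf",
    "fus_fs",
    "fs_pvalue",
    "expansion_time",
    "percent_per_myr",
]


@dataclass(frozen=True)
class MismatchDistribution:
    """Observed frequencies of pairs differing at 0..d_max sites."""

    counts: np.ndarray
    n_pairs: int
    n: int  # sample size the pairs came from

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1

    def is_unimodal(self, tol: float = 0.01) -> bool:
        """True if the profile rises to its mode then falls, ignoring
        counter-movements smaller than ``tol`` (absolute frequency)."""
        f = self.freqs
        mode = int(np.argmax(f))
        rising = np.all(np.diff(f[: mode + 1]) >= -tol)
        falling = np.all(np.diff(f[mode:]) <= tol)
        return bool(rising and falling)


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    expected: np.ndarray
    ssd: float
    raggedness: float
    p_ssd: float | None = None
    p_raggedness: float | None = None
    boundary: bool = False


@dataclass(frozen=True)
class NeutralityResult:
    fs: float
    s_prime: float  # tail probability of the allele-count distribution
    theta_pi: float
    h: int
    n: int
    p_value: float | None = None


@dataclass(frozen=True)
class ExpansionTiming:
    tau: float
    mu: float  # per site per year
    k: int
    t_gen: float
    u: float  # per sequence per generation
    t_generations: float
    T_years: float

    @property
    def T_ma(self) -> float:
        return self.T_years / 1e6

    def rounded_ma(self, ndigits: int = 3) -> float:
        return round(self.T_ma, ndigits)


def percent_per_myr(rate: float) -> float:
    """Convert a rate in %/site/Myr to substitutions/site/year."""
    return rate / 100.0 / 1e6


def mismatch_observed(data: Alignment | np.ndarray) -> MismatchDistribution:
    """Histogram of pairwise difference counts over all unordered pairs."""
    if isinstance(data, Alignment):
        if data.n < 2:
            raise ValueError("mismatch distribution needs n >= 2")
        diffs = pairwise_differences(data)
        n = data.n
    else:
        diffs = np.asarray(data)
        n = diffs.shape[0]
        if n < 2:
            raise ValueError("mismatch distribution needs n >= 2")
    iu = np.triu_indices(n, k=1)
    vals = diffs[iu]
    counts = np.bincount(vals.astype(np.int64))
    return MismatchDistribution(counts=counts.astype(float), n_pairs=len(vals), n=n)


@lru_cache(maxsize=256)
def _log_factorials(d_max: int) -> np.ndarray:
    return gammaln(np.arange(d_max + 1, dtype=float) + 1.0)


@lru_cache(maxsize=256)
def _arange_f(d_max: int) -> np.ndarray:
    return np.arange(d_max + 1, dtype=float)


def _equilibrium_core(theta: float, d_max: int) -> np.ndarray:
    j = _arange_f(d_max)
    if theta <= 0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    return np.exp(j * math.log(theta) - (j + 1) * math.log1p(theta))


def _expected_core(tau: float, theta0: float, theta1: float, d_max: int) -> np.ndarray:
    """Unnormalized sudden-expansion expectation (hot path, no validation)."""
    f1 = _equilibrium_core(theta1, d_max)
    if tau == 0:
        out = _equilibrium_core(theta0, d_max)
    else:
        f0 = _equilibrium_core(theta0, d_max)
        decay = (
            math.exp(-tau * (theta1 + 1.0) / theta1)
            if theta1 > 0
            else math.exp(-tau)
        )
        pois = np.exp(_arange_f(d_max) * math.log(tau) - _log_factorials(d_max))
        out = f1 + decay * np.convolve(pois, f0 - f1)[: d_max + 1]
    np.maximum(out, 0.0, out=out)
    s = out.sum()
    return out / s if s > 0 else out


def equilibrium_mismatch(theta: float, d_max: int) -> np.ndarray:
    """Geometric equilibrium F_j = theta^j / (1 + theta)^(j+1), j = 0..d_max."""
    j = np.arange(d_max + 1, dtype=float)
    if theta == 0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    return np.exp(j * math.log(theta) - (j + 1) * math.log1p(theta))


def expected_mismatch(
    tau: float, theta0: float, theta1: float, d_max: int, renormalize: bool = True
) -> np.ndarray:
    """Sudden-expansion expectation for 0..d_max differences.

    F_j(tau) = F_j(theta1) + exp(-tau (theta1+1)/theta1)
               * sum_{i<=j} tau^i/i! [F_{j-i}(theta0) - F_{j-i}(theta1)]

    collapsing to the equilibrium geometric when ``tau = 0`` or
    ``theta0 == theta1``.  Truncated to ``d_max`` and renormalized.
    """
    if min(tau, theta0, theta1) < 0:
        raise ValueError("parameters must be non-negative")
    if renormalize:
        return _expected_core(tau, theta0, theta1, d_max)
    f1 = equilibrium_mismatch(theta1, d_max)
    f0 = equilibrium_mismatch(theta0, d_max)
    if tau == 0:
        out = f0
    else:
        decay = (
            math.exp(-tau * (theta1 + 1.0) / theta1) if theta1 > 0 else math.exp(-tau)
        )
        i = np.arange(d_max + 1, dtype=float)
        log_pois = i * math.log(tau) - _log_factorials(d_max)
        pois = np.exp(log_pois)
        conv = np.convolve(pois, f0 - f1)[: d_max + 1]
        out = f1 + decay * conv
    return np.clip(out, 0.0, None)


def _ssd(obs_freqs: np.ndarray, expected: np.ndarray) -> float:
    return float(np.sum((obs_freqs - expected) ** 2))


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2.

    ``d`` is the largest class with positive frequency; the convention closes
    the profile with ``x_{d+1} = 0``, making r invariant to trailing empty
    classes.
    """
    x = np.asarray(freqs, dtype=float)
    nz = np.flatnonzero(x > 0)
    if len(nz) == 0:
        raise ValueError("empty distribution")
    d = int(nz[-1])
    if d < 1:
        # point mass at zero differences: single closing term
        return float(x[0] ** 2)
    x = np.append(x[: d + 1], 0.0)
    return float(np.sum(np.diff(x) ** 2))


def fit_sudden_expansion(
    obs: MismatchDistribution,
    theta1_cap: float = 1e5,
) -> ExpansionFit:
    """Least-squares fit of (tau, theta0, theta1) to an observed mismatch.

    Deterministic: a coarse grid seed followed by Nelder-Mead refinement of
    the plain SSD objective, with tau bounded in [0, 2 d_max] and thetas in
    [0, theta1_cap] via clipping inside the objective.  Bootstrap refits use
    this exact procedure too: an asymmetric (cheaper) refit measurably
    biases the goodness-of-fit P-values upward.
    """
    freqs = obs.freqs
    d_max = obs.d_max
    if d_max == 0:
        expected = expected_mismatch(0.0, 0.0, 0.0, 0)
        return ExpansionFit(
            tau=0.0,
            theta0=0.0,
            theta1=0.0,
            expected=expected,
            ssd=_ssd(freqs, expected),
            raggedness=raggedness(freqs),
            boundary=True,
        )
    tau_hi = 2.0 * d_max

    def objective(x) -> float:
        tau = min(max(float(x[0]), 0.0), tau_hi)
        th0 = min(max(float(x[1]), 0.0), theta1_cap)
        th1 = min(max(float(x[2]), 1e-6), theta1_cap)
        diff = freqs - _expected_core(tau, th0, th1, d_max)
        return float(diff @ diff)

    grid_tau = np.linspace(0.0, tau_hi, 17)
    grid_th0 = (0.0, 0.5, 2.0, 10.0)
    grid_th1 = (1.0, 10.0, 100.0, 1000.0, 10000.0)
    # vectorized grid scan: for fixed tau the Poisson convolution over all
    # (theta0, theta1) combinations is one Toeplitz matrix product
    eq0 = {t: _equilibrium_core(t, d_max) for t in grid_th0}
    eq1 = {t: _equilibrium_core(t, d_max) for t in grid_th1}
    pairs = [(a, b) for a in grid_th0 for b in grid_th1]
    D = np.stack([eq0[a] - eq1[b] for a, b in pairs])
    F1 = np.stack([eq1[b] for _, b in pairs])
    j_idx = np.arange(d_max + 1)
    toe_idx = j_idx[:, None] - j_idx[None, :]  # conv index (j - i)
    valid = toe_idx >= 0
    best_val, best_x = math.inf, None
    for tau in grid_tau:
        if tau == 0:
            expect = np.stack([eq0[a] for a, _ in pairs])
        else:
            pois = np.exp(j_idx * math.log(tau) - _log_factorials(d_max))
            toe = np.where(valid, pois[np.clip(toe_idx, 0, d_max)], 0.0)
            decay = np.array(
                [math.exp(-tau * (b + 1.0) / b) for _, b in pairs]
            )
            expect = F1 + decay[:, None] * (D @ toe.T)
        np.maximum(expect, 0.0, out=expect)
        sums = expect.sum(axis=1, keepdims=True)
        expect = np.where(sums > 0, expect / np.where(sums > 0, sums, 1.0), expect)
        vals = ((freqs[None, :] - expect) ** 2).sum(axis=1)
        for p, val in enumerate(vals):
            if val < best_val - 1e-15:
                best_val, best_x = float(val), (tau, *pairs[p])
    res = minimize(
        objective,
        np.array(best_x),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
    )
    x = res.x
    tau = float(np.clip(x[0], 0.0, tau_hi))
    th0 = float(np.clip(x[1], 0.0, theta1_cap))
    th1 = float(np.clip(x[2], 1e-6, theta1_cap))
    expected = expected_mismatch(tau, th0, th1, d_max)
    return ExpansionFit(
        tau=tau,
        theta0=th0,
        theta1=th1,
        expected=expected,
        ssd=_ssd(freqs, expected),
        raggedness=raggedness(freqs),
        boundary=bool(tau == 0.0),
    )


def expansion_gof(
    obs: MismatchDistribution,
    fit: ExpansionFit,
    B: int = 200,
    seed: int | None = None,
) -> ExpansionFit:
    """Parametric-bootstrap P-values for SSD and raggedness.

    Simulates ``B`` coalescent samples of the observed size under the fitted
    expansion, re-fits each and reports the fraction with SSD (raggedness) at
    least as large as observed.
    """
    if B < 1:
        raise ValueError("B >= 1 required")
    rng = np.random.default_rng(seed)
    r_obs = raggedness(obs.freqs)
    hits_ssd = hits_r = 0
    for _ in range(B):
        diffs = simulate_pair_differences(
            obs.n, fit.theta0, fit.theta1, fit.tau, rng
        )
        sim = mismatch_observed(diffs)
        sim_fit = fit_sudden_expansion(sim)
        if sim_fit.ssd >= fit.ssd - 1e-15:
            hits_ssd += 1
        if raggedness(sim.freqs) >= r_obs - 1e-15:
            hits_r += 1
    fit.p_ssd = (hits_ssd + 1) / (B + 1)
    fit.p_raggedness = (hits_r + 1) / (B + 1)
    return fit


# ---------------------------------------------------------------------------
# Fu's Fs via the Ewens sampling formula
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _log_stirling_first(n: int) -> tuple[float, ...]:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n.

    Built with exact integer recurrence then logged, so it is exact for any
    practical n (Python ints do not overflow).
    """
    row = [1]
    for m in range(n):
        new = [0] * (len(row) + 1)
        for k, v in enumerate(row):
            new[k] += m * v
            new[k + 1] += v
        row = new
    return tuple(math.log(v) if v > 0 else -math.inf for v in row)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta, n) for k = 1..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = np.array(_log_stirling_first(n)[1:])  # k = 1..n
    k = np.arange(1, n + 1, dtype=float)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return logs + k * math.log(theta) - log_rising


def fus_fs(n: int, h: int, theta_pi: float) -> NeutralityResult:
    """Fs = ln(S'/(1-S')) with S' = Pr(K >= h | theta_pi, n) under Ewens."""
    if n < 3:
        raise ValueError("Fu's Fs needs n >= 3")
    if not 1 <= h <= n:
        raise ValueError("h must be in 1..n")
    if theta_pi <= 0:
        raise ValueError("theta_pi must be positive (Fs undefined at 0)")
    log_pmf = ewens_log_pmf(n, theta_pi)
    log_s_prime = logsumexp(log_pmf[h - 1 :])
    log_s_lower = logsumexp(log_pmf[: h - 1]) if h > 1 else -math.inf
    # ln(S'/(1-S')) computed from both tails for numerical stability
    fs = float(log_s_prime - log_s_lower) if h > 1 else math.inf
    return NeutralityResult(
        fs=fs, s_prime=float(math.exp(log_s_prime)), theta_pi=theta_pi, h=h, n=n
    )


def fus_fs_from_alignment(aln: Alignment) -> NeutralityResult:
    from .seqcore import collapse_haplotypes

    diffs = pairwise_differences(aln)
    iu = np.triu_indices(aln.n, k=1)
    theta_pi = float(diffs[iu].mean())
    h = collapse_haplotypes(aln).h
    return fus_fs(aln.n, h, theta_pi)


def fs_pvalue(
    result: NeutralityResult,
    n_sim: int = 1000,
    seed: int | None = None,
) -> NeutralityResult:
    """P-value by neutral constant-size coalescent simulation at theta_pi.

    P = fraction of simulations with Fs_sim <= Fs_obs (the conventional
    significance cut-off for Fs is P < 0.02).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        h_sim, k_sim = simulate_haplotype_counts(
            result.n, result.theta_pi, result.theta_pi, 0.0, rng
        )
        if k_sim <= 0:
            fs_sim = math.inf  # monomorphic: no evidence of excess alleles
        else:
            fs_sim = fus_fs(result.n, h_sim, k_sim).fs
        if fs_sim <= result.fs + 1e-15:
            hits += 1
    return NeutralityResult(
        fs=result.fs,
        s_prime=result.s_prime,
        theta_pi=result.theta_pi,
        h=result.h,
        n=result.n,
        p_value=(hits + 1) / (n_sim + 1),
    )


def expansion_time(
    tau: float,
    mu_percent_per_myr: float,
    k: int,
    t_gen: float,
) -> ExpansionTiming:
    """Date an expansion from tau: u = 2 mu k T_gen, t = tau/(2u), T = t T_gen.

    ``mu_percent_per_myr`` is the substitution rate in percent per site per
    million years (e.g. 1.69 for the concatenated fish mtDNA clock).
    """
    if mu_percent_per_myr <= 0 or k <= 0 or t_gen <= 0:
        raise ValueError("mu, k and t_gen must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    mu = percent_per_myr(mu_percent_per_myr)
    u = 2.0 * mu * k * t_gen
    t = tau / (2.0 * u) if tau > 0 else 0.0
    return ExpansionTiming(
        tau=tau,
        mu=mu,
        k=k,
        t_gen=t_gen,
        u=u,
        t_generations=t,
        T_years=t * t_gen,
    )
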