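"""Mismatch distributions and sudden-expansion dating.

Under the sudden-expansion model a population at mutation-scaled size
theta0 grows instantaneously to theta1 at time tau before present, with
tau = 2uT in units of mutations over the sequenced fragment (u is the
per-fragment per-generation mutation rate, T the time in generations).
In the default theta1 -> infinity simplification the expected pairwise-
difference spectrum is a Poisson(tau) convolved with the ancestral
geometric equilibrium of theta0:

    F_j = sum_{i=0..j} e^-tau tau^i / i!  *  theta0^(j-i) / (1+theta0)^(j-i+1)

The finite-theta1 three-parameter form adds the probability of coalescing
before the expansion, which has a closed form via the regularized lower
incomplete gamma function.

tau converts to calendar years as T = tau / (2 r g L) with r the
substitution rate per site per year, g the generation time in years and
L the fragment length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammainc, gammaln

from .diversity import pairwise_diff_matrix
from .seqio import Alignment, InsufficientDataError


@dataclass
class MismatchSpectrum:
    freqs: np.ndarray   # relative frequencies F_0..F_max
    n_pairs: int
    n: int
    L: int

    @property
    def mean(self) -> float:
        j = np.arange(self.freqs.size)
        return float((j * self.freqs).sum())


@dataclass
class MismatchFit:
    tau: float
    theta0: float
    theta1: float          # inf for the two-parameter model
    ssd: float
    expected: np.ndarray
    converged: bool
    p_ssd: float | None = None


@dataclass(frozen=True)
class ExpansionTiming:
    tau: float
    rate_per_site_per_year: float
    generation_years: float
    L: int
    two_u: float
    T_years: float


def mismatch_observed(a: Alignment) -> MismatchSpectrum:
    """Normalised histogram of pairwise difference counts over all pairs."""
    if a.n < 2:
        raise InsufficientDataError("mismatch spectrum needs n >= 2")
    d = pairwise_diff_matrix(a.seqs)
    iu = np.triu_indices(a.n, k=1)
    diffs = d[iu]
    counts = np.bincount(diffs)
    return MismatchSpectrum(freqs=counts / diffs.size, n_pairs=diffs.size,
                            n=a.n, L=a.L)


def _log_poisson(tau: float, i: np.ndarray) -> np.ndarray:
    if tau == 0:
        out = np.full(i.shape, -np.inf)
        out[i == 0] = 0.0
        return out
    return -tau + i * math.log(tau) - gammaln(i + 1)


def mismatch_expected(tau: float, theta0: float, j_max: int,
                      theta1: float = math.inf) -> np.ndarray:
    """Expected mismatch frequencies F_0..F_j_max under sudden expansion.

    tau = 0 reduces to the geometric equilibrium spectrum of theta0;
    theta0 = 0 with infinite theta1 reduces to Poisson(tau).
    """
    if tau < 0 or theta0 < 0 or theta1 <= 0:
        raise ValueError("parameters must be non-negative (theta1 > 0)")
    j = np.arange(j_max + 1)
    pois = np.exp(_log_poisson(tau, j))
    geo = _geometric(theta0, j)
    conv = np.array([float((pois[: jj + 1] * geo[: jj + 1][::-1]).sum())
                     for jj in j])
    if math.isinf(theta1):
        return conv
    # probability of coalescing before the expansion epoch (rate 1/theta1)
    pre = _geometric(theta1, j) * gammainc(j + 1, tau * (1.0 + theta1) / theta1)
    return pre + math.exp(-tau / theta1) * conv


def _geometric(theta: float, j: np.ndarray) -> np.ndarray:
    """theta^j / (1+theta)^(j+1), evaluated in log space to avoid overflow."""
    if theta == 0:
        out = np.zeros(j.shape)
        out[j == 0] = 1.0
        return out
    return np.exp(j * math.log(theta) - (j + 1) * math.log1p(theta))


def fit_sudden_expansion(s: MismatchSpectrum, finite_theta1: bool = False) -> MismatchFit:
    """Least-squares fit of the sudden-expansion model to a spectrum.

    Minimises SSD = sum_j (F_j - Fhat_j)^2 over j = 0..max observed, by
    bounded nonlinear least squares from a small deterministic multistart
    (moment-based tau, several theta0 scales).
    """
    obs = s.freqs
    j_max = obs.size - 1
    mean = s.mean

    def residuals(params):
        if finite_theta1:
            tau, th0, th1 = params
            return mismatch_expected(tau, th0, j_max, theta1=th1) - obs
        tau, th0 = params
        return mismatch_expected(tau, th0, j_max) - obs

    starts = []
    for th0 in (0.01, 0.5, max(mean / 2.0, 0.01)):
        tau0 = max(mean - th0, 0.0)
        starts.append([tau0, th0] + ([max(10 * mean, 10.0)] if finite_theta1 else []))
    lo = [0.0, 0.0] + ([1e-6] if finite_theta1 else [])
    hi = [np.inf] * (3 if finite_theta1 else 2)
    best = None
    ok = False
    for x0 in starts:
        try:
            r = least_squares(residuals, x0, bounds=(lo, hi))
        except Exception:
            continue
        ssd = float((r.fun**2).sum())
        if best is None or ssd < best[0]:
            best = (ssd, r.x)
            ok = ok or r.success
    if best is None:
        raise RuntimeError("sudden-expansion fit failed from every start")
    ssd, x = best
    tau, th0 = float(x[0]), float(x[1])
    th1 = float(x[2]) if finite_theta1 else math.inf
    return MismatchFit(tau=tau, theta0=th0, theta1=th1, ssd=ssd,
                       expected=mismatch_expected(tau, th0, j_max, theta1=th1),
                       converged=ok)


def ssd_test(fit: MismatchFit, n: int, L: int, reps: int = 100,
             seed: int | None = None) -> float:
    """Parametric-bootstrap P-value of the fitted model's SSD.

    Coalescent samples are simulated under the fitted expansion (an
    effectively infinite theta1 is capped for simulation), each is refit,
    and P is the proportion of simulated SSDs >= the observed SSD.
    """
    import warnings

    from . import synthetic_data

    if reps < 100:
        warnings.warn("ssd_test with reps < 100 gives coarse P-values")
    theta1 = fit.theta1 if math.isfinite(fit.theta1) else 1000.0
    theta0 = max(fit.theta0, 1e-6)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(reps):
        sseed = int(rng.integers(1, 2**31 - 1))
        sim = synthetic_data.simulate_expansion_sample(
            n, theta0, theta1, fit.tau, L, sseed)
        sim_fit = fit_sudden_expansion(mismatch_observed(sim))
        if sim_fit.ssd >= fit.ssd:
            ge += 1
    return ge / reps


def expansion_time(tau: float, rate_per_site_per_year: float,
                   generation_years: float, L: int) -> ExpansionTiming:
    """Convert tau to calendar years: T = tau / (2 r g L)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if rate_per_site_per_year <= 0 or generation_years <= 0 or L <= 0:
        raise ValueError("rate, generation time and L must be positive")
    two_u = 2.0 * rate_per_site_per_year * generation_years * L
    return ExpansionTiming(tau=tau, rate_per_site_per_year=rate_per_site_per_year,
                           generation_years=generation_years, L=L,
                           two_u=two_u, T_years=tau / two_u)


def smoothed_modes(freqs: np.ndarray, window: int = 3) -> int:
    """Number of local maxima after a moving-average smoothing.

    Equal-valued runs are collapsed before peak counting, so plateaus count
    once; a spectrum is called bimodal when this returns >= 2.
    """
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        return 0
    k = np.ones(window) / window
    sm = np.convolve(f, k, mode="same")
    vals = [sm[0]]
    for x in sm[1:]:
        if x != vals[-1]:
            vals.append(x)
    vals = [-math.inf] + vals + [-math.inf]
    return sum(1 for i in range(1, len(vals) - 1)
               if vals[i] > vals[i - 1] and vals[i] > vals[i + 1])


def is_bimodal(s: MismatchSpectrum) -> bool:
    return smoothed_modes(s.freqs) >= 2
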