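"""Maximum-likelihood fluctuation analysis (Luria-Delbruck / MSS).

For whole-culture plating (every cell of every replicate exposed to
selection) the mutant-count distribution across cultures is the
Luria-Delbruck distribution with parameter ``m`` = expected mutations per
culture. Its pmf is generated by the Ma-Sandri-Sarkar recursion

    p_0 = exp(-m),    p_r = (m/r) * sum_{i=0}^{r-1} p_i / (r - i + 1),

equivalently a compound Poisson with clone-size law P(j) = 1/(j(j+1)).
``m`` is estimated by maximising the log likelihood over the replicate
counts (golden-section search on ln m), with a chi-square(1) profile
likelihood confidence interval, and converted to a per-division rate by
dividing by the final cell number ``N_t``.

Counts above ``rmax`` enter the likelihood as a censored tail of
probability ``1 - sum_{r<=rmax} p_r`` -- whole-plated cultures of 1e7
cells produce occasional jackpots far beyond any feasible pmf cache.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .rates import CountTable, RateEstimate

__all__ = [
    "ld_pmf",
    "ld_loglik",
    "ld_mle",
    "ld_rate_table",
    "sample_ld_counts",
    "LuriaDelbruckModel",
    "LDResults",
]

_CHI2_95_DF1 = 3.841458820694124  # chi2.ppf(0.95, 1)
_LN_TOL = 1e-6  # optimiser tolerance in ln m


def ld_pmf(m: float, rmax: int) -> np.ndarray:
    """Luria-Delbruck probabilities p_0 .. p_rmax via the MSS recursion."""
    if m < 0:
        raise ValueError("m must be non-negative")
    if rmax < 0:
        raise ValueError("rmax must be non-negative")
    p = np.zeros(rmax + 1)
    p[0] = math.exp(-m)
    if m == 0 or rmax == 0:
        return p
    # weights 1/(r - i + 1) form a reversed harmonic kernel
    inv = 1.0 / np.arange(2, rmax + 2)  # inv[k] = 1/(k+2)
    for r in range(1, rmax + 1):
        # sum_{i=0}^{r-1} p_i / (r - i + 1)
        s = float(np.dot(p[:r], inv[r - 1 :: -1]))
        p[r] = m / r * s
    return p


def ld_loglik(m: float, counts: np.ndarray, rmax: int | None = None) -> float:
    """Log likelihood of replicate counts under the LD distribution.

    Counts above ``rmax`` (default: the largest count, capped at 1,000)
    contribute the censored tail mass ``1 - sum p_r``.
    """
    counts = np.asarray(counts)
    cmax = int(counts.max(initial=0))
    if rmax is None:
        rmax = min(cmax, 1000)
    if m == 0:
        return 0.0 if cmax == 0 else -math.inf
    p = ld_pmf(m, rmax)
    ll = 0.0
    tail = max(1.0 - float(p.sum()), 1e-300)
    for c in counts:
        if c > rmax:
            ll += math.log(tail)
        else:
            ll += math.log(max(float(p[int(c)]), 1e-300))
    return ll


def _bracket_mle(counts: np.ndarray, rmax: int | None) -> tuple[float, float]:
    """Bracket the maximiser in ln m by doubling outward from a moment
    guess (mean count / harmonic-ish clone size)."""
    mean = float(np.mean(counts))
    m0 = max(mean / max(math.log(max(mean, 2.0)), 1.0), 1e-3)
    lo = hi = math.log(m0)
    ll0 = ld_loglik(m0, counts, rmax)
    step = math.log(2.0)
    ll_lo = ll_hi = ll0
    for _ in range(60):
        cand = ld_loglik(math.exp(lo - step), counts, rmax)
        if cand > ll_lo:
            lo -= step
            ll_lo = cand
        else:
            break
    for _ in range(60):
        cand = ld_loglik(math.exp(hi + step), counts, rmax)
        if cand > ll_hi:
            hi += step
            ll_hi = cand
        else:
            break
    return lo - step, hi + step


_INV_PHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_max(f, lo: float, hi: float, tol: float) -> float:
    """Golden-section maximiser on [lo, hi] (unimodal f)."""
    a, b = lo, hi
    c = b - _INV_PHI * (b - a)
    d = a + _INV_PHI * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _INV_PHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INV_PHI * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def ld_mle(
    counts: Sequence[int],
    N_t: float,
    rmax: int | None = None,
    ci_level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """ML estimate of m and the per-division rate mu = m / N_t.

    Returns ``(m_hat, mu_hat, (mu_low, mu_high))`` with a profile
    likelihood CI: the m-range where ``2 [l(m_hat) - l(m)] <= 3.841``
    (chi-square, 1 df, 95%), divided by ``N_t``.

    All-zero counts give ``m_hat = 0`` with the closed-form upper bound
    ``-ln(alpha_tail) / n`` from the likelihood ``exp(-n m)``.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty count list")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if N_t <= 0:
        raise ValueError("N_t must be positive")
    if ci_level != 0.95:
        from scipy.stats import chi2

        crit = float(chi2.ppf(ci_level, 1))
    else:
        crit = _CHI2_95_DF1

    n = counts.size
    if counts.max() == 0:
        m_up = crit / (2.0 * n)  # 2 n m = crit
        return 0.0, 0.0, (0.0, m_up / N_t)

    lo, hi = _bracket_mle(counts, rmax)
    lm_best = _golden_max(
        lambda lm: ld_loglik(math.exp(lm), counts, rmax), lo, hi, _LN_TOL
    )
    m_hat = float(math.exp(lm_best))
    ll_hat = ld_loglik(m_hat, counts, rmax)

    def drop(lm: float) -> float:
        return 2.0 * (ll_hat - ld_loglik(math.exp(lm), counts, rmax)) - crit

    # profile bounds: step outward until the drop exceeds the critical value
    lm_hat = math.log(m_hat)
    lm_lo = lm_hat
    while drop(lm_lo - 1.0) < 0 and lm_lo > lm_hat - 60:
        lm_lo -= 1.0
    m_low = math.exp(brentq(drop, lm_lo - 1.0, lm_hat, xtol=1e-8)) if lm_lo > lm_hat - 60 else 0.0
    lm_hi = lm_hat
    while drop(lm_hi + 1.0) < 0 and lm_hi < lm_hat + 60:
        lm_hi += 1.0
    m_high = math.exp(brentq(drop, lm_hat, lm_hi + 1.0, xtol=1e-8))

    return m_hat, m_hat / N_t, (m_low / N_t, m_high / N_t)


def ld_rate_table(tables: Sequence[CountTable], rmax: int | None = None) -> list[RateEstimate]:
    """Per-table ML rate estimates for whole-culture-plated experiments.

    Every table must have ``s = 1``; partial plating belongs to the Drake
    path (:mod:`lohscape.rates`), not here.
    """
    out = []
    for t in tables:
        if t.s != 1:
            raise ValueError(
                f"{t.label}: s = {t.s} < 1; whole-culture ML needs s = 1 "
                "(use the Drake estimator for partial plating)"
            )
        m_hat, mu, (lo, hi) = ld_mle(t.counts, t.N, rmax=rmax)
        out.append(
            RateEstimate(
                mu=mu,
                ci_low=lo,
                ci_high=hi,
                f_hat=float(np.mean(t.counts)) / t.N,
                n_replicates=t.n_replicates,
                zero_fraction=float(np.mean(np.asarray(t.counts) == 0)),
                nondetect=(max(t.counts) == 0),
                strain=t.strain,
                segment=t.segment,
                medium=t.medium,
            )
        )
    return out


def sample_ld_counts(
    m: float, size: int, rng: np.random.Generator, cap: int = 10**9
) -> np.ndarray:
    """Draw mutant counts from the LD distribution by its compound-Poisson
    form: K ~ Poisson(m) mutations, each founding a clone of size
    J = floor(1/U) (P(J = j) = 1/(j(j+1))), counts = sum of clone sizes.

    Independent of :func:`ld_pmf`; used as its cross-check and as the
    exact whole-culture sampler.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    ks = rng.poisson(m, size=size)
    counts = np.zeros(size, dtype=np.int64)
    total = int(ks.sum())
    if total:
        u = rng.random(total)
        clones = np.minimum(np.floor(1.0 / u).astype(np.int64), cap)
        idx = np.repeat(np.arange(size), ks)
        np.add.at(counts, idx, clones)
    return counts


class LuriaDelbruckModel:
    """Whole-culture-plating fluctuation model (statsmodels-style).

    Parameters
    ----------
    counts : sequence of int
        Mutant colonies per replicate culture (entire culture plated).
    N_t : float
        Final cells per culture.
    rmax : int, optional
        Cap on the pmf cache; larger counts are treated as censored.
    """

    def __init__(self, counts: Sequence[int], N_t: float, rmax: int | None = None):
        self.counts = np.asarray(counts, dtype=int)
        if self.counts.size == 0:
            raise ValueError("empty count list")
        self.N_t = float(N_t)
        self.rmax = rmax

    def loglike(self, m: float) -> float:
        return ld_loglik(m, self.counts, self.rmax)

    def fit(self, ci_level: float = 0.95) -> "LDResults":
        m_hat, mu, ci = ld_mle(self.counts, self.N_t, self.rmax, ci_level)
        return LDResults(self, m_hat, mu, ci, ci_level)


@dataclass
class LDResults:
    model: LuriaDelbruckModel
    m: float
    mu: float
    conf_int: tuple[float, float]
    ci_level: float = 0.95

    def summary(self) -> str:
        lines = [
            "Luria-Delbruck ML fluctuation fit",
            "=" * 46,
            f"cultures             : {self.model.counts.size}",
            f"zero-count cultures  : {int((self.model.counts == 0).sum())}",
            f"m (mutations/culture): {self.m:.4g}",
            f"N_t (cells/culture)  : {self.model.N_t:.3e}",
            f"mu (per division)    : {self.mu:.4e}",
            f"{int(self.ci_level*100)}% profile CI   : "
            f"({self.conf_int[0]:.4e}, {self.conf_int[1]:.4e})",
        ]
        return "\n".join(lines)
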