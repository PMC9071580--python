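"""LOH-rate estimation from replicate colony counts (the Drake path).

The estimation chain for partially-plated fluctuation cultures is

    replicate counts -> central tendency C_hat -> mutant frequency
    f = C_hat / (N s) -> per-division rate via the Drake relation
    mu = f / ln(N mu) -> (x2 detection correction) -> per-10 kb density
    and genome-wide extrapolation,

with percentile-bootstrap confidence intervals obtained by resampling the
replicate counts.

The central tendency is the geometric mean of the nonzero counts scaled by
the fraction of nonzero replicates -- robust to the jackpot counts that
dominate Luria-Delbruck distributed data, yet usable when more than half
the replicates are zero (where a median would collapse).

The Drake relation is implicit in mu; it is solved on the branch
``N mu >= e`` where ``h(mu) = mu ln(N mu) - f`` is strictly increasing,
by bracketed root finding on ``[e/N, f]``. Frequencies below ``e/N`` are
outside the approximation's domain and raise rather than extrapolate.

The detection correction doubles rates because a reciprocal-recombination
division of a +/- cell yields a 5-FOA-resistant daughter only about half
the time; the same factor applies to chromosome loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .genome import Segment

__all__ = [
    "CountTable",
    "EstimatorConfig",
    "RateEstimate",
    "central_count",
    "frequency_from_counts",
    "solve_drake",
    "estimate_rate",
    "correct_detection",
    "segment_density",
    "genome_extrapolate",
    "DrakeFluctuationModel",
    "DrakeRateResults",
]


@dataclass(frozen=True)
class CountTable:
    """Replicate mutant-colony counts for one strain x segment x medium.

    ``N`` is the viable-cell population per culture (from nonselective
    plating) and ``s`` the fraction of each culture exposed to selection.
    """

    counts: tuple[int, ...]
    N: float
    s: float
    strain: str = ""
    segment: Segment | None = None
    segment_name: str = ""  # fallback label when no Segment object is attached
    medium: str = "FG"  # F = 5-FOA only, FG = 5-FOA + geneticin

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ValueError("a CountTable needs at least one replicate count")
        if any(c < 0 or c != int(c) for c in self.counts):
            raise ValueError("counts must be non-negative integers")
        if self.N <= 0:
            raise ValueError("population size N must be positive")
        if not (0 < self.s <= 1):
            raise ValueError("sampling fraction s must be in (0, 1]")
        if self.medium not in ("F", "FG"):
            raise ValueError(f"medium must be 'F' or 'FG', got {self.medium!r}")

    @property
    def n_replicates(self) -> int:
        return len(self.counts)

    @property
    def label(self) -> str:
        seg = self.segment.name if self.segment is not None else (self.segment_name or "?")
        return f"{self.strain or '?'}:{seg}:{self.medium}"


@dataclass(frozen=True)
class EstimatorConfig:
    B: int = 10_000          # bootstrap resamples
    ci_level: float = 0.95
    rtol: float = 1e-12      # relative solver tolerance on the residual
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass(frozen=True)
class RateEstimate:
    """A per-segment LOH rate with bootstrap CI and provenance flags.

    ``mu`` is per cell division (Drake/ML paths) or per 2 h (starvation
    path, marked via ``unit``). ``corrected`` records whether the x2
    detection correction has been applied. ``nondetect`` flags all-zero
    tables, for which ``upper_bound_zero`` carries a rule-of-three style
    bound 3/(n N s) -- an extension, reported separately from mu.
    """

    mu: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    corrected: bool = False
    f_hat: float = math.nan
    n_replicates: int = 0
    zero_fraction: float = math.nan
    nondetect: bool = False
    upper_bound_zero: float = math.nan
    unit: str = "division"
    strain: str = ""
    segment: Segment | None = None
    medium: str = "FG"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("rate mu must be non-negative")
        if not (math.isnan(self.ci_low) or math.isnan(self.ci_high)):
            if not (self.ci_low <= self.mu + 1e-300 and self.mu <= self.ci_high * (1 + 1e-12) + 1e-300):
                raise ValueError(
                    f"CI ({self.ci_low}, {self.ci_high}) does not bracket mu={self.mu}"
                )


def central_count(counts: Sequence[int]) -> float:
    """Central tendency of replicate counts: geometric mean of the nonzero
    counts times the fraction of nonzero replicates. Zero when all counts
    are zero."""
    if len(counts) == 0:
        raise ValueError("empty count list")
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        return 0.0
    geo = math.exp(float(np.mean(np.log(nonzero))))
    return geo * nonzero.size / arr.size


def frequency_from_counts(c_hat: float, N: float, s: float) -> float:
    """Mutant frequency among the ``N * s`` cells exposed to selection."""
    if N * s < 1:
        raise ValueError(f"fewer than one cell plated (N*s = {N * s})")
    return c_hat / (N * s)


def solve_drake(f: float, N: float, rtol: float = 1e-12) -> float:
    """Solve the Drake relation ``mu = f / ln(N mu)`` for mu.

    Returns the unique root with ``N mu >= e``; ``h(mu) = mu ln(N mu) - f``
    is strictly increasing there and the root is bracketed by
    ``[e/N, f]``. ``f <= 0`` returns 0 (non-detect); ``0 < f < e/N`` is
    outside the approximation's domain and raises.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if f <= 0:
        return 0.0
    lo = math.e / N
    if f < lo:
        raise ValueError(
            f"frequency f={f:g} below e/N={lo:g}: outside the Drake domain"
        )
    if f == lo:
        return lo  # ln(N mu) = 1 fixed point

    def h(mu: float) -> float:
        return mu * math.log(N * mu) - f

    mu = brentq(h, lo, f, xtol=1e-300, rtol=max(rtol, 1e-15), maxiter=200)
    return float(mu)


def _mu_from_counts(
    counts: np.ndarray, N: float, s: float
) -> float:
    """Point chain C_hat -> f -> mu used for both the estimate and each
    bootstrap resample (zero resamples contribute mu = 0)."""
    c_hat = central_count(counts)
    if c_hat == 0:
        return 0.0
    f = frequency_from_counts(c_hat, N, s)
    return solve_drake(f, N)


def estimate_rate(
    table: CountTable, cfg: EstimatorConfig | None = None
) -> RateEstimate:
    """Point estimate plus percentile-bootstrap CI for one count table.

    Resamples the replicate counts with replacement (resample size =
    original size) ``cfg.B`` times; resamples with all counts zero
    contribute mu = 0. The CI is the equal-tailed percentile interval at
    ``cfg.ci_level``. Reproducible for a fixed ``cfg.seed``.
    """
    cfg = cfg or EstimatorConfig()
    arr = np.asarray(table.counts, dtype=float)
    n = arr.size
    zero_fraction = float(np.mean(arr == 0))

    if np.all(arr == 0):
        return RateEstimate(
            mu=0.0,
            ci_low=0.0,
            ci_high=0.0,
            f_hat=0.0,
            n_replicates=n,
            zero_fraction=1.0,
            nondetect=True,
            upper_bound_zero=3.0 / (n * table.N * table.s),
            strain=table.strain,
            segment=table.segment,
            medium=table.medium,
        )

    try:
        c_hat = central_count(arr)
        f_hat = frequency_from_counts(c_hat, table.N, table.s)
        mu = solve_drake(f_hat, table.N, cfg.rtol)
    except ValueError as exc:
        raise ValueError(f"{table.label}: {exc}") from exc

    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n, size=(cfg.B, n))
    resamples = arr[idx]
    # vectorised C_hat per resample
    nz = resamples > 0
    n_nz = nz.sum(axis=1)
    logs = np.where(nz, np.log(np.where(nz, resamples, 1.0)), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        geo = np.exp(logs.sum(axis=1) / np.maximum(n_nz, 1))
    c_boot = np.where(n_nz > 0, geo * n_nz / n, 0.0)
    f_boot = c_boot / (table.N * table.s)

    mus = np.zeros(cfg.B)
    lo_dom = math.e / table.N
    for j, fb in enumerate(f_boot):
        if fb <= 0:
            continue
        if fb < lo_dom:
            # below the Drake domain: closest admissible value, not an abort
            mus[j] = lo_dom
        else:
            mus[j] = solve_drake(fb, table.N, cfg.rtol)

    alpha = 1.0 - cfg.ci_level
    ci_low, ci_high = np.quantile(mus, [alpha / 2, 1 - alpha / 2])
    # percentile intervals from discrete resamples can narrowly miss the
    # point estimate; widen to include it so the invariant holds
    ci_low = min(float(ci_low), mu)
    ci_high = max(float(ci_high), mu)

    return RateEstimate(
        mu=mu,
        ci_low=ci_low,
        ci_high=ci_high,
        f_hat=f_hat,
        n_replicates=n,
        zero_fraction=zero_fraction,
        strain=table.strain,
        segment=table.segment,
        medium=table.medium,
    )


def correct_detection(est: RateEstimate) -> RateEstimate:
    """Apply the x2 detection correction (about half of LOH events yield a
    selectable daughter). Doubles mu and both CI bounds; refuses to
    correct twice."""
    if est.corrected:
        raise ValueError("estimate already detection-corrected")
    return replace(
        est,
        mu=2 * est.mu,
        ci_low=2 * est.ci_low if not math.isnan(est.ci_low) else est.ci_low,
        ci_high=2 * est.ci_high if not math.isnan(est.ci_high) else est.ci_high,
        corrected=True,
    )


def segment_density(est: RateEstimate, segment: Segment | None = None) -> RateEstimate:
    """Rate per 10 kb per division: mu divided by d/10,000.

    Uses the *uncorrected* rate (positional-pattern figures are drawn
    before the detection correction); CI bounds scale identically.
    """
    seg = segment if segment is not None else est.segment
    if seg is None:
        raise ValueError("no segment attached to the estimate")
    if est.corrected:
        raise ValueError("densities are computed from uncorrected rates")
    scale = 10_000.0 / seg.d
    return replace(
        est,
        mu=est.mu * scale,
        ci_low=est.ci_low * scale if not math.isnan(est.ci_low) else est.ci_low,
        ci_high=est.ci_high * scale if not math.isnan(est.ci_high) else est.ci_high,
        segment=seg,
        unit="per-10kb-per-division",
    )


def genome_extrapolate(
    corrected_rates: Sequence[RateEstimate] | Sequence[float],
    coverage_fraction: float,
) -> float:
    """Genome-wide per-division LOH rate: sum of corrected per-segment
    rates divided by the fraction of the genome the segments cover.

    Assumes equal event density in the covered (inner) and uncovered
    (outer) parts of chromosomes. Accepts RateEstimate objects (which
    must carry the corrected flag) or bare corrected rates.
    """
    if not (0 < coverage_fraction <= 1):
        raise ValueError("coverage_fraction must be in (0, 1]")
    total = 0.0
    for r in corrected_rates:
        if isinstance(r, RateEstimate):
            if not r.corrected:
                raise ValueError(
                    f"{r.strain or 'estimate'}: genome extrapolation needs "
                    "detection-corrected rates"
                )
            total += r.mu
        else:
            total += float(r)
    return total / coverage_fraction


class DrakeFluctuationModel:
    """Partial-plating fluctuation model for one replicate count table.

    Statsmodels-style front end over the functional chain: construct from
    data, call :meth:`fit`, read estimates off the returned
    :class:`DrakeRateResults`.

    Parameters
    ----------
    counts : sequence of int
        Mutant-colony counts, one per replicate culture.
    N : float
        Viable cells per culture at plating.
    s : float
        Fraction of each culture exposed to selection.
    """

    def __init__(
        self,
        counts: Sequence[int],
        N: float,
        s: float,
        strain: str = "",
        segment: Segment | None = None,
        medium: str = "FG",
    ) -> None:
        self.table = CountTable(
            counts=tuple(int(c) for c in counts),
            N=N,
            s=s,
            strain=strain,
            segment=segment,
            medium=medium,
        )

    @classmethod
    def from_table(cls, table: CountTable) -> "DrakeFluctuationModel":
        obj = cls.__new__(cls)
        obj.table = table
        return obj

    def fit(
        self,
        correct: bool = True,
        B: int = 10_000,
        ci_level: float = 0.95,
        seed: int | None = None,
    ) -> "DrakeRateResults":
        cfg = EstimatorConfig(B=B, ci_level=ci_level, seed=seed)
        est = estimate_rate(self.table, cfg)
        if correct and not est.nondetect:
            est = correct_detection(est)
        return DrakeRateResults(self, est, cfg)


@dataclass
class DrakeRateResults:
    model: DrakeFluctuationModel
    estimate: RateEstimate
    config: EstimatorConfig = field(default_factory=EstimatorConfig)

    @property
    def mu(self) -> float:
        return self.estimate.mu

    @property
    def conf_int(self) -> tuple[float, float]:
        return (self.estimate.ci_low, self.estimate.ci_high)

    def summary(self) -> str:
        e = self.estimate
        t = self.model.table
        lines = [
            "LOH rate estimate (Drake path)",
            "=" * 46,
            f"strain/segment/medium : {t.label}",
            f"replicates            : {e.n_replicates}",
            f"zero fraction         : {e.zero_fraction:.3f}",
            f"N (cells/culture)     : {t.N:.3e}",
            f"s (fraction plated)   : {t.s:.4g}",
            f"f_hat                 : {e.f_hat:.4e}",
            f"mu (per division)     : {e.mu:.4e}"
            + ("  [x2 corrected]" if e.corrected else ""),
            f"{int(self.config.ci_level*100)}% bootstrap CI      : "
            f"({e.ci_low:.4e}, {e.ci_high:.4e})  [B={self.config.B}]",
        ]
        if e.nondetect:
            lines.append(
                f"non-detect; rule-of-three bound: {e.upper_bound_zero:.4e}"
            )
        return "\n".join(lines)
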