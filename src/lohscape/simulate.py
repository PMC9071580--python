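"""Forward simulation of LOH-mutant accumulation and plating.

Emulates the fluctuation-assay design the estimators assume: replicate
microcultures seeded with at most ~100 cells grow to saturation
(~2.2e7 cells); LOH events arise during divisions at rate ``mu`` per
division; a reciprocal event yields a selectable daughter lineage with
probability ``detect_p`` (default 0.5); a fraction ``s`` (default 1/200)
of each saturated culture is plated on selective medium.

Two growth models are available:

``synchronous``
    Cells double in ``g = ceil(log2(N/n0))`` synchronous generations
    (population interpolated geometrically so the total number of
    divisions is exactly ``N - n0``); an event at generation ``i`` founds
    a clone of ``2^(g-i)`` cells. Simple and transparent; clone sizes are
    powers of two, so the count distribution matches the Luria-Delbruck
    law in its low-order terms (p0, p1, mean) but not exactly.

``lea_coulson``
    The exact Luria-Delbruck compound-Poisson form: Poisson(m) events,
    clone sizes P(j) = 1/(j(j+1)) -- the distribution the
    Ma-Sandri-Sarkar recursion encodes. Use when distributional
    exactness matters (e.g. validating the ML estimator).

The starvation generator emulates the nongrowing-cell design: viability
decays exponentially (calibrated by default so that the viable proportion
at day 7 is 0.824), and among survivors the mutant frequency grows
linearly at ``lambda_loh`` per 2-hour unit on top of a baseline carried
over from prior growth. Both platings are Poisson-sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genome import GenomeLayout, Segment
from .rates import CountTable
from .starvation import StarvationSeries

__all__ = [
    "SimConfig",
    "StarvationConfig",
    "simulate_culture",
    "simulate_cultures",
    "simulate_plating",
    "simulate_count_table",
    "simulate_genome_panel",
    "simulate_starvation",
]

#: default death hazard per day, calibrated so that viability at day 7
#: is 0.824 (exp(-7 * 0.0276636...) = 0.824)
DEFAULT_DEATH_RATE = -math.log(0.824) / 7.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one mutant-accumulation culture experiment."""

    mu: float                    # LOH rate per cell division
    n0: int = 100                # inoculum cells per culture
    N: float = 2.2e7             # final cells per culture
    detect_p: float = 0.5        # P(event yields a selectable lineage)
    s: float = 1.0 / 200.0       # fraction of each culture plated
    replicates: int = 30
    seed: int | None = None
    growth_model: str = "synchronous"  # or "lea_coulson"

    def __post_init__(self) -> None:
        if not (0 <= self.mu <= 1):
            raise ValueError("mu must be in [0, 1]")
        if not (1 <= self.n0 < self.N):
            raise ValueError("need 1 <= n0 < N")
        if not (0 < self.s <= 1):
            raise ValueError("s must be in (0, 1]")
        if not (0 <= self.detect_p <= 1):
            raise ValueError("detect_p must be in [0, 1]")
        if self.growth_model not in ("synchronous", "lea_coulson"):
            raise ValueError(f"unknown growth model {self.growth_model!r}")


@dataclass(frozen=True)
class StarvationConfig:
    """Parameters of one starvation time course."""

    lambda_loh: float                          # LOH conversions per cell per 2 h
    death_rate: float = DEFAULT_DEATH_RATE     # per-day mortality hazard
    timepoints: tuple[float, ...] = (3.0, 7.0, 14.0, 21.0)
    replicates: int = 30                       # wells pooled per sampling (controls: 3)
    baseline_freq: float = 1e-4                # mutant frequency at onset
    viable_sampled_fraction: float = 1e-5      # nonselective plating (per well)
    mutant_sampled_fraction: float = 1.0 / 20.0  # selective plating (per well)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lambda_loh < 0 or self.death_rate < 0:
            raise ValueError("rates must be non-negative")
        t = self.timepoints
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.baseline_freq < 0:
            raise ValueError("baseline_freq must be non-negative")


def _generation_schedule(cfg: SimConfig) -> tuple[int, np.ndarray, np.ndarray]:
    """g, divisions per generation, clone size per generation.

    Population is interpolated geometrically between n0 and N over g
    generations so that total divisions sum to exactly N - n0.
    """
    g = math.ceil(math.log2(cfg.N / cfg.n0))
    i = np.arange(g + 1)
    pop = cfg.n0 * (cfg.N / cfg.n0) ** (i / g)
    divisions = np.diff(pop)
    clone = 2.0 ** (g - np.arange(1, g + 1))
    return g, divisions, clone


def simulate_cultures(
    cfg: SimConfig, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Detectable mutant cells in ``size`` independent saturated cultures."""
    if cfg.N / cfg.n0 < 2:
        raise ValueError("need N/n0 >= 2 (at least one doubling)")
    if cfg.mu == 0 or cfg.detect_p == 0:
        return np.zeros(size, dtype=np.int64)
    if cfg.growth_model == "lea_coulson":
        from .luria_delbruck import sample_ld_counts

        m = cfg.mu * (cfg.N - cfg.n0) * cfg.detect_p
        cells = sample_ld_counts(m, size, rng, cap=int(cfg.N))
        return np.minimum(cells, int(cfg.N))
    _, divisions, clone = _generation_schedule(cfg)
    events = rng.poisson(cfg.mu * divisions, size=(size, divisions.size))
    if cfg.detect_p < 1:
        events = rng.binomial(events, cfg.detect_p)
    cells = np.minimum((events * clone).sum(axis=1), cfg.N)
    return cells.astype(np.int64)


def simulate_culture(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> int:
    """Detectable mutant cells in one saturated culture."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return int(simulate_cultures(cfg, 1, rng)[0])


def simulate_plating(
    mutant_cells: int | np.ndarray,
    s: float,
    rng: np.random.Generator | int | None = None,
) -> int | np.ndarray:
    """Colony count from plating a fraction ``s``: Binomial(cells, s)."""
    if not (0 < s <= 1):
        raise ValueError("s must be in (0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = rng.binomial(np.asarray(mutant_cells, dtype=np.int64), s)
    if np.isscalar(mutant_cells) or np.ndim(mutant_cells) == 0:
        return int(out)
    return out


def simulate_count_table(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    strain: str = "sim",
    segment: Segment | None = None,
    segment_name: str = "",
    medium: str = "FG",
) -> CountTable:
    """One replicate fluctuation experiment: growth + plating per culture."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cells = simulate_cultures(cfg, cfg.replicates, rng)
    counts = simulate_plating(cells, cfg.s, rng)
    return CountTable(
        counts=tuple(int(c) for c in np.atleast_1d(counts)),
        N=cfg.N,
        s=cfg.s,
        strain=strain,
        segment=segment,
        segment_name=segment_name,
        medium=medium,
    )


def positional_rate(
    segment: Segment,
    base_rate: float,
    tel_amp: float,
    tel_scale: float,
    cen_amp: float,
    cen_scale: float,
) -> float:
    """Per-division LOH rate of a segment under the positional model:
    proportional to length, amplified toward telomeres, suppressed toward
    centromeres (both exponentially with distance)."""
    rate = (
        segment.d
        * base_rate
        * (1.0 + tel_amp * math.exp(-segment.dist_tel / tel_scale))
        * (1.0 - cen_amp * math.exp(-segment.dist_cen / cen_scale))
    )
    return max(rate, 0.0)


def simulate_genome_panel(
    layout: GenomeLayout,
    segments: Sequence[Segment],
    base_rate: float,
    tel_amp: float,
    tel_scale: float,
    cen_amp: float,
    cen_scale: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    strain: str = "sim",
) -> tuple[dict[str, CountTable], dict[str, float]]:
    """Simulate a whole marker panel under the positional rate model.

    Returns ``(tables, true_rates)`` keyed by segment name; the true
    per-division rates allow recovery testing downstream.
    """
    if tel_amp < 0 or cen_amp < 0:
        raise ValueError("amplitudes must be non-negative")
    if cen_amp > 1:
        raise ValueError("cen_amp > 1 would produce negative rates")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tables: dict[str, CountTable] = {}
    rates: dict[str, float] = {}
    for seg in segments:
        mu = positional_rate(seg, base_rate, tel_amp, tel_scale, cen_amp, cen_scale)
        seg_cfg = replace(cfg, mu=mu, seed=None)
        tables[seg.name] = simulate_count_table(
            seg_cfg, rng, strain=strain, segment=seg
        )
        rates[seg.name] = mu
    return tables, rates


def simulate_starvation(
    cfg: StarvationConfig,
    survivors0: float,
    rng: np.random.Generator | None = None,
    strain: str = "sim",
    segment: Segment | None = None,
    segment_name: str = "",
    medium: str = "FG",
) -> StarvationSeries:
    """One starvation time course.

    Viability decays as exp(-death_rate * days); among survivors the
    mutant frequency is baseline + lambda_loh * (12 * days). Counts pool
    ``cfg.replicates`` wells per sampling; both platings are Poisson.
    """
    if survivors0 <= 0:
        raise ValueError("survivors0 must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.timepoints, dtype=float)
    # survivors0 is per well; cfg.replicates wells are pooled per sampling,
    # each plated at the same fraction, so the fraction itself is unchanged
    survivors = cfg.replicates * survivors0 * np.exp(-cfg.death_rate * t)
    freq = cfg.baseline_freq + cfg.lambda_loh * 12.0 * t
    viable = rng.poisson(survivors * cfg.viable_sampled_fraction)
    mutant = rng.poisson(survivors * cfg.mutant_sampled_fraction * freq)
    return StarvationSeries(
        strain=strain,
        timepoints=tuple(float(x) for x in t),
        viable_counts=tuple(int(v) for v in viable),
        mutant_counts=tuple(int(m) for m in mutant),
        viable_sampled_fraction=cfg.viable_sampled_fraction,
        mutant_sampled_fraction=cfg.mutant_sampled_fraction,
        segment=segment,
        segment_name=segment_name,
        medium=medium,
    )
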