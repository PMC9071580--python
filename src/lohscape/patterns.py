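"""Genome-wide positional pattern statistics for LOH densities.

Covers the three pattern questions the per-segment rates feed into:

* does per-10 kb LOH density fall with chromosome-arm length (Pearson
  correlation against the rank of arm length)?
* does it track proximity to telomeres / centromeres (Spearman rank
  correlations of rate against distance)?
* is it associated with repetitive-element densities or transcription
  intensity (scaled stepwise multiple regression, AIC, both directions)?

plus the two-way arm x strain ANOVA with Tukey contrasts used to compare
homozygote and hybrid strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .genome import GenomeLayout, Segment, arm_length

__all__ = [
    "DensityRecord",
    "RegressionResult",
    "build_density_records",
    "length_rank_correlation",
    "distance_correlation",
    "stepwise_density_regression",
    "strain_anova",
    "AnovaResult",
]


@dataclass(frozen=True)
class DensityRecord:
    """One per-arm LOH density observation with its arm-length rank."""

    segment_name: str
    strain: str
    environment: str
    medium: str
    density: float  # rate per 10 kb per division
    arm_length: int
    length_rank: float

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")


def build_density_records(
    densities: dict[str, float],
    segments: Sequence[Segment],
    layout: GenomeLayout,
    strain: str = "",
    environment: str = "SC",
    medium: str = "FG",
) -> list[DensityRecord]:
    """Attach arm lengths and midrank length ranks to per-segment densities."""
    segs = [s for s in segments if s.name in densities]
    lengths = np.array([arm_length(layout, s) for s in segs])
    ranks = stats.rankdata(lengths)  # midranks on ties
    return [
        DensityRecord(
            segment_name=s.name,
            strain=strain,
            environment=environment,
            medium=medium,
            density=densities[s.name],
            arm_length=int(l),
            length_rank=float(r),
        )
        for s, l, r in zip(segs, lengths, ranks)
    ]


def length_rank_correlation(records: Sequence[DensityRecord]) -> tuple[float, float]:
    """Pearson correlation between LOH density and the rank of arm length."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    dens = np.array([r.density for r in records])
    rank = np.array([r.length_rank for r in records])
    if np.ptp(dens) == 0 or np.ptp(rank) == 0:
        raise ValueError("zero variance in density or rank")
    r, p = stats.pearsonr(dens, rank)
    return float(r), float(p)


def distance_correlation(
    rates: Sequence[float],
    distances: Sequence[float],
    which: str = "telomere",
) -> tuple[float, float]:
    """Spearman rank correlation of rates against distance to a landmark.

    ``which`` is a label ("telomere" or "centromere") recorded for the
    caller's bookkeeping; the statistic is the same either way. Midranks
    on ties; two-sided p via the t approximation.
    """
    if which not in ("telomere", "centromere"):
        raise ValueError("which must be 'telomere' or 'centromere'")
    r = np.asarray(rates, dtype=float)
    d = np.asarray(distances, dtype=float)
    if r.size != d.size:
        raise ValueError("rates and distances differ in length")
    if r.size < 3:
        raise ValueError("need at least 3 pairs")
    rho, p = stats.spearmanr(r, d)
    return float(rho), float(p)


@dataclass
class RegressionResult:
    """Outcome of the scaled stepwise multiple regression."""

    selected: list[str]
    coefficients: dict[str, float]   # standardized
    pvalues: dict[str, float]
    signs: dict[str, int]
    aic: float
    model: object = None             # statsmodels results for diagnostics
    dropped_collinear: list[str] = None

    def summary(self) -> str:
        lines = [
            "Stepwise density regression (standardized predictors, AIC)",
            "=" * 58,
            f"retained predictors : {self.selected or '(none)'}",
        ]
        for name in self.selected:
            sign = "+" if self.signs[name] > 0 else "-"
            lines.append(
                f"  {name:<24s} beta={self.coefficients[name]:+.4f} ({sign}) "
                f"p={self.pvalues[name]:.3g}"
            )
        lines.append(f"AIC                 : {self.aic:.2f}")
        if self.dropped_collinear:
            lines.append(f"dropped (collinear) : {self.dropped_collinear}")
        return "\n".join(lines)


def _fit_ols(y: np.ndarray, X: pd.DataFrame, terms: list[str]):
    design = sm.add_constant(X[terms]) if terms else pd.DataFrame(
        {"const": np.ones(len(y))}, index=X.index
    )
    return sm.OLS(y, design).fit()


def stepwise_density_regression(
    response: Sequence[float],
    predictors: pd.DataFrame,
    standardize: bool = True,
) -> RegressionResult:
    """OLS with AIC stepwise selection, both directions from the full model.

    Predictors are z-scored before selection (``standardize=True``), so
    coefficients are comparable across predictors. An exactly collinear
    predictor pair (|r| = 1) drops the later column with a warning.
    Rows with missing values are excluded (complete cases).
    """
    X = predictors.copy()
    y = np.asarray(response, dtype=float)
    if len(y) != len(X):
        raise ValueError("response and predictors differ in length")
    keep = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    X = X.loc[keep].reset_index(drop=True)
    y = y[keep]

    dropped = []
    cols = list(X.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if b in dropped or a in dropped:
                continue
            if X[a].std() == 0 or X[b].std() == 0:
                continue
            r = np.corrcoef(X[a], X[b])[0, 1]
            if abs(r) >= 1.0 - 1e-12:
                warnings.warn(
                    f"predictors {a!r} and {b!r} exactly collinear; dropping {b!r}",
                    stacklevel=2,
                )
                dropped.append(b)
    X = X.drop(columns=dropped)

    if standardize:
        X = (X - X.mean()) / X.std(ddof=0)
        X = X.drop(columns=[c for c in X.columns if X[c].isna().all()])

    terms = list(X.columns)
    current = terms[:]
    fit = _fit_ols(y, X, current)
    best_aic = fit.aic
    improved = True
    while improved:
        improved = False
        moves = []
        for t in current:
            moves.append(("drop", t, [c for c in current if c != t]))
        for t in terms:
            if t not in current:
                moves.append(("add", t, current + [t]))
        for _, _, cand in moves:
            f = _fit_ols(y, X, cand)
            if f.aic < best_aic - 1e-9:
                best_aic, fit, current, improved = f.aic, f, cand, True
        # greedy: re-evaluate from the new model each round
    selected = [t for t in current]
    coefs = {t: float(fit.params[t]) for t in selected}
    pvals = {t: float(fit.pvalues[t]) for t in selected}
    signs = {t: (1 if coefs[t] > 0 else -1) for t in selected}
    return RegressionResult(
        selected=selected,
        coefficients=coefs,
        pvalues=pvals,
        signs=signs,
        aic=float(best_aic),
        model=fit,
        dropped_collinear=dropped,
    )


@dataclass
class AnovaResult:
    """Two-way arm x strain ANOVA with Tukey contrasts vs a reference."""

    table: pd.DataFrame              # ANOVA table (type II)
    tukey: pd.DataFrame              # all pairwise strain contrasts
    reference_contrasts: pd.DataFrame  # contrasts involving the reference strain
    log_response: bool

    def summary(self) -> str:
        out = ["Two-way ANOVA (arm + strain)", "=" * 46, self.table.to_string()]
        if len(self.reference_contrasts):
            out += ["", "Tukey contrasts vs reference strain:",
                    self.reference_contrasts.to_string(index=False)]
        return "\n".join(out)


def strain_anova(
    rates: pd.DataFrame,
    reference: str | None = None,
    log_response: bool = True,
) -> AnovaResult:
    """Two-factor ANOVA (arm + strain, no interaction) on per-arm rates.

    ``rates`` must be a complete long-format frame with columns
    ``arm``, ``strain``, ``rate`` -- one observation per arm x strain
    cell; missing cells raise, naming them. The response is log10(rate)
    by default (rates span orders of magnitude); raw-rate analysis is
    available via ``log_response=False``. Tukey HSD contrasts of each
    strain pair are computed, and the pairs involving ``reference`` (the
    homozygote, typically) are pulled out separately.
    """
    req = {"arm", "strain", "rate"}
    if not req.issubset(rates.columns):
        raise ValueError(f"rates frame needs columns {sorted(req)}")
    pivot = rates.pivot_table(index="arm", columns="strain", values="rate", aggfunc="count")
    missing = [
        (a, s)
        for a in pivot.index
        for s in pivot.columns
        if pd.isna(pivot.loc[a, s]) or pivot.loc[a, s] == 0
    ]
    if missing:
        raise ValueError(f"missing arm x strain cells: {missing}")

    df = rates.copy()
    if log_response:
        if (df["rate"] <= 0).any():
            raise ValueError("log response needs strictly positive rates")
        df["y"] = np.log10(df["rate"])
    else:
        df["y"] = df["rate"]

    model = sm.OLS.from_formula("y ~ C(arm) + C(strain)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    tk = pairwise_tukeyhsd(df["y"], df["strain"])
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    if reference is not None:
        mask = (tukey["group1"] == reference) | (tukey["group2"] == reference)
        ref = tukey[mask].reset_index(drop=True)
    else:
        ref = tukey.iloc[0:0]
    return AnovaResult(
        table=table, tukey=tukey, reference_contrasts=ref, log_response=log_response
    )
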