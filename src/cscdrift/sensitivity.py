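"""Local sensitivity analysis of the SSD design function.

For each rate parameter the design function F (the sum of squared deviations
between observed and model ratios) is re-evaluated after perturbing that
parameter by +/-1%, ..., +/-5%, giving ten local sensitivity coefficients
(LSCs) per parameter.  The standardized LSC used here is the magnitude of
the finite-difference change divided by the relative perturbation,

    LSC_i(eps) = |F(theta with theta_i*(1+eps)) - F(theta)| / |eps|,

i.e. the absolute semi-elasticity |dF/dtheta_i| * theta_i to first order;
dividing by the relative change makes the coefficients dimensionless in the
parameter and hence comparable across parameters with different scales.
A raw-derivative variant (divide additionally by theta_i) is available.

The four parameters' LSC groups are compared by one-way ANOVA, followed by
Tamhane's T2 post-hoc test -- appropriate because the groups have very
unequal variances -- implemented as all-pairs Welch t statistics with
Welch-Satterthwaite degrees of freedom and Sidak-adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import TimeCourse, sum_squared_deviations
from .model import RateParams

__all__ = [
    "EPSILONS",
    "LscTable",
    "AnovaResult",
    "PairwiseComparison",
    "standardized_lsc",
    "lsc_table",
    "oneway_anova",
    "tamhane_t2",
]

PARAM_IDS = ("k1", "k2", "a", "b")
EPSILONS = tuple(s * e for e in (0.01, 0.02, 0.03, 0.04, 0.05) for s in (1, -1))


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    pairwise: tuple[PairwiseComparison, ...] = ()


@dataclass(frozen=True)
class LscTable:
    """Ten standardized LSCs per parameter plus group summaries."""

    values: pd.DataFrame  # columns: parameter, epsilon, lsc
    baseline_params: RateParams
    baseline_ssd: float

    def group(self, parameter: str) -> np.ndarray:
        return self.values.loc[self.values["parameter"] == parameter,
                               "lsc"].to_numpy()

    def means(self) -> dict[str, float]:
        return {p: float(np.mean(self.group(p))) for p in PARAM_IDS}

    def sds(self) -> dict[str, float]:
        return {p: float(np.std(self.group(p), ddof=1)) for p in PARAM_IDS}

    def anova(self) -> AnovaResult:
        groups = [self.group(p) for p in PARAM_IDS]
        result = oneway_anova(groups)
        return replace(result, pairwise=tamhane_t2(groups, labels=PARAM_IDS))


def standardized_lsc(design_fn: Callable[[RateParams], float],
                     params: RateParams, which: str, epsilon: float,
                     standardize: bool = True) -> float:
    """One local sensitivity coefficient of ``design_fn`` at ``params``.

    ``epsilon`` is the signed relative perturbation of parameter ``which``
    (e.g. +0.05 for a 5% increase).  With ``standardize=True`` (default) the
    value is |delta F| / |epsilon|; with False it is the raw absolute
    finite-difference derivative |delta F| / |epsilon * theta_i|.
    """
    if epsilon == 0:
        raise ValueError("epsilon must be non-zero")
    if which not in PARAM_IDS:
        raise ValueError(f"unknown parameter {which!r}")
    theta = getattr(params, which)
    if theta <= 0:
        raise ValueError(
            f"relative perturbation of {which!r} undefined at value {theta}")
    perturbed = RateParams(**{
        name: getattr(params, name) * (1.0 + epsilon if name == which else 1.0)
        for name in PARAM_IDS})
    change = abs(design_fn(perturbed) - design_fn(params))
    denom = abs(epsilon) if standardize else abs(epsilon * theta)
    return change / denom


def lsc_table(data: TimeCourse, params: RateParams,
              r0: float | None = None,
              design_fn: Callable[[RateParams], float] | None = None,
              standardize: bool = True) -> LscTable:
    """The 4 x 10 table of standardized LSCs of the SSD around ``params``.

    ``params`` should be the fitted point estimate; ``r0`` defaults to the
    first observed ratio.  ``design_fn`` may override the SSD (used in
    testing and for alternative designs).
    """
    if design_fn is None:
        if data.n == 0:
            raise ValueError("need observations to evaluate the SSD")
        r0_val = float(data.ratio[0]) if r0 is None else float(r0)

        def design_fn(p: RateParams) -> float:
            return sum_squared_deviations(p, r0_val, data)

    rows = [
        {"parameter": name, "epsilon": eps,
         "lsc": standardized_lsc(design_fn, params, name, eps,
                                 standardize=standardize)}
        for name in PARAM_IDS for eps in EPSILONS
    ]
    return LscTable(values=pd.DataFrame(rows), baseline_params=params,
                    baseline_ssd=float(design_fn(params)))


def oneway_anova(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across the groups."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(g.size for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if all(np.ptp(g) == 0 for g in groups):
        # zero within-group variance: degenerate by convention
        means = [g[0] for g in groups]
        if np.ptp(means) == 0:
            return AnovaResult(F=0.0, df_between=df_between,
                               df_within=df_within, p=1.0)
        return AnovaResult(F=np.inf, df_between=df_between,
                           df_within=df_within, p=0.0)
    F, p = stats.f_oneway(*groups)
    return AnovaResult(F=float(F), df_between=df_between,
                       df_within=df_within, p=float(p))


def tamhane_t2(groups: Sequence[np.ndarray],
               labels: Sequence[str] | None = None,
               alpha: float = 0.05) -> tuple[PairwiseComparison, ...]:
    """All-pairs Tamhane T2 comparisons (Welch t + Sidak adjustment).

    Each unordered pair is compared with the unequal-variance Welch t
    statistic on Welch-Satterthwaite degrees of freedom; the per-pair
    p-value is Sidak-adjusted for the number of pairs, so with two groups
    the test reduces to a plain Welch test.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in combinations(range(len(groups)), 2):
        gi, gj = groups[i], groups[j]
        vi, vj = np.var(gi, ddof=1), np.var(gj, ddof=1)
        se2 = vi / gi.size + vj / gj.size
        if se2 == 0:
            t_stat, df, p_raw = 0.0, float(gi.size + gj.size - 2), 1.0
        else:
            t_stat = (np.mean(gi) - np.mean(gj)) / np.sqrt(se2)
            df = se2 ** 2 / ((vi / gi.size) ** 2 / (gi.size - 1)
                             + (vj / gj.size) ** 2 / (gj.size - 1))
            p_raw = 2.0 * stats.t.sf(abs(t_stat), df)
        p_adj = 1.0 - (1.0 - min(p_raw, 1.0)) ** m
        out.append(PairwiseComparison(
            group_a=labels[i], group_b=labels[j], statistic=float(t_stat),
            df=float(df), p_raw=float(p_raw), p_adjusted=float(p_adj),
            significant=bool(p_adj < alpha)))
    return tuple(out)
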