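"""Growth-rate formulas, broad-sense heritability, and mutant comparisons.

These are the downstream statistics of the phenotyping platform: percentage
growth rates per plant group, the per-ecotype growth rate over a cold-stress
time course, proportionate tolerance across a panel of ecotypes, one-way
random-effects ANOVA heritability, and mutant-vs-wild-type t-tests under a
Bonferroni-adjusted significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HeritabilityEstimate",
    "MutantComparison",
    "growth_rate_percent",
    "ecotype_growth_rate",
    "proportionate_tolerance",
    "log_transform",
    "broad_sense_heritability",
    "mutant_growth_ratio",
    "compare_mutant",
    "pearson_validation",
]


@dataclass
class HeritabilityEstimate:
    """Broad-sense heritability h2 = sigma2_g / (sigma2_g + sigma2_e)."""

    h2: float
    sigma2_g: float
    sigma2_e: float
    n_groups: int
    reps: float  # effective replicate count (n0 for unbalanced designs)


@dataclass
class MutantComparison:
    """Result of one mutant-vs-Col-0 growth comparison."""

    mutant_id: str
    wt_id: str
    treatment: str
    ratio: float
    t_stat: float
    p_value: float
    alpha: float
    m_comparisons: int
    significant: bool


def growth_rate_percent(initial: float, final: float) -> float:
    """Percent growth between two area measurements of the same plants.

    Computed as (final - initial) * 100 / initial; negative values indicate
    shrinkage or death of the rosette.
    """
    initial = float(initial)
    if initial <= 0:
        raise ValueError("initial area must be positive")
    return (float(final) - initial) * 100.0 / initial


def ecotype_growth_rate(day0: float, day30: float) -> float:
    """Per-ecotype growth rate over the cold time course: day30 * 100 / day0."""
    day0 = float(day0)
    if day0 <= 0:
        raise ValueError("day-0 area must be positive")
    return float(day30) * 100.0 / day0


def proportionate_tolerance(rates) -> np.ndarray:
    """Each ecotype's growth rate as a percentage of the panel total.

    Output sums to 100 for any valid input.
    """
    rates = np.asarray(rates, dtype=float)
    total = rates.sum()
    if total == 0:
        raise ValueError("sum of growth rates is zero")
    return rates * 100.0 / total


def log_transform(values, offset: float = 0.0) -> np.ndarray:
    """Natural log of (value + offset), elementwise.

    Pixel areas are log-transformed ahead of parametric association tests;
    the offset accommodates zero areas.
    """
    values = np.asarray(values, dtype=float)
    shifted = values + offset
    bad = np.flatnonzero(~(shifted > 0))
    if bad.size:
        raise ValueError(
            f"non-positive values after offset at indices {bad[:10].tolist()}"
        )
    return np.log(shifted)


def broad_sense_heritability(
    panel: pd.DataFrame,
    group_col: str = "accession",
    value_col: str = "value",
) -> HeritabilityEstimate:
    """One-way random-effects ANOVA estimate of broad-sense heritability.

    sigma2_e is the within-group mean square; sigma2_g is
    (MS_between - MS_within) / n0 clamped at zero, with
    n0 = (N - sum(n_i^2)/N) / (k - 1) the standard unequal-n replicate
    coefficient (equal to the common replicate count for balanced panels).
    h2 is clamped to [0, 1].
    """
    groups = panel.groupby(group_col)[value_col]
    k = groups.ngroups
    if k < 2:
        raise ValueError("need at least 2 groups")
    n_i = groups.count().to_numpy(dtype=float)
    if np.all(n_i < 2):
        raise ValueError("residual variance inestimable: single replicate everywhere")
    n_tot = n_i.sum()
    grand = panel[value_col].mean()
    means = groups.mean().to_numpy()
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(
        ((panel[value_col] - groups.transform("mean")) ** 2).sum()
    )
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_tot - k)
    n0 = (n_tot - np.sum(n_i**2) / n_tot) / (k - 1)
    sigma2_g = max(0.0, (ms_between - ms_within) / n0)
    sigma2_e = ms_within
    denom = sigma2_g + sigma2_e
    h2 = 0.0 if denom == 0 else min(1.0, sigma2_g / denom)
    return HeritabilityEstimate(
        h2=h2,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        n_groups=int(k),
        reps=float(n0),
    )


def mutant_growth_ratio(mutant_rates, wt_rates) -> float:
    """Mean mutant growth divided by mean wild-type growth.

    May be negative: knockouts that yellow and die under cold stress show
    negative growth rates.
    """
    mutant_rates = np.asarray(mutant_rates, dtype=float)
    wt_rates = np.asarray(wt_rates, dtype=float)
    wt_mean = wt_rates.mean()
    if wt_mean == 0:
        raise ValueError("wild-type mean growth is zero")
    return float(mutant_rates.mean() / wt_mean)


def compare_mutant(
    mutant,
    wt,
    alpha: float = 0.05,
    m: int = 1,
    mutant_id: str = "mutant",
    wt_id: str = "Col-0",
    treatment: str = "cold",
    equal_var: bool = False,
) -> MutantComparison:
    """Two-sided two-sample t-test of mutant vs wild-type growth rates.

    Welch's unequal-variance test by default (``equal_var=True`` gives the
    pooled Student test).  Significance requires p < alpha / m, the
    Bonferroni-adjusted level for ``m`` comparisons in the experiment.  Two
    zero-variance samples with equal means yield p = 1 by convention.
    """
    mutant = np.asarray(mutant, dtype=float)
    wt = np.asarray(wt, dtype=float)
    if mutant.size < 2 or wt.size < 2:
        raise ValueError("each sample needs n >= 2")
    if mutant.var(ddof=1) == 0 and wt.var(ddof=1) == 0 and mutant.mean() == wt.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = sps.ttest_ind(mutant, wt, equal_var=equal_var)
        t_stat, p = float(t_stat), float(p)
    threshold = alpha / m
    return MutantComparison(
        mutant_id=mutant_id,
        wt_id=wt_id,
        treatment=treatment,
        ratio=mutant_growth_ratio(mutant, wt),
        t_stat=t_stat,
        p_value=p,
        alpha=alpha,
        m_comparisons=int(m),
        significant=bool(p < threshold),
    )


def pearson_validation(x, y):
    """Sample Pearson correlation with its two-sided t-based p-value.

    Used to validate the imaging platform against independent measurements
    (e.g. a second image-analysis program, fresh shoot weight, or
    single-plant versus group-of-plants areas).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
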