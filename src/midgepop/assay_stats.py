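"""Vital-rate estimation and assay summaries.

Fecundity is summarized per treatment as mean / sd / se over mating pairs.
Survival proportions are analysed on the angular (arcsine-square-root)
scale — the classical variance-stabilizing transform for binomial
proportions — with point estimates reported back on the raw scale.  Group
comparisons use t-tests (Welch by default) and one-way ANOVA with Tukey HSD
post-hoc adjustment via the studentized-range distribution.  Thermal
profiles are summarized by the maximum within-day temperature change and
the rate of change from the day's minimum to its maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import StudyBundle, ThermalProfile

__all__ = [
    "FecundityEstimate",
    "ProportionEstimate",
    "GroupComparison",
    "AnovaResult",
    "ThermalSummary",
    "angular_transform",
    "inverse_angular_transform",
    "estimate_fecundity",
    "estimate_survival",
    "two_sample_t",
    "oneway_anova_tukey",
    "summarize_thermal_profile",
    "estimates_table",
]


@dataclass(frozen=True)
class FecundityEstimate:
    treatment: str
    n: int
    mean: float
    sd: float
    se: float


@dataclass(frozen=True)
class ProportionEstimate:
    """Survival/viability estimate for one treatment.

    ``pooled_p`` pools counts across replicates; ``mean_transformed`` is the
    mean of per-replicate arcsin(sqrt(p_i)) values (radians) with its
    standard error, and ``back_transformed_p = sin^2(mean_transformed)``.
    """

    treatment: str
    n_replicates: int
    pooled_p: float
    mean_transformed: float
    se_transformed: float
    back_transformed_p: float


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    df: float
    p_value: float
    method: str  # "student" or "welch"


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    tukey_pairs: list  # (label_i, label_j, mean difference, adjusted p)


@dataclass(frozen=True)
class ThermalSummary:
    max_daily_change: float  # deg C
    min_to_max_rate: float  # deg C per hour


def angular_transform(p) -> float | np.ndarray:
    """Arcsine-square-root transform arcsin(sqrt(p)), radians on [0, pi/2]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def inverse_angular_transform(theta) -> float | np.ndarray:
    """Back-transform sin^2(theta); exact inverse of angular_transform."""
    theta = np.asarray(theta, dtype=float)
    out = np.sin(theta) ** 2
    return float(out) if out.ndim == 0 else out


def estimate_fecundity(
    table: pd.DataFrame, treatment: str, use_viable: bool = False
) -> FecundityEstimate:
    """Mean, sample sd (n-1) and se of eggs per pair for one treatment."""
    col = "viable_eggs" if use_viable else "eggs_laid"
    x = table.loc[table["treatment"] == treatment, col].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError(
            f"treatment {treatment!r} has {len(x)} rows; need >= 2 to estimate spread"
        )
    sd = float(np.std(x, ddof=1))
    return FecundityEstimate(
        treatment=treatment, n=len(x), mean=float(np.mean(x)),
        sd=sd, se=sd / math.sqrt(len(x)),
    )


def estimate_survival(table: pd.DataFrame, treatment: str) -> ProportionEstimate:
    """Pooled and angular-scale survival estimates for one treatment."""
    sub = table.loc[table["treatment"] == treatment]
    if len(sub) == 0:
        raise ValueError(f"no replicates for treatment {treatment!r}")
    alive = sub["n_alive"].to_numpy(dtype=float)
    start = sub["n_start"].to_numpy(dtype=float)
    if np.any(alive > start) or np.any(alive < 0):
        raise ValueError("replicates must satisfy 0 <= n_alive <= n_start")
    pooled = float(alive.sum() / start.sum())
    theta = angular_transform(alive / start)
    theta = np.atleast_1d(theta)
    mean_t = float(np.mean(theta))
    se_t = (
        float(np.std(theta, ddof=1) / math.sqrt(len(theta))) if len(theta) > 1 else 0.0
    )
    return ProportionEstimate(
        treatment=treatment, n_replicates=len(sub), pooled_p=pooled,
        mean_transformed=mean_t, se_transformed=se_t,
        back_transformed_p=inverse_angular_transform(mean_t),
    )


def two_sample_t(x, y, welch: bool = True) -> GroupComparison:
    """Two-sided two-sample t-test (Welch by default, Student optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs >= 2 values")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    if np.isnan(res.statistic):  # both samples constant and equal
        return GroupComparison(0.0, float(res.df), 1.0, "welch" if welch else "student")
    return GroupComparison(
        statistic=float(res.statistic), df=float(res.df),
        p_value=float(res.pvalue), method="welch" if welch else "student",
    )


def oneway_anova_tukey(groups: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc comparisons.

    ``groups`` maps labels to samples (each >= 2 values).  With exactly two
    groups the F statistic reduces to the square of the pooled-variance t
    statistic.  Adjusted p-values come from the studentized-range
    distribution.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups; use two_sample_t for a single pair")
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs >= 2 values")

    n_total = sum(len(s) for s in samples)
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(samples) - 1
    df_w = n_total - len(samples)
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else math.inf
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
    p = 1.0 if F == 0 else float(stats.f.sf(F, df_b, df_w))

    hsd = stats.tukey_hsd(*samples)
    pairs = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            pairs.append(
                (
                    labels[i],
                    labels[j],
                    float(samples[i].mean() - samples[j].mean()),
                    float(hsd.pvalue[i, j]),
                )
            )
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w,
                       p_value=p, tukey_pairs=pairs)


def summarize_thermal_profile(
    profile: ThermalProfile, series: str = "outside"
) -> ThermalSummary:
    """Daily temperature-change summary of one series of a thermal profile.

    Days are consecutive 24 h windows from the first timestamp.  For each
    complete day compute max - min; report the maximum over days, and the
    rate of change (deg C / h) between that day's minimum and maximum
    (elapsed time taken as the absolute gap between their timestamps).
    """
    if series not in ("inside", "outside"):
        raise ValueError("series must be 'inside' or 'outside'")
    t = profile.data["time_min"].to_numpy(dtype=float)
    y = profile.data[f"temp_{series}"].to_numpy(dtype=float)
    t = t - t[0]
    day_len = 24 * 60.0
    n_days = int(np.floor((t[-1] + profile.sampling_interval) / day_len))
    if n_days < 1:
        raise ValueError("profile must span at least one full day")

    best_change, best_rate = -np.inf, 0.0
    for d in range(n_days):
        mask = (t >= d * day_len) & (t < (d + 1) * day_len)
        td, yd = t[mask], y[mask]
        i_min, i_max = int(np.argmin(yd)), int(np.argmax(yd))
        change = float(yd[i_max] - yd[i_min])
        if change > best_change:
            best_change = change
            hours = abs(td[i_max] - td[i_min]) / 60.0
            best_rate = change / hours if hours > 0 else 0.0
    return ThermalSummary(max_daily_change=best_change, min_to_max_rate=best_rate)


def estimates_table(bundle: StudyBundle, use_viable: bool = False) -> pd.DataFrame:
    """Tidy table of all vital-rate estimates from a synthetic study bundle.

    Columns: ``treatment, quantity, estimate, se, n`` where quantity is
    ``fecundity_mean`` (eggs per pair) or ``survival_p`` (pooled proportion;
    se on the pooled binomial scale).
    """
    rows = []
    for tr in bundle.fecundity["treatment"].unique():
        est = estimate_fecundity(bundle.fecundity, tr, use_viable=use_viable)
        rows.append((tr, "fecundity_mean", est.mean, est.se, est.n))
    for tr in bundle.survival["treatment"].unique():
        est = estimate_survival(bundle.survival, tr)
        n_tot = int(bundle.survival.loc[bundle.survival["treatment"] == tr, "n_start"].sum())
        se = math.sqrt(est.pooled_p * (1 - est.pooled_p) / n_tot)
        rows.append((tr, "survival_p", est.pooled_p, se, est.n_replicates))
    return pd.DataFrame(rows, columns=["treatment", "quantity", "estimate", "se", "n"])
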