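"""Universal growth-law fitting and the replicate statistics used throughout.

The universal growth law relates a cell's volume at birth to its doubling
time,

    V_b = (1/2) V_i · 2^((C+D)/T_d),

where ``V_i`` is the cell volume per replication origin at initiation of
chromosome replication and ``C+D`` the time from initiation to the division
that segregates the corresponding origins.  Taking log2 linearizes the model:

    log2 V_b = log2(V_i/2) + (C+D) · (1/T_d),

so ``(V_i, C+D)`` are recovered by ordinary least squares of log2(V_b) on
1/T_d; parameter standard errors follow from the OLS covariance by the delta
method.  The module also provides the summary statistics used for replicate
experiments: means over replicates with the s.e.m. computed from the
*replicate means* (never from pooled single cells), Welch's t-test, and
Pearson correlation with a straight-line fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "GrowthLawFit",
    "ReplicateSummary",
    "LinearFit",
    "WelchResult",
    "fit_growth_law",
    "predict_birth_volume",
    "replicate_statistics",
    "welch_t_test",
    "pearson_and_line",
]


@dataclass
class GrowthLawFit:
    v_i: float            # μm³, volume at initiation of replication
    cd_period: float      # min, C+D
    v_i_se: float
    cd_period_se: float
    r_squared: float      # in log2 space
    rmse_log2: float
    n: int


@dataclass
class ReplicateSummary:
    group: str
    replicate_means: dict
    grand_mean: float
    sem: float            # NaN (flagged) for a single replicate
    n_replicates: int
    flags: list = field(default_factory=list)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    pearson_r: float
    slope_se: float
    intercept_se: float
    n: int


@dataclass
class WelchResult:
    statistic: float
    df: float
    p_value: float


def fit_growth_law(birth_volumes, doubling_times) -> GrowthLawFit:
    """Fit (V_i, C+D) by OLS of log2(V_b) on 1/T_d.

    Requires at least 3 strictly positive samples and at least two distinct
    doubling times.  Unweighted least squares; the intercept maps back as
    V_i = 2^(intercept + 1) and its standard error follows by the delta
    method, se(V_i) = V_i · ln 2 · se(intercept).
    """
    vb = np.asarray(birth_volumes, dtype=float)
    td = np.asarray(doubling_times, dtype=float)
    if vb.shape != td.shape or vb.ndim != 1:
        raise ValueError("birth_volumes and doubling_times must be 1D of equal length")
    if vb.size < 3:
        raise ValueError("growth-law fit requires at least 3 samples")
    if np.any(vb <= 0) or np.any(td <= 0):
        raise ValueError("birth volumes and doubling times must be strictly positive")
    inv_td = 1.0 / td
    if np.ptp(inv_td) == 0:
        raise ValueError("degenerate design: all doubling times identical")
    res = scipy.stats.linregress(inv_td, np.log2(vb))
    v_i = 2.0 ** (res.intercept + 1.0)
    resid = np.log2(vb) - (res.intercept + res.slope * inv_td)
    return GrowthLawFit(
        v_i=float(v_i),
        cd_period=float(res.slope),
        v_i_se=float(v_i * math.log(2.0) * res.intercept_stderr),
        cd_period_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
        rmse_log2=float(np.sqrt(np.mean(resid**2))),
        n=int(vb.size),
    )


def predict_birth_volume(fit: GrowthLawFit, td: float) -> float:
    """V_b = (1/2) V_i 2^((C+D)/T_d) for a doubling time ``td`` in minutes."""
    if td <= 0:
        raise ValueError("doubling time must be positive")
    return 0.5 * fit.v_i * 2.0 ** (fit.cd_period / td)


def replicate_statistics(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    replicate: str = "replicate",
) -> list[ReplicateSummary]:
    """Per-group replicate averages with the s.e.m. over replicate means.

    ``table`` is tidy: one row per measured cell, with columns naming the
    quantity/condition (``group``), the replicate id and the value.  Within
    each group the replicate means are computed first; the grand mean is
    their unweighted average and the s.e.m. is sd(replicate means)/√n_rep,
    so unequal cell counts per replicate do not reweight the result.  A
    single replicate yields sem = NaN with a flag.
    """
    if table.empty:
        raise ValueError("replicate table is empty")
    out: list[ReplicateSummary] = []
    for name, sub in table.groupby(group, sort=True):
        means = sub.groupby(replicate)[value].mean()
        n_rep = len(means)
        flags = []
        if n_rep < 2:
            sem = float("nan")
            flags.append("single replicate: s.e.m. undefined")
        else:
            sem = float(means.std(ddof=1) / math.sqrt(n_rep))
        out.append(
            ReplicateSummary(
                group=str(name),
                replicate_means=means.to_dict(),
                grand_mean=float(means.mean()),
                sem=sem,
                n_replicates=n_rep,
                flags=flags,
            )
        )
    return out


def welch_t_test(sample_a, sample_b) -> WelchResult:
    """Welch's unequal-variance t-test (two-sided), with Welch–Satterthwaite df."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples have zero variance; t statistic undefined")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(statistic=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))


def pearson_and_line(x, y) -> LinearFit:
    """Least-squares straight line y = slope·x + intercept with Pearson R."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope undefined")
    res = scipy.stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n=int(x.size),
    )
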