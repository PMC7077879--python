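"""Micro-environmental variance of life span and variance-heterogeneity tests.

The "variance phenotype" of an inbred genotype is the natural log of its
within-line standard deviation, ``ln sigma_eps = 0.5 * ln S^2``.  To make
that phenotype replicable, the replicate vials of each (line, sex,
temperature) cell are split into two groups (vials 1-12 vs 13-24 in the
24-vial design) and the sample variance is computed by pooling all
individuals of a group, so it includes between-vial as well as
within-vial variation.  The resulting table can be fed straight back
into the variance-component machinery with ``ln_sigma_eps`` as the
response, which is how the heritability of micro-environmental variance
is estimated.

Heterogeneity of within-line variances is tested per sex x temperature
with the Brown-Forsythe test (one-way ANOVA of ``|y - median|``) and
Cochran's C test (largest variance over the sum of variances, p-value
from the classical F-quantile relation with the average group size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarHetResult",
    "split_replicate_groups",
    "ln_sigma_eps",
    "brown_forsythe",
    "brown_forsythe_by_context",
    "cochran_c",
    "cochran_c_by_context",
]


@dataclass(frozen=True)
class VarHetResult:
    """One variance-heterogeneity test in one grouping context."""

    test: str
    statistic: float
    df: tuple
    p: float
    context: tuple = ()
    k: int = 0
    average_n: float = np.nan


def split_replicate_groups(
    data: pd.DataFrame, split_point: int | None = None
) -> pd.DataFrame:
    """Assign each vial to replicate group 1 or 2 within its cell.

    Vials are ordered by their id within each (line, sex, temperature)
    cell; the first ``split_point`` vials form group 1 and the rest
    group 2 (default: an even half/half split, e.g. 1-12 / 13-24 for 24
    vials, 1-24 / 25-48 for 48).  Cells whose vial count does not admit
    the split (fewer than 2 vials on either side) are dropped with a
    warning.

    Returns a copy of ``data`` with a ``replicate_group`` column.
    """
    out = []
    dropped = []
    for key, cell in data.groupby(["line", "sex", "temperature"], observed=True):
        vials = np.sort(cell["vial"].unique())
        sp = split_point if split_point is not None else len(vials) // 2
        if sp < 1 or len(vials) - sp < 1 or len(vials) < 2 or (
            split_point is None and len(vials) % 2 != 0
        ):
            dropped.append(key)
            continue
        grp1 = set(vials[:sp])
        cell = cell.copy()
        cell["replicate_group"] = np.where(cell["vial"].isin(grp1), 1, 2)
        out.append(cell)
    if dropped:
        warnings.warn(
            f"{len(dropped)} cell(s) had no valid replicate split and were "
            f"excluded (first: {dropped[0]})"
        )
    if not out:
        raise ValueError("no cell admits the requested replicate split")
    return pd.concat(out, ignore_index=True)


def ln_sigma_eps(
    data: pd.DataFrame, response: str = "lifespan_days"
) -> pd.DataFrame:
    """Per-group within-line variance and its log-SD transform.

    ``data`` must carry a ``replicate_group`` column (see
    :func:`split_replicate_groups`).  Individuals are pooled across the
    group's vials and the unbiased (n-1) sample variance is taken.
    Groups with n < 2 or zero variance cannot yield ``ln sigma_eps``
    and are excluded with a warning.
    """
    g = data.groupby(
        ["line", "sex", "temperature", "replicate_group"], observed=True
    )[response]
    tab = g.agg(n="count", s2=lambda v: v.var(ddof=1)).reset_index()
    bad = (tab["n"] < 2) | ~(tab["s2"] > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} replicate group(s) with n < 2 or zero variance "
            "excluded from the ln sigma_eps table"
        )
    tab = tab[~bad].copy()
    tab["ln_sigma_eps"] = 0.5 * np.log(tab["s2"])
    return tab.reset_index(drop=True)


def brown_forsythe(groups: list[np.ndarray]) -> VarHetResult:
    """Brown-Forsythe test across groups (lines) of raw observations.

    Equivalent to a one-way ANOVA of ``z_ij = |y_ij - median_j|`` with
    ``(k - 1, N - k)`` degrees of freedom.  Groups with fewer than 2
    observations are excluded with a warning.
    """
    clean = [np.asarray(g, float) for g in groups if len(g) >= 2]
    if len(clean) < len(groups):
        warnings.warn(
            f"{len(groups) - len(clean)} group(s) with n < 2 excluded from "
            "the Brown-Forsythe test"
        )
    k = len(clean)
    if k < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    N = sum(len(g) for g in clean)
    if all(np.ptp(g) == 0 for g in clean):
        # identical values within every group: no dispersion to compare
        return VarHetResult("brown_forsythe", 0.0, (k - 1, N - k), 1.0, k=k,
                            average_n=N / k)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.levene(*clean, center="median")
    if not np.isfinite(stat):
        # zero within-group dispersion of |y - median| but between-group
        # differences: heterogeneity is extreme
        stat, p = np.inf, 0.0
    return VarHetResult(
        "brown_forsythe", float(stat), (k - 1, N - k), float(p), k=k,
        average_n=N / k,
    )


def brown_forsythe_by_context(
    data: pd.DataFrame, response: str = "lifespan_days"
) -> pd.DataFrame:
    """Brown-Forsythe heterogeneity of within-line variances per sex x temperature."""
    rows = []
    for (sex, temp), sub in data.groupby(["sex", "temperature"], observed=True):
        groups = [v.to_numpy() for _, v in sub.groupby("line", observed=True)[response]]
        r = brown_forsythe(groups)
        rows.append(
            {
                "sex": sex, "temperature": temp, "df1": r.df[0], "df2": r.df[1],
                "F": r.statistic, "p": r.p, "k": r.k,
            }
        )
    return pd.DataFrame(rows)


def cochran_c(variances, ns) -> VarHetResult:
    """Cochran's C test for an outlying variance among k group variances.

    ``C = max_j S2_j / sum_i S2_i``; the p-value inverts the classical
    critical-value relation ``C_crit = 1 / (1 + (k - 1) / F_{alpha/k}(nu,
    (k - 1) nu))`` with ``nu = average n - 1``, giving the closed form
    ``p = k * P(F_{nu, (k-1) nu} > (k - 1) C / (1 - C))`` clipped to [0, 1].
    """
    s2 = np.asarray(variances, float)
    n = np.asarray(ns, float)
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    k = len(s2)
    if k < 2:
        raise ValueError("need at least 2 variances")
    tot = s2.sum()
    if tot <= 0:
        return VarHetResult("cochran_c", np.nan, (np.nan, np.nan), np.nan, k=k)
    C = float(s2.max() / tot)
    nu = float(n.mean()) - 1.0
    if C >= 1.0:
        p = 0.0
    else:
        f_obs = (k - 1) * C / (1.0 - C)
        p = float(min(1.0, k * stats.f.sf(f_obs, nu, (k - 1) * nu)))
    return VarHetResult(
        "cochran_c", C, (nu, (k - 1) * nu), p, k=k, average_n=float(n.mean())
    )


def cochran_c_by_context(
    data: pd.DataFrame, response: str = "lifespan_days"
) -> pd.DataFrame:
    """Cochran's C heterogeneity of within-line variances per sex x temperature."""
    rows = []
    for (sex, temp), sub in data.groupby(["sex", "temperature"], observed=True):
        g = sub.groupby("line", observed=True)[response]
        tab = g.agg(n="count", s2=lambda v: v.var(ddof=1))
        tab = tab[tab["n"] >= 2]
        r = cochran_c(tab["s2"].to_numpy(), tab["n"].to_numpy())
        rows.append(
            {
                "sex": sex, "temperature": temp, "average_n": r.average_n,
                "k": r.k, "C": r.statistic, "p": r.p,
            }
        )
    return pd.DataFrame(rows)
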