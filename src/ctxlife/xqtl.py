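"""Extreme-QTL statistics for pooled sequencing of long-lived vs control flies.

Pool allele frequencies are estimated as ``f_hat = alt / (ref + alt)``
with a two-stage binomial sampling variance: first 96 diploid flies
(192 chromosomes) are drawn into the pool, then reads are drawn from
the pooled DNA, giving

    Var(f_hat) = f~ (1 - f~) * (1 / (2 * pool_size) + 1 / reads)

where ``f~ = (alt + 0.5) / (reads + 1)`` is a moderated frequency used
inside the variance only, so fixed counts never yield a zero variance
(the frequency difference itself uses the unmoderated estimate).

The within-context test compares the long-lived (H) and control (C)
pools: ``delta_f = mean over replicates of (f_H - f_C)``, with
model-based variance summed over the contributing pools divided by the
squared replicate count, and ``Z = delta_f / sqrt(Var)`` referred to
the standard normal.  Cross-context tests difference two independent
within-context statistics (across sexes within a temperature, across
temperature pairs within a sex, or the sex-by-temperature double
difference).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "estimate_pool_frequency",
    "z_test_hc",
    "cross_context_z",
    "cross_context_contrasts",
    "antagonism_summary",
    "delta_f_correlations",
]


def estimate_pool_frequency(ref_reads, alt_reads, pool_size=96):
    """Pool allele-frequency estimate and its two-stage sampling variance.

    Accepts scalars or arrays; raises on zero total reads.
    """
    ref = np.asarray(ref_reads, float)
    alt = np.asarray(alt_reads, float)
    reads = ref + alt
    if np.any(reads <= 0):
        raise ValueError("pool has zero reads at some variant")
    f = alt / reads
    fmod = (alt + 0.5) / (reads + 1.0)
    var = fmod * (1.0 - fmod) * (1.0 / (2.0 * np.asarray(pool_size, float)) + 1.0 / reads)
    return f, var


def z_test_hc(
    counts: pd.DataFrame, report_p: float = 1e-7
) -> pd.DataFrame:
    """Within-context Z tests of f_H - f_C for every variant.

    ``counts`` is a long pooled-counts table (columns ``variant_id``,
    ``sex``, ``temperature``, ``replicate``, ``pool_type`` in {H, C},
    ``ref_reads``, ``alt_reads``, ``pool_size``).  Returns one row per
    variant x (sex, temperature) with the replicate-averaged frequency
    difference, its model variance, Z, two-sided normal p, a reporting
    flag at ``p < report_p`` and a Bonferroni annotation based on the
    analysed variant count.  The empirical between-replicate variance of
    delta_f is carried along as a diagnostic only.
    """
    df = counts.copy()
    f, var = estimate_pool_frequency(
        df["ref_reads"].to_numpy(), df["alt_reads"].to_numpy(),
        df["pool_size"].to_numpy(),
    )
    df["f_hat"] = f
    df["var_f"] = var

    wide = df.pivot_table(
        index=["variant_id", "chrom", "pos", "sex", "temperature"],
        columns=["pool_type", "replicate"],
        values=["f_hat", "var_f"],
        observed=True,
    )
    reps = sorted({r for (_, t, r) in wide.columns if t == "H"})
    for t in ("H", "C"):
        for r in reps:
            if ("f_hat", t, r) not in wide.columns:
                raise ValueError(f"missing {t} pool for replicate {r} in some context")
    R = len(reps)
    dfs = np.column_stack(
        [wide[("f_hat", "H", r)] - wide[("f_hat", "C", r)] for r in reps]
    )
    vars_ = sum(
        wide[("var_f", "H", r)].to_numpy() + wide[("var_f", "C", r)].to_numpy()
        for r in reps
    ) / R**2
    delta = dfs.mean(axis=1)
    z = delta / np.sqrt(vars_)
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = wide.index.to_frame(index=False)
    out["n_replicates"] = R
    out["delta_f"] = delta
    out["var_delta_f"] = vars_
    out["between_rep_var"] = dfs.var(axis=1, ddof=1) if R > 1 else np.nan
    out["Z"] = z
    out["p"] = p
    out["significant"] = p < report_p
    n_variants = out["variant_id"].nunique()
    out["bonferroni_alpha"] = 0.05 / max(n_variants, 1)
    out["bonferroni_significant"] = p < out["bonferroni_alpha"]
    for r, col in zip(reps, dfs.T):
        out[f"delta_f_rep{r}"] = col
    return out


def _context_frame(stats_df: pd.DataFrame, sex=None, temperature=None) -> pd.DataFrame:
    sub = stats_df
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    if temperature is not None:
        sub = sub[sub["temperature"] == temperature]
    return sub.set_index("variant_id")


def cross_context_z(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    label: str = "contrast",
    report_p: float = 1e-7,
) -> pd.DataFrame:
    """Z test of the difference in delta_f between two independent contexts.

    Both inputs are within-context tables from :func:`z_test_hc`
    restricted to a single context; variants must coincide.
    """
    a = stats_a.set_index("variant_id") if stats_a.index.name != "variant_id" else stats_a
    b = stats_b.set_index("variant_id") if stats_b.index.name != "variant_id" else stats_b
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("contexts share no variants")
    a, b = a.loc[common], b.loc[common]
    dd = a["delta_f"].to_numpy() - b["delta_f"].to_numpy()
    var = a["var_delta_f"].to_numpy() + b["var_delta_f"].to_numpy()
    z = dd / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "variant_id": common,
            "contrast": label,
            "ddelta_f": dd,
            "var": var,
            "Z": z,
            "p": p,
            "significant": p < report_p,
        }
    )
    return out


def cross_context_contrasts(
    within: pd.DataFrame, report_p: float = 1e-7
) -> pd.DataFrame:
    """All standard cross-context contrasts from the within-context table.

    Emits sex contrasts within each temperature (M - F), temperature-pair
    contrasts within each sex (higher - lower), and sex-by-temperature
    double differences.
    """
    sexes = sorted(within["sex"].unique())
    temps = sorted(within["temperature"].unique())
    frames = []
    if len(sexes) == 2:
        f_lab, m_lab = sexes  # alphabetical: F before M
        for t in temps:
            frames.append(
                cross_context_z(
                    _context_frame(within, m_lab, t),
                    _context_frame(within, f_lab, t),
                    label=f"sexdiff@{t}",
                    report_p=report_p,
                )
            )
    for s in sexes:
        for lo, hi in combinations(temps, 2):
            frames.append(
                cross_context_z(
                    _context_frame(within, s, hi),
                    _context_frame(within, s, lo),
                    label=f"{s}:{hi}-{lo}",
                    report_p=report_p,
                )
            )
    if len(sexes) == 2:
        f_lab, m_lab = sexes
        for lo, hi in combinations(temps, 2):
            a = cross_context_z(
                _context_frame(within, m_lab, hi), _context_frame(within, m_lab, lo),
                label="tmp", report_p=report_p,
            ).set_index("variant_id")
            b = cross_context_z(
                _context_frame(within, f_lab, hi), _context_frame(within, f_lab, lo),
                label="tmp", report_p=report_p,
            ).set_index("variant_id")
            dd = a["ddelta_f"] - b["ddelta_f"]
            var = a["var"] + b["var"]
            z = dd / np.sqrt(var)
            p = 2.0 * stats.norm.sf(np.abs(z))
            frames.append(
                pd.DataFrame(
                    {
                        "variant_id": a.index,
                        "contrast": f"sexdiff:{hi}-{lo}",
                        "ddelta_f": dd.to_numpy(),
                        "var": var.to_numpy(),
                        "Z": z,
                        "p": p,
                        "significant": p < report_p,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def delta_f_correlations(within: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Cross-context correlation matrix of delta_f over all variants."""
    wide = within.pivot_table(
        index="variant_id", columns=["sex", "temperature"], values="delta_f",
        observed=True,
    )
    wide.columns = [f"{s}@{t}" for s, t in wide.columns]
    return wide.corr(method=method)


def antagonism_summary(
    within: pd.DataFrame,
    gene_map: pd.DataFrame | None = None,
    p_threshold: float = 1e-7,
) -> dict:
    """Variant- and gene-level context-dependence summaries.

    Per variant (over the sex x temperature analyses): ``ns``,
    ``context-specific`` (significant in exactly one), ``antagonistic``
    (significant in several with opposite delta_f signs) or
    ``concordant``.  With a ``gene_map`` (columns ``variant_id``,
    ``gene_id``), genes are scanned for pairs of distinct significant
    SNPs with opposite delta_f signs in the same context, across
    temperatures within a sex, across sexes within a temperature, and
    across both.
    """
    sig = within[within["p"] < p_threshold]
    per_variant = []
    for vid, sub in within.groupby("variant_id", observed=True):
        s = sub[sub["p"] < p_threshold]
        if len(s) == 0:
            lab = "ns"
        elif len(s) == 1:
            lab = "context-specific"
        else:
            signs = np.sign(s["delta_f"].to_numpy())
            lab = "antagonistic" if signs.max() > 0 and signs.min() < 0 else "concordant"
        per_variant.append(
            {"variant_id": vid, "n_significant": len(s), "label": lab}
        )
    variant_table = pd.DataFrame(per_variant)

    gene_table = None
    if gene_map is not None:
        hits = sig.merge(gene_map, on="variant_id")
        rows = []
        for gene, g in hits.groupby("gene_id", observed=True):
            counts = {
                "same_context": 0, "across_temp_within_sex": 0,
                "across_sex_within_temp": 0, "across_both": 0,
            }
            recs = g[["variant_id", "sex", "temperature", "delta_f"]].to_numpy(object)
            for i in range(len(recs)):
                for j in range(i + 1, len(recs)):
                    vi, si, ti, di = recs[i]
                    vj, sj, tj, dj = recs[j]
                    if vi == vj or di * dj >= 0:
                        continue
                    if si == sj and ti == tj:
                        counts["same_context"] += 1
                    elif si == sj:
                        counts["across_temp_within_sex"] += 1
                    elif ti == tj:
                        counts["across_sex_within_temp"] += 1
                    else:
                        counts["across_both"] += 1
            if any(counts.values()):
                rows.append({"gene_id": gene, **counts})
        gene_table = pd.DataFrame(
            rows, columns=["gene_id", "same_context", "across_temp_within_sex",
                           "across_sex_within_temp", "across_both"],
        )
    return {
        "variants": variant_table,
        "genes": gene_table,
        "delta_f_correlation": delta_f_correlations(within),
    }
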