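"""Mixed-model factorial ANOVA with a fixed genotype contrast.

For functional assessment of a candidate gene, life span of an
RNAi-knockdown genotype and its co-isogenic control is partitioned as

    Y = mu + G + S + T + GxS + GxT + SxT + GxSxT
        + Rep(GxT) + SxRep(GxT) + eps

with genotype, sex and temperature fixed and the replicate-vial terms
random.  For the balanced designs this assay uses, the exact
mixed-model tests are mean-square ratios chosen from the expected mean
squares: terms not involving sex are tested against ``Rep(GxT)``,
terms involving sex against ``SxRep(GxT)``, ``Rep(GxT)`` against
``SxRep(GxT)`` and ``SxRep(GxT)`` against the within-vial error.
Reduced models by sex and/or temperature use the same rules with the
absent factors removed.  Unbalanced data are handled with the same
moment formulas and flagged as approximate.
"""

from __future__ import annotations

import warnings
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fixed_effect_anova"]


def _subsets(factors):
    return chain.from_iterable(combinations(factors, r) for r in range(1, len(factors) + 1))


def fixed_effect_anova(
    data: pd.DataFrame,
    response: str = "lifespan_days",
    genotype_col: str = "genotype",
    control: str | None = None,
    use_sex: bool = True,
    use_temperature: bool = True,
) -> pd.DataFrame:
    """ANOVA table (term, df, SS, MS, F, p) for the genotype-contrast model.

    ``data`` needs columns ``genotype_col``, ``vial``, the response,
    plus ``sex`` / ``temperature`` when used.  ``control`` (optional)
    names the co-isogenic control genotype and must be present.
    """
    df = data.dropna(subset=[response]).copy()
    levels_g = df[genotype_col].unique()
    if len(levels_g) < 2:
        raise ValueError("need at least 2 genotype levels")
    if control is not None and control not in set(levels_g):
        raise ValueError(f"control genotype {control!r} missing from the data")

    factors = [genotype_col]
    if use_sex:
        if "sex" not in df.columns:
            raise ValueError("use_sex=True but no 'sex' column")
        factors.append("sex")
    if use_temperature:
        if "temperature" not in df.columns:
            raise ValueError("use_temperature=True but no 'temperature' column")
        factors.append("temperature")
    if "vial" not in df.columns:
        raise ValueError("replicate vials must be identified by a 'vial' column")

    y = df[response].to_numpy(float)
    N = len(y)
    grand = y.mean()

    # vial nested in genotype x temperature
    nest = [genotype_col] + (["temperature"] if use_temperature else [])
    df["_vial"] = list(zip(*[df[c] for c in nest + ["vial"]]))
    finest = ["_vial", "sex"] if use_sex else ["_vial"]

    counts = df.groupby(finest, observed=True)[response].count()
    balanced = counts.nunique() == 1
    if not balanced:
        warnings.warn("unbalanced design: moment-based F tests are approximate")

    def means(cols):
        if not cols:
            return grand
        return df.groupby(list(cols), observed=True)[response].mean()

    lvl = {f: df[f].nunique() for f in factors}

    rows = []
    # crossed fixed terms by inclusion-exclusion of subset means
    cell_means = {(): grand}
    for sub in _subsets(factors):
        cell_means[sub] = means(sub)
    finest_fixed = tuple(factors)
    cells = df.groupby(list(finest_fixed), observed=True)[response].agg(["mean", "count"])
    for term in _subsets(factors):
        eff = pd.Series(0.0, index=cells.index)
        for sub in chain([()], _subsets(term)):
            sign = (-1) ** (len(term) - len(sub))
            if sub == ():
                eff += sign * grand
            else:
                m = cell_means[sub]
                key = cells.index.to_frame()[list(sub)]
                vals = m.loc[pd.MultiIndex.from_frame(key)] if len(sub) > 1 else m.loc[key.iloc[:, 0]]
                eff += sign * vals.to_numpy()
        ss = float((cells["count"] * eff**2).sum())
        ddf = int(np.prod([lvl[f] - 1 for f in term]))
        rows.append({"term": ":".join(term), "df": ddf, "ss": ss, "_has_sex": "sex" in term})

    # Rep(GxT): vial means about their genotype x temperature cell mean
    vial_stats = df.groupby("_vial", observed=True)[response].agg(["mean", "count"])
    gt_mean = means(tuple(nest))
    gt_of_vial = pd.MultiIndex.from_tuples(
        [v[:-1] for v in vial_stats.index]
    ) if len(nest) > 1 else pd.Index([v[0] for v in vial_stats.index])
    gt_vals = gt_mean.loc[gt_of_vial].to_numpy()
    ss_rep = float((vial_stats["count"] * (vial_stats["mean"].to_numpy() - gt_vals) ** 2).sum())
    n_gt = int(np.prod([lvl[f] for f in nest]))
    df_rep = len(vial_stats) - n_gt
    rep_name = f"Rep({'x'.join(nest)})"
    rows.append({"term": rep_name, "df": df_rep, "ss": ss_rep, "_has_sex": False})

    if use_sex:
        vs = df.groupby(["_vial", "sex"], observed=True)[response].agg(["mean", "count"])
        gts_mean = means(tuple(nest + ["sex"]))
        idx = vs.index.to_frame()
        vial_of = idx["_vial"]
        gts_key = pd.MultiIndex.from_tuples(
            [(*v[:-1], s) for v, s in zip(idx["_vial"], idx["sex"])]
        )
        dev = (
            vs["mean"].to_numpy()
            - vial_stats["mean"].loc[vial_of].to_numpy()
            - gts_mean.loc[gts_key].to_numpy()
            + gt_mean.loc[
                pd.MultiIndex.from_tuples([v[:-1] for v in idx["_vial"]])
                if len(nest) > 1 else pd.Index([v[0] for v in idx["_vial"]])
            ].to_numpy()
        )
        ss_srep = float((vs["count"] * dev**2).sum())
        df_srep = df_rep * (lvl["sex"] - 1)
        rows.append({"term": f"sex:{rep_name}", "df": df_srep, "ss": ss_srep, "_has_sex": True})
        fin = vs
    else:
        fin = vial_stats

    ss_tot = float(((y - grand) ** 2).sum())
    ss_within = ss_tot - sum(r["ss"] for r in rows)
    df_within = N - len(fin)
    rows.append({"term": "within", "df": df_within, "ss": max(ss_within, 0.0),
                 "_has_sex": False})

    tab = pd.DataFrame(rows)
    tab["ms"] = tab["ss"] / tab["df"].replace(0, np.nan)

    ms = tab.set_index("term")["ms"]
    dfx = tab.set_index("term")["df"]
    srep_name = f"sex:{rep_name}" if use_sex else None

    def error_for(row):
        t = row["term"]
        if t == "within":
            return None
        if t == rep_name:
            return srep_name if use_sex else "within"
        if t == srep_name:
            return "within"
        return srep_name if (use_sex and row["_has_sex"]) else rep_name

    Fs, ps, errs = [], [], []
    for _, row in tab.iterrows():
        err = error_for(row)
        if err is None or not np.isfinite(ms.get(err, np.nan)) or ms[err] <= 0:
            Fs.append(np.nan); ps.append(np.nan); errs.append(err or "")
            continue
        F = row["ms"] / ms[err]
        p = stats.f.sf(F, row["df"], dfx[err])
        Fs.append(F); ps.append(p); errs.append(err)
    tab["F"] = Fs
    tab["p"] = ps
    tab["error_term"] = errs
    tab["balanced"] = balanced
    return tab.drop(columns=["_has_sex"])
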