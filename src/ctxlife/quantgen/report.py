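"""Report generator for the standard quantitative-genetic summary tables.

Produces the three classic views of a replicated two-sex,
multi-temperature panel:

* per-temperature genetic parameters (variance components, H2, CVs),
* the genotype-by-sex interaction decomposed into rank-order-change and
  scale-change terms within each temperature, and
* the genotype-by-temperature interaction decomposed likewise for each
  temperature pair within each sex.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .derived import decompose_interaction, derive_genetics
from .model import ModelSpec, fit_variance_components

__all__ = ["panel_report"]


def _sex_means(data: pd.DataFrame, response: str, temp) -> dict:
    sub = data[data["temperature"] == temp]
    return sub.groupby("sex", observed=True)[response].mean().to_dict()


def panel_report(
    data: pd.DataFrame,
    response: str = "lifespan_days",
    vial_terms: bool | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit the reduced models and assemble the three summary tables.

    ``vial_terms`` defaults to True when a ``vial`` column is present
    (raw life span data) and False otherwise (e.g. the replicate-group
    ln sigma_eps table).
    """
    if vial_terms is None:
        vial_terms = "vial" in data.columns
    temps = sorted(data["temperature"].unique())
    sexes = sorted(data["sex"].unique())

    # per-sex, per-temperature among-line SDs from single-context fits
    sigma_l: dict[tuple, float] = {}
    for s in sexes:
        for t in temps:
            sub = data[(data["sex"] == s) & (data["temperature"] == t)]
            res = fit_variance_components(
                sub, ModelSpec.single_context(response, vial_terms=vial_terms)
            )
            sigma_l[(s, t)] = float(np.sqrt(res.components["line"]))

    # Table-1 style: two-sex fits per temperature
    t1_rows, t2_rows = [], []
    for t in temps:
        sub = data[data["temperature"] == t]
        res = fit_variance_components(
            sub, ModelSpec.by_temperature(response, vial_terms=vial_terms)
        )
        means = _sex_means(data, response, t)
        der = derive_genetics(res.components, means)
        t1_rows.append(
            {
                "temperature": t,
                **{f"mean_{s}": means.get(s, np.nan) for s in sexes},
                "sigma2_L": res.components["line"],
                "sigma2_SL": res.components["line:sex"],
                "sigma2_G": der.sigma2_G,
                "sigma2_eps": res.components["residual"],
                "sigma2_P": der.sigma2_G + der.sigma2_E,
                "H2": der.H2,
                "CV_G": der.CV_G,
                "CV_E": der.CV_E,
            }
        )
        s_f, s_m = sigma_l[(sexes[0], t)], sigma_l[(sexes[1], t)]
        dec = decompose_interaction(s_f, s_m, der.r_GMF, *map(str, sexes))
        t2_rows.append(
            {
                "temperature": t,
                "r_GMF": der.r_GMF,
                "sigma_LF": s_f,
                "sigma_LM": s_m,
                "rank_term": dec.rank_term,
                "scale_term": dec.scale_term,
                "pct_rank": dec.pct_rank,
            }
        )

    # Table-3 style: per-sex fits for each temperature pair
    t3_rows = []
    for s in sexes:
        for lo, hi in combinations(temps, 2):
            sub = data[(data["sex"] == s) & (data["temperature"].isin([lo, hi]))]
            res = fit_variance_components(
                sub, ModelSpec.by_sex(response, vial_terms=vial_terms)
            )
            der = derive_genetics(res.components)
            s_i, s_j = sigma_l[(s, lo)], sigma_l[(s, hi)]
            dec = decompose_interaction(s_i, s_j, der.r_GT, str(lo), str(hi))
            t3_rows.append(
                {
                    "sex": s,
                    "pair": f"{lo},{hi}",
                    "r_GT": der.r_GT,
                    "sigma_Li": s_i,
                    "sigma_Lj": s_j,
                    "rank_term": dec.rank_term,
                    "scale_term": dec.scale_term,
                    "pct_rank": dec.pct_rank,
                }
            )

    return {
        "table1": pd.DataFrame(t1_rows),
        "table2": pd.DataFrame(t2_rows),
        "table3": pd.DataFrame(t3_rows),
    }
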