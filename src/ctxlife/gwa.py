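"""Line-mean genome-wide association for life span and its variance phenotype.

Inbred-line GWA works on line means: per line and context the trait is
averaged, derived contrast phenotypes are formed (sex average and sex
difference M - F per temperature, temperature-pair differences per sex
oriented higher - lower, and the sex difference of each temperature
difference, which captures variant-by-sex-by-temperature interaction),
the phenotype is residualised on fixed covariates (Wolbachia infection
status, inversion karyotypes, optionally leading genotype principal
components as a light-weight relatedness adjustment), and each common
variant (minor allele frequency above ``maf_min``, default 0.05) is
tested by simple linear regression of the residual on minor-allele
dosage (0/2 in inbred lines).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "derive_phenotypes",
    "marker_scan",
    "scan_phenotypes",
    "classify_effects",
    "effect_correlations",
    "ld_r2",
]


@dataclass
class GenotypeMatrix:
    """Lines x variants dosage matrix for inbred lines.

    Dosages are 0 or 2 (homozygous inbred lines); heterozygous or
    missing calls are NaN and are dropped per variant.  ``meta`` holds
    variant metadata (``variant_id``, ``chrom``, ``pos``, ``ref``,
    ``alt``) aligned with the dosage columns.
    """

    dosage: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if list(self.meta["variant_id"]) != list(self.dosage.columns):
            raise ValueError("meta rows must align with dosage columns")
        vals = self.dosage.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 2.0))
        if not ok.all():
            raise ValueError("inbred dosages must be 0, 2 or missing")

    @property
    def lines(self):
        return self.dosage.index

    def maf(self) -> pd.Series:
        """Minor-allele frequency per variant over non-missing lines."""
        f = self.dosage.mean(axis=0, skipna=True) / 2.0
        return np.minimum(f, 1.0 - f)


def _cell_means(data: pd.DataFrame, response: str) -> pd.DataFrame:
    if "replicate_group" in data.columns and response == "ln_sigma_eps":
        # micro-environmental table: average the two replicate groups
        g = data.groupby(["line", "sex", "temperature"], observed=True)[response].mean()
    else:
        g = data.groupby(["line", "sex", "temperature"], observed=True)[response].mean()
    return g.unstack(["sex", "temperature"])


def derive_phenotypes(
    data: pd.DataFrame,
    response: str = "lifespan_days",
    sexes: tuple = ("F", "M"),
) -> pd.DataFrame:
    """Per-line context means and every derived contrast phenotype.

    Column naming: ``female_18``, ``male_18``, ``avg_18``, ``sexdiff_18``
    (M - F), then per-pair ``female_25_18`` (value at 25C minus value at
    18C, higher minus lower temperature), ``avg_25_18``, and
    ``sexdiff_25_18`` (the sex difference of the temperature
    difference).  Lines missing either constituent context carry NaN.
    """
    f_lab, m_lab = sexes
    means = _cell_means(data, response)
    temps = sorted({t for (_, t) in means.columns})
    out = pd.DataFrame(index=means.index)
    name = {f_lab: "female", m_lab: "male"}
    for t in temps:
        fcol = means.get((f_lab, t))
        mcol = means.get((m_lab, t))
        out[f"female_{t}"] = fcol
        out[f"male_{t}"] = mcol
        out[f"avg_{t}"] = (fcol + mcol) / 2.0
        out[f"sexdiff_{t}"] = mcol - fcol
    for lo, hi in combinations(temps, 2):
        for base in ("female", "male", "avg", "sexdiff"):
            out[f"{base}_{hi}_{lo}"] = out[f"{base}_{hi}"] - out[f"{base}_{lo}"]
    out.index.name = "line"
    return out


def _residualize(y: pd.Series, covariates: pd.DataFrame | None) -> pd.Series:
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    cov = covariates.reindex(y.index)
    # categorical covariates (e.g. inversion karyotypes) become dummies;
    # missing covariate values become their own level ("imputed-as-level")
    num = cov.select_dtypes(include=[np.number])
    cat = cov.drop(columns=num.columns)
    parts = [num]
    if cat.shape[1]:
        parts.append(pd.get_dummies(cat.fillna("missing").astype(str), drop_first=True))
    X = pd.concat(parts, axis=1).to_numpy(float)
    X = np.column_stack([np.ones(len(X)), X])
    mask = ~np.isnan(y.to_numpy()) & ~np.isnan(X).any(axis=1)
    if np.linalg.matrix_rank(X[mask]) < X.shape[1]:
        raise ValueError("singular covariate design")
    resid = pd.Series(np.nan, index=y.index)
    b, *_ = np.linalg.lstsq(X[mask], y.to_numpy()[mask], rcond=None)
    resid[mask] = y.to_numpy()[mask] - X[mask] @ b
    return resid


def _genotype_pcs(dosage: pd.DataFrame, n_pcs: int) -> pd.DataFrame:
    Z = dosage.to_numpy(float)
    mu = np.nanmean(Z, axis=0)
    Z = np.where(np.isnan(Z), mu, Z) - mu
    sd = Z.std(axis=0)
    Z = Z[:, sd > 0] / sd[sd > 0]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(pcs, index=dosage.index,
                        columns=[f"PC{i+1}" for i in range(pcs.shape[1])])


def marker_scan(
    phenotype: pd.Series,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    report_p: float = 1e-5,
    n_pcs: int = 0,
) -> pd.DataFrame:
    """Single-marker scan of one line-level phenotype.

    The phenotype is residualised on the covariates (two-step
    adjustment), then each variant with MAF > ``maf_min`` is tested by
    OLS of the residual on minor-allele dosage.  Effects are reported
    per minor allele in trait units; ``significant`` flags
    ``p < report_p``.
    """
    common = geno.lines.intersection(phenotype.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 lines shared between phenotype and genotypes")
    y = phenotype.reindex(common)
    cov = covariates
    if n_pcs > 0:
        pcs = _genotype_pcs(geno.dosage.reindex(common), n_pcs)
        cov = pcs if cov is None else pd.concat([cov.reindex(common), pcs], axis=1)
    r = _residualize(y, cov).to_numpy(float)
    D = geno.dosage.reindex(common).to_numpy(float)

    # orient to the minor allele (fixed at scan time over genotyped lines)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(D, axis=0) / 2.0
    flip = freq > 0.5
    D[:, flip] = 2.0 - D[:, flip]
    maf = np.where(flip, 1.0 - freq, freq)

    mask = ~np.isnan(D) & ~np.isnan(r)[:, None]
    Dm = np.where(mask, D, 0.0)
    rm = np.where(mask, r[:, None], 0.0)
    n = mask.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dbar = Dm.sum(axis=0) / n
        rbar = rm.sum(axis=0) / n
        sxx = (Dm**2).sum(axis=0) - n * dbar**2
        sxy = (Dm * rm).sum(axis=0) - n * dbar * rbar
        syy = (rm**2).sum(axis=0) - n * rbar**2
        beta = sxy / sxx
        dof = n - 2
        s2 = np.maximum(syy - beta * sxy, 0.0) / dof
        se = np.sqrt(s2 / sxx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    # exact phenotype = dosage gives zero residual variance: p underflows
    p = np.where(np.isfinite(tstat) & (se == 0), 0.0, p)
    tested = (maf > maf_min) & (sxx > 0) & (dof > 0)

    res = geno.meta.copy()
    res["maf"] = maf
    res["n"] = n.astype(int)
    res["effect"] = beta
    res["se"] = se
    res["t"] = tstat
    res["p"] = p
    res.loc[~tested, ["effect", "se", "t", "p"]] = np.nan
    res["tested"] = tested
    res["significant"] = tested & (res["p"] < report_p)
    return res


def scan_phenotypes(
    phenotypes: pd.DataFrame,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    **kws,
) -> dict[str, pd.DataFrame]:
    """Run :func:`marker_scan` for every phenotype column."""
    return {
        col: marker_scan(phenotypes[col], geno, covariates, **kws)
        for col in phenotypes.columns
    }


def classify_effects(
    results: dict[str, pd.DataFrame], p_threshold: float = 1e-5
) -> pd.DataFrame:
    """Label each variant's behaviour across scanned contexts.

    ``context-specific``: significant in exactly one context;
    ``antagonistic``: significant in several contexts with opposite
    effect signs; ``concordant``: significant in several contexts, all
    with the same sign; ``ns``: significant nowhere.
    """
    contexts = list(results)
    base = results[contexts[0]]
    ids = base["variant_id"].to_numpy()
    for c in contexts[1:]:
        if not np.array_equal(results[c]["variant_id"].to_numpy(), ids):
            raise ValueError("contexts were scanned on different variant sets")
    eff = np.column_stack([results[c]["effect"].to_numpy() for c in contexts])
    pv = np.column_stack([results[c]["p"].to_numpy() for c in contexts])
    sig = np.nan_to_num(pv, nan=1.0) < p_threshold
    nsig = sig.sum(axis=1)
    label = np.full(len(ids), "ns", dtype=object)
    label[nsig == 1] = "context-specific"
    multi = nsig >= 2
    for i in np.flatnonzero(multi):
        signs = np.sign(eff[i, sig[i]])
        label[i] = "antagonistic" if (signs.max() > 0 and signs.min() < 0) else "concordant"
    out = pd.DataFrame({"variant_id": ids, "n_significant": nsig, "label": label})
    for j, c in enumerate(contexts):
        out[f"effect_{c}"] = eff[:, j]
        out[f"sig_{c}"] = sig[:, j]
    return out


def effect_correlations(
    results: dict[str, pd.DataFrame], method: str = "spearman"
) -> pd.DataFrame:
    """Cross-context correlation matrix of per-variant allele effects."""
    eff = pd.DataFrame({c: r.set_index("variant_id")["effect"] for c, r in results.items()})
    return eff.corr(method=method)


def ld_r2(geno: GenotypeMatrix, variant_ids) -> pd.DataFrame:
    """Pairwise genotype correlation squared among selected variants."""
    D = geno.dosage[list(variant_ids)]
    return D.corr() ** 2
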