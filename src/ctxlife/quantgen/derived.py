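"""Quantitative-genetic statistics derived from variance components.

Given REML variance components from the replicated inbred-line design,
these functions compute the standard summaries: broad-sense
heritability ``H2 = sigma2_G / (sigma2_G + sigma2_eps)`` (genotypic
variance over total phenotypic variance, vial terms excluded from
both), coefficients of genetic and environmental variation expressed in
percent of the trait mean, cross-context genetic correlations

    r_GMF = sigma2_L / (sigma2_L + sigma2_LS)          (across sexes)
    r_GT  = sigma2_L / (sigma2_L + sigma2_LT)          (across temperatures)
    r_GST = sigma2_L / (sigma2_L + sigma2_LS + sigma2_LT + sigma2_LST)

and the decomposition of a two-context interaction variance into a
rank-order-change term ``sigma_A * sigma_B * (1 - r)`` and a
scale-change term ``(sigma_A - sigma_B)^2 / 2``.  The two terms sum to
``(sigma_A^2 + sigma_B^2)/2 - r * sigma_A * sigma_B``, the interaction
variance contributed by that pair of contexts, so "% rank" measures how
much of the genotype-by-context interaction reflects genotypes swapping
rank between contexts as opposed to the genetic scale changing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DerivedGenetics",
    "InteractionDecomposition",
    "derive_genetics",
    "decompose_interaction",
    "decompose_interaction_pairs",
]


@dataclass(frozen=True)
class DerivedGenetics:
    """Heritability, variation coefficients and genetic correlations.

    ``nan`` marks a statistic whose inputs were absent or degenerate
    (e.g. zero total variance).
    """

    H2: float = np.nan
    CV_G: float = np.nan
    CV_E: float = np.nan
    r_GMF: float = np.nan
    r_GT: float = np.nan
    r_GST: float = np.nan
    mean: float = np.nan
    sigma2_G: float = np.nan
    sigma2_E: float = np.nan


@dataclass(frozen=True)
class InteractionDecomposition:
    """Rank-change vs scale-change split of an interaction variance."""

    rank_term: float
    scale_term: float
    pct_rank: float  # NaN when both terms are zero (0/0 undefined)
    context_a: str = "A"
    context_b: str = "B"

    @property
    def total(self) -> float:
        return self.rank_term + self.scale_term


def _ratio(num: float, den: float) -> float:
    if den is None or num is None or not np.isfinite(den) or den <= 0:
        return np.nan
    return num / den


def derive_genetics(
    components: Mapping[str, float],
    means: Sequence[float] | Mapping[str, float] | float | None = None,
) -> DerivedGenetics:
    """Compute the derived statistics supported by ``components``.

    Parameters
    ----------
    components :
        Variance components keyed by term name.  Recognised keys:
        ``line``, ``line:sex``, ``line:temperature``,
        ``line:sex:temperature`` and ``residual``.  Statistics whose
        inputs are absent come back as NaN.
    means :
        Context mean(s) of the trait; a sequence (e.g. the female and
        male means) is averaged.  Needed only for CV_G / CV_E.
    """
    c = dict(components)
    s2_line = c.get("line")
    s2_ls = c.get("line:sex")
    s2_lt = c.get("line:temperature")
    s2_lst = c.get("line:sex:temperature")
    s2_e = c.get("residual")

    genetic = [v for k, v in c.items() if k != "residual" and "line" in k.split(":")]
    s2_g = float(sum(genetic)) if genetic else np.nan

    if means is None:
        mean = np.nan
    elif isinstance(means, Mapping):
        mean = float(np.mean(list(means.values())))
    elif np.isscalar(means):
        mean = float(means)
    else:
        mean = float(np.mean(means))

    H2 = np.nan
    if np.isfinite(s2_g) and s2_e is not None:
        H2 = _ratio(s2_g, s2_g + s2_e)

    CV_G = 100.0 * np.sqrt(s2_g) / mean if np.isfinite(s2_g) and mean > 0 else np.nan
    CV_E = (
        100.0 * np.sqrt(s2_e) / mean
        if s2_e is not None and np.isfinite(s2_e) and mean > 0
        else np.nan
    )

    r_gmf = _ratio(s2_line, s2_line + s2_ls) if None not in (s2_line, s2_ls) else np.nan
    r_gt = _ratio(s2_line, s2_line + s2_lt) if None not in (s2_line, s2_lt) else np.nan
    r_gst = (
        _ratio(s2_line, s2_line + s2_ls + s2_lt + s2_lst)
        if None not in (s2_line, s2_ls, s2_lt, s2_lst)
        else np.nan
    )

    return DerivedGenetics(
        H2=H2, CV_G=CV_G, CV_E=CV_E, r_GMF=r_gmf, r_GT=r_gt, r_GST=r_gst,
        mean=mean, sigma2_G=s2_g,
        sigma2_E=float(s2_e) if s2_e is not None else np.nan,
    )


def decompose_interaction(
    sigma_a: float,
    sigma_b: float,
    r: float,
    context_a: str = "A",
    context_b: str = "B",
) -> InteractionDecomposition:
    """Split a two-context interaction variance into rank and scale terms.

    ``sigma_a`` and ``sigma_b`` are the genetic standard deviations in
    the two contexts (square roots of the among-line components) and
    ``r`` their cross-context genetic correlation.
    """
    if sigma_a < 0 or sigma_b < 0:
        raise ValueError("genetic standard deviations must be non-negative")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    rank = sigma_a * sigma_b * (1.0 - r)
    scale = (sigma_a - sigma_b) ** 2 / 2.0
    tot = rank + scale
    pct = 100.0 * (rank / tot) if tot > 0 else np.nan
    return InteractionDecomposition(rank, scale, pct, context_a, context_b)


def decompose_interaction_pairs(
    sigmas: Mapping[str, float], correlations: Mapping[tuple[str, str], float]
) -> tuple[list[InteractionDecomposition], InteractionDecomposition]:
    """Pairwise decompositions plus their average over all context pairs.

    For ``t`` contexts the aggregate interaction variance is the mean
    over the ``t (t-1) / 2`` unordered pairs of each pair's rank and
    scale terms; the averaged terms are returned as a synthetic
    "aggregate" decomposition.
    """
    names = list(sigmas)
    per_pair = []
    for a, b in combinations(names, 2):
        r = correlations.get((a, b), correlations.get((b, a)))
        if r is None:
            raise KeyError(f"missing correlation for pair ({a}, {b})")
        per_pair.append(decompose_interaction(sigmas[a], sigmas[b], r, a, b))
    rank = float(np.mean([d.rank_term for d in per_pair]))
    scale = float(np.mean([d.scale_term for d in per_pair]))
    tot = rank + scale
    agg = InteractionDecomposition(
        rank, scale, 100.0 * rank / tot if tot > 0 else np.nan,
        "+".join(names), "aggregate",
    )
    return per_pair, agg
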