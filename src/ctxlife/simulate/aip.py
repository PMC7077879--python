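"""Generator for outbred-cohort extreme-QTL (xQTL) experiments.

Emulates an advanced-intercross population descended from ~40 inbred
founder lines: founder haplotypes define per-variant allele
frequencies, cohort individuals draw genotype dosages per variant from
those frequencies (linkage equilibrium — the per-variant xQTL
statistics under test do not depend on LD), and life span is a baseline
plus context-dependent additive variant effects plus Gaussian noise.
Effects may differ in sign between sexes or temperatures, producing
antagonistic architectures.  Selection then takes the longest-lived
``top_fraction`` of each cohort into an H pool and an independent
random sample of young individuals into a C control pool, and
pooled sequencing is modelled as binomial read sampling at a coverage
drawn uniformly from the stated range (130-156x by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FounderPanel",
    "AipCohortSpec",
    "AipCohort",
    "simulate_founder_genotypes",
    "simulate_aip_cohort",
    "pool_select_and_sequence",
]


@dataclass
class FounderPanel:
    """Biallelic founder haplotype panel.

    ``haplotypes`` is founders x variants with entries in {0, 1}; every
    variant segregates (founder frequency strictly inside (0, 1)).
    """

    haplotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.haplotypes)
        if h.ndim != 2 or not np.isin(h, (0, 1)).all():
            raise ValueError("haplotypes must be a founders x variants 0/1 matrix")
        f = h.mean(axis=0)
        if np.any((f <= 0) | (f >= 1)):
            raise ValueError("every variant must segregate among the founders")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Realised alt-allele frequency of each variant among founders."""
        return self.haplotypes.mean(axis=0)

    def variant_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]


def simulate_founder_genotypes(
    n_founders: int = 40,
    n_variants: int = 1000,
    maf_spec=(0.05, 0.5),
    seed: int = 0,
    chrom: str = "2L",
) -> FounderPanel:
    """Draw a segregating founder panel with frequencies from ``maf_spec``.

    ``maf_spec`` is either a scalar (point mass) or a ``(lo, hi)`` pair
    for a uniform target-frequency distribution.  Haplotypes are
    Bernoulli draws at the target frequency, redrawn per variant until
    the variant segregates.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders for a segregating panel")
    rng = np.random.default_rng(seed)
    if np.isscalar(maf_spec):
        draw_p = lambda size: np.full(size, float(maf_spec))
    else:
        lo, hi = maf_spec
        draw_p = lambda size: rng.uniform(lo, hi, size)

    H = np.empty((n_founders, n_variants), dtype=np.int8)
    todo = np.arange(n_variants)
    while len(todo):
        p = draw_p(len(todo))
        H[:, todo] = (rng.random((n_founders, len(todo))) < p).astype(np.int8)
        f = H[:, todo].mean(axis=0)
        todo = todo[(f <= 0) | (f >= 1)]
    pos = 1000 * (np.arange(n_variants) + 1)
    return FounderPanel(H, np.full(n_variants, chrom, dtype=object), pos)


@dataclass(frozen=True)
class AipCohortSpec:
    """Cohort, selection and sequencing design for the xQTL experiment.

    ``effects`` maps a variant index to either a scalar additive effect
    (days per alt allele, all contexts) or a ``{(sex, temperature):
    effect}`` mapping; signs may differ between contexts.  The
    environmental (residual) life span SD of the outbred cohort is a
    free parameter (``sd_env``).
    """

    n_per_sex: int = 960
    pool_size: int = 96
    top_fraction: float = 0.10
    replicates: int = 2
    coverage_range: tuple | None = (130, 156)
    sexes: tuple = ("F", "M")
    temperatures: tuple = (18, 25, 28)
    baseline: Mapping | float = 40.0
    sd_env: float = 10.0
    effects: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.pool_size < 1 or self.n_per_sex < 1 or self.replicates < 1:
            raise ValueError("cohort counts must be >= 1")
        if int(round(self.top_fraction * self.n_per_sex)) < self.pool_size:
            raise ValueError(
                "top_fraction x cohort size is smaller than the pool size"
            )

    def baseline_for(self, sex, temp) -> float:
        if isinstance(self.baseline, Mapping):
            return float(self.baseline[(sex, temp)])
        return float(self.baseline)

    def effect_vector(self, n_variants: int, sex, temp) -> np.ndarray:
        beta = np.zeros(n_variants)
        for v, eff in self.effects.items():
            if not 0 <= int(v) < n_variants:
                raise KeyError(f"effect refers to unknown variant index {v}")
            if isinstance(eff, Mapping):
                beta[int(v)] = float(eff.get((sex, temp), 0.0))
            else:
                beta[int(v)] = float(eff)
        return beta


@dataclass
class AipCohort:
    """Simulated cohorts: per (sex, temperature, replicate) genotypes
    (individuals x variants dosage 0/1/2) and life spans, plus the
    founder frequencies used to draw fresh young control flies."""

    panel: FounderPanel
    spec: AipCohortSpec
    genotypes: dict
    lifespans: dict

    def contexts(self):
        return sorted(self.genotypes)


def simulate_aip_cohort(
    panel: FounderPanel, spec: AipCohortSpec, seed: int
) -> AipCohort:
    """Simulate independent cohorts for every context and replicate.

    Each replicate is its own cohort of ``n_per_sex`` individuals (the
    replicated field design collects separate flies per replicate), so
    replicate H pools are independent.
    """
    rng = np.random.default_rng(seed)
    freq = panel.frequencies
    V = panel.n_variants
    genotypes, lifespans = {}, {}
    for sex in spec.sexes:
        for temp in spec.temperatures:
            beta = spec.effect_vector(V, sex, temp)
            for rep in range(1, spec.replicates + 1):
                G = rng.binomial(2, freq, size=(spec.n_per_sex, V)).astype(np.int8)
                y = (
                    spec.baseline_for(sex, temp)
                    + G @ beta
                    + rng.normal(0.0, spec.sd_env, spec.n_per_sex)
                )
                genotypes[(sex, temp, rep)] = G
                lifespans[(sex, temp, rep)] = y
    return AipCohort(panel, spec, genotypes, lifespans)


def _pool_counts(G_pool: np.ndarray, rng, coverage_range):
    """True pool frequencies -> (ref_reads, alt_reads) per variant."""
    n, V = G_pool.shape
    f = G_pool.sum(axis=0) / (2.0 * n)
    if coverage_range is None:
        alt = G_pool.sum(axis=0)
        total = np.full(V, 2 * n)
    else:
        lo, hi = coverage_range
        total = rng.integers(lo, hi + 1, size=V)
        alt = rng.binomial(total, f)
    return total - alt, alt


def pool_select_and_sequence(
    cohort: AipCohort, seed: int, spec: AipCohortSpec | None = None
) -> pd.DataFrame:
    """Select H (longest-lived) and C (random young) pools and sequence.

    Per replicate x sex x temperature the H pool is the top
    ``top_fraction`` of the cohort by life span (truncated to
    ``pool_size`` flies, ties broken by a seed-stable random jitter) and
    the C pool is an independent draw of ``pool_size`` young
    individuals from the founder frequencies.  Read counts per variant
    per pool are binomial at a coverage drawn uniformly from
    ``coverage_range`` (or exact pool allele counts when the range is
    ``None``).
    """
    spec = spec or cohort.spec
    rng = np.random.default_rng(seed)
    panel = cohort.panel
    freq = panel.frequencies
    V = panel.n_variants
    n_top = int(round(spec.top_fraction * spec.n_per_sex))
    if n_top < spec.pool_size:
        raise ValueError("top_fraction x cohort size smaller than pool size")

    rows = []
    vids = panel.variant_ids()
    for (sex, temp, rep) in cohort.contexts():
        G = cohort.genotypes[(sex, temp, rep)]
        y = cohort.lifespans[(sex, temp, rep)]
        order = np.argsort(y + rng.uniform(0, 1e-9, len(y)), kind="stable")
        top = order[-n_top:][-spec.pool_size:]
        Gc = rng.binomial(2, freq, size=(spec.pool_size, V)).astype(np.int8)
        for ptype, Gp in (("H", G[top]), ("C", Gc)):
            ref, alt = _pool_counts(Gp, rng, spec.coverage_range)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": panel.chrom,
                        "pos": panel.pos,
                        "ref": "A",
                        "alt": "T",
                        "variant_id": vids,
                        "sex": sex,
                        "temperature": temp,
                        "replicate": rep,
                        "pool_type": ptype,
                        "ref_reads": ref,
                        "alt_reads": alt,
                        "pool_size": spec.pool_size,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
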