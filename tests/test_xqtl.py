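"""Pooled-sequencing xQTL statistics: variance model, Z tests, antagonism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctxlife.simulate import (
    AipCohortSpec,
    pool_select_and_sequence,
    simulate_aip_cohort,
    simulate_founder_genotypes,
)
from ctxlife.xqtl import (
    antagonism_summary,
    cross_context_contrasts,
    cross_context_z,
    delta_f_correlations,
    estimate_pool_frequency,
    z_test_hc,
)


class TestPoolFrequency:
    def test_formula_instantiation(self):
        f, var = estimate_pool_frequency(100, 100, pool_size=96)
        assert f == 0.5
        fmod = 100.5 / 201.0
        assert var == pytest.approx(fmod * (1 - fmod) * (1 / 192 + 1 / 200))

    def test_infinite_coverage_limit_is_the_pool_sampling_floor(self):
        reads = 10**9
        f, var = estimate_pool_frequency(reads // 2, reads // 2, pool_size=96)
        assert var == pytest.approx(0.25 / 192, rel=1e-4)

    def test_zero_reads_raise(self):
        with pytest.raises(ValueError):
            estimate_pool_frequency(0, 0)

    def test_monte_carlo_variance_oracle(self):
        """Two-stage binomial simulation matches the variance formula."""
        rng = np.random.default_rng(60)
        p, n_pool, cov = 0.3, 96, 150
        f_pool = rng.binomial(2 * n_pool, p, 10_000) / (2 * n_pool)
        f_hat = rng.binomial(cov, f_pool) / cov
        _, var = estimate_pool_frequency(
            int(cov * (1 - p)), int(cov * p), pool_size=n_pool
        )
        assert f_hat.var() == pytest.approx(var, rel=0.10)


def _counts_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "sex", "temperature", "replicate",
            "pool_type", "ref_reads", "alt_reads", "pool_size",
        ],
    )


class TestWithinContextZ:
    def test_equal_frequencies_give_zero_z(self):
        rows = []
        for rep in (1, 2):
            for ptype in ("H", "C"):
                rows.append(("v1", "2L", 100, "F", 25, rep, ptype, 70, 70, 96))
        out = z_test_hc(_counts_frame(rows))
        assert out.loc[0, "Z"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_missing_pool_type_raises(self):
        rows = [("v1", "2L", 100, "F", 25, 1, "H", 70, 70, 96)]
        with pytest.raises(ValueError, match="missing"):
            z_test_hc(_counts_frame(rows))

    def test_h_c_swap_negates_delta_and_preserves_z(self):
        rng = np.random.default_rng(61)
        panel = simulate_founder_genotypes(40, 30, seed=62)
        spec = AipCohortSpec(n_per_sex=200, pool_size=20, top_fraction=0.1,
                             sexes=("F",), temperatures=(25,))
        cohort = simulate_aip_cohort(panel, spec, seed=63)
        counts = pool_select_and_sequence(cohort, seed=64)
        a = z_test_hc(counts)
        swapped = counts.assign(
            pool_type=counts["pool_type"].map({"H": "C", "C": "H"})
        )
        b = z_test_hc(swapped)
        np.testing.assert_allclose(a["delta_f"], -b["delta_f"], atol=1e-12)
        np.testing.assert_allclose(np.abs(a["Z"]), np.abs(b["Z"]), atol=1e-12)

    def test_null_generator_z_is_standard_normal(self):
        """No life span effects: Z over many variants is N(0, 1)-ish."""
        panel = simulate_founder_genotypes(40, 4000, maf_spec=(0.1, 0.5), seed=65)
        spec = AipCohortSpec(n_per_sex=960, pool_size=96, top_fraction=0.1,
                             sexes=("F",), temperatures=(25,))
        cohort = simulate_aip_cohort(panel, spec, seed=66)
        counts = pool_select_and_sequence(cohort, seed=67)
        out = z_test_hc(counts)
        z = out["Z"].to_numpy()
        assert abs(z.mean()) < 0.05
        assert z.std() == pytest.approx(1.0, abs=0.06)

    def test_planted_effect_is_detected_with_matching_sign(self):
        panel = simulate_founder_genotypes(40, 10, maf_spec=0.5, seed=68)
        spec = AipCohortSpec(n_per_sex=960, pool_size=96, top_fraction=0.1,
                             sexes=("F",), temperatures=(25,),
                             effects={0: 8.0}, sd_env=8.0)
        cohort = simulate_aip_cohort(panel, spec, seed=69)
        counts = pool_select_and_sequence(cohort, seed=70)
        out = z_test_hc(counts).set_index("variant_id")
        v0 = panel.variant_ids()[0]
        assert out.loc[v0, "significant"]
        assert out.loc[v0, "delta_f"] > 0

    def test_monotone_response_to_effect_size(self):
        """|E[delta_f]| grows with the planted effect over a grid."""
        panel = simulate_founder_genotypes(40, 5, maf_spec=0.5, seed=71)
        mean_abs = []
        for i, eff in enumerate((0.0, 2.0, 6.0)):
            deltas = []
            for rep in range(40):
                spec = AipCohortSpec(
                    n_per_sex=300, pool_size=30, top_fraction=0.1, replicates=1,
                    sexes=("F",), temperatures=(25,), effects={0: eff}, sd_env=8.0,
                )
                cohort = simulate_aip_cohort(panel, spec, seed=5000 + 100 * i + rep)
                counts = pool_select_and_sequence(cohort, seed=7000 + 100 * i + rep)
                out = z_test_hc(counts).set_index("variant_id")
                deltas.append(out.loc[panel.variant_ids()[0], "delta_f"])
            mean_abs.append(abs(np.mean(deltas)))
        assert mean_abs[0] < mean_abs[1] < mean_abs[2]


class TestCrossContextZ:
    def _within(self, seed, effects=None, sexes=("F", "M")):
        panel = simulate_founder_genotypes(40, 50, maf_spec=(0.2, 0.5), seed=seed)
        spec = AipCohortSpec(n_per_sex=300, pool_size=30, top_fraction=0.1,
                             sexes=sexes, temperatures=(25,),
                             effects=effects or {}, sd_env=8.0)
        cohort = simulate_aip_cohort(panel, spec, seed=seed + 1)
        counts = pool_select_and_sequence(cohort, seed=seed + 2)
        return panel, z_test_hc(counts)

    def test_identical_contexts_give_zero_z(self):
        _, within = self._within(80)
        sub = within[within["sex"] == "F"]
        out = cross_context_z(sub, sub.copy(), label="self")
        np.testing.assert_allclose(out["Z"], 0.0, atol=1e-12)

    def test_disjoint_variants_raise(self):
        _, within = self._within(81)
        a = within[within["sex"] == "F"].set_index("variant_id")
        b = a.copy()
        b.index = pd.Index([f"x{i}" for i in range(len(b))], name="variant_id")
        with pytest.raises(ValueError):
            cross_context_z(a, b)

    def test_antagonistic_variant_amplifies_the_sex_contrast(self):
        """Opposite-sign effects: the cross-sex |Z| beats each within |Z|."""
        vid = None
        cross_bigger = 0
        for rep in range(10):
            panel, within = self._within(
                200 + 10 * rep,
                effects={0: {("F", 25): 6.0, ("M", 25): -6.0}},
            )
            vid = panel.variant_ids()[0]
            w = within.set_index(["variant_id", "sex"])
            zf = abs(w.loc[(vid, "F"), "Z"])
            zm = abs(w.loc[(vid, "M"), "Z"])
            cross = cross_context_contrasts(within)
            zc = abs(
                cross.set_index(["variant_id", "contrast"]).loc[
                    (vid, "sexdiff@25"), "Z"
                ]
            )
            cross_bigger += zc > max(zf, zm)
        assert cross_bigger >= 8

    def test_contrast_labels_cover_all_families(self):
        panel = simulate_founder_genotypes(40, 10, seed=90)
        spec = AipCohortSpec(n_per_sex=100, pool_size=10, top_fraction=0.1,
                             sexes=("F", "M"), temperatures=(18, 25))
        cohort = simulate_aip_cohort(panel, spec, seed=91)
        counts = pool_select_and_sequence(cohort, seed=92)
        cross = cross_context_contrasts(z_test_hc(counts))
        labels = set(cross["contrast"])
        assert {"sexdiff@18", "sexdiff@25", "F:25-18", "M:25-18",
                "sexdiff:25-18"} <= labels


class TestAntagonismSummary:
    def _within_manual(self):
        rows = []
        # v1: significant twice with opposite delta_f; v2 once; v3 never
        data = [
            ("v1", "F", 25, 0.08, 1e-9), ("v1", "M", 25, -0.07, 1e-8),
            ("v2", "F", 25, 0.05, 1e-8), ("v2", "M", 25, 0.01, 0.5),
            ("v3", "F", 25, 0.01, 0.9), ("v3", "M", 25, 0.0, 1.0),
        ]
        for vid, s, t, d, p in data:
            rows.append(
                {"variant_id": vid, "chrom": "2L", "pos": 1, "sex": s,
                 "temperature": t, "delta_f": d, "p": p}
            )
        return pd.DataFrame(rows)

    def test_variant_labels(self):
        out = antagonism_summary(self._within_manual())["variants"]
        out = out.set_index("variant_id")
        assert out.loc["v1", "label"] == "antagonistic"
        assert out.loc["v2", "label"] == "context-specific"
        assert out.loc["v3", "label"] == "ns"

    def test_gene_level_opposite_effect_pairs(self):
        within = pd.DataFrame(
            [
                {"variant_id": "a", "chrom": "2L", "pos": 1, "sex": "F",
                 "temperature": 25, "delta_f": 0.08, "p": 1e-9},
                {"variant_id": "b", "chrom": "2L", "pos": 2, "sex": "F",
                 "temperature": 25, "delta_f": -0.07, "p": 1e-9},
            ]
        )
        gm = pd.DataFrame({"variant_id": ["a", "b"], "gene_id": ["g1", "g1"]})
        genes = antagonism_summary(within, gene_map=gm)["genes"]
        assert genes.set_index("gene_id").loc["g1", "same_context"] == 1

    def test_antagonistic_architecture_gives_negative_cross_sex_correlation(self):
        panel = simulate_founder_genotypes(40, 150, maf_spec=(0.2, 0.5), seed=95)
        effects = {
            v: {("F", 25): e, ("M", 25): -e}
            for v, e in enumerate(np.random.default_rng(96).normal(0, 2.0, 150))
        }
        spec = AipCohortSpec(n_per_sex=960, pool_size=96, top_fraction=0.1,
                             sexes=("F", "M"), temperatures=(25,),
                             effects=effects, sd_env=8.0)
        cohort = simulate_aip_cohort(panel, spec, seed=97)
        counts = pool_select_and_sequence(cohort, seed=98)
        corr = delta_f_correlations(z_test_hc(counts))
        assert corr.loc["F@25", "M@25"] < -0.3
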