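"""Gene mapping, length-weighted permutation enrichment, study overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctxlife.enrichment import (
    go_enrichment,
    map_variants_to_genes,
    study_overlap,
    weighted_sample_indices,
)


class TestVariantMapping:
    def test_inside_gene_body_maps_at_any_window(self, toy_genes):
        v = pd.DataFrame({"variant_id": ["v1"], "chrom": ["2L"], "pos": [1500]})
        for w in (0, 1000, 5000):
            out = map_variants_to_genes(v, toy_genes, window_bp=w)
            assert "g1" in set(out["gene_id"])

    def test_window_semantics_upstream(self, toy_genes):
        # 1,500 bp upstream of g2 (start 8000)
        v = pd.DataFrame({"variant_id": ["v1"], "chrom": ["2L"], "pos": [6500]})
        near = map_variants_to_genes(v, toy_genes, window_bp=2000)
        far = map_variants_to_genes(v, toy_genes, window_bp=1000)
        assert set(near["gene_id"]) == {"g2"}
        assert len(far) == 0

    def test_unknown_chromosome_raises(self, toy_genes):
        v = pd.DataFrame({"variant_id": ["v1"], "chrom": ["X"], "pos": [100]})
        with pytest.raises(ValueError, match="chromosome"):
            map_variants_to_genes(v, toy_genes)

    def test_matches_brute_force_interval_oracle(self, toy_genes):
        rng = np.random.default_rng(101)
        variants = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(40)],
                "chrom": rng.choice(["2L", "2R", "3L"], 40),
                "pos": rng.integers(1, 12_000, 40),
            }
        )
        w = 700
        got = set(
            map(tuple, map_variants_to_genes(variants, toy_genes, w).to_numpy())
        )
        expected = set()
        for v in variants.itertuples(index=False):
            for g in toy_genes.itertuples(index=False):
                if g.chrom == v.chrom and g.start - w <= v.pos <= g.end + w:
                    expected.add((v.variant_id, g.gene_id))
        assert got == expected

    def test_one_bp_gene_boundaries(self):
        genes = pd.DataFrame(
            {"gene_id": ["tiny"], "chrom": ["2L"], "start": [5], "end": [5],
             "length": [1]}
        )
        hits = lambda pos, w: len(
            map_variants_to_genes(
                pd.DataFrame({"variant_id": ["v"], "chrom": ["2L"], "pos": [pos]}),
                genes, window_bp=w,
            )
        )
        assert hits(5, 0) == 1
        assert hits(4, 0) == 0 and hits(6, 0) == 0
        assert hits(4, 1) == 1 and hits(6, 1) == 1


class TestWeightedSampling:
    def test_matches_sequential_brute_force_oracle(self):
        """Exponential-race keys equal literal draw-remove-renormalise."""
        rng = np.random.default_rng(102)
        w = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 1.0, 5.0, 2.0, 6.0, 3.0,
                      1.5, 2.5, 7.0, 1.0, 4.5, 2.0, 3.5, 8.0, 1.0, 2.0])
        k, reps = 5, 20_000
        incl_fast = np.zeros(len(w))
        for _ in range(reps):
            incl_fast[weighted_sample_indices(rng, w, k)] += 1

        rng2 = np.random.default_rng(103)
        incl_seq = np.zeros(len(w))
        for _ in range(reps):
            avail = list(range(len(w)))
            for _ in range(k):
                ww = w[avail]
                j = rng2.choice(len(avail), p=ww / ww.sum())
                incl_seq[avail[j]] += 1
                del avail[j]
        pf, ps = incl_fast / reps, incl_seq / reps
        se = np.sqrt(pf * (1 - pf) / reps + ps * (1 - ps) / reps)
        assert (np.abs(pf - ps) < 4 * se + 1e-9).all()

    def test_inclusion_is_length_proportional_for_small_k(self):
        # for k = 1 inclusion probability is exactly w / sum(w)
        rng = np.random.default_rng(104)
        w = np.array([1.0, 3.0, 6.0])
        incl = np.zeros(3)
        reps = 30_000
        for _ in range(reps):
            incl[weighted_sample_indices(rng, w, 1)] += 1
        np.testing.assert_allclose(incl / reps, w / w.sum(), atol=0.01)

    def test_nonpositive_weights_raise(self):
        with pytest.raises(ValueError):
            weighted_sample_indices(np.random.default_rng(0), np.array([1.0, 0.0]), 1)


def _toy_universe(rng, n_genes=400, n_terms=25, genes_per_term=30,
                  equal_lengths=True):
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    lengths = pd.Series(
        1000.0 if equal_lengths else rng.integers(200, 20_000, n_genes).astype(float),
        index=genes,
    )
    rows = []
    for t in range(n_terms):
        for g in rng.choice(n_genes, genes_per_term, replace=False):
            rows.append((f"g{g}", f"T{t}"))
    ann = pd.DataFrame(rows, columns=["gene_id", "term"])
    return lengths, ann


class TestGoEnrichment:
    def test_gene_set_equal_to_universe(self):
        rng = np.random.default_rng(105)
        lengths, ann = _toy_universe(rng, n_genes=100, n_terms=5)
        res = go_enrichment(list(lengths.index), lengths, ann, n_perm=200, seed=1)
        assert (res["k_obs"] == res["n_annotated"]).all()
        assert (res["p_perm"] == 1.0).all()

    def test_permutation_p_bounds_and_seed_reproducibility(self):
        rng = np.random.default_rng(106)
        lengths, ann = _toy_universe(rng)
        gene_set = list(lengths.index[rng.choice(400, 40, replace=False)])
        a = go_enrichment(gene_set, lengths, ann, n_perm=500, seed=7)
        b = go_enrichment(gene_set, lengths, ann, n_perm=500, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert (a["p_perm"] >= 1.0 / 501.0).all()
        assert (a["p_perm"] <= 1.0).all()

    def test_equal_lengths_agree_with_hypergeometric(self):
        """With equal lengths the weighted null IS the hypergeometric null."""
        rng = np.random.default_rng(107)
        lengths, ann = _toy_universe(rng, equal_lengths=True)
        gene_set = list(lengths.index[rng.choice(400, 60, replace=False)])
        res = go_enrichment(gene_set, lengths, ann, n_perm=4000, seed=11)
        rho = stats.spearmanr(res["p_perm"], res["p_hyper"]).statistic
        assert rho > 0.97
        # and absolute agreement is close, not just rank agreement
        assert (np.abs(res["p_perm"] - res["p_hyper"]) < 0.06).all()

    def test_length_bias_is_corrected(self):
        """A length-biased candidate set fools the naive test only.

        Long genes populate one term; candidates drawn proportionally to
        length are enriched for that term by construction, which the
        hypergeometric test flags, while the length-weighted null
        absorbs it.
        """
        rng = np.random.default_rng(108)
        n = 600
        genes = pd.Index([f"g{i}" for i in range(n)])
        lengths = pd.Series(
            np.where(np.arange(n) < 100, 30_000.0, 1_000.0), index=genes
        )
        ann = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(100)], "term": "LONG"}
        )
        idx = weighted_sample_indices(
            np.random.default_rng(109), lengths.to_numpy(), 80
        )
        gene_set = list(genes[idx])
        res = go_enrichment(gene_set, lengths, ann, n_perm=3000, seed=12)
        row = res.set_index("term").loc["LONG"]
        assert row["p_hyper"] < 1e-4
        assert row["p_perm"] > 0.05

    def test_unknown_gene_raises_and_uncovered_term_warns(self):
        rng = np.random.default_rng(110)
        lengths, ann = _toy_universe(rng, n_genes=50, n_terms=3)
        with pytest.raises(ValueError):
            go_enrichment(["nope"], lengths, ann, n_perm=10, seed=0)
        ann2 = pd.concat(
            [ann, pd.DataFrame({"gene_id": ["zzz"], "term": ["ORPHAN"]})]
        )
        with pytest.warns(UserWarning, match="skipped"):
            res = go_enrichment(list(lengths.index[:5]), lengths, ann2,
                                n_perm=10, seed=0)
        assert "ORPHAN" not in set(res["term"])


class TestStudyOverlap:
    def test_shared_genes(self):
        res = study_overlap({"s1": ["A", "B", "C"], "s2": ["B", "C", "D"],
                             "s3": ["E"]})
        assert set(res["shared_genes"]) == {"B", "C"}
        assert res["overlap_matrix"].loc["s1", "s2"] == 2

    def test_identical_lists_have_minimal_enrichment_p(self):
        uni = [f"g{i}" for i in range(1000)]
        lists = {"a": uni[:20], "b": uni[:20]}
        res = study_overlap(lists, universe=uni)
        assert res["enrichment_p"].loc["a", "b"] < 1e-20

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            study_overlap({"a": ["x"], "b": []})

    def test_null_overlap_enrichment_p_is_uniform(self):
        rng = np.random.default_rng(111)
        uni = np.array([f"g{i}" for i in range(2000)])
        ps = []
        for _ in range(300):
            la = rng.choice(uni, 60, replace=False)
            lb = rng.choice(uni, 60, replace=False)
            res = study_overlap({"a": la, "b": lb}, universe=uni)
            ps.append(res["enrichment_p"].loc["a", "b"])
        # discrete p-values are conservative; demand no anti-conservatism
        assert np.mean(np.array(ps) < 0.05) < 0.08
        assert np.mean(ps) > 0.4
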