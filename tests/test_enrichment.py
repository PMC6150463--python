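"""Wakefield credible sets and permutation-based cell-type enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import t2dclust as tc
from t2dclust.enrichment import CellTypeAnnotation


def cs(locus, positions, betas, ses, chrom="1", omega=0.04):
    df = pd.DataFrame({
        "variant_id": [f"{locus}_v{i}" for i in range(len(positions))],
        "chrom": chrom, "pos": positions, "beta": betas, "se": ses})
    return tc.credible_set(locus, df, omega)


def annot(name, intervals, chrom="1", state="Active Enhancer 1"):
    bed = pd.DataFrame([(chrom, s, e, state) for s, e in intervals],
                       columns=["chrom", "start", "end", "state"])
    return CellTypeAnnotation.from_frame(name, bed)


class TestWakefieldAbf:
    def test_zero_prior_variance_gives_unit_bf(self):
        assert tc.wakefield_abf(3.0, 0.1, 0.0) == pytest.approx(1.0)

    def test_null_effect_favors_null(self):
        se, omega = 0.1, 0.04
        expected = math.sqrt(se**2 / (se**2 + omega))
        got = tc.wakefield_abf(0.0, se, omega)
        assert got == pytest.approx(expected)
        assert got < 1.0

    def test_closed_form_hand_value(self):
        beta, se, omega = 0.1, 0.05, 0.04
        v = se * se
        expected = math.sqrt(v / (v + omega)) * math.exp(
            omega * beta * beta / (2 * v * (v + omega)))
        assert tc.wakefield_abf(beta, se, omega) == pytest.approx(expected,
                                                                  rel=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            tc.wakefield_abf(0.1, 0.0, 0.04)


class TestCredibleSet:
    def test_single_variant_posterior_one(self):
        s = cs("L", [100], [0.2], [0.05])
        assert s.variants["posterior"].iloc[0] == pytest.approx(1.0)

    def test_identical_stats_split_evenly(self):
        s = cs("L", [100, 200], [0.2, 0.2], [0.05, 0.05])
        np.testing.assert_allclose(s.variants["posterior"], [0.5, 0.5])

    def test_three_variants_match_hand_normalization(self):
        betas, ses, omega = [0.10, 0.05, 0.02], [0.04, 0.05, 0.06], 0.04
        abfs = [tc.wakefield_abf(b, s, omega) for b, s in zip(betas, ses)]
        s = cs("L", [1, 2, 3], betas, ses, omega=omega)
        np.testing.assert_allclose(s.variants["posterior"],
                                   np.array(abfs) / np.sum(abfs), rtol=1e-12)

    def test_posteriors_always_normalized(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = rng.integers(1, 8)
            s = cs("L", rng.integers(1, 10**6, n),
                   rng.normal(0, 0.2, n), rng.uniform(0.01, 0.3, n))
            assert s.variants["posterior"].sum() == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_empty_locus_rejected(self):
        with pytest.raises(ValueError):
            tc.credible_set("L", pd.DataFrame(
                columns=["variant_id", "chrom", "pos", "beta", "se"]), 0.04)


class TestCelltypeProbability:
    def test_full_overlap_gives_one(self):
        s = cs("L", [101, 105], [0.2, 0.1], [0.05, 0.05])
        a = annot("ct", [(100, 110)])
        assert tc.celltype_probability([s], a) == pytest.approx(1.0)

    def test_no_overlap_gives_zero(self):
        s = cs("L", [101], [0.2], [0.05])
        a = annot("ct", [(500, 600)])
        assert tc.celltype_probability([s], a) == 0.0

    def test_hand_arithmetic_two_loci(self):
        # posterior mass 0.6 and 0.2 overlapped across two loci -> 0.4
        s1 = cs("L1", [101, 201], [0.2, 0.2], [0.05, 0.05])  # 0.5 + 0.5
        s1.variants["posterior"] = [0.6, 0.4]
        s2 = cs("L2", [301, 401], [0.2, 0.2], [0.05, 0.05])
        s2.variants["posterior"] = [0.2, 0.8]
        a = annot("ct", [(100, 101), (300, 301)])  # covers pos 101 and 301
        assert tc.celltype_probability([s1, s2], a) == pytest.approx(0.4)

    def test_bed_half_open_boundaries(self):
        a = annot("ct", [(100, 110)])
        assert a.contains("1", 101)       # first base inside
        assert a.contains("1", 110)       # last base inside
        assert not a.contains("1", 100)   # before the interval
        assert not a.contains("1", 111)   # past the half-open end

    def test_invariant_to_splitting_intervals(self):
        s = cs("L", [101, 105, 108], [0.2, 0.1, 0.05],
               [0.05, 0.05, 0.05])
        whole = annot("ct", [(100, 110)])
        split = annot("ct", [(100, 104), (104, 107), (107, 110)])
        assert tc.celltype_probability([s], whole) == pytest.approx(
            tc.celltype_probability([s], split))

    def test_duplicate_locus_counted_once(self):
        s = cs("L", [101], [0.2], [0.05])
        a = annot("ct", [(100, 110)])
        assert tc.celltype_probability([s, s], a) == pytest.approx(1.0)


class TestPermutationTests:
    def two_ct_instance(self, seed=0):
        rng = np.random.default_rng(seed)
        loci = [cs(f"L{i}", [1000 * i + 1], [float(rng.uniform(0, 0.3))],
                   [0.05]) for i in range(3)]
        a1 = annot("ct1", [(1000 * i, 1000 * i + 10) for i in (0, 1)])
        a2 = annot("ct2", [(2000, 2010)])
        return loci, [a1, a2]

    def test_extreme_observed_hits_floor(self):
        # observed score beats every sampled permutation -> p = 1/(n_perm+1);
        # many empty cell types make re-drawing the identity assignment
        # (probability 12^-5 per permutation) negligible
        loci = [cs(f"L{i}", [10 * i + 1], [0.2], [0.05]) for i in range(5)]
        a_hit = annot("ct_hit", [(10 * i, 10 * i + 5) for i in range(5)])
        misses = [annot(f"ct_miss{j}", [(9000 + 20 * j, 9010 + 20 * j)])
                  for j in range(11)]
        cfg = tc.EnrichConfig(n_perm=100, seed=1)
        p = tc.permute_within(loci, [a_hit] + misses, cfg)
        assert p["ct_hit"] == pytest.approx(1 / 101)

    def test_constant_scores_give_p_one(self):
        loci = [cs(f"L{i}", [10 * i + 1], [0.2], [0.05]) for i in range(3)]
        a1 = annot("ct1", [(10 * i, 10 * i + 5) for i in range(3)])
        a2 = annot("ct2", [(10 * i, 10 * i + 5) for i in range(3)])
        cfg = tc.EnrichConfig(n_perm=50, seed=2)
        p = tc.permute_within(loci, [a1, a2], cfg)
        assert (p == 1.0).all()

    def test_sampled_p_matches_exhaustive_enumeration(self):
        # 3 loci x 2 cell types: every joint row-permutation assignment is
        # enumerable (2^3), giving the exact null probability
        loci, annots = self.two_ct_instance()
        M = tc.overlap_matrix(loci, annots).to_numpy()
        observed = M.sum(axis=0) / M.shape[0]
        exact = []
        for col in range(2):
            hits = total = 0
            for flips in itertools.product([False, True], repeat=3):
                perm = np.array([row[::-1] if f else row
                                 for row, f in zip(M, flips)])
                total += 1
                hits += (perm.sum(axis=0) / 3)[col] >= observed[col]
            exact.append(hits / total)
        cfg = tc.EnrichConfig(n_perm=20_000, seed=5)
        sampled = tc.permute_within(loci, annots, cfg)
        for col, ct in enumerate(["ct1", "ct2"]):
            se = math.sqrt(exact[col] * (1 - exact[col]) / cfg.n_perm)
            assert abs(sampled[ct] - exact[col]) <= 3 * se + 2 / cfg.n_perm

    def test_within_degenerate_space_rejected(self):
        loci = [cs("L", [1], [0.2], [0.05])]
        with pytest.raises(ValueError):
            tc.permute_within(loci, [annot("ct", [(0, 5)])],
                              tc.EnrichConfig(n_perm=10))

    def test_across_requires_two_clusters(self):
        loci = [cs("L", [1], [0.2], [0.05])]
        with pytest.raises(ValueError):
            tc.permute_across({"c1": loci}, [annot("ct", [(0, 5)])],
                              tc.EnrichConfig(n_perm=10))

    def test_across_deterministic_given_seed(self):
        sets = tc.gen_credible_sets({"c1": ["a", "b"], "c2": ["c", "d"]},
                                    seed=3)
        beds, _ = tc.gen_annotations(sets, ["ct1", "ct2"], seed=4,
                                     overlap_prob_high=0.5,
                                     overlap_prob_low=0.5)
        annots = [CellTypeAnnotation.from_frame(ct, bed)
                  for ct, bed in beds.items()]
        cfg = tc.EnrichConfig(n_perm=200, seed=9)
        p1 = tc.permute_across(sets, annots, cfg)
        p2 = tc.permute_across(sets, annots, cfg)
        pd.testing.assert_frame_equal(p1, p2)

    def test_exchangeable_clusters_average_p_near_half(self):
        # two same-size clusters drawn from one null: across-cluster p is
        # approximately uniform, so its mean over instances is ~0.5
        rng = np.random.default_rng(21)
        ps = []
        for i in range(60):
            sets = tc.gen_credible_sets(
                {"c1": [f"a{i}_{j}" for j in range(3)],
                 "c2": [f"b{i}_{j}" for j in range(3)]},
                seed=int(rng.integers(2**31)))
            beds, _ = tc.gen_annotations(sets, ["ct"], seed=int(
                rng.integers(2**31)), overlap_prob_high=0.5,
                overlap_prob_low=0.5)
            annots = [CellTypeAnnotation.from_frame("ct", beds["ct"])]
            cfg = tc.EnrichConfig(n_perm=99, seed=int(rng.integers(2**31)))
            p = tc.permute_across(sets, annots, cfg)
            ps.extend(p.to_numpy().ravel())
        assert abs(np.mean(ps) - 0.5) < 0.08

    def test_planted_enrichment_detected(self):
        sets = tc.gen_credible_sets(
            {"c1": [f"a{j}" for j in range(6)],
             "c2": [f"b{j}" for j in range(6)]}, seed=0)
        beds, _ = tc.gen_annotations(
            sets, ["ct_target", "ct_other"],
            enriched_pairs={("c1", "ct_target")},
            overlap_prob_high=0.95, overlap_prob_low=0.05, seed=1)
        annots = [CellTypeAnnotation.from_frame(ct, bed)
                  for ct, bed in beds.items()]
        cfg = tc.EnrichConfig(n_perm=10_000, seed=2)
        table = tc.enrichment_table({"c1": sets["c1"], "c2": sets["c2"]},
                                    annots, cfg)
        row = table[(table.cluster == "c1")
                    & (table.cell_type == "ct_target")].iloc[0]
        assert row["p_within"] < 0.05
        assert row["p_across"] < 0.05

    def test_p_values_respect_add_one_bounds(self):
        loci, annots = self.two_ct_instance(seed=8)
        cfg = tc.EnrichConfig(n_perm=37, seed=3)
        p = tc.permute_within(loci, annots, cfg)
        assert ((p >= 1 / 38) & (p <= 1.0)).all()
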