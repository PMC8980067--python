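"""Genotype QC, relatedness, clumping, and PRS tests against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gxebrain.genotype import (
    GenotypeMatrix,
    QcThresholds,
    align_alleles,
    compute_prs,
    genotype_pca,
    greedy_clump,
    hwe_exact_test,
    ibd_estimate,
    ld_r2,
    optimize_threshold,
    prune_for_ibd,
    snp_qc,
)
from gxebrain.simulate import (
    SimulationConfig,
    offspring_dosage,
    simulate_genotypes,
    simulate_gwas_weights,
)


def make_matrix(dosage, chrom=None, pos=None, quality=None):
    dosage = np.asarray(dosage, dtype=float)
    n_sub, n_var = dosage.shape
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(n_var)],
            "chrom": chrom if chrom is not None else ["1"] * n_var,
            "pos": pos if pos is not None else 1 + 1000 * np.arange(n_var),
            "ref": ["A"] * n_var,
            "alt": ["G"] * n_var,
        }
    )
    return GenotypeMatrix(
        [f"S{i}" for i in range(n_sub)], variants, dosage, quality=quality
    )


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact HWE p via the conditional distribution of the het count.

    P(h | n, n_a) = 2^h n! n_a! n_A! / (nAA! h! naa! (2n)!), enumerated with
    exact integer arithmetic over every compatible heterozygote count.
    """
    from fractions import Fraction

    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    f = math.factorial
    norm = Fraction(f(n) * f(n_a) * f(n_A), f(2 * n))
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - hom_rare - h
        probs[h] = norm * Fraction(2**h, f(hom_rare) * f(h) * f(hom_common))
    total = sum(probs.values())
    obs = probs[n_Aa] / total
    return float(min(1, sum(v / total for v in probs.values() if v <= probs[n_Aa])))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(10, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_matches_enumeration_oracle_351(self):
        assert hwe_exact_test(3, 5, 1) == pytest.approx(
            hwe_enumeration_oracle(3, 5, 1), abs=1e-12
        )

    @pytest.mark.parametrize(
        "table", [(3, 5, 1), (10, 1, 10), (0, 20, 0), (5, 5, 5), (1, 1, 1), (12, 3, 0)]
    )
    def test_matches_enumeration_oracle(self, table):
        assert hwe_exact_test(*table) == pytest.approx(
            hwe_enumeration_oracle(*table), abs=1e-12
        )

    @given(
        st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_allele_label_symmetry(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(
            hwe_exact_test(b, h, a), abs=1e-12
        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestSnpQc:
    def test_low_call_rate_variant_removed(self):
        dosage = np.ones((20, 2))
        dosage[:10, 0] += np.arange(10) % 2  # variant 0 polymorphic
        dosage[:10, 1] += np.arange(10) % 2
        dosage[:2, 1] = np.nan  # 10% missing < 95% call rate
        g = make_matrix(dosage)
        kept, report = snp_qc(g, QcThresholds(min_subject_call_rate=0.0))
        assert report.variant_table.loc[1, "pass_call_rate"] == False  # noqa: E712
        assert "v1" not in list(kept.variants["id"])

    def test_monomorphic_variant_removed(self):
        dosage = np.column_stack([np.zeros(30), np.arange(30) % 3])
        g = make_matrix(dosage)
        kept, report = snp_qc(g)
        assert list(kept.variants["id"]) == ["v1"]
        assert report.variant_table.loc[0, "maf"] == 0.0

    def test_quality_masking_only_with_matrix(self):
        dosage = np.tile(np.arange(20) % 3, (2, 1)).T.astype(float)
        quality = np.ones_like(dosage)
        quality[:3, 0] = 0.05  # below 0.2 -> masked -> call rate 17/20 = 0.85
        g = make_matrix(dosage, quality=quality)
        kept, report = snp_qc(g, QcThresholds(min_subject_call_rate=0.0))
        assert report.n_calls_masked_quality == 3
        assert list(kept.variants["id"]) == ["v1"]

    def test_subject_call_rate_filter(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(20, 50)).astype(float)
        dosage[0, :10] = np.nan  # subject 0 call rate 0.8
        g = make_matrix(dosage)
        kept, report = snp_qc(g, QcThresholds(min_maf=0.0, min_hwe_p=0.0,
                                              min_variant_call_rate=0.0))
        assert "S0" not in kept.subject_ids
        assert report.n_subjects_removed == 1

    def test_filter_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(42)
        dosage = rng.integers(0, 3, size=(20, 50)).astype(float)
        dosage[rng.random(dosage.shape) < 0.03] = np.nan
        g = make_matrix(dosage)
        thr = QcThresholds(min_subject_call_rate=0.0)
        kept, report = snp_qc(g, thr)
        # brute-force recount per variant
        n_pass = 0
        for j in range(50):
            col = dosage[:, j]
            obs = col[~np.isnan(col)]
            cr = len(obs) / 20
            af = obs.mean() / 2
            maf = min(af, 1 - af)
            hwe = hwe_exact_test(
                int((obs == 2).sum()), int((obs == 1).sum()), int((obs == 0).sum())
            )
            if cr >= thr.min_variant_call_rate and maf >= thr.min_maf and hwe >= thr.min_hwe_p:
                n_pass += 1
        assert kept.n_variants == n_pass

    def test_everything_filtered_raises(self):
        g = make_matrix(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="no variants"):
            snp_qc(g)


# ---------------------------------------------------------------------------
# LD and clumping
# ---------------------------------------------------------------------------

class TestLdR2:
    def test_self_correlation_is_one(self, rng):
        d = rng.integers(0, 3, 50).astype(float)
        assert ld_r2(d, d) == pytest.approx(1.0)

    def test_perfect_anticorrelation_squares_to_one(self, rng):
        d = rng.integers(0, 3, 50).astype(float)
        assert ld_r2(d, 2 - d) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(40):
            a = rng.binomial(2, 0.3, 1000).astype(float)
            b = rng.binomial(2, 0.3, 1000).astype(float)
            hits += ld_r2(a, b) < 0.02
        assert hits / 40 >= 0.95

    def test_zero_variance_returns_zero(self):
        assert ld_r2(np.ones(10), np.arange(10, dtype=float) % 3) == 0.0


def clump_oracle(gwas, genotypes, r2_threshold, window_kb):
    """Order-respecting exhaustive re-implementation of greedy clumping."""
    meta = genotypes.variants.set_index("id")
    shared = gwas[gwas["id"].isin(meta.index)].copy()
    shared["c"] = [meta.at[i, "chrom"] for i in shared["id"]]
    shared["bp"] = [meta.at[i, "pos"] for i in shared["id"]]
    order = shared.sort_values(["p_value", "c", "bp"], kind="mergesort")
    kept = []
    col = {v: i for i, v in enumerate(genotypes.variants["id"])}
    for row in order.itertuples():
        ok = True
        for kid in kept:
            same_chrom = meta.at[kid, "chrom"] == row.c
            close = abs(meta.at[kid, "pos"] - row.bp) <= window_kb * 1000
            if same_chrom and close:
                r2 = ld_r2(
                    genotypes.dosage[:, col[row.id]], genotypes.dosage[:, col[kid]]
                )
                if r2 >= r2_threshold:
                    ok = False
                    break
        if ok:
            kept.append(row.id)
    return kept


class TestClump:
    def test_correlated_pair_keeps_most_significant(self, rng):
        d = rng.integers(0, 3, size=(100, 1)).astype(float)
        dosage = np.hstack([d, d])  # perfect LD
        g = make_matrix(dosage, pos=[1000, 2000])
        gwas = pd.DataFrame(
            {"id": ["v0", "v1"], "p_value": [1e-4, 1e-8], "weight": [0.1, 0.1],
             "effect_allele": ["G", "G"], "other_allele": ["A", "A"]}
        )
        assert greedy_clump(gwas, g, 0.1, 250.0) == ["v1"]

    def test_threshold_one_keeps_all_noisy_variants(self, rng):
        dosage = rng.integers(0, 3, size=(60, 10)).astype(float)
        g = make_matrix(dosage)
        gwas = pd.DataFrame(
            {"id": [f"v{j}" for j in range(10)],
             "p_value": rng.uniform(size=10), "weight": np.zeros(10),
             "effect_allele": ["G"] * 10, "other_allele": ["A"] * 10}
        )
        assert len(greedy_clump(gwas, g, 1.0, 250.0)) == 10

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        cfg = SimulationConfig(
            n_subjects=120, n_bds=60, n_snps=30, n_causal_snps=5,
            ld_block_size=3, ld_rho=0.7, seed=8,
        )
        g = simulate_genotypes(cfg)
        gwas, *_ = simulate_gwas_weights(cfg, g)
        ours = greedy_clump(gwas, g, 0.2, 50.0)
        oracle = clump_oracle(gwas, g, 0.2, 50.0)
        assert ours == oracle


# ---------------------------------------------------------------------------
# IBD
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def population():
    cfg = SimulationConfig(
        n_subjects=40, n_bds=20, n_snps=2000, n_causal_snps=0,
        ld_block_size=1, ld_rho=0.0, maf_range=(0.2, 0.5), seed=17,
    )
    return simulate_genotypes(cfg)


class TestIbd:
    def test_duplicate_subject_detected(self, population):
        dup = GenotypeMatrix(
            ["A", "B"], population.variants,
            np.vstack([population.dosage[0], population.dosage[0]]),
        )
        est = ibd_estimate(dup)[0]
        assert est.pi_hat >= 0.95

    def test_unrelated_pairs_near_zero(self, population):
        sub = population.subset_subjects(np.arange(12))
        ests = ibd_estimate(sub)
        assert np.mean([e.pi_hat for e in ests]) < 0.05

    def test_parent_offspring_near_half(self, population):
        rng = np.random.default_rng(19)
        child = offspring_dosage(population.dosage[0], population.dosage[1], rng)
        trio = GenotypeMatrix(
            ["mother", "father", "child"], population.variants,
            np.vstack([population.dosage[0], population.dosage[1], child]),
        )
        ests = {(e.subject_a, e.subject_b): e.pi_hat for e in ibd_estimate(trio)}
        assert 0.4 <= ests[("mother", "child")] <= 0.6
        assert 0.4 <= ests[("father", "child")] <= 0.6
        assert ests[("mother", "father")] < 0.1

    def test_low_information_flagged(self, population):
        sub = population.subset_subjects(np.arange(2)).subset_variants(np.arange(30))
        est = ibd_estimate(sub)[0]
        assert est.low_information

    def test_prune_reduces_ld(self, small_cohort):
        g = small_cohort.genotypes
        pruned = prune_for_ibd(g, r2_threshold=0.2)
        assert 0 < len(pruned) < g.n_variants
        cols = g.variant_index(pruned)
        worst = 0.0
        for a, b in itertools.combinations(cols[:40], 2):
            if abs(g.variants["pos"].iat[a] - g.variants["pos"].iat[b]) < 25000:
                worst = max(worst, ld_r2(g.dosage[:, a], g.dosage[:, b]))
        assert worst < 0.2


# ---------------------------------------------------------------------------
# allele alignment and PRS
# ---------------------------------------------------------------------------

class TestAlignAndPrs:
    def gwas_for(self, g, weights, p_values, effect_is_alt=True):
        v = g.variants
        return pd.DataFrame(
            {
                "id": v["id"],
                "effect_allele": v["alt"] if effect_is_alt else v["ref"],
                "other_allele": v["ref"] if effect_is_alt else v["alt"],
                "weight": weights,
                "p_value": p_values,
            }
        )

    def test_hand_arithmetic(self):
        g = make_matrix(np.array([[2.0, 1.0]]))
        gwas = self.gwas_for(g, [0.1, -0.2], [0.01, 0.01])
        res = compute_prs(g, gwas, ["v0", "v1"], 0.05)
        assert res.scores.iloc[0] == pytest.approx(0.2 - 0.2, abs=1e-12)

    def test_zero_weights_zero_scores(self, rng):
        g = make_matrix(rng.integers(0, 3, (10, 4)).astype(float))
        gwas = self.gwas_for(g, np.zeros(4), np.full(4, 0.01))
        res = compute_prs(g, gwas, list(g.variants["id"]), 0.05)
        assert np.all(res.scores == 0)

    def test_ref_effect_allele_flips_dosage(self):
        g = make_matrix(np.array([[0.0], [1.0], [2.0]]))
        gwas = self.gwas_for(g, [0.5], [0.01], effect_is_alt=False)
        res = compute_prs(g, gwas, ["v0"], 0.05)
        # w*(2-d): 1.0, 0.5, 0.0
        np.testing.assert_allclose(res.scores.to_numpy(), [1.0, 0.5, 0.0])

    def test_flip_invariance(self, rng):
        dosage = rng.integers(0, 3, (30, 8)).astype(float)
        g = make_matrix(dosage)
        w = rng.normal(size=8)
        p = rng.uniform(0.001, 0.04, 8)
        gwas_alt = self.gwas_for(g, w, p, effect_is_alt=True)
        # express the same effects on the other allele: swap alleles, negate w
        gwas_ref = self.gwas_for(g, -w, p, effect_is_alt=False)
        ids = list(g.variants["id"])
        s1 = compute_prs(g, gwas_alt, ids, 0.05).scores.to_numpy()
        s2 = compute_prs(g, gwas_ref, ids, 0.05).scores.to_numpy()
        # identical up to the constant offset 2*sum(w)
        np.testing.assert_allclose(s1 - s1.mean(), s2 - s2.mean(), atol=1e-12)

    def test_strand_ambiguous_dropped(self):
        dosage = np.array([[0.0, 1.0], [1.0, 2.0]])
        variants = pd.DataFrame(
            {"id": ["amb", "ok"], "chrom": ["1", "1"], "pos": [1, 1001],
             "ref": ["A", "A"], "alt": ["T", "G"]}
        )
        g = GenotypeMatrix(["S0", "S1"], variants, dosage)
        gwas = pd.DataFrame(
            {"id": ["amb", "ok"], "effect_allele": ["A", "G"],
             "other_allele": ["T", "A"], "weight": [1.0, 1.0],
             "p_value": [0.01, 0.01]}
        )
        aln = align_alleles(gwas, variants)
        assert aln.dropped_ambiguous == ["amb"]
        assert "ok" in aln.weights

    def test_mismatched_alleles_dropped(self):
        variants = pd.DataFrame(
            {"id": ["v0"], "chrom": ["1"], "pos": [1], "ref": ["A"], "alt": ["G"]}
        )
        gwas = pd.DataFrame(
            {"id": ["v0"], "effect_allele": ["C"], "other_allele": ["A"],
             "weight": [1.0], "p_value": [0.01]}
        )
        aln = align_alleles(gwas, variants)
        assert aln.dropped_mismatch == ["v0"]

    def test_missing_dosage_imputed_with_allele_frequency(self):
        dosage = np.array([[2.0], [0.0], [np.nan], [2.0]])
        g = make_matrix(dosage)
        gwas = self.gwas_for(g, [1.0], [0.01])
        res = compute_prs(g, gwas, ["v0"], 0.05)
        af = (2 + 0 + 2) / 6  # ALT frequency among observed
        assert res.scores.iloc[2] == pytest.approx(2 * af)

    def test_threshold_sets_nested(self, small_cohort):
        g = small_cohort.genotypes
        gwas = small_cohort.gwas
        clumped = greedy_clump(gwas, g)
        sets = {}
        for pt in (0.05, 0.10, 0.25, 0.50):
            sets[pt] = set(compute_prs(g, gwas, clumped, pt).variant_ids)
        assert sets[0.05] <= sets[0.10] <= sets[0.25] <= sets[0.50]

    def test_empty_threshold_warns_and_zeroes(self, small_cohort):
        g = small_cohort.genotypes
        clumped = greedy_clump(small_cohort.gwas, g)
        with pytest.warns(UserWarning, match="no variants"):
            res = compute_prs(g, small_cohort.gwas, clumped, 1e-300)
        assert np.all(res.scores == 0)


class TestOptimizeThreshold:
    def test_single_point_grid_returned(self, small_cohort):
        g = small_cohort.genotypes
        clumped = greedy_clump(small_cohort.gwas, g)
        fh = small_cohort.subjects.set_index("subject_id")["family_history"]
        res = optimize_threshold(g, small_cohort.gwas, clumped, fh,
                                 grid=np.array([0.3]))
        assert res.p_threshold == 0.3
        assert len(res.scan) == 1

    def test_causal_structure_selects_small_threshold(self):
        # family history driven by the true PRS; causal GWAS p-values < 1e-3;
        # non-causal SNPs carry sizeable noise weights so permissive
        # thresholds dilute the signal and the informative region is small
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_subjects=300, n_bds=150, n_snps=200, n_causal_snps=20,
                ld_block_size=5, seed=100 + seed,
            )
            g = simulate_genotypes(cfg)
            gwas, causal_ids, causal_w = simulate_gwas_weights(
                cfg, g, np.random.default_rng(cfg.seed + 1), null_weight_sd=0.15
            )
            dosage = np.nan_to_num(g.dosage)
            score = dosage[:, g.variant_index(causal_ids)] @ causal_w
            score = (score - score.mean()) / score.std(ddof=1)
            rng = np.random.default_rng(1000 + seed)
            fh = pd.Series(
                (rng.random(g.n_subjects) < 1 / (1 + np.exp(-1.5 * score))).astype(int),
                index=g.subject_ids,
            )
            clumped = greedy_clump(gwas, g)
            res = optimize_threshold(
                g, gwas, clumped, fh,
                grid=np.round(np.arange(0.01, 0.51, 0.02), 4),
            )
            hits += res.p_threshold <= 0.05
        assert hits >= 0.8 * n_seeds - 1

    def test_single_class_rejected(self, small_cohort):
        g = small_cohort.genotypes
        fh = pd.Series(1, index=g.subject_ids)
        with pytest.raises(ValueError, match="class"):
            optimize_threshold(g, small_cohort.gwas, [], fh)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestGenotypePca:
    def test_two_populations_separate_on_pc1(self):
        cfg_a = SimulationConfig(n_subjects=60, n_bds=30, n_snps=300,
                                 n_causal_snps=0, maf_range=(0.05, 0.2), seed=51)
        cfg_b = SimulationConfig(n_subjects=60, n_bds=30, n_snps=300,
                                 n_causal_snps=0, maf_range=(0.3, 0.5), seed=52)
        ga = simulate_genotypes(cfg_a)
        gb = simulate_genotypes(cfg_b)
        merged = GenotypeMatrix(
            [f"A{i}" for i in range(60)] + [f"B{i}" for i in range(60)],
            ga.variants,
            np.vstack([ga.dosage, gb.dosage]),
        )
        coords, var_exp = genotype_pca(merged, 2)
        labels = np.array([0] * 60 + [1] * 60)
        r = np.corrcoef(coords[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_variance_explained_non_increasing_and_components_orthogonal(
        self, small_cohort
    ):
        coords, var_exp = genotype_pca(small_cohort.genotypes, 5)
        assert np.all(np.diff(var_exp) <= 1e-12)
        gram = coords.T @ coords
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_rank_truncation_warns(self):
        g = make_matrix(np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]]))
        with pytest.warns(UserWarning, match="rank"):
            coords, _ = genotype_pca(g, 5)
        assert coords.shape[1] <= 2
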