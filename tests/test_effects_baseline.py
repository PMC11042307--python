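import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from giftmap.effects_baseline import (
    bonferroni_threshold,
    fixed_effects_adjust,
    gene_effect_dominance,
    group_means,
    hwe_exact_test,
    ld_prune,
    marker_effects,
    ols_marker_test,
    snp_filters,
    two_group_ttest,
)
from giftmap.encoding import GenotypeMatrix, MicrostateVector, SnpRecord


def _vec(values):
    return MicrostateVector("s", np.array(values, dtype=float))


class TestGroupMeansAndEffects:
    def test_means_per_group(self):
        mu_plus, mu_zero, mu_minus = group_means([1.0, 2.0, 3.0], _vec([1, 1, -1]))
        assert mu_plus == 1.5 and mu_minus == 3.0 and math.isnan(mu_zero)

    @pytest.mark.parametrize(
        "mus,expected",
        [((1.0, 0.0, -1.0), (1.0, 0.0)), ((2.0, 2.0, 0.0), (1.0, 1.0))],
    )
    def test_additive_and_dominant_hand_cases(self, mus, expected):
        assert gene_effect_dominance(*mus) == pytest.approx(expected)

    def test_undefined_when_homozygote_group_empty(self):
        eff = marker_effects([1.0, 2.0], _vec([1, 0]))
        assert not eff.defined
        assert math.isnan(eff.a)

    def test_alternative_convention_switch(self):
        a, d = gene_effect_dominance(2.0, 0.5, 0.0, convention="a_minus_mu0")
        assert (a, d) == (1.0, 0.5)
        with pytest.raises(ValueError):
            gene_effect_dominance(1, 1, 1, convention="bogus")

    def test_equivariance_shift_and_scale(self, rng):
        res = rng.normal(size=90)
        vals = rng.choice([1.0, 0.0, -1.0], size=90)
        v = _vec(vals)
        e0 = marker_effects(res, v)
        e_shift = marker_effects(res + 10, v)
        assert e_shift.a == pytest.approx(e0.a) and e_shift.d == pytest.approx(e0.d)
        e_scale = marker_effects(3 * res, v)
        assert e_scale.a == pytest.approx(3 * e0.a)
        assert e_scale.d == pytest.approx(3 * e0.d)


class TestTTestAndOls:
    def test_identical_groups(self):
        t, p = two_group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_p_monotone_in_shift(self):
        last = 1.1
        for shift in (0.0, 2.0, 5.0, 20.0):
            _, p = two_group_ttest([0.0, 1.0], [0.0 + shift, 1.0 + shift])
            assert p <= last + 1e-12
            last = p

    def test_exact_linear_relation(self):
        v = _vec([1, 0, -1, 1, 0, -1])
        beta, se, p = ols_marker_test([2.0, 0.0, -2.0, 2.0, 0.0, -2.0], v)
        assert beta == pytest.approx(2.0)
        assert p < 1e-10

    def test_monomorphic_undefined(self):
        beta, se, p = ols_marker_test([1.0, 2.0, 3.0], _vec([0, 0, 0]))
        assert math.isnan(p)

    def test_null_p_uniform(self, rng):
        # residual independent of dosage: KS distance from uniform is small
        ps = []
        for _ in range(400):
            vals = rng.choice([1.0, -1.0], size=40)
            res = rng.normal(size=40)
            ps.append(ols_marker_test(res, _vec(vals))[2])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").statistic < 0.08

    def test_slope_t_equals_two_group_t_without_heterozygotes(self, rng):
        vals = np.repeat([1.0, -1.0], [12, 9])
        res = rng.normal(size=21)
        v = _vec(vals)
        _, _, p_ols = ols_marker_test(res, v)
        _, p_t = two_group_ttest(res[vals == 1], res[vals == -1])
        assert p_ols == pytest.approx(p_t, rel=1e-9)


class TestFixedEffects:
    def test_single_factor_gives_within_group_deviations(self):
        y = np.array([1.0, 3.0, 10.0, 14.0])
        f = pd.DataFrame({"g": ["a", "a", "b", "b"]})
        res = fixed_effects_adjust(y, f)
        np.testing.assert_allclose(res, [-1.0, 1.0, -2.0, 2.0], atol=1e-9)

    def test_idempotent(self, rng):
        y = rng.normal(size=60)
        f = pd.DataFrame(
            {"farm": rng.integers(0, 5, 60), "sex": rng.integers(0, 2, 60)}
        )
        r1 = fixed_effects_adjust(y, f)
        r2 = fixed_effects_adjust(r1, f)
        np.testing.assert_allclose(r1, r2, atol=1e-9)
        assert abs(r1.sum()) < 1e-8

    def test_log_transform(self):
        res = fixed_effects_adjust(np.array([1.0, math.e]), None, log_transform=True)
        np.testing.assert_allclose(res, [-0.5, 0.5])
        with pytest.raises(ValueError):
            fixed_effects_adjust(np.array([-1.0]), None, log_transform=True)

    def test_noise_variance_recovery_farm_sex_design(self, rng):
        n = 360
        farm = rng.integers(0, 11, n)
        sex = rng.integers(0, 2, n)
        noise = rng.normal(0, 1.0, n)
        y = 5.0 + 0.8 * farm + 1.5 * sex + noise
        res = fixed_effects_adjust(y, pd.DataFrame({"farm": farm, "sex": sex}))
        assert res.var() == pytest.approx(noise.var(), rel=0.10)

    def test_collinear_factor_harmless(self, rng):
        f = pd.DataFrame({"a": ["x", "x", "y", "y"], "b": ["x", "x", "y", "y"]})
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = fixed_effects_adjust(y, f)
        np.testing.assert_allclose(res, [-0.5, 0.5, -0.5, 0.5], atol=1e-9)

    def test_singleton_level_warns(self):
        with pytest.warns(UserWarning, match="single-observation"):
            fixed_effects_adjust(
                np.array([1.0, 2.0, 3.0]), pd.DataFrame({"g": ["a", "a", "b"]})
            )


def _hwe_oracle(n_het, n_hom_a, n_hom_b):
    """Exact-Fraction conditional distribution of heterozygote counts."""
    n = n_het + n_hom_a + n_hom_b
    rare = 2 * min(n_hom_a, n_hom_b) + n_het
    common = 2 * n - rare
    f = math.factorial

    def prob(h):
        hom_r = (rare - h) // 2
        hom_c = (common - h) // 2
        return Fraction(
            f(n) * 2**h * f(rare) * f(common),
            f(hom_r) * f(hom_c) * f(h) * f(2 * n),
        )

    hs = [h for h in range(rare % 2, min(rare, common) + 1, 2)]
    probs = {h: prob(h) for h in hs}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    @pytest.mark.parametrize(
        "het,hom_a,hom_b",
        [(50, 25, 25), (10, 1, 39), (0, 5, 5), (7, 3, 2), (21, 10, 69)],
    )
    def test_matches_fraction_oracle(self, het, hom_a, hom_b):
        assert hwe_exact_test(het, hom_a, hom_b) == pytest.approx(
            _hwe_oracle(het, hom_a, hom_b), rel=1e-9
        )

    def test_equilibrium_counts_kept(self):
        assert hwe_exact_test(50, 25, 25) > 0.99

    def test_contract(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 0)
        assert hwe_exact_test(0, 0, 0) == 1.0


def _matrix(columns, chrom="1"):
    """columns: dict snp_id -> list of calls."""
    n = len(next(iter(columns.values())))
    return GenotypeMatrix(
        [f"i{k}" for k in range(n)],
        [
            SnpRecord(sid, chrom, j + 1, calls)
            for j, (sid, calls) in enumerate(columns.items())
        ],
    )


class TestSnpFilters:
    def test_monomorphic_dropped_by_maf(self):
        gm = _matrix({"mono": [("A", "A")] * 10})
        kept, qc = snp_filters(gm)
        assert kept == []
        assert qc.loc[0, "dropped_reason"] == "maf"

    def test_missingness_threshold(self):
        calls = [("A", "G")] * 8 + [None, None]  # 20% missing
        gm = _matrix({"gappy": calls})
        kept, qc = snp_filters(gm)
        assert kept == []
        assert qc.loc[0, "dropped_reason"] == "missingness"

    def test_hwe_violation_dropped(self):
        # all heterozygotes: extreme HWE departure at n=100
        gm = _matrix({"het": [("A", "G")] * 100})
        kept, qc = snp_filters(gm)
        assert kept == []
        assert qc.loc[0, "dropped_reason"] == "hwe"
        assert qc.loc[0, "hwe_p"] < 1e-6

    def test_good_snp_kept_and_idempotent(self):
        calls = [("A", "A")] * 25 + [("A", "G")] * 50 + [("G", "G")] * 25
        gm = _matrix({"ok": calls})
        kept, qc = snp_filters(gm)
        assert kept == ["ok"]
        assert qc.loc[0, "hwe_p"] > 0.99
        gm2 = GenotypeMatrix(
            gm.individual_ids, [r for r in gm.snps if r.snp_id in kept]
        )
        kept2, _ = snp_filters(gm2)
        assert kept2 == kept

    def test_all_missing_reported(self):
        gm = _matrix({"void": [None] * 5})
        kept, qc = snp_filters(gm)
        assert qc.loc[0, "dropped_reason"] == "all_missing"


class TestLdPrune:
    def test_duplicate_column_pruned(self):
        calls = [("A", "A")] * 5 + [("A", "G")] * 5 + [("G", "G")] * 5
        gm = _matrix({"a": calls, "b": list(calls)})
        assert ld_prune(gm) == ["a"]

    def test_different_chromosomes_not_compared(self):
        calls = [("A", "A")] * 5 + [("G", "G")] * 5
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(10)],
            [
                SnpRecord("a", "1", 1, calls),
                SnpRecord("b", "2", 1, list(calls)),
            ],
        )
        assert ld_prune(gm) == ["a", "b"]

    def test_independent_snps_mostly_kept(self, rng):
        n, m = 500, 30
        cols = {}
        for j in range(m):
            states = rng.choice([("A", "A"), ("A", "G"), ("G", "G")], size=n, p=[0.25, 0.5, 0.25])
            cols[f"s{j}"] = [tuple(c) for c in states]
        kept = ld_prune(_matrix(cols), r2_threshold=0.1)
        assert len(kept) >= m - 2  # null r2 ~ 1/n rarely exceeds 0.1

    def test_correlated_trio_keeps_one(self, rng):
        n = 200
        base = rng.choice([1, 0, -1], size=n, p=[0.25, 0.5, 0.25])
        letters = {1: ("A", "A"), 0: ("A", "G"), -1: ("G", "G")}
        cols = {}
        for j in range(3):
            copy = base.copy()
            flip = rng.random(n) < 0.03  # r2 ~ 0.9
            copy[flip] = rng.choice([1, 0, -1], size=flip.sum())
            cols[f"s{j}"] = [letters[int(v)] for v in copy]
        kept = ld_prune(_matrix(cols), r2_threshold=0.1)
        assert len(kept) == 1


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,level,expected",
        [(1, 0.05, 1.3010), (10433, 0.01, 6.0184), (10433, 0.05, 5.3194)],
    )
    def test_thresholds(self, n, level, expected):
        assert bonferroni_threshold(n, level) == pytest.approx(expected, abs=5e-5)

    def test_contract(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)
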