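"""Asymmetric LD, EM haplotype frequencies, and biallelic r^2."""

import numpy as np
import pandas as pd
import pytest

from hlafinemap.core import CALLED, NO_CALL
from hlafinemap.ld import (
    DUMMY_ALLELE,
    AldResult,
    HaplotypeFreqTable,
    ald_matrix,
    asymmetric_ld,
    biallelic_r2,
    em_haplotype_frequencies,
    gene_pair_ald,
    pool_rare_alleles,
)
from conftest import make_calls


def hf(h, **kw):
    h = np.asarray(h, dtype=float)
    return HaplotypeFreqTable(
        "A", "B",
        [f"a{i}" for i in range(h.shape[0])],
        [f"b{j}" for j in range(h.shape[1])],
        h, **kw,
    )


def brute_force_w(h):
    """Direct evaluation of the conditional-variance formula."""
    h = np.asarray(h, dtype=float)
    p = h.sum(axis=1)
    q = h.sum(axis=0)
    num_a = sum(
        (h[i, j] - p[i] * q[j]) ** 2 / q[j]
        for i in range(len(p)) for j in range(len(q)) if q[j] > 0
    )
    num_b = sum(
        (h[i, j] - p[i] * q[j]) ** 2 / p[i]
        for i in range(len(p)) for j in range(len(q)) if p[i] > 0
    )
    return np.sqrt(num_a / (1 - (p**2).sum())), np.sqrt(num_b / (1 - (q**2).sum()))


class TestAsymmetricLd:
    def test_perfect_coupling(self):
        res = asymmetric_ld(hf(np.diag([0.5, 0.5])))
        assert res.w_a_given_b == pytest.approx(1.0)
        assert res.w_b_given_a == pytest.approx(1.0)

    def test_independence(self):
        p = np.array([0.6, 0.4])
        q = np.array([0.2, 0.3, 0.5])
        res = asymmetric_ld(hf(np.outer(p, q)))
        assert res.w_a_given_b == pytest.approx(0.0, abs=1e-12)
        assert res.w_b_given_a == pytest.approx(0.0, abs=1e-12)

    def test_biallelic_equals_r(self):
        # D = 0.15, r^2 = D^2/(p1 p2 q1 q2) = 0.36 -> W = 0.6
        res = asymmetric_ld(hf([[0.4, 0.1], [0.1, 0.4]]))
        assert res.w_a_given_b == pytest.approx(0.6)
        assert res.w_b_given_a == pytest.approx(0.6)
        assert res.w_avg == pytest.approx(0.6)

    def test_asymmetric_table_matches_brute_force(self):
        h = np.array([[0.25, 0.05], [0.05, 0.30], [0.20, 0.15]])
        res = asymmetric_ld(hf(h))
        wa, wb = brute_force_w(h)
        assert res.w_a_given_b == pytest.approx(wa, abs=1e-12)
        assert res.w_b_given_a == pytest.approx(wb, abs=1e-12)
        assert res.w_a_given_b != pytest.approx(res.w_b_given_a)

    def test_deterministic_function_is_directional(self):
        # A is a function of B (each B allele maps to one A allele)
        h = np.array([[0.3, 0.2, 0.0], [0.0, 0.0, 0.5]])
        res = asymmetric_ld(hf(h))
        assert res.w_a_given_b == pytest.approx(1.0)
        assert res.w_b_given_a < 1.0

    def test_monomorphic_flagged_not_nan_propagation(self):
        res = asymmetric_ld(hf([[0.7], [0.3]]))
        assert not res.defined

    def test_random_biallelic_tables_match_r(self, rng):
        for _ in range(2000):
            h = rng.dirichlet(np.ones(4)).reshape(2, 2)
            p, q = h.sum(axis=1), h.sum(axis=0)
            if min(p.min(), q.min()) < 1e-3:
                continue
            d = h[0, 0] - p[0] * q[0]
            r2 = d**2 / (p[0] * p[1] * q[0] * q[1])
            res = asymmetric_ld(hf(h))
            assert abs(res.w_a_given_b - np.sqrt(r2)) < 1e-10
            assert abs(res.w_b_given_a - np.sqrt(r2)) < 1e-10

    def test_w_bounded_on_random_tables(self, rng):
        for _ in range(2000):
            i, j = rng.integers(2, 5, size=2)
            h = rng.dirichlet(np.ones(i * j)).reshape(i, j)
            res = asymmetric_ld(hf(h))
            if res.defined:
                assert 0.0 <= res.w_a_given_b <= 1.0
                assert 0.0 <= res.w_b_given_a <= 1.0


def pairs_df(rows):
    return pd.DataFrame(rows, columns=["a1", "a2", "b1", "b2"])


class TestEmHaplotypes:
    def test_unambiguous_equals_direct_counting(self):
        # all individuals homozygous at A: no phase ambiguity
        pairs = pairs_df(
            [("a1", "a1", "b1", "b2"), ("a2", "a2", "b1", "b1"), ("a1", "a1", "b2", "b2")]
        )
        res = em_haplotype_frequencies(pairs)
        # direct haplotype counts: a1b1:1, a1b2:3, a2b1:2 over 6
        t = pd.DataFrame(res.h, index=res.alleles_a, columns=res.alleles_b)
        assert t.loc["a1", "b1"] == pytest.approx(1 / 6)
        assert t.loc["a1", "b2"] == pytest.approx(3 / 6)
        assert t.loc["a2", "b1"] == pytest.approx(2 / 6)

    def test_single_double_het_fixed_point(self):
        # product init is already the symmetric EM fixed point: 0.25 each
        res = em_haplotype_frequencies(pairs_df([("a1", "a2", "b1", "b2")]))
        assert np.allclose(res.h, 0.25)

    def test_simulation_recovery(self, rng):
        truth = np.array([[0.35, 0.10], [0.05, 0.50]])
        n = 200
        flat = truth.ravel()
        draws = rng.choice(4, size=(n, 2), p=flat)
        rows = []
        for h1, h2 in draws:
            rows.append((f"a{h1 // 2 + 1}", f"a{h2 // 2 + 1}",
                         f"b{h1 % 2 + 1}", f"b{h2 % 2 + 1}"))
        res = em_haplotype_frequencies(pairs_df(rows))
        se = np.sqrt(truth * (1 - truth) / (2 * n))
        assert np.all(np.abs(res.h - truth) <= 3 * se)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            em_haplotype_frequencies(pairs_df([]))


class TestPooling:
    def cohort(self):
        rows = []
        # 40/40/15/5 percent alleles over 10 participants (20 slots)
        alleles = (["HLA-A*01:01"] * 8 + ["HLA-A*02:01"] * 8
                   + ["HLA-A*03:01"] * 3 + ["HLA-A*11:01"] * 1)
        for i in range(10):
            rows.append(("p%d" % i, "HLA-A", alleles[2 * i], alleles[2 * i + 1], CALLED))
        return make_calls(rows)

    def test_common_alleles_unchanged(self):
        out = pool_rare_alleles(self.cohort(), "HLA-A", min_af=0.01)
        assert DUMMY_ALLELE not in set(out["a1"]) | set(out["a2"])

    def test_rare_allele_pooled(self):
        out = pool_rare_alleles(self.cohort(), "HLA-A", min_af=0.10)
        assert DUMMY_ALLELE in set(out["a1"]) | set(out["a2"])

    def test_no_call_becomes_dummy(self):
        calls = make_calls(
            [("p1", "HLA-A", "HLA-A*01:01", "HLA-A*01:01", CALLED),
             ("p2", "HLA-A", None, None, NO_CALL)]
        )
        out = pool_rare_alleles(calls, "HLA-A", min_af=0.0)
        assert out.loc["p2"].tolist() == [DUMMY_ALLELE, DUMMY_ALLELE]


class TestAldMatrix:
    def test_perfectly_coupled_genes(self, rng):
        rows = []
        for i in range(500):
            k = rng.integers(0, 2, size=2)
            a = [f"HLA-A*0{x + 1}:01" for x in k]
            b = [f"HLA-B*0{x + 7}:02" for x in k]  # same index: perfect LD
            rows.append((f"p{i}", "HLA-A", a[0], a[1], CALLED))
            rows.append((f"p{i}", "HLA-B", b[0], b[1], CALLED))
        m = ald_matrix(make_calls(rows), ["HLA-A", "HLA-B"])
        assert m.loc["HLA-A", "HLA-B"] == pytest.approx(1.0, abs=1e-6)
        assert m.loc["HLA-A", "HLA-A"] == 1.0

    def test_independent_genes_near_zero(self, rng):
        rows = []
        for i in range(2000):
            a = rng.integers(0, 3, size=2)
            b = rng.integers(0, 3, size=2)
            rows.append((f"p{i}", "HLA-A", f"HLA-A*0{a[0] + 1}:01", f"HLA-A*0{a[1] + 1}:01", CALLED))
            rows.append((f"p{i}", "HLA-B", f"HLA-B*0{b[0] + 7}:02", f"HLA-B*0{b[1] + 7}:02", CALLED))
        m = ald_matrix(make_calls(rows), ["HLA-A", "HLA-B"])
        assert m.loc["HLA-A", "HLA-B"] < 0.1

    def test_simulated_cohort_recovers_dr_dq_structure(self, sim_truth):
        m = ald_matrix(sim_truth, ["HLA-A", "HLA-DRB1", "HLA-DQB1"], stratum="EUR")
        # DR-DQ coupling in the generator far exceeds A-DQ background LD
        assert m.loc["HLA-DRB1", "HLA-DQB1"] > m.loc["HLA-A", "HLA-DQB1"]


class TestBiallelicR2:
    def test_identical_columns(self):
        x = np.array([0, 1, 2, 1, 0, 2])
        assert biallelic_r2(x, x) == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        x = np.array([0.0, 1, 2, 1, 0, 2])
        y = np.array([1.0, 1, 0, 2, 0, 2])
        r = np.corrcoef(x, y)[0, 1]
        assert biallelic_r2(x, y) == pytest.approx(r**2)
        # hand value: cov/sd product computed once, frozen
        assert biallelic_r2(x, y) == pytest.approx(0.0625, abs=1e-12)

    def test_independent_columns_small(self, rng):
        x = rng.binomial(2, 0.3, size=10_000).astype(float)
        y = rng.binomial(2, 0.3, size=10_000).astype(float)
        assert biallelic_r2(x, y) < 0.01

    def test_zero_variance_flagged(self):
        assert np.isnan(biallelic_r2(np.ones(5), np.arange(5.0)))
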