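"""Firth regression, scans, meta-analysis, residue expansion, conditioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from hlafinemap.association import (
    DEFAULT_ALPHA,
    conditional_scan,
    expand_amino_acids,
    firth_logistic_fit,
    meta_analyze,
    meta_fixed,
    or_with_ci,
    scan,
    significance_filter,
    stratified_scan,
)
from hlafinemap.core import CALLED, DosageMatrix
from conftest import make_calls


def simple_pheno(y, index, ancestry="EUR", rng=None, extra=None):
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame(
        {"status": y, "ancestry": ancestry,
         "age": rng.normal(55, 8, len(y)), "sex": rng.integers(0, 2, len(y))},
        index=index,
    )
    if extra is not None:
        for k, v in extra.items():
            df[k] = v
    return df


def dosage_matrix(cols: dict, index) -> DosageMatrix:
    data = pd.DataFrame(cols, index=index, dtype=float)
    meta = pd.DataFrame(
        {"gene": "HLA-A", "label": list(cols), "resolution": 3,
         "af": [np.nanmean(v) / 2 for v in data.T.values]},
        index=pd.Index(list(cols), name="marker"),
    )
    return DosageMatrix(data, meta)


class TestFirthFit:
    def test_haldane_2x2_closed_form(self):
        # table (5,5; 0,10): Firth equals the 2x2 log-OR with +1/2 cells
        y = np.array([1] * 5 + [0] * 5 + [1] * 0 + [0] * 10, dtype=float)
        x = np.array([1] * 10 + [0] * 10, dtype=float)
        X = np.column_stack([np.ones(20), x])
        fit = firth_logistic_fit(y, X)
        assert fit.beta[1] == pytest.approx(np.log(21), abs=1e-4)

    def test_null_estimate_small(self, rng):
        n = 10_000
        x = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, 0.3, n).astype(float)
        fit = firth_logistic_fit(y, np.column_stack([np.ones(n), x]))
        assert abs(fit.beta[1]) < 3 * fit.se[1]

    def test_recovers_simulated_effect(self, rng):
        n = 10_000
        beta = 0.5
        x = rng.binomial(2, 0.2, n).astype(float)
        y = rng.binomial(1, expit(-1.0 + beta * x)).astype(float)
        fit = firth_logistic_fit(y, np.column_stack([np.ones(n), x]))
        assert fit.beta[1] == pytest.approx(beta, abs=3 * fit.se[1])

    def test_matches_unpenalized_ml_when_well_behaved(self, rng):
        """On large balanced data the Jeffreys penalty is negligible."""
        import statsmodels.api as sm

        n = 20_000
        x = rng.binomial(2, 0.4, n).astype(float)
        y = rng.binomial(1, expit(0.2 + 0.3 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = firth_logistic_fit(y, X)
        ml = sm.Logit(y, X).fit(disp=0)
        assert abs(fit.beta[1] - ml.params[1]) < 0.01

    def test_finite_under_separation(self):
        # perfect separation: plain ML diverges, Firth stays finite
        y = np.array([1] * 10 + [0] * 10, dtype=float)
        x = y.copy()
        fit = firth_logistic_fit(y, np.column_stack([np.ones(20), x]))
        assert np.isfinite(fit.beta).all() and np.isfinite(fit.se).all()


class TestScan:
    def test_zero_mac_marker_skipped(self, rng):
        idx = [f"p{i}" for i in range(200)]
        d = dosage_matrix(
            {"m0": np.zeros(200), "m1": rng.binomial(2, 0.3, 200)}, idx
        )
        ph = simple_pheno(rng.binomial(1, 0.5, 200), idx)
        res = scan(d, ph, stratum="EUR", min_cases=10, covariates=("age", "sex"))
        assert res["marker"].tolist() == ["m1"]

    def test_stratum_below_min_cases_skipped(self, rng):
        idx = [f"p{i}" for i in range(200)]
        y = np.zeros(200)
        y[:49] = 1  # 49 cases < 50
        d = dosage_matrix({"m1": rng.binomial(2, 0.3, 200)}, idx)
        res = scan(d, simple_pheno(y, idx), stratum="EUR", covariates=("age", "sex"))
        assert len(res) == 0

    def test_power_for_or2(self, rng):
        n = 5000
        idx = [f"p{i}" for i in range(n)]
        x = rng.binomial(2, 0.2, n).astype(float)
        eta = -2.4 + np.log(2) * x
        y = rng.binomial(1, expit(eta)).astype(float)
        assert y.sum() >= 400  # several hundred cases
        d = dosage_matrix({"m1": x}, idx)
        res = scan(d, simple_pheno(y, idx, rng=rng), stratum="EUR",
                   covariates=("age", "sex"))
        assert res["p"].iloc[0] < 1e-4
        assert res["beta"].iloc[0] == pytest.approx(np.log(2), abs=3 * res["se"].iloc[0])


class TestMetaFixed:
    def test_identical_strata(self):
        df = pd.DataFrame(
            {"marker": "m", "stratum": ["AFR", "EUR"], "beta": [0.5, 0.5],
             "se": [0.1, 0.1]}
        )
        m = meta_fixed(df)
        assert m.beta == pytest.approx(0.5)
        assert m.se == pytest.approx(0.1 / np.sqrt(2))
        assert m.q == pytest.approx(0.0)
        assert m.q_p == pytest.approx(1.0)
        assert m.direction == "++"

    def test_single_stratum_identity(self):
        df = pd.DataFrame(
            {"marker": "m", "stratum": ["EUR"], "beta": [-0.3], "se": [0.12]}
        )
        m = meta_fixed(df)
        assert (m.beta, m.se) == (-0.3, 0.12)
        assert m.direction == "-" and m.k == 1

    def test_hand_calculated_q(self):
        df = pd.DataFrame(
            {"marker": "m", "stratum": ["AFR", "EUR"], "beta": [0.0, 1.0],
             "se": [0.1, 0.1]}
        )
        m = meta_fixed(df)
        assert m.beta == pytest.approx(0.5)
        assert m.q == pytest.approx(50.0)
        assert m.q_p == pytest.approx(stats.chi2.sf(50, 1))

    def test_q_invariant_to_stratum_relabeling(self):
        a = pd.DataFrame({"marker": "m", "stratum": ["AFR", "EUR", "SAS"],
                          "beta": [0.1, 0.4, -0.2], "se": [0.1, 0.2, 0.15]})
        b = a.assign(stratum=["SAS", "AFR", "EUR"])
        assert meta_fixed(a).q == pytest.approx(meta_fixed(b).q)

    def test_q_zero_iff_equal_betas(self, rng):
        betas = rng.normal(size=3)
        df = pd.DataFrame({"marker": "m", "stratum": ["AFR", "EUR", "SAS"],
                           "beta": betas, "se": [0.1, 0.2, 0.3]})
        assert (meta_fixed(df).q == 0) == bool(np.allclose(betas, betas[0]))
        df2 = df.assign(beta=[0.2, 0.2, 0.2])
        assert meta_fixed(df2).q == pytest.approx(0.0)


class TestOrConversion:
    @pytest.mark.parametrize(
        "beta,expected_or",
        [(1.88, 6.55), (0.59, 1.80), (0.96, 2.61)],
    )
    def test_published_style_conversions(self, beta, expected_or):
        orr, lo, hi = or_with_ci(beta, 0.05)
        assert orr == pytest.approx(expected_or, abs=0.01)
        assert lo < orr < hi

    def test_null_symmetric(self):
        orr, lo, hi = or_with_ci(0.0, 0.2)
        assert orr == 1.0
        assert lo * hi == pytest.approx(1.0)


class TestSignificanceFilter:
    def test_threshold_arithmetic(self):
        meta = pd.DataFrame(
            {"marker": ["a", "b"], "p": [4e-9, 5e-9], "q_p": [0.5, 0.5]}
        )
        out = significance_filter(meta, n_phenotypes=11)
        assert out["marker"].tolist() == ["a"]  # 4e-9 < 4.55e-9 <= 5e-9

    def test_heterogeneity_flag_uses_realized_test_count(self):
        n = 13576
        meta = pd.DataFrame(
            {"marker": [f"m{i}" for i in range(3)], "p": [1e-10, 1e-10, 0.5],
             "q_p": [3e-6, 2e-2, 0.9]}
        )
        # realized count is 3 here -> cutoff 0.05/3
        out = significance_filter(meta)
        assert out["heterogeneous"].tolist() == [True, False]
        assert 0.05 / n == pytest.approx(3.68e-6, rel=1e-3)


class TestAminoAcidExpansion:
    def align(self):
        # two alleles differing only at column 3 (0-based 2): A vs D
        return {
            "HLA-A*01:01": "MKA" + "QRST",
            "HLA-A*02:01": "MKD" + "QRST",
        }

    def test_single_polymorphic_column(self):
        calls = make_calls(
            [("p1", "HLA-A", "HLA-A*01:01", "HLA-A*02:01", CALLED),
             ("p2", "HLA-A", "HLA-A*01:01", "HLA-A*01:01", CALLED)]
        )
        d = expand_amino_acids(calls, self.align())
        assert sorted(d.markers) == ["HLA-A_pos3_A", "HLA-A_pos3_D"]
        assert d.data.loc["p1", "HLA-A_pos3_A"] == 1
        assert d.data.loc["p1", "HLA-A_pos3_D"] == 1
        assert d.data.loc["p2", "HLA-A_pos3_A"] == 2

    def test_gap_column_excluded(self):
        align = {"HLA-A*01:01": "MK-QA", "HLA-A*02:01": "MKDQD"}
        calls = make_calls(
            [("p1", "HLA-A", "HLA-A*01:01", "HLA-A*02:01", CALLED)]
        )
        d = expand_amino_acids(calls, align)
        assert all("pos3" not in m for m in d.markers)  # indel column dropped
        assert any("pos5" in m for m in d.markers)

    def test_allele_missing_from_alignment_is_missing_data(self):
        calls = make_calls(
            [("p1", "HLA-A", "HLA-A*01:01", "HLA-A*02:01", CALLED),
             ("p2", "HLA-A", "HLA-A*03:01", "HLA-A*01:01", CALLED)]
        )
        d = expand_amino_acids(calls, self.align())
        assert np.isnan(d.data.loc["p2"]).all()


class TestConditionalScan:
    def _pheno_and_dosages(self, rng, n=4000, tag_r=0.0):
        causal = rng.binomial(2, 0.25, n).astype(float)
        other = rng.binomial(2, 0.25, n).astype(float)
        if tag_r > 0:
            # tag shares haplotypes with the causal allele with prob tag_r
            keep = rng.random((n, 2)) < tag_r
            c_h = np.column_stack([(causal >= 1), (causal == 2)]).astype(float)
            t_h = np.where(keep, c_h, rng.binomial(1, 0.25, (n, 2)))
            other = t_h.sum(axis=1)
        y = rng.binomial(1, expit(-1.2 + 0.6 * causal + (0.6 * other if tag_r == 0 else 0)))
        idx = [f"p{i}" for i in range(n)]
        d = dosage_matrix({"causal": causal, "tag": other}, idx)
        ph = simple_pheno(y.astype(float), idx, rng=rng)
        return d, ph

    def test_self_conditioning_flagged(self, rng):
        d, ph = self._pheno_and_dosages(rng)
        out = conditional_scan(d, ph, condition_on=["causal"], strata=("EUR",),
                               covariates=("age", "sex"), min_cases=10)
        assert "causal" not in out.loc[~out["undefined"], "marker"].tolist()

    def test_two_independent_causals_stay_significant(self, rng):
        d, ph = self._pheno_and_dosages(rng, tag_r=0.0)
        out = conditional_scan(d, ph, condition_on=["tag"], strata=("EUR",),
                               covariates=("age", "sex"), min_cases=10)
        row = out[out["marker"] == "causal"].iloc[0]
        assert row["p"] < 1e-6

    def test_tag_signal_attenuates_after_conditioning(self, rng):
        d, ph = self._pheno_and_dosages(rng, tag_r=0.95)
        naive = stratified_scan(d, ph, strata=("EUR",), covariates=("age", "sex"),
                                min_cases=10)
        tag_naive = naive[(naive["marker"] == "tag")]["p"].iloc[0]
        assert tag_naive < 1e-8  # tag looks associated before conditioning
        out = conditional_scan(d, ph, condition_on=["causal"], strata=("EUR",),
                               covariates=("age", "sex"), min_cases=10)
        row = out[out["marker"] == "tag"].iloc[0]
        assert row["p"] > 1e-4  # signal collapses once the causal is held


class TestScanCalibration:
    def test_null_pvalues_roughly_uniform(self, rng):
        """Small version of the type-I error property (200 null markers)."""
        n, m = 1000, 200
        idx = [f"p{i}" for i in range(n)]
        y = rng.binomial(1, 0.3, n).astype(float)
        cols = {f"m{j}": rng.binomial(2, 0.3, n).astype(float) for j in range(m)}
        d = dosage_matrix(cols, idx)
        res = scan(d, simple_pheno(y, idx, rng=rng), stratum="EUR",
                   covariates=("age", "sex"), min_cases=10)
        rate = (res["p"] < 0.05).mean()
        assert 0.01 < rate < 0.10
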