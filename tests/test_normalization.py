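import numpy as np
import pandas as pd
import pytest

from scbn.io import ConservedSet
from scbn.normalization import (
    MedianNormalizer,
    SCBNNormalizer,
    empirical_type1_deviation,
    median_factor,
    pfdr_estimate,
    scbn_factor,
)

from conftest import make_table


class TestTypeIDeviation:
    @pytest.mark.parametrize(
        "pvals,alpha,expected",
        [
            ([1, 1, 1, 1], 0.05, 0.05),
            ([0.01, 0.2, 0.3, 0.4], 0.05, 0.20),
            (np.arange(0.05, 1.001, 0.05), 0.05, 0.05),  # strict '<' rejects none
        ],
    )
    def test_examples(self, pvals, alpha, expected):
        assert empirical_type1_deviation(pvals, alpha) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            empirical_type1_deviation([], 0.05)


class TestMedianNormalizer:
    def test_constant_adjusted_ratio(self):
        # x1 = x2 per gene so N1 = N2; ratio reduces to L2/L1 = 1.7 everywhere
        t = make_table(
            [10, 20, 30, 40, 50],
            [10, 20, 30, 40, 50],
            L1=[100] * 5,
            L2=[170] * 5,
        )
        est = MedianNormalizer().fit(t, t.gene_ids)
        assert est.scaling_factor_ == pytest.approx(1.7)

    def test_symmetric_table_gives_unity(self):
        t = make_table([10, 20, 30, 40], [10, 20, 30, 40])
        assert MedianNormalizer().fit(t, t.gene_ids).scaling_factor_ == pytest.approx(
            1.0
        )

    def test_requires_doubly_expressed_genes(self):
        t = make_table([5, 0], [0, 7])
        with pytest.raises(ValueError):
            MedianNormalizer().fit(t, t.gene_ids)

    def test_recovers_true_factor_on_null_data(self, null_sim):
        table, conserved, truth = null_sim
        c = MedianNormalizer().fit(table, conserved).scaling_factor_
        assert abs(c / truth.c_true - 1) < 0.10


class TestSCBNNormalizer:
    def test_empty_conserved_errors(self, toy_table):
        with pytest.raises(ValueError):
            SCBNNormalizer().fit(toy_table, [])

    def test_all_zero_conserved_gene_errors(self):
        t = make_table([0, 9], [0, 4], ids=["z", "e"])
        with pytest.raises(ValueError, match="zero total count"):
            SCBNNormalizer().fit(t, ["z"])

    def test_recovers_true_factor_on_null_data(self, null_sim):
        table, conserved, truth = null_sim
        est = SCBNNormalizer().fit(table, conserved)
        assert abs(est.scaling_factor_ / truth.c_true - 1) < 0.10
        lo, hi = est.plateau_
        assert lo <= est.scaling_factor_ <= hi
        assert 0 <= est.objective_value_ <= 0.95

    def test_deterministic_fit(self, null_sim):
        table, conserved, _ = null_sim
        a = SCBNNormalizer().fit(table, conserved)
        b = SCBNNormalizer().fit(table, conserved)
        assert a.scaling_factor_ == b.scaling_factor_
        assert a.plateau_ == b.plateau_

    def test_species_swap_inverts_factor(self, null_sim):
        """Swapping the two species' columns must (nearly) invert the
        estimated scaling factor: c <-> 1/c within grid resolution."""
        table, conserved, _ = null_sim
        c_fwd = SCBNNormalizer().fit(table, conserved).scaling_factor_
        df = table.data.rename(
            columns={"x1": "x2", "x2": "x1", "L1": "L2", "L2": "L1"}
        )
        swapped = type(table)(df[["gene_id", "x1", "L1", "x2", "L2"]])
        c_rev = SCBNNormalizer().fit(swapped, conserved).scaling_factor_
        assert abs(np.log(c_fwd * c_rev)) < 0.05

    def test_sklearn_params_roundtrip(self):
        est = SCBNNormalizer(alpha=0.01)
        params = est.get_params()
        assert params["alpha"] == 0.01
        est.set_params(alpha=0.2)
        assert est.alpha == 0.2


class TestFunctionalWrappers:
    def test_scbn_factor_matches_estimator(self, null_sim):
        table, conserved, _ = null_sim
        res = scbn_factor(table, conserved, alpha=0.05)
        est = SCBNNormalizer(alpha=0.05).fit(table, conserved)
        assert res.c_opt == est.scaling_factor_
        assert res.method == "scbn"
        assert res.plateau == est.plateau_

    def test_median_factor_scale_is_test_compatible(self, null_sim):
        table, conserved, truth = null_sim
        res = median_factor(table, conserved)
        # same scale as the exact test's c: close to the true S2/S1
        assert abs(res.c_opt / truth.c_true - 1) < 0.10
        assert res.method == "median"


class TestPfdr:
    def test_plug_in_substitution(self):
        # V0: 20 genes, exactly one rejected (rate 0.05); V1: 10 genes, all rejected
        p = np.concatenate([[0.01], np.full(19, 0.5), np.full(10, 0.001)])
        v0 = np.concatenate([np.ones(20, bool), np.zeros(10, bool)])
        est = pfdr_estimate(p, v0, alpha=0.05, prior_h0=0.5)
        assert est.value == pytest.approx(0.05 / 1.05)
        assert est.rejection_rates == (0.05, 1.0)

    def test_all_rejections_null(self):
        p = np.concatenate([np.full(5, 0.001), np.full(5, 0.9)])
        v0 = np.concatenate([np.ones(5, bool), np.zeros(5, bool)])
        assert pfdr_estimate(p, v0, alpha=0.05).value == 1.0

    def test_no_rejections_errors(self):
        p = np.full(10, 0.9)
        v0 = np.arange(10) < 5
        with pytest.raises(ValueError, match="undefined pFDR"):
            pfdr_estimate(p, v0, alpha=0.05)

    def test_equal_rates_give_prior(self):
        # identical rejection rates in V0 and V1 -> pFDR equals P(H0)
        p = np.tile([0.001, 0.9], 10)
        v0 = np.arange(20) < 10
        est = pfdr_estimate(p, v0, alpha=0.05, prior_h0=0.3)
        assert est.value == pytest.approx(0.3)

    def test_empirical_prior(self):
        p = np.concatenate([np.full(30, 0.001), np.full(10, 0.001)])
        v0 = np.arange(40) < 30
        est = pfdr_estimate(p, v0, alpha=0.05)
        assert est.prior_h0 == pytest.approx(0.75)
        assert 0.0 <= est.value <= 1.0
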