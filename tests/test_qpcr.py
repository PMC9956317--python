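"""Efficiency estimation, Pfaffl ratios, randomization test and bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import strokerecovery as sr
from strokerecovery.errors import StandardCurveError


def _dilution(e, amounts=(2.5, 5.0, 10.0, 50.0, 100.0, 200.0), base=28.0):
    slope = -1.0 / math.log10(e)
    rows = [dict(gene="g", input_ng=a, replicate=1,
                 cq=base + slope * math.log10(a / 20.0), is_ntc=False)
            for a in amounts]
    rows.append(dict(gene="g", input_ng=0.0, replicate=1, cq=np.nan, is_ntc=True))
    return pd.DataFrame(rows)


class TestEfficiency:
    @pytest.mark.parametrize("e_true", [1.8, 1.9, 2.0])
    def test_noiseless_round_trip(self, e_true):
        res = sr.estimate_efficiency(_dilution(e_true))
        assert res.e == pytest.approx(e_true, abs=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.slope < 0

    def test_perfect_doubling_slope(self):
        res = sr.estimate_efficiency(_dilution(2.0))
        assert res.slope == pytest.approx(-1.0 / math.log10(2.0), abs=1e-9)  # -3.3219
        assert res.e == pytest.approx(2.0, abs=1e-9)

    def test_constant_cq_is_invalid_curve(self):
        df = _dilution(2.0)
        df.loc[~df.is_ntc, "cq"] = 25.0
        with pytest.raises(StandardCurveError):
            sr.estimate_efficiency(df)

    def test_too_few_amounts_rejected(self):
        df = _dilution(2.0, amounts=(5.0, 50.0))
        with pytest.raises(ValueError):
            sr.estimate_efficiency(df)

    def test_ntc_rows_ignored(self):
        df = _dilution(1.9)
        df.loc[df.is_ntc, "cq"] = 39.0  # late spurious amplification
        res = sr.estimate_efficiency(df)
        assert res.e == pytest.approx(1.9, abs=1e-6)

    def test_implausible_efficiency_warns(self):
        with pytest.warns(UserWarning, match="outside the plausible"):
            sr.estimate_efficiency(_dilution(1.3))


class TestExpressionRatio:
    def test_ddct_identity_example(self):
        # dct_target=2, dct_ref=0, E=2 -> 2^2
        res = sr.expression_ratio([23.0], [25.0], [20.0], [20.0])
        assert res.ratio == pytest.approx(4.0, abs=1e-12)

    def test_identity_case(self):
        res = sr.expression_ratio([25.0], [25.0], [20.0], [20.0])
        assert res.ratio == pytest.approx(1.0, abs=1e-12)

    def test_efficiency_corrected_hand_value(self):
        # e_t = 1.9, dct_t = 3; e_r = 2.0, dct_r = 1 -> 1.9^3 / 2
        res = sr.expression_ratio([22.0], [25.0], [19.0], [20.0],
                                  e_target=1.9, e_ref=2.0)
        assert res.ratio == pytest.approx(1.9 ** 3 / 2.0, abs=1e-12)
        assert res.ratio == pytest.approx(3.4295, abs=1e-4)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_ddct_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 6, size=2)
        ts, rs = rng.normal(25, 2, n1), rng.normal(18, 2, n1)
        tc, rc = rng.normal(25, 2, n2), rng.normal(18, 2, n2)
        res = sr.expression_ratio(ts, tc, rs, rc, 2.0, 2.0)
        ddct = res.dct_target - res.dct_ref
        assert res.ratio == pytest.approx(2.0 ** ddct, rel=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_shift_invariance_of_one_gene(self, seed):
        rng = np.random.default_rng(seed)
        ts, rs = rng.normal(25, 2, 4), rng.normal(18, 2, 4)
        tc, rc = rng.normal(25, 2, 3), rng.normal(18, 2, 3)
        base = sr.expression_ratio(ts, tc, rs, rc, 1.9, 2.0).ratio
        shift = sr.expression_ratio(ts + 5.0, tc + 5.0, rs, rc, 1.9, 2.0).ratio
        assert shift == pytest.approx(base, rel=1e-9)

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError):
            sr.expression_ratio([25.0, 26.0], [25.0], [20.0], [20.0])


class TestRandomizationTest:
    def test_identical_groups_p_is_one(self):
        ts = tc = np.array([25.0, 25.0, 25.0])
        rs = rc = np.array([20.0, 20.0, 20.0])
        res = sr.randomization_test(ts, rs, tc, rc)
        assert res.p == 1.0

    def test_complete_separation_3v3_exhaustive(self):
        # target Cq completely separated, reference constant: only the two
        # extreme allocations reach |observed| -> p = 2 / C(6,3) = 0.1
        ts, tc = np.array([20.0, 20.5, 21.0]), np.array([25.0, 25.5, 26.0])
        rs = rc = np.array([18.0, 18.0, 18.0])
        res = sr.randomization_test(ts, rs, tc, rc)
        assert res.method == "exhaustive"
        assert res.n_permutations == 20
        assert res.p == pytest.approx(2.0 / 20.0, abs=1e-12)

    def test_antisymmetry_swap_groups(self):
        rng = np.random.default_rng(42)
        ts, rs = rng.normal(24, 1, 4), rng.normal(18, 0.5, 4)
        tc, rc = rng.normal(26, 1, 4), rng.normal(18, 0.5, 4)
        fwd = sr.randomization_test(ts, rs, tc, rc, 1.9, 2.0)
        rev = sr.randomization_test(tc, rc, ts, rs, 1.9, 2.0)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)
        assert fwd.statistic == pytest.approx(-rev.statistic, abs=1e-12)
        r_fwd = sr.expression_ratio(ts, tc, rs, rc, 1.9, 2.0).ratio
        r_rev = sr.expression_ratio(tc, ts, rc, rs, 1.9, 2.0).ratio
        assert r_fwd == pytest.approx(1.0 / r_rev, rel=1e-12)

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(1)
        ts, rs = rng.normal(24, 1, 5), rng.normal(18, 0.5, 5)
        tc, rc = rng.normal(25, 1, 5), rng.normal(18, 0.5, 5)
        ex = sr.randomization_test(ts, rs, tc, rc)
        assert ex.method == "exhaustive"
        mc = sr.randomization_test(ts, rs, tc, rc, n_perm=50000, seed=0,
                                   exhaustive_cap=10)
        assert mc.method == "monte_carlo"
        se = math.sqrt(ex.p * (1 - ex.p) / 50000)
        assert abs(mc.p - ex.p) <= 3 * se + 1e-4

    def test_small_n_perm_warns(self):
        ts, rs = np.array([24.0, 25.0]), np.array([18.0, 18.0])
        with pytest.warns(UserWarning, match="n_perm"):
            sr.randomization_test(ts, rs, ts, rs, n_perm=50, exhaustive_cap=1)


class TestDispersion:
    def test_zero_noise_zero_se(self):
        ts = tc = np.array([25.0, 25.0, 25.0])
        rs = rc = np.array([20.0, 20.0, 20.0])
        res = sr.ratio_dispersion(ts, rs, tc, rc, seed=0)
        assert res.se_log == pytest.approx(0.0, abs=1e-12)

    def test_single_animal_group_unavailable(self):
        res = sr.ratio_dispersion([25.0], [20.0], [24.0, 26.0], [20.0, 20.0], seed=0)
        assert not res.available

    def test_bootstrap_se_stable_and_near_delta_method(self):
        # Cq noise sd known -> delta-method SE of the log ratio
        sd, n = 0.4, 6
        rng = np.random.default_rng(3)
        ts, rs = rng.normal(24, sd, n), rng.normal(18, sd, n)
        tc, rc = rng.normal(25, sd, n), rng.normal(18, sd, n)
        res1 = sr.ratio_dispersion(ts, rs, tc, rc, B=2000, seed=0)
        res2 = sr.ratio_dispersion(ts, rs, tc, rc, B=4000, seed=1)
        assert res1.se_log == pytest.approx(res2.se_log, rel=0.15)
        # 4 independent group means, each var sd^2/n, on the log-2 scale
        delta = math.sqrt(4 * sd ** 2 / n) * math.log(2.0)
        assert res1.se_log == pytest.approx(delta, rel=0.5)
        assert res1.lo < sr.expression_ratio(ts, tc, rs, rc).ratio < res1.hi


class TestRelativeExpressionTable:
    def test_noiseless_fold_change_recovered_exactly(self, small_qpcr):
        eff = sr.efficiency_table(small_qpcr.dilution)
        tab = sr.relative_expression_table(small_qpcr.cq, efficiencies=eff,
                                           n_perm=200, bootstrap=50, seed=0)
        row = tab[(tab.sample_group == "poor") & (tab.control_group == "sham")].iloc[0]
        assert row["ratio"] == pytest.approx(4.0, abs=1e-9)

    def test_unit_fold_changes_give_unit_ratios(self):
        cfg = sr.QpcrSimConfig(
            genes=("Adora2a", "Drd2"), regions=("Str",), hemispheres=("il",),
            endpoints=(28,), group_fold_change={},
            efficiency_true={"Adora2a": 1.9, "Drd2": 1.95, "Gapdh": 2.0},
            replicate_sd=0.0, animal_sd=0.0,
            n_per_group={28: {"good": 3, "poor": 3, "sham": 3}}, seed=8)
        ds = sr.gen_qpcr_dataset(cfg)
        eff = sr.efficiency_table(ds.dilution)
        tab = sr.relative_expression_table(ds.cq, efficiencies=eff,
                                           n_perm=200, bootstrap=50, seed=0)
        assert np.allclose(tab["ratio"], 1.0, atol=1e-9)
        assert (tab["p"] == 1.0).all()

    def test_control_group_convention(self, small_qpcr):
        tab = sr.relative_expression_table(small_qpcr.cq, n_perm=200,
                                           bootstrap=50, seed=0)
        assert set(zip(tab.sample_group, tab.control_group)) == {("poor", "sham")}

    def test_missing_reference_gene_raises(self, small_qpcr):
        cq = small_qpcr.cq[small_qpcr.cq.gene != "Gapdh"]
        with pytest.raises(ValueError, match="Gapdh"):
            sr.relative_expression_table(cq)
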