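"""Carbon-fate model: TCA bookkeeping, position fates, ratios, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import mc_position_release
from thermoprobe import fate

unit = st.floats(min_value=0.0, max_value=1.0)
label = st.floats(min_value=0.0, max_value=10.0)


class TestTcaTurn:
    @given(label, label, label, label, label, label, unit)
    @settings(max_examples=200, deadline=None)
    def test_conservation(self, c1, i2, i3, c4, ac, am, a):
        state = fate.OaaLabelState(c1, i2, i3, c4)
        new, co2, div = fate.tca_turn(state, ac, am, a)
        total_in = state.total + ac + am
        assert co2 + div + new.total == pytest.approx(total_in, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fate.tca_turn(fate.OaaLabelState(-1, 0, 0, 0), 0, 0, 0)


class TestReleaseSchedule:
    def test_carboxyl_released_on_second_cycle(self):
        s = fate.tca_release_schedule(acetyl_carboxyl=1.0)
        assert s.per_turn[:2] == [0.0, 1.0]
        assert s.first_release_turn == 2
        assert s.released == pytest.approx(1.0, abs=1e-9)

    def test_methyl_half_per_cycle_from_third(self):
        s = fate.tca_release_schedule(acetyl_methyl=1.0)
        assert s.first_release_turn == 3
        np.testing.assert_allclose(s.per_turn[2:7],
                                   [0.5, 0.25, 0.125, 0.0625, 0.03125])
        assert s.released == pytest.approx(1.0, abs=1e-8)

    def test_carboxyl_with_diversion_closed_form(self):
        # two diversion opportunities (entry turn and release turn)
        for a in (0.1, 0.3, 0.7):
            s = fate.tca_release_schedule(acetyl_carboxyl=1.0, a_tca=a)
            assert s.released == pytest.approx((1 - a) ** 2, abs=1e-9)
            assert s.retained == pytest.approx(1 - (1 - a) ** 2, abs=1e-9)

    def test_methyl_with_diversion_closed_form(self):
        # geometric sum: beta^3/2 * sum (beta/2)^k = beta^3/(2-beta)
        for a in (0.1, 0.3, 0.7):
            b = 1 - a
            s = fate.tca_release_schedule(acetyl_methyl=1.0, a_tca=a)
            assert s.released == pytest.approx(b**3 / (2 - b), abs=1e-9)

    def test_truncation_flag(self):
        s = fate.tca_release_schedule(acetyl_methyl=1.0, a_tca=0.0,
                                      tol=1e-9, max_turns=5)
        assert s.truncated and s.residual > 0


class TestPredictFates:
    def test_catabolic_releases_everything(self, catabolic_params):
        for iso in (fate.glucose(range(1, 7)), fate.pyruvate([1, 2, 3]),
                    fate.acetate([1, 2])):
            pred = fate.predict_fates(iso, catabolic_params)
            for pos, f in pred.positions.items():
                assert f.released == pytest.approx(1.0, abs=1e-8), (iso, pos)

    def test_pyruvate_diversion(self):
        pred = fate.predict_fates(fate.pyruvate([1]),
                                  fate.FluxParameters(a_pyr=0.4))
        assert pred.positions[1].released == pytest.approx(0.6)

    def test_ppp_retains_pentose(self):
        params = fate.FluxParameters(phi_ppp=1.0, a_pent=1.0)
        c1 = fate.predict_fates(fate.glucose([1]), params)
        assert c1.positions[1].released == pytest.approx(1.0)
        rest = fate.predict_fates(fate.glucose([2, 3, 4, 5, 6]), params)
        for pos, f in rest.positions.items():
            assert f.released == pytest.approx(0.0), pos

    def test_glucose_c1_glycolytic_shares_methyl_schedule(self):
        # with no PPP, glucose C1 ends as acetyl methyl carbon
        params = fate.FluxParameters()
        c1 = fate.predict_fates(fate.glucose([1]), params).positions[1]
        meth = fate.tca_release_schedule(acetyl_methyl=1.0)
        assert c1.released == pytest.approx(meth.released, abs=1e-9)

    def test_unknown_substrate(self):
        iso = fate.SubstrateIsotopomer("citrate", [1], 6)
        with pytest.raises(fate.UnsupportedSubstrateError):
            fate.predict_fates(iso, fate.FluxParameters())

    @given(unit, unit, unit, unit, st.floats(0, 0.95))
    @settings(max_examples=60, deadline=None)
    def test_label_conservation_all_positions(self, p, ap, aq, ac, at):
        params = fate.FluxParameters(p, ap, aq, ac, at)
        for iso in (fate.glucose(range(1, 7)), fate.pyruvate([1, 2, 3]),
                    fate.acetate([1, 2])):
            pred = fate.predict_fates(iso, params)
            for pos, f in pred.positions.items():
                assert f.released + f.retained + f.residual == pytest.approx(
                    1.0, abs=1e-9)
                assert -1e-12 <= f.released <= 1 + 1e-12

    @pytest.mark.parametrize("name", ["phi_ppp", "a_pent", "a_pyr", "a_ac",
                                      "a_tca"])
    def test_monotone_in_each_diversion(self, name):
        base = dict(phi_ppp=0.2, a_pent=0.3, a_pyr=0.1, a_ac=0.2, a_tca=0.2)
        iso = fate.glucose(range(1, 7))
        prev = None
        for v in np.linspace(0, 0.9, 7):
            kw = dict(base)
            kw[name] = v
            total = sum(
                f.released for f in
                fate.predict_fates(iso, fate.FluxParameters(**kw)).positions.values())
            if prev is not None and name != "phi_ppp":
                assert total <= prev + 1e-9
            prev = total


class TestTheoreticalRatio:
    def test_catabolic_values(self, catabolic_params):
        assert fate.theoretical_ratio("pyruvate", catabolic_params).value == (
            pytest.approx(0.5, abs=1e-8))
        assert fate.theoretical_ratio("glucose", catabolic_params).value == (
            pytest.approx(6.0, abs=1e-7))
        assert fate.theoretical_ratio("acetate", catabolic_params).value == (
            pytest.approx(1.0, abs=1e-8))

    def test_purity_cancels_within_pair(self):
        params = fate.FluxParameters(phi_ppp=0.4, a_ac=0.3)
        r1 = fate.theoretical_ratio("glucose", params, purity=0.99).value
        r2 = fate.theoretical_ratio("glucose", params, purity=0.5).value
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_undefined_ratio(self):
        with pytest.raises(fate.UndefinedRatioError):
            fate.theoretical_ratio("acetate", fate.FluxParameters(a_ac=1.0))


class TestFit:
    def test_catabolic_observed_gives_zeros(self):
        res = fate.fit_flux_params(dict(fate.CATABOLIC_RATIOS))
        assert res.params.as_array() == pytest.approx(np.zeros(5), abs=1e-4)

    def test_forward_invert_round_trip(self):
        truth = fate.FluxParameters(phi_ppp=0.3, a_ac=0.2)
        obs = {p: fate.theoretical_ratio(p, truth).value for p in fate.PAIRS}
        res = fate.fit_flux_params(obs)
        assert res.params.phi_ppp == pytest.approx(0.3, abs=0.05)
        assert res.params.a_ac == pytest.approx(0.2, abs=0.05)
        assert res.objective < 1e-10
        assert "a_ac" not in res.degenerate

    def test_single_pyruvate_ratio_degenerate(self):
        res = fate.fit_flux_params({"pyruvate": 1.0}, free=("a_pyr", "a_ac"))
        assert "a_pyr" in res.degenerate
        assert res.objective < 1e-10

    def test_phi_ppp_a_pyr_ridge_flagged(self):
        truth = fate.FluxParameters(phi_ppp=0.3, a_pyr=0.2, a_ac=0.4)
        obs = {p: fate.theoretical_ratio(p, truth).value for p in fate.PAIRS}
        res = fate.fit_flux_params(obs, free=("phi_ppp", "a_pyr", "a_ac",
                                              "a_tca"))
        assert {"phi_ppp", "a_pyr"} <= res.degenerate
        assert res.params.a_ac == pytest.approx(0.4, abs=0.01)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            fate.fit_flux_params({})


class TestStochasticOracle:
    """Deterministic recursion vs single-molecule tracking (small n here;
    the full 1e5-molecule sweep runs in the acceptance suite)."""

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_agreement(self, seed):
        rng = np.random.default_rng(seed)
        params = fate.FluxParameters(*rng.uniform(0, 0.9, 5))
        n = 20_000
        for sub, pos in (("pyruvate", 2), ("acetate", 2), ("glucose", 1)):
            det = fate.predict_fates(
                getattr(fate, sub)([pos]), params).positions[pos].released
            mc = mc_position_release(sub, pos, params, n, rng)
            se = max(np.sqrt(det * (1 - det) / n), 1e-4)
            assert abs(mc - det) < 3 * se + 1e-9, (sub, pos, det, mc)
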