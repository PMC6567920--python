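import numpy as np
import pandas as pd
import pytest

from pcdcea.cea import (DominanceStatus, StrategyOutcome, ZeroEffectDifferenceError,
                        build_frontier, ceac, cer_table, icer, ratio_summary,
                        tornado)
from pcdcea.decision import DO_NOTHING, PRESETS
from pcdcea.psa import PSAResult, run_psa


def make_psa(costs, effects, seed=0):
    n = len(next(iter(costs.values())))
    idx = pd.RangeIndex(n, name="iteration")
    return PSAResult(draws=pd.DataFrame(index=idx),
                     costs=pd.DataFrame(costs, index=idx),
                     effects=pd.DataFrame(effects, index=idx),
                     seed=seed)


class TestICER:
    def test_arithmetic(self):
        assert icer(200, 100, 50, 40) == 10

    def test_equal_costs(self):
        assert icer(7, 7, 3, 1) == 0

    def test_zero_effect_difference(self):
        with pytest.raises(ZeroEffectDifferenceError):
            icer(1, 2, 5, 5)

    def test_published_deterministic_means(self):
        # frontier ICER recomputed from the published mean cost/effect table;
        # differs from the published 2097 figure, which averaged
        # per-iteration ratios rather than taking the ratio of means
        assert icer(209_000, 136_000, 313, 273) == pytest.approx(1825.0)


def hull_oracle(outcomes, n_lambda=20001, lam_max=1e7):
    """Independent frontier oracle: a strategy is on the frontier iff it is
    the unique net-monetary-benefit maximizer for some willingness-to-pay."""
    names = set()
    for lam in np.linspace(0, lam_max, n_lambda):
        nmb = [lam * o.effect - o.cost for o in outcomes]
        best = max(nmb)
        winners = [o for o, v in zip(outcomes, nmb) if v == best]
        if len(winners) == 1:
            names.add(winners[0].name)
    return names


class TestFrontier:
    def outcomes(self):
        return [
            StrategyOutcome("Do nothing", 0, 0),
            StrategyOutcome("nNO+HSVM", 136_000, 273),
            StrategyOutcome("nNO+TEM", 150_000, 198),
            StrategyOutcome("nNO/HSVM+TEM", 209_000, 313),
        ]

    def test_published_dominance_structure(self):
        entries = {e.strategy: e for e in build_frontier(self.outcomes())}
        assert entries["nNO+TEM"].status is DominanceStatus.SIMPLY_DOMINATED
        on = [e.strategy for e in build_frontier(self.outcomes())
              if e.status is DominanceStatus.ON_FRONTIER]
        assert on == ["Do nothing", "nNO+HSVM", "nNO/HSVM+TEM"]
        assert entries["nNO/HSVM+TEM"].icer_vs_previous == pytest.approx(1825.0)
        assert entries["nNO+HSVM"].icer_vs_previous == pytest.approx(136_000 / 273)

    def test_frontier_icers_strictly_increase(self):
        entries = build_frontier(self.outcomes())
        icers = [e.icer_vs_previous for e in entries
                 if e.status is DominanceStatus.ON_FRONTIER
                 and e.icer_vs_previous is not None]
        assert icers == sorted(icers)
        assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_matches_hull_oracle(self):
        outcomes = self.outcomes()
        on = {e.strategy for e in build_frontier(outcomes)
              if e.status is DominanceStatus.ON_FRONTIER}
        assert on == hull_oracle(outcomes)

    def test_identical_strategies_tiebreak_by_name(self):
        entries = {e.strategy: e for e in build_frontier([
            StrategyOutcome("a", 10, 5), StrategyOutcome("b", 10, 5)])}
        assert entries["a"].status is DominanceStatus.ON_FRONTIER
        assert entries["b"].status is DominanceStatus.SIMPLY_DOMINATED

    def test_collinear_middle_extendedly_dominated(self):
        outcomes = [StrategyOutcome("lo", 0, 0), StrategyOutcome("mid", 100, 1),
                    StrategyOutcome("hi", 200, 2)]
        entries = {e.strategy: e for e in build_frontier(outcomes)}
        assert entries["mid"].status is DominanceStatus.EXTENDEDLY_DOMINATED
        assert entries["hi"].icer_vs_previous == pytest.approx(100.0)
        # oracle: the middle point is never a unique NMB maximizer
        assert "mid" not in hull_oracle(outcomes, lam_max=1000)

    def test_extended_dominance_classic_case(self):
        outcomes = [StrategyOutcome("base", 0, 0),
                    StrategyOutcome("kink", 500, 1),     # ICER 500 then 100
                    StrategyOutcome("top", 600, 2)]
        entries = {e.strategy: e for e in build_frontier(outcomes)}
        assert entries["kink"].status is DominanceStatus.EXTENDEDLY_DOMINATED
        assert entries["top"].icer_vs_previous == pytest.approx(300.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_outcomes_match_hull_oracle(self, seed):
        rng = np.random.default_rng(seed)
        outcomes = [StrategyOutcome(f"s{i}", float(rng.integers(0, 1000)),
                                    float(rng.integers(0, 100)))
                    for i in range(6)]
        on = {e.strategy for e in build_frontier(outcomes)
              if e.status is DominanceStatus.ON_FRONTIER}
        oracle = hull_oracle(outcomes, lam_max=1e5)
        # hull oracle can miss frontier members only through λ-grid ties;
        # it must never name a strategy the frontier rejects
        assert oracle <= on

    def test_needs_two_strategies(self):
        with pytest.raises(ValueError):
            build_frontier([StrategyOutcome("only", 0, 0)])


class TestCEAC:
    def test_degenerate_step_function(self):
        psa = make_psa({"a": np.full(100, 3000.0), "b": np.full(100, 1000.0)},
                       {"a": np.full(100, 11.0), "b": np.full(100, 10.0)})
        curve = ceac(psa, "a", "b", [0, 1000, 1999, 2000, 2001, 5000])
        np.testing.assert_array_equal(curve.probability, [0, 0, 0, 1, 1, 1])

    def test_lambda_zero_is_cost_saving_fraction(self):
        rng = np.random.default_rng(1)
        d_cost = rng.normal(0, 1, 2000)
        psa = make_psa({"a": d_cost, "b": np.zeros(2000)},
                       {"a": np.ones(2000), "b": np.zeros(2000)})
        curve = ceac(psa, "a", "b", [0.0])
        assert curve.probability[0] == pytest.approx((d_cost <= 0).mean())

    def test_symmetric_nmb_centred_at_half(self):
        rng = np.random.default_rng(2)
        n = 20000
        d_cost = rng.normal(0, 50, n)  # symmetric about 0
        psa = make_psa({"a": d_cost, "b": np.zeros(n)},
                       {"a": np.zeros(n), "b": np.zeros(n)})
        curve = ceac(psa, "a", "b", [1000.0])
        # 3 binomial standard errors around 0.5
        assert curve.probability[0] == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_monotone_when_effect_positive(self, params):
        psa = run_psa(params, [PRESETS["nNO/HSVM+TEM"], PRESETS["nNO+HSVM"]],
                      n_iter=400, seed=17)
        d_eff = (psa.effects["nNO/HSVM+TEM"] - psa.effects["nNO+HSVM"]).to_numpy()
        assume_positive = (d_eff > 0).all()
        grid = np.linspace(0, 50000, 200)
        curve = ceac(psa, "nNO/HSVM+TEM", "nNO+HSVM", grid)
        if assume_positive:
            assert (np.diff(curve.probability) >= 0).all()
        assert ((curve.probability >= 0) & (curve.probability <= 1)).all()

    def test_empty_grid_rejected(self):
        psa = make_psa({"a": np.ones(5), "b": np.ones(5)},
                       {"a": np.ones(5), "b": np.zeros(5)})
        with pytest.raises(ValueError):
            ceac(psa, "a", "b", [])

    def test_unknown_strategy_rejected(self):
        psa = make_psa({"a": np.ones(5)}, {"a": np.ones(5)})
        with pytest.raises(KeyError):
            ceac(psa, "a", "zzz", [0.0])


class TestRatioEstimators:
    def test_agree_for_degenerate_psa(self):
        summ = ratio_summary(np.full(50, 900.0), np.full(50, 30.0))
        assert summ.mean_of_ratios == pytest.approx(30.0)
        assert summ.ratio_of_means == pytest.approx(30.0)
        assert summ.ratio_ci == (pytest.approx(30.0), pytest.approx(30.0))
        assert summ.n_excluded == 0

    def test_zero_effect_iterations_excluded_and_counted(self):
        summ = ratio_summary(np.array([10.0, 10.0, 10.0]),
                             np.array([1.0, 0.0, 2.0]))
        assert summ.n_excluded == 1
        assert summ.mean_of_ratios == pytest.approx((10 + 5) / 2)

    def test_estimators_differ_for_skewed_draws(self):
        rng = np.random.default_rng(3)
        d_eff = rng.uniform(0.5, 4.0, 5000)
        d_cost = np.full(5000, 100.0)
        summ = ratio_summary(d_cost, d_eff)
        # Jensen: E[c/e] > E[c]/E[e] for nondegenerate e
        assert summ.mean_of_ratios > summ.ratio_of_means

    def test_cer_table_columns(self, params, all_strategies):
        psa = run_psa(params, all_strategies, n_iter=200, seed=8)
        table = cer_table(psa)
        assert "Do nothing" not in table.index
        assert {"cer_mean_of_ratios", "cer_ratio_of_means"} <= set(table.columns)
        assert (table["cer_mean_of_ratios"] > 0).all()


@pytest.fixture(scope="module")
def tornado_entries(params):
    return tornado(params, PRESETS["nNO/HSVM+TEM"], PRESETS["nNO+HSVM"])


class TestTornado:

    def test_sorted_by_descending_span(self, tornado_entries):
        spans = [e.span for e in tornado_entries]
        assert spans == sorted(spans, reverse=True)

    def test_hsvm_sensitivity_has_nonzero_span(self, tornado_entries):
        by_name = {e.parameter: e for e in tornado_entries}
        assert by_name["hsvm.sensitivity"].span > 0

    def test_unused_parameter_zero_span(self, params):
        entries = tornado(params, PRESETS["nNO+HSVM"], DO_NOTHING)
        by_name = {e.parameter: e for e in entries}
        # the pair performs no ultrastructure test, so its cost inputs are inert
        assert by_name["tem_cost.capital_cost"].span == 0
        assert by_name["tem_cost.capital_cost"] == entries[-1] or \
            entries[-1].span == 0

    def test_restricted_parameter_list(self, params):
        entries = tornado(params, PRESETS["nNO/HSVM+TEM"], PRESETS["nNO+HSVM"],
                          parameters=["prevalence"])
        assert [e.parameter for e in entries] == ["prevalence"]
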