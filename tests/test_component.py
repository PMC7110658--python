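"""Component reliability: closed form vs Monte Carlo, mode combination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

import spinerel as sr
from spinerel.component import Method, deterministic_failure
from spinerel.errors import (
    DegenerateDistributionError,
    MissingEntryError,
    UnknownTokenError,
)
from spinerel.materials import LoadMode, TissueKind


def _limit_state(mu_r, s_r, mu_q, s_q, tissue="cortical", mode="tension"):
    return sr.LimitState(
        sr.YieldStrengthDistribution(tissue, mode, mu_r, s_r),
        sr.DemandDistribution("X", tissue, mode, mu_q, s_q),
    )


class TestClosedForm:
    def test_equal_means_give_beta_zero(self):
        assert sr.beta_closed_form(10.0, 2.0, 10.0, 1.0) == 0.0

    def test_hand_value_cortical_tension(self):
        # (75 - 20) / sqrt(13.98^2 + 5^2)
        assert sr.beta_closed_form(75.0, 13.98, 20.0, 5.0) == pytest.approx(3.704, abs=1e-3)

    @given(
        c=st.floats(0.1, 100.0),
        mu_r=st.floats(10.0, 100.0),
        mu_q=st.floats(0.1, 9.0),
        s_r=st.floats(0.1, 3.0),
        s_q=st.floats(0.1, 3.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_scale_invariance(self, c, mu_r, mu_q, s_r, s_q):
        b1 = sr.beta_closed_form(mu_r, s_r, mu_q, s_q)
        b2 = sr.beta_closed_form(c * mu_r, c * s_r, c * mu_q, c * s_q)
        assert b2 == pytest.approx(b1, rel=1e-9)

    def test_both_sigmas_zero_is_a_named_error(self):
        with pytest.raises(DegenerateDistributionError):
            sr.beta_closed_form(10.0, 0.0, 5.0, 0.0)
        assert deterministic_failure(10.0, 5.0) == 0.0
        assert deterministic_failure(5.0, 10.0) == 1.0

    def test_truncation_warning_for_low_margin_resistance(self):
        with pytest.warns(UserWarning, match="mean/std"):
            sr.beta_closed_form(1.9, 0.86, 0.5, 0.05)


class TestMonteCarlo:
    def test_degenerate_distributions_give_exact_pf(self):
        ls = _limit_state(10.0, 0.0, 5.0, 0.0)
        pf, se = sr.pf_monte_carlo(ls, 1000, seed=0)
        assert pf == 0.0 and se == 0.0

    def test_matches_closed_form_oracle(self):
        ls = _limit_state(75.0, 13.98, 20.0, 5.0)
        beta = sr.beta_closed_form(75.0, 13.98, 20.0, 5.0)
        expected = float(ndtr(-beta))  # ~1.06e-4
        pf, se = sr.pf_monte_carlo(ls, 10**6, seed=13)
        assert abs(pf - expected) < 3 * math.sqrt(expected * (1 - expected) / 10**6)

    def test_identical_distributions_give_half(self):
        ls = _limit_state(5.0, 1.0, 5.0, 1.0)
        pf, se = sr.pf_monte_carlo(ls, 10**5, seed=21)
        assert abs(pf - 0.5) < 3 * se

    def test_reproducible_under_seed(self):
        ls = _limit_state(10.0, 2.0, 8.0, 1.0)
        assert sr.pf_monte_carlo(ls, 10**4, seed=3) == sr.pf_monte_carlo(ls, 10**4, seed=3)

    def test_batching_does_not_change_the_estimate(self, monkeypatch):
        import spinerel.component as comp

        ls = _limit_state(10.0, 2.0, 8.0, 1.0)
        whole = sr.pf_monte_carlo(ls, 30_000, seed=8)
        monkeypatch.setattr(comp, "_MC_BATCH", 7_000)
        assert sr.pf_monte_carlo(ls, 30_000, seed=8) == whole

    def test_mismatched_limit_state_rejected(self):
        r = sr.YieldStrengthDistribution("cortical", "tension", 75.0, 13.98)
        q = sr.DemandDistribution("X", "cancellous", "tension", 1.0, 0.1)
        with pytest.raises(UnknownTokenError):
            sr.LimitState(r, q)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            sr.pf_monte_carlo(_limit_state(10, 1, 5, 1), 0, seed=0)


class TestCombineModes:
    def test_governing_takes_the_larger(self):
        assert sr.combine_modes(0.0, 0.3) == 0.3
        assert sr.combine_modes(0.2, 0.1) == 0.2

    def test_series_hand_value(self):
        assert sr.combine_modes(0.1, 0.2, policy="series") == pytest.approx(0.28)

    def test_governing_never_exceeds_series_on_a_grid(self):
        grid = np.linspace(0.0, 1.0, 21)
        for pt in grid:
            for pc in grid:
                gov = sr.combine_modes(pt, pc, "governing")
                ser = sr.combine_modes(pt, pc, "series")
                assert gov <= ser + 1e-15

    def test_unknown_policy_rejected(self):
        with pytest.raises(UnknownTokenError):
            sr.combine_modes(0.1, 0.2, policy="worst")


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestComponentReliability:
    def test_closed_form_and_mc_agree(self, resistances):
        demands = sr.index_demands([
            sr.DemandDistribution("X", "cortical", "tension", 30.0, 6.0),
            sr.DemandDistribution("X", "cortical", "compression", 100.0, 15.0),
        ])
        cf = sr.component_reliability("X", "cortical", resistances, demands)
        mc = sr.component_reliability(
            "X", "cortical", resistances, demands,
            method="monte_carlo", n=10**6, seed=17,
        )
        assert cf.method is Method.CLOSED_FORM and mc.method is Method.MONTE_CARLO
        assert mc.mc_n == 10**6 and mc.seed == 17 and mc.mc_stderr is not None
        assert cf.mc_n is None and cf.seed is None
        assert abs(mc.pf - cf.pf) < 3 * mc.mc_stderr

    def test_zero_demand_gives_zero_pf_and_infinite_beta(self, resistances):
        demands = sr.index_demands([
            sr.DemandDistribution("X", "annulus", m, 0.0, 0.0) for m in LoadMode
        ])
        out = sr.component_reliability("X", "annulus", resistances, demands)
        assert out.pf == 0.0
        assert out.beta == math.inf

    def test_beta_strictly_decreasing_in_demand_mean(self, resistances):
        betas = []
        for mu in (10.0, 20.0, 30.0):
            demands = sr.index_demands([
                sr.DemandDistribution("X", "cortical", m, mu, 2.0) for m in LoadMode
            ])
            betas.append(
                sr.component_reliability("X", "cortical", resistances, demands).beta
            )
        assert betas[0] > betas[1] > betas[2]

    def test_missing_demand_entry_is_named(self, resistances):
        with pytest.raises(MissingEntryError, match="no demand entry"):
            sr.component_reliability("X", "cortical", resistances, {})

    def test_rule_of_three_bound_attached_when_no_failures(self, resistances):
        demands = sr.index_demands([
            sr.DemandDistribution("X", "cortical", m, 1.0, 0.1) for m in LoadMode
        ])
        out = sr.component_reliability(
            "X", "cortical", resistances, demands,
            method="monte_carlo", n=1000, seed=2,
        )
        assert out.pf == 0.0
        assert out.mc_pf_upper95 == pytest.approx(3.0 / 1000)


@pytest.mark.filterwarnings("ignore::UserWarning")
class TestOracleEquivalenceSweep:
    """Closed-form pf equals MC counting across a parameter sweep when both
    distributions sit far from the truncation point."""

    @given(
        mu_r=st.floats(40.0, 120.0),
        ratio=st.floats(0.3, 0.8),
        cov_r=st.floats(0.05, 0.15),
        cov_q=st.floats(0.05, 0.15),
        seed=st.integers(0, 2**16),
    )
    @settings(derandomize=True, max_examples=10, deadline=None)
    def test_mc_within_three_se_of_phi(self, mu_r, ratio, cov_r, cov_q, seed):
        mu_q = ratio * mu_r
        s_r, s_q = cov_r * mu_r, cov_q * mu_q
        beta = sr.beta_closed_form(mu_r, s_r, mu_q, s_q)
        expected = float(ndtr(-beta))
        n = 10**5
        pf, _ = sr.pf_monte_carlo(_limit_state(mu_r, s_r, mu_q, s_q), n, seed=seed)
        se = math.sqrt(max(expected * (1 - expected), 1e-12) / n)
        assert abs(pf - expected) <= 4 * se + 1e-6
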