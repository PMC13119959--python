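"""Microbial rate laws: Monod uptake, Hill toxicity, Luedeking-Piret production."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biobattery import (
    AnolyteState,
    MicrobialParams,
    growth_rate,
    microbial_derivatives,
    production_rate,
    specific_uptake,
    toxicity_factor,
)

positive = st.floats(min_value=1e-6, max_value=1e3, allow_nan=False)


@pytest.mark.parametrize(
    "S, expected",
    [
        (0.0, 0.0),                       # no substrate, no uptake
        (0.10, 5.0),                      # half-saturation: qS_max/2
        (10.0, 10.0 * 10.0 / 10.1),       # 100x K_S, near saturation
    ],
)
def test_specific_uptake_examples(S, expected, mp):
    assert specific_uptake(S, mp) == pytest.approx(expected, rel=1e-12)


def test_specific_uptake_bounded_and_monotone(mp):
    values = [specific_uptake(s, mp) for s in (0, 0.01, 0.1, 1, 10, 1e6)]
    assert all(0 <= v <= mp.qS_max for v in values)
    assert values == sorted(values)


@pytest.mark.parametrize(
    "P_tot, n_inh, expected",
    [
        (0.0, 2.0, 1.0),
        (0.010, 2.0, 0.5),     # half-inhibition at K_inh by construction
        (0.020, 2.0, 0.2),     # 1/(1+2^2)
    ],
)
def test_toxicity_factor_examples(P_tot, n_inh, expected):
    p = MicrobialParams(n_inh=n_inh)
    assert toxicity_factor(P_tot, p) == pytest.approx(expected, rel=1e-12)


@given(K_inh=positive, n_inh=st.floats(min_value=1.0, max_value=8.0))
def test_toxicity_half_at_K_inh(K_inh, n_inh):
    """The Hill factor equals 1/2 exactly at P_tot = K_inh, for any shape."""
    p = MicrobialParams(K_inh=K_inh, n_inh=n_inh)
    assert toxicity_factor(K_inh, p) == pytest.approx(0.5, rel=1e-9)


@given(
    P=st.lists(st.floats(min_value=0, max_value=10), min_size=2, max_size=6, unique=True),
    K_inh=positive,
    n_inh=st.floats(min_value=1.0, max_value=6.0),
)
def test_toxicity_monotone_decreasing(P, K_inh, n_inh):
    p = MicrobialParams(K_inh=K_inh, n_inh=n_inh)
    P = sorted(P)
    f = [toxicity_factor(v, p) for v in P]
    assert all(a >= b for a, b in zip(f, f[1:]))


def test_toxicity_strictly_decreasing_on_grid(mp):
    f = [toxicity_factor(v, mp) for v in (0.0, 0.001, 0.005, 0.01, 0.05, 0.5)]
    assert all(a > b for a, b in zip(f, f[1:]))


@pytest.mark.parametrize("fn, args", [
    (specific_uptake, (-1.0,)),
    (toxicity_factor, (-0.1,)),
])
def test_negative_concentrations_rejected(fn, args, mp):
    with pytest.raises(ValueError):
        fn(*args, mp)


class TestGrowthRate:
    def test_zero_substrate(self, mp):
        state = AnolyteState(S=0.0, P_red=0.004, P_ox=0.001)
        assert growth_rate(state, mp) == 0.0

    def test_saturated_uninhibited_limit(self, mp):
        """S >> K_S with no phenazine: mu -> Y_XS * qS_max = 0.9 1/h."""
        state = AnolyteState(S=1e6)
        assert growth_rate(state, mp) == pytest.approx(0.9, rel=1e-6)

    def test_half_inhibited_at_K_inh(self, mp):
        state = AnolyteState(S=1e6, P_red=0.005, P_ox=0.005)
        assert growth_rate(state, mp) == pytest.approx(0.45, rel=1e-6)

    @given(
        S1=st.floats(min_value=0, max_value=100),
        S2=st.floats(min_value=0, max_value=100),
        P1=st.floats(min_value=0, max_value=1),
        P2=st.floats(min_value=0, max_value=1),
        alpha=positive,
        K_inh=positive,
    )
    def test_monotonicity(self, S1, S2, P1, P2, alpha, K_inh):
        """mu is non-decreasing in S and non-increasing in total phenazine."""
        p = MicrobialParams(alpha_P=alpha, K_inh=K_inh)
        lo_S, hi_S = sorted((S1, S2))
        lo_P, hi_P = sorted((P1, P2))
        assert growth_rate(AnolyteState(S=lo_S, P_red=lo_P), p) <= \
            growth_rate(AnolyteState(S=hi_S, P_red=lo_P), p) + 1e-15
        assert growth_rate(AnolyteState(S=hi_S, P_red=hi_P), p) <= \
            growth_rate(AnolyteState(S=hi_S, P_red=lo_P), p) + 1e-15


class TestProductionRate:
    @pytest.mark.parametrize("mu, X, expected", [
        (0.5, 0.0, 0.0),
        (0.0, 1.0, 0.0),           # purely growth-associated default
        (0.9, 1.0, 0.027),         # alpha_P * mu * X
    ])
    def test_examples(self, mu, X, expected, mp):
        assert production_rate(mu, X, mp) == pytest.approx(expected, rel=1e-12)

    def test_non_growth_term(self):
        p = MicrobialParams(beta_P=0.002)
        assert production_rate(0.0, 2.0, p) == pytest.approx(0.004)

    def test_production_ceases_with_growth(self, mp):
        """With beta_P = 0 and exhausted substrate, production stops."""
        state = AnolyteState(X=1.0, S=0.0)
        mu = growth_rate(state, mp)
        assert production_rate(mu, state.X, mp) == 0.0


class TestDerivatives:
    def test_empty_reactor_fixed_point(self, mp):
        state = AnolyteState(X=0, S=0, P_red=0, P_ox=0)
        assert microbial_derivatives(state, 0.0, mp) == (0, 0, 0, 0)

    def test_baseline_rates(self, mp):
        """Monod at S = 10 with K_S = 0.1: qS = 9.901, mu = 0.891."""
        state = AnolyteState(X=0.1, S=10.0)
        dX, dS, dPr, dPo = microbial_derivatives(state, 0.0, mp)
        assert dX == pytest.approx(0.08910891089108912, rel=1e-10)
        assert dS == pytest.approx(-0.9900990099009901, rel=1e-10)
        assert dPr == pytest.approx(mp.alpha_P * dX, rel=1e-10)
        assert dPo == 0.0

    @given(
        X=st.floats(min_value=0, max_value=5),
        S=st.floats(min_value=0, max_value=50),
        Pr=st.floats(min_value=0, max_value=1),
        Po=st.floats(min_value=0, max_value=1),
        v=st.floats(min_value=-10, max_value=10),
        k_deg=positive,
    )
    def test_total_phenazine_balance(self, X, S, Pr, Po, v, k_deg):
        """d(P_red+P_ox)/dt = production - k_deg*P_tot for any electrode flux."""
        p = MicrobialParams(k_deg=k_deg)
        state = AnolyteState(X=X, S=S, P_red=Pr, P_ox=Po)
        dX, dS, dPr, dPo = microbial_derivatives(state, v, p)
        mu = growth_rate(state, p)
        expected = production_rate(mu, X, p) - k_deg * (Pr + Po)
        assert dPr + dPo == pytest.approx(expected, abs=1e-14, rel=1e-12)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        {"qS_max": 0.0}, {"K_S": -1.0}, {"Y_XS": 0.0}, {"alpha_P": -0.1},
        {"k_deg": 0.0}, {"K_inh": -0.01}, {"n_inh": 0.5}, {"beta_P": -1e-6},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            MicrobialParams(**kw)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            MicrobialParams.from_dict({"qS_max": 10, "bogus": 1})
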