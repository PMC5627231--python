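"""Kinetics, control law and right-hand-side identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rscm import (
    DomainError,
    ModelParameters,
    ModelState,
    STATE_NAMES,
    cybernetic_u,
    derived_rates,
    instantaneous_yield,
    monod_factor,
    rhs,
    synthesis_rates,
    unregulated_rates,
)
from conftest import random_states

P = ModelParameters()
S = ModelState()


@pytest.mark.parametrize(
    "x, K, expected",
    [
        (0.0, 0.25, 0.0),                 # zero substrate
        (0.25, 0.25, 0.5),                # half-saturation point
        (61.1, 0.25, 61.1 / 61.35),       # batch initial DOC against Kd
    ],
)
def test_monod_factor_values(x, K, expected):
    assert monod_factor(x, K) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("x, K", [(-0.1, 0.25), (1.0, 0.0), (1.0, -1.0)])
def test_monod_factor_domain_errors(x, K):
    with pytest.raises(DomainError):
        monod_factor(x, K)


@given(st.floats(0, 1e6), st.floats(1e-9, 1e3))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_monod_factor_bounded(x, K):
    v = monod_factor(x, K)
    assert 0.0 <= v < 1.0


def test_unregulated_rates_acceptor_specific():
    no_doc = S.with_updates(xDOC=0.0)
    assert unregulated_rates(no_doc, P) == (0.0, 0.0)
    r1, r2 = unregulated_rates(S, P)  # initial NO2 is zero
    assert r2 == 0.0 and r1 > 0.0


def test_unregulated_rates_initial_value():
    # direct arithmetic: k1 * DOC/(Kd+DOC) * NO3/(Ka+NO3)
    expected = 6.23 * (61.1 / 61.35) * (18.3 / 18.301)
    r1, _ = unregulated_rates(S, P)
    assert r1 == pytest.approx(expected, rel=1e-12)
    assert r1 == pytest.approx(6.2040, abs=5e-4)


@pytest.mark.parametrize(
    "p1, p2, expected",
    [(1.0, 1.0, (0.5, 0.5)), (3.0, 1.0, (0.75, 0.25)), (0.0, 0.0, (0.0, 0.0))],
)
def test_cybernetic_u_matching_law(p1, p2, expected):
    assert cybernetic_u(p1, p2) == pytest.approx(expected)


def test_cybernetic_u_rejects_negative():
    with pytest.raises(DomainError):
        cybernetic_u(-1.0, 1.0)


@given(st.floats(0, 1e3), st.floats(0, 1e3))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_cybernetic_u_sums_to_one(p1, p2):
    u1, u2 = cybernetic_u(p1, p2)
    if p1 + p2 > 0:
        assert u1 + u2 == pytest.approx(1.0)
    else:
        assert (u1, u2) == (0.0, 0.0)


def test_synthesis_rates_cascade_gating():
    # no resource pool: neither transcription nor translation of pathway 1
    s = S.with_updates(rho1=0.0, tau1=0.0)
    rR1, _, rT1, _, rE1, _ = synthesis_rates(s, P)
    assert rT1 == 0.0 and rE1 == 0.0 and rR1 > 0.0
    # transcript gone but resource present: transcription restarts first
    s = S.with_updates(tau1=0.0, rho1=0.5)
    _, _, rT1, _, rE1, _ = synthesis_rates(s, P)
    assert rE1 == 0.0 and rT1 > 0.0


def test_synthesis_rates_initial_value():
    expected = 2.84 * (61.1 / 61.35) * (18.3 / 18.301)
    rR1 = synthesis_rates(S, P)[0]
    assert rR1 == pytest.approx(expected, rel=1e-12)
    assert rR1 == pytest.approx(2.8282, abs=5e-4)


def test_rhs_biomass_only_state():
    s = ModelState(**{n: 0.0 for n in STATE_NAMES}).with_updates(xBM=1.0)
    dy = rhs(s, P)
    by_name = dict(zip(STATE_NAMES, dy))
    assert by_name["xDOC"] == pytest.approx(5 * P.kdeg)
    assert by_name["xBM"] == pytest.approx(-P.kdeg)
    assert by_name["rho1"] == pytest.approx(P.alphaR1)
    assert by_name["rho2"] == pytest.approx(P.alphaR2)
    for n in ("xNO3", "xNO2", "xN2", "xDIC", "tau1", "tau2", "e1", "e2"):
        assert by_name[n] == 0.0


def test_rhs_initial_nitrate_consumption():
    dy = rhs(S, P)
    r1_kin, _ = unregulated_rates(S, P)
    assert dy[1] == pytest.approx(-2 * 0.56 * 0.001 * r1_kin, rel=1e-12)
    assert dy[1] == pytest.approx(-0.006949, abs=5e-6)


def test_rhs_conservation_identities(rng):
    """Carbon (DOC + DIC + 5 BM) and nitrogen (NO3 + NO2 + 2 N2) are exact
    invariants of the equations at every state."""
    for y in random_states(rng, 1000):
        dy = rhs(ModelState.from_array(y), P)
        carbon = dy[0] + dy[4] + 5.0 * dy[5]
        nitrogen = dy[1] + dy[2] + 2.0 * dy[3]
        assert abs(carbon) < 1e-12 * max(1.0, abs(dy[0]))
        assert abs(nitrogen) < 1e-12 * max(1.0, abs(dy[1]))


def test_no_enzyme_no_uptake(rng):
    """With e_i = 0 the regulated rate of pathway i vanishes regardless of
    substrate levels."""
    for y in random_states(rng, 50):
        y[10] = 0.0
        d = derived_rates(ModelState.from_array(y), P)
        assert d.r1 == 0.0


def test_rates_monotone_in_substrate(rng):
    """Unregulated rates never decrease when a substrate increases."""
    for y in random_states(rng, 50):
        s = ModelState.from_array(y)
        r1, r2 = unregulated_rates(s, P)
        s_up = s.with_updates(xDOC=s.xDOC * 2 + 0.1, xNO3=s.xNO3 * 2 + 0.1)
        r1_up, _ = unregulated_rates(s_up, P)
        assert r1_up >= r1


@pytest.mark.parametrize(
    "r1, r2, expected",
    [
        (2.0, 0.0, (1 - 0.56) / 5),   # single-pathway limit
        (0.0, 0.0, 0.0),              # degenerate case
        (1.0, 1.0, 0.045),            # ((1-0.56)/5 + (1-0.99)/5) / 2
    ],
)
def test_instantaneous_yield(r1, r2, expected):
    assert instantaneous_yield(r1, r2, P) == pytest.approx(expected)


def test_parameter_validation():
    with pytest.raises(DomainError):
        ModelParameters(f1=1.2)
    with pytest.raises(DomainError):
        ModelParameters(k1=-0.1)
    with pytest.raises(DomainError):
        ModelParameters(Kd1=0.0)
    # zero rate constants are legal limiting cases
    ModelParameters(k1=0.0, kdeg=0.0)


def test_state_validation_and_roundtrip():
    with pytest.raises(DomainError):
        ModelState(xDOC=-1.0)
    with pytest.raises(DomainError):
        ModelState(e1=float("nan"))
    y = S.to_array()
    assert ModelState.from_array(y) == S
    assert list(y) == [getattr(S, n) for n in STATE_NAMES]
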