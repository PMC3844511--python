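"""The closed-form conditional cell probabilities and their algebraic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famlrt import (
    ParameterDomainError,
    RiskModelParams,
    dyad_probabilities,
    monad_probabilities,
    normalizer,
    schaid_sommer_unordered_probability,
    triad_probabilities,
)
from famlrt.model import dyad_probabilities_complex

params_strategy = st.builds(
    RiskModelParams,
    p=st.floats(0.001, 0.999),
    psi1=st.floats(0.0, 100.0),
    psi2=st.floats(0.0, 100.0),
)


@pytest.mark.parametrize(
    "p, psi1, psi2, expected",
    [
        (0.5, 1.0, 1.0, 1.0),      # null: R = (p + q)^2
        (0.5, 1.0, 2.0, 1.25),
        (0.2, 2.0, 4.0, 1.44),     # 0.16 + 0.64 + 0.64
    ],
)
def test_normalizer_hand_values(p, psi1, psi2, expected):
    assert normalizer(RiskModelParams(p, psi1, psi2)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(p=0.0, psi1=1, psi2=1),
        dict(p=1.0, psi1=1, psi2=1),
        dict(p=-0.2, psi1=1, psi2=1),
        dict(p=0.5, psi1=-0.1, psi2=1),
        dict(p=0.5, psi1=1, psi2=-3),
        dict(p=float("nan"), psi1=1, psi2=1),
        dict(p=0.5, psi1=float("inf"), psi2=1),
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ParameterDomainError):
        RiskModelParams(**kwargs)


def test_triad_probabilities_null_are_hwe_times_mendel():
    probs = triad_probabilities(RiskModelParams(0.5, 1, 1))
    expected = [0.0625, 0.125, 0.125, 0.125, 0.0625, 0.125, 0.0625, 0.125, 0.125, 0.0625]
    np.testing.assert_allclose(probs, expected, atol=1e-15)


def test_triad_cell1_with_elevated_homozygote_risk():
    # p^4 psi2 / R = 0.0625 * 2 / 1.25
    probs = triad_probabilities(RiskModelParams(0.5, 1, 2))
    assert probs[0] == pytest.approx(0.1, abs=1e-14)


def test_null_reduction_matches_random_mating_oracle():
    """At psi = 1 each triad cell is HWE mating-type frequency x Mendelian share."""
    for p in (0.1, 0.37, 0.8):
        q = 1 - p
        # (mating type HWE frequency, Mendelian probability of the child cell)
        oracle = [
            (p**4, 1.0),
            (4 * p**3 * q, 0.5), (4 * p**3 * q, 0.5),
            (2 * p**2 * q**2, 1.0),
            (4 * p**2 * q**2, 0.25), (4 * p**2 * q**2, 0.5), (4 * p**2 * q**2, 0.25),
            (4 * p * q**3, 0.5), (4 * p * q**3, 0.5),
            (q**4, 1.0),
        ]
        expected = [mt * mendel for mt, mendel in oracle]
        np.testing.assert_allclose(
            triad_probabilities(RiskModelParams(p, 1, 1)), expected, atol=1e-14
        )


def test_dyad_probabilities_null_and_elevated_risk():
    np.testing.assert_allclose(
        dyad_probabilities(RiskModelParams(0.5, 1, 1)),
        [0.125, 0.125, 0.125, 0.25, 0.125, 0.125, 0.125],
        atol=1e-15,
    )
    # cell m3 (parent Aa, child AA): p^2 q psi2 / R = 0.125 * 2 / 1.25
    assert dyad_probabilities(RiskModelParams(0.5, 1, 2))[2] == pytest.approx(0.2, abs=1e-14)


def test_monad_probabilities_examples():
    np.testing.assert_allclose(
        monad_probabilities(RiskModelParams(0.5, 1, 1)), [0.25, 0.5, 0.25], atol=1e-15
    )
    np.testing.assert_allclose(
        monad_probabilities(RiskModelParams(0.5, 1, 2)), [0.4, 0.4, 0.2], atol=1e-14
    )


@settings(deadline=None, max_examples=150, derandomize=True)
@given(params=params_strategy)
def test_probability_vectors_sum_to_one(params):
    for fn in (triad_probabilities, dyad_probabilities, monad_probabilities):
        assert abs(fn(params).sum() - 1.0) < 5e-12


@settings(deadline=None, max_examples=100, derandomize=True)
@given(params=params_strategy)
def test_simplified_dyads_equal_missing_parent_sum(params):
    """The monomial dyad column equals the sum over the unobserved parent."""
    np.testing.assert_allclose(
        dyad_probabilities(params), dyad_probabilities_complex(params), atol=1e-12, rtol=1e-12
    )


def test_dyad_marginalisation_oracle():
    """Independent reconstruction: halve unordered mixed mating types, sum over partner."""
    rng = np.random.default_rng(2024)
    for _ in range(50):
        params = RiskModelParams(rng.uniform(0.02, 0.98), rng.uniform(0, 6), rng.uniform(0, 6))
        t = triad_probabilities(params)
        expected = np.array(
            [
                t[0] + t[1] / 2,
                t[2] / 2 + t[3] / 2,
                t[1] / 2 + t[4],
                t[2] / 2 + t[5] + t[7] / 2,
                t[6] + t[8] / 2,
                t[3] / 2 + t[7] / 2,
                t[8] / 2 + t[9],
            ]
        )
        np.testing.assert_allclose(dyad_probabilities(params), expected, atol=1e-13)


def test_schaid_sommer_unordered_exceeds_ordered_cell():
    assert schaid_sommer_unordered_probability(
        RiskModelParams(0.5, 1, 1)
    ) == pytest.approx(0.1875, abs=1e-14)
    assert schaid_sommer_unordered_probability(
        RiskModelParams(0.5, 1, 2)
    ) == pytest.approx(0.3, abs=1e-14)
    # exceeds the ordered (parent Aa, child AA) dyad cell by p^3 q psi2 / R exactly
    rng = np.random.default_rng(7)
    for _ in range(20):
        params = RiskModelParams(rng.uniform(0.05, 0.95), rng.uniform(0, 4), rng.uniform(0, 4))
        p, q = params.p, params.q
        gap = p**3 * q * params.psi2 / normalizer(params)
        assert schaid_sommer_unordered_probability(params) - dyad_probabilities(params)[
            2
        ] == pytest.approx(gap, abs=1e-13)
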