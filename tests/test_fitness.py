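"""Dominance table, coefficient sampling, and multiplicative fitness arrays."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flypsd import (
    FitnessArray,
    SCHEMES,
    SelectionCoefficients,
    build_fitness_array,
    build_fitness_arrays,
    sample_selection_coefficients,
    single_pair_fitness,
)
from flypsd.genotypes import FEMALE, MALE, InvalidGenotypeError


@pytest.mark.parametrize(
    "scheme,s,count,sex,pair,expected",
    [
        ("additive", 0.4, 1, MALE, 0, 0.8),        # 1 - 0.5s heterozygote
        ("additive", 0.4, 0, MALE, 0, 0.6),
        ("additive", 0.4, 2, MALE, 0, 1.0),
        ("additive", -0.6, 1, FEMALE, 1, 0.7),     # 1 + 0.5s
        ("additive", -0.6, 2, FEMALE, 1, 0.4),     # 1 + s
        ("dominant", 0.3, 0, MALE, 0, 0.7),
        ("dominant", 0.3, 1, MALE, 0, 1.0),
        ("dominant", -0.5, 1, FEMALE, 0, 0.5),     # 1 + s, from the printed table
        ("dominant", -0.5, 2, FEMALE, 0, 0.5),
        ("recessive", 0.3, 0, MALE, 1, 0.7),
        ("recessive", 0.3, 1, MALE, 1, 0.7),
        ("recessive", -0.3, 1, MALE, 1, 1.0),
        ("recessive", -0.3, 2, MALE, 1, 0.7),
        ("overdominant", 0.3, 0, MALE, 1, 0.7),    # heterozygote advantage
        ("overdominant", 0.3, 1, MALE, 1, 1.0),
        ("overdominant", 0.3, 2, MALE, 1, 0.7),
        ("overdominant", -0.3, 0, MALE, 1, 0.7),
        ("overdominant", -0.3, 2, MALE, 1, 0.7),
        # IV^F: single carrier state, full effect for either sign
        ("additive", 0.4, 1, FEMALE, 2, 0.6),
        ("dominant", -0.4, 1, FEMALE, 2, 1.4),
        ("recessive", 0.4, 0, FEMALE, 2, 1.0),
    ],
)
def test_single_pair_table(scheme, s, count, sex, pair, expected):
    assert single_pair_fitness(scheme, s, count, sex, pair) == pytest.approx(expected)


@pytest.mark.parametrize("scheme", SCHEMES)
@pytest.mark.parametrize("count,sex,pair", [(0, MALE, 0), (1, FEMALE, 1), (2, MALE, 1)])
def test_neutral_coefficient_is_neutral(scheme, count, sex, pair):
    assert single_pair_fitness(scheme, 0.0, count, sex, pair) == 1.0


def test_female_overdominant_falls_back_to_additive():
    for s in (-0.8, -0.2, 0.3, 0.9):
        for count in (0, 1, 2):
            assert single_pair_fitness("overdominant", s, count, FEMALE, 0) == (
                single_pair_fitness("additive", s, count, FEMALE, 0)
            )


def test_ivf_homozygote_rejected():
    with pytest.raises(InvalidGenotypeError):
        single_pair_fitness("additive", 0.2, 2, FEMALE, 2)


@given(st.sampled_from(SCHEMES), st.floats(-1, 1))
def test_table_orderings(scheme, s):
    """The printed row orderings hold for every coefficient in [-1, 1]."""
    w = [single_pair_fitness(scheme, s, c, MALE, 0) for c in (0, 1, 2)]
    assert all(0.0 <= v <= 2.0 for v in w)
    if scheme == "additive":
        if s >= 0:
            assert w[0] <= w[1] <= w[2]
        else:
            assert w[0] >= w[1] >= w[2]
    elif scheme == "dominant":
        assert w[1] == w[2]
        assert (w[0] <= w[1]) if s >= 0 else (w[0] >= w[1])
    elif scheme == "recessive":
        assert w[0] == w[1]
        assert (w[1] <= w[2]) if s >= 0 else (w[1] >= w[2])
    else:  # overdominant: male heterozygote always at the top with fitness 1
        assert w[1] == 1.0
        assert w[0] == w[2] <= 1.0


def test_sampling_reproducible_and_in_range():
    a = sample_selection_coefficients(np.random.default_rng(42))
    b = sample_selection_coefficients(np.random.default_rng(42))
    assert a == b
    arr = a.as_array()
    assert arr.shape == (2, 3)
    assert (np.abs(arr) < 1.0).all()


def test_sampling_uniform_statistics():
    """10,000 draws: mean near 0 (CLT bound), extremes reach past +/-0.9."""
    draws = sample_selection_coefficients(np.random.default_rng(7), size=10_000)
    assert draws.shape == (10_000, 2, 3)
    means = draws.mean(axis=0)
    assert (np.abs(means) < 0.03).all()
    assert (draws.min(axis=0) < -0.9).all()
    assert (draws.max(axis=0) > 0.9).all()


def test_sampling_prefix_stability():
    """Extending the batch never perturbs earlier coefficient rows."""
    small = sample_selection_coefficients(np.random.default_rng(3), size=100)
    large = sample_selection_coefficients(np.random.default_rng(3), size=500)
    assert np.array_equal(small, large[:100])


@pytest.mark.parametrize("scheme", SCHEMES)
def test_neutral_fitness_array_is_all_ones(scheme, space):
    arr = build_fitness_array(SelectionCoefficients.neutral(), scheme, space)
    assert np.array_equal(arr.w_f, np.ones(10))
    assert np.array_equal(arr.w_m, np.ones(8))


def test_multiplicative_example(space):
    """m4 = X/Y^M; III/III^M; IV/IV under additive effects: 0.8 * 0.9 * 1."""
    coeffs = SelectionCoefficients(female=(0, 0, 0), male=(0.4, -0.2, 0.0))
    arr = build_fitness_array(coeffs, "additive", space)
    m4 = space.index["m4"] - 10
    assert arr.w_m[m4] == pytest.approx(0.8 * 0.9)
    # f1 carries no derived chromosome: always fitness 1
    assert arr.w_f[0] == 1.0


@pytest.mark.parametrize("scheme", SCHEMES)
def test_f1_always_neutral_and_male_ivf_never_consulted(scheme, space):
    rng = np.random.default_rng(11)
    base = sample_selection_coefficients(rng)
    arr = base.as_array()
    perturbed = arr.copy()
    perturbed[1, 2] = -perturbed[1, 2] if perturbed[1, 2] else 0.77
    a = build_fitness_array(SelectionCoefficients.from_array(arr), scheme, space)
    b = build_fitness_array(SelectionCoefficients.from_array(perturbed), scheme, space)
    assert a.w_f[0] == 1.0
    assert np.array_equal(a.w_f, b.w_f)
    assert np.array_equal(a.w_m, b.w_m)


@pytest.mark.parametrize("scheme", SCHEMES)
def test_batch_builder_matches_scalar_exactly(scheme, space):
    """Vectorised arrays equal per-genotype scalar recomputation bitwise."""
    coeffs = sample_selection_coefficients(np.random.default_rng(5), size=50)
    w_f, w_m = build_fitness_arrays(coeffs, scheme, space)
    assert w_f.shape == (50, 10) and w_m.shape == (50, 8)
    assert np.isfinite(w_f).all() and (w_f >= 0).all()
    for i in range(50):
        scalar = build_fitness_array(
            SelectionCoefficients.from_array(coeffs[i]), scheme, space
        )
        assert np.array_equal(w_f[i], scalar.w_f)
        assert np.array_equal(w_m[i], scalar.w_m)


def test_fitness_array_validation():
    with pytest.raises(ValueError):
        FitnessArray(np.ones(9), np.ones(8))
    with pytest.raises(ValueError):
        FitnessArray(-np.ones(10), np.ones(8))
    with pytest.raises(ValueError):
        SelectionCoefficients(female=(0, 0, 1.5), male=(0, 0, 0))
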