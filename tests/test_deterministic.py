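"""Two-sex recursion: oracle equivalence, fixed points, classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flypsd import (
    ExtinctionError,
    FitnessArray,
    PopulationState,
    SelectionCoefficients,
    build_fitness_array,
    chromosome_frequencies,
    monogenic_zw_start,
    equal_start,
    next_generation,
    run_deterministic,
)
from flypsd.deterministic import FIXED, LOST, POLYMORPHIC, classify
from tests.conftest import random_state_and_fitness


def test_engine_matches_mating_table_oracle(engine, oracle):
    """Vectorised update equals the explicit 80-cross recursion to 1e-12."""
    rng = np.random.default_rng(123)
    for _ in range(100):
        freqs, w_f, w_m = random_state_and_fitness(rng)
        expected = oracle.step(freqs, w_f, w_m)
        got, ext = engine.step_batch(freqs[None], w_f[None], w_m[None])
        assert not ext[0]
        np.testing.assert_allclose(got[0], expected, atol=1e-12, rtol=0)


def test_engine_matches_oracle_over_generations(engine, oracle):
    """Agreement persists along 50-generation trajectories."""
    rng = np.random.default_rng(99)
    for _ in range(5):
        freqs, w_f, w_m = random_state_and_fitness(rng)
        cur_o = freqs.copy()
        cur_e = freqs[None].copy()
        for _ in range(50):
            cur_o = oracle.step(cur_o, w_f, w_m)
            cur_e, _ = engine.step_batch(cur_e, w_f[None], w_m[None])
        np.testing.assert_allclose(cur_e[0], cur_o, atol=1e-12, rtol=0)


def test_monogenic_zw_fixed_point(engine):
    """{f10: 1/2, m8: 1/2} is exactly invariant under neutral fitness."""
    state = monogenic_zw_start()
    fit = FitnessArray.neutral()
    nxt = engine.next_generation(state, fit)
    assert np.array_equal(nxt.freqs, state.freqs)
    res = engine.run(state, fit, 500)
    assert res.final_frequencies == {"YM": 1.0, "IIIM": 1.0, "IVF": 0.25}
    assert res.outcomes == {"YM": "fixed", "IIIM": "fixed", "IVF": "polymorphic"}
    assert not res.psd_maintained


@pytest.mark.parametrize(
    "freq_dict,expected",
    [
        ({"f10": 0.5, "m8": 0.5}, (1.0, 1.0, 0.25)),
        ({"f1": 0.5, "m3": 0.5}, (0.25, 0.0, 0.0)),
    ],
)
def test_chromosome_frequency_examples(engine, freq_dict, expected):
    state = PopulationState.from_dict(freq_dict, engine.space)
    cf = engine.chromosome_frequencies(state.freqs)
    np.testing.assert_array_equal(cf, expected)


def test_chromosome_frequency_uniform_state(engine):
    """Equal genotype frequencies put IV^F at 9/36 of fourth chromosomes (f1 carries none)."""
    cf = engine.chromosome_frequencies(equal_start().freqs)
    assert cf[2] == pytest.approx(9 / 36)


def test_neutral_run_maintains_from_equal_start(engine):
    res = engine.run(equal_start(), FitnessArray.neutral(), 1000)
    assert res.psd_maintained
    assert all(0.001 < f < 0.999 for f in res.final_frequencies.values())


def test_lethal_ivf_females_lose_ivf(engine, space):
    """Zero fitness for all IV^F-carrying females drives IV^F out."""
    coeffs = SelectionCoefficients(female=(0, 0, 1.0), male=(0, 0, 0))
    fit = build_fitness_array(coeffs, "additive", space)
    assert fit.w_f[1:].max() == 0.0  # every IV^F carrier female is lethal
    res = engine.run(equal_start(), fit, 1000)
    assert res.outcomes["IVF"] == "lost"
    assert res.final_state.female_share > 0  # population persists via f1


def test_extinction_when_one_sex_absent(engine):
    state = PopulationState.from_dict({"f1": 1.0}, engine.space)
    with pytest.raises(ExtinctionError):
        engine.next_generation(state, FitnessArray.neutral())


def test_module_level_wrappers(engine):
    state = monogenic_zw_start()
    nxt = next_generation(state, FitnessArray.neutral())
    assert np.array_equal(nxt.freqs, state.freqs)
    cf = chromosome_frequencies(state)
    assert cf == {"YM": 1.0, "IIIM": 1.0, "IVF": 0.25}
    res = run_deterministic(state, FitnessArray.neutral(), 10)
    assert res.generations_run == 10


@given(st.integers(0, 2**32 - 1))
def test_frequency_conservation(engine, seed):
    """States stay nonnegative and sum to 1 within 1e-12 along trajectories."""
    rng = np.random.default_rng(seed)
    freqs, w_f, w_m = random_state_and_fitness(rng)
    cur = freqs[None]
    for _ in range(20):
        cur, ext = engine.step_batch(cur, w_f[None], w_m[None])
        assert not ext[0]
        assert (cur >= 0).all()
        assert abs(cur.sum() - 1.0) < 1e-12


def test_batch_equals_one_at_a_time(engine):
    """Batch rows are bitwise identical to single-row processing."""
    rng = np.random.default_rng(17)
    states, wfs, wms = [], [], []
    for _ in range(20):
        f, wf, wm = random_state_and_fitness(rng)
        states.append(f)
        wfs.append(wf)
        wms.append(wm)
    states, wfs, wms = map(np.array, (states, wfs, wms))
    batch = engine.run_batch(states, wfs, wms, 30)
    for i in range(20):
        single = engine.run_batch(states[i], wfs[i][None], wms[i][None], 30)
        assert np.array_equal(batch.final_freqs[i], single.final_freqs[0])
        assert np.array_equal(batch.chromosome_freqs[i], single.chromosome_freqs[0])


def test_early_exit_preserves_classification(engine):
    """Classifications agree with early exit on and off."""
    rng = np.random.default_rng(31)
    from flypsd import build_fitness_arrays, sample_selection_coefficients

    coeffs = sample_selection_coefficients(rng, size=20)
    w_f, w_m = build_fitness_arrays(coeffs, "dominant", engine.space)
    start = equal_start().freqs
    fast = engine.run_batch(start, w_f, w_m, 20_000, early_exit=True)
    slow = engine.run_batch(start, w_f, w_m, 20_000, early_exit=False)
    assert np.array_equal(fast.outcomes, slow.outcomes)
    assert np.array_equal(fast.psd_maintained, slow.psd_maintained)
    assert (fast.generations_run <= slow.generations_run).all()
    np.testing.assert_allclose(
        fast.chromosome_freqs, slow.chromosome_freqs, atol=1e-9, rtol=0
    )


def test_classification_thresholds():
    assert classify(0.0005) == LOST
    assert classify(0.001) == POLYMORPHIC  # open interval boundary
    assert classify(0.5) == POLYMORPHIC
    assert classify(0.999) == POLYMORPHIC
    assert classify(0.9995) == FIXED
    # monotone in frequency
    grid = np.linspace(0, 1, 101)
    codes = [classify(f) for f in grid]
    assert codes == sorted(codes)


def test_population_state_validation():
    with pytest.raises(ValueError):
        PopulationState(np.full(18, 0.1))  # sums to 1.8
    with pytest.raises(ValueError):
        PopulationState(np.concatenate([[-0.1, 1.1], np.zeros(16)]))
    st_ok = PopulationState(np.full(18, 1 / 18))
    assert st_ok.female_share == pytest.approx(10 / 18)
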