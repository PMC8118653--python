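"""Expansion-index pipeline: calibration, main-peak calling, EI arithmetic."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cagmosaic.expansion_index import (
    CalibrationError,
    EIConfig,
    ExpandedAlleleProfile,
    NoExpandedAlleleError,
    calibrate_repeats,
    compute_expansion_index,
    ei_from_trace,
    identify_main_peak,
    mutant_allele_distribution,
)
from cagmosaic.synthetic_data import SimulatedTrace, TraceSimParams, expected_ei, simulate_trace
from cagmosaic.trace_io import FragmentTrace, Peak


def _trace(*peaks):
    return FragmentTrace("t", peaks=list(peaks))


def _cag_trace(height_by_cag: dict[int, float]) -> FragmentTrace:
    return _trace(
        *(Peak(size_bp=87.0 + 3.0 * cag, height=h, repeat_length=cag) for cag, h in height_by_cag.items())
    )


# --------------------------------------------------------------------------
# calibration


def test_anchor_calibration_snaps_to_nearest_rung():
    trace = _trace(Peak(210.0, 5000.0), Peak(213.1, 2000.0))
    out = calibrate_repeats(trace, anchor_cag=42, anchor_size_bp=210.0)
    assert [p.repeat_length for p in out.peaks] == [42, 43]
    assert not any(p.off_ladder for p in out.peaks)


def test_peak_beyond_tolerance_is_flagged_off_ladder():
    trace = _trace(Peak(210.0, 5000.0), Peak(211.4, 900.0))
    out = calibrate_repeats(trace, anchor_cag=42, anchor_size_bp=210.0)
    assert out.peaks[1].off_ladder  # 1.4 bp from the nearest rung, tolerance 1.0
    assert not out.peaks[0].off_ladder


def test_called_alleles_pass_through_without_anchor():
    trace = _cag_trace({42: 5000.0, 43: 100.0})
    assert calibrate_repeats(trace) is trace
    with pytest.raises(CalibrationError):
        calibrate_repeats(_trace(Peak(210.0, 1.0)))
    with pytest.raises(CalibrationError):
        calibrate_repeats(_trace(Peak(210.0, 1.0)), anchor_cag=42)  # size missing


@given(st.integers(0, 2**31 - 1))
def test_jittered_ladder_recovers_generator_truth(seed):
    params = TraceSimParams(size_jitter_sd=0.3, max_offset=5)
    sim = simulate_trace(params, seed=seed)
    out = calibrate_repeats(sim.trace, anchor_cag=params.cag_ref, anchor_size_bp=params.main_size_bp)
    for peak, truth in zip(out.peaks, sim.true_repeats):
        assert peak.repeat_length == truth and not peak.off_ladder


# --------------------------------------------------------------------------
# main-peak identification


def test_normal_allele_excluded_by_repeat_cutoff():
    profile = identify_main_peak(_cag_trace({17: 9000.0, 42: 5000.0, 43: 2000.0}))
    assert profile.cag_main == 42
    assert profile.right_ratios == {1: pytest.approx(0.4)}


def test_left_peaks_are_stutter_and_discarded():
    profile = identify_main_peak(_cag_trace({42: 5000.0, 41: 4000.0}))
    assert profile.cag_main == 42 and profile.right_ratios == {}


def test_equal_height_tie_breaks_toward_larger_repeat():
    profile = identify_main_peak(_cag_trace({42: 5000.0, 44: 5000.0}))
    assert profile.cag_main == 44


def test_no_expanded_allele_raises():
    with pytest.raises(NoExpandedAlleleError):
        identify_main_peak(_cag_trace({17: 9000.0, 20: 500.0}))


def test_off_ladder_peaks_do_not_enter_profile():
    trace = _trace(
        Peak(213.0, 5000.0, repeat_length=42),
        Peak(216.0, 1000.0, repeat_length=43),
        Peak(217.5, 9999.0, repeat_length=43, off_ladder=True),
    )
    profile = identify_main_peak(trace)
    assert profile.right_ratios == {1: pytest.approx(0.2)}


# --------------------------------------------------------------------------
# EI arithmetic


@pytest.mark.parametrize(
    "ratios, expected_value, expected_offsets",
    [
        ({}, 0.0, ()),
        ({1: 0.40, 2: 0.10, 3: 0.02}, 0.60, (1, 2)),
        ({1: 0.03}, 0.03, (1,)),  # boundary ratio retained: only peaks *below* 3% drop
        ({2: 0.25}, 0.50, (2,)),
    ],
)
def test_expansion_index_hand_computed_cases(ratios, expected_value, expected_offsets):
    profile = ExpandedAlleleProfile(cag_main=42, main_height=5000.0, right_ratios=ratios)
    res = compute_expansion_index(profile)
    assert res.ei == pytest.approx(expected_value, abs=1e-12)
    assert res.retained_offsets == expected_offsets
    assert (res.ei == 0) == (len(res.retained_offsets) == 0)


ratios_st = st.dictionaries(st.integers(1, 12), st.floats(0.0, 0.9, allow_nan=False), max_size=8)


@given(ratios_st)
def test_ei_matches_direct_recomputation_and_is_nonnegative(ratios):
    profile = ExpandedAlleleProfile(cag_main=40, main_height=100.0, right_ratios=ratios)
    res = compute_expansion_index(profile, threshold=0.03)
    direct = sum(r * i for i, r in ratios.items() if r >= 0.03)
    assert res.ei == pytest.approx(direct, abs=1e-12)
    assert res.ei >= 0


@given(ratios_st, st.floats(0.1, 50.0, allow_nan=False))
def test_ei_invariant_under_uniform_height_scaling(ratios, scale):
    base = _cag_trace({42: 5000.0, **{42 + i: 5000.0 * r for i, r in ratios.items() if r > 0}})
    scaled = _trace(*(Peak(p.size_bp, p.height * scale, repeat_length=p.repeat_length) for p in base.peaks))
    ei_a = compute_expansion_index(identify_main_peak(base)).ei
    ei_b = compute_expansion_index(identify_main_peak(scaled)).ei
    assert ei_b == pytest.approx(ei_a, rel=1e-12, abs=1e-12)


@given(ratios_st, st.integers(1, 12), st.floats(0.0001, 0.0299))
def test_sub_threshold_right_peak_never_changes_ei(ratios, offset, tiny_ratio):
    profile = ExpandedAlleleProfile(40, 100.0, ratios)
    with_tiny = dict(ratios)
    if with_tiny.get(offset, 1.0) < 0.03:  # only inject where it stays sub-threshold
        with_tiny[offset] = tiny_ratio
        augmented = ExpandedAlleleProfile(40, 100.0, with_tiny)
        assert compute_expansion_index(augmented).ei == pytest.approx(
            compute_expansion_index(profile).ei, abs=1e-12
        )


def test_ei_nondecreasing_in_retained_peak_height():
    lo = ExpandedAlleleProfile(40, 100.0, {1: 0.10, 2: 0.05})
    hi = ExpandedAlleleProfile(40, 100.0, {1: 0.10, 2: 0.25})
    assert compute_expansion_index(hi).ei > compute_expansion_index(lo).ei


# --------------------------------------------------------------------------
# mutant-allele distribution


def test_mutant_distribution_single_peak_and_symmetry():
    assert mutant_allele_distribution(ExpandedAlleleProfile(40, 50.0, {})) == {0: 100.0}
    halves = mutant_allele_distribution(ExpandedAlleleProfile(40, 50.0, {1: 1.0}))
    assert halves == {0: pytest.approx(50.0), 1: pytest.approx(50.0)}


@given(ratios_st)
def test_mutant_distribution_sums_to_100(ratios):
    profile = ExpandedAlleleProfile(40, 321.0, ratios)
    dist = mutant_allele_distribution(profile)
    assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)
    assert all(v >= 0 for v in dist.values())
    assert 0 in dist


# --------------------------------------------------------------------------
# full pipeline vs generator ground truth


def _pipeline_ei(sim: SimulatedTrace) -> float:
    return ei_from_trace(
        sim.trace,
        EIConfig(),
        anchor_cag=sim.params.cag_ref,
        anchor_size_bp=sim.params.main_size_bp,
    ).ei


def test_pipeline_matches_closed_form_on_clean_trace():
    params = TraceSimParams(expansion_scale=0.5, expansion_decay=0.5, max_offset=3)
    sim = simulate_trace(params, seed=0)
    assert sim.expected_ei == pytest.approx(1.375, abs=1e-12)  # 0.5*1 + 0.25*2 + 0.125*3
    assert _pipeline_ei(sim) == pytest.approx(sim.expected_ei, abs=1e-9)


def test_target_ei_half_reproduced_exactly():
    params = TraceSimParams(expansion_scale=0.5, expansion_decay=0.5, max_offset=1)
    sim = simulate_trace(params, seed=0)
    assert _pipeline_ei(sim) == pytest.approx(0.5, abs=1e-9)


@given(
    st.floats(0.05, 0.95),
    st.floats(0.1, 0.9),
    st.integers(1, 10),
    st.integers(0, 2**31 - 1),
)
def test_pipeline_equals_closed_form_with_jitter_noise_and_stutter(scale, decay, max_offset, seed):
    params = TraceSimParams(
        expansion_scale=scale,
        expansion_decay=decay,
        max_offset=max_offset,
        size_jitter_sd=0.3,
        noise_peak_rate=2.0,
    )
    sim = simulate_trace(params, seed=seed)
    assert _pipeline_ei(sim) == pytest.approx(sim.expected_ei, abs=1e-6)


def test_sub_threshold_tail_and_stutter_do_not_alter_pipeline_ei():
    base = TraceSimParams(expansion_scale=0.4, expansion_decay=0.5, max_offset=4)
    with_tail = TraceSimParams(expansion_scale=0.4, expansion_decay=0.5, max_offset=12)
    no_stutter = TraceSimParams(
        expansion_scale=0.4, expansion_decay=0.5, max_offset=4, stutter_ratios=()
    )
    eis = {_pipeline_ei(simulate_trace(p, seed=5)) for p in (base, with_tail, no_stutter)}
    assert len(eis) == 1  # tail below 3% and left-side stutter are both ignored
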