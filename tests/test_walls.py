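import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellfiler import (
    DetectorParams,
    IntensityProfile,
    Polyline,
    add_manual_walls,
    detect_wall_candidates,
    detect_walls,
    fit_spline,
    segment_cells,
)
from cellfiler.walls import Wall, WallSet

from oracles import naive_candidates, naive_walls


def _profile(values, step_um=1.0, pixel_size_um=1.0):
    v = np.asarray(values, dtype=float)
    return IntensityProfile(
        s_um=np.arange(len(v)) * step_um, intensity=v, pixel_size_um=pixel_size_um
    )


def test_constant_profile_yields_no_walls():
    """A flat profile has no peaks: v >= v * stringency fails for stringency > 1."""
    prof = _profile(np.full(100, 10.0))
    ws = detect_walls(prof, DetectorParams(window=9, stringency=1.1, min_intensity=0.0))
    assert len(ws) == 0


def test_isolated_spike_is_one_wall():
    v = np.zeros(101)
    v[50] = 100.0
    ws = detect_walls(_profile(v), DetectorParams(window=9, stringency=2.0, min_intensity=10.0))
    assert len(ws) == 1
    assert ws.walls[0].sample_index == pytest.approx(50.0)


def test_min_intensity_floor_guards_low_signal():
    """In all-zero stretches i_min = 0 makes the stringency condition
    vacuous, so flat dark regions produce spurious walls; the absolute
    floor is the guard that removes them."""
    v = np.zeros(101)
    v[50] = 100.0
    params_low = DetectorParams(window=9, stringency=2.0, min_intensity=0.0)
    params_floor = DetectorParams(window=9, stringency=2.0, min_intensity=10.0)
    assert len(detect_walls(_profile(v), params_low)) > 1  # false positives
    ws = detect_walls(_profile(v), params_floor)
    assert len(ws) == 1 and ws.walls[0].sample_index == 50.0


@pytest.mark.parametrize("stringency", [1.1, 1.5, 2.0])
@pytest.mark.parametrize("seed", range(10))
def test_candidates_match_naive_transcription(seed, stringency):
    rng = np.random.default_rng(seed)
    v = rng.uniform(0.0, 1.0, size=1000)
    params = DetectorParams(window=9, stringency=stringency, min_intensity=0.2)
    got = detect_wall_candidates(v, params)
    expected = naive_candidates(v, 9, stringency, 0.2)
    np.testing.assert_array_equal(got, expected)


@pytest.mark.parametrize("seed", range(10))
def test_merged_walls_match_naive_pipeline(seed):
    rng = np.random.default_rng(100 + seed)
    v = rng.uniform(0.0, 1.0, size=1000)
    params = DetectorParams(window=9, stringency=1.5, min_intensity=0.2)
    ws = detect_walls(_profile(v), params)
    expected = naive_walls(v, 9, 1.5, 0.2)
    np.testing.assert_allclose([w.sample_index for w in ws.walls], expected, atol=1e-9)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    values=st.lists(
        st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
        min_size=10, max_size=60,
    ),
    stringency=st.floats(min_value=1.0, max_value=3.0, allow_nan=False),
)
def test_candidates_equal_naive_for_arbitrary_profiles(values, stringency):
    """The vectorized candidate rule agrees with the literal per-sample loop
    on arbitrary non-negative profiles, including plateaus and zeros."""
    v = np.asarray(values)
    params = DetectorParams(window=5, stringency=stringency, min_intensity=1.0)
    np.testing.assert_array_equal(
        detect_wall_candidates(v, params),
        naive_candidates(v, 5, stringency, 1.0),
    )


def test_plateau_merges_to_weighted_centroid():
    v = np.zeros(101)
    v[50] = v[51] = 100.0  # flat-topped ridge
    ws = detect_walls(_profile(v), DetectorParams(window=9, stringency=2.0, min_intensity=1.0))
    assert len(ws) == 1
    assert ws.walls[0].sample_index == pytest.approx(50.5)


@pytest.mark.parametrize("scale", [0.25, 3.0, 1000.0])
def test_intensity_scale_invariance(scale):
    """The rule uses only ratios and ordering, so scaling intensities and the
    floor together must not change the wall set."""
    rng = np.random.default_rng(7)
    v = rng.uniform(0.0, 1.0, size=800)
    base = detect_walls(_profile(v), DetectorParams(9, 1.5, 0.2))
    scaled = detect_walls(_profile(v * scale), DetectorParams(9, 1.5, 0.2 * scale))
    np.testing.assert_allclose(
        [w.sample_index for w in scaled.walls],
        [w.sample_index for w in base.walls],
        atol=1e-9,
    )


@pytest.mark.parametrize("seed", range(5))
def test_stringency_monotonicity(seed):
    """Raising stringency can only shrink the candidate set, and never adds a
    wall on the random suite."""
    rng = np.random.default_rng(200 + seed)
    v = rng.uniform(0.0, 1.0, size=800)
    prev_cand = None
    prev_nwalls = None
    for stringency in (1.0, 1.2, 1.5, 2.0, 3.0):
        cand = detect_wall_candidates(v, DetectorParams(9, stringency, 0.1))
        nwalls = len(detect_walls(_profile(v), DetectorParams(9, stringency, 0.1)))
        if prev_cand is not None:
            assert not np.any(cand & ~prev_cand), "candidate set must shrink"
            assert nwalls <= prev_nwalls
        prev_cand, prev_nwalls = cand, nwalls


def test_profile_must_exceed_window():
    with pytest.raises(ValueError):
        detect_walls(_profile(np.zeros(9)), DetectorParams(window=9))


def test_detector_params_validation():
    for bad in (dict(window=2), dict(window=8), dict(stringency=0.5), dict(min_intensity=-1)):
        with pytest.raises(ValueError):
            DetectorParams(**bad)


def _wallset(positions_um, step_um=1.0):
    walls = tuple(Wall(sample_index=p / step_um, s_um=p) for p in positions_um)
    return WallSet(walls=walls, pixel_size_um=1.0, step_um=step_um)


def test_add_manual_walls_sorted_insert():
    ws = add_manual_walls(_wallset([5.0, 20.0]), [12.5])
    assert [w.s_um for w in ws.walls] == [5.0, 12.5, 20.0]
    assert [w.source for w in ws.walls] == ["auto", "manual", "auto"]


def test_add_manual_wall_before_first_becomes_wall_one():
    ws = add_manual_walls(_wallset([5.0, 20.0]), [1.0])
    assert ws.walls[0].s_um == 1.0
    assert ws.walls[0].source == "manual"


def test_add_manual_duplicate_rejected_with_warning(caplog):
    with caplog.at_level(logging.WARNING, logger="cellfiler"):
        ws = add_manual_walls(_wallset([5.0, 20.0]), [5.3])
    assert len(ws) == 2
    assert any("duplicates" in r.message for r in caplog.records)


def test_add_manual_wall_outside_profile_errors():
    poly = Polyline(anchors=[[0, 0], [30, 0]])
    path = fit_spline(poly, step_px=1.0)
    with pytest.raises(ValueError, match="outside"):
        add_manual_walls(_wallset([5.0, 20.0]), [45.0], path=path)


def test_segment_cells_lengths():
    cf = segment_cells(_wallset([0.0, 10.0, 25.0]), include_start_as_wall=True)
    np.testing.assert_allclose(cf.lengths_um, [10.0, 15.0])
    np.testing.assert_allclose(cf.starts_um, [0.0, 10.0])


def test_segment_single_wall_with_start_boundary():
    cf = segment_cells(_wallset([10.0]), include_start_as_wall=True)
    np.testing.assert_allclose(cf.lengths_um, [10.0])


def test_segment_requires_two_boundaries():
    with pytest.raises(ValueError):
        segment_cells(_wallset([10.0]), include_start_as_wall=False)


@pytest.mark.parametrize("seed", range(5))
def test_length_conservation(seed):
    """Sum of cell lengths equals the arc span between first and last boundary."""
    rng = np.random.default_rng(300 + seed)
    pos = np.sort(rng.uniform(1.0, 100.0, size=8))
    cf = segment_cells(_wallset(list(pos)), include_start_as_wall=True)
    assert cf.lengths_um.sum() == pytest.approx(pos[-1])
    cf2 = segment_cells(_wallset(list(pos)), include_start_as_wall=False)
    assert cf2.lengths_um.sum() == pytest.approx(pos[-1] - pos[0])
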