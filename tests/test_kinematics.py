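"""Feature extraction and interaction annotation from two-fly pose."""

import numpy as np
import pandas as pd
import pytest

from songrules.kinematics import (
    FEATURE_NAMES,
    FeedbackFeatures,
    InteractionMask,
    PosePair,
    assign_roles,
    compute_features,
    detect_head_transitions,
    polar_occupancy,
    quadrant_probability,
    song_enrichment_before_transitions,
    wing_extensions,
)
from songrules.synthetic import _skeleton


def make_pose(pos_c, heading_c, pos_p, heading_p, frame_rate=100.0, fly_length=2.5):
    """PosePair from scripted thorax paths and headings (radians)."""
    T = len(pos_c)
    wings = np.zeros((T, 2))
    xy = np.stack([
        _skeleton(np.asarray(pos_c, float), np.asarray(heading_c, float), fly_length, wings),
        _skeleton(np.asarray(pos_p, float), np.asarray(heading_p, float), fly_length, wings),
    ])
    return PosePair(xy=xy, frame_rate=frame_rate,
                    fly_length=np.array([fly_length, fly_length]))


def features_df(T=100, **overrides):
    base = {
        "cFV": 0.0, "pFV": 0.0, "cLS": 0.0, "pLS": 0.0, "cRS": 0.0, "pRS": 0.0,
        "dis": 20.0, "ctheta": 90.0, "ptheta": 90.0, "phi": 90.0,
    }
    base.update(overrides)
    cols = {k: np.full(T, v, dtype=float) if np.isscalar(v) else np.asarray(v, float)
            for k, v in base.items()}
    return FeedbackFeatures(data=pd.DataFrame(cols), frame_rate=30.0,
                            fly_length=np.array([2.5, 2.5]))


# -- compute_features --------------------------------------------------------


def test_stationary_pair_zero_speeds():
    T = 200
    pose = make_pose(np.zeros((T, 2)), np.zeros(T),
                     np.tile([5.0, 0.0], (T, 1)), np.zeros(T))
    f = compute_features(pose, target_rate=30.0)
    arr = f.data
    # tolerance covers polyphase-resampler ripple, far below behavioral scale
    for col in ("cFV", "pFV", "cLS", "pLS", "cRS", "pRS"):
        np.testing.assert_allclose(arr[col], 0.0, atol=0.01)
    np.testing.assert_allclose(arr["dis"], 5.0, atol=1e-3)


def test_translation_along_heading_is_pure_forward_velocity():
    T, rate, v = 300, 100.0, 10.0
    t = np.arange(T) / rate
    pos_c = np.stack([v * t, np.zeros(T)], axis=1)
    pose = make_pose(pos_c, np.zeros(T), np.tile([0.0, 6.0], (T, 1)), np.zeros(T))
    f = compute_features(pose, target_rate=30.0)
    mid = slice(10, -10)  # away from resampling edge effects
    np.testing.assert_allclose(f.data["cFV"][mid], v, rtol=5e-3)
    np.testing.assert_allclose(f.data["cLS"][mid], 0.0, atol=0.01)


def test_circular_track_rotational_speed_matches_finite_difference_oracle():
    # heading rotating at a constant 90 deg/s on a circular trajectory
    T, rate, omega = 600, 100.0, 90.0
    t = np.arange(T) / rate
    theta = np.radians(omega) * t
    radius = 4.0
    pos = radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    heading = theta + np.pi / 2  # tangent
    pose = make_pose(pos, heading, np.tile([20.0, 20.0], (T, 1)), np.zeros(T))
    f = compute_features(pose, target_rate=30.0)
    mid = slice(20, -20)
    # finite-difference oracle on the analytic heading at 30 Hz
    t30 = np.arange(len(f)) / 30.0
    oracle = np.abs(np.gradient(np.degrees(np.radians(omega) * t30), 1 / 30.0))
    np.testing.assert_allclose(f.data["cRS"][mid], oracle[mid], rtol=0.02)
    # tangential speed = r * omega
    np.testing.assert_allclose(
        f.data["cFV"][mid], radius * np.radians(omega), rtol=0.02
    )


def test_relative_angles_follow_geometry():
    # courter 3 mm behind the partner, both heading +x: courter sees the
    # partner dead ahead (ptheta=0) and sits at the partner's tail
    # (ctheta=180); phi = 0
    T = 120
    pose = make_pose(np.tile([0.0, 0.0], (T, 1)), np.zeros(T),
                     np.tile([3.0, 0.0], (T, 1)), np.zeros(T))
    f = compute_features(pose, target_rate=30.0)
    mid = slice(5, -5)
    np.testing.assert_allclose(f.data["ptheta"][mid], 0.0, atol=0.5)
    np.testing.assert_allclose(f.data["ctheta"][mid], 180.0, atol=0.5)
    np.testing.assert_allclose(f.data["phi"][mid], 0.0, atol=0.5)
    np.testing.assert_allclose(f.data["dis"][mid], 3.0, atol=0.01)


def test_compute_features_too_short_track_errors():
    pose = make_pose(np.zeros((1, 2)), np.zeros(1), np.ones((1, 2)), np.zeros(1))
    with pytest.raises(ValueError, match="two frames"):
        compute_features(pose)


def test_missing_keypoints_beyond_budget_error():
    T = 200
    pose = make_pose(np.zeros((T, 2)), np.zeros(T),
                     np.tile([5.0, 0.0], (T, 1)), np.zeros(T))
    pose.xy[0, 50:90, 2, :] = np.nan  # 0.4 s gap at 100 Hz
    with pytest.raises(ValueError, match="gaps"):
        compute_features(pose)


def test_short_gap_interpolated():
    T = 200
    pose = make_pose(np.zeros((T, 2)), np.zeros(T),
                     np.tile([5.0, 0.0], (T, 1)), np.zeros(T))
    pose.xy[0, 50:60, 2, :] = np.nan  # 0.1 s gap, inside the budget
    f = compute_features(pose, target_rate=30.0)
    assert np.isfinite(f.array()).all()


def test_assign_roles_invariant_to_global_rotation():
    rng = np.random.default_rng(0)
    T = 150
    pos_c = np.cumsum(rng.normal(0, 0.05, (T, 2)), axis=0)
    pos_p = pos_c + np.array([3.0, 1.0]) + np.cumsum(rng.normal(0, 0.02, (T, 2)), axis=0)
    h_c = np.cumsum(rng.normal(0, 0.02, T))
    h_p = h_c + 0.3
    ang = 1.1
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    shift = np.array([17.0, -4.0])
    m1 = assign_roles(compute_features(make_pose(pos_c, h_c, pos_p, h_p)))
    m2 = assign_roles(compute_features(
        make_pose(pos_c @ R.T + shift, h_c + ang, pos_p @ R.T + shift, h_p + ang)
    ))
    np.testing.assert_array_equal(m1.interacting, m2.interacting)
    np.testing.assert_array_equal(m1.courter_id, m2.courter_id)
    np.testing.assert_array_equal(m1.head_quadrant, m2.head_quadrant)


# -- assign_roles ------------------------------------------------------------


def test_close_facing_pair_interacts():
    f = features_df(dis=5.0, ptheta=30.0, ctheta=120.0)
    mask = assign_roles(f)
    assert mask.interacting.all()
    assert (mask.courter_id == 0).all()


def test_distant_pair_does_not_interact():
    mask = assign_roles(features_df(dis=20.0, ptheta=0.0))
    assert not mask.interacting.any()
    assert (mask.courter_id == -1).all()


def test_mutual_facing_retains_previous_courter():
    # fly 0 courts alone first (partner looks away), then both face each
    # other; the established courter keeps the role
    T = 60
    ctheta = np.concatenate([np.full(30, 170.0), np.full(30, 20.0)])
    f = features_df(T=T, dis=5.0, ptheta=10.0, ctheta=ctheta)
    mask = assign_roles(f)
    assert (mask.courter_id == 0).all()


def test_quadrant_split_at_90_degrees():
    f = features_df(dis=5.0, ptheta=10.0,
                    ctheta=np.concatenate([np.full(50, 45.0), np.full(50, 135.0)]))
    mask = assign_roles(f)
    assert mask.head_quadrant[:50].all() and not mask.head_quadrant[50:].any()
    assert mask.tail_quadrant[50:].all() and not mask.tail_quadrant[:50].any()
    assert not (mask.head_quadrant & mask.tail_quadrant).any()


# -- quadrant_probability ----------------------------------------------------


def test_single_quadrant_fraction_one():
    mask = assign_roles(features_df(dis=5.0, ptheta=10.0, ctheta=45.0))
    q = quadrant_probability(mask)
    assert q["head"] == 1.0
    assert q["tail"] == 0.0


def test_short_bout_excluded_and_gap_merged():
    """Frame-counting oracle on a toy sequence at 30 Hz:
    a 0.4 s head bout inside a tail epoch is dropped; two head bouts
    separated by 0.3 s merge (the gap frames count as head)."""
    rate = 30
    # 3 s tail, 0.4 s head, 3 s tail  -> head fraction 0
    ctheta = np.concatenate([
        np.full(3 * rate, 135.0), np.full(int(0.4 * rate), 45.0), np.full(3 * rate, 135.0),
    ])
    mask = assign_roles(features_df(T=len(ctheta), dis=5.0, ptheta=10.0, ctheta=ctheta))
    q = quadrant_probability(mask, min_bout_s=0.5)
    assert q["head"] == 0.0
    # 1 s head, 0.3 s tail, 1 s head: gap merges into one head bout
    ctheta = np.concatenate([
        np.full(rate, 45.0), np.full(int(0.3 * rate), 135.0), np.full(rate, 45.0),
    ])
    T = len(ctheta)
    mask = assign_roles(features_df(T=T, dis=5.0, ptheta=10.0, ctheta=ctheta))
    q = quadrant_probability(mask, min_bout_s=0.5)
    assert q["head"] == pytest.approx(1.0)  # merged gap counts as head


def test_no_interaction_flags_nan():
    mask = assign_roles(features_df(dis=20.0))
    with pytest.warns(UserWarning, match="no interacting"):
        q = quadrant_probability(mask)
    assert np.isnan(q["head"])


def test_head_plus_tail_partition_interaction():
    # alternating 1 s epochs: all bouts survive smoothing, no gaps to merge,
    # so the smoothed quadrant fractions partition the interaction exactly
    rate = 30
    ctheta = np.concatenate([
        np.full(rate, 45.0) if i % 2 == 0 else np.full(rate, 135.0) for i in range(10)
    ])
    f = features_df(T=len(ctheta), dis=5.0, ptheta=10.0, ctheta=ctheta)
    q = quadrant_probability(assign_roles(f), min_bout_s=0.5)
    assert q["head"] + q["tail"] == pytest.approx(1.0)
    assert q["head"] == pytest.approx(0.5)


# -- polar occupancy ---------------------------------------------------------


def test_polar_point_mass():
    f = features_df(dis=2.5, ctheta=2.0)  # 1 fly length, near head
    h = polar_occupancy(f)
    assert h.density.sum() == pytest.approx(1.0)
    assert (h.density > 0).sum() == 1


def test_polar_excludes_beyond_three_fly_lengths():
    f = features_df(dis=10.0)  # 4 fly lengths
    h = polar_occupancy(f)
    assert h.density.sum() == 0.0


def test_polar_uniform_angle_near_uniform_marginal():
    rng = np.random.default_rng(2)
    T = 20000
    f = features_df(T=T, dis=2.5, ctheta=rng.uniform(0, 180, T))
    h = polar_occupancy(f)
    marginal = h.density.sum(axis=0)
    np.testing.assert_allclose(marginal, 1 / 36, atol=0.01)


# -- transitions -------------------------------------------------------------


def make_mask(quadrants, rate=30):
    """InteractionMask from a list of (duration_s, 'head'|'tail'|None)."""
    head, tail = [], []
    for dur, q in quadrants:
        n = int(round(dur * rate))
        head += [q == "head"] * n
        tail += [q == "tail"] * n
    head, tail = np.array(head), np.array(tail)
    inter = head | tail
    return InteractionMask(interacting=inter, courter_id=np.where(inter, 0, -1),
                           head_quadrant=head, tail_quadrant=tail, frame_rate=rate)


def test_transition_requires_two_seconds_each():
    assert len(detect_head_transitions(None, make_mask([(3, "tail"), (3, "head")]))) == 1
    assert len(detect_head_transitions(None, make_mask([(1, "tail"), (3, "head")]))) == 0
    assert len(detect_head_transitions(None, make_mask(
        [(3, "tail"), (1.5, "head"), (3, "tail")]))) == 0


def test_transition_time_is_first_head_frame():
    ev = detect_head_transitions(None, make_mask([(3, "tail"), (3, "head")]))
    assert ev[0] == pytest.approx(3.0, abs=1 / 30)


def test_transition_count_invariant_to_frame_rate_doubling():
    seq = [(3, "tail"), (3, "head"), (1, None), (2.5, "tail"), (2.2, "head")]
    n30 = len(detect_head_transitions(None, make_mask(seq, rate=30)))
    n60 = len(detect_head_transitions(None, make_mask(seq, rate=60)))
    assert n30 == n60 == 2


# -- wing extensions ---------------------------------------------------------


def make_winged_pose(angles_deg):
    """One fly with scripted wing angles; partner far away."""
    T = len(angles_deg)
    wings = np.asarray(angles_deg, float)
    pos = np.zeros((T, 2))
    xy = np.stack([
        _skeleton(pos, np.zeros(T), 2.5, wings),
        _skeleton(np.tile([30.0, 0.0], (T, 1)), np.zeros(T), 2.5, np.zeros((T, 2))),
    ])
    return PosePair(xy=xy, frame_rate=30.0, fly_length=np.array([2.5, 2.5]))


def test_bilateral_extension_above_30_degrees():
    pose = make_winged_pose(np.tile([40.0, 40.0], (50, 1)))
    res = wing_extensions(pose)
    assert res["bwe"].all()


def test_folded_wings_no_extension():
    pose = make_winged_pose(np.zeros((50, 2)))
    res = wing_extensions(pose)
    assert not res["bwe"].any() and not res["uwe"].any()


def test_uwe_threshold_recovered_by_sweep():
    # synthetic labels generated with a known 25-degree cut: the
    # exhaustive threshold sweep must recover it
    rng = np.random.default_rng(3)
    T = 400
    left = rng.uniform(0, 60, T)
    angles = np.stack([left, np.zeros(T)], axis=1)
    pose = make_winged_pose(angles)
    ref = left > 25.0
    res = wing_extensions(pose, reference_uwe_labels=ref)
    assert abs(res["uwe_threshold_deg"] - 25.0) <= 1.0


def test_uwe_reference_length_mismatch_errors():
    pose = make_winged_pose(np.zeros((50, 2)))
    with pytest.raises(ValueError, match="length"):
        wing_extensions(pose, reference_uwe_labels=np.zeros(10, bool))


# -- song enrichment ---------------------------------------------------------


def test_enrichment_constant_song_equal_probabilities():
    rate = 30.0
    T = int(600 * rate)
    res = song_enrichment_before_transitions(
        song_mask=np.ones(T, bool), transitions_s=np.array([300.0]),
        interaction_mask=np.ones(T, bool), frame_rate=rate, rng=0,
    )
    assert res["pre_mean"] == pytest.approx(res["control_mean"]) == 1.0


def test_enrichment_song_only_before_transitions():
    rate = 30.0
    T = int(900 * rate)
    song = np.zeros(T, bool)
    transitions = np.array([300.0, 600.0])
    for t in transitions:
        song[int((t - 10) * rate): int(t * rate)] = True
    res = song_enrichment_before_transitions(
        song_mask=song, transitions_s=transitions,
        interaction_mask=np.ones(T, bool), frame_rate=rate, rng=0,
    )
    assert res["pre_mean"] > res["control_mean"]
    assert res["pre_mean"] == pytest.approx(1.0)


def test_enrichment_drops_low_interaction_windows():
    rate = 30.0
    T = int(600 * rate)
    inter = np.zeros(T, bool)
    inter[::10] = True  # 10% interaction everywhere
    res = song_enrichment_before_transitions(
        song_mask=np.ones(T, bool), transitions_s=np.array([300.0]),
        interaction_mask=inter, frame_rate=rate, rng=0,
    )
    assert len(res["pre_transition"]) == 0 and len(res["control"]) == 0
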