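"""Kinematic feedback features and interaction annotations from two-fly pose.

Six tracked body parts per fly (head, neck, thorax, abdomen, left and right
wingtip) are reduced to ten per-frame metrics describing each fly's
locomotion and the pair's relative geometry.  These metrics are the feedback
cues for the song-patterning model and the raw material for the social maps:

========  =====================================================  ========
name      meaning                                                units
========  =====================================================  ========
cFV, pFV  forward velocity along the body axis (signed)          mm/s
cLS, pLS  lateral speed, magnitude of the perpendicular          mm/s
          velocity component
cRS, pRS  rotational speed, magnitude of the heading rate        deg/s
dis       thorax-to-thorax distance                              mm
ctheta    courter's angular position in the partner's frame      deg
          (0 = at the partner's head, 180 = at its tail)
ptheta    partner's angular position in the courter's frame      deg
phi       absolute difference of the two body angles             deg
========  =====================================================  ========

``c`` prefixes the courter (the fly doing the singing), ``p`` the partner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

BODY_PARTS = ("head", "neck", "thorax", "abdomen", "left_wingtip", "right_wingtip")
FEATURE_NAMES = ("cFV", "pFV", "cLS", "pLS", "cRS", "pRS", "dis", "ctheta", "ptheta", "phi")

HEAD, NECK, THORAX, ABDOMEN, LEFT_WING, RIGHT_WING = range(6)

# interaction rule constants
INTERACTION_DISTANCE_MM = 8.0
FIELD_OF_VIEW_DEG = 60.0
HEAD_QUADRANT_DEG = 90.0


@dataclass
class PosePair:
    """Planar keypoint tracks for a pair of flies.

    Attributes
    ----------
    xy : (2, T, 6, 2) array
        Coordinates in mm, indexed (fly, frame, body part, x/y).  Body
        parts are ordered as in :data:`BODY_PARTS`.  Missing detections
        are NaN.
    frame_rate : float
        Acquisition rate in Hz.
    fly_length : (2,) array
        Head-abdomen reference length per fly, mm.
    """

    xy: np.ndarray
    frame_rate: float
    fly_length: np.ndarray = field(default=None)
    time: np.ndarray = field(default=None)

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 4 or self.xy.shape[0] != 2 or self.xy.shape[2:] != (6, 2):
            raise ValueError("xy must have shape (2, T, 6, 2)")
        if self.time is None:
            self.time = np.arange(self.n_frames) / self.frame_rate
        if self.fly_length is None:
            d = np.linalg.norm(
                self.xy[:, :, HEAD] - self.xy[:, :, ABDOMEN], axis=-1
            )
            self.fly_length = np.nanmedian(d, axis=1)
        self.fly_length = np.asarray(self.fly_length, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.xy.shape[1]


@dataclass
class FeedbackFeatures:
    """The ten feedback-cue time series at a fixed frame rate."""

    data: pd.DataFrame  # columns FEATURE_NAMES, one row per frame
    frame_rate: float
    courter_id: int = 0
    fly_length: np.ndarray = None  # (2,) mm, courter first

    def __post_init__(self):
        missing = set(FEATURE_NAMES) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing feature columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    def array(self) -> np.ndarray:
        """Features as a (T, 10) array in canonical column order."""
        return self.data.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)

    def swapped_roles(self) -> "FeedbackFeatures":
        """The same pair with courter and partner exchanged."""
        df = self.data.copy()
        for c, p in (("cFV", "pFV"), ("cLS", "pLS"), ("cRS", "pRS"), ("ctheta", "ptheta")):
            df[c], df[p] = self.data[p], self.data[c]
        return replace(
            self,
            data=df,
            courter_id=1 - self.courter_id,
            fly_length=None if self.fly_length is None else self.fly_length[::-1],
        )


@dataclass
class InteractionMask:
    """Per-frame interaction state at the feature frame rate."""

    interacting: np.ndarray      # bool (T,)
    courter_id: np.ndarray       # int (T,), -1 when not interacting
    head_quadrant: np.ndarray    # bool (T,)
    tail_quadrant: np.ndarray    # bool (T,)
    frame_rate: float


@dataclass
class PolarHistogram:
    """Density of the courter's position around the partner."""

    density: np.ndarray          # (n_radial, n_angular)
    radial_edges: np.ndarray     # in partner fly lengths
    angular_edges: np.ndarray    # degrees, 0 = head


# ---------------------------------------------------------------------------
# geometry helpers


def _interpolate_gaps(xy: np.ndarray, frame_rate: float, max_gap_s: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate NaN runs up to ``max_gap_s``; flag longer runs.

    Returns the filled array and a (T,) validity mask (False where a gap
    exceeded the interpolation budget).
    """
    out = xy.copy()
    T = xy.shape[1]
    valid = np.ones(T, dtype=bool)
    max_gap = max(1, int(round(max_gap_s * frame_rate)))
    t = np.arange(T)
    for fly in range(2):
        for part in range(xy.shape[2]):
            for dim in range(2):
                col = out[fly, :, part, dim]
                bad = ~np.isfinite(col)
                if not bad.any():
                    continue
                if bad.all():
                    raise ValueError(f"keypoint {BODY_PARTS[part]} of fly {fly} entirely missing")
                col[bad] = np.interp(t[bad], t[~bad], col[~bad])
                out[fly, :, part, dim] = col
                # flag runs longer than the budget
                edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.astype(int), [0]))))
                for start, stop in zip(edges[::2], edges[1::2]):
                    if stop - start > max_gap:
                        valid[start:stop] = False
    return out, valid


def _resample(x: np.ndarray, src_rate: float, dst_rate: float) -> np.ndarray:
    """Anti-aliased rate conversion along axis 0 (polyphase when rational)."""
    if src_rate == dst_rate:
        return x
    from fractions import Fraction

    frac = Fraction(dst_rate / src_rate).limit_denominator(1000)
    # line padding keeps constant/linear tracks transient-free at the edges
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=0, padtype="line")


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    return 180.0 - np.mod(180.0 - a, 360.0)


def compute_features(
    pose: PosePair,
    target_rate: float = 30.0,
    courter_id: int = 0,
    max_gap_s: float = 0.2,
) -> FeedbackFeatures:
    """Transform a two-fly pose track into the ten feedback features.

    Positions are low-pass resampled from the acquisition rate to
    ``target_rate`` before differentiation; headings are unwrapped before
    the rotational-speed derivative so that 360-degree jumps do not inflate
    it.  Missing keypoints are linearly interpolated up to ``max_gap_s``;
    longer gaps raise.

    Raises
    ------
    ValueError
        If the track has fewer than two frames or a keypoint gap exceeds
        the interpolation budget.
    """
    if pose.n_frames < 2:
        raise ValueError("need at least two frames to differentiate")
    xy, valid = _interpolate_gaps(pose.xy, pose.frame_rate, max_gap_s)
    if not valid.all():
        raise ValueError(
            f"{(~valid).sum()} frames have keypoint gaps longer than {max_gap_s} s"
        )

    partner_id = 1 - courter_id
    dt = 1.0 / target_rate

    # per-fly quantities, computed at the target rate
    thorax = _resample(np.swapaxes(pose_xy_part(xy, THORAX), 0, 1), pose.frame_rate, target_rate)
    axis_vec_raw = pose_xy_part(xy, HEAD) - pose_xy_part(xy, ABDOMEN)  # (2, T, 2)
    heading_raw = np.unwrap(np.arctan2(axis_vec_raw[..., 1], axis_vec_raw[..., 0]), axis=1)
    heading = _resample(np.swapaxes(heading_raw, 0, 1), pose.frame_rate, target_rate)  # (T', 2)

    vel = np.gradient(thorax, dt, axis=0)  # (T', 2 flies, 2)
    u = np.stack([np.cos(heading), np.sin(heading)], axis=-1)       # body axis
    n = np.stack([-np.sin(heading), np.cos(heading)], axis=-1)      # left normal
    fv = np.einsum("tfd,tfd->tf", vel, u)
    ls = np.abs(np.einsum("tfd,tfd->tf", vel, n))
    rs = np.abs(np.degrees(np.gradient(heading, dt, axis=0)))

    sep = thorax[:, partner_id] - thorax[:, courter_id]  # courter -> partner
    dis = np.linalg.norm(sep, axis=-1)
    line_angle = np.degrees(np.arctan2(sep[:, 1], sep[:, 0]))
    heading_deg = np.degrees(heading)
    # partner's position in the courter's frame
    ptheta = np.abs(_wrap_deg(line_angle - heading_deg[:, courter_id]))
    # courter's position in the partner's frame (line points partner->courter)
    ctheta = np.abs(_wrap_deg((line_angle + 180.0) - heading_deg[:, partner_id]))
    phi = np.abs(_wrap_deg(heading_deg[:, courter_id] - heading_deg[:, partner_id]))

    df = pd.DataFrame(
        {
            "cFV": fv[:, courter_id],
            "pFV": fv[:, partner_id],
            "cLS": ls[:, courter_id],
            "pLS": ls[:, partner_id],
            "cRS": rs[:, courter_id],
            "pRS": rs[:, partner_id],
            "dis": dis,
            "ctheta": ctheta,
            "ptheta": ptheta,
            "phi": phi,
        }
    )
    lengths = np.array([pose.fly_length[courter_id], pose.fly_length[partner_id]])
    return FeedbackFeatures(data=df, frame_rate=target_rate, courter_id=courter_id, fly_length=lengths)


def pose_xy_part(xy: np.ndarray, part: int) -> np.ndarray:
    return xy[:, :, part, :]


# ---------------------------------------------------------------------------
# interaction / role assignment


def assign_roles(
    features: FeedbackFeatures,
    distance_mm: float = INTERACTION_DISTANCE_MM,
    fov_deg: float = FIELD_OF_VIEW_DEG,
) -> InteractionMask:
    """Mark interacting frames and assign the courter role.

    A frame is interacting when the flies are closer than ``distance_mm``
    and at least one fly holds the other within ``fov_deg`` of its heading.
    When both flies face each other, the previously assigned courter keeps
    the role; at the very first mutual-facing frame the fly seeing the
    partner more centrally is chosen (ties go to fly 0).  The head quadrant
    covers courter positions ``ctheta`` in [0, 90), the tail quadrant
    [90, 180].
    """
    arr = features.data
    if not np.isfinite(arr[["dis", "ctheta", "ptheta"]].to_numpy()).all():
        raise ValueError("features contain non-finite values")

    dis = arr["dis"].to_numpy()
    # view angle of fly (features.courter_id) onto the other fly:
    view_c = arr["ptheta"].to_numpy()
    # view angle of the other fly onto fly courter_id:
    view_p = arr["ctheta"].to_numpy()
    c_id, p_id = features.courter_id, 1 - features.courter_id

    close = dis < distance_mm
    c_ok = close & (view_c < fov_deg)
    p_ok = close & (view_p < fov_deg)

    T = len(arr)
    interacting = c_ok | p_ok
    courter = np.full(T, -1, dtype=int)
    prev = -1
    for t in range(T):
        if not interacting[t]:
            continue  # courter identity persists across gaps
        if c_ok[t] and p_ok[t]:
            if prev >= 0:
                courter[t] = prev
            else:
                courter[t] = c_id if view_c[t] <= view_p[t] else p_id
        elif c_ok[t]:
            courter[t] = c_id
        else:
            courter[t] = p_id
        prev = courter[t]

    # quadrant of the courter in the partner's frame
    ctheta = arr["ctheta"].to_numpy()
    ptheta = arr["ptheta"].to_numpy()
    pos_angle = np.where(courter == c_id, ctheta, ptheta)
    head = interacting & (pos_angle < HEAD_QUADRANT_DEG)
    tail = interacting & ~head
    return InteractionMask(
        interacting=interacting,
        courter_id=courter,
        head_quadrant=head,
        tail_quadrant=tail,
        frame_rate=features.frame_rate,
    )


def _bouts(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def _smooth_bouts(mask: np.ndarray, min_frames: int) -> np.ndarray:
    """Merge same-state bouts separated by < min_frames, then drop bouts
    shorter than min_frames."""
    out = mask.copy()
    runs = _bouts(out)
    # merge across short gaps
    for (s0, e0), (s1, e1) in zip(runs[:-1], runs[1:]):
        if s1 - e0 < min_frames:
            out[e0:s1] = True
    # drop short bouts
    for s, e in _bouts(out):
        if e - s < min_frames:
            out[s:e] = False
    return out


def quadrant_probability(
    mask: InteractionMask, min_bout_s: float = 0.5
) -> dict[str, float]:
    """P(head|interaction) and P(tail|interaction) after bout smoothing.

    Quadrant bouts shorter than ``min_bout_s`` are dropped and same-quadrant
    bouts separated by less than ``min_bout_s`` are merged before counting;
    probabilities are quadrant frames over interacting frames.  With zero
    interacting frames both probabilities are NaN (flagged, not 0/0).
    """
    n_int = int(mask.interacting.sum())
    if n_int == 0:
        warnings.warn("no interacting frames; quadrant probabilities undefined")
        return {"head": np.nan, "tail": np.nan, "n_interacting": 0}
    min_frames = max(1, int(round(min_bout_s * mask.frame_rate)))
    head = _smooth_bouts(mask.head_quadrant, min_frames)
    tail = _smooth_bouts(mask.tail_quadrant, min_frames)
    return {
        "head": head.sum() / n_int,
        "tail": tail.sum() / n_int,
        "n_interacting": n_int,
    }


def polar_occupancy(
    features: FeedbackFeatures,
    mask: InteractionMask | None = None,
    n_radial: int = 15,
    max_fly_lengths: float = 3.0,
    angular_bin_deg: float = 5.0,
) -> PolarHistogram:
    """Histogram of the courter's position around the partner.

    Distance is expressed in partner fly lengths and limited to
    ``max_fly_lengths`` (frames farther out are excluded); |ctheta| is
    binned in ``angular_bin_deg`` bins over [0, 180].  The histogram is
    normalized to a density over its occupied support.
    """
    if features.fly_length is None:
        raise ValueError("fly_length required to express distance in fly lengths")
    partner_len = features.fly_length[1]
    r = features.data["dis"].to_numpy() / partner_len
    a = np.abs(features.data["ctheta"].to_numpy())
    keep = r <= max_fly_lengths
    if mask is not None:
        keep &= mask.interacting
    r_edges = np.linspace(0, max_fly_lengths, n_radial + 1)
    a_edges = np.arange(0.0, 180.0 + angular_bin_deg, angular_bin_deg)
    counts, _, _ = np.histogram2d(r[keep], a[keep], bins=[r_edges, a_edges])
    total = counts.sum()
    density = counts / total if total > 0 else counts
    return PolarHistogram(density=density, radial_edges=r_edges, angular_edges=a_edges)


def detect_head_transitions(
    features: FeedbackFeatures,
    mask: InteractionMask,
    min_epoch_s: float = 2.0,
) -> np.ndarray:
    """Times (s) of tail-to-head transitions.

    An event requires a tail-quadrant interaction epoch of at least
    ``min_epoch_s`` immediately followed by a head-quadrant epoch of at
    least ``min_epoch_s``; the event time is the first head frame.
    """
    min_frames = int(round(min_epoch_s * mask.frame_rate))
    tail_runs = _bouts(mask.tail_quadrant)
    head_runs = {s: e for s, e in _bouts(mask.head_quadrant)}
    events = []
    for s, e in tail_runs:
        if e - s < min_frames:
            continue
        if e in head_runs and head_runs[e] - e >= min_frames:
            events.append(e / mask.frame_rate)
    return np.asarray(events)


# ---------------------------------------------------------------------------
# wing extensions


def wing_angles(pose: PosePair) -> np.ndarray:
    """Per-frame wing angles (deg), shape (2 flies, T, 2 wings).

    The wing angle is measured between the thorax->head line and the
    thorax->wingtip line, folded so that a wing lying along the body axis
    (pointing backwards) scores 0 and a perpendicular wing scores 90.
    """
    xy, _ = _interpolate_gaps(pose.xy, pose.frame_rate)
    head = xy[:, :, HEAD]
    thorax = xy[:, :, THORAX]
    fwd = head - thorax
    out = np.empty((2, pose.n_frames, 2))
    for w, part in enumerate((LEFT_WING, RIGHT_WING)):
        wing = xy[:, :, part] - thorax
        cosang = np.einsum("ftd,ftd->ft", fwd, wing) / (
            np.linalg.norm(fwd, axis=-1) * np.linalg.norm(wing, axis=-1) + 1e-12
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        out[:, :, w] = 180.0 - ang
    return out


def wing_extensions(
    pose: PosePair,
    reference_uwe_labels: np.ndarray | None = None,
    bwe_threshold_deg: float = 30.0,
    default_uwe_threshold_deg: float = 30.0,
    fly: int = 0,
) -> dict:
    """Unilateral and bilateral wing-extension masks for one fly.

    Bilateral extension requires both wing angles above
    ``bwe_threshold_deg``.  The unilateral threshold is chosen per trial as
    the angle maximizing frame agreement with ``reference_uwe_labels`` when
    provided (exhaustive 1-degree sweep), otherwise the configured default.
    """
    ang = wing_angles(pose)[fly]  # (T, 2)
    if reference_uwe_labels is not None:
        ref = np.asarray(reference_uwe_labels, dtype=bool)
        if len(ref) != pose.n_frames:
            raise ValueError("reference labels length does not match pose frames")
        candidates = np.arange(1.0, 91.0)
        agreement = [
            ((ang.max(axis=1) > th) == ref).sum() for th in candidates
        ]
        uwe_threshold = float(candidates[int(np.argmax(agreement))])
    else:
        uwe_threshold = float(default_uwe_threshold_deg)

    any_ext = ang.max(axis=1) > uwe_threshold
    bwe = (ang > bwe_threshold_deg).all(axis=1)
    uwe = any_ext & ~bwe
    return {"uwe": uwe, "bwe": bwe, "uwe_threshold_deg": uwe_threshold}


# ---------------------------------------------------------------------------
# song enrichment before tail-to-head transitions


def song_enrichment_before_transitions(
    song_mask: np.ndarray,
    transitions_s: np.ndarray,
    interaction_mask: np.ndarray,
    frame_rate: float,
    window_s: float = 10.0,
    n_control: int = 100,
    min_interaction: float = 0.25,
    control_exclusion_s: float = 60.0,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Song probability in windows ending at transitions vs matched controls.

    For each transition the window covers the ``window_s`` seconds before
    it.  Control windows are ``n_control`` random windows whose endpoints
    lie at least ``control_exclusion_s`` from every transition.  Windows
    (of either kind) whose interaction ratio is below ``min_interaction``
    are discarded.
    """
    rng = np.random.default_rng(rng)
    song = np.asarray(song_mask, dtype=bool)
    inter = np.asarray(interaction_mask, dtype=bool)
    T = len(song)
    w = int(round(window_s * frame_rate))

    def window_prob(end_frame: int) -> float | None:
        s = end_frame - w
        if s < 0:
            return None
        if inter[s:end_frame].mean() < min_interaction:
            return None
        return song[s:end_frame].mean()

    pre = [p for t in transitions_s if (p := window_prob(int(round(t * frame_rate)))) is not None]

    excl = int(round(control_exclusion_s * frame_rate))
    trans_frames = np.round(np.asarray(transitions_s) * frame_rate).astype(int)
    eligible = np.ones(T, dtype=bool)
    eligible[:w] = False
    for tf in trans_frames:
        eligible[max(0, tf - excl): tf + excl] = False
    idx = np.flatnonzero(eligible)
    control: list[float] = []
    if idx.size == 0:
        warnings.warn("no eligible control windows")
    else:
        ends = rng.choice(idx, size=min(n_control, idx.size), replace=idx.size < n_control)
        control = [p for e in ends if (p := window_prob(int(e))) is not None]

    return {
        "pre_transition": np.asarray(pre),
        "control": np.asarray(control),
        "pre_mean": float(np.mean(pre)) if pre else np.nan,
        "control_mean": float(np.mean(control)) if control else np.nan,
    }
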