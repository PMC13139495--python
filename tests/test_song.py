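"""Pulse/sine signal metrics, bout structure, and pulse-type clustering."""

import numpy as np
import pandas as pd
import pytest

from songrules.song import (
    AUDIO_RATE,
    PulseWaveform,
    attribute_mutual_song,
    bout_statistics,
    cluster_pulse_types,
    extract_pulse_waveforms,
    frame_labels_from_intervals,
    interpulse_intervals,
    pulse_metrics,
    sine_carrier,
    snippet_length,
)


def make_pulse(carrier_hz=250.0, width_ms=4.0, rate=AUDIO_RATE, amplitude=1.0):
    """Gaussian-enveloped carrier snippet of the standard 35 ms length."""
    n = snippet_length(rate)
    t = (np.arange(n) - n // 2) / rate
    sigma = width_ms / 1000.0 / (2 * np.sqrt(2 * np.log(2)))
    env = np.exp(-0.5 * (t / sigma) ** 2)
    return PulseWaveform(samples=amplitude * env * np.sin(2 * np.pi * carrier_hz * t))


# -- pulse metrics -----------------------------------------------------------


def test_carrier_frequency_recovered_within_fft_bin():
    # spectral argmax oracle: 250 Hz carrier, FFT bin width ~28.5 Hz
    m = pulse_metrics([make_pulse(carrier_hz=250.0)])
    bin_hz = AUDIO_RATE / snippet_length(AUDIO_RATE)
    assert abs(m["carrier_hz"][0] - 250.0) <= bin_hz


def test_width_is_amplitude_invariant():
    m1 = pulse_metrics([make_pulse(amplitude=1.0)])
    m2 = pulse_metrics([make_pulse(amplitude=37.5)])
    assert m1["width_ms"][0] == pytest.approx(m2["width_ms"][0], abs=1e-9)


def test_width_matches_analytic_convolution_oracle():
    """A Gaussian envelope (FWHM w) smoothed by a Gaussian of sd s stays
    Gaussian with FWHM' = sqrt(w^2 + (2.355 s)^2); the measured half-peak
    duration must match within discretization and carrier leakage."""
    width, smooth_sd = 6.0, 1.5  # ms; wide pulse keeps several carrier cycles
    m = pulse_metrics([make_pulse(carrier_hz=500.0, width_ms=width)])
    k = 2 * np.sqrt(2 * np.log(2))
    expected = np.hypot(width, k * smooth_sd)
    assert m["width_ms"][0] == pytest.approx(expected, abs=0.7)


def test_multi_peak_flagged():
    n = snippet_length(AUDIO_RATE)
    t = (np.arange(n) - n // 2) / AUDIO_RATE
    sigma = 2.0 / 1000
    env = np.exp(-0.5 * ((t - 0.008) / sigma) ** 2) + np.exp(-0.5 * ((t + 0.008) / sigma) ** 2)
    w = PulseWaveform(samples=env * np.sin(2 * np.pi * 300 * t))
    m = pulse_metrics([w])
    assert m["multi_peak"][0]
    assert np.isnan(m["width_ms"][0])


def test_near_flat_envelope_flagged_noisy():
    # a continuous tone spans the whole snippet: its envelope is flat, so
    # max-mean of the normalized envelope falls below the 0.08 threshold
    n = snippet_length(AUDIO_RATE)
    t = np.arange(n) / AUDIO_RATE
    w = PulseWaveform(samples=np.sin(2 * np.pi * 300.0 * t))
    m = pulse_metrics([w])
    assert m["noisy"][0]
    assert np.isnan(m["width_ms"][0])


def test_wrong_snippet_length_errors():
    with pytest.raises(ValueError, match="35 ms"):
        pulse_metrics([PulseWaveform(samples=np.zeros(100))])


def test_extract_waveforms_fixed_length_and_edge_skipping():
    audio = np.zeros(AUDIO_RATE)  # 1 s
    wfs = extract_pulse_waveforms(audio, np.array([0.005, 0.5, 0.999]))
    assert len(wfs) == 1  # both edge pulses dropped
    assert len(wfs[0].samples) == snippet_length(AUDIO_RATE)


# -- IPIs --------------------------------------------------------------------


def test_regular_train_ipis():
    centers = np.arange(0, 1.0, 0.036)
    ipis = interpulse_intervals(centers)
    np.testing.assert_allclose(ipis, 36.0)


def test_long_gaps_excluded():
    assert len(interpulse_intervals(np.array([0.0, 0.15]))) == 0


def test_single_pulse_empty():
    assert len(interpulse_intervals(np.array([0.5]))) == 0


def test_ipi_translation_invariance():
    c = np.array([0.1, 0.14, 0.18, 0.35])
    np.testing.assert_allclose(
        interpulse_intervals(c), interpulse_intervals(c + 123.4)
    )


# -- sine carrier ------------------------------------------------------------


def test_pure_tone_carrier():
    t = np.arange(2 * AUDIO_RATE) / AUDIO_RATE
    audio = np.sin(2 * np.pi * 150.0 * t)
    f = sine_carrier(audio, [(0.2, 1.8)])
    assert abs(f - 150.0) <= AUDIO_RATE / 256  # one segment-FFT bin


def test_modal_frequency_across_segments():
    # 150 Hz for most of the bout, 250 Hz for a short stretch -> mode 150
    t = np.arange(2 * AUDIO_RATE) / AUDIO_RATE
    audio = np.sin(2 * np.pi * 150.0 * t)
    sl = slice(int(1.7 * AUDIO_RATE), int(1.9 * AUDIO_RATE))
    audio[sl] = np.sin(2 * np.pi * 250.0 * t[sl])
    f = sine_carrier(audio, [(0.0, 2.0)])
    assert abs(f - 150.0) <= AUDIO_RATE / 256


def test_empty_intervals_none():
    assert sine_carrier(np.zeros(1000), []) is None


def test_short_interval_skipped_with_warning():
    with pytest.warns(UserWarning, match="shorter"):
        assert sine_carrier(np.zeros(AUDIO_RATE), [(0.0, 0.01)]) is None


# -- bouts -------------------------------------------------------------------


def labels_from(spec, rate=30):
    """Labels from (duration_s, label) pairs."""
    out = []
    for dur, lab in spec:
        out += [lab] * int(round(dur * rate))
    return np.array(out, dtype=object)


def test_pulse_only_bout_order_one():
    labels = labels_from([(1, "silence"), (2, "pulse"), (1, "silence")])
    res = bout_statistics(labels, window_s=2.0)
    assert len(res["bouts"]) == 1
    assert res["bouts"]["bout_order"][0] == 1


def test_single_transition_bout_order_two():
    # pulse then sine with a 50 ms gap: one bout, order two
    labels = labels_from([(1, "silence"), (1, "pulse"), (0.05, "silence"),
                          (1, "sine"), (1, "silence")])
    res = bout_statistics(labels, window_s=2.0)
    assert len(res["bouts"]) == 1
    assert res["bouts"]["bout_order"][0] == 2


def test_gap_over_100ms_splits_bouts():
    labels = labels_from([(1, "pulse"), (0.15, "silence"), (1, "pulse")])
    res = bout_statistics(labels, window_s=1.0)
    assert len(res["bouts"]) == 2
    assert (res["bouts"]["bout_order"] == 1).all()


def test_windowed_amount_onset_duration_identity():
    rng = np.random.default_rng(4)
    spec = []
    for _ in range(40):
        spec.append((rng.uniform(0.2, 2.0), rng.choice(["pulse", "sine", "silence"])))
    labels = labels_from(spec)
    res = bout_statistics(labels, window_s=10.0)
    for mode in ("pulse", "sine", "song"):
        w = res["windowed"][mode]
        assert 0.0 <= w["amount"] <= 1.0


def test_window_longer_than_trial_warns():
    labels = labels_from([(1, "pulse")])
    with pytest.warns(UserWarning, match="window longer"):
        bout_statistics(labels, window_s=60.0)


def test_bout_partition_covers_every_song_frame():
    rng = np.random.default_rng(5)
    spec = [(rng.uniform(0.05, 1.0), rng.choice(["pulse", "sine", "silence"]))
            for _ in range(60)]
    labels = labels_from(spec)
    res = bout_statistics(labels, window_s=10.0)
    rate = 30
    covered = np.zeros(len(labels), bool)
    for _, b in res["bouts"].iterrows():
        s, e = int(round(b["onset_s"] * rate)), int(round(b["offset_s"] * rate))
        assert not covered[s:e].any(), "bouts must not overlap"
        covered[s:e] = True
    song = np.isin(labels, ("pulse", "sine"))
    assert covered[song].all(), "every song frame belongs to exactly one bout"


# -- clustering --------------------------------------------------------------


def _waveform_family(rng, n, width_ms, carrier_hz):
    out = []
    for _ in range(n):
        w = make_pulse(carrier_hz=carrier_hz + rng.normal(0, 5),
                       width_ms=width_ms + rng.normal(0, 0.2))
        w.samples = w.samples + rng.normal(0, 0.02, len(w.samples))
        out.append(w)
    return out


def test_two_waveform_families_recovered():
    rng = np.random.default_rng(6)
    fast = _waveform_family(rng, 60, width_ms=3.0, carrier_hz=400.0)
    slow = _waveform_family(rng, 60, width_ms=9.0, carrier_hz=180.0)
    truth = np.array([0] * 60 + [1] * 60)
    labels = cluster_pulse_types(fast + slow, seed=0)
    acc = max((labels == truth).mean(), (labels == 1 - truth).mean())
    assert acc >= 0.99
    # fast label (0) must be the shorter-envelope family
    assert (labels[:60] == 0).mean() > 0.5


def test_identical_waveforms_single_type_fallback():
    wfs = [make_pulse() for _ in range(30)]
    with pytest.warns(UserWarning, match="single pulse type"):
        labels = cluster_pulse_types(wfs, seed=0)
    assert (labels == 0).all()


def test_too_few_waveforms_errors():
    with pytest.raises(ValueError, match="at least"):
        cluster_pulse_types([make_pulse()], seed=0)


# -- mutual song attribution -------------------------------------------------


def test_conflicting_overlap_takes_pre_onset_type():
    c = labels_from([(1, "sine"), (0.5, "pulse"), (1, "silence")])
    p = labels_from([(1, "silence"), (0.5, "sine"), (1, "silence")])
    resolved = attribute_mutual_song(c, p)
    rate = 30
    assert (resolved[int(1 * rate):int(1.5 * rate)] == "sine").all()


def test_no_overlap_unchanged():
    c = labels_from([(1, "pulse"), (1, "silence")])
    p = labels_from([(1, "silence"), (1, "sine")])
    np.testing.assert_array_equal(attribute_mutual_song(c, p), c)


def test_identical_overlap_unchanged():
    c = labels_from([(2, "sine")])
    p = labels_from([(2, "sine")])
    np.testing.assert_array_equal(attribute_mutual_song(c, p), c)


def test_frame_labels_from_intervals_roundtrip():
    iv = pd.DataFrame({
        "onset_s": [0.5, 2.0], "offset_s": [1.5, 3.0], "label": ["pulse", "sine"],
    })
    labels = frame_labels_from_intervals(iv, duration_s=4.0, frame_rate=30.0)
    assert len(labels) == 120
    assert (labels[15:45] == "pulse").all()
    assert (labels[60:90] == "sine").all()
    assert (labels[:15] == "silence").all()
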