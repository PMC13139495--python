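"""Signal- and pattern-level statistics of courtship song.

Pulse song is a train of brief carrier-modulated impulses, sine song a
sustained oscillation near 150 Hz.  This module measures per-pulse carrier
frequency and width, inter-pulse intervals, sine carrier frequency, bout
structure (runs of song separated by <100 ms of silence), and clusters
pulse waveforms into the fast and slow pulse types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

AUDIO_RATE = 10_000
SNIPPET_MS = 35.0
LABELS = ("pulse", "sine", "silence", "agonistic")


@dataclass
class PulseWaveform:
    """A 35 ms audio snippet centered on one pulse at 10 kHz."""

    samples: np.ndarray
    center_s: float = np.nan
    noisy: bool = False
    multi_peak: bool = False


def snippet_length(rate: int = AUDIO_RATE) -> int:
    return int(round(SNIPPET_MS / 1000.0 * rate)) + 1


def extract_pulse_waveforms(
    audio: np.ndarray, centers_s: np.ndarray, rate: int = AUDIO_RATE
) -> list[PulseWaveform]:
    """Cut fixed-length snippets around each pulse center (edge pulses skipped)."""
    half = snippet_length(rate) // 2
    out = []
    for c in np.asarray(centers_s, float):
        i = int(round(c * rate))
        if i - half < 0 or i + half + 1 > len(audio):
            continue
        out.append(PulseWaveform(samples=audio[i - half: i + half + 1].copy(), center_s=c))
    return out


# ---------------------------------------------------------------------------
# per-pulse metrics


def _normalized_envelope(x: np.ndarray, rate: int, gaussian_ms: float = 1.5) -> np.ndarray:
    """Hilbert envelope, Gaussian-smoothed (sd = gaussian_ms), unit peak."""
    env = np.abs(hilbert(x))
    sigma = gaussian_ms / 1000.0 * rate
    half = int(np.ceil(4 * sigma))
    tt = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (tt / sigma) ** 2)
    kern /= kern.sum()
    sm = np.convolve(env, kern, mode="same")
    peak = sm.max()
    return sm / peak if peak > 0 else sm


def _above_half_regions(env: np.ndarray) -> list[tuple[int, int]]:
    above = env > 0.5
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def pulse_metrics(
    waveforms: list[PulseWaveform],
    rate: int = AUDIO_RATE,
    freq_cutoff_hz: float = 1000.0,
    noise_threshold: float = 0.08,
    gaussian_ms: float = 1.5,
) -> pd.DataFrame:
    """Carrier frequency, width and rejection flags for each pulse.

    Carrier frequency is the dominant spectral frequency below the cutoff.
    Width is the time the smoothed, unit-peak Hilbert envelope stays above
    half its peak.  A pulse is flagged ``noisy`` when max-mean of the
    normalized envelope falls below ``noise_threshold`` (near-flat
    envelope) and ``multi_peak`` when more than one contiguous region
    exceeds the half-peak level; flagged pulses get NaN width so they drop
    out of width summaries.

    Raises on snippets that are not 35 ms long.
    """
    n_expect = snippet_length(rate)
    rows = []
    for w in waveforms:
        x = np.asarray(w.samples, float)
        if len(x) != n_expect:
            raise ValueError(f"snippet length {len(x)} != {n_expect} samples (35 ms)")
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(len(x), 1.0 / rate)
        keep = (freqs > 0) & (freqs <= freq_cutoff_hz)
        carrier = float(freqs[keep][np.argmax(spec[keep])])

        env = _normalized_envelope(x, rate, gaussian_ms)
        noisy = (env.max() - env.mean()) < noise_threshold
        regions = _above_half_regions(env)
        multi = len(regions) > 1
        if noisy or multi:
            width = np.nan
        else:
            width = sum(e - s for s, e in regions) / rate * 1000.0
        w.noisy, w.multi_peak = bool(noisy), bool(multi)
        rows.append(
            {"carrier_hz": carrier, "width_ms": width, "noisy": noisy, "multi_peak": multi}
        )
    return pd.DataFrame(rows)


def interpulse_intervals(centers_s: np.ndarray, max_ipi_ms: float = 100.0) -> np.ndarray:
    """IPIs (ms) between successive pulse centers; gaps > 100 ms span bouts
    and are excluded."""
    c = np.sort(np.asarray(centers_s, float))
    if c.size < 2:
        return np.empty(0)
    ipi = np.diff(c) * 1000.0
    return ipi[ipi <= max_ipi_ms]


def sine_carrier(
    audio: np.ndarray,
    sine_intervals: list[tuple[float, float]],
    rate: int = AUDIO_RATE,
    segment: int = 256,
) -> float | None:
    """Modal per-segment dominant frequency across all sine-song segments.

    Each interval is split into non-overlapping 256-sample (~25 ms)
    segments; the dominant FFT frequency of each segment is computed and
    the mode across segments returned.  Intervals shorter than one segment
    are skipped with a warning; returns None when nothing qualifies.
    """
    freqs_all = []
    for onset, offset in sine_intervals:
        i0, i1 = int(round(onset * rate)), int(round(offset * rate))
        if i1 - i0 < segment:
            warnings.warn(f"sine interval ({onset}, {offset}) shorter than one segment")
            continue
        for s in range(i0, i1 - segment + 1, segment):
            x = audio[s: s + segment]
            spec = np.abs(np.fft.rfft(x))
            fr = np.fft.rfftfreq(segment, 1.0 / rate)
            freqs_all.append(fr[1:][np.argmax(spec[1:])])
    if not freqs_all:
        return None
    vals, counts = np.unique(np.round(freqs_all, 6), return_counts=True)
    return float(vals[np.argmax(counts)])


# ---------------------------------------------------------------------------
# bout structure


def frame_labels_from_intervals(
    intervals: pd.DataFrame, duration_s: float, frame_rate: float = 30.0
) -> np.ndarray:
    """Per-frame string labels from an (onset_s, offset_s, label) table."""
    T = int(round(duration_s * frame_rate))
    labels = np.full(T, "silence", dtype=object)
    for _, row in intervals.iterrows():
        i0 = int(round(row["onset_s"] * frame_rate))
        i1 = int(round(row["offset_s"] * frame_rate))
        labels[i0:i1] = row["label"]
    return labels


def _runs(labels: np.ndarray) -> list[tuple[int, int, str]]:
    out = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            out.append((start, t, labels[start]))
            start = t
    return out


def bout_statistics(
    labels: np.ndarray,
    frame_rate: float = 30.0,
    window_s: float = 60.0,
    overlap: float = 0.5,
    max_gap_ms: float = 100.0,
    song_modes: tuple = ("pulse", "sine"),
) -> dict:
    """Song bouts and windowed amount/onsets/duration per mode.

    A bout is a maximal run of song segments (pulse or sine) whose silent
    gaps are all shorter than ``max_gap_ms``; its order is one plus the
    number of mode transitions inside it.  Windowed statistics use
    ``window_s`` windows at ``overlap`` overlap: *amount* is the fraction
    of frames in a mode, *onsets* the number of transitions into the mode,
    *duration* their ratio.  Per-trial values average over windows.
    """
    labels = np.asarray(labels, dtype=object)
    T = len(labels)
    gap_frames = max_gap_ms / 1000.0 * frame_rate

    song = np.isin(labels, song_modes)
    # bridge short silent gaps between song runs
    bridged = song.copy()
    gaps = [(s, e) for s, e, v in _runs(np.where(song, "song", "gap").astype(object)) if v == "gap"]
    for s, e in gaps:
        if s > 0 and e < T and (e - s) < gap_frames:
            bridged[s:e] = True

    bouts = []
    for s, e in ((a, b) for a, b, v in _runs(np.where(bridged, "in", "out").astype(object)) if v == "in"):
        if not song[s:e].any():
            continue
        modes = [v for _, _, v in _runs(labels[s:e]) if v in song_modes]
        transitions = sum(1 for a, b in zip(modes[:-1], modes[1:]) if a != b)
        bouts.append(
            {"onset_s": s / frame_rate, "offset_s": e / frame_rate,
             "bout_order": 1 + transitions, "modes": modes}
        )

    win = int(round(window_s * frame_rate))
    if win >= T:
        warnings.warn("window longer than trial; using one truncated window")
        starts = [0]
        win = T
    else:
        step = max(1, int(round(win * (1 - overlap))))
        starts = list(range(0, T - win + 1, step))

    track = {"pulse": labels == "pulse", "sine": labels == "sine", "song": song}
    windowed = {}
    for mode, m in track.items():
        amounts, onsets, durations = [], [], []
        for s in starts:
            seg = m[s: s + win]
            amt = seg.mean()
            ons = int(np.sum(np.diff(seg.astype(int)) == 1) + (1 if seg[0] else 0))
            amounts.append(amt)
            onsets.append(ons)
            durations.append(amt * win / frame_rate / ons if ons > 0 else np.nan)
        windowed[mode] = {
            "amount": float(np.mean(amounts)),
            "onsets": float(np.mean(onsets)),
            "duration_s": float(np.nanmean(durations)) if not np.all(np.isnan(durations)) else np.nan,
        }
    return {"bouts": pd.DataFrame(bouts), "windowed": windowed}


# ---------------------------------------------------------------------------
# pulse-type clustering


def cluster_pulse_types(
    waveforms: list[PulseWaveform],
    seed: int = 0,
    min_waveforms: int = 20,
    min_cluster_size: int = 10,
) -> np.ndarray:
    """Label pulses as fast (0) or slow (1) by unsupervised clustering.

    Unit-peak, polarity-fixed waveforms are embedded in 2-D (UMAP) and
    density-clustered (HDBSCAN).  The two largest clusters define the
    types: the cluster with the shorter mean envelope width is the fast
    type.  Remaining pulses are labeled by a support-vector classifier
    trained on the two clusters.  Falls back to a single type (all zeros,
    with a warning) when clustering finds fewer than two clusters.
    """
    import umap
    from sklearn.cluster import HDBSCAN
    from sklearn.svm import SVC

    X = np.stack([np.asarray(w.samples, float) for w in waveforms])
    if len(X) < min_waveforms:
        raise ValueError(f"need at least {min_waveforms} waveforms, got {len(X)}")
    peak = np.abs(X).max(axis=1, keepdims=True)
    X = X / np.where(peak > 0, peak, 1.0)
    # fix polarity by correlation with a reference, then with the aligned
    # mean (a per-waveform extremum rule is unstable for symmetric pulses)
    ref = X[0]
    for _ in range(2):
        sign = np.sign(X @ ref)
        X = X * np.where(sign == 0, 1.0, sign)[:, None]
        ref = X.mean(axis=0)

    if np.allclose(X.std(axis=0), 0):
        warnings.warn("identical waveforms; assigning a single pulse type")
        return np.zeros(len(X), dtype=int)

    emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(X)
    cl = HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(emb)
    ids, counts = np.unique(cl[cl >= 0], return_counts=True)
    if ids.size < 2:
        warnings.warn("fewer than two clusters found; assigning a single pulse type")
        return np.zeros(len(X), dtype=int)
    top2 = ids[np.argsort(-counts)[:2]]

    def env_width(idx: np.ndarray) -> float:
        mean_env = np.abs(hilbert(X[idx], axis=1)).mean(axis=0)
        return float((mean_env > 0.5 * mean_env.max()).sum())

    w0, w1 = env_width(cl == top2[0]), env_width(cl == top2[1])
    fast, slow = (top2[0], top2[1]) if w0 <= w1 else (top2[1], top2[0])

    labels = np.full(len(X), -1, dtype=int)
    labels[cl == fast] = 0
    labels[cl == slow] = 1
    rest = labels < 0
    if rest.any():
        svc = SVC(kernel="rbf", random_state=seed)
        svc.fit(X[~rest], labels[~rest])
        labels[rest] = svc.predict(X[rest])
    return labels


# ---------------------------------------------------------------------------
# mutual-song attribution


def attribute_mutual_song(
    courter_labels: np.ndarray, partner_labels: np.ndarray, song_modes: tuple = ("pulse", "sine")
) -> np.ndarray:
    """Resolve the courter's labels during conflicting mutual singing.

    Where both flies sing simultaneously with different song types, the
    courter's frames take the type he was producing immediately before
    the mutual-singing onset.  Aligned label arrays required.
    """
    c = np.asarray(courter_labels, dtype=object).copy()
    p = np.asarray(partner_labels, dtype=object)
    if len(c) != len(p):
        raise ValueError("annotations must be aligned")
    both = np.isin(c, song_modes) & np.isin(p, song_modes)
    conflict = both & (c != p)
    for s, e in ((a, b) for a, b, v in _runs(np.where(conflict, "x", "-").astype(object)) if v == "x"):
        pre = None
        for t in range(s - 1, -1, -1):
            if c[t] in song_modes:
                pre = c[t]
                break
            if c[t] == "silence":
                break
        if pre is not None:
            c[s:e] = pre
    return c
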