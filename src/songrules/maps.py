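"""Behavioral maps: embedding, density estimation, watershed segmentation.

Social maps embed the joint short-history dynamics of both flies' feedback
cues into 2-D (UMAP fitted on a temporally uniform subsample), estimate a
kernel density over the embedding, and carve the inverted density into
modes with a watershed transform.  Per-fly maps do the same on Morlet
wavelet spectrograms of egocentrically aligned pose coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .kinematics import ABDOMEN, HEAD, THORAX, FeedbackFeatures, PosePair


def embed_2d(X: np.ndarray, seed: int = 0, n_neighbors: int = 30, min_dist: float = 0.1):
    """Fit a seeded 2-D UMAP on X; returns the fitted reducer's embedding."""
    import umap

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    return reducer.fit_transform(X)


@dataclass
class SocialMap:
    """A fitted embedding with density surface and watershed mode labels."""

    reducer: object                 # fitted umap.UMAP
    embedded: np.ndarray            # (n, 2) all training frames
    trial_slices: list[slice]       # frame ranges per input trial
    grid_x: np.ndarray              # (G,) cell centers
    grid_y: np.ndarray
    density: np.ndarray             # (G, G), integrates to 1 over the grid
    labels: np.ndarray              # (G, G) int, 0 = background
    n_modes: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.reducer.transform(X)

    def assign_modes(self, points: np.ndarray) -> np.ndarray:
        """Watershed mode label (0 = background) for embedded points."""
        ix = np.clip(np.searchsorted(self.grid_x, points[:, 0]), 0, len(self.grid_x) - 1)
        iy = np.clip(np.searchsorted(self.grid_y, points[:, 1]), 0, len(self.grid_y) - 1)
        return self.labels[iy, ix]


def social_lag_design(features: FeedbackFeatures | np.ndarray, n_lags: int = 15) -> np.ndarray:
    """Per-frame flattened time history of all ten cues, shape (T, n_lags*10).

    Row t concatenates samples t-n_lags+1 .. t of every feature (most
    recent last); rows before a full history repeat the first sample.
    """
    arr = features.array() if isinstance(features, FeedbackFeatures) else np.asarray(features, float)
    T, F = arr.shape
    if T < n_lags:
        raise ValueError(f"trial length {T} shorter than the lag window {n_lags}")
    padded = np.vstack([np.repeat(arr[:1], n_lags - 1, axis=0), arr])
    out = np.empty((T, n_lags * F))
    for lag in range(n_lags):
        out[:, lag * F:(lag + 1) * F] = padded[lag: lag + T]
    return out


def density_and_watershed(
    points: np.ndarray,
    grid_size: int = 512,
    smoothing: float = 4.0,
    background_quantile: float = 0.01,
    pad_frac: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """KDE surface and watershed modes for a 2-D point cloud.

    The density is a binned KDE (histogram convolved with a Gaussian of
    ``smoothing`` grid cells), normalized to sum to 1.  Watershed runs on
    the inverted density restricted to cells above the
    ``background_quantile`` of positive density.  Returns
    (grid_x, grid_y, density, labels).
    """
    from skimage.segmentation import watershed

    lo = points.min(axis=0)
    hi = points.max(axis=0)
    pad = pad_frac * (hi - lo + 1e-9)
    lo, hi = lo - pad, hi + pad
    H, xe, ye = np.histogram2d(
        points[:, 0], points[:, 1], bins=grid_size,
        range=[[lo[0], hi[0]], [lo[1], hi[1]]],
    )
    density = gaussian_filter(H.T, smoothing)  # (y, x)
    density /= density.sum()
    pos = density[density > 0]
    thresh = np.quantile(pos, background_quantile)
    mask = density > thresh
    labels = watershed(-density, mask=mask)
    gx = 0.5 * (xe[:-1] + xe[1:])
    gy = 0.5 * (ye[:-1] + ye[1:])
    return gx, gy, density, labels


def fit_social_map(
    designs: list[np.ndarray],
    subsample: float = 0.1,
    seed: int = 0,
    grid_size: int = 512,
    smoothing: float = 4.0,
    n_neighbors: int = 30,
    min_dist: float = 0.1,
    background_quantile: float = 0.01,
) -> SocialMap:
    """Fit the social map from per-trial lag designs.

    The embedding is fitted on a temporally uniform ``subsample`` fraction
    of the pooled frames and then applied to every frame; density and
    watershed modes are computed on the full embedded cloud.
    """
    import umap

    if not designs or sum(len(d) for d in designs) == 0:
        raise ValueError("no input frames")
    pooled = np.vstack(designs)
    step = max(1, int(round(1.0 / subsample)))
    train = pooled[::step]
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    reducer.fit(train)
    embedded = reducer.transform(pooled)
    gx, gy, density, labels = density_and_watershed(
        embedded, grid_size=grid_size, smoothing=smoothing,
        background_quantile=background_quantile,
    )
    slices, start = [], 0
    for d in designs:
        slices.append(slice(start, start + len(d)))
        start += len(d)
    return SocialMap(
        reducer=reducer, embedded=embedded, trial_slices=slices,
        grid_x=gx, grid_y=gy, density=density, labels=labels,
        n_modes=int(labels.max()),
    )


def mode_occupancy(
    smap: SocialMap,
    condition_masks: dict[str, np.ndarray] | None = None,
) -> dict:
    """Per-trial mode fractions and optional condition difference maps.

    Fractions are over all frames of a trial (background excluded from
    modes, so they sum to <= 1).  For each pair of conditions the
    difference between their normalized density surfaces is returned.
    """
    modes = smap.assign_modes(smap.embedded)
    per_trial = []
    for sl in smap.trial_slices:
        m = modes[sl]
        counts = np.bincount(m, minlength=smap.n_modes + 1).astype(float)
        per_trial.append(counts[1:] / max(len(m), 1))
    out: dict = {"mode_fractions": np.asarray(per_trial)}

    if condition_masks:
        dens = {}
        for name, mask in condition_masks.items():
            mask = np.asarray(mask, bool)
            if mask.sum() == 0:
                warnings.warn(f"condition {name!r} has zero frames")
                dens[name] = None
                continue
            pts = smap.embedded[mask]
            H, _, _ = np.histogram2d(
                pts[:, 0], pts[:, 1],
                bins=[len(smap.grid_x), len(smap.grid_y)],
                range=[
                    [smap.grid_x[0], smap.grid_x[-1]],
                    [smap.grid_y[0], smap.grid_y[-1]],
                ],
            )
            d = gaussian_filter(H.T, 4.0)
            dens[name] = d / d.sum()
        names = [n for n, d in dens.items() if d is not None]
        diffs = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                diffs[f"{a}-{b}"] = dens[a] - dens[b]
        out["condition_density"] = dens
        out["difference_maps"] = diffs
    return out


# ---------------------------------------------------------------------------
# wavelet (per-fly) behavior maps


def dyadic_frequencies(n: int = 25, f_min: float = 1.0, f_max: float = 25.0) -> np.ndarray:
    """n frequencies spaced dyadically (log2-uniform) over [f_min, f_max] Hz."""
    return 2.0 ** np.linspace(np.log2(f_min), np.log2(f_max), n)


def egocentric_coordinates(pose: PosePair) -> np.ndarray:
    """(T, 24) pose channels: both flies' six parts, egocentrically aligned.

    Each fly's keypoints are translated to its thorax, rotated so the
    body axis points along +x, and scaled by the fly length.
    """
    T = pose.n_frames
    out = np.empty((T, 24))
    for fly in range(2):
        xy = pose.xy[fly]
        thorax = xy[:, THORAX]
        axis = xy[:, HEAD] - xy[:, ABDOMEN]
        ang = np.arctan2(axis[:, 1], axis[:, 0])
        c, s = np.cos(-ang), np.sin(-ang)
        rel = xy - thorax[:, None, :]
        xr = c[:, None] * rel[..., 0] - s[:, None] * rel[..., 1]
        yr = s[:, None] * rel[..., 0] + c[:, None] * rel[..., 1]
        scale = pose.fly_length[fly]
        out[:, fly * 12: fly * 12 + 6] = xr / scale
        out[:, fly * 12 + 6: fly * 12 + 12] = yr / scale
    return out


def wavelet_power(
    channels: np.ndarray, frame_rate: float, freqs: np.ndarray | None = None
) -> np.ndarray:
    """Morlet wavelet power of each channel, shape (T, n_channels * n_freqs)."""
    import pywt

    freqs = dyadic_frequencies() if freqs is None else np.asarray(freqs, float)
    scales = pywt.frequency2scale("morl", freqs / frame_rate)
    longest = int(np.ceil(scales.max() * 8))
    T, C = channels.shape
    if T <= longest:
        raise ValueError(
            f"trial of {T} frames shorter than the longest wavelet support ({longest})"
        )
    out = np.empty((T, C * len(freqs)))
    for c in range(C):
        coef, _ = pywt.cwt(channels[:, c], scales, "morl")
        out[:, c * len(freqs):(c + 1) * len(freqs)] = np.abs(coef).T ** 2
    return out


def wavelet_behavior_map(
    pose: PosePair,
    freqs: np.ndarray | None = None,
    subsample: float = 0.1,
    seed: int = 0,
    target_rate: float = 30.0,
    **map_kwargs,
) -> tuple[np.ndarray, SocialMap]:
    """Per-fly behavior map from wavelet spectrograms of the pose.

    Returns the (T, 600) wavelet feature matrix (24 egocentric channels x
    25 dyadic frequencies by default) and the fitted map.
    """
    from .kinematics import _resample

    coords = egocentric_coordinates(pose)
    coords = _resample(coords, pose.frame_rate, target_rate)
    power = wavelet_power(coords, target_rate, freqs=freqs)
    smap = fit_social_map([power], subsample=subsample, seed=seed, **map_kwargs)
    return power, smap
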