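"""Raised-cosine lag bases for covariate-history regression.

A categorical GLM driven by 4 s of feedback-cue history at 30 Hz would need
120 free coefficients per cue per song mode.  Projecting each cue's lag
vector onto a small bank of raised-cosine bumps whose peaks are log-spaced
in lag (narrow near lag zero, broad at long delays) keeps the filters smooth
and cuts the dimensionality from ``n_lags`` to ``n_basis`` per cue, while
preserving fine temporal resolution where recent history matters most.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BasisSet:
    """A bank of raised-cosine bumps over a discrete lag axis.

    Attributes
    ----------
    matrix : (n_lags, n_basis) array
        Column ``j`` is the j-th basis function evaluated at lags
        ``0 .. n_lags-1`` (lag 0 = current sample).  Entries are
        nonnegative and every lag has positive total mass.
    frame_rate : float
        Sampling rate of the lag axis in Hz (30 by default upstream).
    """

    matrix: np.ndarray
    frame_rate: float = 30.0
    log_stretch: float = field(default=10.0)

    @property
    def n_lags(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[1]

    def project(self, lagged: np.ndarray) -> np.ndarray:
        """Project a (..., n_lags) lag vector onto the basis -> (..., n_basis)."""
        return np.asarray(lagged) @ self.matrix


def raised_cosine_basis(
    n_lags: int = 120,
    n_basis: int = 10,
    frame_rate: float = 30.0,
    log_stretch: float = 10.0,
) -> BasisSet:
    """Build ``n_basis`` raised-cosine bumps with log-spaced peaks.

    Each bump is ``0.5 * (1 + cos(pi * (phi - c_j) / (2 d)))`` on the
    warped lag axis ``phi = log(lag + stretch)``, zero outside
    ``|phi - c_j| <= 2 d`` where ``d`` is the center spacing.  Linear
    spacing of centers on the warped axis makes later-peaking bumps
    broader on the raw lag axis, so the basis resolves recent history
    finely and integrates distant history coarsely.

    Parameters
    ----------
    n_lags : int
        Length of the covariate history in samples (default 120, i.e. 4 s
        at 30 Hz).
    n_basis : int
        Number of bumps.  Must satisfy ``1 <= n_basis <= n_lags``.
    log_stretch : float
        Offset inside the log warp, in samples.  Larger values make the
        warp closer to linear.

    Raises
    ------
    ValueError
        If ``n_basis`` exceeds ``n_lags`` or either is < 1.
    """
    if n_basis < 1 or n_lags < 1:
        raise ValueError("n_lags and n_basis must be >= 1")
    if n_basis > n_lags:
        raise ValueError(f"n_basis ({n_basis}) may not exceed n_lags ({n_lags})")

    lags = np.arange(n_lags, dtype=float)
    phi = np.log(lags + log_stretch)
    centers = np.linspace(phi[0], phi[-1], n_basis)
    # Half-width of two center spacings => neighbouring bumps overlap and
    # every lag keeps positive total mass.  Degenerate n_basis == 1 gets a
    # single bump spanning the whole axis.
    if n_basis > 1:
        spacing = centers[1] - centers[0]
    else:
        # single bump: widen so the support strictly covers the lag axis
        spacing = 0.75 * (phi[-1] - phi[0]) or 1.0

    arg = (phi[:, None] - centers[None, :]) / (2.0 * spacing)
    arg = np.clip(arg, -1.0, 1.0)
    mat = 0.5 * (1.0 + np.cos(np.pi * arg))
    return BasisSet(matrix=mat, frame_rate=frame_rate, log_stretch=log_stretch)
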