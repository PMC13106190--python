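"""Movement-onset peak detection: multiscale AMPD plus three filtering rules.

Automatic multiscale-based peak detection (AMPD) marks a sample as a
candidate peak when it is a local maximum simultaneously at every window
scale ``k = 1..lambda``, where lambda is the scale whose row of the
local-maxima scalogram contains the most maxima.  This variant uses a
deterministic 0/1 scalogram (no random fill), so detection needs no seed and
is exactly reproducible.

Candidates are then screened by three rules tailored to repetitive-movement
accelerometry:

1. *boundary*: a candidate at the very first or last sample is incomplete
   and is removed;
2. *low amplitude*: candidates below 0.3x the highest candidate amplitude
   (tremor blips, partial movements) are removed;
3. *flat*: candidates whose local sharpness — the windowed integral of the
   absolute first derivative over +/- two samples — is at most 0.1x the
   sharpest candidate's are removed.

Both thresholds are relative, so the retained index set is invariant to
scaling the signal by any positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

from .preprocess import Segment

__all__ = [
    "PeakFilterConfig",
    "PeakSet",
    "ampd_detect",
    "drop_boundary_peaks",
    "filter_low_amplitude_peaks",
    "filter_flat_peaks",
    "detect_movement_peaks",
]


@dataclass(frozen=True)
class PeakFilterConfig:
    low_amp_ratio: float = 0.3
    flat_ratio: float = 0.1
    flat_halfwidth: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.low_amp_ratio < 1.0:
            raise ValueError("low_amp_ratio must be in (0, 1)")
        if not 0.0 < self.flat_ratio < 1.0:
            raise ValueError("flat_ratio must be in (0, 1)")
        if self.flat_halfwidth < 1:
            raise ValueError("flat_halfwidth must be >= 1")


@dataclass
class PeakSet:
    """Retained peaks plus the fate of every AMPD candidate.

    ``provenance`` maps each candidate index to one of
    ``{"kept", "boundary", "low_amplitude", "flat"}``.
    """

    indices: np.ndarray
    amplitudes: np.ndarray
    provenance: dict[int, str]

    def __len__(self) -> int:
        return len(self.indices)


def ampd_detect(signal: np.ndarray, max_scale: int | None = None) -> np.ndarray:
    """AMPD candidate peaks of a 1-D signal.

    The signal is linearly detrended; at scale ``k`` sample ``i`` counts as a
    local maximum when it strictly exceeds its neighbours ``i - k`` and
    ``i + k`` (a missing neighbour beyond the boundary counts as exceeded,
    so an edge sample that dominates everything inside its scale window can
    surface as a candidate — rule 1 deals with it).  Returns the samples that
    are maxima at every scale up to the most populated one.  Too-short or
    constant signals yield an empty candidate list.
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if n < 8:
        return np.array([], dtype=int)
    scale = np.ptp(x)
    x = detrend(x)
    # a linear (or constant) signal detrends to float dust, not exact zero
    if np.ptp(x) <= 1e-10 * max(scale, 1e-300):
        return np.array([], dtype=int)

    max_k = int(np.ceil(n / 2)) - 1
    if max_scale is not None:
        max_k = min(max_k, max_scale)
    gammas = np.empty(max_k, dtype=int)
    rows = np.empty((max_k, n), dtype=bool)
    for k in range(1, max_k + 1):
        left = np.ones(n, dtype=bool)
        left[k:] = x[k:] > x[:-k]
        right = np.ones(n, dtype=bool)
        right[:-k] = x[:-k] > x[k:]
        rows[k - 1] = left & right
        # scale selection counts interior maxima only: near the half-period
        # scale almost every sample of the dominant lobe beats both its
        # k-distant neighbours, which is what makes lambda track the rhythm
        gammas[k - 1] = int(rows[k - 1][k:n - k].sum())
    lam = int(np.argmax(gammas)) + 1
    mask = rows[:lam].all(axis=0)
    return np.flatnonzero(mask)


def drop_boundary_peaks(candidates: np.ndarray, signal_len: int) -> np.ndarray:
    """Rule 1: remove candidates sitting exactly on the first or last sample."""
    c = np.asarray(candidates, dtype=int)
    return c[(c != 0) & (c != signal_len - 1)]


def filter_low_amplitude_peaks(signal: np.ndarray, candidates: np.ndarray,
                               config: PeakFilterConfig = PeakFilterConfig()) -> np.ndarray:
    """Rule 2: keep candidates at >= `low_amp_ratio` x the highest amplitude."""
    c = np.asarray(candidates, dtype=int)
    if len(c) == 0:
        return c
    amps = np.asarray(signal, dtype=float)[c]
    return c[amps >= config.low_amp_ratio * amps.max()]


def peak_sharpness(signal: np.ndarray, candidates: np.ndarray,
                   halfwidth: int = 2) -> np.ndarray:
    """Windowed integral of |first derivative| around each candidate.

    ``s[i] = sum of |x[n+1]-x[n]|`` for n in ``[i-halfwidth, i+halfwidth-1]``,
    clipped at the signal edges.
    """
    x = np.asarray(signal, dtype=float)
    d = np.abs(np.diff(x))
    out = np.empty(len(candidates), dtype=float)
    for j, i in enumerate(candidates):
        lo = max(0, i - halfwidth)
        hi = min(len(d), i + halfwidth)
        out[j] = d[lo:hi].sum()
    return out


def filter_flat_peaks(signal: np.ndarray, candidates: np.ndarray,
                      config: PeakFilterConfig = PeakFilterConfig()) -> np.ndarray:
    """Rule 3: remove candidates whose sharpness is <= `flat_ratio` x the max.

    The sharpest candidate (ties included) is always retained.
    """
    c = np.asarray(candidates, dtype=int)
    if len(c) == 0:
        return c
    s = peak_sharpness(signal, c, config.flat_halfwidth)
    smax = s.max()
    keep = (s > config.flat_ratio * smax) | (s == smax)
    return c[keep]


def detect_movement_peaks(segment: Segment,
                          config: PeakFilterConfig = PeakFilterConfig()) -> PeakSet:
    """Full chain on the y-axis: AMPD -> boundary -> low-amplitude -> flat."""
    y = segment.y
    candidates = ampd_detect(y)
    provenance: dict[int, str] = {}

    after_boundary = drop_boundary_peaks(candidates, len(y))
    for i in np.setdiff1d(candidates, after_boundary):
        provenance[int(i)] = "boundary"

    after_amp = filter_low_amplitude_peaks(y, after_boundary, config)
    for i in np.setdiff1d(after_boundary, after_amp):
        provenance[int(i)] = "low_amplitude"

    kept = filter_flat_peaks(y, after_amp, config)
    for i in np.setdiff1d(after_amp, kept):
        provenance[int(i)] = "flat"
    for i in kept:
        provenance[int(i)] = "kept"

    return PeakSet(indices=kept, amplitudes=y[kept].copy(), provenance=provenance)
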