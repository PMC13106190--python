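"""Hand-crafted features from peak series and signal channels.

Four families are computed per segment:

* kinematic — from the retained y-axis peak series: movement speed, interval
  count, and per-series statistics (location, spread, shape, fatigue and
  monotone-run rates) of both the inter-peak durations and the peak
  amplitudes.  The fatigue statistics quantify the sequence effect (relative
  change of the last-N vs first-N values); the ascending/descending
  frequencies quantify rhythm instability.
* time domain — 19 sub-features per channel (x, y, z, magnitude): moments,
  RMS, range, zero-crossing and slope-sign-change rates, Teager-Kaiser
  energy, amplitude-histogram entropy, interquartile range of the
  autocovariance, harmonic mean, detrended fluctuation exponent, order-4
  Burg autoregressive coefficients, and the peak normalized
  cross-correlation with the magnitude channel.
* frequency domain — dominant frequency and its power, spectral centroid,
  normalized spectral entropy and spectral flatness, per channel.
* physiological — age (years) and gender (0 = male, 1 = female).

Degenerate inputs (too few peaks, too-short or constant channels) produce a
documented sentinel value of 0.0, never NaN: downstream models always see a
finite, schema-stable matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spst
from statsmodels.regression.linear_model import burg

from .peaks import PeakFilterConfig, PeakSet, detect_movement_peaks
from .preprocess import Segment

__all__ = [
    "IntervalSeries",
    "FeatureVector",
    "kinematic_features",
    "time_domain_features",
    "frequency_domain_features",
    "assemble_feature_vector",
    "features_dataframe",
    "build_schema",
    "SCHEMA_VERSION",
]

SENTINEL = 0.0
SCHEMA_VERSION = "1"
CHANNELS = ("x", "y", "z", "magnitude")
ENTROPY_BINS = 16
AR_ORDER = 4
HMEAN_EPS = 1e-8
SPECF_EPS = 1e-20
SPECF_BLOCKS = 8
TD_MIN_LEN = 32

_SERIES_STATS = ("median", "mean", "std", "range", "cv", "sk", "ku", "mse",
                 "fatigue1", "fatigue2", "fatigue5", "ascdf", "dscdf")
_TD_STATS = ("mean", "std", "var", "rms", "range", "sk", "ku", "zcr", "ssc",
             "tkeo", "entropy", "iqr_autocov", "hmean", "dfa",
             "arc1", "arc2", "arc3", "arc4", "crosscorr")
_FD_STATS = ("mainamp", "mainf", "meanf", "se", "specf")


@dataclass
class IntervalSeries:
    """Inter-peak durations (s) and peak amplitudes (m/s^2) of one segment."""

    durations: np.ndarray
    amplitudes: np.ndarray

    @classmethod
    def from_peakset(cls, peaks: PeakSet, fs: float) -> "IntervalSeries":
        times = np.asarray(peaks.indices, dtype=float) / fs
        return cls(durations=np.diff(times), amplitudes=np.asarray(peaks.amplitudes, float))


@dataclass
class FeatureVector:
    recording_id: str
    window_index: int
    names: list[str]
    values: np.ndarray
    label: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


# ---------------------------------------------------------------- kinematic

def _skew(v: np.ndarray) -> float:
    if np.std(v) == 0:
        return SENTINEL
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant data
        return float(spst.skew(v))


def _kurt(v: np.ndarray) -> float:
    if np.std(v) == 0:
        return SENTINEL
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(spst.kurtosis(v))


def _fatigue(v: np.ndarray, n: int) -> float:
    """Relative change of the mean of the last n values vs the first n."""
    if len(v) < n:
        return SENTINEL
    first = v[:n].mean()
    if first == 0:
        return SENTINEL
    return float((v[-n:].mean() - first) / first)


def _run_rate(v: np.ndarray, ascending: bool) -> float:
    if len(v) < 2:
        return SENTINEL
    d = np.diff(v)
    return float(np.mean(d > 0) if ascending else np.mean(d < 0))


def _series_block(v: np.ndarray) -> dict[str, float]:
    if len(v) == 0:
        return {s: SENTINEL for s in _SERIES_STATS}
    mean = float(np.mean(v))
    std = float(np.std(v))
    return {
        "median": float(np.median(v)),
        "mean": mean,
        "std": std,
        "range": float(np.ptp(v)),
        "cv": std / mean if mean != 0 else SENTINEL,
        "sk": _skew(v),
        "ku": _kurt(v),
        "mse": float(np.mean(v**2)),
        "fatigue1": _fatigue(v, 1),
        "fatigue2": _fatigue(v, 2),
        "fatigue5": _fatigue(v, 5),
        "ascdf": _run_rate(v, True),
        "dscdf": _run_rate(v, False),
    }


def kinematic_features(iv: IntervalSeries, segment_duration: float) -> dict[str, float]:
    """Kinematic block from the retained peak series.

    Speed is always the retained-peak count per second.  With fewer than two
    peaks the interval series is undefined and every per-series statistic
    takes the sentinel value 0, with NI = 0.
    """
    n_peaks = len(iv.amplitudes)
    out: dict[str, float] = {"speed": n_peaks / segment_duration}
    if n_peaks < 2:
        out["ni"] = 0.0
        for prefix in ("dur", "amp"):
            for s in _SERIES_STATS:
                out[f"{prefix}_{s}"] = SENTINEL
        return out
    out["ni"] = float(len(iv.durations))
    for prefix, v in (("dur", iv.durations), ("amp", iv.amplitudes)):
        for s, val in _series_block(np.asarray(v, float)).items():
            out[f"{prefix}_{s}"] = val
    return out


# -------------------------------------------------------------- time domain

def _entropy_hist(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return SENTINEL
    counts, _ = np.histogram(x, bins=ENTROPY_BINS)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _autocov_iqr(x: np.ndarray) -> float:
    xm = x - x.mean()
    n = len(x)
    full = np.correlate(xm, xm, mode="full")[n - 1:] / n  # biased estimator
    c = full[: n // 2 + 1]
    return float(np.percentile(c, 75) - np.percentile(c, 25))


def dfa_exponent(x: np.ndarray) -> float:
    """Detrended fluctuation analysis scaling exponent.

    Box sizes double from 4 up to len/4; each box of the integrated,
    mean-removed series is linearly detrended and the RMS fluctuation F(n)
    recorded; the exponent is the log-log slope.  Uncorrelated noise gives
    an exponent near 0.5.
    """
    n = len(x)
    sizes = []
    s = 4
    while s <= n // 4:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return SENTINEL
    profile = np.cumsum(x - x.mean())
    fluct = []
    for s in sizes:
        nbox = n // s
        segs = profile[: nbox * s].reshape(nbox, s)
        t = np.arange(s)
        # per-box linear detrend
        tm = t - t.mean()
        denom = (tm**2).sum()
        slopes = segs @ tm / denom
        resid = segs - segs.mean(axis=1, keepdims=True) - slopes[:, None] * tm
        fluct.append(np.sqrt(np.mean(resid**2)))
    fluct = np.asarray(fluct)
    if np.any(fluct <= 0):
        return SENTINEL
    slope = np.polyfit(np.log(sizes), np.log(fluct), 1)[0]
    return float(slope)


def _burg_coefficients(x: np.ndarray) -> np.ndarray:
    if np.std(x) == 0:
        return np.zeros(AR_ORDER)
    try:
        rho, _ = burg(x, order=AR_ORDER, demean=True)
    except Exception:
        return np.zeros(AR_ORDER)
    rho = np.asarray(rho, dtype=float)
    if not np.all(np.isfinite(rho)):
        return np.zeros(AR_ORDER)
    return rho


def _max_crosscorr(x: np.ndarray, ref: np.ndarray) -> float:
    a = x - x.mean()
    b = ref - ref.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return SENTINEL
    c = sps.correlate(a, b, mode="full", method="auto")
    return float(c.max() / (na * nb))


def time_domain_features(channel: np.ndarray, magnitude: np.ndarray) -> dict[str, float]:
    """Time-domain block for one channel.

    `magnitude` is the reference for the cross-correlation sub-feature (the
    magnitude channel correlated with itself gives exactly 1.0).  Channels
    shorter than 32 samples return the sentinel block.
    """
    x = np.asarray(channel, dtype=float)
    if len(x) < TD_MIN_LEN:
        return {s: SENTINEL for s in _TD_STATS}
    n = len(x)
    d = np.diff(x)
    sgn = np.sign(x)
    out = {
        "mean": float(x.mean()),
        "std": float(x.std()),
        "var": float(x.var()),
        "rms": float(np.sqrt(np.mean(x**2))),
        "range": float(np.ptp(x)),
        "sk": _skew(x),
        "ku": _kurt(x),
        "zcr": float(np.sum(sgn[:-1] * sgn[1:] < 0) / (n - 1)),
        "ssc": float(np.sum(d[:-1] * d[1:] < 0) / (n - 2)),
        "tkeo": float(np.mean(x[1:-1] ** 2 - x[:-2] * x[2:])),
        "entropy": _entropy_hist(x),
        "iqr_autocov": _autocov_iqr(x),
        "hmean": float(spst.hmean(np.abs(x) + HMEAN_EPS)),
        "dfa": dfa_exponent(x),
    }
    arc = _burg_coefficients(x)
    for i in range(AR_ORDER):
        out[f"arc{i + 1}"] = float(arc[i])
    out["crosscorr"] = _max_crosscorr(x, np.asarray(magnitude, float))
    return out


# --------------------------------------------------------- frequency domain

def _bartlett_psd(x: np.ndarray, fs: float) -> np.ndarray:
    """Block-averaged periodogram (DC excluded) used for spectral flatness.

    A raw periodogram's bins stay chi-squared distributed however long the
    signal, which pins the geometric/arithmetic-mean ratio of white noise
    near exp(-gamma) ~ 0.56; averaging 8 non-overlapping blocks makes the
    estimate consistent, so flatness approaches 1 for white noise while a
    pure tone still collapses to a single bin.
    """
    n = len(x)
    nper = n // SPECF_BLOCKS
    if nper < 16:
        nper = n
    nblocks = n // nper
    acc = None
    for b in range(nblocks):
        _, p = sps.periodogram(x[b * nper:(b + 1) * nper], fs=fs,
                               window="boxcar", detrend=False)
        acc = p if acc is None else acc + p
    return acc[1:] / nblocks


def frequency_domain_features(channel: np.ndarray, fs: float) -> dict[str, float]:
    """Frequency-domain block from the one-sided periodogram, DC excluded."""
    x = np.asarray(channel, dtype=float)
    if len(x) < 16:
        raise ValueError("channel must have at least 16 samples")
    f, p = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    f, p = f[1:], p[1:]
    if np.all(p <= 0):
        return {s: SENTINEL for s in _FD_STATS}
    imax = int(np.argmax(p))
    total = p.sum()
    prob = p / total
    nz = prob[prob > 0]
    se = float(-np.sum(nz * np.log(nz)) / np.log(len(p)))
    pb = _bartlett_psd(x, fs)
    gm = float(np.exp(np.mean(np.log(pb + SPECF_EPS))))
    am = float(np.mean(pb))
    specf = float(np.clip(gm / (am + SPECF_EPS), 0.0, 1.0))
    return {
        "mainamp": float(p[imax]),
        "mainf": float(f[imax]),
        "meanf": float(np.sum(f * p) / total),
        "se": se,
        "specf": specf,
    }


# ----------------------------------------------------------------- assembly

def feature_names() -> list[str]:
    names = ["kin_speed", "kin_ni"]
    names += [f"kin_dur_{s}" for s in _SERIES_STATS]
    names += [f"kin_amp_{s}" for s in _SERIES_STATS]
    for ch in CHANNELS:
        names += [f"td_{ch}_{s}" for s in _TD_STATS]
    for ch in CHANNELS:
        names += [f"fd_{ch}_{s}" for s in _FD_STATS]
    names += ["phys_age", "phys_gender"]
    return names


def build_schema() -> list[dict[str, str]]:
    """Feature-name manifest: family, channel and formula id per sub-feature."""
    schema = []
    for name in feature_names():
        if name.startswith("kin_"):
            family, channel = "kinematic", "y_peaks"
            formula = name.removeprefix("kin_")
        elif name.startswith("td_"):
            family = "time_domain"
            _, channel, formula = name.split("_", 2)
        elif name.startswith("fd_"):
            family = "frequency_domain"
            _, channel, formula = name.split("_", 2)
        else:
            family, channel = "physiological", "none"
            formula = name.removeprefix("phys_")
        schema.append({"name": name, "family": family, "channel": channel,
                       "formula_id": f"{formula}_v{SCHEMA_VERSION}",
                       "version": SCHEMA_VERSION})
    return schema


def _encode_gender(gender: str) -> float:
    if gender not in ("M", "F"):
        raise ValueError(f"gender must be 'M' or 'F', got {gender!r}")
    return 0.0 if gender == "M" else 1.0


def assemble_feature_vector(segment: Segment, peaks: PeakSet,
                            age: float | None = None,
                            gender: str | None = None) -> FeatureVector:
    """Concatenate all four families into one schema-ordered vector.

    Kinematic features come from the y-axis peak series; time- and
    frequency-domain features are computed on every channel; age and gender
    default to the segment's metadata.  The label is the mapped score
    (raw 4 folded into 3).
    """
    age = segment.age if age is None else age
    gender = segment.gender if gender is None else gender
    iv = IntervalSeries.from_peakset(peaks, segment.fs)

    values: dict[str, float] = {}
    for k, v in kinematic_features(iv, segment.duration).items():
        values[f"kin_{k}"] = v
    for ch in CHANNELS:
        for k, v in time_domain_features(segment.channels[ch], segment.magnitude).items():
            values[f"td_{ch}_{k}"] = v
    for ch in CHANNELS:
        for k, v in frequency_domain_features(segment.channels[ch], segment.fs).items():
            values[f"fd_{ch}_{k}"] = v
    values["phys_age"] = float(age)
    values["phys_gender"] = _encode_gender(gender)

    names = feature_names()
    vec = np.array([values[n] for n in names], dtype=float)
    vec = np.nan_to_num(vec, nan=SENTINEL, posinf=SENTINEL, neginf=SENTINEL)
    label = min(segment.score_raw, 3) if segment.score_raw >= 0 else -1
    return FeatureVector(recording_id=segment.recording_id,
                         window_index=segment.window_index,
                         names=names, values=vec, label=label)


META_COLUMNS = ("subject_id", "record_id", "window_index", "task", "side", "score_raw")


def features_dataframe(segments: list[Segment],
                       peak_config: PeakFilterConfig = PeakFilterConfig()) -> pd.DataFrame:
    """Detect peaks and extract features for a list of segments.

    Returns a wide DataFrame: metadata columns (`META_COLUMNS`) followed by
    the schema-ordered feature columns.  Raises if the segments would produce
    inconsistent schemas (they cannot, by construction, but the contract is
    enforced).
    """
    rows = []
    names = feature_names()
    for seg in segments:
        pk = detect_movement_peaks(seg, peak_config)
        fv = assemble_feature_vector(seg, pk)
        if fv.names != names:
            raise ValueError("feature schema mismatch across segments")
        row = {"subject_id": seg.subject_id, "record_id": seg.recording_id,
               "window_index": seg.window_index, "task": seg.task,
               "side": seg.side, "score_raw": seg.score_raw}
        row.update(zip(fv.names, fv.values))
        rows.append(row)
    return pd.DataFrame(rows)
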