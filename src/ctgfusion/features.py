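"""Stage II: the 68-dimensional feature description of a 10-minute segment.

Five families are concatenated in a fixed, documented order:

* 8 time-domain moments and summaries (``mean`` ... ``cumsum``);
* 4 spectral band energies of the mean-removed signal (``SP_ULF`` ...
  ``SP_HF``), over the conventional FHR bands by default;
* 7 statistics of the local extrema of the normalized autocorrelation
  function over lags 1..240 (one minute at 4 Hz);
* 36 EMG-inspired waveform descriptors (integrated amplitude, waveform
  length, zero crossings, cardinality, Teager-Kaiser energy, ...), computed
  by their standard surface-electromyography toolbox definitions;
* 13 morphological features built on an estimated baseline heart rate:
  acceleration/deceleration counts, amplitudes, durations and
  within-deceleration signal statistics.

All statistics are total functions: zero-variance signals and empty event
sets produce 0 rather than NaN, so a feature matrix never contains missing
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.ndimage import median_filter, uniform_filter1d
from statsmodels.regression.linear_model import yule_walker

from .preprocessing import Segment
from .signal_io import ClassLabel

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "BaselineCurve",
    "Event",
    "EventList",
    "TIME_FEATURES",
    "SPECTRAL_FEATURES",
    "AUTOCORR_FEATURES",
    "EMG_FEATURES",
    "MORPH_FEATURES",
    "FEATURE_NAMES",
    "FAMILY_SIZES",
    "time_features",
    "spectral_band_energies",
    "autocorrelation",
    "autocorr_features",
    "emg_features",
    "estimate_baseline",
    "morphological_features",
    "extract_all",
]

TIME_FEATURES = (
    "mean", "std", "mad", "diff", "skew", "kurtosis", "pulseindicator", "cumsum",
)
SPECTRAL_FEATURES = ("SP_ULF", "SP_VLF", "SP_LF", "SP_HF")
AUTOCORR_FEATURES = (
    "MAX_MINS", "MAX_SUM", "MAX_MEDIAN", "MAX_STD",
    "MIN_SUM", "MIN_MEDIAN", "MIN_STD",
)
# The EMG family keeps 36 of the 40 toolbox names; the four plain moment
# duplicates of the time family (skew, kurt, sd, var) are excluded.
EMG_FEATURES = (
    "emav", "ewl", "fzc", "asm", "ass", "msr", "ltkeo", "lcov", "card",
    "ldasdv", "ldamv", "dvarv", "vo", "tm", "damv", "ar", "mad.1", "iqr",
    "cov", "ae", "iemg", "mav", "ssc", "zc", "wl", "rms", "aac", "dasdv",
    "ld", "mmav", "mmav2", "myop", "ssi", "vare", "wa", "mfl",
)
MORPH_FEATURES = (
    "num_acc", "num_dec", "num_prolonged_dec",
    "avg_acc_amp", "avg_dec_amp", "avg_acc_dur", "avg_dec_dur",
    "iqr_dec_dur", "skew_dec_dur", "var_dec_dur",
    "avg_dec_card", "std_dec_kurt", "total_dec_time_fraction",
)
FEATURE_NAMES: tuple[str, ...] = (
    TIME_FEATURES + SPECTRAL_FEATURES + AUTOCORR_FEATURES
    + EMG_FEATURES + MORPH_FEATURES
)
FAMILY_SIZES = {
    "time": len(TIME_FEATURES),
    "spectral": len(SPECTRAL_FEATURES),
    "autocorrelation": len(AUTOCORR_FEATURES),
    "emg": len(EMG_FEATURES),
    "morphological": len(MORPH_FEATURES),
}
assert len(FEATURE_NAMES) == 68

_EPS = 1e-12


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable constants of the extraction battery.

    ``band_edges`` are in Hz and must increase strictly; the default four
    bands (ULF up to 0.03, VLF to 0.15, LF to 0.5, HF to 2.0 = Nyquist at
    4 Hz) follow the usual FHR variability convention.  ``deadband_factor``
    scales the signal's standard deviation into the amplitude deadband of
    the crossing-type EMG features.  Acceleration/deceleration detection
    uses the clinical 15 bpm / 15 s rule with 180 s marking a prolonged
    deceleration.
    """

    band_edges: tuple[float, ...] = (0.0, 0.03, 0.15, 0.5, 2.0)
    n_lags: int = 240
    deadband_factor: float = 0.01
    card_decimals: int = 3
    event_bpm: float = 15.0
    event_min_seconds: float = 15.0
    event_smooth_seconds: float = 2.0
    prolonged_seconds: float = 180.0
    baseline_smooth_seconds: float = 60.0
    baseline_median_seconds: float = 180.0
    baseline_trim_bpm: float = 15.0
    baseline_tol_bpm: float = 0.5
    baseline_max_iter: int = 10
    ar_order: int = 4
    vo_order: int = 2
    tm_order: int = 3


@dataclass
class FeatureVector:
    """The ordered 68-value description of one segment, with provenance."""

    names: tuple[str, ...]
    values: np.ndarray
    record_id: str = ""
    segment_index: int = 0
    label: ClassLabel | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __len__(self) -> int:
        return self.values.size


@dataclass
class BaselineCurve:
    """Per-sample baseline heart rate estimate and its iteration history."""

    values: np.ndarray
    iteration_deltas: list[float] = field(default_factory=list)


@dataclass
class Event:
    start: int
    end: int  # exclusive
    peak_deviation: float  # bpm, positive for both event types
    duration_s: float
    prolonged: bool = False


@dataclass
class EventList:
    accelerations: list[Event] = field(default_factory=list)
    decelerations: list[Event] = field(default_factory=list)


def _segment_array(segment) -> np.ndarray:
    x = segment.samples if isinstance(segment, Segment) else segment
    return np.asarray(x, dtype=float)


def _safe_skew(x: np.ndarray) -> float:
    if np.std(x) == 0:
        return 0.0
    return float(sps.skew(x))


def _safe_kurtosis(x: np.ndarray) -> float:
    if np.std(x) == 0:
        return 0.0
    return float(sps.kurtosis(x))


def time_features(segment) -> dict[str, float]:
    """The 8 time-domain features.

    ``diff`` is the sum of successive differences (telescopes to
    last - first), ``pulseindicator`` is max/mean and ``cumsum`` the total
    sum of the samples.  Moments of a zero-variance signal are 0 by
    convention.
    """
    x = _segment_array(segment)
    mean = float(np.mean(x))
    return {
        "mean": mean,
        "std": float(np.std(x)),
        "mad": float(np.median(np.abs(x - np.median(x)))),
        "diff": float(x[-1] - x[0]),
        "skew": _safe_skew(x),
        "kurtosis": _safe_kurtosis(x),
        "pulseindicator": float(np.max(x) / mean) if mean != 0 else 0.0,
        "cumsum": float(np.sum(x)),
    }


def spectral_band_energies(
    segment,
    band_edges: tuple[float, ...] | None = None,
    sampling_rate: float | None = None,
) -> dict[str, float]:
    """Band energies of the one-sided power spectrum of the demeaned signal.

    Bands are half-open intervals ``(lo, hi]`` over the edge sequence; when
    the four bands tile (0, Nyquist] their energies sum to the total
    spectral energy exactly.

    Raises
    ------
    ValueError
        On malformed band edges.
    """
    x = _segment_array(segment)
    fs = sampling_rate or getattr(segment, "sampling_rate", 4.0)
    edges = tuple(band_edges or FeatureConfig().band_edges)
    if len(edges) != len(SPECTRAL_FEATURES) + 1:
        raise ValueError("band_edges must supply 5 edges for 4 bands")
    if any(b <= a for a, b in zip(edges, edges[1:])) or edges[0] < 0:
        raise ValueError(f"band_edges must increase strictly from >= 0: {edges}")
    if edges[-1] > fs / 2 + 1e-9:
        raise ValueError("band edges exceed the Nyquist frequency")
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    power = np.abs(np.fft.rfft(x - np.mean(x))) ** 2
    out = {}
    for name, lo, hi in zip(SPECTRAL_FEATURES, edges, edges[1:]):
        sel = (freqs > lo) & (freqs <= hi)
        out[name] = float(np.sum(power[sel]))
    return out


def autocorrelation(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Normalized (statistical) autocorrelation at lags 1..n_lags.

    ``r[k-1] = sum((x_i - xbar)(x_{i+k} - xbar)) / sum((x_i - xbar)^2)``;
    all zeros for a zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    xc = x - np.mean(x)
    denom = float(np.dot(xc, xc))
    if denom == 0:
        return np.zeros(n_lags)
    return np.array([np.dot(xc[:-k], xc[k:]) / denom for k in range(1, n_lags + 1)])


def autocorr_features(segment, n_lags: int = 240) -> dict[str, float]:
    """Statistics of the local extrema of the autocorrelation function.

    Interior strict local maxima and minima of r(1..n_lags) are located;
    the features are the combined extremum count and the sum, median and
    standard deviation of each extremum family (0 for empty families).

    Raises
    ------
    ValueError
        If fewer than 3 lags are requested or the segment is too short.
    """
    if n_lags < 3:
        raise ValueError("need at least 3 lags")
    x = _segment_array(segment)
    if x.size <= n_lags:
        raise ValueError(f"segment length {x.size} must exceed n_lags {n_lags}")
    r = autocorrelation(x, n_lags)
    interior = r[1:-1]
    is_max = (interior > r[:-2]) & (interior > r[2:])
    is_min = (interior < r[:-2]) & (interior < r[2:])
    maxima, minima = interior[is_max], interior[is_min]

    def _stats(v: np.ndarray) -> tuple[float, float, float]:
        if v.size == 0:
            return 0.0, 0.0, 0.0
        return float(np.sum(v)), float(np.median(v)), float(np.std(v))

    mx_sum, mx_med, mx_std = _stats(maxima)
    mn_sum, mn_med, mn_std = _stats(minima)
    return {
        "MAX_MINS": float(maxima.size + minima.size),
        "MAX_SUM": mx_sum,
        "MAX_MEDIAN": mx_med,
        "MAX_STD": mx_std,
        "MIN_SUM": mn_sum,
        "MIN_MEDIAN": mn_med,
        "MIN_STD": mn_std,
    }


def _signed_power(x: np.ndarray, p) -> np.ndarray:
    return np.sign(x) * np.abs(x) ** p


def emg_features(segment, config: FeatureConfig | None = None) -> dict[str, float]:
    """The 36 EMG-inspired waveform descriptors.

    Amplitude-type features (iemg, mav, ae, ssi, ld, ...) act on the raw
    bpm values; crossing-type features with a deadband (zc, fzc, ssc, wa,
    myop) act on the mean-removed signal so they remain informative for a
    strictly positive series, and the deadband itself is
    ``deadband_factor * std`` — both choices keep these features invariant
    under a constant bpm offset.
    """
    cfg = config or FeatureConfig()
    x = _segment_array(segment)
    n = x.size
    d = np.diff(x)
    mean = float(np.mean(x))
    std = float(np.std(x))
    xc = x - mean
    db = cfg.deadband_factor * std
    idx = np.arange(n)

    # position-dependent exponents/weights of the "enhanced"/"modified" family
    p_enh = np.where((idx >= 0.2 * n) & (idx <= 0.8 * n), 0.75, 0.5)
    i_d = np.arange(1, n)
    p_enh_d = np.where((i_d >= 0.2 * n) & (i_d <= 0.8 * n), 0.75, 0.5)
    w_mmav = np.where((idx >= 0.25 * n) & (idx <= 0.75 * n), 1.0, 0.5)
    w_mmav2 = np.where(
        idx < 0.25 * n, 4.0 * idx / n,
        np.where(idx > 0.75 * n, 4.0 * (n - idx) / n, 1.0),
    )

    cov = std / abs(mean) if mean != 0 else 0.0
    damv = float(np.mean(np.abs(d))) if d.size else 0.0
    dasdv = float(np.sqrt(np.mean(d ** 2))) if d.size else 0.0
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]

    zc = int(np.sum((xc[:-1] * xc[1:] < 0) & (np.abs(np.diff(xc)) >= db)))
    fzc = int(np.sum(
        ((xc[:-1] > db) & (xc[1:] < -db)) | ((xc[:-1] < -db) & (xc[1:] > db))
    ))
    ssc_inner = (xc[1:-1] - xc[:-2]) * (xc[1:-1] - xc[2:])
    ssc = int(np.sum(ssc_inner > db))
    wa = int(np.sum(np.abs(d) > db))
    myop = float(np.mean(np.abs(xc) > db))

    if std > 0:
        rho, _sigma = yule_walker(x, order=cfg.ar_order, method="mle")
        ar1 = float(rho[0])
    else:
        ar1 = 0.0  # AR fit undefined on a constant signal

    return {
        "emav": float(np.mean(np.abs(x) ** p_enh)),
        "ewl": float(np.mean(np.abs(d) ** p_enh_d)) if d.size else 0.0,
        "fzc": float(fzc),
        "asm": float(abs(np.sum(_signed_power(x, p_enh)))),
        "ass": float(abs(np.sum(_signed_power(x, 0.5)))),
        "msr": float(np.mean(_signed_power(x, 0.5))),
        "ltkeo": float(np.log(abs(np.sum(psi)) + _EPS)),
        "lcov": float(np.log(cov + _EPS)),
        "card": float(np.unique(np.round(x, cfg.card_decimals)).size),
        "ldasdv": float(np.log(dasdv + _EPS)),
        "ldamv": float(np.log(damv + _EPS)),
        "dvarv": float(np.sum(d ** 2) / (n - 2)) if n > 2 else 0.0,
        "vo": float(np.mean(np.abs(x) ** cfg.vo_order) ** (1.0 / cfg.vo_order)),
        "tm": float(abs(np.mean(x ** cfg.tm_order))),
        "damv": damv,
        "ar": ar1,
        "mad.1": float(np.mean(np.abs(x - mean))),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "cov": float(cov),
        "ae": float(np.mean(x ** 2)),
        "iemg": float(np.sum(np.abs(x))),
        "mav": float(np.mean(np.abs(x))),
        "ssc": float(ssc),
        "zc": float(zc),
        "wl": float(np.sum(np.abs(d))),
        "rms": float(np.sqrt(np.mean(x ** 2))),
        "aac": damv,
        "dasdv": dasdv,
        "ld": float(np.exp(np.mean(np.log(np.abs(x) + _EPS)))),
        "mmav": float(np.mean(w_mmav * np.abs(x))),
        "mmav2": float(np.mean(w_mmav2 * np.abs(x))),
        "myop": myop,
        "ssi": float(np.sum(x ** 2)),
        "vare": float(np.sum(x ** 2) / (n - 1)) if n > 1 else 0.0,
        "wa": float(wa),
        "mfl": float(np.log10(np.sqrt(np.sum(d ** 2)) + _EPS)),
    }


def estimate_baseline(
    segment,
    config: FeatureConfig | None = None,
    sampling_rate: float | None = None,
) -> BaselineCurve:
    """Estimate the baseline heart rate by iterative trimmed smoothing.

    The initial estimate is a centered three-minute moving *median* —
    robust to accelerations and decelerations, which occupy well under
    half of such a window.  Then, iteratively: samples deviating more than
    ``baseline_trim_bpm`` from the current baseline are replaced by the
    current baseline value (so excluded excursions cannot drag the
    estimate), and the result is re-smoothed with a one-minute moving
    average.  Iteration stops when the maximum baseline change
    drops below ``baseline_tol_bpm`` or after ``baseline_max_iter``
    rounds.  The output is clipped to the physiological range
    [50, 200] bpm.
    """
    cfg = config or FeatureConfig()
    x = _segment_array(segment)
    fs = sampling_rate or getattr(segment, "sampling_rate", 4.0)
    win = max(3, int(round(cfg.baseline_smooth_seconds * fs)))
    med_win = max(3, int(round(cfg.baseline_median_seconds * fs)))

    def smooth(v: np.ndarray) -> np.ndarray:
        return uniform_filter1d(v, size=win, mode="nearest")

    baseline = median_filter(x, size=min(med_win, x.size), mode="nearest")
    deltas: list[float] = []
    for _ in range(cfg.baseline_max_iter):
        keep = np.abs(x - baseline) <= cfg.baseline_trim_bpm
        if keep.sum() < 2:
            break
        filled = np.where(keep, x, baseline)
        new = smooth(filled)
        delta = float(np.max(np.abs(new - baseline)))
        deltas.append(delta)
        baseline = new
        if delta < cfg.baseline_tol_bpm:
            break
    return BaselineCurve(values=np.clip(baseline, 50.0, 200.0), iteration_deltas=deltas)


def morphological_features(
    segment,
    baseline: BaselineCurve | np.ndarray,
    config: FeatureConfig | None = None,
    sampling_rate: float | None = None,
) -> tuple[EventList, dict[str, float]]:
    """Detect accelerations/decelerations and derive 13 event features.

    An acceleration (deceleration) is an excursion more than ``event_bpm``
    above (below) the baseline sustained for at least
    ``event_min_seconds``; a deceleration lasting ``prolonged_seconds`` or
    more is flagged prolonged.  Event amplitudes are peak deviations from
    the baseline.  Statistics over empty event sets are 0.

    Raises
    ------
    ValueError
        If baseline and segment lengths differ.
    """
    cfg = config or FeatureConfig()
    x = _segment_array(segment)
    fs = sampling_rate or getattr(segment, "sampling_rate", 4.0)
    b = baseline.values if isinstance(baseline, BaselineCurve) else np.asarray(baseline)
    if b.shape != x.shape:
        raise ValueError("baseline and segment are not aligned")
    dev = x - b
    # light smoothing before thresholding so short-term variability does
    # not split one sustained excursion into several sub-threshold runs
    ev_win = max(1, int(round(cfg.event_smooth_seconds * fs)))
    dev_s = uniform_filter1d(dev, size=ev_win, mode="nearest")
    min_len = int(round(cfg.event_min_seconds * fs))
    prolonged_len = cfg.prolonged_seconds

    from .preprocessing import _runs  # same run-finding helper

    def find(condition: np.ndarray) -> list[Event]:
        events = []
        for start, stop in _runs(condition):
            if stop - start < min_len:
                continue
            dur = (stop - start) / fs
            events.append(Event(
                start=int(start), end=int(stop),
                peak_deviation=float(np.max(np.abs(dev[start:stop]))),
                duration_s=dur,
                prolonged=dur >= prolonged_len,
            ))
        return events

    accs = find(dev_s > cfg.event_bpm)
    decs = find(dev_s < -cfg.event_bpm)

    def mean_of(vals) -> float:
        vals = list(vals)
        return float(np.mean(vals)) if vals else 0.0

    dec_durs = np.array([e.duration_s for e in decs])
    dec_cards = [
        float(np.unique(np.round(x[e.start:e.end], cfg.card_decimals)).size)
        for e in decs
    ]
    dec_kurts = [_safe_kurtosis(x[e.start:e.end]) for e in decs]
    features = {
        "num_acc": float(len(accs)),
        "num_dec": float(len(decs)),
        "num_prolonged_dec": float(sum(e.prolonged for e in decs)),
        "avg_acc_amp": mean_of(e.peak_deviation for e in accs),
        "avg_dec_amp": mean_of(e.peak_deviation for e in decs),
        "avg_acc_dur": mean_of(e.duration_s for e in accs),
        "avg_dec_dur": mean_of(e.duration_s for e in decs),
        "iqr_dec_dur": (
            float(np.percentile(dec_durs, 75) - np.percentile(dec_durs, 25))
            if dec_durs.size else 0.0
        ),
        "skew_dec_dur": _safe_skew(dec_durs) if dec_durs.size >= 2 else 0.0,
        "var_dec_dur": float(np.var(dec_durs)) if dec_durs.size else 0.0,
        "avg_dec_card": mean_of(dec_cards),
        "std_dec_kurt": float(np.std(dec_kurts)) if len(dec_kurts) >= 2 else 0.0,
        "total_dec_time_fraction": float(sum(e.end - e.start for e in decs) / x.size),
    }
    return EventList(accelerations=accs, decelerations=decs), features


def extract_all(segment: Segment, config: FeatureConfig | None = None) -> FeatureVector:
    """Concatenate the five feature families into the 68-value vector."""
    cfg = config or FeatureConfig()
    fs = getattr(segment, "sampling_rate", 4.0)
    x = _segment_array(segment)
    values: dict[str, float] = {}
    values.update(time_features(x))
    values.update(spectral_band_energies(x, cfg.band_edges, fs))
    values.update(autocorr_features(x, cfg.n_lags))
    values.update(emg_features(x, cfg))
    baseline = estimate_baseline(x, cfg, fs)
    _, morph = morphological_features(x, baseline, cfg, fs)
    values.update(morph)
    ordered = np.array([values[name] for name in FEATURE_NAMES])
    return FeatureVector(
        names=FEATURE_NAMES,
        values=ordered,
        record_id=getattr(segment, "record_id", ""),
        segment_index=getattr(segment, "segment_index", 0),
        label=getattr(segment, "label", None),
    )
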