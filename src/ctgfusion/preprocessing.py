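"""Stage I: artifact repair and segmentation of FHR recordings.

Doppler-derived FHR traces show three artifact families: missing runs
(encoded as 0 bpm), out-of-range spikes (above 200 or below 50 bpm, often
maternal-heart or sensor artifacts) and single-sample instabilities (jumps
larger than 25 bpm between adjacent samples, physiologically implausible at
4 Hz).  Cleaning applies three interpolation rules in a fixed order:

1. zero runs shorter than 15 s are linearly interpolated between their
   flanking valid samples; longer runs are dropped outright;
2. out-of-range samples are replaced by shape-preserving (monotone cubic
   Hermite) interpolation anchored on the surrounding in-range samples,
   which cannot overshoot the physiological range;
3. samples that jump more than 25 bpm from the previously retained sample
   are replaced by linear interpolation to the next retained sample.

Cleaned recordings are then cut into fixed-length 10-minute windows.
Windows tile each valid stretch anchored at its *end*, so "the latest"
window always ends at the last valid sample — late-in-labor data carries
the most diagnostic weight.  Normal and Suspicious recordings contribute
only their latest valid window; Pathological recordings contribute every
valid window, compensating the class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .signal_io import ClassLabel, FHRRecord

__all__ = [
    "MaskFlag",
    "CleanParams",
    "SegmentPolicy",
    "CleanedSignal",
    "Segment",
    "UnusableRecordError",
    "clean_fhr",
    "segment_signal",
]


class UnusableRecordError(ValueError):
    """Recording has no usable signal (e.g. all samples missing)."""


class MaskFlag:
    """Per-sample provenance flags of a cleaned signal."""

    CLEAN = 0
    GAP_FILLED = 1
    SPIKE_FILLED = 2
    UNSTABLE_FILLED = 3
    DROPPED = 4


@dataclass(frozen=True)
class CleanParams:
    """Cleaning rule constants (bpm thresholds and gap limit in seconds)."""

    gap_limit_seconds: float = 15.0
    bpm_low: float = 50.0
    bpm_high: float = 200.0
    instability_bpm: float = 25.0
    #: after this many seconds of consecutive instability rejections the
    #: current sample is accepted as the new reference — a sustained level
    #: shift is real signal (e.g. a deceleration), not a point artifact.
    reanchor_seconds: float = 5.0


@dataclass(frozen=True)
class SegmentPolicy:
    """Windowing policy: window length and the interpolation validity cap."""

    window_seconds: float = 600.0
    validity_cap: float = 0.20


@dataclass
class CleanedSignal:
    samples: np.ndarray
    mask: np.ndarray  # MaskFlag per sample
    sampling_rate: float

    @property
    def retained(self) -> np.ndarray:
        return self.mask != MaskFlag.DROPPED


@dataclass
class Segment:
    """One cleaned 10-minute window carrying its recording's label."""

    samples: np.ndarray
    record_id: str
    segment_index: int
    label: ClassLabel | None
    interpolated_fraction: float
    sampling_rate: float = 4.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def _runs(condition: np.ndarray):
    """Yield (start, stop) of maximal True runs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], condition.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def clean_fhr(record: FHRRecord, params: CleanParams | None = None) -> CleanedSignal:
    """Apply the three interpolation rules, in order, to one recording.

    Returns a :class:`CleanedSignal` whose mask records which rule fired on
    each sample.  After cleaning every non-dropped sample lies inside
    ``[bpm_low, bpm_high]``.

    Raises
    ------
    UnusableRecordError
        If the signal is entirely missing.
    ValueError
        If the sampling rate is not positive.
    """
    params = params or CleanParams()
    if not record.sampling_rate > 0:
        raise ValueError("sampling_rate must be > 0")
    fs = record.sampling_rate
    x = record.samples.astype(float).copy()
    n = x.size
    if np.all(x == 0):
        raise UnusableRecordError(f"{record.record_id}: all samples missing")
    mask = np.full(n, MaskFlag.CLEAN, dtype=np.int8)

    # Rule (a): zero runs. Short runs are bridged linearly; long or
    # edge-touching runs (no flank on one side) are dropped.
    gap_limit = params.gap_limit_seconds * fs
    anchor_ok = (x >= params.bpm_low) & (x <= params.bpm_high)  # excludes 0
    for start, stop in _runs(x == 0):
        length = stop - start
        li = start - 1
        while li >= 0 and not anchor_ok[li]:
            li -= 1
        ri = stop
        while ri < n and not anchor_ok[ri]:
            ri += 1
        if length < gap_limit and li >= 0 and ri < n:
            t = (np.arange(start, stop) - li) / (ri - li)
            x[start:stop] = x[li] + t * (x[ri] - x[li])
            mask[start:stop] = MaskFlag.GAP_FILLED
        else:
            mask[start:stop] = MaskFlag.DROPPED

    # Rule (b): out-of-range spikes among non-dropped samples, repaired by
    # monotone cubic Hermite interpolation over the in-range anchors (local:
    # each repaired value depends on two anchors per side and cannot leave
    # the anchors' envelope).
    live = mask != MaskFlag.DROPPED
    in_range = (x >= params.bpm_low) & (x <= params.bpm_high)
    bad = live & ~in_range
    good = live & in_range
    if np.any(bad):
        gi = np.flatnonzero(good)
        bi = np.flatnonzero(bad)
        if gi.size >= 2:
            interior = (bi > gi[0]) & (bi < gi[-1])
            fill = bi[interior]
            if fill.size:
                x[fill] = PchipInterpolator(gi, x[gi])(fill)
                mask[fill] = MaskFlag.SPIKE_FILLED
            edge = bi[~interior]
        else:
            edge = bi
        if len(edge):
            mask[edge] = MaskFlag.DROPPED

    # Rule (c): instability. Walk the retained samples; a sample deviating
    # more than instability_bpm from the previously accepted one is flagged
    # and later bridged linearly between accepted neighbours.
    live_idx = np.flatnonzero(mask != MaskFlag.DROPPED)
    if live_idx.size:
        accepted = [live_idx[0]]
        unstable = []
        ref = x[live_idx[0]]
        reanchor = max(1, int(round(params.reanchor_seconds * fs)))
        rejected_run = 0
        for i in live_idx[1:]:
            if abs(x[i] - ref) > params.instability_bpm and rejected_run < reanchor:
                unstable.append(i)
                rejected_run += 1
            else:
                ref = x[i]
                accepted.append(i)
                rejected_run = 0
        if unstable:
            unstable = np.asarray(unstable)
            accepted = np.asarray(accepted)
            x[unstable] = np.interp(unstable, accepted, x[accepted])
            mask[unstable] = MaskFlag.UNSTABLE_FILLED

    return CleanedSignal(samples=x, mask=mask, sampling_rate=fs)


def segment_signal(
    cleaned: CleanedSignal,
    label: ClassLabel | None,
    policy: SegmentPolicy | None = None,
    record_id: str = "",
) -> list[Segment]:
    """Cut a cleaned signal into valid, non-overlapping 10-minute windows.

    Candidate windows tile each dropped-free stretch anchored at its end;
    a window is valid when at most ``validity_cap`` of its samples were
    interpolated.  Normal and Suspicious recordings return only the latest
    valid window; Pathological recordings return all of them.  May return
    an empty list.
    """
    policy = policy or SegmentPolicy()
    fs = cleaned.sampling_rate
    window_len = int(round(policy.window_seconds * fs))
    windows: list[tuple[int, int]] = []
    for start, stop in _runs(cleaned.retained):
        k = (stop - start) // window_len
        # anchored at the stretch end, in temporal order
        for j in range(k, 0, -1):
            windows.append((stop - j * window_len, stop - (j - 1) * window_len))
    windows.sort()

    valid: list[tuple[int, int, float]] = []
    for a, b in windows:
        frac = float(np.mean(cleaned.mask[a:b] != MaskFlag.CLEAN))
        if frac <= policy.validity_cap:
            valid.append((a, b, frac))

    if label is not None and ClassLabel(label) is not ClassLabel.PATHOLOGICAL:
        valid = valid[-1:]

    return [
        Segment(
            samples=cleaned.samples[a:b],
            record_id=record_id,
            segment_index=i,
            label=None if label is None else ClassLabel(label),
            interpolated_fraction=frac,
            sampling_rate=fs,
        )
        for i, (a, b, frac) in enumerate(valid)
    ]
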