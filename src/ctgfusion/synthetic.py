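"""Class-conditional synthetic FHR recordings with pH metadata.

The generator emulates the statistical structure the pipeline exercises: a
slowly drifting baseline around a class-dependent mean, band-limited
short-term variability (0.03-1 Hz filtered noise), raised-cosine
acceleration and deceleration events at class-dependent rates and depths,
plus the two artifact families the cleaning stage repairs (zero-dropout
runs and out-of-range spikes).  Each recording draws a cord pH uniformly
inside its class's label interval (with a 0.01 guard band off the
boundaries), so labels and pH are always mutually consistent.

Clinical motivation for the defaults: compromised fetuses tend toward a
higher, flatter baseline (reduced variability) with frequent, deep,
occasionally prolonged decelerations and few accelerations; healthy ones
show lively variability and accelerations with rare shallow dips.  The
default cohort reproduces the 351/114/37 Normal/Suspicious/Pathological
imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import ClassLabel, FHRRecord, label_from_ph

__all__ = ["ClassParams", "SimulationParams", "default_params",
           "simulate_record", "simulate_dataset", "DEFAULT_COUNTS"]

DEFAULT_COUNTS = (351, 114, 37)


@dataclass(frozen=True)
class ClassParams:
    """Per-class generator settings (bpm, seconds, events per 10 min)."""

    baseline_mean: float
    baseline_sd: float
    variability_bpm: float
    accel_rate: float
    accel_amp: float
    accel_dur_s: float
    decel_rate: float
    decel_depth: float
    decel_dur_s: float
    prolonged_prob: float
    ph_low: float
    ph_high: float


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-level generator settings; rates are per 10 minutes."""

    per_class: dict = field(default_factory=dict)
    variability_band: tuple[float, float] = (0.03, 1.0)
    drift_amp_bpm: tuple[float, float] = (2.0, 5.0)
    drift_period_s: tuple[float, float] = (240.0, 480.0)
    dropout_rate: float = 1.0
    dropout_len_s: tuple[float, float] = (2.0, 10.0)
    max_dropouts: int = 3
    spike_rate: float = 2.0
    max_spikes: int = 6
    duration_s: float = 660.0
    sampling_rate: float = 4.0
    #: probability that a recording's trace morphology is drawn from an
    #: adjacent severity class while its pH (hence label) stays true —
    #: cord pH is an outcome proxy only loosely coupled to the trace, so
    #: real cohorts contain such dissociated cases and classes overlap.
    atypical_prob: float = 0.25

    def __post_init__(self) -> None:
        for cls, cp in self.per_class.items():
            for ph in (cp.ph_low, cp.ph_high):
                if label_from_ph(ph) is not ClassLabel(cls):
                    raise ValueError(
                        f"pH range ({cp.ph_low}, {cp.ph_high}) does not map to {cls}"
                    )


def default_params() -> SimulationParams:
    return SimulationParams(per_class={
        ClassLabel.NORMAL: ClassParams(
            baseline_mean=135.0, baseline_sd=8.0, variability_bpm=6.0,
            accel_rate=2.0, accel_amp=20.0, accel_dur_s=25.0,
            decel_rate=0.3, decel_depth=18.0, decel_dur_s=25.0,
            prolonged_prob=0.0, ph_low=7.22, ph_high=7.45,
        ),
        ClassLabel.SUSPICIOUS: ClassParams(
            baseline_mean=142.0, baseline_sd=8.0, variability_bpm=4.0,
            accel_rate=1.0, accel_amp=18.0, accel_dur_s=22.0,
            decel_rate=1.5, decel_depth=25.0, decel_dur_s=35.0,
            prolonged_prob=0.05, ph_low=7.06, ph_high=7.19,
        ),
        ClassLabel.PATHOLOGICAL: ClassParams(
            baseline_mean=150.0, baseline_sd=8.0, variability_bpm=2.0,
            accel_rate=0.3, accel_amp=17.0, accel_dur_s=20.0,
            decel_rate=4.0, decel_depth=35.0, decel_dur_s=45.0,
            prolonged_prob=0.15, ph_low=6.85, ph_high=7.04,
        ),
    })


def _band_limited_noise(rng, n, fs, band, target_sd):
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[(freqs < band[0]) | (freqs > band[1])] = 0.0
    x = np.fft.irfft(spectrum, n)
    sd = np.std(x)
    return x * (target_sd / sd) if sd > 0 else x


def _bump(n, center, half_width, amp):
    """Raised-cosine excursion added in place support [center-hw, center+hw]."""
    lo = max(0, int(center - half_width))
    hi = min(n, int(center + half_width))
    t = np.arange(lo, hi)
    return lo, hi, amp * 0.5 * (1 + np.cos(np.pi * (t - center) / half_width))


def simulate_record(
    label: ClassLabel,
    params: SimulationParams | None = None,
    seed: int = 0,
    duration_s: float | None = None,
    record_id: str | None = None,
) -> FHRRecord:
    """Generate one labeled recording, fully determined by ``seed``.

    Raises
    ------
    ValueError
        If the duration cannot hold a single 10-minute segment.
    """
    params = params or default_params()
    label = ClassLabel(label)
    duration = float(duration_s if duration_s is not None else params.duration_s)
    if duration < 600:
        raise ValueError("duration_s must be >= 600 (one segment)")
    fs = params.sampling_rate
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)

    # Trace morphology follows the true class, except for "atypical"
    # recordings whose morphology comes from an adjacent severity class.
    morph_label = label
    if rng.uniform() < params.atypical_prob:
        if label is ClassLabel.SUSPICIOUS:
            shift = -1 if rng.uniform() < 0.5 else 1
        else:
            shift = 1 if label is ClassLabel.NORMAL else -1
        morph_label = ClassLabel(int(label) + shift)
    cp_ph = params.per_class[label]
    cp = params.per_class[morph_label]

    base = float(np.clip(rng.normal(cp.baseline_mean, cp.baseline_sd), 115, 165))
    amp = rng.uniform(*params.drift_amp_bpm)
    period = rng.uniform(*params.drift_period_s)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    x = base + amp * np.sin(2 * np.pi * t / period + phase)
    x = x + _band_limited_noise(rng, n, fs, params.variability_band, cp.variability_bpm)

    scale = duration / 600.0
    for _ in range(rng.poisson(cp.accel_rate * scale)):
        dur = rng.uniform(16.0, max(17.0, cp.accel_dur_s * 1.4)) * fs
        lo, hi, bump = _bump(n, rng.uniform(dur, n - dur), dur / 2,
                             cp.accel_amp * rng.uniform(0.9, 1.2))
        x[lo:hi] += bump
    n_dec = rng.poisson(cp.decel_rate * scale)
    for _ in range(n_dec):
        if rng.uniform() < cp.prolonged_prob:
            dur = rng.uniform(185.0, 240.0) * fs
        else:
            dur = rng.uniform(18.0, max(19.0, cp.decel_dur_s * 1.4)) * fs
        lo, hi, bump = _bump(n, rng.uniform(dur, n - dur), dur / 2,
                             cp.decel_depth * rng.uniform(0.9, 1.2))
        x[lo:hi] -= bump
    x = np.clip(x, 55.0, 198.0)

    # artifacts: short zero-dropout runs away from the edges, then spikes
    margin = int(5 * fs)
    n_drop = min(rng.poisson(params.dropout_rate * scale), params.max_dropouts)
    starts: list[int] = []
    for _ in range(n_drop):
        run = int(rng.uniform(*params.dropout_len_s) * fs)
        for _attempt in range(20):
            s = int(rng.integers(margin, n - margin - run))
            if all(abs(s - s0) > run + 80 for s0 in starts):
                starts.append(s)
                x[s:s + run] = 0.0
                break
    n_spk = min(rng.poisson(params.spike_rate * scale), params.max_spikes)
    if n_spk:
        pos = rng.integers(margin, n - margin, n_spk)
        x[pos] = rng.uniform(205.0, 230.0, n_spk)

    ph = float(rng.uniform(cp_ph.ph_low, cp_ph.ph_high))
    return FHRRecord(
        record_id=record_id or f"sim-{label.name.lower()}-{seed}",
        samples=x,
        sampling_rate=fs,
        ph=ph,
        label=label,
    )


def simulate_dataset(
    counts: tuple[int, int, int] = DEFAULT_COUNTS,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> list[FHRRecord]:
    """Generate a cohort with the given per-class counts (default 351/114/37)."""
    params = params or default_params()
    total = int(sum(counts))
    child_seeds = np.random.SeedSequence(seed).generate_state(total) & 0x7FFFFFFF
    records = []
    i = 0
    for label, count in zip(ClassLabel, counts):
        for j in range(count):
            records.append(simulate_record(
                label, params, seed=int(child_seeds[i]),
                record_id=f"sim-{label.name.lower()}-{j:04d}",
            ))
            i += 1
    return records
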