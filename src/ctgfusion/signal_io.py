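"""Reading and writing fetal heart rate (FHR) recordings and feature tables.

An FHR recording is a beats-per-minute series sampled at 4 Hz, where the
value 0 encodes a missing sample (sensor dropout).  Each recording carries
an optional umbilical-artery pH, from which the three-class outcome label
(Normal / Suspicious / Pathological) is derived: low cord pH indicates
possible hypoxia-driven metabolic acidosis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClassLabel",
    "FHRRecord",
    "ParseError",
    "label_from_ph",
    "read_fhr_table",
    "write_feature_table",
    "read_feature_table",
]

#: pH strictly above this value -> Normal.
PH_NORMAL_ABOVE = 7.20
#: pH at or below this value -> Pathological.
PH_PATHOLOGICAL_BELOW = 7.05


class ParseError(ValueError):
    """A delimited signal file contained a cell that could not be parsed."""


class ClassLabel(enum.IntEnum):
    """Three-class fetal state with a fixed ordinal severity order.

    The ordinal order ``Normal < Suspicious < Pathological`` is relied on
    everywhere: probability vectors, confusion matrices and weighted kappa
    all use this class order.
    """

    NORMAL = 0
    SUSPICIOUS = 1
    PATHOLOGICAL = 2

    @property
    def display(self) -> str:
        return self.name.capitalize()

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown class label {name!r}") from None


def label_from_ph(ph: float) -> ClassLabel:
    """Map umbilical-artery pH to the three-class outcome label.

    pH above 7.20 is Normal and pH at or below 7.05 is Pathological;
    everything between is Suspicious.  The two boundary values fall on the
    more severe side (7.20 -> Suspicious, 7.05 -> Pathological), consistent
    with the pathological-first priority of the decision rule downstream.

    Raises
    ------
    ValueError
        If ``ph`` is non-finite or not positive.
    """
    ph = float(ph)
    if not math.isfinite(ph) or ph <= 0:
        raise ValueError(f"pH must be finite and positive, got {ph!r}")
    if ph > PH_NORMAL_ABOVE:
        return ClassLabel.NORMAL
    if ph <= PH_PATHOLOGICAL_BELOW:
        return ClassLabel.PATHOLOGICAL
    return ClassLabel.SUSPICIOUS


@dataclass
class FHRRecord:
    """One recording: a 4 Hz bpm series with optional pH and class label.

    ``samples`` may contain 0 (missing) and out-of-range artifacts; the
    preprocessing stage repairs or drops those.
    """

    record_id: str
    samples: np.ndarray
    sampling_rate: float = 4.0
    ph: float | None = None
    label: ClassLabel | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if np.any(self.samples < 0):
            raise ValueError("bpm samples must be >= 0 (0 encodes missing)")
        if self.ph is not None and self.label is not None:
            if label_from_ph(self.ph) is not ClassLabel(self.label):
                raise ValueError(
                    f"label {self.label!r} inconsistent with pH {self.ph}"
                )

    @property
    def duration_seconds(self) -> float:
        return self.samples.size / self.sampling_rate

    def resolved_label(self) -> ClassLabel | None:
        if self.label is not None:
            return ClassLabel(self.label)
        if self.ph is not None:
            return label_from_ph(self.ph)
        return None


def read_fhr_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sampling_rate: float = 4.0,
    delimiter: str | None = None,
) -> FHRRecord:
    """Read one recording from a delimited text file.

    The file has one numeric signal column; ``column_map`` names it under
    the key ``"signal"`` and may also name ``"ph"`` and ``"record_id"``
    metadata columns (their first non-empty value is used).  Blank signal
    cells become 0, the missing-sample encoding.

    Raises
    ------
    ParseError
        On a non-numeric signal cell (the message names the row).
    ValueError
        On an empty file.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     skip_blank_lines=False)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    column_map = dict(column_map or {})
    signal_col = column_map.get("signal", df.columns[0])
    if signal_col not in df.columns:
        raise ValueError(f"{path}: no column named {signal_col!r}")

    raw = df[signal_col].astype(str).str.strip()
    samples = np.zeros(len(raw), dtype=float)
    for i, cell in enumerate(raw):
        if cell == "" or cell.lower() == "nan":
            continue  # missing -> 0
        try:
            samples[i] = float(cell)
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric signal value {cell!r} at data row {i}"
            ) from None

    def _first_value(key: str) -> str | None:
        col = column_map.get(key)
        if col is None or col not in df.columns:
            return None
        vals = df[col].astype(str).str.strip()
        nonempty = vals[vals != ""]
        return None if nonempty.empty else str(nonempty.iloc[0])

    ph_text = _first_value("ph")
    ph = float(ph_text) if ph_text is not None else None
    record_id = _first_value("record_id") or path.stem
    label = label_from_ph(ph) if ph is not None else None
    return FHRRecord(
        record_id=record_id,
        samples=samples,
        sampling_rate=sampling_rate,
        ph=ph,
        label=label,
    )


def write_feature_table(feature_vectors, path: str | Path) -> None:
    """Write segment feature vectors as a CSV with a fixed column order.

    Columns are the 68 ordered feature names followed by ``record_id``,
    ``segment_index`` and ``label``.  Values round-trip exactly through
    :func:`read_feature_table` (Python float repr is written).

    Raises
    ------
    ValueError
        If the vectors do not all share the same ordered feature names.
    """
    path = Path(path)
    feature_vectors = list(feature_vectors)
    if feature_vectors:
        names = feature_vectors[0].names
        for fv in feature_vectors[1:]:
            if fv.names != names:
                raise ValueError("feature vectors have inconsistent feature names")
    else:
        from .features import FEATURE_NAMES

        names = FEATURE_NAMES
    rows = []
    for fv in feature_vectors:
        row = {name: repr(float(v)) for name, v in zip(names, fv.values)}
        row["record_id"] = fv.record_id
        row["segment_index"] = fv.segment_index
        row["label"] = ClassLabel(fv.label).display if fv.label is not None else ""
        rows.append(row)
    columns = list(names) + ["record_id", "segment_index", "label"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_feature_table(path: str | Path):
    """Read a feature table written by :func:`write_feature_table`."""
    from .features import FeatureVector

    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    meta = {"record_id", "segment_index", "label"}
    names = tuple(c for c in df.columns if c not in meta)
    out = []
    for _, row in df.iterrows():
        values = np.array([float(row[n]) for n in names])
        label = ClassLabel.from_name(row["label"]) if row["label"] else None
        out.append(
            FeatureVector(
                names=names,
                values=values,
                record_id=row["record_id"],
                segment_index=int(row["segment_index"]),
                label=label,
            )
        )
    return out
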