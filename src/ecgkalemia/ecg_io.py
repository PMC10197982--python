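"""Reading and writing ECG records.

Two on-disk dialects are supported:

* a minimal WFDB-style pairing of a plain-text header with a binary signal
  file packed in MIT-BIH Format 212 (two 12-bit two's-complement samples in
  three bytes, leads multiplexed frame by frame), and
* a plain CSV matrix (one column per lead, header row of lead names) for
  low-friction fixtures.

Amplitudes are held in memory in millivolts; the ADC gain (ADC units per mV)
and baseline offset recorded in the header make the conversion affine and
invertible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, RangeError, ValidationError

__all__ = [
    "ECGRecord",
    "PotassiumLabel",
    "STANDARD_LEADS",
    "pack_format212",
    "unpack_format212",
    "read_record",
    "write_record",
    "read_csv_record",
    "write_csv_record",
    "read_labels",
    "write_labels",
]

STANDARD_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

_ADC_MIN, _ADC_MAX = -2048, 2047
_DEFAULT_GAIN = 200.0  # ADC units per mV, MIT-BIH convention
_LABEL_PHASES = ("pre_dialysis", "post_dialysis", "synthetic")


@dataclass
class ECGRecord:
    """A multi-lead ECG signal in millivolts.

    Attributes
    ----------
    record_id : str
        Identifier used to join the record with its potassium label.
    fs : float
        Sampling frequency in Hz.
    lead_names : tuple of str
        Ordered lead names, a subset of the standard 12-lead set.
    signal : ndarray, shape (n_samples, n_leads)
        Amplitude in mV.
    gain : ndarray, shape (n_leads,)
        ADC units per mV per lead (used when writing Format 212).
    baseline_adc : ndarray, shape (n_leads,)
        ADC value corresponding to 0 mV per lead.
    """

    record_id: str
    fs: float
    lead_names: tuple
    signal: np.ndarray
    gain: np.ndarray = field(default=None)  # type: ignore[assignment]
    baseline_adc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (n_samples, n_leads)")
        n_leads = self.signal.shape[1]
        self.lead_names = tuple(self.lead_names)
        if len(self.lead_names) != n_leads:
            raise ValidationError(
                f"{len(self.lead_names)} lead names for {n_leads} signal columns"
            )
        if len(set(self.lead_names)) != n_leads:
            raise ValidationError("lead names must be unique")
        unknown = [l for l in self.lead_names if l not in STANDARD_LEADS]
        if unknown:
            raise ValidationError(f"unknown lead names: {unknown}")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite samples")
        if self.gain is None:
            self.gain = np.full(n_leads, _DEFAULT_GAIN)
        self.gain = np.asarray(self.gain, dtype=float)
        if self.baseline_adc is None:
            self.baseline_adc = np.zeros(n_leads)
        self.baseline_adc = np.asarray(self.baseline_adc, dtype=float)
        if self.gain.shape != (n_leads,) or self.baseline_adc.shape != (n_leads,):
            raise ValidationError("gain/baseline_adc must have one entry per lead")
        if np.any(self.gain <= 0):
            raise ValidationError("gain must be positive for every lead")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead as a 1-D mV series."""
        try:
            j = self.lead_names.index(name)
        except ValueError:
            raise ValidationError(f"record has no lead {name!r}") from None
        return self.signal[:, j]


@dataclass(frozen=True)
class PotassiumLabel:
    """Serum potassium measurement paired with one ECG record."""

    record_id: str
    k_mmol_per_l: float
    phase: str = "synthetic"

    def __post_init__(self) -> None:
        if not 1.0 <= self.k_mmol_per_l <= 10.0:
            raise ValidationError(
                f"potassium {self.k_mmol_per_l} mmol/L outside plausible range [1, 10]"
            )
        if self.phase not in _LABEL_PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")


# ---------------------------------------------------------------------------
# Format 212 packing
# ---------------------------------------------------------------------------

def pack_format212(samples: Sequence[int]) -> bytes:
    """Pack 12-bit two's-complement samples into MIT-BIH Format 212 bytes.

    Each consecutive pair (s1, s2) becomes three bytes: the low byte of s1;
    the high nibble of s2 shifted left 4 or-ed with the high nibble of s1;
    the low byte of s2. An odd-length input is padded with one zero sample.
    """
    arr = np.asarray(samples, dtype=np.int64)
    if arr.ndim != 1:
        raise ValidationError("samples must be one-dimensional")
    bad = np.nonzero((arr < _ADC_MIN) | (arr > _ADC_MAX))[0]
    if bad.size:
        i = int(bad[0])
        raise RangeError(
            f"sample {arr[i]} at index {i} outside 12-bit range [{_ADC_MIN}, {_ADC_MAX}]"
        )
    if arr.size % 2:
        arr = np.concatenate([arr, [0]])
    u = (arr & 0xFFF).astype(np.uint16)  # two's complement in 12 bits
    s1, s2 = u[0::2], u[1::2]
    out = np.empty(3 * s1.size, dtype=np.uint8)
    out[0::3] = s1 & 0xFF
    out[1::3] = ((s2 >> 8) << 4) | (s1 >> 8)
    out[2::3] = s2 & 0xFF
    return out.tobytes()


def unpack_format212(buf: bytes, n_samples: int) -> np.ndarray:
    """Inverse of :func:`pack_format212`; sign-extends 12-bit values."""
    if n_samples < 0:
        raise ValidationError("n_samples must be non-negative")
    n_pairs = (n_samples + 1) // 2
    if len(buf) < 3 * n_pairs:
        raise ParseError(
            f"buffer of {len(buf)} bytes too short for {n_samples} samples "
            f"(need {3 * n_pairs})"
        )
    b = np.frombuffer(buf, dtype=np.uint8, count=3 * n_pairs).astype(np.int64)
    b0, b1, b2 = b[0::3], b[1::3], b[2::3]
    s1 = ((b1 & 0x0F) << 8) | b0
    s2 = ((b1 & 0xF0) << 4) | b2
    out = np.empty(2 * n_pairs, dtype=np.int64)
    out[0::2], out[1::2] = s1, s2
    out[out >= 2048] -= 4096  # sign extension
    return out[:n_samples]


# ---------------------------------------------------------------------------
# WFDB-style header + Format-212 data files
# ---------------------------------------------------------------------------

def write_record(record: ECGRecord, header_path, data_path) -> None:
    """Write ``record`` as a text header plus a Format-212 signal file.

    mV amplitudes are quantised to the nearest ADC step at the record's
    per-lead gain; an amplitude that overflows the 12-bit ADC range raises
    :class:`RangeError` with a gain suggestion.
    """
    header_path, data_path = Path(header_path), Path(data_path)
    adc = np.rint(record.signal * record.gain + record.baseline_adc).astype(np.int64)
    if adc.min() < _ADC_MIN or adc.max() > _ADC_MAX:
        worst = np.abs(record.signal).max()
        max_gain = _ADC_MAX / worst if worst > 0 else float("inf")
        raise RangeError(
            f"amplitude {worst:.3g} mV overflows 12-bit ADC at the declared gain; "
            f"reduce gain below {max_gain:.1f} ADC/mV"
        )
    lines = [f"{record.record_id} {record.n_leads} {record.fs:g} {record.n_samples}"]
    for j, name in enumerate(record.lead_names):
        lines.append(
            f"{data_path.name} 212 {record.gain[j]:g} "
            f"{record.baseline_adc[j]:g} {name}"
        )
    header_path.write_text("\n".join(lines) + "\n")
    data_path.write_bytes(pack_format212(adc.reshape(-1)))  # frame-multiplexed


def read_record(header_path, data_path=None) -> ECGRecord:
    """Read a record written in the WFDB-style header + Format-212 dialect.

    If ``data_path`` is omitted it is taken from the header's per-lead
    filename, resolved relative to the header.
    """
    header_path = Path(header_path)
    lines = [
        ln.strip() for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ParseError(f"{header_path}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise ParseError(f"{header_path}: header line needs 'id n_leads fs n_samples'")
    record_id = head[0]
    try:
        n_leads, fs, n_samples = int(head[1]), float(head[2]), int(head[3])
    except ValueError as exc:
        raise ParseError(f"{header_path}: malformed header line: {exc}") from None
    if fs <= 0:
        raise ValidationError(f"{header_path}: fs must be positive, got {fs}")
    if len(lines) - 1 != n_leads:
        raise ParseError(
            f"{header_path}: header declares {n_leads} leads but lists {len(lines) - 1}"
        )
    lead_names, gains, baselines, data_names = [], [], [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) < 2:
            raise ParseError(f"{header_path}: malformed lead line {ln!r}")
        data_names.append(parts[0])
        fmt = parts[1]
        if fmt != "212":
            raise ParseError(f"unsupported signal format {fmt!r} (only 212)")
        gains.append(float(parts[2]) if len(parts) > 2 else _DEFAULT_GAIN)
        baselines.append(float(parts[3]) if len(parts) > 3 else 0.0)
        lead_names.append(parts[4] if len(parts) > 4 else f"V{len(lead_names) + 1}")
    if data_path is None:
        data_path = header_path.parent / data_names[0]
    buf = Path(data_path).read_bytes()
    total = n_samples * n_leads
    if len(buf) < 3 * ((total + 1) // 2):
        raise ParseError(
            f"{data_path}: {len(buf)} bytes cannot hold {n_samples} samples "
            f"x {n_leads} leads"
        )
    adc = unpack_format212(buf, total).reshape(n_samples, n_leads).astype(float)
    signal = (adc - np.asarray(baselines)) / np.asarray(gains)
    return ECGRecord(
        record_id=record_id,
        fs=fs,
        lead_names=tuple(lead_names),
        signal=signal,
        gain=np.asarray(gains),
        baseline_adc=np.asarray(baselines),
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_csv_record(record: ECGRecord, path) -> None:
    """Write the mV signal matrix as CSV with a lead-name header row."""
    pd.DataFrame(record.signal, columns=list(record.lead_names)).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_csv_record(path, fs: float, record_id: str | None = None) -> ECGRecord:
    """Read a CSV signal matrix (one column per lead, header of lead names)."""
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: no samples")
    return ECGRecord(
        record_id=record_id or Path(path).stem,
        fs=fs,
        lead_names=tuple(df.columns),
        signal=df.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Potassium label tables
# ---------------------------------------------------------------------------

def read_labels(path) -> list[PotassiumLabel]:
    """Read a delimited label table with columns record_id, k_mmol_per_l, phase.

    Duplicate (record_id, phase) keys and out-of-range potassium values are
    rejected.
    """
    df = pd.read_csv(path)
    required = {"record_id", "k_mmol_per_l", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    keys = list(zip(df["record_id"], df["phase"]))
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ValidationError(f"{path}: duplicated (record_id, phase) key {dup}")
    return [
        PotassiumLabel(str(r.record_id), float(r.k_mmol_per_l), str(r.phase))
        for r in df.itertuples()
    ]


def write_labels(labels: Sequence[PotassiumLabel], path) -> None:
    """Write a label table readable by :func:`read_labels`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "k_mmol_per_l", "phase"])
        for lab in labels:
            w.writerow([lab.record_id, f"{lab.k_mmol_per_l:.4f}", lab.phase])
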