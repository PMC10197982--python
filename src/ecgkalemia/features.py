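"""Beat detection, fiducial delineation and morphological feature extraction.

Twelve features are computed per lead on the chest leads V2-V5 (48 in all):

* slope class — T right slope, T left slope, ST-segment slope (mV/s);
* amplitude class — T, R and S amplitudes relative to the isoelectric
  level (mV, signed so that inverted waves are not silently rectified);
* area class — T, R and S areas (mV*s, absolute deviation from the
  isoelectric level) and the same areas divided by the preceding RR
  interval ("area per second").

The isoelectric reference is the PR-segment median just before QRS onset,
standard delineation practice. Per-record features are the per-feature
median across all usable beats in the analysis window, which keeps a single
mis-delineated beat from contaminating the record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .ecg_io import ECGRecord
from .errors import DelineationError, ValidationError
from .preprocess import bandpass_filter

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_LEADS",
    "FEATURE_VECTOR_NAMES",
    "BeatFiducials",
    "LeadFeatures",
    "FeatureVector",
    "detect_r_peaks",
    "delineate_beat",
    "compute_lead_features",
    "extract_feature_vector",
]

FEATURE_NAMES = (
    "t_right_slope", "t_left_slope", "st_slope",
    "t_amp", "r_amp", "s_amp",
    "t_area", "r_area", "s_area",
    "t_area_per_s", "r_area_per_s", "s_area_per_s",
)
FEATURE_LEADS = ("V2", "V3", "V4", "V5")
#: canonical lead-major ordering of the 48-value vector
FEATURE_VECTOR_NAMES = tuple(
    f"{lead}_{feat}" for lead in FEATURE_LEADS for feat in FEATURE_NAMES
)

_REFRACTORY_S = 0.2
_MIN_T_AMP_MV = 0.04  # below this the T wave is treated as absent


@dataclass(frozen=True)
class BeatFiducials:
    """Landmark sample indices for one beat.

    Ordering invariant: q_onset < r_peak < s_trough <= s_offset < t_onset
    < t_peak < t_offset.
    """

    r_peak: int
    q_onset: int
    s_offset: int
    s_trough: int
    t_onset: int
    t_peak: int
    t_offset: int
    rr_prev_s: float
    iso_level_mv: float

    def __post_init__(self) -> None:
        order = (self.q_onset, self.r_peak, self.s_trough)
        if not (order[0] < order[1] < order[2] <= self.s_offset):
            raise ValidationError("QRS fiducials out of order")
        if not self.s_offset < self.t_onset < self.t_peak < self.t_offset:
            raise ValidationError("T-wave fiducials out of order")
        if not self.rr_prev_s > 0.2:
            raise ValidationError(f"implausible RR interval {self.rr_prev_s}")


@dataclass(frozen=True)
class LeadFeatures:
    """The twelve morphological features of one lead."""

    t_right_slope: float
    t_left_slope: float
    st_slope: float
    t_amp: float
    r_amp: float
    s_amp: float
    t_area: float
    r_area: float
    s_area: float
    t_area_per_s: float
    r_area_per_s: float
    s_area_per_s: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass(frozen=True)
class FeatureVector:
    """48 named feature values in canonical lead-major order."""

    values: np.ndarray
    names: tuple = FEATURE_VECTOR_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.names),):
            raise ValidationError(
                f"expected {len(self.names)} values, got {self.values.shape}"
            )
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")

    def __len__(self) -> int:
        return self.values.size

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(signal: np.ndarray, fs: float) -> np.ndarray:
    """Locate R peaks via QRS-band derivative energy.

    The signal is band-passed to the QRS band (5-22 Hz), differentiated,
    squared and integrated over a 150-ms window; peaks of this envelope
    separated by at least the 200-ms refractory period, above an adaptive
    fraction of the typical candidate height, are refined to the local
    maximum of the raw signal. The adaptive threshold makes detection
    invariant to global amplitude scaling.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValidationError("signal must be 1-D")
    if x.size < 2 * fs:
        raise ValidationError("need at least 2 s of signal")
    high = min(22.0, 0.45 * fs)
    qrs = bandpass_filter(x, fs, 5.0, high, order=2)
    energy = np.gradient(qrs) ** 2
    win = max(1, int(round(0.15 * fs)))
    envelope = np.convolve(energy, np.ones(win) / win, mode="same")
    dist = int(round(_REFRACTORY_S * fs))
    cand, _ = find_peaks(envelope, distance=dist)
    if cand.size == 0:
        raise DelineationError("no QRS energy peaks found")
    # adaptive: typical QRS envelope height from the upper candidates
    typical = np.median(np.sort(envelope[cand])[-max(2, cand.size // 2):])
    if typical <= 0:
        raise DelineationError("flat signal, no beats detected")
    keep = cand[envelope[cand] > 0.2 * typical]
    # refine to the raw-signal extremum (largest |deviation|) within +-60 ms
    half = int(round(0.06 * fs))
    peaks = []
    for c in keep:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        seg = x[lo:hi]
        peaks.append(lo + int(np.argmax(np.abs(seg - np.median(x)))))
    peaks = np.unique(peaks)
    # enforce refractory period after refinement
    out = []
    for p in peaks:
        if not out or p - out[-1] >= dist:
            out.append(int(p))
        elif abs(x[p]) > abs(x[out[-1]]):
            out[-1] = int(p)
    if len(out) < 2:
        raise DelineationError(f"only {len(out)} beats detected; record unusable")
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# Single-beat delineation
# ---------------------------------------------------------------------------

def _sustained_quiet(deriv: np.ndarray, thr: float, run: int) -> np.ndarray:
    """Boolean mask of positions opening a run of |deriv| < thr of length run."""
    quiet = np.abs(deriv) < thr
    if run <= 1:
        return quiet
    kernel = np.ones(run)
    counts = np.convolve(quiet.astype(float), kernel, mode="full")[run - 1:]
    return counts[: deriv.size] >= run - 0.5


def delineate_beat(
    signal: np.ndarray,
    fs: float,
    r_peak: int,
    rr_prev_s: float,
) -> BeatFiducials:
    """Locate the fiducial points of one beat around a known R peak.

    QRS onset/offset come from a slope-threshold search within +-120 ms of
    R (the first sustained low-slope sample walking outward), the S trough
    is the minimum in the 120 ms after R, the T peak is the largest
    absolute deviation from the isoelectric level in the window from
    QRS offset + 60 ms to QRS offset + 0.6 RR, and T onset/offset are the
    intersections of the steepest-flank tangents with the isoelectric line.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    guard = int(round(0.4 * rr_prev_s * fs))
    if r_peak - guard < 0 or r_peak + guard >= n:
        raise DelineationError("beat too close to the record edge")
    d = np.gradient(x) * fs  # mV/s
    w = int(round(0.12 * fs))
    run = max(2, int(round(0.008 * fs)))

    qrs_lo, qrs_hi = max(0, r_peak - w), min(n, r_peak + w + 1)
    slope_scale = np.max(np.abs(d[qrs_lo:qrs_hi]))
    if slope_scale <= 0:
        raise DelineationError("flat QRS region")
    thr = 0.03 * slope_scale

    # --- QRS onset: walk left from R for the first sustained quiet run
    left = d[qrs_lo:r_peak]
    quiet_left = _sustained_quiet(left[::-1], thr, run)
    hit = np.nonzero(quiet_left)[0]
    q_onset = r_peak - 1 - int(hit[0]) if hit.size else qrs_lo

    # --- S trough: minimum within (R, R + 120 ms]
    s_seg = x[r_peak + 1:qrs_hi]
    if s_seg.size == 0:
        raise DelineationError("no room for S wave")
    s_trough = r_peak + 1 + int(np.argmin(s_seg))

    # --- QRS offset (J point): first sustained quiet run after the S trough
    right = d[s_trough:qrs_hi]
    quiet_right = _sustained_quiet(right, thr, run)
    hit = np.nonzero(quiet_right)[0]
    s_offset = s_trough + int(hit[0]) if hit.size else qrs_hi - 1

    # --- isoelectric level: 40-ms median ending 20 ms before QRS onset
    iso_hi = q_onset - int(round(0.02 * fs))
    iso_lo = iso_hi - int(round(0.04 * fs))
    if iso_lo < 0:
        raise DelineationError("no PR segment available for baseline")
    iso = float(np.median(x[iso_lo:iso_hi]))

    # --- T peak: largest |deviation| in [J + 60 ms, J + 0.6 RR]
    t_lo = s_offset + int(round(0.06 * fs))
    t_hi = min(n - 1, s_offset + int(round(0.6 * rr_prev_s * fs)))
    if t_hi <= t_lo + 2:
        raise DelineationError("T search window truncated by record edge")
    t_seg = x[t_lo:t_hi + 1] - iso
    t_peak = t_lo + int(np.argmax(np.abs(t_seg)))
    t_amp = x[t_peak] - iso
    if abs(t_amp) < _MIN_T_AMP_MV:
        raise DelineationError("T wave absent (amplitude below threshold)")

    t_onset = _tangent_crossing(x, d, iso, t_lo, t_peak, ascending=True, fs=fs)
    t_offset = _tangent_crossing(x, d, iso, t_peak, t_hi, ascending=False, fs=fs)
    if t_onset <= s_offset:
        t_onset = s_offset + 1
    if t_onset >= t_peak or t_offset <= t_peak:
        raise DelineationError("degenerate T-wave flanks")

    return BeatFiducials(
        r_peak=int(r_peak), q_onset=int(q_onset), s_offset=int(s_offset),
        s_trough=int(s_trough), t_onset=int(t_onset), t_peak=int(t_peak),
        t_offset=int(min(t_offset, n - 1)), rr_prev_s=float(rr_prev_s),
        iso_level_mv=iso,
    )


def _tangent_crossing(
    x: np.ndarray,
    d: np.ndarray,
    iso: float,
    lo: int,
    hi: int,
    ascending: bool,
    fs: float = 1.0,
) -> int:
    """Project the steepest flank in [lo, hi] onto the isoelectric line.

    Returns the sample index where the tangent at the point of maximal
    |slope| crosses ``iso`` — the classical tangent method for T-wave
    boundaries.
    """
    if hi <= lo:
        raise DelineationError("empty flank window")
    seg = d[lo:hi + 1]
    i = lo + int(np.argmax(np.abs(seg)))
    slope = d[i]  # mV/s
    if slope == 0:
        raise DelineationError("flat T flank")
    # tangent through (i, x[i]) with that slope crosses iso after
    # (iso - x[i])/slope seconds, i.e. fs times as many samples
    cross = i + fs * (iso - x[i]) / slope
    idx = int(round(cross))
    if ascending:
        return max(lo - 1, min(idx, hi))
    return min(hi + 1, max(idx, lo))


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------

def compute_lead_features(
    signal: np.ndarray,
    fs: float,
    fid: BeatFiducials,
) -> LeadFeatures:
    """Compute the twelve features of one beat from its fiducials.

    Slopes are straight-line rises over their defining intervals (ST slope
    is the OLS slope over [J point, T onset]); amplitudes are signed
    deviations from the isoelectric level; areas integrate |v - iso| by the
    trapezoidal rule, the QRS interval being split into its positive (R)
    and negative (S) lobes; "per second" areas divide by the preceding RR.
    """
    x = np.asarray(signal, dtype=float)
    v = x - fid.iso_level_mv
    dt = 1.0 / fs

    def _span_s(a: int, b: int) -> float:
        s = (b - a) * dt
        if s <= 0:
            raise ValidationError("zero-duration segment in feature computation")
        return s

    t_left = (v[fid.t_peak] - v[fid.t_onset]) / _span_s(fid.t_onset, fid.t_peak)
    t_right = (v[fid.t_offset] - v[fid.t_peak]) / _span_s(fid.t_peak, fid.t_offset)

    st = v[fid.s_offset:fid.t_onset + 1]
    if st.size < 2:
        raise ValidationError("zero-duration ST segment")
    tt = np.arange(st.size) * dt
    st_slope = float(np.polynomial.polynomial.polyfit(tt, st, 1)[1])

    qrs = v[fid.q_onset:fid.s_offset + 1]
    if qrs.size < 2:
        raise ValidationError("zero-duration QRS segment")
    r_area = float(np.trapezoid(np.clip(qrs, 0.0, None), dx=dt))
    s_area = float(np.trapezoid(np.clip(-qrs, 0.0, None), dx=dt))
    t_area = float(np.trapezoid(np.abs(v[fid.t_onset:fid.t_offset + 1]), dx=dt))

    rr = fid.rr_prev_s
    return LeadFeatures(
        t_right_slope=float(t_right),
        t_left_slope=float(t_left),
        st_slope=st_slope,
        t_amp=float(v[fid.t_peak]),
        r_amp=float(v[fid.r_peak]),
        s_amp=float(v[fid.s_trough]),
        t_area=t_area,
        r_area=r_area,
        s_area=s_area,
        t_area_per_s=t_area / rr,
        r_area_per_s=r_area / rr,
        s_area_per_s=s_area / rr,
    )


def extract_feature_vector(record: ECGRecord, reference_lead: str = "V2"):
    """Extract the 48-value feature vector from a preprocessed record.

    Beats are detected on the reference lead; each required chest lead is
    delineated beat by beat with the shared R-peak train, and per-lead
    features are aggregated as the per-feature median across usable beats.
    Beats whose search windows are truncated by the record edge or whose T
    wave is absent are skipped, not fatal; a record where every beat fails
    on some lead raises :class:`DelineationError`.
    """
    missing = [l for l in FEATURE_LEADS if l not in record.lead_names]
    if missing:
        raise ValidationError(f"record lacks required leads {missing}")
    ref = reference_lead if reference_lead in record.lead_names else FEATURE_LEADS[0]
    r_peaks = detect_r_peaks(record.lead(ref), record.fs)
    rr_prev = np.diff(r_peaks) / record.fs

    blocks: list[np.ndarray] = []
    for lead in FEATURE_LEADS:
        x = record.lead(lead)
        per_beat = []
        for i in range(1, r_peaks.size):
            rr = float(rr_prev[i - 1])
            if rr <= 0.25:
                continue
            try:
                fid = delineate_beat(x, record.fs, int(r_peaks[i]), rr)
                per_beat.append(compute_lead_features(x, record.fs, fid).as_array())
            except (DelineationError, ValidationError):
                continue
        if not per_beat:
            raise DelineationError(
                f"no usable beats on lead {lead} of record {record.record_id}"
            )
        blocks.append(np.median(np.vstack(per_beat), axis=0))
    return FeatureVector(values=np.concatenate(blocks))
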