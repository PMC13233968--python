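"""Core QT/QTc arithmetic and the median-beat baseline QT measurer.

This module houses the interval conventions used throughout the package:

* Bazett's heart-rate correction, ``QTc = QT / sqrt(RR)`` with RR in seconds.
* Long-QT classification with an *inclusive* boundary (``QTc >= threshold``).
* Record exclusion rules (spurious QTc outside [250, 600] ms; three or more
  incomplete leads).
* A median-beat QT measurer modelled on the behaviour of conventional
  commercial ECG analysis programs: beats are aligned on the R peak, a
  pointwise per-lead median beat is formed, and QT is the interval from the
  earliest Q-wave onset to the latest T-wave offset across leads, with the
  T offset located by the tangent method.

All intervals are milliseconds, all voltages millivolts, and sample indices
are 0-based at the record's sampling frequency (500 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, savgol_filter, sosfiltfilt

__all__ = [
    "QTcLabel",
    "ExclusionReport",
    "MedianBeat",
    "QTMeasurement",
    "InsufficientBeatsError",
    "MeasurementFailure",
    "bazett_qtc",
    "classify_lqts",
    "apply_exclusions",
    "detect_r_peaks",
    "median_beat",
    "measure_qt_median_beat",
]

DEFAULT_FS = 500.0
#: thresholds (ms) at which long QT is usually operationalised clinically
LQTS_THRESHOLDS = (460.0, 470.0, 500.0)

QTC_SPURIOUS_LOW = 250.0
QTC_SPURIOUS_HIGH = 600.0
#: a record is incomplete when >= this many leads fall short of 10 s
INCOMPLETE_LEAD_COUNT = 3


class InsufficientBeatsError(ValueError):
    """Raised when fewer than three beats are available for the median beat."""


class MeasurementFailure(RuntimeError):
    """Raised when no lead yields a usable Q onset / T offset pair."""


@dataclass(frozen=True)
class QTcLabel:
    """A (QT, mean RR, QTc) triple satisfying the Bazett identity."""

    qt_ms: float
    rr_ms: float
    qtc_ms: float

    def __post_init__(self) -> None:
        if self.qt_ms <= 0 or self.rr_ms <= 0 or self.qtc_ms <= 0:
            raise ValueError("intervals must be positive")
        expected = bazett_qtc(self.qt_ms, self.rr_ms)
        if abs(expected - self.qtc_ms) > 0.01:
            raise ValueError(
                f"qtc_ms={self.qtc_ms} inconsistent with Bazett value {expected:.4f}"
            )


@dataclass(frozen=True)
class ExclusionReport:
    record_id: str
    kept: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept flag must match empty reasons")


def bazett_qtc(qt_ms, rr_ms):
    """Bazett-corrected QT: ``QT / sqrt(RR)`` with RR in seconds.

    Accepts scalars or arrays; returns ms.
    """
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(qt <= 0) or np.any(rr <= 0):
        raise ValueError("qt_ms and rr_ms must be positive")
    out = qt / np.sqrt(rr / 1000.0)
    if np.isscalar(qt_ms) and np.isscalar(rr_ms):
        return float(out)
    return out


def classify_lqts(qtc_ms, threshold_ms, allowed=LQTS_THRESHOLDS):
    """Long-QT flag at a clinical cutoff: positive iff ``qtc >= threshold``.

    The boundary is inclusive.  ``allowed`` restricts the supported cutoffs;
    pass ``allowed=None`` to accept any positive threshold.
    """
    if allowed is not None and float(threshold_ms) not in {float(t) for t in allowed}:
        raise ValueError(f"threshold {threshold_ms} not in supported set {allowed}")
    qtc = np.asarray(qtc_ms, dtype=float)
    flag = qtc >= float(threshold_ms)
    if np.isscalar(qtc_ms):
        return bool(flag)
    return flag


def apply_exclusions(record_ids, lead_sample_counts, gold_qtc_ms,
                     full_length=5000):
    """Apply the cohort exclusion rules to a set of records.

    Parameters
    ----------
    record_ids : sequence of str
    lead_sample_counts : array-like, shape (n_records, n_leads)
        Number of valid samples per lead; a lead with fewer than
        ``full_length`` samples counts as incomplete.
    gold_qtc_ms : array-like, shape (n_records,)
        Expert-measured QTc per record.

    A record is excluded when its gold QTc lies outside (250, 600) ms, or
    when three or more of its leads are incomplete.
    """
    counts = np.atleast_2d(np.asarray(lead_sample_counts))
    qtc = np.asarray(gold_qtc_ms, dtype=float)
    reports = []
    for rid, row, q in zip(record_ids, counts, qtc, strict=True):
        reasons = []
        if q > QTC_SPURIOUS_HIGH or q < QTC_SPURIOUS_LOW:
            reasons.append("qtc_out_of_range")
        if int(np.sum(row < full_length)) >= INCOMPLETE_LEAD_COUNT:
            reasons.append("incomplete_leads")
        reports.append(ExclusionReport(rid, kept=not reasons, reasons=tuple(reasons)))
    return reports


def exclusion_frame(reports):
    """Exclusion reports as a DataFrame (record_id, kept, reasons)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in reports],
            "kept": [r.kept for r in reports],
            "reasons": [";".join(r.reasons) for r in reports],
        }
    )


# ---------------------------------------------------------------------------
# beat detection and the median beat
# ---------------------------------------------------------------------------

def detect_r_peaks(signal, fs=DEFAULT_FS, refractory_ms=200.0):
    """R-peak detection by squared-derivative thresholding.

    Intended for lead II.  The squared first difference is smoothed, peaks
    above 25% of its robust maximum are taken left to right with a 200 ms
    refractory period, and each detection is refined to the local extremum
    of the raw signal.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("detect_r_peaks expects a single lead")
    d = np.diff(x)
    energy = d * d
    # ~24 ms moving average
    w = max(3, int(round(0.024 * fs)))
    kernel = np.ones(w) / w
    energy = np.convolve(energy, kernel, mode="same")
    ref = np.percentile(energy, 99.8)
    if ref <= 0:
        return np.array([], dtype=int)
    thresh = 0.25 * ref
    refractory = int(round(refractory_ms * fs / 1000.0))
    peaks = []
    i = 0
    n = energy.size
    while i < n:
        if energy[i] >= thresh:
            j = min(i + refractory, n)
            k = i + int(np.argmax(energy[i:j]))
            # refine on the raw signal around the energy peak
            lo = max(0, k - int(0.04 * fs))
            hi = min(x.size, k + int(0.04 * fs))
            peaks.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
            i = k + refractory
        else:
            i += 1
    return np.asarray(sorted(set(peaks)), dtype=int)


@dataclass(frozen=True)
class MedianBeat:
    """Per-lead median beat: array (window_samples, n_leads), R at ``r_index``."""

    template: np.ndarray
    r_index: int
    fs: float
    n_beats: int

    @property
    def n_leads(self) -> int:
        return self.template.shape[1]

    def to_frame(self):
        import pandas as pd

        t_ms = (np.arange(self.template.shape[0]) - self.r_index) * 1000.0 / self.fs
        df = pd.DataFrame(self.template)
        df.insert(0, "t_ms", t_ms)
        return df


def median_beat(waveform, r_peaks=None, fs=DEFAULT_FS,
                pre_ms=300.0, post_ms=600.0, remove_baseline=True):
    """Pointwise per-lead median of R-aligned beat windows.

    The window is nominally [-300, +600] ms around the R peak, clipped so it
    fits within the median RR interval (leaving room for the next QRS).
    Beats whose window would run off the record are dropped; at least three
    usable beats are required.  Baseline wander is removed first with a
    zero-phase 0.5 Hz high-pass (standard ECG preprocessing) unless
    ``remove_baseline`` is false.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if remove_baseline and x.shape[0] > 50:
        sos = butter(2, 0.5, btype="highpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, x, axis=0)
    if r_peaks is None:
        r_peaks = detect_r_peaks(x[:, min(1, x.shape[1] - 1)], fs=fs)
    r_peaks = np.asarray(r_peaks, dtype=int)
    if r_peaks.size < 3:
        raise InsufficientBeatsError(f"need >= 3 beats, got {r_peaks.size}")
    rr_med_ms = float(np.median(np.diff(r_peaks))) * 1000.0 / fs
    pre = int(round(min(pre_ms, 0.35 * rr_med_ms) * fs / 1000.0))
    post = int(round(min(post_ms, rr_med_ms - 60.0) * fs / 1000.0))
    if post <= 0 or pre <= 0:
        raise InsufficientBeatsError("RR interval too short for a beat window")
    windows = [
        x[r - pre : r + post]
        for r in r_peaks
        if r - pre >= 0 and r + post <= x.shape[0]
    ]
    if len(windows) < 3:
        raise InsufficientBeatsError(
            f"only {len(windows)} complete beat windows available"
        )
    template = np.median(np.stack(windows, axis=0), axis=0)
    return MedianBeat(template=template, r_index=pre, fs=fs, n_beats=len(windows))


@dataclass(frozen=True)
class QTMeasurement:
    qt_ms: float
    q_onset_ms: np.ndarray  # per lead, relative to R (NaN where undetectable)
    t_offset_ms: np.ndarray  # per lead, relative to R (NaN where undetectable)

    @property
    def n_leads_used(self) -> int:
        return int(np.sum(np.isfinite(self.t_offset_ms)))


def _lead_q_onset(v, r_index, fs, scan_ms=90.0, sustain_ms=8.0, rel_thresh=0.02):
    """Q onset: first sample before R where |dV/dt| exceeds ``rel_thresh`` of
    the maximal QRS slope for at least ``sustain_ms``."""
    dt_ms = 1000.0 / fs
    deriv = np.gradient(v) / dt_ms
    qrs_lo = max(0, r_index - int(60 / dt_ms))
    qrs_hi = min(v.size, r_index + int(60 / dt_ms))
    r_slope = np.max(np.abs(deriv[qrs_lo:qrs_hi]))
    if r_slope <= 0:
        return None
    lo = max(0, r_index - int(scan_ms / dt_ms))
    seg = np.abs(deriv[lo : r_index + 1]) >= rel_thresh * r_slope
    need = max(1, int(round(sustain_ms / dt_ms)))
    run = 0
    for i, flag in enumerate(seg):
        run = run + 1 if flag else 0
        if run >= need:
            onset = lo + i - need + 1
            return (onset - r_index) * dt_ms
    return None


def _lead_t_offset(v, r_index, fs, baseline, min_t_amp_mv=0.04):
    """T offset by the tangent method: the line through the steepest
    descending point after the T peak, intersected with the isoelectric
    baseline."""
    dt_ms = 1000.0 / fs
    start = r_index + int(90 / dt_ms)
    if start >= v.size - 4:
        return None
    seg = v[start:] - baseline
    t_peak = start + int(np.argmax(seg))
    if v[t_peak] - baseline < min_t_amp_mv:
        return None
    hi = min(v.size - 1, t_peak + int(150 / dt_ms))
    if hi <= t_peak + 2:
        return None
    deriv = np.gradient(v[t_peak : hi + 1]) / dt_ms
    k = int(np.argmin(deriv))
    slope = deriv[k]
    if slope >= 0:
        return None
    t_s = t_peak + k
    # tangent through (t_s, v[t_s]) with the fitted slope meets the baseline
    return (t_s - r_index) * dt_ms + (baseline - v[t_s]) / slope


def measure_qt_median_beat(beat: MedianBeat, min_t_amp_mv=0.04):
    """QT from a median beat: earliest Q onset to latest T offset, any lead.

    Each lead is lightly smoothed (Savitzky-Golay, 11 samples, order 3)
    before onset/offset detection.  Leads with a flat or undetectable T wave
    are skipped; if no lead is measurable a :class:`MeasurementFailure` is
    raised so the caller can drop the record.
    """
    fs = beat.fs
    dt_ms = 1000.0 / fs
    n_leads = beat.n_leads
    q_on = np.full(n_leads, np.nan)
    t_off = np.full(n_leads, np.nan)
    for j in range(n_leads):
        v = beat.template[:, j]
        if v.size >= 11:
            v = savgol_filter(v, 11, 3)
        # isoelectric baseline from the PR segment
        b_lo = max(0, beat.r_index - int(90 / dt_ms))
        b_hi = max(b_lo + 1, beat.r_index - int(55 / dt_ms))
        baseline = float(np.median(v[b_lo:b_hi]))
        q = _lead_q_onset(v, beat.r_index, fs)
        t = _lead_t_offset(v, beat.r_index, fs, baseline, min_t_amp_mv)
        if q is not None and t is not None and t > 0 > q:
            q_on[j] = q
            t_off[j] = t
    if not np.any(np.isfinite(t_off)):
        raise MeasurementFailure("no lead yielded a measurable QT")
    qt = float(np.nanmax(t_off) - np.nanmin(q_on))
    return QTMeasurement(qt_ms=qt, q_onset_ms=q_on, t_offset_ms=t_off)
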