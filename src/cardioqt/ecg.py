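"""Single-lead ECG feature extraction.

The pipeline mirrors standard small-animal and clinical practice:

1. zero-phase high-pass filtering to remove baseline wander,
2. R-peak detection with a refractory window,
3. per-beat delineation of P onset, Q onset, S end (isoelectric crossing),
   T peak and T end (90% decline of the T wave),
4. interval averaging over all delineatable beats, and
5. heart-rate correction of QT: Bazett (divide by sqrt RR in s), Hodges
   (QT + 1.75*(HR-60)), and the murine normalisation QT / sqrt(RR/100 ms).

Measurement conventions: the PR interval runs from the onset of the positive
P deflection to the R peak; QRS from Q onset to where the S wave crosses the
isoelectric line; QT from Q onset to the point where the T wave has completed
90% of its decline back to the isoelectric level. Onsets and crossings are
located with linear interpolation between samples, so fiducials carry
sub-sample precision and are stored as float sample positions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "ECGRecord",
    "BeatFiducials",
    "IntervalSet",
    "QTcValue",
    "TWaveMetrics",
    "DelineationConfig",
    "highpass_baseline",
    "detect_r_peaks",
    "delineate_beat",
    "delineate_record",
    "average_intervals",
    "qtc_bazett_human",
    "qtc_hodges",
    "qtc_mitchell_mouse",
    "t_wave_metrics",
]

Species = Literal["mouse", "human"]


@dataclass(frozen=True)
class ECGRecord:
    """A sampled single-lead voltage series (mV) with its sampling rate (Hz)."""

    samples: np.ndarray
    sampling_rate: float
    lead_label: str = "II"
    species_hint: Species = "mouse"

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n / self.sampling_rate

    def ms_to_samples(self, ms: float) -> float:
        return ms * self.sampling_rate / 1000.0

    def samples_to_ms(self, idx: float) -> float:
        return idx * 1000.0 / self.sampling_rate


@dataclass(frozen=True)
class BeatFiducials:
    """Per-beat landmarks as (possibly fractional) sample positions.

    Absent landmarks (e.g. no discernible P wave) are ``None``; intervals
    that need them are then undefined for this beat.
    """

    r_peak: float
    isoelectric_level: float
    p_onset: float | None = None
    q_onset: float | None = None
    s_end: float | None = None
    t_peak: float | None = None
    t_end90: float | None = None

    def interval_ms(self, fs: float, a: str, b: str) -> float | None:
        """Duration in ms between two named fiducials, if both exist."""
        ia, ib = getattr(self, a), getattr(self, b)
        if ia is None or ib is None:
            return None
        return (ib - ia) * 1000.0 / fs


@dataclass(frozen=True)
class IntervalSet:
    """Averaged ECG intervals (ms) and heart rate (bpm)."""

    PR_ms: float | None
    QRS_ms: float | None
    QT_ms: float | None
    RR_ms: float
    HR_bpm: float
    n_beats_averaged: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class QTcValue:
    """A heart-rate-corrected QT value, tagged with the formula used.

    ``qtc_ms`` keeps full precision; integer reporting conventions differ by
    formula (see :meth:`reported`).
    """

    qt_ms: float
    rr_ms: float
    hr_bpm: float
    formula: Literal["bazett_human", "hodges", "mitchell_mouse"]
    qtc_ms: float

    def reported(self, precision: Literal["integer", "full"] = "full") -> float:
        """Report the value; integer mode applies the formula's convention.

        Bazett values are truncated toward zero; Hodges (and the murine
        normalisation) round half up.
        """
        if precision == "full":
            return self.qtc_ms
        if self.formula == "bazett_human":
            return float(math.trunc(self.qtc_ms))
        return float(math.floor(self.qtc_ms + 0.5))


@dataclass(frozen=True)
class TWaveMetrics:
    """T-wave morphology: peak amplitude (mV) and mean area (mV*ms)."""

    amplitude_mV: float
    area_mV_ms: float
    n_beats_amplitude: int
    n_beats_area: int
    area_from_fewer_than_5: bool


# ---------------------------------------------------------------------------
# filtering & peak detection


def highpass_baseline(record: ECGRecord, cutoff_hz: float = 0.5) -> ECGRecord:
    """Zero-phase high-pass filter (forward-backward 2nd-order Butterworth).

    Removes DC offset and slow baseline wander while preserving the phase of
    every deflection; output has the same length as the input.
    """
    if not np.all(np.isfinite(record.samples)):
        raise ValueError("cannot filter a record with non-finite samples")
    nyq = record.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, {nyq}) Hz")
    sos = signal.butter(2, cutoff_hz, btype="highpass", fs=record.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, record.samples)
    return replace(record, samples=filtered)


def _refractory_ms(species: Species) -> float:
    return 40.0 if species == "mouse" else 250.0


def detect_r_peaks(
    record: ECGRecord,
    *,
    min_rr_ms: float | None = None,
    height_fraction: float = 0.5,
) -> np.ndarray:
    """Locate one R peak per beat on a baseline-corrected record.

    A peak must exceed ``height_fraction`` of the largest positive excursion
    above the record median and be separated from its neighbours by a
    species-dependent refractory window.
    """
    v = record.samples
    base = float(np.median(v))
    vmax = float(np.max(v)) - base
    if vmax <= 0 or not np.any(np.abs(v - base) > 1e-12):
        warnings.warn("no R peaks found (flat or inverted record)", stacklevel=2)
        return np.array([], dtype=int)
    if min_rr_ms is None:
        min_rr_ms = _refractory_ms(record.species_hint)
    distance = max(1, int(round(record.ms_to_samples(min_rr_ms))))
    peaks, _ = signal.find_peaks(v, height=base + height_fraction * vmax, distance=distance)
    if peaks.size == 0:
        warnings.warn("no R peaks found", stacklevel=2)
    return peaks


# ---------------------------------------------------------------------------
# delineation


@dataclass(frozen=True)
class DelineationConfig:
    """Search windows (ms) for per-beat delineation; defaults per species."""

    p_search_ms: float
    q_search_ms: float
    s_search_ms: float
    t_peak_frac_rr: float
    t_end_frac_rr: float
    baseline_window_ms: float = 10.0
    baseline_gap_ms: float = 5.0
    smooth_ms: float = 1.0
    min_wave_mV: float = 0.03

    @staticmethod
    def for_species(species: Species) -> "DelineationConfig":
        if species == "mouse":
            return DelineationConfig(
                p_search_ms=50.0, q_search_ms=15.0, s_search_ms=20.0,
                t_peak_frac_rr=0.6, t_end_frac_rr=0.9,
            )
        return DelineationConfig(
            p_search_ms=300.0, q_search_ms=60.0, s_search_ms=80.0,
            t_peak_frac_rr=0.55, t_end_frac_rr=0.85, smooth_ms=2.0,
        )


def _smooth(v: np.ndarray, fs: float, smooth_ms: float) -> np.ndarray:
    w = max(1, int(round(smooth_ms * fs / 1000.0)))
    if w <= 1:
        return v
    kernel = np.ones(w) / w
    return np.convolve(v, kernel, mode="same")


def _cross_down(v: np.ndarray, start: int, stop: int, level: float) -> float | None:
    """First interpolated index in [start, stop) where v falls to <= level."""
    seg = v[start:stop]
    below = np.nonzero(seg <= level)[0]
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return float(start)
    x0, x1 = seg[i - 1], seg[i]
    frac = (x0 - level) / (x0 - x1) if x1 != x0 else 0.0
    return float(start + i - 1 + frac)


def _cross_up_backward(v: np.ndarray, peak: int, start: int, level: float) -> float | None:
    """Last interpolated index in [start, peak] where v rises through level."""
    seg = v[start : peak + 1]
    below = np.nonzero(seg <= level)[0]
    if below.size == 0:
        return None
    i = below[-1]
    if i == seg.size - 1:
        return float(peak)
    x0, x1 = seg[i], seg[i + 1]
    frac = (level - x0) / (x1 - x0) if x1 != x0 else 0.0
    return float(start + i + frac)


def delineate_beat(
    record: ECGRecord,
    r_peak: int,
    *,
    rr_ms: float | None = None,
    config: DelineationConfig | None = None,
) -> BeatFiducials:
    """Delineate one beat around a detected R peak.

    ``rr_ms`` bounds the T-wave search (defaults to a species-typical cycle
    length when the neighbouring beat is unknown). The isoelectric level is
    the median of a short window ending just before the detected P onset
    (first pass uses a window preceding the P search region).
    """
    cfg = config or DelineationConfig.for_species(record.species_hint)
    fs = record.sampling_rate
    v = _smooth(record.samples, fs, cfg.smooth_ms)
    n = v.size
    r = int(round(r_peak))
    if not 0 <= r < n:
        raise ValueError("r_peak outside record")
    if rr_ms is None:
        rr_ms = 120.0 if record.species_hint == "mouse" else 1000.0

    def s_at(ms: float) -> int:
        return int(round(record.ms_to_samples(ms)))

    # first-pass baseline: window just before the P search region
    b_hi = max(0, r - s_at(cfg.p_search_ms + cfg.baseline_gap_ms))
    b_lo = max(0, b_hi - s_at(cfg.baseline_window_ms))
    iso = float(np.median(v[b_lo:b_hi])) if b_hi > b_lo else float(np.median(v[: max(1, r)]))

    # Q trough and onset
    q_lo = max(0, r - s_at(cfg.q_search_ms))
    q_onset = None
    qi = None
    if q_lo < r:
        qi = q_lo + int(np.argmin(v[q_lo:r]))
        q_depth = iso - v[qi]
        if q_depth >= cfg.min_wave_mV / 3.0:
            # onset where the downward deflection is within 10% of Q depth
            level = iso - 0.1 * q_depth
            seg_rev = v[q_lo : qi + 1][::-1]
            above = np.nonzero(seg_rev >= level)[0]
            if above.size:
                j = above[0]
                if j == 0:
                    q_onset = float(qi)
                else:
                    x1, x0 = seg_rev[j], seg_rev[j - 1]
                    frac = (level - x0) / (x1 - x0) if x1 != x0 else 0.0
                    q_onset = float(qi - (j - 1) - frac)

    # S trough and isoelectric crossing
    s_hi = min(n, r + s_at(cfg.s_search_ms))
    s_end = None
    si = None
    if r + 1 < s_hi:
        si = r + 1 + int(np.argmin(v[r + 1 : s_hi]))
        if iso - v[si] >= cfg.min_wave_mV / 3.0:
            stop = min(n, r + 2 * s_at(cfg.s_search_ms))
            s_end = _cross_down(-v[:stop], si, stop, -iso)  # first rise of v through iso

    # T peak
    t_peak = None
    t_end90 = None
    t_start = int(math.ceil(s_end)) if s_end is not None else (si or r) + 1
    t_hi = min(n, r + s_at(cfg.t_peak_frac_rr * rr_ms))
    if t_start < t_hi:
        tp = t_start + int(np.argmax(v[t_start:t_hi]))
        t_amp = v[tp] - iso
        if t_amp >= cfg.min_wave_mV:
            t_peak = float(tp)
            stop = min(n, r + s_at(cfg.t_end_frac_rr * rr_ms))
            t_end90 = _cross_down(v, tp, stop, iso + 0.1 * t_amp)

    # P peak and onset
    p_onset = None
    p_lo = max(0, r - s_at(cfg.p_search_ms))
    p_hi = int(q_onset) if q_onset is not None else max(p_lo + 1, r - s_at(cfg.q_search_ms))
    if p_lo < p_hi:
        pi = p_lo + int(np.argmax(v[p_lo:p_hi]))
        p_amp = v[pi] - iso
        if p_amp >= cfg.min_wave_mV:
            p_onset = _cross_up_backward(v, pi, p_lo, iso + 0.1 * p_amp)

    # refined baseline: 10-ms window ending 5 ms before P onset
    if p_onset is not None:
        b_hi2 = max(0, int(p_onset) - s_at(cfg.baseline_gap_ms))
        b_lo2 = max(0, b_hi2 - s_at(cfg.baseline_window_ms))
        if b_hi2 > b_lo2:
            iso = float(np.median(v[b_lo2:b_hi2]))

    return BeatFiducials(
        r_peak=float(r), isoelectric_level=iso, p_onset=p_onset,
        q_onset=q_onset, s_end=s_end, t_peak=t_peak, t_end90=t_end90,
    )


def delineate_record(
    record: ECGRecord,
    r_peaks: Sequence[int] | None = None,
    *,
    config: DelineationConfig | None = None,
) -> list[BeatFiducials]:
    """Delineate every beat with a full window inside the record."""
    if r_peaks is None:
        r_peaks = detect_r_peaks(record)
    r_peaks = np.asarray(r_peaks, dtype=int)
    beats: list[BeatFiducials] = []
    if r_peaks.size == 0:
        return beats
    rr_samples = np.median(np.diff(r_peaks)) if r_peaks.size >= 2 else None
    rr_ms = record.samples_to_ms(rr_samples) if rr_samples is not None else None
    cfg = config or DelineationConfig.for_species(record.species_hint)
    margin_pre = record.ms_to_samples(cfg.p_search_ms + cfg.baseline_gap_ms + cfg.baseline_window_ms)
    for k, r in enumerate(r_peaks):
        if r - margin_pre < 0:
            continue
        rr_k = rr_ms
        if rr_k is None:
            rr_k = None
        if r + record.ms_to_samples((rr_k or 120.0)) >= record.n:
            continue
        beats.append(delineate_beat(record, int(r), rr_ms=rr_k, config=config))
    return beats


def average_intervals(
    beats: Sequence[BeatFiducials],
    record: ECGRecord,
) -> IntervalSet:
    """Average PR, QRS and QT over all beats carrying the needed fiducials.

    RR is the mean spacing of successive R peaks; HR = 60000 / RR.
    """
    if len(beats) == 0:
        raise ValueError("no delineated beats to average")
    fs = record.sampling_rate
    counts: dict[str, int] = {}

    def mean_interval(a: str, b: str) -> float | None:
        vals = [x for x in (bt.interval_ms(fs, a, b) for bt in beats) if x is not None]
        counts[f"{a}->{b}"] = len(vals)
        return float(np.mean(vals)) if vals else None

    pr = mean_interval("p_onset", "r_peak")
    qrs = mean_interval("q_onset", "s_end")
    qt = mean_interval("q_onset", "t_end90")
    r_times = np.array([bt.r_peak for bt in sorted(beats, key=lambda b: b.r_peak)])
    if r_times.size >= 2:
        rr = float(np.mean(np.diff(r_times)) * 1000.0 / fs)
        counts["rr"] = r_times.size - 1
        hr = 60000.0 / rr
    else:  # single beat: within-beat intervals stand, no cycle length
        rr = float("nan")
        counts["rr"] = 0
        hr = float("nan")
    return IntervalSet(PR_ms=pr, QRS_ms=qrs, QT_ms=qt, RR_ms=rr, HR_bpm=hr, n_beats_averaged=counts)


# ---------------------------------------------------------------------------
# QT correction


def qtc_bazett_human(qt_ms: float, hr_bpm: float) -> QTcValue:
    """Bazett correction with RR derived from heart rate: QTc = QT/sqrt(RR s)."""
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    rr_s = 60.0 / hr_bpm
    qtc = qt_ms / math.sqrt(rr_s)
    return QTcValue(qt_ms=qt_ms, rr_ms=rr_s * 1000.0, hr_bpm=hr_bpm,
                    formula="bazett_human", qtc_ms=qtc)


def qtc_hodges(qt_ms: float, hr_bpm: float) -> QTcValue:
    """Hodges correction: QTc = QT + 1.75*(HR - 60)."""
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    qtc = qt_ms + 1.75 * (hr_bpm - 60.0)
    return QTcValue(qt_ms=qt_ms, rr_ms=60000.0 / hr_bpm, hr_bpm=hr_bpm,
                    formula="hodges", qtc_ms=qtc)


def qtc_mitchell_mouse(qt_ms: float, rr_ms: float) -> QTcValue:
    """Murine QT normalisation: QTc = QT / sqrt(RR / 100 ms).

    Normalises to a 100-ms cycle length, the murine analogue of Bazett's
    1-s normalisation in humans.
    """
    if rr_ms <= 0:
        raise ValueError("RR must be positive")
    qtc = qt_ms / math.sqrt(rr_ms / 100.0)
    return QTcValue(qt_ms=qt_ms, rr_ms=rr_ms, hr_bpm=60000.0 / rr_ms,
                    formula="mitchell_mouse", qtc_ms=qtc)


# ---------------------------------------------------------------------------
# T-wave morphology


def t_wave_metrics(
    record: ECGRecord,
    beats: Sequence[BeatFiducials],
    *,
    n_area_beats: int = 5,
) -> TWaveMetrics:
    """Mean T-peak amplitude above isoelectric and mean T-wave area.

    The area is the trapezoidal integral of (V - isoelectric) from the end
    of the QRS (S crossing) to the 90%-decline point, averaged over the
    first ``n_area_beats`` beats with complete T fiducials (all available
    beats, flagged, when fewer exist).
    """
    v = record.samples
    fs = record.sampling_rate
    with_t = [b for b in beats if b.t_peak is not None]
    if not with_t:
        raise ValueError("no beats with a T wave")
    amps = [v[int(round(b.t_peak))] - b.isoelectric_level for b in with_t]
    full = [b for b in with_t if b.s_end is not None and b.t_end90 is not None]
    areas = []
    for b in full[:n_area_beats]:
        lo, hi = int(math.ceil(b.s_end)), int(math.floor(b.t_end90))
        if hi <= lo:
            continue
        seg = v[lo : hi + 1] - b.isoelectric_level
        areas.append(float(np.trapezoid(seg, dx=1000.0 / fs)))
    if not areas:
        raise ValueError("no beats with complete T-wave bounds")
    return TWaveMetrics(
        amplitude_mV=float(np.mean(amps)),
        area_mV_ms=float(np.mean(areas)),
        n_beats_amplitude=len(amps),
        n_beats_area=len(areas),
        area_from_fewer_than_5=len(areas) < n_area_beats,
    )
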