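"""Short-term beat-to-beat QT variability statistics.

Six markers commonly used as arrhythmia-risk indices are computed from an
ordered beat-to-beat QT series (ms), optionally paired with a beat-aligned
heart-rate series (bpm):

* ``QTvar``  — unbiased sample variance of the QT intervals (ms^2)
* ``SDqt``   — its square root (ms)
* ``STVqt``  — mean absolute successive QT difference divided by sqrt(2) (ms)
* ``QTVN``   — QT variance normalised to the squared mean QT (dimensionless)
* ``QTVI``   — log10 of the ratio of normalised QT variance to normalised
  heart-rate variance (dimensionless)
* ``RMSSDqt``— root mean square of successive QT differences (ms)

All statistics use the series' own means unless an override is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "QTSeries",
    "HRSeries",
    "QTVPanel",
    "qtvar",
    "sdqt",
    "stvqt",
    "qtvn",
    "qtvi_hr",
    "rmssdqt",
    "qtv_panel",
]


@dataclass(frozen=True)
class QTSeries:
    """Ordered beat-to-beat QT intervals in milliseconds."""

    qt_ms: np.ndarray
    mean_override_ms: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.qt_ms, dtype=float)
        if arr.ndim != 1:
            raise ValueError("QT series must be one-dimensional")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("QT series contains non-finite values")
        if np.any(arr <= 0):
            raise ValueError("QT intervals must be positive")
        object.__setattr__(self, "qt_ms", arr)

    @property
    def n(self) -> int:
        return self.qt_ms.size

    @property
    def qtm(self) -> float:
        """Mean QT (ms); an override is honoured for fixture replication."""
        if self.mean_override_ms is not None:
            return float(self.mean_override_ms)
        return float(np.mean(self.qt_ms))


@dataclass(frozen=True)
class HRSeries:
    """Beat-aligned heart-rate series in beats per minute."""

    hr_bpm: np.ndarray
    mean_override_bpm: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.hr_bpm, dtype=float)
        if arr.ndim != 1:
            raise ValueError("HR series must be one-dimensional")
        if np.any(arr <= 0) or (arr.size and not np.all(np.isfinite(arr))):
            raise ValueError("HR values must be positive and finite")
        object.__setattr__(self, "hr_bpm", arr)

    @property
    def n(self) -> int:
        return self.hr_bpm.size

    @property
    def hrm(self) -> float:
        if self.mean_override_bpm is not None:
            return float(self.mean_override_bpm)
        return float(np.mean(self.hr_bpm))

    @property
    def hrvar(self) -> float:
        _require_n(self.hr_bpm, 2, "HR variance")
        return float(np.var(self.hr_bpm, ddof=1))


@dataclass(frozen=True)
class QTVPanel:
    """The six QT-variability markers for one subject/series."""

    QTvar_ms2: float
    SDqt_ms: float
    STVqt_ms: float
    QTVN: float
    QTVI: float
    RMSSDqt_ms: float
    n_beats: int
    qtvi_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "QTvar": self.QTvar_ms2,
            "SDqt": self.SDqt_ms,
            "STVqt": self.STVqt_ms,
            "QTVN": self.QTVN,
            "QTVI": self.QTVI,
            "RMSSDqt": self.RMSSDqt_ms,
        }


def _coerce(series: QTSeries | Sequence[float]) -> QTSeries:
    if isinstance(series, QTSeries):
        return series
    return QTSeries(np.asarray(series, dtype=float))


def _require_n(arr: np.ndarray, n: int, what: str) -> None:
    if arr.size < n:
        raise ValueError(f"{what} requires at least {n} beats, got {arr.size}")


def qtvar(series: QTSeries | Sequence[float]) -> float:
    """Unbiased sample variance of the QT intervals, ms^2.

    Deviations are taken from the series mean (or its override), with the
    1/(n-1) normalisation.
    """
    s = _coerce(series)
    _require_n(s.qt_ms, 2, "QT variance")
    dev = s.qt_ms - s.qtm
    return float(np.sum(dev * dev) / (s.n - 1))


def sdqt(series: QTSeries | Sequence[float]) -> float:
    """Standard deviation of the QT intervals, ms (sqrt of :func:`qtvar`)."""
    return math.sqrt(qtvar(series))


def stvqt(series: QTSeries | Sequence[float], *, n_diffs: int | None = None) -> float:
    """Short-term QT variability, ms.

    Sum of absolute successive differences divided by ``n_d * sqrt(2)``.
    ``n_d`` defaults to the number of successive differences actually present
    (n - 1); pass ``n_diffs=30`` for the conventional fixed 30-beat window
    denominator.
    """
    s = _coerce(series)
    _require_n(s.qt_ms, 2, "STVqt")
    diffs = np.abs(np.diff(s.qt_ms))
    nd = diffs.size if n_diffs is None else int(n_diffs)
    if nd <= 0:
        raise ValueError("denominator n_d must be positive")
    return float(np.sum(diffs) / (nd * math.sqrt(2.0)))


def qtvn(series: QTSeries | Sequence[float]) -> float:
    """QT variance normalised to the squared mean QT (dimensionless)."""
    s = _coerce(series)
    return qtvar(s) / s.qtm**2


def qtvi_hr(qt: QTSeries | Sequence[float], hr: HRSeries | Sequence[float]) -> float:
    """QT variability index: log10[(QTvar/QTm^2) / (HRvar/HRm^2)].

    Raises ``ValueError`` when the heart-rate variance is zero (the index is
    undefined); a constant QT series yields ``-inf``.
    """
    q = _coerce(qt)
    h = hr if isinstance(hr, HRSeries) else HRSeries(np.asarray(hr, dtype=float))
    hr_norm = h.hrvar / h.hrm**2
    if hr_norm == 0.0:
        raise ValueError("QTVI undefined: heart-rate variance is zero")
    qt_norm = qtvn(q)
    if qt_norm == 0.0:
        return float("-inf")
    return math.log10(qt_norm / hr_norm)


def rmssdqt(series: QTSeries | Sequence[float]) -> float:
    """Root mean square of successive QT differences, ms.

    sqrt( (1/(n-1)) * sum of squared successive differences ), where n-1 is
    the number of differences.
    """
    s = _coerce(series)
    _require_n(s.qt_ms, 2, "RMSSDqt")
    diffs = np.diff(s.qt_ms)
    return float(math.sqrt(np.sum(diffs * diffs) / diffs.size))


def qtv_panel(
    qt: QTSeries | Sequence[float],
    hr: HRSeries | Sequence[float] | None = None,
    *,
    stv_n_diffs: int | None = None,
) -> QTVPanel:
    """Compute all six markers on one series.

    When ``hr`` is omitted or QTVN is zero the index QTVI is reported as
    ``nan``/``-inf`` respectively with ``qtvi_defined=False``.
    """
    q = _coerce(qt)
    var = qtvar(q)
    sd = math.sqrt(var)
    assert abs(sd * sd - var) <= 1e-9 * max(var, 1.0)
    qtvi = float("nan")
    defined = False
    if hr is not None:
        h = hr if isinstance(hr, HRSeries) else HRSeries(np.asarray(hr, dtype=float))
        try:
            qtvi = qtvi_hr(q, h)
            defined = math.isfinite(qtvi)
        except ValueError:
            qtvi = float("nan")
    return QTVPanel(
        QTvar_ms2=var,
        SDqt_ms=sd,
        STVqt_ms=stvqt(q, n_diffs=stv_n_diffs),
        QTVN=qtvn(q),
        QTVI=qtvi,
        RMSSDqt_ms=rmssdqt(q),
        n_beats=q.n,
        qtvi_defined=defined,
    )
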