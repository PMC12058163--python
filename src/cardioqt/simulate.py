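"""Synthetic-data generators with machine-readable ground truth.

Every raw-input class the analysis modules consume can be generated here
with known truth, so round-trip tests never rely on re-derived constants:

* :func:`gen_ecg` — parametric single-lead ECG. Each beat is a sum of
  Gaussian deflections (P, Q, R, S, T). Placement realises the programmed
  intervals *under the measurement conventions themselves*: the S-wave
  centre is root-solved so the waveform's isoelectric crossing after the S
  trough falls exactly at Q onset + QRS, and the T-wave centre so the 90%
  decline falls exactly at Q onset + QT. Additive white noise, sinusoidal
  baseline wander and per-beat QT jitter are applied on top; the returned
  fiducials refer to the noiseless construction.
* :func:`gen_qt_series` — stationary AR(1) beat-to-beat QT (and optionally
  heart-rate) series with stated mean, SD and lag-1 correlation.
* :func:`gen_voltage_clamp` — Hodgkin-Huxley-style gating-model sweep sets
  for the recognised pulse protocols, with analytic peak densities as truth.
* :func:`gen_ap` — an action potential whose APD20/50/90 are exact by
  construction (monotone interpolation through the programmed crossings).
* :func:`gen_masks` — rod-shaped cell cartoons whose ICD fraction,
  lateralisation ratio and fibrosis percentage are realised by pixel
  allocation.

Identical spec + seed always yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .clamp import Sweep, SweepSet
from .ecg import BeatFiducials, ECGRecord
from .histo import MaskSet
from .qtv import HRSeries, QTSeries

__all__ = [
    "ECGSpec",
    "GatingSpec",
    "MaskSpec",
    "gen_ecg",
    "gen_qt_series",
    "gen_voltage_clamp",
    "gen_ap",
    "gen_masks",
    "CLAMP_PROTOCOLS",
]

DEFAULT_SEED = 20250507

# Gaussian 10%-amplitude half-width in units of sigma: exp(-K^2/2) = 0.1
_K10 = math.sqrt(2.0 * math.log(10.0))


# ---------------------------------------------------------------------------
# ECG


@dataclass(frozen=True)
class ECGSpec:
    """Parameters of a synthetic single-lead ECG.

    Defaults emulate an anesthetised adult mouse (heart rate ~500 bpm,
    QT ~45 ms); :meth:`human` gives a resting-adult preset.
    """

    hr_bpm: float = 500.0
    pr_ms: float = 40.0
    qrs_ms: float = 10.0
    qt_ms: float = 45.0
    t_amplitude_mV: float = 0.25
    qt_sd_ms: float = 1.0
    noise_sd_mV: float = 0.01
    wander_hz: float = 0.2
    wander_mV: float = 0.2
    n_beats: int = 60
    sampling_hz: float = 4000.0
    seed: int = DEFAULT_SEED
    species: Literal["mouse", "human"] = "mouse"
    r_amplitude_mV: float = 1.0
    p_amplitude_mV: float = 0.15
    q_amplitude_mV: float = 0.2
    s_amplitude_mV: float = 0.3
    j_amplitude_mV: float = 0.05  # small J-point hump: steep S-end crossing

    @staticmethod
    def human(**overrides) -> "ECGSpec":
        base = dict(
            hr_bpm=60.0, pr_ms=160.0, qrs_ms=90.0, qt_ms=400.0,
            t_amplitude_mV=0.3, qt_sd_ms=5.0, noise_sd_mV=0.005,
            wander_hz=0.15, wander_mV=0.1, n_beats=30, sampling_hz=1000.0,
            species="human",
        )
        base.update(overrides)
        return ECGSpec(**base)

    @property
    def rr_ms(self) -> float:
        return 60000.0 / self.hr_bpm

    def validate(self) -> None:
        if self.hr_bpm <= 0 or self.sampling_hz <= 0 or self.n_beats < 1:
            raise ValueError("rate, sampling and beat count must be positive")
        if min(self.qt_sd_ms, self.noise_sd_mV, self.wander_mV) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.qt_ms >= self.rr_ms:
            raise ValueError("QT must be shorter than the cycle length")
        # the T wave must end before the next beat's P region
        t_end = -0.4 * self.qrs_ms + self.qt_ms
        if t_end >= self.rr_ms - self.pr_ms - 10.0:
            raise ValueError("infeasible interval combination: T overlaps next P")


@dataclass(frozen=True)
class _Bump:
    center_ms: float
    sigma_ms: float
    amp_mV: float

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        z = (np.asarray(t, dtype=float) - self.center_ms) / self.sigma_ms
        return self.amp_mV * np.exp(-0.5 * z * z)


def _beat_template(spec: ECGSpec) -> dict:
    """Place the five deflections of one beat (times relative to R = 0)."""
    pr, qrs, qt = spec.pr_ms, spec.qrs_ms, spec.qt_ms
    sig_p, sig_q = 0.12 * pr, 0.07 * qrs
    sig_r, sig_s, sig_t = 0.08 * qrs, 0.10 * qrs, 0.12 * qt

    q_onset = -0.4 * qrs
    s_end = q_onset + qrs
    t_end = q_onset + qt

    p = _Bump(-pr + _K10 * sig_p, sig_p, spec.p_amplitude_mV)
    q = _Bump(q_onset + _K10 * sig_q, sig_q, -spec.q_amplitude_mV)
    r = _Bump(0.0, sig_r, spec.r_amplitude_mV)
    # J-point hump just after the S crossing: the waveform then crosses the
    # isoelectric line with a usable slope instead of a flat Gaussian tail
    sig_j = 0.15 * qrs
    j = _Bump(s_end + sig_j, sig_j, spec.j_amplitude_mV)

    c_t = t_end - _K10 * sig_t  # initial guess: isolated T wave
    c_s = s_end - 2.0 * sig_s
    for _ in range(3):  # alternate the two placements; converges immediately
        t_bump = _Bump(c_t, sig_t, spec.t_amplitude_mV)
        # S centre: waveform must cross the isoelectric line exactly at s_end
        others_at_send = float(p(s_end) + q(s_end) + r(s_end) + j(s_end) + t_bump(s_end))
        if not 0.0 < others_at_send < spec.s_amplitude_mV:
            raise ValueError("infeasible interval combination: no S crossing")
        c_s = s_end - sig_s * math.sqrt(-2.0 * math.log(others_at_send / spec.s_amplitude_mV))
        s_bump = _Bump(c_s, sig_s, -spec.s_amplitude_mV)

        # T centre: the 90%-decline point must fall exactly at t_end
        def w(t: float, ct: float) -> float:
            tb = _Bump(ct, sig_t, spec.t_amplitude_mV)
            return float(p(t) + q(t) + r(t) + s_bump(t) + j(t) + tb(t))

        def f(ct: float) -> float:
            peak = w(ct, ct)  # waveform height at the T centre
            return w(t_end, ct) - 0.1 * peak

        lo, hi = t_end - 6.0 * sig_t, t_end - 0.3 * sig_t
        if f(lo) >= 0 or f(hi) <= 0:
            raise ValueError("infeasible interval combination: T decline")
        c_t = brentq(f, lo, hi, xtol=1e-10)

    t_bump = _Bump(c_t, sig_t, spec.t_amplitude_mV)
    return {
        "bumps": (p, q, r, _Bump(c_s, sig_s, -spec.s_amplitude_mV), j),
        "t_bump": t_bump,
        "q_onset": q_onset,
        "s_end": s_end,
        "t_end": t_end,
        "p_onset": -pr,
    }


def gen_ecg(spec: ECGSpec) -> tuple[ECGRecord, list[BeatFiducials]]:
    """Generate an ECG record and its ground-truth fiducials.

    Per-beat QT jitter (SD ``qt_sd_ms``) shifts the whole T wave; all other
    intervals are constant across beats. Fiducials are float sample
    positions into the returned record; the isoelectric truth is 0 mV.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tpl = _beat_template(spec)
    fs = spec.sampling_hz
    rr = spec.rr_ms

    pad_pre = spec.pr_ms + 40.0 if spec.species == "mouse" else spec.pr_ms + 200.0
    pad_post = rr
    total_ms = pad_pre + spec.n_beats * rr + pad_post
    n = int(round(total_ms * fs / 1000.0))
    t_ms = np.arange(n) * (1000.0 / fs)
    v = np.zeros(n)

    dqt = rng.normal(0.0, spec.qt_sd_ms, size=spec.n_beats) if spec.qt_sd_ms > 0 else np.zeros(spec.n_beats)

    def add(bump: _Bump, center_abs: float) -> None:
        lo = np.searchsorted(t_ms, center_abs - 8.0 * bump.sigma_ms)
        hi = np.searchsorted(t_ms, center_abs + 8.0 * bump.sigma_ms)
        z = (t_ms[lo:hi] - center_abs) / bump.sigma_ms
        v[lo:hi] += bump.amp_mV * np.exp(-0.5 * z * z)

    truth: list[BeatFiducials] = []
    for k in range(spec.n_beats):
        r_time = pad_pre + k * rr
        for b in tpl["bumps"]:
            add(b, r_time + b.center_ms)
        tb = tpl["t_bump"]
        add(tb, r_time + tb.center_ms + dqt[k])

        def smp(ms: float) -> float:
            return ms * fs / 1000.0

        truth.append(
            BeatFiducials(
                r_peak=smp(r_time),
                isoelectric_level=0.0,
                p_onset=smp(r_time + tpl["p_onset"]),
                q_onset=smp(r_time + tpl["q_onset"]),
                s_end=smp(r_time + tpl["s_end"]),
                t_peak=smp(r_time + tpl["t_bump"].center_ms + dqt[k]),
                t_end90=smp(r_time + tpl["t_end"] + dqt[k]),
            )
        )

    if spec.wander_mV > 0:
        v += spec.wander_mV * np.sin(2.0 * math.pi * spec.wander_hz * t_ms / 1000.0)
    if spec.noise_sd_mV > 0:
        v += rng.normal(0.0, spec.noise_sd_mV, size=n)

    record = ECGRecord(samples=v, sampling_rate=fs, lead_label="II", species_hint=spec.species)
    return record, truth


def gen_qt_series(
    n: int,
    qtm_ms: float,
    sd_ms: float,
    lag1_corr: float = 0.0,
    seed: int = DEFAULT_SEED,
    *,
    hr_mean_bpm: float | None = None,
    hr_sd_bpm: float = 3.0,
    hr_lag1_corr: float = 0.0,
) -> QTSeries | tuple[QTSeries, HRSeries]:
    """Stationary AR(1) beat-to-beat QT series (and optional aligned HR).

    The process has exact stationary mean ``qtm_ms``, SD ``sd_ms`` and
    lag-1 autocorrelation ``lag1_corr``.
    """
    if not -1.0 < lag1_corr < 1.0:
        raise ValueError("|lag-1 correlation| must be < 1")
    rng = np.random.default_rng(seed)

    def ar1(n, mu, sd, phi):
        x = np.empty(n)
        if sd == 0:
            x[:] = mu
            return x
        innov_sd = sd * math.sqrt(1.0 - phi * phi)
        x[0] = mu + rng.normal(0.0, sd)
        for i in range(1, n):
            x[i] = mu + phi * (x[i - 1] - mu) + rng.normal(0.0, innov_sd)
        return x

    qt = QTSeries(ar1(n, qtm_ms, sd_ms, lag1_corr))
    if hr_mean_bpm is None:
        return qt
    hr = HRSeries(ar1(n, hr_mean_bpm, hr_sd_bpm, hr_lag1_corr))
    return qt, hr


# ---------------------------------------------------------------------------
# voltage clamp


@dataclass(frozen=True)
class GatingSpec:
    """Parameters of the gating model generating voltage-clamp sweeps.

    The model is ``I(t) = Gmax * m_inf(V) * (1 - exp(-t/tau_act)) * h(t) *
    (V - Erev)`` with ``m_inf`` a rising Boltzmann and ``h`` a biexponential
    availability decay toward ``late_fraction``. Prepulse availability and
    paired-pulse recovery follow the inactivation Boltzmann and ``tau_react``.
    Presets carry typical wildtype mouse ventricular values.
    """

    Gmax_nS: float = 150.0
    Erev_mV: float = 65.0
    Vh_act_mV: float = -52.9
    k_act_mV: float = 4.0
    Vh_inact_mV: float = -86.9
    k_inact_mV: float = 5.0
    tau_act_ms: float = 0.5
    tau_f_ms: float = 1.3
    tau_s_ms: float = 4.5
    frac_fast: float = 0.9
    late_fraction: float = 0.005
    tau_react_ms: float = 8.2
    noise_sd_pA: float = 0.0
    capacitance_pF: float = 150.0
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if not self.tau_f_ms < self.tau_s_ms:
            raise ValueError("tau_f must be < tau_s")
        if not 0.0 <= self.late_fraction < 1.0:
            raise ValueError("late_fraction must be in [0, 1)")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ValueError("frac_fast must be in [0, 1]")
        if min(self.tau_act_ms, self.tau_f_ms, self.capacitance_pF) <= 0:
            raise ValueError("time constants and capacitance must be positive")

    @staticmethod
    def wt_na(**overrides) -> "GatingSpec":
        """Fast sodium current, wildtype-like."""
        return GatingSpec(**overrides)

    @staticmethod
    def wt_cal(**overrides) -> "GatingSpec":
        """L-type calcium current, wildtype-like."""
        base = dict(
            Gmax_nS=20.0, Erev_mV=60.0, Vh_act_mV=-11.1, k_act_mV=6.4,
            Vh_inact_mV=-33.5, k_inact_mV=5.2, tau_act_ms=1.1,
            tau_f_ms=20.1, tau_s_ms=72.2, frac_fast=0.7, late_fraction=0.02,
            tau_react_ms=50.0,
        )
        base.update(overrides)
        return GatingSpec(**base)

    @staticmethod
    def wt_outward_k(**overrides) -> "GatingSpec":
        """Transient + sustained outward potassium current, wildtype-like."""
        base = dict(
            Gmax_nS=40.0, Erev_mV=-85.0, Vh_act_mV=-4.6, k_act_mV=14.3,
            Vh_inact_mV=-32.9, k_inact_mV=7.6, tau_act_ms=1.0,
            tau_f_ms=156.0, tau_s_ms=1560.0, frac_fast=1.0,
            late_fraction=0.35, tau_react_ms=15.5,
        )
        base.update(overrides)
        return GatingSpec(**base)


CLAMP_PROTOCOLS: dict[str, dict] = {
    "iv_na": dict(hold=-120.0, potentials=np.arange(-100.0, 35.0, 5.0),
                  pulse_ms=50.0, fs=50000.0),
    "inact_na": dict(hold=-120.0, prepulses=np.arange(-140.0, -10.0, 10.0),
                     test=-20.0, pulse_ms=50.0, fs=50000.0),
    "recovery_na": dict(hold=-120.0, test=-40.0, pulse_ms=50.0, fs=50000.0,
                        intervals=(0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0,
                                   20.0, 50.0, 100.0, 200.0, 500.0)),
    "late_na": dict(hold=-120.0, potentials=np.array([-40.0]),
                    pulse_ms=500.0, fs=50000.0),
    "iv_cal": dict(hold=-80.0, potentials=np.arange(-40.0, 55.0, 5.0),
                   pulse_ms=500.0, fs=4000.0),
    "inact_cal": dict(hold=-70.0, prepulses=np.arange(-90.0, 55.0, 10.0),
                      test=0.0, pulse_ms=500.0, fs=4000.0),
    "ik1": dict(hold=-80.0, potentials=np.arange(-120.0, -25.0, 10.0),
                pulse_ms=250.0, fs=4000.0),
    "outward_k": dict(hold=-80.0, potentials=np.arange(-80.0, 55.0, 10.0),
                      pulse_ms=500.0, fs=4000.0),
}

_PRE_MS = 5.0
_POST_MS = 5.0


def _m_inf(spec: GatingSpec, v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - spec.Vh_act_mV) / spec.k_act_mV))


def _h_inf(spec: GatingSpec, v: float) -> float:
    return 1.0 / (1.0 + math.exp((v - spec.Vh_inact_mV) / spec.k_inact_mV))


def _pulse_current(spec: GatingSpec, v: float, t_ms: np.ndarray, *, avail: float = 1.0,
                   mono_decay: bool = False) -> np.ndarray:
    """Noiseless gating-model current (pA) at test potential v, t from pulse start."""
    if mono_decay:
        h = (1.0 - spec.late_fraction) * np.exp(-t_ms / spec.tau_f_ms) + spec.late_fraction
    else:
        h = (1.0 - spec.late_fraction) * (
            spec.frac_fast * np.exp(-t_ms / spec.tau_f_ms)
            + (1.0 - spec.frac_fast) * np.exp(-t_ms / spec.tau_s_ms)
        ) + spec.late_fraction
    act = 1.0 - np.exp(-t_ms / spec.tau_act_ms)
    return spec.Gmax_nS * _m_inf(spec, v) * act * h * (v - spec.Erev_mV) * avail


def _assemble(spec: GatingSpec, rng, fs: float, pulse_ms: float, v: float,
              hold: float, current_fn, meta: dict | None = None) -> Sweep:
    dt = 1000.0 / fs
    n_pre = int(round(_PRE_MS / dt))
    n_pulse = int(round(pulse_ms / dt))
    n_post = int(round(_POST_MS / dt))
    t = np.arange(n_pre + n_pulse + n_post) * dt
    i = np.zeros_like(t)
    tp = t[n_pre : n_pre + n_pulse] - t[n_pre]
    i[n_pre : n_pre + n_pulse] = current_fn(tp)
    if spec.noise_sd_pA > 0:
        i = i + rng.normal(0.0, spec.noise_sd_pA, size=i.size)
    return Sweep(
        time_ms=t, current_pA=i, test_potential_mV=v, holding_potential_mV=hold,
        pulse_start_ms=float(t[n_pre]), pulse_duration_ms=pulse_ms,
        meta=meta or {},
    )


def gen_voltage_clamp(spec: GatingSpec, protocol: str) -> SweepSet:
    """Generate a sweep set for one of the recognised pulse protocols.

    The returned set's ``truth`` carries the generator parameters and the
    noiseless peak current density (peak minus end level, pA/pF) per sweep.
    """
    spec.validate()
    if protocol not in CLAMP_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; known: {sorted(CLAMP_PROTOCOLS)}")
    geo = CLAMP_PROTOCOLS[protocol]
    rng = np.random.default_rng(spec.seed)
    fs, pulse_ms, hold = geo["fs"], geo["pulse_ms"], geo["hold"]
    cm = spec.capacitance_pF
    sweeps: list[Sweep] = []
    peak_truth: dict[float, float] = {}

    def record_truth(key: float, i_clean: np.ndarray) -> None:
        end = float(np.mean(i_clean[int(0.95 * i_clean.size):]))
        pk = i_clean[int(np.argmax(np.abs(i_clean - end)))]
        peak_truth[key] = (pk - end) / cm

    late_truth: dict[float, float] = {}
    if protocol in ("iv_na", "iv_cal", "late_na"):
        for v in geo["potentials"]:
            clean = lambda tp, v=v: _pulse_current(spec, v, tp)
            sweeps.append(_assemble(spec, rng, fs, pulse_ms, float(v), hold, clean))
            tp = np.arange(int(round(pulse_ms * fs / 1000.0))) * (1000.0 / fs)
            i_clean = _pulse_current(spec, float(v), tp)
            record_truth(float(v), i_clean)
            pk = i_clean[int(np.argmax(np.abs(i_clean)))]
            if pk != 0.0:
                late = float(np.mean(i_clean[int(0.9 * i_clean.size):]))
                late_truth[float(v)] = 100.0 * late / pk
    elif protocol in ("inact_na", "inact_cal"):
        v_test = geo["test"]
        for vp in geo["prepulses"]:
            avail = _h_inf(spec, float(vp))
            clean = lambda tp, a=avail: _pulse_current(spec, v_test, tp, avail=a)
            sweeps.append(
                _assemble(spec, rng, fs, pulse_ms, v_test, hold, clean,
                          meta={"prepulse_mV": float(vp)})
            )
            peak_truth[float(vp)] = avail
    elif protocol == "recovery_na":
        v = geo["test"]
        dt = 1000.0 / fs
        for interval in geo["intervals"]:
            gap = max(interval, dt)
            n_pre = int(round(_PRE_MS / dt))
            n_pulse = int(round(pulse_ms / dt))
            n_gap = int(round(gap / dt))
            n_post = int(round(_POST_MS / dt))
            n = n_pre + 2 * n_pulse + n_gap + n_post
            t = np.arange(n) * dt
            i = np.zeros(n)
            tp = np.arange(n_pulse) * dt
            i[n_pre : n_pre + n_pulse] = _pulse_current(spec, v, tp)
            recov = 1.0 - math.exp(-gap / spec.tau_react_ms)
            p2_start = n_pre + n_pulse + n_gap
            i[p2_start : p2_start + n_pulse] = _pulse_current(spec, v, tp, avail=recov)
            if spec.noise_sd_pA > 0:
                i = i + rng.normal(0.0, spec.noise_sd_pA, size=n)
            sweeps.append(
                Sweep(
                    time_ms=t, current_pA=i, test_potential_mV=v,
                    holding_potential_mV=hold, pulse_start_ms=float(t[n_pre]),
                    pulse_duration_ms=pulse_ms,
                    meta={
                        "p1_start_ms": float(t[n_pre]),
                        "p2_start_ms": float(t[p2_start]),
                        "interval_ms": float(gap),
                    },
                )
            )
            peak_truth[float(gap)] = recov
    elif protocol == "ik1":
        # quasi-ohmic inward rectifier: steady I = Gmax * (V - EK)
        for v in geo["potentials"]:
            clean = lambda tp, v=v: spec.Gmax_nS * (v - spec.Erev_mV) * (1.0 - np.exp(-tp / spec.tau_act_ms))
            sweeps.append(_assemble(spec, rng, fs, pulse_ms, float(v), hold, clean))
            peak_truth[float(v)] = spec.Gmax_nS * (float(v) - spec.Erev_mV) / cm
    elif protocol == "outward_k":
        for v in geo["potentials"]:
            clean = lambda tp, v=v: _pulse_current(spec, v, tp, mono_decay=True)
            sweeps.append(_assemble(spec, rng, fs, pulse_ms, float(v), hold, clean))
            tp = np.arange(int(round(pulse_ms * fs / 1000.0))) * (1000.0 / fs)
            record_truth(float(v), _pulse_current(spec, float(v), tp, mono_decay=True))

    truth = {"spec": asdict(spec), "peak": peak_truth}
    if late_truth:
        truth["late_percent"] = late_truth
    return SweepSet(
        sweeps=tuple(sweeps),
        protocol=protocol,
        cell_capacitance_pF=cm,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# action potentials


def gen_ap(
    rmp_mV: float = -75.0,
    apa_mV: float = 110.0,
    apd20_ms: float = 4.0,
    apd50_ms: float = 12.0,
    apd90_ms: float = 60.0,
    sampling_hz: float = 10000.0,
    seed: int = DEFAULT_SEED,
    *,
    noise_sd_mV: float = 0.0,
) -> Sweep:
    """A single action potential with exact programmed APD20/50/90.

    Repolarisation is a monotone piecewise-cubic through the programmed
    crossing points measured from the peak, so the three durations are
    realised by construction. Stimulus window and truth live in ``meta``.
    """
    if not 0 < apd20_ms < apd50_ms < apd90_ms:
        raise ValueError("APDs must satisfy 0 < APD20 < APD50 < APD90")
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_hz
    stim_start, stim_dur, upstroke = 20.0, 2.0, 1.5
    t_peak = stim_start + upstroke
    peak = rmp_mV + apa_mV
    tail = apd90_ms * 0.4 + 5.0
    total = t_peak + apd90_ms + tail + 20.0
    t = np.arange(int(round(total / dt))) * dt
    v = np.full(t.size, rmp_mV, dtype=float)

    if apa_mV > 0:
        up = (t >= stim_start) & (t < t_peak)
        v[up] = rmp_mV + apa_mV * 0.5 * (1.0 - np.cos(math.pi * (t[up] - stim_start) / upstroke))
        knots_t = np.array([0.0, apd20_ms, apd50_ms, apd90_ms, apd90_ms + tail])
        knots_v = np.array([
            peak,
            peak - 0.20 * apa_mV,
            peak - 0.50 * apa_mV,
            peak - 0.90 * apa_mV,
            rmp_mV,
        ])
        repol = PchipInterpolator(knots_t, knots_v)
        rp = (t >= t_peak) & (t <= t_peak + apd90_ms + tail)
        v[rp] = repol(t[rp] - t_peak)
    if noise_sd_mV > 0:
        v = v + rng.normal(0.0, noise_sd_mV, size=v.size)

    return Sweep(
        time_ms=t, current_pA=v, test_potential_mV=0.0, holding_potential_mV=rmp_mV,
        pulse_start_ms=stim_start, pulse_duration_ms=stim_dur,
        meta={
            "kind": "action_potential",
            "stim_window_ms": (stim_start, stim_start + stim_dur),
            "truth": {
                "RMP_mV": rmp_mV, "APA_mV": apa_mV,
                "APD20_ms": apd20_ms, "APD50_ms": apd50_ms, "APD90_ms": apd90_ms,
            },
        },
    )


# ---------------------------------------------------------------------------
# histology masks


@dataclass(frozen=True)
class MaskSpec:
    """Parameters of the rod-cell mask cartoon; truths in percent."""

    icd_fraction_truth: float = 40.0
    lateral_ratio_truth: float = 30.0
    fibrosis_truth: float = 5.0
    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    n_cells: int | None = None
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if min(self.icd_fraction_truth, self.lateral_ratio_truth, self.fibrosis_truth) < 0:
            raise ValueError("truth fractions must be non-negative")
        if self.icd_fraction_truth > 100 or self.fibrosis_truth > 100:
            raise ValueError("ICD fraction and fibrosis are percentages of an area")


def gen_masks(spec: MaskSpec) -> tuple[MaskSet, dict]:
    """Rod-shaped cell cartoons realising the spec's area fractions.

    Cells are rectangles with N-Cadherin ICD bands at both ends and
    WGA-positive membrane along the ends and long sides. Cx43 and PSR
    pixels are randomly allocated inside the appropriate compartments to
    hit the programmed fractions up to pixel rounding; the achieved exact
    fractions are returned as truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    tissue = np.zeros((h, w), dtype=bool)
    tissue[4 : h - 4, 4 : w - 4] = True

    ncadh = np.zeros_like(tissue)
    wga = np.zeros_like(tissue)
    cell_h, cell_w, gap, icd_w, mem_w = 20, 60, 4, 5, 3
    placed = 0
    for row0 in range(6, h - 6 - cell_h, cell_h + gap):
        for col0 in range(6, w - 6 - cell_w, cell_w + gap):
            if spec.n_cells is not None and placed >= spec.n_cells:
                break
            r1, c1 = row0 + cell_h, col0 + cell_w
            ncadh[row0:r1, col0 : col0 + icd_w] = True
            ncadh[row0:r1, c1 - icd_w : c1] = True
            wga[row0:r1, col0 : col0 + icd_w] = True
            wga[row0:r1, c1 - icd_w : c1] = True
            wga[row0 : row0 + mem_w, col0:c1] = True
            wga[r1 - mem_w : r1, col0:c1] = True
            placed += 1

    lateral_only = wga & ~ncadh
    cx43 = np.zeros_like(tissue)

    def allocate(region: np.ndarray, count: int) -> None:
        idx = np.flatnonzero(region)
        if count > idx.size:
            raise ValueError("requested fraction exceeds compartment capacity")
        chosen = rng.choice(idx, size=count, replace=False)
        cx43.flat[chosen] = True

    n_icd = int(round(spec.icd_fraction_truth / 100.0 * ncadh.sum()))
    allocate(ncadh, n_icd)
    n_lat = int(round(spec.lateral_ratio_truth / 100.0 * n_icd))
    allocate(lateral_only, n_lat)

    psr = np.zeros_like(tissue)
    n_psr = int(round(spec.fibrosis_truth / 100.0 * tissue.sum()))
    idx = np.flatnonzero(tissue)
    psr.flat[rng.choice(idx, size=n_psr, replace=False)] = True

    masks = MaskSet(
        masks={"cx43": cx43, "ncadh": ncadh, "wga_lateral": wga, "psr": psr, "tissue": tissue},
        pixel_size_um=spec.pixel_size_um,
    )
    truth = {
        "icd_fraction_pct": 100.0 * (cx43 & ncadh).sum() / ncadh.sum(),
        "lateral_ratio_pct": (
            100.0 * (cx43 & lateral_only).sum() / max((cx43 & ncadh).sum(), 1)
        ),
        "fibrosis_pct": 100.0 * (psr & tissue).sum() / tissue.sum(),
        "n_cells": placed,
    }
    return masks, truth
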