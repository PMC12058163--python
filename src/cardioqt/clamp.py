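"""Whole-cell voltage-clamp and current-clamp analysis.

Implements the standard curve analyses for cardiomyocyte recordings:

* peak / sustained amplitudes (peak-minus-end and end-of-pulse conventions),
* current densities (pA/pF) and current-voltage (I-V) relationships,
* I-V fits of the form ``I = (Vm - Erev) * Gmax / (1 + exp(-(Vm - Vh)/k))``
  yielding the maximal conductance, reversal potential and activation
  midpoint/slope,
* conductance transformation ``G = I / (Vm - Erev)`` and Boltzmann fits of
  normalised activation / availability curves,
* steady-state inactivation curves from prepulse protocols,
* recovery from inactivation (paired-pulse P2/P1 ratio, monoexponential),
* mono/biexponential decay kinetics, late-current percentage, and charge
  integration (area between peak and end-of-pulse level),
* action-potential metrics: RMP, amplitude, APD at 20/50/90% repolarisation.

Sign conventions follow electrophysiological practice: inward currents are
negative. Slope factors ``k`` are reported positive for both activation and
inactivation; the direction of the sigmoid is carried separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from lmfit import Model

__all__ = [
    "Sweep",
    "SweepSet",
    "IVCurve",
    "GatingFit",
    "KineticsFit",
    "ChargeCurve",
    "APMetrics",
    "peak_amplitude",
    "sustained_amplitude",
    "current_density",
    "build_iv",
    "fit_iv",
    "conductance_curve",
    "boltzmann_fit",
    "inactivation_curve",
    "recovery_from_inactivation",
    "decay_kinetics",
    "late_current_percent",
    "charge_density",
    "charge_curve",
    "ik1_measure",
    "ap_metrics",
]

DEFAULT_BLANK_MS = 0.3  # capacitive-transient blanking at pulse onset
END_WINDOW_FRAC = 0.05  # "end of pulse" = mean over the last 5% of the pulse


@dataclass(frozen=True)
class Sweep:
    """One trace: uniformly sampled current (pA) or voltage (mV) vs time (ms)."""

    time_ms: np.ndarray
    current_pA: np.ndarray
    test_potential_mV: float
    holding_potential_mV: float
    pulse_start_ms: float
    pulse_duration_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        i = np.asarray(self.current_pA, dtype=float)
        if t.shape != i.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("time and current must be matching 1-D arrays")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")
        if self.pulse_start_ms < t[0] or self.pulse_start_ms + self.pulse_duration_ms > t[-1] + dt[0] / 2:
            raise ValueError("pulse window outside trace")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "current_pA", i)

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass(frozen=True)
class SweepSet:
    """Sweeps from one protocol on one cell, with its capacitance."""

    sweeps: tuple[Sweep, ...]
    protocol: str
    cell_capacitance_pF: float
    truth: dict | None = None  # ground truth when synthetic

    def __post_init__(self) -> None:
        if self.cell_capacitance_pF <= 0:
            raise ValueError("capacitance must be positive")
        object.__setattr__(self, "sweeps", tuple(self.sweeps))


@dataclass(frozen=True)
class IVCurve:
    """Current density (pA/pF) vs test potential (mV)."""

    vm_mV: np.ndarray
    density_pA_pF: np.ndarray
    measurement: Literal["peak_minus_end", "end_of_pulse"]


@dataclass(frozen=True)
class GatingFit:
    """Parameters of an I-V / Boltzmann gating fit; ``k_mV`` is positive."""

    Gmax: float
    Erev_mV: float
    Vh_mV: float
    k_mV: float
    curve_role: Literal["activation_conductance", "availability_inactivation"]
    fit_rmse: float


@dataclass(frozen=True)
class KineticsFit:
    """Exponential time constants (ms) from kinetics fits."""

    tau_act_ms: float | None = None
    tau_fast_inact_ms: float | None = None
    tau_slow_inact_ms: float | None = None
    amp_fast_fraction: float | None = None
    tau_react_ms: float | None = None
    tau_inact_mono_ms: float | None = None
    fit_rmse: float | None = None
    degraded_to_mono: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class ChargeCurve:
    """Charge density (pC/pF) vs test potential (mV)."""

    vm_mV: np.ndarray
    charge_pC_pF: np.ndarray


@dataclass(frozen=True)
class APMetrics:
    """Action-potential metrics: potentials in mV, durations in ms."""

    RMP_mV: float
    APA_mV: float
    APD20_ms: float
    APD50_ms: float
    APD90_ms: float


# ---------------------------------------------------------------------------
# amplitudes


def _pulse_indices(sweep: Sweep, blank_ms: float) -> np.ndarray:
    # half-open [start + blank, start + duration): the sample at exactly
    # start + duration already belongs to the post-pulse segment
    t = sweep.time_ms
    lo = sweep.pulse_start_ms + blank_ms
    hi = sweep.pulse_start_ms + sweep.pulse_duration_ms
    idx = np.nonzero((t >= lo) & (t < hi))[0]
    if idx.size < 2:
        raise ValueError("pulse shorter than the blanking window")
    return idx


def _end_level(sweep: Sweep) -> float:
    t = sweep.time_ms
    hi = sweep.pulse_start_ms + sweep.pulse_duration_ms
    lo = hi - END_WINDOW_FRAC * sweep.pulse_duration_ms
    idx = np.nonzero((t >= lo) & (t < hi))[0]
    return float(np.mean(sweep.current_pA[idx]))


def peak_amplitude(
    sweep: Sweep,
    polarity: Literal["inward", "outward", "auto"] = "auto",
    *,
    blank_ms: float = DEFAULT_BLANK_MS,
) -> float:
    """Signed transient amplitude: pulse extremum minus end-of-pulse level.

    The extremum search excludes a short blanking window at the pulse onset
    (residual capacitive transient). ``polarity`` selects the minimum
    (inward) or maximum (outward); ``auto`` takes whichever deviates more
    from the end-of-pulse level.
    """
    idx = _pulse_indices(sweep, blank_ms)
    seg = sweep.current_pA[idx]
    end = _end_level(sweep)
    if polarity == "inward":
        extremum = float(np.min(seg))
    elif polarity == "outward":
        extremum = float(np.max(seg))
    else:
        mn, mx = float(np.min(seg)), float(np.max(seg))
        extremum = mn if abs(mn - end) >= abs(mx - end) else mx
    return extremum - end


def sustained_amplitude(sweep: Sweep) -> float:
    """End-of-pulse current relative to the pre-pulse baseline (pA)."""
    t = sweep.time_ms
    pre = np.nonzero(t < sweep.pulse_start_ms)[0]
    baseline = float(np.mean(sweep.current_pA[pre])) if pre.size else 0.0
    return _end_level(sweep) - baseline


def current_density(amplitude_pA: float, capacitance_pF: float) -> float:
    """Normalise a current amplitude to cell capacitance (pA/pF)."""
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be positive")
    return amplitude_pA / capacitance_pF


# ---------------------------------------------------------------------------
# I-V construction and fitting


def build_iv(
    sweep_set: SweepSet,
    measurement: Literal["peak_minus_end", "end_of_pulse"] = "peak_minus_end",
    *,
    polarity: Literal["inward", "outward", "auto"] = "auto",
    blank_ms: float = DEFAULT_BLANK_MS,
) -> IVCurve:
    """Current density vs test potential, ordered by potential."""
    vms = np.array([s.test_potential_mV for s in sweep_set.sweeps], dtype=float)
    if np.unique(vms).size != vms.size:
        raise ValueError("duplicate test potentials in I-V protocol")
    if measurement == "peak_minus_end":
        amps = np.array([peak_amplitude(s, polarity, blank_ms=blank_ms) for s in sweep_set.sweeps])
    else:
        amps = np.array([sustained_amplitude(s) for s in sweep_set.sweeps])
    dens = amps / sweep_set.cell_capacitance_pF
    order = np.argsort(vms)
    if not np.all(np.isfinite(dens)):
        raise ValueError("non-finite current density")
    return IVCurve(vm_mV=vms[order], density_pA_pF=dens[order], measurement=measurement)


def _iv_model(vm, gmax, erev, vh, k):
    return (vm - erev) * gmax / (1.0 + np.exp(-(vm - vh) / k))


def _guess_erev(vm: np.ndarray, i: np.ndarray) -> float:
    """Reversal potential initial guess: zero crossing beyond the peak."""
    ipk = int(np.argmax(np.abs(i)))
    for j in range(ipk, len(i) - 1):
        if i[j] == 0.0:
            return float(vm[j])
        if i[j] * i[j + 1] < 0:
            f = i[j] / (i[j] - i[j + 1])
            return float(vm[j] + f * (vm[j + 1] - vm[j]))
    # extrapolate the quasi-linear limb through zero
    if len(i) >= 2 and i[-1] != i[-2]:
        slope = (i[-1] - i[-2]) / (vm[-1] - vm[-2])
        if slope != 0:
            return float(vm[-1] - i[-1] / slope)
    return float(vm[-1] + 20.0)


def _guess_vh_k(vm: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    gmax = np.max(np.abs(g))
    gn = np.abs(g) / gmax if gmax > 0 else g

    def crossing(level: float) -> float:
        above = np.nonzero(gn >= level)[0]
        if above.size == 0:
            return float(vm[-1])
        j = above[0]
        if j == 0:
            return float(vm[0])
        f = (level - gn[j - 1]) / (gn[j] - gn[j - 1])
        return float(vm[j - 1] + f * (vm[j] - vm[j - 1]))

    vh = crossing(0.5)
    span = crossing(0.9) - crossing(0.1)
    k = max(span / 4.4, 0.5)
    return vh, k


def fit_iv(curve: IVCurve) -> GatingFit:
    """Least-squares fit of ``I = (Vm - Erev) * Gmax * Boltzmann(Vm)``.

    The Boltzmann occupancy rises with depolarisation; ``k`` is reported
    positive. Initialisation: ``Erev`` from the zero crossing beyond the
    peak, ``Vh``/``k`` from the normalised chord-conductance curve, ``Gmax``
    from the largest chord conductance.
    """
    vm, i = curve.vm_mV, curve.density_pA_pF
    if vm.size < 5:
        raise ValueError("need at least 5 I-V points")
    erev0 = _guess_erev(vm, i)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(np.abs(vm - erev0) > 1.0, i / (vm - erev0), np.nan)
    ok = np.isfinite(g)
    vh0, k0 = _guess_vh_k(vm[ok], g[ok])
    gmax0 = float(np.nanmax(np.abs(g))) or 1.0
    model = Model(_iv_model)
    params = model.make_params(gmax=gmax0, erev=erev0, vh=vh0, k=k0)
    params["k"].set(min=0.1, max=50.0)
    params["vh"].set(min=vh0 - 50.0, max=vh0 + 50.0)
    result = model.fit(i, params, vm=vm)
    if not result.success:
        raise RuntimeError(
            f"I-V fit did not converge (init Gmax={gmax0:.3g}, Erev={erev0:.3g}, "
            f"Vh={vh0:.3g}, k={k0:.3g})"
        )
    p = result.params
    rmse = float(np.sqrt(np.mean(result.residual**2)))
    return GatingFit(
        Gmax=float(p["gmax"].value),
        Erev_mV=float(p["erev"].value),
        Vh_mV=float(p["vh"].value),
        k_mV=abs(float(p["k"].value)),
        curve_role="activation_conductance",
        fit_rmse=rmse,
    )


def conductance_curve(
    curve: IVCurve, erev_mV: float, *, exclusion_mV: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised chord conductance ``G = I/(Vm - Erev)`` vs potential.

    Points within ``exclusion_mV`` of the reversal potential are excluded
    (the chord conductance is singular there).
    """
    keep = np.abs(curve.vm_mV - erev_mV) >= exclusion_mV
    if not np.any(keep):
        raise ValueError("all points excluded: potentials too close to Erev")
    vm = curve.vm_mV[keep]
    g = curve.density_pA_pF[keep] / (vm - erev_mV)
    gmax = np.max(np.abs(g))
    if gmax == 0:
        return vm, g
    return vm, g / gmax


def _boltz(vm, vh, k, sign):
    return 1.0 / (1.0 + np.exp(sign * (vm - vh) / k))


def boltzmann_fit(
    vm: Sequence[float],
    y: Sequence[float],
    direction: Literal["rising", "falling"] = "rising",
) -> tuple[float, float]:
    """Fit ``y = 1/(1 + exp(±(Vm - Vh)/k))`` to a normalised curve.

    ``direction='rising'`` (activation) increases with depolarisation;
    ``'falling'`` (availability/inactivation) decreases. Returns ``(Vh, k)``
    with ``k > 0``.
    """
    vm = np.asarray(vm, dtype=float)
    y = np.asarray(y, dtype=float)
    if vm.size < 5:
        raise ValueError("need at least 5 points")
    sign = -1.0 if direction == "rising" else 1.0
    vh0, k0 = _guess_vh_k(vm, y if direction == "rising" else 1.0 - y)
    model = Model(lambda vm, vh, k: _boltz(vm, vh, k, sign))
    params = model.make_params(vh=vh0, k=k0)
    params["k"].set(min=0.05, max=100.0)
    result = model.fit(y, params, vm=vm)
    if not result.success:
        raise RuntimeError("Boltzmann fit did not converge")
    return float(result.params["vh"].value), abs(float(result.params["k"].value))


# ---------------------------------------------------------------------------
# inactivation / recovery protocols


def inactivation_curve(sweep_set: SweepSet) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state availability: normalised test-pulse peak vs prepulse Vm."""
    pre, amps = [], []
    for s in sweep_set.sweeps:
        if "prepulse_mV" not in s.meta:
            raise ValueError("sweep lacks prepulse metadata; not an inactivation protocol")
        pre.append(float(s.meta["prepulse_mV"]))
        amps.append(peak_amplitude(s))
    pre = np.asarray(pre)
    amps = np.asarray(amps)
    peak = np.max(np.abs(amps))
    if peak == 0:
        raise ValueError("no test-pulse current in any sweep")
    norm = np.abs(amps) / peak
    order = np.argsort(pre)
    return pre[order], norm[order]


def recovery_from_inactivation(
    sweep_set: SweepSet, *, fit_plateau: bool = False
) -> KineticsFit:
    """Recovery time constant from a paired-pulse (P1/P2) protocol.

    Each sweep holds two identical pulses separated by a coupling interval
    (sweep ``meta``: ``p1_start_ms``, ``p2_start_ms``, ``interval_ms``).
    The P2/P1 peak ratio vs interval is fitted with
    ``r(t) = plateau * (1 - exp(-t/tau))``; the plateau is fixed at 1 unless
    ``fit_plateau`` is set.
    """
    intervals, ratios = [], []
    for s in sweep_set.sweeps:
        meta = s.meta
        if not {"p1_start_ms", "p2_start_ms", "interval_ms"} <= meta.keys():
            raise ValueError("sweep lacks paired-pulse metadata")
        dur = s.pulse_duration_ms
        p1 = Sweep(s.time_ms, s.current_pA, s.test_potential_mV, s.holding_potential_mV,
                   meta["p1_start_ms"], dur, meta)
        p2 = Sweep(s.time_ms, s.current_pA, s.test_potential_mV, s.holding_potential_mV,
                   meta["p2_start_ms"], dur, meta)
        a1, a2 = peak_amplitude(p1), peak_amplitude(p2)
        if a1 == 0:
            continue
        intervals.append(float(meta["interval_ms"]))
        ratios.append(a2 / a1)
    if len(intervals) < 4:
        raise ValueError("need at least 4 coupling intervals")
    t = np.asarray(intervals)
    r = np.asarray(ratios)

    def recov(t, tau, plateau):
        return plateau * (1.0 - np.exp(-t / tau))

    model = Model(recov)
    tau0 = max(t[np.argmin(np.abs(r - (1 - math.exp(-1))))], t.min())
    params = model.make_params(tau=tau0, plateau=1.0)
    params["tau"].set(min=1e-3)
    params["plateau"].set(vary=fit_plateau, min=0.1, max=1.5)
    result = model.fit(r, params, t=t)
    if not result.success:
        raise RuntimeError("recovery fit did not converge")
    rmse = float(np.sqrt(np.mean(result.residual**2)))
    return KineticsFit(tau_react_ms=float(result.params["tau"].value), fit_rmse=rmse)


# ---------------------------------------------------------------------------
# decay kinetics, late current, charge


def decay_kinetics(
    sweep: Sweep,
    model: Literal["mono", "bi"] = "mono",
    *,
    blank_ms: float = DEFAULT_BLANK_MS,
    min_fraction: float = 0.02,
) -> KineticsFit:
    """Fit the current decay from the pulse peak to the end of the pulse.

    ``mono``: ``A*exp(-t/tau) + C``. ``bi``: two exponentials with
    ``tau_fast < tau_slow`` enforced by ordering after the fit. A
    biexponential fit whose minor component carries under ``min_fraction``
    of the decaying amplitude falls back to the monoexponential, flagged.
    A flat trace is flagged degenerate (no identifiable decay).
    """
    idx = _pulse_indices(sweep, blank_ms)
    seg_t = sweep.time_ms[idx]
    seg_i = sweep.current_pA[idx]
    end = _end_level(sweep)
    ipk = int(np.argmax(np.abs(seg_i - end)))
    t = seg_t[ipk:] - seg_t[ipk]
    i = seg_i[ipk:]
    amp0 = i[0] - end
    if abs(amp0) < 1e-9 or np.ptp(i) < 1e-9:
        return KineticsFit(degenerate=True)

    def mono(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    tau0 = max(t[-1] / 5.0, t[1] if t.size > 1 else 1.0)
    mono_model = Model(mono)
    mp = mono_model.make_params(a=amp0, tau=tau0, c=end)
    mp["tau"].set(min=1e-4)
    mono_res = mono_model.fit(i, mp, t=t)
    mono_rmse = float(np.sqrt(np.mean(mono_res.residual**2)))
    mono_fit = KineticsFit(
        tau_inact_mono_ms=float(mono_res.params["tau"].value), fit_rmse=mono_rmse
    )
    if model == "mono":
        return mono_fit

    def bi(t, af, tauf, as_, taus, c):
        return af * np.exp(-t / tauf) + as_ * np.exp(-t / taus) + c

    bi_model = Model(bi)
    bp = bi_model.make_params(
        af=amp0 * 0.6, tauf=tau0 / 3.0, as_=amp0 * 0.4, taus=tau0 * 3.0, c=end
    )
    bp["tauf"].set(min=1e-4)
    bp["taus"].set(min=1e-4)
    bi_res = bi_model.fit(i, bp, t=t)
    if not bi_res.success:
        raise RuntimeError("biexponential fit did not converge")
    p = bi_res.params
    af, tauf = float(p["af"].value), float(p["tauf"].value)
    as_, taus = float(p["as_"].value), float(p["taus"].value)
    if tauf > taus:  # enforce tau_fast < tau_slow by ordering
        af, as_ = as_, af
        tauf, taus = taus, tauf
    total = abs(af) + abs(as_)
    if total == 0 or min(abs(af), abs(as_)) / total < min_fraction:
        return KineticsFit(
            tau_inact_mono_ms=mono_fit.tau_inact_mono_ms,
            fit_rmse=mono_rmse,
            degraded_to_mono=True,
        )
    rmse = float(np.sqrt(np.mean(bi_res.residual**2)))
    return KineticsFit(
        tau_fast_inact_ms=tauf,
        tau_slow_inact_ms=taus,
        amp_fast_fraction=abs(af) / total,
        fit_rmse=rmse,
    )


def late_current_percent(
    sweep: Sweep, *, late_window_frac: float = 0.1, blank_ms: float = DEFAULT_BLANK_MS
) -> float:
    """Persistent current as a percentage of the peak current.

    The late level is the mean over the last ``late_window_frac`` of the
    pulse; peak and late share the sign convention (both measured from the
    zero-current baseline).
    """
    idx = _pulse_indices(sweep, blank_ms)
    seg = sweep.current_pA[idx]
    peak = seg[int(np.argmax(np.abs(seg)))]
    if abs(peak) < 1e-9:
        raise ValueError("peak current is zero; late fraction undefined")
    t = sweep.time_ms
    hi = sweep.pulse_start_ms + sweep.pulse_duration_ms
    lo = hi - late_window_frac * sweep.pulse_duration_ms
    late = float(np.mean(sweep.current_pA[(t >= lo) & (t < hi)]))
    return 100.0 * late / peak


def charge_density(
    sweep: Sweep, capacitance_pF: float, *, blank_ms: float = DEFAULT_BLANK_MS
) -> float:
    """Transient charge density (pC/pF): integral of the current above the
    end-of-pulse level, from the peak to the end of the pulse.

    A purely sustained (flat) current therefore carries zero charge by this
    definition.
    """
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be positive")
    idx = _pulse_indices(sweep, blank_ms)
    seg_i = sweep.current_pA[idx]
    end = _end_level(sweep)
    ipk = int(np.argmax(np.abs(seg_i - end)))
    t = sweep.time_ms[idx][ipk:]
    i = seg_i[ipk:]
    q_pA_ms = float(np.trapezoid(i - end, t))
    return q_pA_ms / 1000.0 / capacitance_pF  # pA*ms -> pC


def charge_curve(sweep_set: SweepSet, *, blank_ms: float = DEFAULT_BLANK_MS) -> ChargeCurve:
    """Charge density vs test potential for a step protocol."""
    vms = np.array([s.test_potential_mV for s in sweep_set.sweeps], dtype=float)
    q = np.array([
        charge_density(s, sweep_set.cell_capacitance_pF, blank_ms=blank_ms)
        for s in sweep_set.sweeps
    ])
    order = np.argsort(vms)
    return ChargeCurve(vm_mV=vms[order], charge_pC_pF=q[order])


def ik1_measure(sweep_set: SweepSet) -> IVCurve:
    """Inward-rectifier I-V: current measured at the end of each pulse."""
    return build_iv(sweep_set, measurement="end_of_pulse")


# ---------------------------------------------------------------------------
# action potentials


def ap_metrics(
    trace: Sweep,
    stim_window_ms: tuple[float, float],
    *,
    reference: Literal["peak", "upstroke"] = "peak",
    min_apa_mV: float = 10.0,
) -> APMetrics:
    """RMP, amplitude and APD20/50/90 from a single action potential.

    ``trace.current_pA`` holds membrane voltage in mV here (current-clamp).
    RMP is the mean voltage before the stimulus; APA the peak above RMP.
    APDx is measured from the reference time (peak by default, or the
    upstroke half-amplitude crossing) to the first interpolated crossing of
    ``peak - x% * APA`` during repolarisation.
    """
    t = trace.time_ms
    v = trace.current_pA
    stim_start, stim_end = stim_window_ms
    pre = v[t < stim_start]
    if pre.size == 0:
        raise ValueError("no pre-stimulus window for RMP")
    rmp = float(np.mean(pre))
    after = np.nonzero(t >= stim_start)[0]
    ipk = after[int(np.argmax(v[after]))]
    peak = float(v[ipk])
    apa = peak - rmp
    if apa < min_apa_mV:
        raise ValueError("no action potential elicited (amplitude below threshold)")

    if reference == "peak":
        t_ref = float(t[ipk])
    else:
        half = rmp + 0.5 * apa
        ups = np.nonzero((t >= stim_start) & (t <= t[ipk]))[0]
        j = ups[np.nonzero(v[ups] >= half)[0][0]]
        if j == 0 or v[j] == v[j - 1]:
            t_ref = float(t[j])
        else:
            f = (half - v[j - 1]) / (v[j] - v[j - 1])
            t_ref = float(t[j - 1] + f * (t[j] - t[j - 1]))

    def apd(pct: float) -> float:
        level = peak - pct / 100.0 * apa
        for j in range(ipk + 1, v.size):
            if v[j] <= level:
                if v[j] == v[j - 1]:
                    tc = t[j]
                else:
                    f = (v[j - 1] - level) / (v[j - 1] - v[j])
                    tc = t[j - 1] + f * (t[j] - t[j - 1])
                return float(tc - t_ref)
        raise ValueError(f"repolarisation never reached {pct}%")

    a20, a50, a90 = apd(20), apd(50), apd(90)
    return APMetrics(RMP_mV=rmp, APA_mV=apa, APD20_ms=a20, APD50_ms=a50, APD90_ms=a90)
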