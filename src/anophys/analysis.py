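"""Current-trace analysis: amplitude windows, activation threshold,
relaxation kinetics, tail-current reversal potential, Hill fits.

The analysis chain mirrors standard practice for strongly outward
rectifying, slowly activating currents:

* *instantaneous* amplitude = mean current 5-10 ms after step onset,
  *steady* amplitude = mean over a late window (275-300 ms by default);
  their difference isolates the time-dependent component;
* the activation threshold ``V_threshold`` is the first step at which the
  difference current exceeds twice the end-of-pulse noise SD;
* relaxations are fitted with single exponentials;
* the reversal potential is read from tail currents after an activating
  prepulse: each tail is fitted with a single exponential, extrapolated
  back to the step onset, and the zero crossing of a linear fit within a
  +/-40 mV window around the crossing gives ``V_rev``;
* Ca2+ dependence is fitted with the modified Hill equation
  ``y = base + (max - base) / (1 + (Ca/Ca_0.5)^h)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .recordings import Recording

__all__ = [
    "IVCurve",
    "ThresholdResult",
    "RelaxationFit",
    "VrevResult",
    "HillFitResult",
    "extract_amplitudes",
    "detect_threshold",
    "fit_relaxation",
    "estimate_vrev",
    "fit_hill",
]


@dataclass
class IVCurve:
    """Per-sweep amplitudes (pA) against command voltage (mV)."""

    voltages_mV: np.ndarray
    instantaneous_pA: np.ndarray
    steady_pA: np.ndarray
    difference_pA: np.ndarray
    noise_sd_pA: np.ndarray
    inst_window_ms: tuple[float, float] = (5.0, 10.0)
    steady_window_ms: tuple[float, float] = (275.0, 300.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voltages_mV, dtype=float)
        if v.size and not (np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)):
            raise ValueError("voltages must be strictly monotone in sweep order")


@dataclass
class ThresholdResult:
    """Detected activation threshold, or an explicit absence."""

    v_threshold_mV: float | None
    passed: np.ndarray
    multiplier: float
    left_censored: bool = False

    @property
    def detected(self) -> bool:
        return self.v_threshold_mV is not None


@dataclass
class RelaxationFit:
    voltage_mV: float
    tau_ms: float
    amplitude_pA: float
    offset_pA: float
    rmse_pA: float
    quality_flag: str | None = None

    @property
    def ok(self) -> bool:
        return self.quality_flag is None


@dataclass
class VrevResult:
    v_rev_mV: float
    step_voltages_mV: np.ndarray
    tail_amplitudes_pA: np.ndarray
    slope_pA_per_mV: float
    fit_window_mV: float
    window_mask: np.ndarray = field(repr=False, default=None)


@dataclass
class HillFitResult:
    i_base: float
    i_max: float
    ec50_um: float
    hill: float
    residuals: np.ndarray
    converged: bool


# ---------------------------------------------------------------------------


def _window_slice(rec: Recording, start_ms: float, stop_ms: float) -> slice:
    khz = rec.protocol.sampling_khz
    i0 = int(round(start_ms * khz))
    i1 = int(round(stop_ms * khz))
    return slice(i0, i1)


def extract_amplitudes(rec: Recording,
                       inst_window_ms: tuple[float, float] = (5.0, 10.0),
                       steady_window_ms: tuple[float, float] = (275.0, 300.0),
                       ) -> IVCurve:
    """Instantaneous/steady amplitudes and end-of-pulse noise per sweep.

    Windows are relative to the step onset.  The noise SD is computed on
    linearly detrended samples of the steady window, per sweep.
    """
    proto = rec.protocol
    for name, (a, b) in (("instantaneous", inst_window_ms),
                         ("steady", steady_window_ms)):
        if not (0.0 <= a < b <= proto.step_ms):
            raise ValueError(f"{name} window {a, b} outside the step (0-{proto.step_ms} ms)")
    onset = proto.step_start_ms
    sl_inst = _window_slice(rec, onset + inst_window_ms[0], onset + inst_window_ms[1])
    sl_steady = _window_slice(rec, onset + steady_window_ms[0], onset + steady_window_ms[1])

    inst = rec.sweeps_pA[:, sl_inst].mean(axis=1)
    late = rec.sweeps_pA[:, sl_steady]
    steady = late.mean(axis=1)

    # linear detrend of the late window, per sweep
    n = late.shape[1]
    x = np.arange(n) - (n - 1) / 2.0
    denom = float(np.sum(x * x))
    slope = (late * x).sum(axis=1) / denom
    resid = late - steady[:, None] - slope[:, None] * x
    noise = resid.std(axis=1, ddof=2) if n > 2 else np.zeros(late.shape[0])

    return IVCurve(
        voltages_mV=proto.step_voltages.astype(float),
        instantaneous_pA=inst,
        steady_pA=steady,
        difference_pA=steady - inst,
        noise_sd_pA=noise,
        inst_window_ms=inst_window_ms,
        steady_window_ms=steady_window_ms,
    )


def detect_threshold(iv: IVCurve, multiplier: float = 2.0) -> ThresholdResult:
    """First step voltage whose difference current beats ``multiplier`` x noise.

    Only positive (outward, activating) differences qualify.  Returns an
    explicit "none detected" result when no sweep passes; the result is
    flagged left-censored when the very first voltage already qualifies.
    """
    if iv.voltages_mV.size == 0:
        raise ValueError("empty IV curve")
    order = np.argsort(iv.voltages_mV)
    diff = np.asarray(iv.difference_pA)[order]
    noise = np.asarray(iv.noise_sd_pA)[order]
    volts = np.asarray(iv.voltages_mV)[order]
    passed = (diff > multiplier * noise) & (diff > 0)
    idx = np.flatnonzero(passed)
    if idx.size == 0:
        return ThresholdResult(None, passed, multiplier)
    first = int(idx[0])
    return ThresholdResult(float(volts[first]), passed, multiplier,
                           left_censored=(first == 0))


# ---------------------------------------------------------------------------


def _exp_model(segment: str):
    if segment == "activation":
        return lambda t, a, tau, c: a * (1.0 - np.exp(-t / tau)) + c
    return lambda t, a, tau, c: a * np.exp(-t / tau) + c


def fit_relaxation(rec: Recording, sweep: int,
                   segment: str = "activation",
                   blank_ms: float = 5.0) -> RelaxationFit:
    """Single-exponential fit of one sweep's activation or tail relaxation.

    Activation: ``a (1 - e^{-t/tau}) + c`` on the step; tail:
    ``a e^{-t/tau} + c`` on the tail pulse.  The first ``blank_ms`` after
    the transition are blanked (capacitative transient).  Poorly
    identified fits (amplitude within the residual noise, or tau at its
    bounds) are flagged, not raised.
    """
    proto = rec.protocol
    if segment == "activation":
        t0, dur = proto.step_start_ms, proto.step_ms
        voltage = float(proto.step_voltages[sweep])
    elif segment == "tail":
        if proto.tail_ms <= 0:
            raise ValueError("protocol has no tail pulse")
        t0, dur = proto.tail_start_ms, proto.tail_ms
        voltage = float(proto.tail_mV)
    else:
        raise ValueError("segment must be 'activation' or 'tail'")

    sl = _window_slice(rec, t0 + blank_ms, t0 + dur)
    y = rec.sweeps_pA[sweep, sl]
    if y.size < 20:
        raise ValueError("segment too short: need >= 20 samples after blanking")
    t = (np.arange(y.size) / proto.sampling_khz) + blank_ms

    model_fn = _exp_model(segment)
    model = lmfit.Model(model_fn)
    span = float(y.max() - y.min())
    a0 = span if segment == "activation" else (y[0] - y[-1])
    params = model.make_params(
        a=dict(value=a0 if a0 != 0 else 1.0),
        tau=dict(value=dur / 5.0, min=0.05, max=50.0 * dur),
        c=dict(value=float(y[0] if segment == "activation" else y[-1])),
    )
    result = model.fit(y, params, t=t)
    a = float(result.params["a"].value)
    tau = float(result.params["tau"].value)
    c = float(result.params["c"].value)
    rmse = float(np.sqrt(np.mean(result.residual**2)))

    flag = None
    scale = max(1.0, abs(c), abs(a))
    if abs(a) <= max(3.0 * rmse, 1e-2 * max(1.0, abs(c))):
        flag = "amplitude_within_noise"
    elif tau <= 0.06 or tau >= 49.0 * dur:
        flag = "tau_at_bounds"
    elif not result.success:
        flag = "fit_failed"
    del scale
    return RelaxationFit(voltage_mV=voltage, tau_ms=tau, amplitude_pA=a,
                         offset_pA=c, rmse_pA=rmse, quality_flag=flag)


# ---------------------------------------------------------------------------


def estimate_vrev(tail_rec: Recording, blank_ms: float = 5.0,
                  fit_window_mV: float = 40.0) -> VrevResult:
    """Reversal potential from tail currents after an activating prepulse.

    Each post-prepulse step is fitted with a decaying exponential and
    extrapolated back to the step onset (instantaneous tail amplitude,
    channels still open).  ``V_rev`` is the zero crossing of a linear fit
    restricted to ``+/- fit_window_mV`` around the crossing; two passes
    re-centre the window on the refined crossing.
    """
    proto = tail_rec.protocol
    if proto.prepulse_ms <= 0:
        raise ValueError("reversal-potential estimation needs a prepulse protocol")
    volts = proto.step_voltages.astype(float)
    if volts.size < 5:
        raise ValueError("need tail steps at >= 5 voltages")

    amps = np.empty(volts.size)
    sl = _window_slice(tail_rec, proto.step_start_ms + blank_ms,
                       proto.step_start_ms + proto.step_ms)
    t = (np.arange(sl.stop - sl.start) / proto.sampling_khz) + blank_ms
    model = lmfit.Model(lambda t, a, tau, c: a * np.exp(-t / tau) + c)
    for j in range(volts.size):
        y = tail_rec.sweeps_pA[j, sl]
        params = model.make_params(
            a=dict(value=float(y[0] - y[-1]) or 1.0),
            tau=dict(value=proto.step_ms / 5.0, min=0.05, max=50.0 * proto.step_ms),
            c=dict(value=float(y[-1])),
        )
        res = model.fit(y, params, t=t)
        # value extrapolated to the step onset (t = 0)
        amps[j] = float(res.params["a"].value + res.params["c"].value)

    signs = np.sign(amps)
    change = np.flatnonzero(np.diff(signs) != 0)
    if change.size == 0:
        raise ValueError("V_rev out of range: tail amplitudes do not change sign")
    j = int(change[0])
    # coarse crossing by local interpolation
    v0, v1, a0, a1 = volts[j], volts[j + 1], amps[j], amps[j + 1]
    crossing = v0 - a0 * (v1 - v0) / (a1 - a0)

    mask = np.zeros_like(volts, dtype=bool)
    slope = math.nan
    for _ in range(2):
        mask = np.abs(volts - crossing) <= fit_window_mV + 1e-9
        if mask.sum() < 2:
            mask = np.zeros_like(volts, dtype=bool)
            mask[j:j + 2] = True
        coeff = np.polyfit(volts[mask], amps[mask], 1)
        slope = float(coeff[0])
        crossing = float(-coeff[1] / coeff[0])
    return VrevResult(v_rev_mV=crossing, step_voltages_mV=volts,
                      tail_amplitudes_pA=amps, slope_pA_per_mV=slope,
                      fit_window_mV=fit_window_mV, window_mask=mask)


# ---------------------------------------------------------------------------


def _hill(ca, base, ymax, ec50, h):
    ca = np.asarray(ca, dtype=float)
    out = np.full(ca.shape, ymax, dtype=float)
    nz = ca > 0
    out[nz] = base + (ymax - base) / (1.0 + (ca[nz] / ec50) ** h)
    return out


def fit_hill(ca_um, y, direction: str = "decreasing",
             weights=None) -> HillFitResult:
    """Least-squares fit of the modified Hill equation.

    ``y = base + (max - base) / (1 + (Ca/Ca_0.5)^h)``; a zero
    concentration is handled exactly (the Hill term vanishes and
    ``y -> max``).  ``direction`` states whether the observable decreases
    or increases with Ca2+ and seeds the plateaus accordingly.
    """
    ca = np.asarray(ca_um, dtype=float)
    y = np.asarray(y, dtype=float)
    if ca.shape != y.shape:
        raise ValueError("ca and y must have the same length")
    if np.unique(ca).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if np.allclose(y, y[0]):
        raise ValueError("all observations equal; Hill fit is unidentified")
    if direction not in ("decreasing", "increasing"):
        raise ValueError("direction must be 'decreasing' or 'increasing'")

    order = np.argsort(ca)
    ca_s, y_s = ca[order], y[order]
    if direction == "decreasing":
        ymax0, base0 = float(y_s[0]), float(y_s[-1])
    else:
        ymax0, base0 = float(y_s[-1]), float(y_s[0])
    mid = 0.5 * (ymax0 + base0)
    pos = ca_s > 0
    # log-interpolated concentration where y crosses the midpoint
    ec50_0 = float(np.exp(np.interp(
        mid, np.sort(y_s[pos]), np.log(ca_s[pos])[np.argsort(y_s[pos])])))
    ec50_0 = min(max(ec50_0, ca_s[pos].min() / 10), ca_s[pos].max() * 10)

    model = lmfit.Model(_hill, independent_vars=["ca"])
    params = model.make_params(
        base=dict(value=base0),
        ymax=dict(value=ymax0),
        ec50=dict(value=ec50_0, min=1e-6 * ec50_0, max=1e6 * ec50_0),
        h=dict(value=1.0, min=0.1, max=10.0),
    )
    result = model.fit(y, params, ca=ca, weights=weights)
    return HillFitResult(
        i_base=float(result.params["base"].value),
        i_max=float(result.params["ymax"].value),
        ec50_um=float(result.params["ec50"].value),
        hill=float(result.params["h"].value),
        residuals=np.asarray(result.residual),
        converged=bool(result.success),
    )
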