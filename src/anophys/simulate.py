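"""Synthetic whole-cell currents for a Ca2+-activated, voltage-gated scramblase.

The generative model combines

* GHK (constant-field) open-channel permeation over a small ion panel,
  which produces the outward rectification and the reversal-potential
  behaviour of a poorly selective pore;
* a Boltzmann voltage activation whose midpoint shifts with cytosolic
  [Ca2+] along a Hill curve -- the activation-threshold statistic
  measured on such currents inherits this Ca2+ dependence;
* single-exponential relaxation toward the voltage-dependent open
  probability (constant time constant by default);
* ohmic leak, white Gaussian noise, capacitative transients, and
  log-normal/Gaussian inter-cell variability for population simulations.

The Boltzmann midpoint sits well above the detectable activation
threshold (currents do not saturate inside the protocol range), so the
model separates the *true* threshold curve ``true_threshold`` from the
gating midpoint by a calibrated detection offset ``delta``:
``V_mid(Ca) = true_threshold(Ca) + delta``.  ``calibrate_detection_offset``
chooses ``delta`` so that the population mean of the detected threshold
equals the requested true threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np

from .recordings import Recording, RecordingMeta, VoltageProtocol

__all__ = [
    "THERMAL_VOLTAGE_MV",
    "IonSpec",
    "PermeationSpec",
    "GatingParams",
    "PopulationSpec",
    "CalibrationError",
    "ghk_current",
    "ghk_reversal",
    "true_threshold",
    "simulate_sweep_set",
    "simulate_population",
    "simulate_control",
    "calibrate_detection_offset",
    "calibrate_permeability_ratio",
    "load_param_sets",
    "get_gating",
    "get_permeation",
]

# RT/F at 22 degC (room-temperature recordings, 20-24 degC)
THERMAL_VOLTAGE_MV = 25.43

MAX_SEED = 2**31 - 1


class CalibrationError(RuntimeError):
    """Detection-offset or permeability calibration failed to converge."""


@dataclass(frozen=True)
class IonSpec:
    name: str
    z: int
    in_mM: float
    out_mM: float
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.z not in (-2, -1, 1, 2):
            raise ValueError("valence must be one of -2, -1, +1, +2")
        if self.in_mM < 0 or self.out_mM < 0 or self.p < 0:
            raise ValueError("concentrations and permeability must be >= 0")


@dataclass(frozen=True)
class PermeationSpec:
    """Per-ion concentrations (mM) and relative permeabilities."""

    ions: tuple[IonSpec, ...]
    temperature_c: float = 22.0

    def __post_init__(self) -> None:
        if not self.ions:
            raise ValueError("at least one permeant ion is required")

    def with_bath(self, **out_mM: float) -> "PermeationSpec":
        """Return a copy with selected external concentrations replaced."""
        new = tuple(
            replace(ion, out_mM=out_mM[ion.name]) if ion.name in out_mM else ion
            for ion in self.ions
        )
        return replace(self, ions=new)

    def scale_permeability(self, name: str, factor: float) -> "PermeationSpec":
        new = tuple(
            replace(ion, p=ion.p * factor) if ion.name == name else ion
            for ion in self.ions
        )
        return replace(self, ions=new)


def ghk_current(perm: PermeationSpec, v_mV, vt_mV: float = THERMAL_VOLTAGE_MV):
    """GHK constant-field current, pA per unit permeability.

    Sum over ions of ``P z^2 u (c_in - c_out e^{-zu}) / (1 - e^{-zu})``
    with ``u = V / (RT/F)``; continuous at V = 0 through the series limit
    ``z (c_in - c_out)``.  Concentrations are in mM, so the absolute scale
    is arbitrary; population parameters carry the conductance scale.
    """
    v = np.asarray(v_mV, dtype=float)
    u = v / vt_mV
    total = np.zeros_like(u)
    for ion in self_ions(perm):
        zu = ion.z * u
        small = np.abs(zu) < 1e-8
        zu_safe = np.where(small, 1.0, zu)
        em = -np.expm1(-zu_safe)  # 1 - e^{-zu}
        ratio = (ion.in_mM - ion.out_mM * np.exp(-zu_safe)) / em
        ratio = np.where(small,
                         (ion.in_mM - ion.out_mM) / zu_safe + ion.out_mM,
                         ratio)
        term = ion.p * ion.z**2 * u * ratio
        term = np.where(small, ion.p * ion.z * (ion.in_mM - ion.out_mM)
                        + ion.p * ion.z**2 * u * ion.out_mM, term)
        total = total + term
    return total if total.shape else float(total)


def self_ions(perm: PermeationSpec) -> Sequence[IonSpec]:
    return [ion for ion in perm.ions if ion.p > 0]


def ghk_reversal(perm: PermeationSpec, vt_mV: float = THERMAL_VOLTAGE_MV,
                 bracket: tuple[float, float] = (-150.0, 150.0)) -> float:
    """Zero-current potential (mV) of the GHK sum, by root finding."""
    from scipy.optimize import brentq

    f = lambda v: ghk_current(perm, v, vt_mV)
    lo, hi = bracket
    if f(lo) * f(hi) > 0:
        raise ValueError("no GHK zero crossing inside bracket")
    return float(brentq(f, lo, hi, xtol=1e-10))


@dataclass(frozen=True)
class GatingParams:
    """Generative gating/conduction parameters for one construct.

    ``v_half_max_mV`` is the zero-Ca2+ plateau of the *threshold* curve and
    ``delta_v_mV`` the maximal Ca2+-induced downward shift; ``ec50_um`` /
    ``hill`` set the Hill-type Ca2+ dependence.  ``detection_offset_mV``
    places the Boltzmann midpoint above the threshold curve (see module
    docstring).
    """

    gmax: float = 1.7            # pA per GHK flux unit
    v_half_max_mV: float = 127.0
    delta_v_mV: float = 65.0
    slope_mV: float = 14.0
    ec50_um: float = 2.9
    hill: float = 1.5
    tau_ms: float = 60.0
    leak_ns: float = 0.5
    noise_sd_pA: float = 10.0
    cap_amp_pA: float = 500.0
    cap_tau_ms: float = 0.5
    detection_offset_mV: float = 90.0

    def __post_init__(self) -> None:
        if self.slope_mV <= 0 or self.ec50_um <= 0 or self.hill <= 0:
            raise ValueError("slope, EC50 and Hill coefficient must be > 0")
        if self.tau_ms <= 0:
            raise ValueError("relaxation time constant must be > 0")
        if self.noise_sd_pA < 0:
            raise ValueError("noise SD must be >= 0")


def true_threshold(ca_um: float, g: GatingParams) -> float:
    """Hill-type Ca2+ dependence of the activation threshold (mV).

    ``V_thr(Ca) = (V_max - dV) + dV / (1 + (Ca/EC50)^h)``; strictly
    decreasing in Ca, with plateaus ``V_max`` (zero Ca) and ``V_max - dV``
    (saturating Ca).
    """
    if ca_um < 0:
        raise ValueError("Ca2+ concentration must be >= 0")
    base = g.v_half_max_mV - g.delta_v_mV
    if ca_um == 0:
        return g.v_half_max_mV
    return base + g.delta_v_mV / (1.0 + (ca_um / g.ec50_um) ** g.hill)


def _p_inf(v, v_mid: float, k: float):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - v_mid) / k))


def simulate_sweep_set(g: GatingParams, perm: PermeationSpec,
                       protocol: VoltageProtocol, ca_um: float,
                       seed: int | None = 0,
                       meta: RecordingMeta | None = None,
                       v_mid_offset_mV: float = 0.0,
                       g_factor: float = 1.0) -> Recording:
    """Simulate one cell's episodic sweep set under ``protocol``.

    Per sweep, ``I(t) = leak + noise + capacitative transient +
    G * phi_GHK(V) * p(t)`` where the open probability ``p`` relaxes
    single-exponentially toward a Boltzmann ``p_inf`` centred on
    ``true_threshold(ca) + detection_offset`` with slope ``slope_mV``.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(None if seed is None else int(seed) % MAX_SEED)
    v_mid = true_threshold(ca_um, g) + g.detection_offset_mV + v_mid_offset_mV
    k = g.slope_mV
    gmax = g.gmax * g_factor

    n_sweeps, n_samples = protocol.n_sweeps, protocol.n_samples
    t = protocol.time_ms()
    current = np.zeros((n_sweeps, n_samples))

    # segment list: (start_ms, duration_ms, voltage per sweep)
    steps = protocol.step_voltages.astype(float)
    segments = [(0.0, protocol.baseline_ms,
                 np.full(n_sweeps, protocol.holding_mV))]
    if protocol.prepulse_ms > 0:
        segments.append((protocol.baseline_ms, protocol.prepulse_ms,
                         np.full(n_sweeps, float(protocol.prepulse_mV))))
    segments.append((protocol.step_start_ms, protocol.step_ms, steps))
    if protocol.tail_ms > 0:
        segments.append((protocol.tail_start_ms, protocol.tail_ms,
                         np.full(n_sweeps, float(protocol.tail_mV))))

    p_prev = _p_inf(np.full(n_sweeps, protocol.holding_mV), v_mid, k)
    v_before = np.full(n_sweeps, protocol.holding_mV)
    for start_ms, dur_ms, v_seg in segments:
        i0 = int(round(start_ms * protocol.sampling_khz))
        i1 = int(round((start_ms + dur_ms) * protocol.sampling_khz))
        if i1 <= i0:
            continue
        t_loc = t[i0:i1] - start_ms
        p_inf_seg = _p_inf(v_seg, v_mid, k)
        decay = np.exp(-t_loc[None, :] / g.tau_ms)
        p = p_inf_seg[:, None] + (p_prev - p_inf_seg)[:, None] * decay
        phi = ghk_current(perm, v_seg)
        current[:, i0:i1] += gmax * np.asarray(phi)[:, None] * p
        current[:, i0:i1] += g.leak_ns * v_seg[:, None]
        if g.cap_amp_pA > 0 and start_ms > 0:
            dv = v_seg - v_before
            current[:, i0:i1] += (g.cap_amp_pA * (dv[:, None] / 100.0)
                                  * np.exp(-t_loc[None, :] / g.cap_tau_ms))
        # carry p across the segment boundary (evaluated at segment end)
        p_prev = p_inf_seg + (p_prev - p_inf_seg) * math.exp(-dur_ms / g.tau_ms)
        v_before = v_seg

    if g.noise_sd_pA > 0:
        current += rng.normal(0.0, g.noise_sd_pA, size=current.shape)

    meta = meta or RecordingMeta(ca_free_um=ca_um, seed=seed)
    return Recording(sweeps_pA=current, protocol=protocol, meta=meta)


@dataclass(frozen=True)
class PopulationSpec:
    """A cohort of cells sharing gating/permeation, with inter-cell spread."""

    n: int
    gating: GatingParams
    perm: PermeationSpec
    ca_um: float
    midpoint_sd_mV: float = 13.0
    conductance_cv: float = 0.3
    base_seed: int = 0
    construct: str = "WT"
    cell_line: str = "HEK293"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if self.midpoint_sd_mV < 0 or self.conductance_cv < 0:
            raise ValueError("spread parameters must be >= 0")


def simulate_population(pop: PopulationSpec,
                        protocol: VoltageProtocol) -> list[Recording]:
    """Simulate ``pop.n`` cells; cell ``i`` uses seed ``base_seed + i``.

    Each cell draws a Normal midpoint offset and a log-normal conductance
    factor (unit mean, CV ``conductance_cv``); bit-reproducible for a
    fixed base seed.
    """
    out = []
    sigma = math.sqrt(math.log(1.0 + pop.conductance_cv**2))
    for i in range(pop.n):
        cell_seed = (pop.base_seed + i) % MAX_SEED
        cell_rng = np.random.default_rng(cell_seed)
        dv = cell_rng.normal(0.0, pop.midpoint_sd_mV) if pop.midpoint_sd_mV else 0.0
        gf = (math.exp(cell_rng.normal(-0.5 * sigma**2, sigma))
              if pop.conductance_cv else 1.0)
        meta = RecordingMeta(construct=pop.construct, cell_line=pop.cell_line,
                             ca_free_um=pop.ca_um, cell_id=f"cell{i:03d}",
                             seed=cell_seed, transfected=True)
        out.append(simulate_sweep_set(pop.gating, pop.perm, protocol,
                                      pop.ca_um, seed=cell_seed, meta=meta,
                                      v_mid_offset_mV=dv, g_factor=gf))
    return out


def simulate_control(protocol: VoltageProtocol, noise_sd_pA: float = 10.0,
                     leak_ns: float = 1.0, seed: int | None = 0,
                     ca_um: float = 0.0,
                     perm: PermeationSpec | None = None) -> Recording:
    """Non-transfected control: leak + noise, no time-dependent component.

    At very high cytosolic Ca2+ a small endogenous outward component
    appears at the most extreme positive potentials only, mirroring the
    background currents of untransfected cells.
    """
    g = GatingParams(gmax=0.0, leak_ns=leak_ns, noise_sd_pA=noise_sd_pA,
                     detection_offset_mV=0.0)
    if ca_um >= 50.0:
        # endogenous background: small, appears only at the top steps
        g = replace(g, gmax=0.12 * ca_um / (ca_um + 100.0),
                    v_half_max_mV=205.0, delta_v_mV=20.0, ec50_um=50.0,
                    hill=2.0, slope_mV=12.0, detection_offset_mV=0.0)
    perm = perm or get_permeation("nonselective")
    meta = RecordingMeta(construct="non-transfected", ca_free_um=ca_um,
                         seed=seed, transfected=False)
    return simulate_sweep_set(g, perm, protocol, ca_um, seed=seed, meta=meta)


# ---------------------------------------------------------------------------
# calibrations


def _population_mean_threshold(g: GatingParams, perm: PermeationSpec,
                               protocol: VoltageProtocol, ca_um: float,
                               n_cells: int, base_seed: int,
                               midpoint_sd_mV: float, conductance_cv: float,
                               multiplier: float) -> float:
    from .analysis import detect_threshold, extract_amplitudes

    pop = PopulationSpec(n=n_cells, gating=g, perm=perm, ca_um=ca_um,
                         midpoint_sd_mV=midpoint_sd_mV,
                         conductance_cv=conductance_cv, base_seed=base_seed)
    detected = []
    for rec in simulate_population(pop, protocol):
        res = detect_threshold(extract_amplitudes(rec), multiplier=multiplier)
        if res.v_threshold_mV is not None:
            detected.append(res.v_threshold_mV)
    if not detected:
        return math.inf
    return float(np.mean(detected))


def calibrate_detection_offset(g: GatingParams, perm: PermeationSpec,
                               protocol: VoltageProtocol, ca_um: float,
                               target_mean_mV: float | None = None,
                               n_cells: int = 400, base_seed: int = 12345,
                               midpoint_sd_mV: float = 13.0,
                               conductance_cv: float = 0.3,
                               multiplier: float = 2.0,
                               bracket: tuple[float, float] = (20.0, 160.0),
                               tol_mV: float = 0.5) -> float:
    """Detection offset delta reconciling gating midpoint and threshold.

    Monte-Carlo bisection with common random numbers: find delta such that
    the population mean of the detected threshold equals the target
    (default: the true threshold at ``ca_um``).  Idempotent to within the
    Monte-Carlo resolution when re-applied.
    """
    target = target_mean_mV if target_mean_mV is not None else true_threshold(ca_um, g)

    def mean_at(delta: float) -> float:
        trial = replace(g, detection_offset_mV=delta)
        return _population_mean_threshold(
            trial, perm, protocol, ca_um, n_cells, base_seed,
            midpoint_sd_mV, conductance_cv, multiplier)

    lo, hi = bracket
    f_lo, f_hi = mean_at(lo) - target, mean_at(hi) - target
    if not (f_lo < 0 < f_hi):
        raise CalibrationError(
            f"target mean {target:.1f} mV not bracketed by delta in {bracket}: "
            f"f({lo})={f_lo:+.1f}, f({hi})={f_hi:+.1f}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = mean_at(mid) - target
        if abs(f_mid) <= tol_mV or hi - lo < 0.25:
            return mid
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("detection-offset bisection did not converge")


def calibrate_permeability_ratio(perm: PermeationSpec,
                                 low_bath: dict[str, float],
                                 v_mV: float = 140.0,
                                 target_ratio: float = 0.69,
                                 anion: str = "Cl") -> float:
    """Anion:cation permeability ratio matching a prepulse-current ratio.

    Finds the factor on the anion permeability such that the GHK current
    at ``v_mV`` in the reduced-NaCl bath divided by the standard-bath
    current equals ``target_ratio``.
    """
    from scipy.optimize import brentq

    def ratio(r: float) -> float:
        spec = perm.scale_permeability(anion, r)
        hi = ghk_current(spec, v_mV)
        lo = ghk_current(spec.with_bath(**low_bath), v_mV)
        return lo / hi

    try:
        return float(brentq(lambda r: ratio(r) - target_ratio, 1e-3, 10.0,
                            xtol=1e-10))
    except ValueError as exc:  # pragma: no cover - degenerate ion panels
        raise CalibrationError(f"ratio {target_ratio} unreachable: {exc}")


# ---------------------------------------------------------------------------
# named parameter sets


def load_param_sets(path=None) -> dict:
    """Versioned named parameter sets (gating, permeation, scrambling)."""
    if path is None:
        text = resources.files("anophys.data").joinpath("param_sets.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return json.loads(text)


def get_gating(name: str, sets: dict | None = None) -> GatingParams:
    sets = sets or load_param_sets()
    try:
        entry = sets["gating"][name]
    except KeyError:
        raise KeyError(
            f"unknown gating parameter set {name!r}; available: "
            f"{sorted((sets or load_param_sets())['gating'])}"
        )
    fields = {k: v for k, v in entry.items()
              if k in GatingParams.__dataclass_fields__}
    return GatingParams(**fields)


def population_defaults(name: str, sets: dict | None = None) -> dict:
    """Population-level defaults (midpoint SD, conductance CV) for a set."""
    sets = sets or load_param_sets()
    entry = sets["gating"][name]
    return {
        "midpoint_sd_mV": entry.get("midpoint_sd_mV", 13.0),
        "conductance_cv": entry.get("conductance_cv", 0.3),
    }


def get_permeation(name: str, sets: dict | None = None) -> PermeationSpec:
    sets = sets or load_param_sets()
    try:
        entry = sets["permeation"][name]
    except KeyError:
        raise KeyError(f"unknown permeation spec {name!r}")
    ions = tuple(IonSpec(name=i["name"], z=i["z"], in_mM=i["in_mM"],
                         out_mM=i["out_mM"], p=i["p"]) for i in entry["ions"])
    return PermeationSpec(ions=ions, temperature_c=entry.get("temperature_c", 22.0))
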