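"""Free-Ca2+ equilibrium in chelator-buffered pipette solutions.

Patch-pipette solutions set the cytosolic free Ca2+ concentration with
chelators (EGTA, HEDTA) whose Ca2+ affinity is strongly pH dependent,
because protons compete with the metal for the fully deprotonated ligand.
This module computes multi-ligand metal/proton speciation -- the same
calculation chelator programs such as WinMAXC perform -- from a bundled
table of absolute stepwise association constants, with Davies
activity corrections and van't Hoff temperature corrections.

Conventions
-----------
* Stepwise association constants, log10, molar scale:
  ``HL``:  K = [HL] / ([H][L]);  ``H2L``: K = [H2L] / ([H][HL]); ...
  ``CaL``: K = [CaL] / ([Ca][L]) with L the fully deprotonated ligand.
* pH is treated as a measured activity by default and converted to a
  proton concentration through the Davies single-ion activity
  coefficient; pH is fixed (buffered), never solved for.
* All concentrations handed to the solver are molar; :class:`SolutionSpec`
  takes recipe concentrations in mM as printed on a solution sheet.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "BufferConstants",
    "BufferOptions",
    "SolutionSpec",
    "EquilibriumResult",
    "ConfigurationError",
    "SolverError",
    "load_constants",
    "davies_log_gamma",
    "proton_alpha",
    "apparent_constant",
    "solve_equilibrium",
    "total_for_free",
]

R_GAS = 8.31446  # J / (mol K)


class ConfigurationError(ValueError):
    """Missing or inconsistent binding constants for a requested ligand."""


class SolverError(RuntimeError):
    """Speciation solver failed to reach the mass-balance tolerance."""


@dataclass(frozen=True)
class BufferConstants:
    """Absolute stepwise association constants for one ligand.

    ``log_k`` maps species labels (``"CaL"``, ``"MgL"``, ``"HL"``,
    ``"H2L"``, ...) to log10 association constants at the reference
    temperature and ionic strength.  ``delta_h`` holds reaction enthalpies
    (kJ/mol) for the van't Hoff correction; species without an entry are
    treated as temperature independent.
    """

    ligand: str
    log_k: Mapping[str, float]
    delta_h: Mapping[str, float] = field(default_factory=dict)
    t_ref_c: float = 25.0
    i_ref_m: float = 0.1

    def __post_init__(self) -> None:
        if not any(k.endswith("L") and k.startswith("H") for k in self.log_k):
            raise ConfigurationError(
                f"ligand {self.ligand!r} has no proton association constants"
            )
        for key, val in self.log_k.items():
            if not math.isfinite(val):
                raise ConfigurationError(
                    f"non-finite log K for {self.ligand!r}:{key!r}"
                )

    @property
    def n_protons(self) -> int:
        """Number of stepwise protonation constants (= |charge| of L)."""
        n = 0
        while self._proton_key(n + 1) in self.log_k:
            n += 1
        return n

    @staticmethod
    def _proton_key(i: int) -> str:
        return "HL" if i == 1 else f"H{i}L"

    @property
    def ligand_charge(self) -> int:
        # fully deprotonated ligand; one negative charge per dissociable proton
        return -self.n_protons

    def proton_log_k(self) -> list[float]:
        return [self.log_k[self._proton_key(i + 1)] for i in range(self.n_protons)]


class BufferOptions(BaseModel):
    """Activity/temperature correction switches for the speciation model."""

    davies: bool = True
    davies_a: float = 0.51
    davies_linear: float = 0.3
    ph_is_activity: bool = True
    vant_hoff: bool = True
    max_iter: int = 200
    tol_m: float = 1e-12
    damping: float = 0.7


class SolutionSpec(BaseModel):
    """A pipette/bath recipe as printed on a solution sheet (mM units)."""

    salts: dict[str, float] = Field(default_factory=dict)
    ligands_mM: dict[str, float] = Field(default_factory=dict)
    total_ca_mM: float = 0.0
    total_mg_mM: float = 0.0
    pH: float
    temperature_c: float = 22.0
    ionic_strength_m: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "SolutionSpec":
        for name, c in {**self.salts, **self.ligands_mM}.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}")
        if self.total_ca_mM < 0 or self.total_mg_mM < 0:
            raise ValueError("total metal concentrations must be >= 0")
        if not 0.0 < self.pH < 14.0:
            raise ValueError("pH must lie in (0, 14)")
        if not 0.0 <= self.temperature_c <= 40.0:
            raise ValueError("temperature must lie in 0-40 degC")
        return self


@dataclass
class EquilibriumResult:
    """Speciation output: free metals (M), per-ligand species (M), residual."""

    free: dict[str, float]
    bound: dict[str, dict[str, float]]
    residual_m: float
    ionic_strength_m: float
    iterations: int

    def free_ca(self) -> float:
        return self.free.get("Ca", 0.0)


# ---------------------------------------------------------------------------
# constants table


def load_constants(path=None) -> dict[str, BufferConstants]:
    """Load the bundled (or a user-supplied) binding-constant CSV.

    Columns: ligand, species, log10_k, delta_h_kj_mol, t_ref_c, i_ref_m.
    Lines starting with ``#`` are comments.
    """
    if path is None:
        source = resources.files("anophys.data").joinpath("binding_constants.csv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = [
        row
        for row in csv.DictReader(
            line for line in text.splitlines() if line.strip() and not line.startswith("#")
        )
    ]
    seen: set[tuple[str, str]] = set()
    by_ligand: dict[str, dict] = {}
    for row in rows:
        key = (row["ligand"], row["species"])
        if key in seen:
            raise ConfigurationError(f"duplicate constant for {key}")
        seen.add(key)
        entry = by_ligand.setdefault(
            row["ligand"],
            {"log_k": {}, "delta_h": {}, "t_ref_c": float(row["t_ref_c"]),
             "i_ref_m": float(row["i_ref_m"])},
        )
        entry["log_k"][row["species"]] = float(row["log10_k"])
        dh = row.get("delta_h_kj_mol", "")
        if dh not in ("", None):
            entry["delta_h"][row["species"]] = float(dh)
    return {
        lig: BufferConstants(ligand=lig, **vals) for lig, vals in by_ligand.items()
    }


# ---------------------------------------------------------------------------
# activity / temperature corrections


def davies_log_gamma(charge: int, ionic_strength_m: float,
                     a: float = 0.51, linear: float = 0.3) -> float:
    """Davies-equation log10 activity coefficient for a ``charge``-valent ion."""
    if ionic_strength_m <= 0:
        return 0.0
    s = math.sqrt(ionic_strength_m)
    return -a * charge * charge * (s / (1.0 + s) - linear * ionic_strength_m)


def _species_delta_z2(species: str, ligand_charge: int) -> int:
    """z^2(product) - sum z^2(reactants) for a stepwise association."""
    n = -ligand_charge
    if species in ("CaL", "MgL"):
        return (2 - n) ** 2 - 4 - n * n
    if species == "HL":
        return (1 - n) ** 2 - 1 - n * n
    if species.startswith("H") and species.endswith("L"):
        i = int(species[1:-1])
        return (i - n) ** 2 - 1 - (i - 1 - n) ** 2
    raise ConfigurationError(f"unknown species label {species!r}")


def corrected_log_k(constants: BufferConstants, species: str,
                    temperature_c: float, ionic_strength_m: float,
                    options: BufferOptions) -> float:
    """Stepwise log K moved from the tabulated (T_ref, I_ref) to (T, I)."""
    if species not in constants.log_k:
        raise ConfigurationError(
            f"no {species!r} constant for ligand {constants.ligand!r}"
        )
    logk = constants.log_k[species]
    if options.vant_hoff:
        dh = constants.delta_h.get(species, 0.0) * 1000.0
        t = temperature_c + 273.15
        t_ref = constants.t_ref_c + 273.15
        logk -= dh / (math.log(10.0) * R_GAS) * (1.0 / t - 1.0 / t_ref)
    if options.davies:
        dz2 = _species_delta_z2(species, constants.ligand_charge)

        def f(i: float) -> float:
            s = math.sqrt(i)
            return s / (1.0 + s) - options.davies_linear * i

        logk += options.davies_a * dz2 * (f(ionic_strength_m) - f(constants.i_ref_m))
    return logk


def proton_concentration(pH: float, ionic_strength_m: float,
                         options: BufferOptions) -> float:
    """[H+] in M; converts an activity-scale pH if ``ph_is_activity``."""
    if options.ph_is_activity and options.davies:
        log_gamma = davies_log_gamma(1, ionic_strength_m,
                                     options.davies_a, options.davies_linear)
        return 10.0 ** (-pH - log_gamma)
    return 10.0 ** (-pH)


def proton_alpha(constants: BufferConstants, pH: float, temperature_c: float,
                 ionic_strength_m: float,
                 options: BufferOptions | None = None) -> float:
    """Proton-competition factor alpha_H = 1 + sum_i beta_Hi [H]^i."""
    options = options or BufferOptions()
    h = proton_concentration(pH, ionic_strength_m, options)
    alpha = 1.0
    cum = 0.0
    for i in range(constants.n_protons):
        key = constants._proton_key(i + 1)
        cum += corrected_log_k(constants, key, temperature_c, ionic_strength_m, options)
        alpha += 10.0 ** cum * h ** (i + 1)
    return alpha


def apparent_constant(constants: BufferConstants, pH: float,
                      temperature_c: float = 22.0,
                      ionic_strength_m: float = 0.15,
                      metal: str = "Ca",
                      options: BufferOptions | None = None) -> float:
    """Apparent (conditional) metal-ligand association constant, 1/M.

    The absolute constant divided by the proton-competition factor
    alpha_H; monotonically non-decreasing in pH.
    """
    options = options or BufferOptions()
    if not 0.0 < pH < 14.0:
        raise ValueError("pH must lie in (0, 14)")
    logk = corrected_log_k(constants, f"{metal}L", temperature_c,
                           ionic_strength_m, options)
    alpha = proton_alpha(constants, pH, temperature_c, ionic_strength_m, options)
    return 10.0 ** logk / alpha


# ---------------------------------------------------------------------------
# speciation solver


_SALT_IONIC_FACTOR = {
    # mol ionic strength per mol salt, assuming full dissociation
    "HEPES": 0.0,  # zwitterionic buffer, minor net charge at pH ~7
    "glucose": 0.0,
    "sucrose": 0.0,
}


def estimate_ionic_strength(solution: SolutionSpec,
                            constants: Mapping[str, BufferConstants]) -> float:
    """Rough recipe-level ionic strength (M), documented approximation.

    1:1 salts contribute their concentration; a chelator is counted as its
    dominant near-neutral-pH species HL^(1-n) with monovalent counterions;
    buffered metal chloride counts the ML complex plus the chloride.
    """
    i = 0.0
    for name, c_mm in solution.salts.items():
        c = c_mm * 1e-3
        i += _SALT_IONIC_FACTOR.get(name, 1.0) * c
    capacity = 0.0
    for name, c_mm in solution.ligands_mM.items():
        c = c_mm * 1e-3
        capacity += c
        n = constants[name].n_protons if name in constants else 3
        z_hl = n - 1
        i += 0.5 * c * (z_hl * z_hl + z_hl)
    for c_mm in (solution.total_ca_mM, solution.total_mg_mM):
        c = c_mm * 1e-3
        i += (1.5 if capacity >= c else 3.0) * c
    return i


def solve_equilibrium(solution: SolutionSpec,
                      constants: Mapping[str, BufferConstants],
                      options: BufferOptions | None = None) -> EquilibriumResult:
    """Solve metal/ligand/proton speciation by damped fixed-point iteration.

    Unknowns are the free metal concentrations and the free fully
    deprotonated ligand concentrations; pH is fixed.  Mass balance is
    enforced to ``options.tol_m`` (default 1e-12 M) and the update is
    damped in log space for robustness.
    """
    options = options or BufferOptions()
    for name in solution.ligands_mM:
        if name not in constants:
            raise ConfigurationError(f"no binding constants for ligand {name!r}")

    ionic = (solution.ionic_strength_m
             if solution.ionic_strength_m is not None
             else estimate_ionic_strength(solution, constants))
    temp = solution.temperature_c
    ligands = [name for name, c in solution.ligands_mM.items() if c > 0]
    metals = [m for m, tot in (("Ca", solution.total_ca_mM),
                               ("Mg", solution.total_mg_mM)) if tot > 0]
    totals_m = {"Ca": solution.total_ca_mM * 1e-3,
                "Mg": solution.total_mg_mM * 1e-3}
    l_tot = {name: solution.ligands_mM[name] * 1e-3 for name in ligands}

    alpha = {name: proton_alpha(constants[name], solution.pH, temp, ionic, options)
             for name in ligands}
    k_ml = {}
    for name in ligands:
        for m in metals:
            key = f"{m}L"
            if key in constants[name].log_k:
                k_ml[(m, name)] = 10.0 ** corrected_log_k(
                    constants[name], key, temp, ionic, options)
            else:
                k_ml[(m, name)] = 0.0

    free = {m: totals_m[m] for m in metals}
    x = {name: l_tot[name] / alpha[name] for name in ligands}

    def residuals() -> float:
        res = 0.0
        for m in metals:
            bound = sum(k_ml[(m, nm)] * free[m] * x[nm] for nm in ligands)
            res = max(res, abs(totals_m[m] - free[m] - bound))
        for nm in ligands:
            held = x[nm] * alpha[nm] + sum(
                k_ml[(m, nm)] * free[m] * x[nm] for m in metals)
            res = max(res, abs(l_tot[nm] - held))
        return res

    lam = options.damping
    n_iter = 0
    converged = False
    for n_iter in range(1, options.max_iter + 1):
        for nm in ligands:
            denom = alpha[nm] + sum(k_ml[(m, nm)] * free[m] for m in metals)
            cand = l_tot[nm] / denom
            x[nm] = x[nm] ** (1 - lam) * cand ** lam if x[nm] > 0 else cand
        for m in metals:
            denom = 1.0 + sum(k_ml[(m, nm)] * x[nm] for nm in ligands)
            cand = totals_m[m] / denom
            free[m] = free[m] ** (1 - lam) * cand ** lam if free[m] > 0 else cand
        if residuals() <= options.tol_m:
            converged = True
            break

    if not converged and (metals or ligands):
        # Newton (MINPACK hybr) on log10 free concentrations from the
        # fixed-point iterate; handles the stiff near-saturation regime.
        from scipy.optimize import root as _root

        names = [("M", m) for m in metals] + [("L", nm) for nm in ligands]

        def unpack(vec):
            fr = {m: 10.0 ** vec[i] for i, (kind, m) in enumerate(names)
                  if kind == "M"}
            xs = {nm: 10.0 ** vec[i] for i, (kind, nm) in enumerate(names)
                  if kind == "L"}
            return fr, xs

        def fun(vec):
            fr, xs = unpack(vec)
            out = []
            for kind, key in names:
                if kind == "M":
                    bound_m = sum(k_ml[(key, nm)] * fr[key] * xs[nm]
                                  for nm in ligands)
                    out.append(totals_m[key] - fr[key] - bound_m)
                else:
                    held = xs[key] * alpha[key] + sum(
                        k_ml[(m, key)] * fr[m] * xs[key] for m in metals)
                    out.append(l_tot[key] - held)
            return out

        x0 = [math.log10(max(free[k] if kind == "M" else x[k], 1e-300))
              for kind, k in names]
        sol_root = _root(fun, x0, method="hybr", options={"xtol": 1e-14})
        free_n, x_n = unpack(sol_root.x)
        free.update(free_n)
        x.update(x_n)
        if residuals() > max(options.tol_m, 1e-12):
            raise SolverError(
                f"speciation did not converge in {options.max_iter} iterations; "
                f"max mass-balance residual {residuals():.3e} M"
            )

    # undamped polish: a few exact alternating substitutions
    for _ in range(5):
        for nm in ligands:
            x[nm] = l_tot[nm] / (alpha[nm] + sum(k_ml[(m, nm)] * free[m]
                                                 for m in metals))
        for m in metals:
            free[m] = totals_m[m] / (1.0 + sum(k_ml[(m, nm)] * x[nm]
                                               for nm in ligands))

    out_free = {m: free.get(m, totals_m.get(m, 0.0)) for m in ("Ca", "Mg")}
    if "Ca" not in metals:
        out_free["Ca"] = totals_m["Ca"]
    if "Mg" not in metals:
        out_free["Mg"] = totals_m["Mg"]
    bound = {}
    for nm in ligands:
        entry = {m: k_ml[(m, nm)] * free[m] * x[nm] for m in metals}
        entry["H"] = x[nm] * (alpha[nm] - 1.0)
        entry["L"] = x[nm]
        bound[nm] = entry
    return EquilibriumResult(free=out_free, bound=bound,
                             residual_m=residuals(), ionic_strength_m=ionic,
                             iterations=n_iter)


def total_for_free(target_free_ca_m: float, solution: SolutionSpec,
                   constants: Mapping[str, BufferConstants],
                   options: BufferOptions | None = None) -> float:
    """Total Ca (mM) that yields the requested free Ca2+ (M) in ``solution``.

    Inverts :func:`solve_equilibrium` with a bracketing root search; the
    round trip reproduces the target to well below 0.1%.
    """
    from scipy.optimize import brentq

    options = options or BufferOptions()
    if target_free_ca_m <= 0:
        raise ValueError("target free Ca2+ must be > 0")
    capacity_mm = sum(solution.ligands_mM.values())
    if not capacity_mm:
        return target_free_ca_m * 1e3

    def free_at(total_mm: float) -> float:
        trial = solution.model_copy(update={"total_ca_mM": total_mm})
        return solve_equilibrium(trial, constants, options).free_ca()

    lo = target_free_ca_m * 1e3
    hi = target_free_ca_m * 1e3 + 2.0 * capacity_mm
    if free_at(hi) < target_free_ca_m:
        raise ValueError("target free Ca2+ unreachable within ligand capacity bracket")
    return float(brentq(lambda t: free_at(t) - target_free_ca_m, lo, hi,
                        xtol=1e-12, rtol=1e-12))
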