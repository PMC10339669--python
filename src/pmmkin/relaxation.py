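"""The Lb <=> La => piSigma* relaxation network and its observables.

The interconversion of the two emitting singlets is much faster than
either their radiative decay or the irreversible transitions to the
dark piSigma* state, so the emitting population is treated as an
equilibrated Lb/La mixture with fractions set by the reaction free
energy: K_eq = exp(-dA / kB T), f_a = K_eq / (1 + K_eq).  The mixture's
radiative and nonradiative lifetimes are population-weighted harmonic
combinations of the component lifetimes,

    tau_r  = (f_b / tau_r,b + f_a / tau_r,a)^-1
    tau_nr = (f_b / tau_b   + f_a / tau_a  )^-1

and the fluorescence lifetime and quantum yield follow as
1/tau_F = 1/tau_r + 1/tau_nr and Phi = tau_F / tau_r.  An optional
intersystem-crossing channel enters as a parallel first-order rate
added to the nonradiative side.

Dark-state back transitions are orders of magnitude slower than every
other step and are excluded from tau_nr by default; a full three-state
master-equation solve is available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB
from .qc_pmm import InputError

__all__ = [
    "RelaxationScheme",
    "NetworkReport",
    "free_energy_from_ensembles",
    "equilibrium_fractions",
    "combined_lifetime",
    "fluorescence_observables",
    "network_summary",
    "master_equation_lifetime",
]


def free_energy_from_ensembles(
    mean_gap_lb: float,
    mean_gap_la: float,
    estimator: str = "linear_response",
    var_lb: Optional[float] = None,
    var_la: Optional[float] = None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Reaction free energy dA (kJ/mol) of the Lb -> La transition.

    Both arguments are equilibrium averages of the *Lb -> La* transition
    energy (positive = La above Lb), taken in the Lb and the La ensemble
    respectively.  The default two-sided linear-response estimator is
    their mean; the ``gaussian`` estimator adds the second-order
    fluctuation terms, averaging the two one-sided cumulant expansions
    ``<dU>_Lb - var_Lb/(2 kB T)`` and ``<dU>_La + var_La/(2 kB T)``.
    """
    if estimator == "linear_response":
        return 0.5 * (mean_gap_lb + mean_gap_la)
    if estimator == "gaussian":
        if var_lb is None or var_la is None:
            raise InputError("gaussian estimator needs both gap variances")
        beta = 1.0 / (KB * temperature)
        est_lb = mean_gap_lb - 0.5 * beta * var_lb
        est_la = mean_gap_la + 0.5 * beta * var_la
        return 0.5 * (est_lb + est_la)
    raise InputError(f"unknown estimator {estimator!r}")


def equilibrium_fractions(delta_a: float, temperature: float = DEFAULT_TEMPERATURE):
    """(K_eq, f_b, f_a) for the Lb <=> La pre-equilibrium."""
    if not temperature > 0:
        raise InputError("temperature must be positive")
    k_eq = math.exp(-delta_a / (KB * temperature))
    f_a = k_eq / (1.0 + k_eq)
    return k_eq, 1.0 - f_a, f_a


def combined_lifetime(f_b: float, tau_b: float, f_a: float, tau_a: float) -> float:
    """Population-weighted harmonic lifetime (f_b/tau_b + f_a/tau_a)^-1."""
    if tau_b <= 0 or tau_a <= 0:
        raise InputError("component lifetimes must be positive")
    if abs(f_b + f_a - 1.0) > 1e-9:
        raise InputError("fractions must sum to 1")
    return 1.0 / (f_b / tau_b + f_a / tau_a)


def fluorescence_observables(
    tau_r: float, tau_nr: float, tau_isc: Optional[float] = None
):
    """Fluorescence lifetime and quantum yield (tau_F, Phi).

    1/tau_F = 1/tau_r + 1/tau_nr, with an optional ISC channel folded
    into the nonradiative side first; Phi = tau_F / tau_r.
    """
    if tau_r <= 0 or tau_nr <= 0:
        raise InputError("lifetimes must be positive")
    inv_nr = 1.0 / tau_nr
    if tau_isc is not None:
        if tau_isc <= 0:
            raise InputError("tau_ISC must be positive")
        inv_nr += 1.0 / tau_isc
    tau_f = 1.0 / (1.0 / tau_r + inv_nr)
    return tau_f, tau_f / tau_r


@dataclass(frozen=True)
class RelaxationScheme:
    """Inputs of the relaxation network, with optional standard errors.

    Lifetimes in ns, free energy in kJ/mol; standard errors live in
    ``uncertainties`` keyed by field name (missing entries mean zero).
    """

    temperature: float = DEFAULT_TEMPERATURE
    delta_a: Optional[float] = None     # kJ/mol, Lb -> La
    tau_r_b: Optional[float] = None     # ns, Lb radiative
    tau_r_a: Optional[float] = None     # ns, La radiative
    tau_b: Optional[float] = None       # ns, Lb -> piSigma*
    tau_a: Optional[float] = None       # ns, La -> piSigma*
    tau_isc: Optional[float] = None     # ns, optional ISC channel
    uncertainties: dict = field(default_factory=dict)

    _COMPONENTS = ("delta_a", "tau_r_b", "tau_r_a", "tau_b", "tau_a")

    def missing(self):
        return [k for k in self._COMPONENTS if getattr(self, k) is None]


@dataclass(frozen=True)
class NetworkReport:
    """Derived observables of the relaxation network with propagated SEs."""

    k_eq: Optional[float] = None
    f_b: Optional[float] = None
    f_a: Optional[float] = None
    tau_r: Optional[float] = None    # ns
    tau_nr: Optional[float] = None   # ns
    tau_f: Optional[float] = None    # ns
    phi: Optional[float] = None
    uncertainties: dict = field(default_factory=dict)
    missing: tuple = ()

    def as_dict(self) -> dict:
        return {
            "K_eq": self.k_eq, "f_b": self.f_b, "f_a": self.f_a,
            "tau_r_ns": self.tau_r, "tau_nr_ns": self.tau_nr,
            "tau_F_ns": self.tau_f, "Phi": self.phi,
        }


_OUTPUT_NAMES = ("k_eq", "f_b", "f_a", "tau_r", "tau_nr", "tau_f", "phi")


def _chain(params: dict, temperature: float) -> np.ndarray:
    k_eq, f_b, f_a = equilibrium_fractions(params["delta_a"], temperature)
    tau_r = combined_lifetime(f_b, params["tau_r_b"], f_a, params["tau_r_a"])
    tau_nr = combined_lifetime(f_b, params["tau_b"], f_a, params["tau_a"])
    tau_f, phi = fluorescence_observables(tau_r, tau_nr, params.get("tau_isc"))
    return np.array([k_eq, f_b, f_a, tau_r, tau_nr, tau_f, phi])


def network_summary(scheme: RelaxationScheme) -> NetworkReport:
    """Full observable chain dA -> fractions -> lifetimes -> (tau_F, Phi).

    Uncertainties propagate to first order (delta method) from the
    component standard errors; with missing components the derived
    values are withheld and listed.
    """
    missing = scheme.missing()
    if missing:
        return NetworkReport(missing=tuple(missing))
    params = {k: getattr(scheme, k) for k in scheme._COMPONENTS}
    if scheme.tau_isc is not None:
        params["tau_isc"] = scheme.tau_isc
    out = _chain(params, scheme.temperature)

    # delta method with central finite differences
    var = np.zeros_like(out)
    for name in list(params):
        se = scheme.uncertainties.get(name, 0.0)
        if se == 0.0:
            continue
        x = params[name]
        h = 1e-6 * max(abs(x), 1.0)
        up, dn = dict(params), dict(params)
        up[name] = x + h
        dn[name] = x - h
        grad = (_chain(up, scheme.temperature) - _chain(dn, scheme.temperature)) / (2 * h)
        var += (grad * se) ** 2
    ses = dict(zip(_OUTPUT_NAMES, np.sqrt(var)))
    return NetworkReport(*out, uncertainties=ses)


def master_equation_lifetime(
    scheme: RelaxationScheme,
    tau_interconv_ba: float,
    tau_back_b: Optional[float] = None,
    tau_back_a: Optional[float] = None,
):
    """Three-state master-equation fluorescence lifetime (sensitivity tool).

    Solves dp/dt = -K p over (Lb, La, piSigma*) with explicit
    interconversion (``tau_interconv_ba``: Lb -> La reaction lifetime in
    ns; the reverse follows from detailed balance via K_eq), radiative
    and nonradiative decays, and optional dark-state back transitions.
    Returns the intensity-weighted mean fluorescence decay time
    ``integral(t S) / integral(S)`` for the emission signal
    S(t) = k_r,b p_Lb + k_r,a p_La starting from a pure Lb population.
    """
    if scheme.missing():
        raise InputError(f"scheme incomplete: missing {scheme.missing()}")
    k_eq, _, _ = equilibrium_fractions(scheme.delta_a, scheme.temperature)
    k_ba = 1.0 / tau_interconv_ba           # Lb -> La
    k_ab = k_ba / k_eq                      # detailed balance
    k_rb, k_ra = 1.0 / scheme.tau_r_b, 1.0 / scheme.tau_r_a
    k_bd, k_ad = 1.0 / scheme.tau_b, 1.0 / scheme.tau_a
    k_isc = 0.0 if scheme.tau_isc is None else 1.0 / scheme.tau_isc
    k_db = 0.0 if tau_back_b is None else 1.0 / tau_back_b
    k_da = 0.0 if tau_back_a is None else 1.0 / tau_back_a
    K = np.array([
        [k_ba + k_rb + k_bd + k_isc, -k_ab, -k_db],
        [-k_ba, k_ab + k_ra + k_ad + k_isc, -k_da],
        [-k_bd, -k_ad, k_db + k_da],
    ])
    p0 = np.array([1.0, 0.0, 0.0])
    w = np.array([k_rb, k_ra, 0.0])
    if k_db == 0.0 and k_da == 0.0:
        # purely absorbing dark state never feeds back: the emitting block
        # is closed and the full matrix is singular
        K, p0, w = K[:2, :2], p0[:2], w[:2]
    m1 = np.linalg.solve(K, p0)             # integral p dt
    m2 = np.linalg.solve(K, m1)             # integral t p dt
    denom = float(w @ m1)
    if denom <= 0:
        raise InputError("no radiative signal in the network")
    return float(w @ m2) / denom
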