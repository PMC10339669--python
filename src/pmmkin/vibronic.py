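"""Franck-Condon factors, vertical/vibronic spectra and radiative rates.

Vibrational modes are treated as identical displaced harmonic
oscillators in the two electronic states (same frequencies, minima
shifted by a mass-weighted displacement ``d``), so the 0 -> n overlap of
one mode is Poissonian with Huang-Rhys factor ``S = omega d^2 / (2
hbar)``:

    xi_n^2 = exp(-S) S^n / n!

Modes split at temperature T into *quantum* modes (hbar*omega > kB*T),
which generate discrete vibronic progressions, and *classical* modes,
which only broaden each line; the classical-limit broadening is the
Marcus-type width ``sigma_G = sqrt(2 kB T lambda_cl)`` with
``lambda_cl = sum_cl S_i hbar omega_i``.

Ensemble spectra are built by histogramming the per-frame vertical
transition energies into bins, averaging the squared transition dipole
per bin, and summing one Gaussian per bin weighted by the bin population
and the frequency/dipole prefactor (absorption ~ nu |mu|^2, spontaneous
emission ~ nu^3 |mu|^2).  Absolute emission intensities integrate to the
ensemble spontaneous-emission rate, whose reciprocal is the radiative
lifetime.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .constants import (
    AMU_NM2_FS2_TO_KJMOL,
    AVOGADRO,
    C_LIGHT_SI,
    DEFAULT_TEMPERATURE,
    EPSILON0_SI,
    E_CHARGE_SI,
    HBAR,
    KB,
    PLANCK_SI,
    kjmol_to_hz,
)
from .qc_pmm import InputError

__all__ = [
    "VibronicModeSet",
    "SpectrumBin",
    "Spectrum",
    "huang_rhys",
    "fc_factor",
    "fc_series",
    "multimode_fc",
    "classical_broadening",
    "vertical_spectrum",
    "vibronic_shift",
    "vibronic_spectrum",
    "assemble_spectrum",
    "einstein_a",
    "radiative_lifetime",
]

# 16 pi^3 / (3 eps0 h c^3) with the dipole in C m and nu in Hz -> A in s^-1
_EINSTEIN_PREF_SI = (
    16.0 * math.pi**3 / (3.0 * EPSILON0_SI * PLANCK_SI * C_LIGHT_SI**3)
)
_E_NM_TO_CM = E_CHARGE_SI * 1.0e-9


def huang_rhys(omega: float, displacement: float) -> float:
    """Huang-Rhys factor S = omega d^2 / (2 hbar).

    ``omega`` is the angular mode frequency in fs^-1 and ``displacement``
    the mass-weighted minimum shift in amu^1/2 nm.
    """
    return AMU_NM2_FS2_TO_KJMOL * omega * displacement**2 / (2.0 * HBAR)


@dataclass(frozen=True)
class VibronicModeSet:
    """Displaced identical-frequency harmonic modes of one state pair."""

    omegas: np.ndarray            # angular frequencies, fs^-1
    displacements: np.ndarray     # mass-weighted minimum shifts, amu^1/2 nm
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        object.__setattr__(self, "omegas", np.atleast_1d(np.asarray(self.omegas, float)))
        object.__setattr__(
            self, "displacements", np.atleast_1d(np.asarray(self.displacements, float))
        )
        if self.omegas.shape != self.displacements.shape:
            raise InputError("one displacement per mode frequency required")
        if np.any(self.omegas <= 0):
            raise InputError("mode frequencies must be positive")
        if not self.temperature > 0:
            raise InputError("temperature must be positive")

    @property
    def quantum_mask(self) -> np.ndarray:
        """True for quantum modes: hbar*omega above the thermal energy."""
        return HBAR * self.omegas > KB * self.temperature

    @property
    def huang_rhys(self) -> np.ndarray:
        return huang_rhys(self.omegas, self.displacements)

    @property
    def mode_energies(self) -> np.ndarray:
        """Vibrational quanta hbar*omega, kJ/mol."""
        return HBAR * self.omegas


def fc_factor(S, n):
    """Single-mode 0 -> n Franck-Condon factor exp(-S) S^n / n!."""
    S = np.asarray(S, dtype=float)
    n = np.asarray(n)
    if np.any(S < 0):
        raise InputError("Huang-Rhys factor must be nonnegative")
    if np.any(n < 0):
        raise InputError("vibrational quantum number must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.where(
            (S == 0) & (n > 0),
            -np.inf,
            n * np.log(np.where(S > 0, S, 1.0)) - S - gammaln(np.asarray(n) + 1.0),
        )
    out = np.exp(log_p)
    return float(out) if out.ndim == 0 else out


def fc_series(S: float, tol: float = 1e-6, max_n: int = 10_000) -> np.ndarray:
    """0 -> n factors until the cumulative probability reaches 1 - tol."""
    terms = [fc_factor(S, 0)]
    total = terms[0]
    n = 0
    while total < 1.0 - tol and n < max_n:
        n += 1
        terms.append(terms[-1] * S / n)
        total += terms[-1]
    return np.array(terms)


def multimode_fc(
    factors_per_mode: Sequence[np.ndarray],
    energies_per_mode: Optional[Sequence[float]] = None,
    max_terms: int = 1_000_000,
    cum_tol: float = 1e-6,
):
    """Best-first enumeration of multi-mode Franck-Condon products.

    Yields ``(quanta, probability, energy)`` triples in decreasing
    probability, where ``energy = sum_i n_i * hbar omega_i`` when mode
    energies are supplied (0.0 otherwise), stopping once ``max_terms``
    terms are emitted or the cumulative probability exceeds
    ``1 - cum_tol``.
    """
    fpm = [np.asarray(f, dtype=float) for f in factors_per_mode]
    if not fpm:
        yield (), 1.0, 0.0
        return
    de = (
        np.zeros(len(fpm))
        if energies_per_mode is None
        else np.asarray(energies_per_mode, dtype=float)
    )
    start = (0,) * len(fpm)
    p0 = float(np.prod([f[0] for f in fpm]))
    heap = [(-p0, start)]
    seen = {start}
    emitted = 0
    cum = 0.0
    while heap and emitted < max_terms and cum < 1.0 - cum_tol:
        neg_p, q = heapq.heappop(heap)
        p = -neg_p
        yield q, p, float(np.dot(q, de))
        emitted += 1
        cum += p
        for i, f in enumerate(fpm):
            n = q[i]
            if n + 1 < len(f) and f[n] > 0:
                nq = q[:i] + (n + 1,) + q[i + 1 :]
                if nq not in seen:
                    seen.add(nq)
                    heapq.heappush(heap, (-(p * f[n + 1] / f[n]), nq))


def classical_broadening(modes: VibronicModeSet) -> float:
    """Gaussian line width from the classical-like modes, kJ/mol.

    Classical-limit energy-gap fluctuation sigma^2 = 2 kB T lambda_cl
    with the classical reorganization energy lambda_cl = sum S_i hbar
    omega_i over classical modes.
    """
    cl = ~modes.quantum_mask
    lam = float(np.sum(modes.huang_rhys[cl] * modes.mode_energies[cl]))
    return math.sqrt(2.0 * KB * modes.temperature * lam)


@dataclass(frozen=True)
class SpectrumBin:
    """One vertical-energy histogram bin of an MD subensemble."""

    reference_energy: float   # kJ/mol (bin center)
    count: int
    mean_mu2: float           # e^2 nm^2, bin average of |mu_0i|^2
    broadening: float         # kJ/mol


@dataclass
class Spectrum:
    """Intensity on a strictly increasing energy grid (kJ/mol)."""

    grid: np.ndarray
    intensity: np.ndarray
    kind: str = "emission"                 # emission | absorption
    normalization: str = "absolute"        # absolute | area | peak

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.size and np.any(np.diff(self.grid) <= 0):
            raise InputError("spectrum grid must be strictly increasing")
        if np.any(self.intensity < -1e-300):
            raise InputError("spectrum intensities must be nonnegative")

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.grid)) if self.grid.size else 0.0

    @property
    def peak_position(self) -> float:
        return float(self.grid[np.argmax(self.intensity)])

    def normalized(self, mode: str = "area") -> "Spectrum":
        if mode == "area":
            scale = self.area
        elif mode == "peak":
            scale = float(self.intensity.max(initial=0.0))
        else:
            raise InputError(f"unknown normalization {mode!r}")
        out = self.intensity / scale if scale > 0 else self.intensity.copy()
        return Spectrum(self.grid, out, kind=self.kind, normalization=mode)


def _prefactor(energy: np.ndarray, mu2: np.ndarray, kind: str) -> np.ndarray:
    """Frequency/dipole prefactor per line: nu|mu|^2 or the Einstein A."""
    if kind == "emission":
        return einstein_a(energy, mu2)
    if kind == "absorption":
        return energy * mu2
    raise InputError(f"unknown spectrum kind {kind!r}")


def bin_frames(gaps, dipoles, bin_width: float, broadening: Optional[float] = None):
    """Histogram per-frame vertical energies; average |mu|^2 per bin."""
    if bin_width <= 0:
        raise InputError("bin width must be positive")
    gaps = np.asarray(gaps, dtype=float)
    dip = np.asarray(dipoles, dtype=float)
    mu2 = np.sum(dip**2, axis=-1) if dip.ndim == 2 else dip**2
    if mu2.shape != gaps.shape:
        raise InputError("one dipole per frame required")
    if gaps.size == 0:
        return []
    lo = math.floor(gaps.min() / bin_width)
    idx = np.floor(gaps / bin_width).astype(int) - lo
    sig = float(broadening) if broadening is not None else float(bin_width)
    bins = []
    for k in np.unique(idx):
        sel = idx == k
        bins.append(
            SpectrumBin(
                reference_energy=(lo + k + 0.5) * bin_width,
                count=int(sel.sum()),
                mean_mu2=float(mu2[sel].mean()),
                broadening=sig,
            )
        )
    return bins


def _gaussian_sum(centers, weights, sigmas, grid=None, pad: float = 5.0):
    centers = np.asarray(centers, float)
    weights = np.asarray(weights, float)
    sigmas = np.asarray(sigmas, float)
    if grid is None:
        lo = (centers - pad * sigmas).min()
        hi = (centers + pad * sigmas).max()
        step = max(sigmas.min() / 6.0, 1e-12)
        grid = np.arange(lo, hi + step, step)
    out = np.zeros_like(grid)
    for c, w, s in zip(centers, weights, sigmas):
        out += w / (s * math.sqrt(2 * math.pi)) * np.exp(-((grid - c) ** 2) / (2 * s**2))
    return grid, out


def vertical_spectrum(
    gaps,
    dipoles,
    bin_width: float = 1.0,
    broadening: Optional[float] = None,
    kind: str = "emission",
    grid: Optional[np.ndarray] = None,
    normalization: str = "absolute",
) -> Spectrum:
    """Vertical electronic spectrum of one subensemble.

    Each histogram bin contributes one Gaussian weighted by its frame
    fraction n(E_ref)/N_f, its mean squared transition dipole and the
    frequency prefactor of the chosen ``kind``.
    """
    bins = bin_frames(gaps, dipoles, bin_width, broadening)
    if not bins:
        return Spectrum(np.array([]), np.array([]), kind=kind)
    n_f = sum(b.count for b in bins)
    centers = [b.reference_energy for b in bins]
    weights = [
        b.count / n_f * _prefactor(b.reference_energy, b.mean_mu2, kind) for b in bins
    ]
    sigmas = [b.broadening for b in bins]
    g, y = _gaussian_sum(centers, weights, sigmas, grid=grid)
    sp = Spectrum(g, y, kind=kind)
    return sp if normalization == "absolute" else sp.normalized(normalization)


def vibronic_shift(nu_ref, nu_m0, nu_el0):
    """Bin reference frequency of the m-th vibronic line.

    ``nu_ref + (nu_m0 - nu_el0)``: the perturbed vertical line shifted by
    the unperturbed vibronic-versus-vertical offset.  Any consistent
    frequency or energy unit may be used.
    """
    return np.asarray(nu_ref, float) + (np.asarray(nu_m0, float) - np.asarray(nu_el0, float))


def vibronic_spectrum(
    gaps,
    dipoles,
    modes: VibronicModeSet,
    e_00: float,
    e_vertical: float,
    bin_width: float = 1.0,
    broadening: Optional[float] = None,
    kind: str = "emission",
    grid: Optional[np.ndarray] = None,
    fc_tol: float = 1e-6,
    max_terms: int = 1_000_000,
    normalization: str = "absolute",
) -> Spectrum:
    """Vibronic spectrum: vertical bins dressed with FC progressions.

    ``e_00`` is the unperturbed 0-0 transition energy (kJ/mol, after any
    experimental-matching correction) and ``e_vertical`` the unperturbed
    vertical transition energy; quantum-mode progressions build on their
    difference, emission lines stepping down and absorption lines
    stepping up by the product-state vibrational quanta.
    """
    bins = bin_frames(gaps, dipoles, bin_width, broadening)
    if not bins:
        return Spectrum(np.array([]), np.array([]), kind=kind)
    qm = modes.quantum_mask
    S = modes.huang_rhys[qm]
    de = modes.mode_energies[qm]
    series = [fc_series(s, tol=fc_tol) for s in S]
    sign = -1.0 if kind == "emission" else 1.0
    terms = list(multimode_fc(series, de, max_terms=max_terms, cum_tol=fc_tol))
    if broadening is None:
        sig_cl = classical_broadening(modes)
        sig = sig_cl if sig_cl > 0 else float(bin_width)
    else:
        sig = float(broadening)
    n_f = sum(b.count for b in bins)
    centers, weights, sigmas = [], [], []
    for b in bins:
        for _, p, e_vib in terms:
            e_line = vibronic_shift(b.reference_energy, e_00 + sign * e_vib, e_vertical)
            centers.append(e_line)
            weights.append(b.count / n_f * p * _prefactor(e_line, b.mean_mu2, kind))
            sigmas.append(sig)
    g, y = _gaussian_sum(centers, weights, sigmas, grid=grid)
    sp = Spectrum(g, y, kind=kind)
    return sp if normalization == "absolute" else sp.normalized(normalization)


def assemble_spectrum(spectra: Sequence[Spectrum], weights) -> Spectrum:
    """Statistically weighted subensemble mixture on the union grid."""
    weights = np.asarray(weights, dtype=float)
    if len(spectra) != weights.size:
        raise InputError("one weight per spectrum required")
    if np.any(weights < 0):
        raise InputError("weights must be nonnegative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise InputError("weights must sum to 1")
    grid = spectra[0].grid
    for sp in spectra[1:]:
        grid = np.union1d(grid, sp.grid)
    total = np.zeros_like(grid)
    for w, sp in zip(weights, spectra):
        if sp.grid.size:
            total += w * np.interp(grid, sp.grid, sp.intensity, left=0.0, right=0.0)
    return Spectrum(grid, total, kind=spectra[0].kind)


def einstein_a(energy, mu2):
    """Spontaneous-emission coefficient A (s^-1).

    ``energy`` in kJ/mol, ``mu2`` the squared transition dipole norm in
    e^2 nm^2; A = 16 pi^3 nu^3 |mu|^2 / (3 eps0 h c^3).
    """
    nu = kjmol_to_hz(np.asarray(energy, dtype=float))
    mu2_si = np.asarray(mu2, dtype=float) * _E_NM_TO_CM**2
    return _EINSTEIN_PREF_SI * nu**3 * mu2_si


def radiative_lifetime(energies, mu2, weights=None) -> Optional[float]:
    """Radiative lifetime (ns) of an ensemble of emission transitions.

    The spontaneous rate is the (optionally weighted) ensemble mean of
    the per-transition Einstein A coefficients; the lifetime is its
    reciprocal.  Returns None when every dipole vanishes.
    """
    energies = np.atleast_1d(np.asarray(energies, dtype=float))
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    if energies.size == 0:
        raise InputError("at least one transition is required")
    a = einstein_a(energies, mu2)
    rate = float(np.average(a, weights=weights))
    if rate <= 0.0:
        return None
    return 1.0e9 / rate
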