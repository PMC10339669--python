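"""Perturbed electronic Hamiltonians for a quantum center (PMM).

The quantum center (QC) is described by a small basis of unperturbed
(gas-phase) electronic eigenstates.  The classical environment enters
only through the electric potential it exerts at the QC atom positions
and the electric field at a reference point (typically the QC center of
mass).  Per frame, the perturbed electronic Hamiltonian is built with

* diagonal elements  ``H_jj = eps_j0 + sum_N q_Nj * V(R_N) + dV``
  (unperturbed energy, atomic-charge/potential coupling, and a
  state-independent scalar ``dV`` collecting higher-order terms), and
* off-diagonal elements ``H_jl = -E(r0) . mu_jl0`` coupling the states
  through their unperturbed transition dipoles in the dipolar
  approximation.

Diagonalizing per frame yields perturbed (adiabatic) energies,
eigenvectors and transition dipoles; the diagonal elements themselves
are the diabatic energies whose differences drive the crossing
kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "KNOWN_LABELS",
    "UnperturbedState",
    "Atom",
    "QuantumCenter",
    "PerturbationFrame",
    "PerturbedState",
    "DiabaticAssignment",
    "build_hamiltonian",
    "diagonalize",
    "assign_diabatic_character",
    "diabatic_gap",
]

#: Recognised diabatic state labels: ground state, the two pi-pi*
#: singlets of indole-like chromophores, the dark pi-sigma* state, and a
#: catch-all for anything else.
KNOWN_LABELS = ("GS", "Lb", "La", "piSigma", "other")

_CHARGE_TOL = 1e-9
_TIE_TOL = 1e-12


class InputError(ValueError):
    """Raised on malformed or non-conformable inputs."""


@dataclass(frozen=True)
class Atom:
    element: str
    mass: float              # amu
    position: np.ndarray     # nm, reference geometry

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise InputError("atom position must be a 3-vector")
        if not self.mass > 0:
            raise InputError("atom mass must be positive")


@dataclass(frozen=True)
class UnperturbedState:
    """One gas-phase electronic eigenstate of the quantum center.

    ``vibronic_correction`` is an additive shift (kJ/mol) applied to any
    diabatic gap involving this state, used to bring computed 0-0
    transitions onto their experimental gas-phase values.
    """

    label: str
    energy: float                       # kJ/mol
    atomic_charges: np.ndarray          # e, one per atom
    diagonal_dipole: np.ndarray         # e*nm
    vibronic_correction: float = 0.0    # kJ/mol

    def __post_init__(self):
        if self.label not in KNOWN_LABELS:
            raise InputError(
                f"unknown state label {self.label!r}; expected one of {KNOWN_LABELS}"
            )
        object.__setattr__(
            self, "atomic_charges", np.asarray(self.atomic_charges, dtype=float)
        )
        object.__setattr__(
            self, "diagonal_dipole", np.asarray(self.diagonal_dipole, dtype=float)
        )
        if self.diagonal_dipole.shape != (3,):
            raise InputError("diagonal dipole must be a 3-vector")
        if not np.isfinite(self.energy):
            raise InputError("state energy must be finite")

    @property
    def total_charge(self) -> float:
        return float(self.atomic_charges.sum())


@dataclass(frozen=True)
class QuantumCenter:
    """Unperturbed electronic (and optionally vibrational) description."""

    atoms: tuple
    states: tuple
    transition_dipoles: np.ndarray          # (n_states, n_states, 3), e*nm
    mode_sets: dict = field(default_factory=dict)  # label -> VibronicModeSet

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(self, "states", tuple(self.states))
        mu = np.asarray(self.transition_dipoles, dtype=float)
        object.__setattr__(self, "transition_dipoles", mu)
        n = len(self.states)
        if mu.shape != (n, n, 3):
            raise InputError("transition dipole matrix must have shape (n, n, 3)")
        if not np.allclose(mu, mu.transpose(1, 0, 2), atol=1e-12):
            raise InputError("transition dipole matrix must be symmetric")
        n_atoms = len(self.atoms)
        q_tot = self.states[0].total_charge
        for j, s in enumerate(self.states):
            if s.atomic_charges.shape != (n_atoms,):
                raise InputError(
                    f"state {s.label!r}: {s.atomic_charges.size} charges for "
                    f"{n_atoms} atoms"
                )
            if abs(s.total_charge - q_tot) > _CHARGE_TOL:
                raise InputError(
                    "all states must carry the same total charge "
                    f"({s.label!r}: {s.total_charge} vs {q_tot})"
                )
            if not np.allclose(mu[j, j], s.diagonal_dipole, atol=1e-9):
                raise InputError(
                    f"diagonal of transition dipole matrix disagrees with the "
                    f"diagonal dipole of state {s.label!r}"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def labels(self) -> tuple:
        return tuple(s.label for s in self.states)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.states])

    def state_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(f"no state labelled {label!r} in this quantum center")


@dataclass(frozen=True)
class PerturbationFrame:
    """One time point of the classical environment seen by the QC."""

    time: float                    # fs
    site_potentials: np.ndarray    # kJ mol^-1 e^-1, one per atom
    field: np.ndarray              # kJ mol^-1 e^-1 nm^-1, at the reference point
    offset: float = 0.0            # kJ/mol, state-independent dV

    def __post_init__(self):
        object.__setattr__(
            self, "site_potentials", np.asarray(self.site_potentials, dtype=float)
        )
        object.__setattr__(self, "field", np.asarray(self.field, dtype=float))
        if self.field.shape != (3,):
            raise InputError("field must be a 3-vector")
        if not np.isfinite(self.offset):
            raise InputError("offset dV must be finite")
        if not (
            np.all(np.isfinite(self.site_potentials)) and np.all(np.isfinite(self.field))
        ):
            raise InputError("potentials and field must be finite")


@dataclass(frozen=True)
class PerturbedState:
    """Eigen-decomposition of one perturbed Hamiltonian.

    ``coefficients[j, i]`` is the weight of unperturbed state *j* in
    perturbed (adiabatic) state *i*; columns are orthonormal and
    eigenvalues ascend.
    """

    energies: np.ndarray                      # kJ/mol, ascending
    coefficients: np.ndarray                  # (n, n)
    perturbed_transition_dipoles: np.ndarray  # (n, 3), 0 -> i, e*nm

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if not np.allclose(c.T @ c, np.eye(c.shape[0]), atol=1e-10):
            raise InputError("eigenvector matrix is not orthonormal")
        if np.any(np.diff(self.energies) < -1e-12):
            raise InputError("perturbed energies must be nondecreasing")


class DiabaticAssignment(NamedTuple):
    label: str
    weight: float
    tie: bool


def build_hamiltonian(qc: QuantumCenter, frame: PerturbationFrame) -> np.ndarray:
    """Perturbed electronic Hamiltonian matrix (kJ/mol) for one frame."""
    if frame.site_potentials.shape != (qc.n_atoms,):
        raise InputError(
            f"{frame.site_potentials.size} site potentials for {qc.n_atoms} atoms"
        )
    n = qc.n_states
    H = np.empty((n, n))
    # off-diagonal dipolar coupling; overwritten on the diagonal below
    H[:] = -np.tensordot(qc.transition_dipoles, frame.field, axes=([2], [0]))
    for j, s in enumerate(qc.states):
        H[j, j] = (
            s.energy + float(s.atomic_charges @ frame.site_potentials) + frame.offset
        )
    return H


def diagonalize(H: np.ndarray, qc: QuantumCenter) -> PerturbedState:
    """Eigen-decompose a perturbed Hamiltonian and rotate the dipoles.

    The perturbed transition dipole from the perturbed ground state to
    perturbed state *i* is ``sum_jl c_j0 c_li mu_jl0``.
    """
    H = np.asarray(H, dtype=float)
    if H.shape != (qc.n_states, qc.n_states) or not np.allclose(H, H.T, atol=1e-9):
        raise InputError("Hamiltonian must be a square symmetric matrix over the basis")
    w, c = np.linalg.eigh(H)
    mu = np.einsum("j,jlk,li->ik", c[:, 0], qc.transition_dipoles, c)
    return PerturbedState(energies=w, coefficients=c, perturbed_transition_dipoles=mu)


def assign_diabatic_character(
    state_index: int, ps: PerturbedState, qc: QuantumCenter
) -> DiabaticAssignment:
    """Diabatic label of a perturbed state by maximum squared coefficient.

    Ties within 1e-12 are flagged and resolved toward the
    lower-(unperturbed-)energy label.
    """
    w2 = ps.coefficients[:, state_index] ** 2
    best = float(w2.max())
    contenders = np.flatnonzero(w2 >= best - _TIE_TOL)
    tie = contenders.size > 1
    if tie:
        j = int(min(contenders, key=lambda k: (qc.states[k].energy, k)))
    else:
        j = int(contenders[0])
    return DiabaticAssignment(label=qc.states[j].label, weight=float(w2[j]), tie=tie)


def diabatic_gap(
    qc: QuantumCenter, frame: PerturbationFrame, R: str, P: str
) -> float:
    """Diabatic transition energy R -> P (kJ/mol) for one frame.

    ``H_PP - H_RR`` plus the vibronic 0-0 correction difference of the
    two states; positive means the product diabatic surface lies above
    the reactant one.
    """
    if R == P:
        raise InputError("reactant and product labels must differ")
    iR, iP = qc.state_index(R), qc.state_index(P)
    if frame.site_potentials.shape != (qc.n_atoms,):
        raise InputError(
            f"{frame.site_potentials.size} site potentials for {qc.n_atoms} atoms"
        )
    sR, sP = qc.states[iR], qc.states[iP]
    dq = sP.atomic_charges - sR.atomic_charges
    gap = (sP.energy - sR.energy) + float(dq @ frame.site_potentials)
    return gap + (sP.vibronic_correction - sR.vibronic_correction)
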