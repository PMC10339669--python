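"""Surrogate inputs with the statistical structure the analysis assumes.

The equilibrium transition-energy fluctuations of a solvated
chromophore are emulated by a stationary, differentiable Gaussian
process: a second-order (underdamped) Langevin oscillator whose
position marginal is N(mean, sigma^2) and whose velocity marginal is
N(0, sigma_v^2).  The second-order form matters because the crossing
kinetics need a well-defined gap velocity; a plain Ornstein-Uhlenbeck
position process has none.  The discretization uses the exact Gaussian
transition kernel of the linear system, so no step-size bias enters the
sampled moments.

Perturbing fields and site potentials are generated as (optionally
cross-correlated) Ornstein-Uhlenbeck components, and toy quantum
centers with physically consistent charges, dipoles and mode sets allow
every stage of the pipeline to run without any electronic-structure or
MD input.  One global seed expands deterministically into independent
per-stream seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .constants import DEFAULT_TEMPERATURE, HBAR, KB
from .kinetics import TransitionEnergyTrace
from .qc_pmm import (
    Atom,
    InputError,
    PerturbationFrame,
    QuantumCenter,
    UnperturbedState,
)
from .vibronic import VibronicModeSet

__all__ = [
    "GapProcessSpec",
    "FieldProcessSpec",
    "gen_gap_trace",
    "gen_gap_ensemble",
    "gen_reactant_starts",
    "gen_toy_qc",
    "gen_field_frames",
    "spawn_seeds",
]


def spawn_seeds(seed: int, n: int) -> list:
    """Expand one global seed into n independent stream seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass(frozen=True)
class GapProcessSpec:
    """Stationary Gaussian gap process specification.

    ``mean``/``sigma`` set the stationary gap distribution (kJ/mol),
    ``sigma_v`` the stationary velocity spread (kJ mol^-1 fs^-1);
    alternatively ``corr_time`` (fs) sets the damping.  Defaults emulate
    the fast interconversion channel of an aqueous indole-like
    chromophore: mean 3.62, sigma 7.1, mean |velocity| 0.4 (sigma_v =
    0.4 sqrt(pi/2)), sampled at 1 fs.
    """

    mean: float = 3.62
    sigma: float = 7.1
    sigma_v: Optional[float] = 0.4 * np.sqrt(np.pi / 2.0)
    corr_time: Optional[float] = None
    dt: float = 1.0
    duration: float = 10_000.0
    seed: int = 0

    def __post_init__(self):
        if not self.sigma > 0:
            raise InputError("sigma must be positive")
        if self.sigma_v is None and self.corr_time is None:
            raise InputError("give sigma_v or corr_time")
        if not self.dt > 0 or not self.duration >= self.dt:
            raise InputError("need a positive step shorter than the duration")

    @property
    def omega0(self) -> float:
        """Oscillator frequency sigma_v / sigma fixing the velocity marginal."""
        if self.sigma_v is not None:
            return self.sigma_v / self.sigma
        return 2.0 / self.corr_time

    @property
    def gamma(self) -> float:
        """Friction; the position autocorrelation decays on ~2/gamma."""
        if self.corr_time is not None:
            return 2.0 / self.corr_time
        return self.omega0

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt)) + 1

    def validate_resolution(self):
        # >= 20 samples per correlation time / oscillation period so that
        # crossings are resolved and moments unbiased at the sample level
        tau_c = min(2.0 / self.gamma, 2.0 * np.pi / self.omega0)
        if self.dt > tau_c / 20.0:
            raise InputError(
                f"time step {self.dt} fs too coarse for correlation time "
                f"{tau_c:.1f} fs (need >= 20 samples per correlation time)"
            )


def _langevin_kernel(spec: GapProcessSpec):
    """Exact one-step Gaussian transition kernel of the (x, v) system."""
    w0, gam = spec.omega0, spec.gamma
    A = np.array([[0.0, 1.0], [-(w0**2), -gam]])
    M = expm(A * spec.dt)
    sigma_v = spec.sigma * w0
    s_inf = np.diag([spec.sigma**2, sigma_v**2])
    s_step = s_inf - M @ s_inf @ M.T
    # guard tiny negative eigenvalues from cancellation
    s_step = (s_step + s_step.T) / 2.0
    w, q = np.linalg.eigh(s_step)
    if np.any(w < -1e-12 * max(w.max(), 1.0)):
        raise InputError("unstable discretization: step too large")
    L_step = q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    L_inf = np.linalg.cholesky(s_inf)
    return M, L_step, L_inf


def _propagate(spec: GapProcessSpec, n_traj: int, rng) -> np.ndarray:
    """(n_steps, n_traj, 2) array of stationary (gap, velocity) paths."""
    spec.validate_resolution()
    M, L_step, L_inf = _langevin_kernel(spec)
    z = rng.standard_normal((n_traj, 2)) @ L_inf.T      # stationary start
    out = np.empty((spec.n_steps, n_traj, 2))
    for i in range(spec.n_steps):
        out[i] = z
        z = z @ M.T + rng.standard_normal((n_traj, 2)) @ L_step.T
    out[..., 0] += spec.mean
    return out


def gen_gap_trace(spec: GapProcessSpec) -> TransitionEnergyTrace:
    """One stationary gap trajectory, reproducible under the spec seed."""
    rng = np.random.default_rng(spec.seed)
    path = _propagate(spec, 1, rng)[:, 0, :]
    times = np.arange(spec.n_steps) * spec.dt
    return TransitionEnergyTrace(times=times, gap=path[:, 0], velocity=path[:, 1])


def gen_gap_ensemble(spec: GapProcessSpec, n_traj: int) -> list:
    """Independent stationary gap trajectories sharing one spec/seed."""
    rng = np.random.default_rng(spec.seed)
    paths = _propagate(spec, n_traj, rng)
    times = np.arange(spec.n_steps) * spec.dt
    return [
        TransitionEnergyTrace(times=times, gap=paths[:, k, 0], velocity=paths[:, k, 1])
        for k in range(n_traj)
    ]


def gen_reactant_starts(
    trace: TransitionEnergyTrace, n: int, seed: int = 0
) -> np.ndarray:
    """Block-wise start frames with positive gap.

    The trace is divided into ``n`` equal-length subtrajectories; within
    each, frames are drawn at random (without replacement) until one
    with a positive transition energy is found, mirroring the
    nonequilibrium start-selection protocol.  Blocks with no positive
    frame are skipped with a warning.
    """
    n_frames = trace.gap.size
    block = n_frames // n
    if block < 1:
        raise InputError("trace shorter than the requested number of blocks")
    rng = np.random.default_rng(seed)
    starts = []
    for b in range(n):
        idx = b * block + rng.permutation(block)
        pos = idx[trace.gap[idx] > 0]
        if pos.size == 0:
            warnings.warn(f"block {b}: no positive-gap frame, skipped")
            continue
        starts.append(int(pos[0]))
    return np.array(starts, dtype=int)


def gen_toy_qc(
    n_states: int,
    n_atoms: int,
    seed: int = 0,
    temperature: float = DEFAULT_TEMPERATURE,
    n_modes: int = 6,
) -> QuantumCenter:
    """Random but physically consistent quantum center.

    Neutral per-state charge sets, a symmetric transition-dipole matrix,
    and per-state mode sets whose frequencies straddle the
    classical/quantum boundary at the given temperature.
    """
    if n_states < 2:
        raise InputError("need at least two states")
    rng = np.random.default_rng(seed)
    labels = ["GS", "Lb", "La", "piSigma"][:n_states]
    labels += ["other"] * (n_states - len(labels))
    elements = ["C", "N", "H"]
    masses = {"C": 12.011, "N": 14.007, "H": 1.008}
    atoms = []
    for k in range(n_atoms):
        el = elements[k % len(elements)]
        atoms.append(Atom(el, masses[el], rng.uniform(-0.3, 0.3, size=3)))
    mu = rng.normal(scale=0.05, size=(n_states, n_states, 3))
    mu = (mu + mu.transpose(1, 0, 2)) / 2.0
    energies = np.concatenate([[0.0], np.sort(rng.uniform(350.0, 500.0, n_states - 1))])
    states = []
    for j in range(n_states):
        q = rng.normal(scale=0.2, size=n_atoms)
        q -= q.mean()  # neutral
        states.append(
            UnperturbedState(
                label=labels[j],
                energy=float(energies[j]),
                atomic_charges=q,
                diagonal_dipole=mu[j, j],
            )
        )
    # mode frequencies straddling hbar*omega = kB*T
    w_thermal = KB * temperature / HBAR
    omegas = w_thermal * np.exp(rng.uniform(-1.5, 3.0, size=n_modes))
    disp = rng.uniform(0.005, 0.03, size=n_modes)
    mode_sets = {
        s.label: VibronicModeSet(omegas, disp, temperature=temperature)
        for s in states
    }
    return QuantumCenter(
        atoms=atoms, states=states, transition_dipoles=mu, mode_sets=mode_sets
    )


@dataclass(frozen=True)
class FieldProcessSpec:
    """Ornstein-Uhlenbeck model of site potentials and reference field.

    ``means``/``covariance`` describe the stationary distribution of the
    stacked vector (V_1..V_n_atoms, E_x, E_y, E_z); a diagonal
    covariance may be given as a 1-D variance vector.  All components
    share one correlation time.
    """

    means: np.ndarray
    covariance: np.ndarray
    corr_time: float = 50.0    # fs
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self):
        m = np.atleast_1d(np.asarray(self.means, float))
        c = np.asarray(self.covariance, float)
        if c.ndim == 1:
            c = np.diag(c)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariance", c)
        if c.shape != (m.size, m.size):
            raise InputError("covariance must be square and match the means")
        if not np.allclose(c, c.T, atol=1e-12):
            raise InputError("covariance must be symmetric")
        w = np.linalg.eigvalsh(c)
        if np.any(w < -1e-10 * max(abs(w).max(), 1.0)):
            raise InputError("covariance must be positive semidefinite")
        if not self.corr_time > 0 or not self.dt > 0:
            raise InputError("correlation time and step must be positive")


def gen_field_frames(spec: FieldProcessSpec, n: int) -> list:
    """n PerturbationFrame samples of the OU field process.

    The last three components of the process vector are the reference
    field; the rest are site potentials.  Uses the exact OU update
    x_{k+1} = mean + phi (x_k - mean) + noise with phi = exp(-dt/tau_c).
    """
    if spec.means.size < 4:
        raise InputError("process must cover >= 1 site potential plus the field")
    rng = np.random.default_rng(spec.seed)
    dim = spec.means.size
    w, q = np.linalg.eigh(spec.covariance)
    L = q @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    phi = np.exp(-spec.dt / spec.corr_time)
    innov = np.sqrt(1.0 - phi**2)
    x = spec.means + rng.standard_normal(dim) @ L.T
    frames = []
    for k in range(n):
        frames.append(
            PerturbationFrame(
                time=k * spec.dt,
                site_potentials=x[:-3].copy(),
                field=x[-3:].copy(),
            )
        )
        x = spec.means + phi * (x - spec.means) + innov * (
            rng.standard_normal(dim) @ L.T
        )
    return frames
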