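"""First-crossing kinetics of diabatic energy gaps.

A reactant trajectory starts with a positive diabatic transition energy
(gap) and reacts when the gap first reaches zero.  The kinetics are
characterized at three levels:

* **explicit sampling** — detect first crossings on an ensemble of gap
  traces, build the survival curve, and fit a constrained biexponential
  ``n1 exp(-t/tau1) + n2 exp(-t/tau2)`` (n1 + n2 = 1) whose weighted
  mean ``tau0 = n1 tau1 + n2 tau2`` is the fully adiabatic lifetime;

* **Gaussian approximation** — when crossings are too rare to sample,
  the attempt rate follows from the reactant-ensemble gap statistics:
  ``k0 = <v> rho(0) / 2`` with rho the Gaussian density of the gap and
  the 1/2 keeping only downward (reactive-direction) crossings.  This is
  Rice's level-crossing rate when the gap velocity is Gaussian;

* **transmission** — each transition-region approach hops with the
  Landau-Zener electronic adiabatic fraction
  ``chi_e = 1 - exp(-2 pi |H|^2 / (hbar v_cr))`` weighted by the
  vibronic overlap sum Omega, giving the transmission coefficient
  ``alpha_G = 1 - <(1 - chi_e)^Omega>`` (or the mean-field approximation
  ``1 - (1 - alpha_e)^<Omega>``).  The reaction lifetime allows two hop
  opportunities per approach (inbound and outbound traversal):
  ``tau = tau0 / (1 - (1 - alpha_G)^2)``.

The mean-coupling route estimates ``alpha_e`` from equilibrium field
statistics alone: at a crossing the field component along the diabatic
dipole difference is fixed by the crossing condition, and the coupling
second moment is assembled from that component and the orthogonal
in-plane field statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .constants import HBAR
from .qc_pmm import InputError

__all__ = [
    "TransitionEnergyTrace",
    "CrossingEvent",
    "GapStatistics",
    "CouplingGeometry",
    "RateEstimate",
    "SurvivalFit",
    "detect_first_crossing",
    "survival_trace",
    "fit_survival",
    "lz_adiabatic_fraction",
    "omega",
    "transmission_explicit",
    "transmission_approx",
    "gaussian_rate",
    "crossing_rate",
    "mean_coupling_alpha_e",
    "reaction_lifetime",
    "bootstrap_se",
]


@dataclass(frozen=True)
class TransitionEnergyTrace:
    """Uniformly sampled diabatic gap time series with its derivative."""

    times: np.ndarray       # fs, strictly increasing, uniform step
    gap: np.ndarray         # kJ/mol
    velocity: np.ndarray    # kJ mol^-1 fs^-1

    def __post_init__(self):
        t = np.asarray(self.times, float)
        g = np.asarray(self.gap, float)
        v = np.asarray(self.velocity, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "gap", g)
        object.__setattr__(self, "velocity", v)
        if t.size < 2:
            raise InputError("a trace needs at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise InputError("times must be strictly increasing with uniform step")
        if g.shape != t.shape or v.shape != t.shape:
            raise InputError("gap and velocity must match the time grid")

    @classmethod
    def from_gap(cls, times, gap) -> "TransitionEnergyTrace":
        """Build a trace, deriving the velocity by central differences."""
        times = np.asarray(times, float)
        gap = np.asarray(gap, float)
        return cls(times, gap, np.gradient(gap, times))

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class CrossingEvent:
    """One first crossing of a diabatic gap."""

    time: float                      # fs
    speed: float                     # |d gap/dt| at the crossing
    coupling: Optional[float] = None  # |H_RP| kJ/mol
    chi_e: Optional[float] = None     # LZ adiabatic fraction
    n_p: Optional[int] = None         # traversed product vibronic surfaces
    omega: Optional[float] = None     # squared vibrational overlap sum

    def __post_init__(self):
        if not self.speed > 0:
            raise InputError("crossing speed must be positive")
        if self.chi_e is not None and not 0.0 <= self.chi_e <= 1.0:
            raise InputError("chi_e must lie in [0, 1]")
        if self.omega is not None and not 0.0 < self.omega <= 1.0 + 1e-12:
            raise InputError("Omega must lie in (0, 1]")


@dataclass(frozen=True)
class GapStatistics:
    """Reactant-ensemble moments of a transition energy."""

    mean: float         # kJ/mol
    sigma: float        # kJ/mol
    mean_speed: float   # kJ mol^-1 fs^-1, <|d gap/dt|>

    def __post_init__(self):
        if not self.sigma > 0:
            raise InputError("gap standard deviation must be positive")
        if not self.mean_speed > 0:
            raise InputError("mean gap speed must be positive")

    @classmethod
    def from_trace(cls, trace: TransitionEnergyTrace) -> "GapStatistics":
        return cls(
            mean=float(trace.gap.mean()),
            sigma=float(trace.gap.std(ddof=1)),
            mean_speed=float(np.abs(trace.velocity).mean()),
        )


def gap_mode(trace: TransitionEnergyTrace) -> float:
    """Sample mode of the gap distribution (diagnostic; equals the mean
    under the Gaussian assumption)."""
    kde = stats.gaussian_kde(trace.gap)
    grid = np.linspace(trace.gap.min(), trace.gap.max(), 512)
    return float(grid[np.argmax(kde(grid))])


@dataclass(frozen=True)
class RateEstimate:
    """Attempt lifetime, transmission and reaction lifetime of a channel."""

    tau0: float                     # fs, fully adiabatic mean lifetime
    alpha_g: Optional[float] = None
    tau: Optional[float] = None     # fs
    method: str = "explicit"        # explicit | gaussian | mean_coupling
    tau0_se: Optional[float] = None
    alpha_g_se: Optional[float] = None

    def __post_init__(self):
        if not self.tau0 > 0:
            raise InputError("tau0 must be positive")
        if self.alpha_g is not None and not 0.0 < self.alpha_g <= 1.0:
            raise InputError("alpha_G must lie in (0, 1]")
        if self.tau is not None and self.tau < self.tau0 - 1e-9:
            raise InputError("reaction lifetime cannot undercut tau0")

    def with_transmission(self, alpha_g: float, alpha_g_se=None) -> "RateEstimate":
        return replace(
            self,
            alpha_g=alpha_g,
            alpha_g_se=alpha_g_se,
            tau=reaction_lifetime(self.tau0, alpha_g),
        )


# ---------------------------------------------------------------------------
# explicit crossing sampling


def detect_first_crossing(trace: TransitionEnergyTrace) -> Optional[CrossingEvent]:
    """First sign change of the gap, or None if the trace never crosses.

    The crossing time is linearly interpolated between the bracketing
    samples and the crossing speed is the bracketing-interval slope.
    The trace must start on the reactant side (positive gap).
    """
    g = trace.gap
    if g[0] <= 0:
        raise InputError(
            "trace starts at nonpositive gap; re-select the start frame "
            "so the transition energy is positive"
        )
    below = g <= 0
    if not below.any():
        return None
    i = int(below.argmax())  # first nonpositive sample; i >= 1 since g[0] > 0
    t0, t1 = trace.times[i - 1], trace.times[i]
    g0, g1 = g[i - 1], g[i]
    t_cross = t0 if g1 == g0 else t0 + (t1 - t0) * g0 / (g0 - g1)
    v_cr = abs(g1 - g0) / (t1 - t0)
    if v_cr == 0.0:
        v_cr = abs(trace.velocity[i])
    return CrossingEvent(time=float(t_cross), speed=float(v_cr))


def survival_trace(
    events: Sequence[Optional[CrossingEvent]],
    horizon: float,
    grid: Optional[np.ndarray] = None,
):
    """Fraction of trajectories that have not yet crossed at each time.

    Trajectories without a crossing (None) are right-censored: they
    count as surviving through the whole horizon.
    """
    if len(events) == 0:
        raise InputError("at least one trajectory is required")
    times = np.sort([e.time for e in events if e is not None and e.time <= horizon])
    if grid is None:
        grid = np.linspace(0.0, horizon, 512)
    else:
        grid = np.asarray(grid, float)
    surv = 1.0 - np.searchsorted(times, grid, side="right") / len(events)
    return grid, surv


@dataclass(frozen=True)
class SurvivalFit:
    n1: float
    tau1: float
    n2: float
    tau2: float
    tau0: float              # n1 tau1 + n2 tau2, fs
    single: bool = False     # True when the single-exponential fallback was used
    message: str = ""


def _biexp(t, n1, tau1, tau2):
    return n1 * np.exp(-t / tau1) + (1.0 - n1) * np.exp(-t / tau2)


def fit_survival(t, survival) -> SurvivalFit:
    """Constrained biexponential fit of a survival curve.

    Fits ``n1 exp(-t/tau1) + n2 exp(-t/tau2)`` with n1 + n2 = 1 and all
    parameters positive; reports the mean lifetime tau0 = n1 tau1 + n2
    tau2.  Falls back to a single exponential when the two timescales
    are within a factor of two of each other or the fit fails.
    """
    t = np.asarray(t, float)
    s = np.asarray(survival, float)
    if s.min() >= s.max() - 1e-12:
        raise InputError("survival curve must decrease somewhere")
    # crude single-exponential scale from the integrated curve
    tau_guess = max(float(np.trapezoid(s, t)), t[1] - t[0])

    def _single_fit():
        (tau,), _ = optimize.curve_fit(
            lambda tt, tau: np.exp(-tt / tau), t, s, p0=[tau_guess],
            bounds=(1e-12, np.inf), maxfev=10_000,
        )
        return SurvivalFit(1.0, tau, 0.0, tau, tau, single=True,
                           message="single-exponential fit")

    try:
        p0 = [0.5, 0.5 * tau_guess, 2.0 * tau_guess]
        popt, _ = optimize.curve_fit(
            _biexp, t, s, p0=p0,
            bounds=([0.0, 1e-12, 1e-12], [1.0, np.inf, np.inf]),
            maxfev=20_000,
        )
        n1, tau1, tau2 = popt
    except (RuntimeError, ValueError) as exc:
        fit = _single_fit()
        return replace(fit, message=f"biexponential fit failed ({exc}); {fit.message}")
    ratio = tau1 / tau2
    if 0.5 <= ratio <= 2.0:
        return _single_fit()
    n2 = 1.0 - n1
    tau0 = n1 * tau1 + n2 * tau2
    if tau1 > tau2:  # report the fast component first
        n1, n2, tau1, tau2 = n2, n1, tau2, tau1
    return SurvivalFit(float(n1), float(tau1), float(n2), float(tau2), float(tau0))


# ---------------------------------------------------------------------------
# Landau-Zener transmission


def lz_adiabatic_fraction(coupling, v_cr):
    """Landau-Zener adiabatic fraction chi_e = 1 - exp(-2 pi |H|^2 / (hbar v))."""
    coupling = np.asarray(coupling, float)
    v_cr = np.asarray(v_cr, float)
    if np.any(v_cr <= 0):
        raise InputError("crossing speed must be positive")
    out = 1.0 - np.exp(-2.0 * math.pi * coupling**2 / (HBAR * v_cr))
    return float(out) if out.ndim == 0 else out


def omega(fc_factors, n_p: int) -> float:
    """Squared vibrational overlap sum over the first n_p product surfaces."""
    if n_p < 1:
        raise InputError("n_p must be at least 1")
    xi2 = np.asarray(fc_factors, float)
    return float(min(xi2[: int(n_p)].sum(), 1.0))


def transmission_explicit(
    events: Sequence[CrossingEvent],
    n_boot: int = 1000,
    seed: Optional[int] = None,
):
    """Transmission coefficient alpha_G = <1 - (1 - chi_e)^Omega>.

    Averaged over crossing events, each carrying its own adiabatic
    fraction and vibronic overlap sum; returns (alpha_G, bootstrap SE).
    """
    if len(events) == 0:
        raise InputError("no crossing events supplied")
    chi = np.array([e.chi_e for e in events], dtype=float)
    om = np.array([e.omega for e in events], dtype=float)
    if np.any(np.isnan(chi)) or np.any(np.isnan(om)):
        raise InputError("every event needs chi_e and Omega")
    vals = 1.0 - (1.0 - chi) ** om
    return float(vals.mean()), bootstrap_se(vals, n_boot=n_boot, seed=seed)


def transmission_approx(alpha_e: float, mean_omega: float) -> float:
    """Mean-field transmission alpha_G = 1 - (1 - alpha_e)^<Omega>.

    ``mean_omega`` is typically xi_0^2 (single accessible crossing, the
    dark-state default) or 1 (all product vibronic surfaces traversed).
    """
    if not 0.0 <= alpha_e <= 1.0:
        raise InputError("alpha_e must lie in [0, 1]")
    if not 0.0 < mean_omega <= 1.0:
        raise InputError("<Omega> must lie in (0, 1]")
    return 1.0 - (1.0 - alpha_e) ** mean_omega


# ---------------------------------------------------------------------------
# Gaussian (Rice) approximation and the mean-coupling route


def gaussian_rate(gap_stats: GapStatistics) -> RateEstimate:
    """Fully adiabatic attempt lifetime from Gaussian gap statistics.

    The attempt rate is the unidirectional zero-crossing rate of a
    Gaussian transition energy: k0 = <v> rho(0) / 2, with rho the
    Gaussian density centered on the reactant-ensemble mean gap.  For a
    Gaussian velocity (<|v|> = sigma_v sqrt(2/pi)) this is exactly
    Rice's level-crossing rate (sigma_v / 2 pi sigma) exp(-mu^2/2 sigma^2).
    """
    if gap_stats.mean <= 0:
        raise InputError("reactant-ensemble mean gap must be positive")
    rho0 = stats.norm.pdf(0.0, loc=gap_stats.mean, scale=gap_stats.sigma)
    k0 = gap_stats.mean_speed * rho0 / 2.0
    return RateEstimate(tau0=1.0 / k0, method="gaussian")


def crossing_rate(trace: TransitionEnergyTrace) -> float:
    """Empirical downward zero-crossing rate of a gap trace (fs^-1).

    Counts positive-to-nonpositive sign changes per unit time; the
    stationary-ensemble counterpart of the Gaussian attempt rate.
    """
    g = trace.gap
    down = int(np.count_nonzero((g[:-1] > 0) & (g[1:] <= 0)))
    return down / (trace.times[-1] - trace.times[0])


@dataclass(frozen=True)
class CouplingGeometry:
    """Equilibrium field statistics resolved along the crossing geometry.

    ``delta_mu`` is the diabatic diagonal-dipole difference mu_R0 -
    mu_P0 defining the parallel unit vector; the perpendicular unit
    vector lies in the plane of ``delta_mu`` and the mean transition
    dipole.  ``delta_eps`` is the zero-field diabatic gap (product minus
    reactant, including any 0-0 corrections), which fixes the parallel
    field component at a crossing.  ``e_perp_mean`` / ``e_perp_sq_mean``
    are the first two moments of the perpendicular field component over
    the reactant equilibrium ensemble.
    """

    delta_mu: np.ndarray             # e*nm
    mean_transition_dipole: np.ndarray  # e*nm
    delta_eps: float                 # kJ/mol
    e_perp_mean: float               # kJ mol^-1 e^-1 nm^-1
    e_perp_sq_mean: float
    eta_perp_override: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "delta_mu", np.asarray(self.delta_mu, float))
        object.__setattr__(
            self, "mean_transition_dipole",
            np.asarray(self.mean_transition_dipole, float),
        )
        if np.linalg.norm(self.delta_mu) < 1e-9:
            raise InputError(
                "diabatic dipole difference too small: crossing condition undefined"
            )
        if self.e_perp_sq_mean < self.e_perp_mean**2 - 1e-9:
            raise InputError("<E_perp^2> cannot undercut <E_perp>^2")

    @property
    def eta_par(self) -> np.ndarray:
        return self.delta_mu / np.linalg.norm(self.delta_mu)

    @property
    def eta_perp(self) -> np.ndarray:
        if self.eta_perp_override is not None:
            e = np.asarray(self.eta_perp_override, float)
            if abs(e @ self.eta_par) > 1e-12 or abs(np.linalg.norm(e) - 1) > 1e-9:
                raise InputError("eta_perp override must be a unit vector "
                                 "orthogonal to eta_par")
            return e
        par = self.eta_par
        resid = self.mean_transition_dipole - (self.mean_transition_dipole @ par) * par
        n = np.linalg.norm(resid)
        if n < 1e-12:
            # transition dipole parallel to eta_par: any orthogonal direction
            # works, the perpendicular projection of the dipole being zero
            probe = np.eye(3)[np.argmin(np.abs(par))]
            resid = probe - (probe @ par) * par
            n = np.linalg.norm(resid)
        return resid / n

    @property
    def e_par_crossing(self) -> float:
        """Parallel field component enforced by the crossing condition.

        The gap within the dipolar approximation is
        ``delta_eps + E . delta_mu``; it vanishes when
        E_par = -delta_eps / |delta_mu|.
        """
        return -self.delta_eps / float(np.linalg.norm(self.delta_mu))

    def coupling_moments(self):
        """(<H>, <H^2>) of the off-diagonal coupling -E . mu at crossings."""
        m_par = float(self.mean_transition_dipole @ self.eta_par)
        m_perp = float(self.mean_transition_dipole @ self.eta_perp)
        a = self.e_par_crossing * m_par
        mean_h = -(a + m_perp * self.e_perp_mean)
        mean_h2 = (
            a**2
            + 2.0 * a * m_perp * self.e_perp_mean
            + m_perp**2 * self.e_perp_sq_mean
        )
        return mean_h, mean_h2


def mean_coupling_alpha_e(geom: CouplingGeometry, mean_speed: float) -> float:
    """Electronic transmission from equilibrium field statistics.

    alpha_e = 1 - exp(-2 pi <|H|^2> / (hbar <v_cr>)), the crossing mean
    coupling approximation with <v_cr> taken as the reactant-ensemble
    mean gap speed.
    """
    if not mean_speed > 0:
        raise InputError("mean crossing speed must be positive")
    _, mean_h2 = geom.coupling_moments()
    return 1.0 - math.exp(-2.0 * math.pi * mean_h2 / (HBAR * mean_speed))


def reaction_lifetime(tau0: float, alpha_g: float) -> Optional[float]:
    """Reaction mean lifetime tau = tau0 / (1 - (1 - alpha_G)^2).

    Each transition-region approach offers two hop opportunities
    (inbound and outbound traversal), each succeeding with probability
    alpha_G.  Returns None (absent: infinite lifetime) when alpha_G = 0.
    """
    if not tau0 > 0:
        raise InputError("tau0 must be positive")
    if not 0.0 <= alpha_g <= 1.0:
        raise InputError("alpha_G must lie in [0, 1]")
    if alpha_g == 0.0:
        return None
    return tau0 / (1.0 - (1.0 - alpha_g) ** 2)


def bootstrap_se(values, n_boot: int = 1000, seed: Optional[int] = None) -> float:
    """Bootstrap standard error of the mean of a sample."""
    values = np.asarray(values, float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    return float(values[idx].mean(axis=1).std(ddof=1))
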