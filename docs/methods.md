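# Methods

## Unit system

Energies in kJ/mol, time in fs, length in nm, charge in e, mass in amu;
dipoles in e·nm, fields in kJ mol⁻¹ e⁻¹ nm⁻¹.  These are MD conventions
with time rescaled to fs, keeping condensed-phase transition energies
(units of 1–300 kJ/mol) and gap velocities (~1 kJ mol⁻¹ fs⁻¹)
order-one.  ħ = 63.5078 kJ mol⁻¹ fs and k_B = 8.31446×10⁻³ kJ mol⁻¹ K⁻¹.
Spontaneous-emission coefficients are evaluated in SI internally and
returned as rates in s⁻¹ / lifetimes in ns.

## Perturbed Hamiltonian

The electronic Hamiltonian over the unperturbed eigenstate basis has
diagonal elements ε_j⁰ + Σ_N q_{N,j}⁰ V(R_N) + ΔV and off-diagonal
elements −E(r₀)·μ_jl⁰.  ΔV is state-independent; it cancels in every
gap and defaults to 0, but is kept as a frame field for fidelity to the
formalism.  Mass-weighted fitting of reference geometries to MD frames
is assumed done upstream: the package consumes already-projected
potentials and fields.

Diabatic character is assigned by the maximum squared eigenvector
coefficient; a dipole-based comparison would serve equally, but the
coefficient criterion is exact in the unperturbed limit and needs no
thresholds.  Degenerate weights (within 10⁻¹²) are flagged and resolved
toward the lower unperturbed energy.  Diabatic gaps are differences of
diagonal elements plus the difference of per-state 0–0 corrections
(e.g. the −0.32 eV and −0.57 eV shifts that bring the computed
GS → L_b and GS → L_a transitions onto gas-phase experiment; no
correction exists for the dark state, whose gaps are therefore used
uncorrected).

## Franck–Condon treatment and spectra

Both electronic states share vibrational modes and frequencies; minima
differ by a mass-weighted displacement d, so the 0→n overlap of one
mode is Poissonian with Huang–Rhys factor S = ωd²/(2ħ).  Per mode the
series is truncated at cumulative probability 1−10⁻⁶; multi-mode
products are enumerated best-first on a heap, capped at 10⁶ terms.
Modes with ħω below k_BT are classical: they do not generate discrete
progressions but broaden each line, with the classical-limit width
σ_G = √(2 k_B T λ_cl), λ_cl = Σ_cl S_i ħω_i (the Marcus relation).  A
constant override is available; the plain vertical spectrum without
mode information defaults to σ_G = bin width (resolution-matched
smoothing).

Ensemble spectra histogram vertical energies into bins (default width
1 kJ/mol), average |μ|² per bin, and sum one Gaussian per bin (or per
vibronic line) weighted by the bin's frame fraction.  Emission uses the
full Einstein-A prefactor, so the absolute emission spectrum integrates
to the ensemble spontaneous-emission rate and the radiative lifetime is
its reciprocal; absorption uses the relative ν|μ|² prefactor (absolute
absorption cross-sections are not needed anywhere downstream, so their
constant is left out deliberately).

## Crossing kinetics

The gap velocity is obtained by central differences (the expected
sampling interval is 1 fs); the crossing time by linear interpolation
in the bracketing interval and the crossing speed from that interval's
slope.  Trajectories that never cross within the horizon are
right-censored in the survival estimate rather than discarded,
avoiding bias for slow channels.

Survival curves are fitted by constrained least squares to
n₁e^(−t/τ₁) + (1−n₁)e^(−t/τ₂) with positive parameters; when the two
fitted timescales agree within a factor of two the single-exponential
(nested) model is refitted instead.  τ₀ = n₁τ₁ + n₂τ₂.

The Gaussian-approximation attempt rate is k⁰ = ⟨v⟩ρ(0)/2: the flux of
downward zero-crossings of a stationary Gaussian gap with the
reactant-ensemble mean and σ, the ½ keeping the reactive direction
only.  For a Gaussian velocity (⟨|v|⟩ = σ_v√(2/π)) this equals Rice's
level-crossing rate (σ_v/2πσ)·exp(−μ²/2σ²), which the tests verify both
analytically and against seeded Langevin surrogates.  Two caveats are
inherited from the underlying model and are visible in the surrogate
experiments: (i) k⁰ is the stationary crossing rate, which matches the
mean *first*-passage time from equilibrated positive starts only when
the mean gap is at least about two standard deviations above zero —
for smaller ratios the survival-based lifetime is systematically
shorter (by ~40% at μ/σ = 0.5), which is why the explicit-sampling and
Gaussian lifetimes of the fast interconversion channel differ while the
slow dark-state channels (μ/σ ≈ 4–7) are accurately Gaussian; (ii) the
sample mean is used for the center of the Gaussian (mean = mode under
the Gaussian assumption), with a KDE-based sample mode available as a
diagnostic.

Transmission: χ_e = 1 − exp(−2π|H̄|²/(ħv_cr)) per crossing;
α_G = ⟨1 − (1−χ_e)^Ω⟩ over crossing events, or the mean-field form
1 − (1−α_e)^⟨Ω⟩ with ⟨Ω⟩ = ξ₀² when only the first product vibronic
surface is accessible (the dark-state channels) or ⟨Ω⟩ = 1 when a full
progression is traversed.  The reaction lifetime is
τ = τ₀/(1 − (1−α_G)²): an approach to the transition region crosses the
seam twice (inbound and outbound), giving two independent hop
opportunities of probability α_G.

The crossing-mean-coupling route needs no crossing sampling: with
η_∥ the unit vector along Δμ⁰ = μ_R⁰ − μ_P⁰, the dipolar-approximation
gap Δε + E·Δμ⁰ vanishes at a crossing, fixing E_∥ = −Δε/|Δμ⁰|.  With
η_⊥ the in-plane orthogonal unit vector (plane of Δμ⁰ and the mean
transition dipole μ̄; an explicit override is accepted for geometries
where μ̄ leaves that plane), the coupling second moment is
⟨H̄²⟩ = (E_∥ μ̄·η_∥)² + 2(E_∥ μ̄·η_∥)(μ̄·η_⊥)⟨E_⊥⟩ + (μ̄·η_⊥)²⟨E_⊥²⟩
from reactant-equilibrium field statistics, and
α_e = 1 − exp(−2π⟨H̄²⟩/(ħ⟨v⟩)).  Placing the ensemble average inside
one exponential is a mean-coupling approximation; it agrees with
brute-force averaging over sampled couplings to within ~10% when
couplings are weak (the regime the approximation is meant for), as the
ensemble-oracle test checks.

Bootstrap standard errors (1000 resamples, seeded) accompany all
event-sampled quantities.

## Relaxation network

ΔA for L_b → L_a defaults to the two-sided linear-response estimator
(⟨ΔU⟩_Lb + ⟨ΔU⟩_La)/2; a Gaussian-fluctuation variant averaging the two
one-sided second-order cumulant expansions is selectable when gap
variances are available.  K_eq, fractions, harmonic lifetime
combinations, τ_F and Φ follow the equations above; uncertainties
propagate to first order (delta method, central differences), with the
component standard errors taken as independent.  ISC enters only as a
user-supplied parallel rate on the nonradiative side.  Dark-state back
transitions (μs–ms) are excluded from τ_nr by default as effectively
irreversible; `master_equation_lifetime` solves the full three-state
network (interconversion from the forward lifetime plus detailed
balance, optional back rates) and returns the intensity-weighted mean
emission decay time for sensitivity checks — in the fast
pre-equilibrium limit it reproduces the mixture τ_F to ~1%.

## Synthetic surrogates

Gap traces are generated by a second-order (underdamped) Langevin
oscillator — not a plain OU process, because the kinetics need a
well-defined gap velocity.  Setting ω₀ = σ_v/σ fixes both stationary
marginals, N(μ, σ²) in position and N(0, σ_v²) in velocity; the damping
defaults to γ = ω₀ (quality factor ~1, a solvent-like correlation
structure) or follows from a requested correlation time.  Propagation
uses the exact Gaussian transition kernel of the linear system (matrix
exponential plus exact step covariance), so sampled moments carry no
step-size bias; a resolution guard requires ≥20 samples per correlation
time/oscillation period.  Default parameters sit in the regime of the
fast interconversion channel of an aqueous indole-like chromophore
(mean 3.62 kJ/mol, σ 7.1 kJ/mol, mean speed 0.4 kJ mol⁻¹ fs⁻¹, 1 fs
sampling); the slow-channel regimes (means up to ~270 kJ/mol, σ up to
40 kJ/mol, speeds up to 2.6 kJ mol⁻¹ fs⁻¹) are reached by passing the
corresponding statistics.  Reactant starts follow the block-wise
rejection protocol: the trace is cut into equal blocks and random
frames are discarded until one with positive transition energy is
found.

Fields and site potentials are exact-update OU components with a common
correlation time and arbitrary (PSD) stationary covariance.  Toy
quantum centers have neutral per-state charges, symmetric dipole
matrices and mode sets straddling the classical/quantum boundary.

What the surrogates deliberately do not emulate: real solvent spectral
densities (TIP3P hydrogen-bond librations etc.), non-Gaussian gap
statistics from conformational substates, and any correlation between
gap and coupling fluctuations.  Tests passing on surrogates therefore
validate the estimators under the model's own assumptions — Gaussian,
stationary, Markovian environment — not the assumptions themselves.

One global seed expands into independent per-stream seeds via
`numpy.random.SeedSequence`, making every pipeline stage reproducible.

## Problem sizes

Statistical tests use ensembles of 50–200 surrogate trajectories of
10–40 ps at 1 fs sampling (10⁵–10⁶ samples per check) and Monte-Carlo
samples of 2×10⁵ for ensemble-averaged couplings; these sizes keep
Monte-Carlo error a factor ≥3 below each asserted tolerance.

## Known limitations

* Duschinsky rotation and Herzberg–Teller vibronic coupling are out of
  scope (identical-mode approximation throughout).
* The absorption prefactor is relative, not an absolute cross-section.
* The survival fit assumes a single reactant kinetic state; internal
  reactant relaxation on the reaction timescale shows up as
  biexponential survival and is absorbed into τ₀ rather than modeled.
* The mean-coupling route assumes E_∥ and E_⊥ statistically
  independent and the reactant-ensemble E_⊥ distribution representative
  of the crossing ensemble.
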