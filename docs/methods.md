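# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `lvcdyn`, in the spirit of a methods appendix.

## Coordinates, units, conventions

All dynamics happens in dimensionless mass–frequency-weighted normal
coordinates: the ground-state backbone is `V0 = Σ (ω_i/2) Q_i²`, the
kinetic energy `T = Σ (ω_i/2) P_i²`, and Hamilton's equations read
`dQ_i/dt = ω_i P_i`, `dP_i/dt = −∂V/∂Q_i`. This makes the harmonic
ground-state Wigner distribution parameter-free (every mode has
`Var Q = Var P = 1/2`) and removes masses and lengths from the dynamics
entirely. Internally everything is in Hartree atomic units (ħ = 1);
cm⁻¹, eV, fs and amu are converted once, at I/O boundaries.

Cartesian inputs (gradients, NAC vectors, displacements) are projected
onto modes by mass-weighting followed by ω-scaling. Displacements
(contravariant) and derivative vectors (covariant) transform with
reciprocal factors of √ω; both directions are exposed and round-trip to
1e-10.

## The vibronic coupling model

The diabatic potential matrix is a Taylor expansion around the reference
geometry: vertical energies `E_n` and constant couplings `η_nm`
(zeroth order), per-state gradients `κ_i^(n)` and interstate couplings
`λ_i^(nm)` (first order — the LVC model), and optionally diagonal
per-state second-order coefficients `γ_i^(n)` (a restricted quadratic
extension, off by default; bilinear mode–mode couplings are not
implemented). `η` may be complex Hermitian and is the carrier for
spin–orbit coupling: each spin multiplet appears with all `2S+1`
components and constant `η` blocks couple components across
multiplicities, so intersystem crossing emerges from ordinary
adiabatic-surface dynamics on the diagonalized complex matrix.

Adiabatic quantities are analytic. With `U` the eigenvectors of `W(Q)`,
gradients are `g_a = ω·Q + [U†(∂W/∂Q)U]_aa` and NAC vectors
`h_ab = [U†(∂W/∂Q)U]_ab/(V_b − V_a)` (Hellmann–Feynman). Pairs closer
than a configurable degeneracy threshold (default 1e-8 Hartree) are
flagged and their NAC set to zero instead of dividing by a vanishing gap.
Eigenvector phases are fixed by overlap with the previous step's `U`
(identity at t = 0); degenerate blocks are rotated onto the reference via
the unitary factor of the overlap's polar decomposition, which maximizes
`Re tr(U_ref† U X)` over unitary `X`. Without a reference, the
largest-magnitude component of each column is made real positive.

Closed forms used as internal anchors: the isolated diabatic minimum
`Q_min = −κ/ω`, `E_min = E_n − Σ κ²/(2ω)`; the 2×2 eigenvalues
`(a+b)/2 ∓ √(((a−b)/2)² + c²)`.

## Parametrization

*One-shot*: `κ` are the mode-projected state gradients; `λ = ΔE·h` with
`h` the mode-projected NAC, exact for the LVC form at the reference
point; `η` from a supplied SOC matrix. Vertical energies are referenced
to the lowest selected state. Modes below 50 cm⁻¹ (configurable) are
excluded with a warning — nearly-free torsions are badly harmonic and are
the classic source of spuriously displaced minima.

*Finite differences*: given pre-diabatized matrices `W(±δ e_i)` (default
step δ = 0.05), central differences recover `κ` and `λ` exactly for
linear potentials; quadratic contamination cancels identically. The
construction consumes `2f` displaced evaluations and reports that count.
Wave-function-overlap diabatization itself is out of scope; the package
accepts its output.

## Surface hopping

Each nuclear step (velocity Verlet, default `dt = 0.5 fs`) is followed by
electronic propagation with 25 substeps (default): the effective
adiabatic Hamiltonian `H = diag(V) − i σ`, `σ_ab = h_ab·Q̇`, is Hermitian
(σ is anti-Hermitian), linearly interpolated across the step, and each
substep applies the exact unitary `exp(−iH dτ)` from an
eigendecomposition, so the coefficient norm is preserved to round-off. A
local-diabatization variant propagates under `W(Q(t)) + V0` along the
interpolated path and transforms with the endpoint eigenvector matrices;
it is preferable when the NAC is a near-delta spike between two nuclear
steps.

Hopping uses the propagator-based fewest-switches probability: the total
leaving probability `1 − |c_a(t+dt)|²/|c_a(t)|²` is distributed over
targets in proportion to the population flux
`Re[c_b(t+dt)(A_ba c_a(t))*]`, with negative contributions clamped to
zero. Because `A` is unitary the unclamped fluxes sum exactly to the
survival deficit, which the test suite asserts as an identity.

The protocol matrix:

* **Momentum rescaling.** `p`: nothing (total energy jumps by ΔV);
  `E`: uniform rescaling; `Ep_g`/`Ep_h`: solve the quadratic for a shift
  along the gradient-difference or NAC direction, choosing the
  smaller-|β| root, conserving energy to 1e-10 and leaving orthogonal
  components untouched. No real root → the hop is frustrated. A
  zero-length direction falls back to uniform rescaling with a warning.
* **Frustrated hops.** `+`: nothing. `−`: the momentum component along
  the direction (NAC for `p`/`E`/`Ep_h`, gradient difference for `Ep_g`)
  is reflected in the kinetic-energy metric — preserving T exactly —
  but only when the target-surface force opposes the momentum projection
  (product-of-projections rule; the literature states only "under
  certain conditions", so the criterion is logged per event).
* **Decoherence.** `none`; `edc`: non-active amplitudes damped with
  `τ_b = (1/|ΔV|)(1 + C/E_kin)`, C = 0.1 Hartree default, active
  amplitude renormalized, damping skipped at zero kinetic energy or zero
  gap; `afssh`: per-surface auxiliary position/momentum moments driven by
  the population-weighted force difference, with stochastic collapse at
  rate `(ΔF·δR)/2 − 2|F_na·δR|` and moment reset at rate `−(ΔF·δR)/2`
  (clamped at zero), moments zeroed on hops and collapses. This is the
  independent-trajectory moment formulation of augmented FSSH; the
  collapse-rate sign conventions follow the moment-growth picture
  (collapse when the auxiliary packets separate).

Presets: `full` enumerates the 3×4×2 = 24 factorial; `benchmark` is a
curated 13-member subset (all decoherence flavors crossed with the
physically distinct rescaling/reflection choices, dropping reflection
variants that cannot trigger for momentum-conserving hops).

Per-trajectory RNG streams derive from (master seed, trajectory index)
via a seed sequence, so ensembles are bit-reproducible and invariant
under execution order and chunking; merging disjoint sub-ensembles is
exact concatenation.

### Integrator accuracy

Velocity Verlet is symplectic: energy error is a bounded oscillation of
relative amplitude ≈ (ω dt)²/8 with no secular drift. At the default
0.5 fs this meets 1e-6 Hartree over 10⁴ steps for modes up to a few
hundred cm⁻¹ (the regime the default targets); stiffer modes need a
proportionally smaller step. Near narrowly avoided crossings the local
curvature of the adiabatic surface is much larger than any ω, so
transient energy oscillations there exceed the harmonic estimate; hops
themselves conserve energy exactly under the E/Ep schemes.

## Exact grid oracle

A split-operator propagator (Strang: half potential, full kinetic via
FFT, half potential) on a tensor grid of up to 2 modes and 8 states. The
potential matrix is time-independent, so its half-step propagators are
precomputed per grid point from an eigendecomposition; propagation is
unitary to round-off and norm drift beyond 1e-8 aborts with
grid-refinement advice. Adiabatic populations are measured by rotating
the grid amplitudes with the pointwise eigenvectors.

Numerical caveats established while validating: the splitting error
scales as `(dt·k_max)²` — refining the spatial grid at fixed `dt`
*raises* the energy drift because the maximum momentum doubles — and an
undersized box lets the exponential tunneling tail wrap around the
periodic boundary, biasing populations at the 1e-5 level long before the
norm shows anything. `auto_grid` therefore uses a 10-unit margin beyond
all diabatic minima by default. With 256 points, margin 10 and
dt = 0.005–0.05 fs the oracle passes its analytic anchors: two-level Rabi
populations `cos²(ηt)` to 1e-6 (nuclear motion factorizes when the
diagonal potentials are identical) and the coherent-state revival
`|⟨ψ(0)|ψ(2π/ω)⟩| = 1` to 1e-4.

## Analysis

* **Diabatic populations** from SH ensembles: the *active-projector*
  estimator `⟨|U_{n,a}|²⟩` (default) and the *coefficient* estimator
  `⟨|(Uc)_n|²⟩` are both provided — they answer slightly different
  questions (ensemble character of the occupied surfaces vs the coherent
  electronic wave function) and bracket the ambiguity in comparing SH to
  QD. Both sum to one by unitarity.
* **Wigner DOS diagnostic**: adiabatic energies over the ground-state
  Wigner cloud, grouped by each adiabat's *dominant diabatic character* —
  not by energy order, because a spuriously displaced state dives below
  the true ground state and becomes the lowest eigenvalue, where sorted
  indexing would hide it. Samples with an excited-character adiabat below
  the reference energy are flagged; they mark artificial population traps.
* **Mode importance**: the plain coupling sum
  `Σ_n |κ_i^(n)| + Σ_{n<m} |λ_i^(nm)|` per mode (used for reduction
  ranking), plus the ω-weighted reorganization energy `κ²/2ω` per
  (state, mode), which is the quantity that actually controls spurious
  low-energy minima.
* **Model reduction** deletes mode slices and state blocks; spin
  multiplets are removed atomically. Evaluating a reduced model on the
  kept coordinates equals evaluating the parent with removed coordinates
  pinned at zero — removing a fully uncoupled mode that is also excluded
  from sampling reproduces trajectories to machine precision.
* **Kinetic fits**: first-order networks `P(t) = expm(Kt)P(0)` fitted by
  bounded least squares (rates ≥ 0) over all states and frames jointly;
  covariance from the Gauss–Newton normal matrix, with a warning when the
  topology is ill-identified. Exponential decay times via `curve_fit`
  with standard errors; flat traces are flagged divergent rather than
  filled.

## Synthetic models

`generate_fixture` draws spin-boson-like models: frequencies uniform in
300–1700 cm⁻¹, vertical energies in 0.08–0.20 Hartree, Gaussian κ
(scale 0.005) and λ (scale 0.002, same-spin same-M_S pairs only),
complex Hermitian spin–orbit η between multiplicities (scale 100 cm⁻¹) —
magnitudes typical of medium-sized chromophores. Multiplet components
share E and κ (the spin-free part of the Hamiltonian). By default κ is
shrunk per state so every diabatic minimum stays ≥ 0.01 Hartree above the
reference; the `pathological` variant instead tilts the last multiplet so
its diabat turns negative already at a 1.5σ Wigner displacement,
guaranteeing the DOS diagnostic has something to find.

The SH-vs-QD benchmark (`avoided_crossing_model`) is a one-mode,
two-state avoided crossing (ω = 0.005, E = (0, 0.02), κ = (0.005, −0.01),
λ = 0.005 Hartree) passed moderately adiabatically — the regime
fewest-switches hopping is built for, where the best protocols
(AFSSH with NAC-direction rescaling) reproduce the exact final branching
to a few 0.01. At much weaker coupling the 1-D dynamics becomes
interference-dominated recrossing and independent trajectories
systematically overestimate coherence; the hop machinery itself is
validated separately against the closed-form Landau–Zener single-passage
probability (agreement to three digits), so that deviation is a real,
known SH limitation, not an implementation artifact.

## What the synthetic tests do and do not show

The generator emulates harmonic diabatic surfaces with linear couplings —
exactly the regime where the LVC ansatz is valid. Passing tests therefore
demonstrate correctness of the machinery (sampling, propagation, hopping,
analysis) and internal consistency between SH and exact dynamics on
*identical* potentials. They say nothing about anharmonicity, torsions or
dissociation (outside the VC form by construction), about the quality of
any particular ab initio parametrization, or about SH accuracy in the
weak-coupling interference regime noted above.

## Problem sizes

Default test and acceptance workloads: 10⁴ random 2×2 adiabatizations;
3-state/4-mode derivative checks; 10⁵ Wigner samples; 10⁴-step
conservation runs; 200-trajectory two-mode ensembles; 2000 trajectories ×
150 fs for the SH-vs-QD benchmark against a 256-point grid reference;
3000-sample DOS scans. These sizes give stochastic errors comfortably
below the tolerances they are tested against (e.g. binomial error
≈ 0.011 at n = 2000 versus a 0.1 population tolerance).
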