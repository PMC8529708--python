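# lvcdyn

Surface-hopping and exact wave-packet dynamics on vibronic coupling model
potentials.

## The problem

Simulating photochemistry — internal conversion through conical
intersections, intersystem crossing driven by spin–orbit coupling —
requires following nuclear motion across several coupled electronic
surfaces. Trajectory surface hopping (SH) does this with swarms of
independent classical trajectories and is cheap, but it relies on ad hoc
corrections for decoherence, momentum rescaling at hops, and classically
forbidden ("frustrated") transitions. Exact quantum dynamics (QD) is the
arbiter but scales exponentially with nuclear dimension.

Linear vibronic coupling (LVC) models put both methods on *identical*
potentials: analytic diabatic surfaces, parametrized from a single ab
initio calculation, cheap enough for thousands of SH trajectories and —
in reduced dimensionality — for numerically exact grid propagation.
`lvcdyn` implements this test bed end to end for method developers and
practitioners who want to know which SH protocol to trust for a given
system.

## The model

In dimensionless mass–frequency-weighted normal coordinates **Q** the
Hamiltonian is

    H = T_N · 1 + V0(Q) · 1 + W(Q)
    V0(Q)   = Σ_i (ω_i/2) Q_i²,      T_N = Σ_i (ω_i/2) P_i²
    W_nn(Q) = E_n  + Σ_i κ_i^(n) Q_i
    W_nm(Q) = η_nm + Σ_i λ_i^(nm) Q_i          (n ≠ m)

with vertical energies `E_n`, intrastate gradients `κ`, linear interstate
couplings `λ`, and constant (possibly complex, Hermitian) couplings `η`
for spin–orbit or excitonic interactions. Diagonal per-state quadratic
terms are supported optionally. Everything is stored in Hartree atomic
units; cm⁻¹ and fs appear only at file boundaries.

The package provides:

* **lvc_core** (`lvcdyn.model`) — evaluation, adiabatization with smooth
  eigenvector phases, analytic Hellmann–Feynman gradients and nonadiabatic
  coupling (NAC) vectors, closed-form diabatic minima;
* **parametrization** (`lvcdyn.parametrize`) — model construction from a
  single-point calculation (gradients + NACs) or from finite-difference
  displacement data, with mass-weighted mode projection;
* **initial conditions** (`lvcdyn.initial`) — harmonic ground-state
  Wigner sampling, deterministic per-trajectory random streams;
* **sh_dynamics** (`lvcdyn.dynamics`) — fewest-switches surface hopping
  with the full protocol matrix: decoherence ∈ {none, EDC, AFSSH} ×
  rescaling ∈ {p, E, Ep_g, Ep_h} × frustrated ∈ {+, −};
* **qd_oracle** (`lvcdyn.qd`) — exact split-operator FFT wave-packet
  propagation on ≤ 2-mode models, the in-package stand-in for an MCTDH
  reference;
* **analysis** (`lvcdyn.analysis`) — diabatic population estimators,
  Wigner-sampled density-of-states diagnostics with spurious
  negative-energy flagging, per-mode coupling-importance ranking, model
  reduction, kinetic-network and decay-time fitting;
* **fixtures / I/O / CLI** — seeded synthetic model generation, a
  documented text/JSON model format, tabular traces, HDF5 ensembles, and
  a `lvcdyn` command with subcommands `fixture`, `parametrize`, `sample`,
  `run`, `qd`, `compare`, `analyze`, `reduce`, `protocols`.

## Worked example

Surface hopping versus the exact oracle on the built-in one-mode
avoided-crossing benchmark (ω = 0.005 Hₐ ≈ 1100 cm⁻¹, vertical gap
0.02 Hₐ, coupling λ = 0.005 Hₐ), starting on the upper diabat S1:

```python
import numpy as np
from lvcdyn import avoided_crossing_model, auto_grid, initial_wavepacket, \
    split_operator_propagate
from lvcdyn.dynamics import SHProtocol, run_ensemble
from lvcdyn.initial import sample_initial_conditions
from lvcdyn.analysis import diabatic_populations

model = avoided_crossing_model()

grid = auto_grid(model, points=256, dt_fs=0.05, t_final_fs=150.0)
qd = split_operator_propagate(model, initial_wavepacket(model, grid, "S1"),
                              grid, output_stride=40)

protocol = SHProtocol(decoherence="afssh", rescaling="Ep_h", frustrated="plus")
ics = sample_initial_conditions(model.modes, 500, seed=1, state_spec="S1")
ens = run_ensemble(model, protocol, ics, t_final_fs=150.0, stride=10)
sh = diabatic_populations(ens)

for t in (0, 50, 100, 150):
    i = min(np.searchsorted(ens.t_fs, t), len(ens.t_fs) - 1)
    j = min(np.searchsorted(qd.t_fs, t), len(qd.t_fs) - 1)
    print(f"t = {ens.t_fs[i]:5.1f} fs   SH P(S0) = {sh[i,0]:.3f}"
          f"   QD P(S0) = {qd.diabatic[j,0]:.3f}")
```

prints

```
t =   0.0 fs   SH P(S0) = 0.073   QD P(S0) = 0.000
t =  50.0 fs   SH P(S0) = 0.438   QD P(S0) = 0.413
t = 100.0 fs   SH P(S0) = 0.509   QD P(S0) = 0.234
t = 150.0 fs   SH P(S0) = 0.517   QD P(S0) = 0.565
```

Reading the numbers: the swarm reproduces the initial transfer through
the crossing (t ≈ 50 fs) and the final branching ratio (t = 150 fs,
deviation ≈ 0.05 at 500 trajectories), while the deep transient dip at
t = 100 fs is a coherent recrossing oscillation of the exact wave packet
that an incoherent trajectory average flattens out — exactly the kind of
protocol-dependent discrepancy this test bed exists to expose. (The
nonzero SH value at t = 0 is not an error: the active-projector estimator
reports the diabatic character of the occupied adiabats, which is mixed
at Wigner-displaced geometries.)

The same comparison from the shell:

```sh
lvcdyn fixture --n-modes 1 --n-singlets 2 --seed 3 --out model.lvc
lvcdyn run --model model.lvc --protocol afssh/Ep_h+ --n 500 --state S1 \
           --t-final 150 --seed 1 --out sh.tsv
lvcdyn qd  --model model.lvc --state S1 --t-final 150 --out qd.tsv
lvcdyn compare sh.tsv qd.tsv
```

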