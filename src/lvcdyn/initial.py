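"""Initial-condition sampling for trajectory ensembles.

Nuclear phase-space points are drawn from the Wigner distribution of the
harmonic vibrational ground state.  In dimensionless mass-frequency-
weighted coordinates that distribution is a product of independent
Gaussians with Var(Q_i) = Var(P_i) = 1/2 per mode, independent of the
frequency, so sampling is parameter-free; only the zero-point energy
sum_i omega_i/2 depends on the mode spectrum.

Per-trajectory random streams are derived from the master seed and the
trajectory index with a seed sequence, so ensembles are reproducible
independent of execution order or chunking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LVCModel, ModeSet, adiabatic_point

__all__ = ["InitialCondition", "wigner_sample", "sample_initial_conditions",
           "assign_initial_state", "ics_to_table", "ics_from_table"]


@dataclass(frozen=True)
class InitialCondition:
    index: int
    Q: np.ndarray
    P: np.ndarray
    state_spec: str | int  # diabatic label (str) or adiabatic index (int)
    seed: tuple[int, ...]  # entropy used for this trajectory's RNG stream

    def __post_init__(self):
        if not (np.all(np.isfinite(self.Q)) and np.all(np.isfinite(self.P))):
            raise ValueError("initial condition contains non-finite entries")


def wigner_sample(modes: ModeSet, n: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw n (Q, P) pairs from the ground-state Wigner distribution."""
    if n < 1:
        raise ValueError("sample count must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(0.5)
    Q = rng.normal(0.0, sigma, size=(n, modes.count))
    P = rng.normal(0.0, sigma, size=(n, modes.count))
    return [(Q[i], P[i]) for i in range(n)]


def sample_initial_conditions(modes: ModeSet, n: int, seed: int,
                              state_spec: str | int) -> list[InitialCondition]:
    """Wigner-sample an ensemble, recording a per-trajectory RNG seed."""
    pairs = wigner_sample(modes, n, seed)
    return [
        InitialCondition(index=i, Q=q, P=p, state_spec=state_spec,
                         seed=(int(seed), int(i)))
        for i, (q, p) in enumerate(pairs)
    ]


def assign_initial_state(model: LVCModel, ic: InitialCondition,
                         rng: np.random.Generator
                         ) -> tuple[int, np.ndarray, np.ndarray]:
    """Initial active surface and electronic coefficients for one trajectory.

    An adiabatic spec (integer k) puts the trajectory on surface k with a
    unit coefficient.  A diabatic spec (state label) expresses that
    diabatic unit vector in the adiabatic basis at the sampled geometry,
    c_a = U*_{na}, and draws the active surface stochastically with
    probability |U_{na}|^2.

    Returns (active_surface, coefficients, U) with U the diabatic-to-
    adiabatic transformation at Q.
    """
    pt = adiabatic_point(model, ic.Q, derivatives=False)
    n = model.n_states
    spec = ic.state_spec
    if isinstance(spec, (int, np.integer)):
        k = int(spec)
        if not 0 <= k < n:
            raise ValueError(f"adiabatic index {k} out of range 0..{n - 1}")
        c = np.zeros(n, dtype=complex)
        c[k] = 1.0
        return k, c, pt.U
    idx = model.basis.index(str(spec))
    c = pt.U[idx, :].conj()  # components of diabatic |idx> on the adiabats
    probs = np.abs(c) ** 2
    probs = probs / probs.sum()
    active = int(rng.choice(n, p=probs))
    return active, c, pt.U


def ics_to_table(ics: list[InitialCondition]) -> "np.ndarray":
    """Serialize initial conditions to a structured text table (str rows)."""
    import pandas as pd

    f = ics[0].Q.size
    rows = []
    for ic in ics:
        row = {"index": ic.index, "seed": ":".join(map(str, ic.seed)),
               "state": str(ic.state_spec)}
        for i in range(f):
            row[f"Q{i + 1}"] = ic.Q[i]
            row[f"P{i + 1}"] = ic.P[i]
        rows.append(row)
    return pd.DataFrame(rows)


def ics_from_table(df) -> list[InitialCondition]:
    qcols = sorted((c for c in df.columns if c.startswith("Q")),
                   key=lambda c: int(c[1:]))
    pcols = sorted((c for c in df.columns if c.startswith("P")),
                   key=lambda c: int(c[1:]))
    out = []
    for _, row in df.iterrows():
        spec: str | int = row["state"]
        try:
            spec = int(spec)
        except (TypeError, ValueError):
            pass
        out.append(InitialCondition(
            index=int(row["index"]),
            Q=np.array([row[c] for c in qcols], float),
            P=np.array([row[c] for c in pcols], float),
            state_spec=spec,
            seed=tuple(int(x) for x in str(row["seed"]).split(":")),
        ))
    return out
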