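"""Synthetic vibronic-coupling model generation.

Random spin-boson-like models with tunable dimension and coupling
strengths stand in for quantum-chemistry parametrizations in tests and
benchmarks.  Generation is fully deterministic for a fixed seed.  By
default every diabatic minimum stays above the ground-state reference
energy (no spurious negative-energy states); the ``pathological`` variant
deliberately gives one excited state a reorganization energy exceeding
its vertical energy, the situation that produces spurious low-energy
states in density-of-states diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .model import BasisSpec, LVCModel, ModeSet, ModelValidationError, diabatic_minimum

__all__ = ["FixtureSpec", "generate_fixture", "avoided_crossing_model", "rabi_model"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a random LVC model.

    ``multiplets`` lists (name, spin, count) entries, e.g.
    ``[("S", 0.0, 3), ("T", 1.0, 1)]`` for three singlets and one triplet;
    the first generated state is a ground state with zero kappa.  Scales
    are Hartree; frequencies are drawn uniformly from ``freq_range_cm1``.
    """

    n_modes: int = 3
    multiplets: tuple = (("S", 0.0, 3),)
    freq_range_cm1: tuple[float, float] = (300.0, 1700.0)
    e_range: tuple[float, float] = (0.08, 0.20)
    kappa_scale: float = 0.005
    lambda_scale: float = 0.002
    lambda_sparsity: float = 0.0  # fraction of same-spin pairs with zero lambda
    soc_scale_cm1: float = 100.0
    seed: int = 0
    pathological: bool = False
    min_gap_to_zero: float = 0.01  # Hartree margin kept above the reference

    def __post_init__(self):
        if self.n_modes < 1:
            raise ModelValidationError("n_modes must be >= 1")
        total = sum(int(round(2 * s + 1)) * c for _, s, c in self.multiplets)
        if total < 1:
            raise ModelValidationError("at least one electronic state required")
        for name, scale in [
            ("kappa_scale", self.kappa_scale),
            ("lambda_scale", self.lambda_scale),
            ("soc_scale_cm1", self.soc_scale_cm1),
        ]:
            if scale < 0:
                raise ModelValidationError(f"{name} must be >= 0")


def generate_fixture(spec: FixtureSpec) -> LVCModel:
    """Draw a random LVC model according to ``spec`` (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    f = spec.n_modes
    freqs_cm1 = rng.uniform(*spec.freq_range_cm1, size=f)
    modes = ModeSet(frequencies=units.cm1_to_hartree(np.sort(freqs_cm1)))

    triples = []
    for name, spin, count in spec.multiplets:
        for k in range(count):
            triples.append((f"{name}{k}", float(spin), name))
    basis = BasisSpec.from_multiplets(triples)
    n = len(basis)

    E = np.empty(n)
    kappa = np.zeros((n, f))
    # multiplet components share E and kappa (spin-free Hamiltonian part)
    mult_E: dict[str, float] = {}
    mult_kappa: dict[str, np.ndarray] = {}
    first = basis.multiplet_names[0]
    for name in basis.multiplet_names:
        if name == first:
            mult_E[name] = 0.0
            mult_kappa[name] = np.zeros(f)
        else:
            mult_E[name] = float(rng.uniform(*spec.e_range))
            mult_kappa[name] = rng.normal(0.0, spec.kappa_scale, size=f)
    for i, s in enumerate(basis.states):
        E[i] = mult_E[s.multiplet]
        kappa[i] = mult_kappa[s.multiplet]

    lam = np.zeros((n, n, f))
    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = basis.states[a], basis.states[b]
            same_mult = sa.multiplet == sb.multiplet
            if sa.spin != sb.spin or sa.ms != sb.ms or same_mult:
                continue
            if rng.random() < spec.lambda_sparsity:
                continue
            v = rng.normal(0.0, spec.lambda_scale, size=f)
            lam[a, b] = v
            lam[b, a] = v

    eta = np.zeros((n, n), dtype=complex)
    soc = spec.soc_scale_cm1 * units.CM1_TO_HARTREE
    if soc > 0:
        for a in range(n):
            for b in range(a + 1, n):
                sa, sb = basis.states[a], basis.states[b]
                if sa.spin == sb.spin:
                    continue
                z = rng.normal(0.0, soc) + 1j * rng.normal(0.0, soc)
                eta[a, b] = z
                eta[b, a] = z.conjugate()

    model = LVCModel(modes=modes, basis=basis, E=E, eta=eta, kappa=kappa, lam=lam)

    # enforce (or break) the positivity of excited diabatic minima
    for name in basis.multiplet_names[1:]:
        idx = basis.multiplet_indices(name)[0]
        _, e_min = diabatic_minimum(model, idx)
        reorg = model.E[idx] - e_min
        target_floor = spec.min_gap_to_zero
        if not spec.pathological and e_min < target_floor and reorg > 0:
            # shrink kappa so E_min = target_floor
            scale = np.sqrt(max(model.E[idx] - target_floor, 0.0) / reorg)
            for i in basis.multiplet_indices(name):
                kappa[i] *= scale
            model = model.with_(kappa=kappa)
    if spec.pathological:
        # Tilt the last multiplet so its diabat already turns negative at a
        # 1.5-sigma Wigner displacement (sigma_Q = 1/sqrt(2) per mode): the
        # spurious below-reference region then overlaps the sampled cloud
        # instead of hiding at an unreachable displaced minimum.
        name = basis.multiplet_names[-1]
        idx = basis.multiplet_indices(name)[0]
        if np.linalg.norm(kappa[idx]) < 1e-12:
            kappa[basis.multiplet_indices(name), :] = spec.kappa_scale or 0.005
            model = model.with_(kappa=kappa)
        khat = kappa[idx] / np.linalg.norm(kappa[idx])
        s0 = 1.5 * np.sqrt(0.5)
        curv = float(model.omega @ khat ** 2)  # V0 curvature along khat
        needed = (1.5 * model.E[idx] + 0.5 * curv * s0 ** 2) / s0
        scale = needed / np.linalg.norm(kappa[idx])
        for i in basis.multiplet_indices(name):
            kappa[i] *= scale
        model = model.with_(kappa=kappa)
        _, e_min = diabatic_minimum(model, idx)
        assert e_min < 0.0
    return model


def avoided_crossing_model() -> LVCModel:
    """One-mode, two-state avoided-crossing benchmark model.

    A bright displaced diabat (S1) crosses the flat ground diabat along a
    ~1100 cm^-1 mode with a moderate constant-gradient coupling; starting
    a wave packet (or trajectory swarm) vertically on S1 produces partial,
    oscillatory population transfer.  The coupling is strong enough that
    the crossing is passed moderately adiabatically — the regime fewest-
    switches surface hopping is built for; far weaker couplings turn the
    1-D dynamics into interference-dominated recrossing, where independent
    trajectories are known to overestimate coherence.
    """
    modes = ModeSet(frequencies=np.array([0.005]))
    basis = BasisSpec.singlets(2)
    E = np.array([0.0, 0.02])
    kappa = np.array([[0.005], [-0.01]])
    lam = np.zeros((2, 2, 1))
    lam[0, 1, 0] = lam[1, 0, 0] = 0.005
    return LVCModel(modes=modes, basis=basis, E=E, kappa=kappa, lam=lam)


def two_mode_crossing_model() -> LVCModel:
    """Two-state avoided crossing over two low-frequency modes.

    Frequencies of roughly 100 and 200 cm^-1 (typical skeletal motions)
    keep the 0.5 fs default time step well inside its accuracy range, and
    both modes carry gradients and couplings so hops exchange energy with
    a genuinely multidimensional bath.
    """
    modes = ModeSet(frequencies=np.array([4.5e-4, 9.0e-4]))
    basis = BasisSpec.singlets(2)
    E = np.array([0.0, 0.008])
    kappa = np.array([[0.0008, 0.0012], [-0.0015, -0.002]])
    lam = np.zeros((2, 2, 2))
    lam[0, 1] = lam[1, 0] = (0.0012, 0.0008)
    return LVCModel(modes=modes, basis=basis, E=E, kappa=kappa, lam=lam)


def rabi_model(eta: float = 0.002, omega: float = 0.005,
               kappa: float = 0.0) -> LVCModel:
    """Two degenerate states with a constant coupling (Rabi limit).

    With identical diagonal potentials the nuclear motion factorizes and
    the diabatic populations oscillate as cos^2(eta * t) exactly.
    """
    modes = ModeSet(frequencies=np.array([omega]))
    basis = BasisSpec.singlets(2)
    eta_m = np.array([[0.0, eta], [eta, 0.0]], dtype=complex)
    kap = np.array([[kappa], [kappa]])
    return LVCModel(modes=modes, basis=basis, E=np.zeros(2), eta=eta_m, kappa=kap,
                    lam=np.zeros((2, 2, 1)))
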