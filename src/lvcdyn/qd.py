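"""Exact grid wave-packet propagation for small vibronic coupling models.

A split-operator (Strang) propagator on a tensor-product coordinate grid,
limited to at most two modes and eight electronic states.  The kinetic
step sum_i (omega_i/2) P_i^2 is applied in Fourier space; the potential
step exponentiates the full diabatic matrix W(Q) + V0(Q) pointwise on the
grid.  Because the potential matrix is time-independent, its half-step
propagators are precomputed once from an eigendecomposition per grid
point, making the propagation exactly unitary up to round-off.

This module serves as the quantum-dynamics reference that trajectory
surface hopping is validated against on identical potentials, playing the
role a full MCTDH treatment plays for larger models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .model import LVCModel, evaluate_potential, adiabatize, diabatic_minimum

__all__ = ["GridSpec", "WavePacket", "PopulationTraces", "auto_grid",
           "initial_wavepacket", "split_operator_propagate", "compare_sh_qd",
           "ComparisonMetrics"]

MAX_MODES = 2
MAX_STATES = 8


@dataclass(frozen=True)
class GridSpec:
    """Uniform coordinate grid and time discretization for the oracle."""

    points: tuple[int, ...]  # per-mode grid sizes (powers of two)
    q_min: tuple[float, ...]
    q_max: tuple[float, ...]
    dt_fs: float = 0.1
    t_final_fs: float = 100.0

    def __post_init__(self):
        if not 1 <= len(self.points) <= MAX_MODES:
            raise ValueError(f"grid supports 1..{MAX_MODES} modes")
        for npt in self.points:
            if npt < 32 or npt & (npt - 1):
                raise ValueError("grid sizes must be powers of two >= 32")
        if len(self.q_min) != len(self.points) or len(self.q_max) != len(self.points):
            raise ValueError("q_min/q_max must match the number of modes")
        for lo, hi in zip(self.q_min, self.q_max):
            if hi <= lo:
                raise ValueError("q_max must exceed q_min")
        if self.dt_fs <= 0 or self.t_final_fs <= 0:
            raise ValueError("time parameters must be positive")

    def axes(self) -> list[np.ndarray]:
        return [np.linspace(lo, hi, npt, endpoint=False)
                for lo, hi, npt in zip(self.q_min, self.q_max, self.points)]

    def momenta(self) -> list[np.ndarray]:
        out = []
        for lo, hi, npt in zip(self.q_min, self.q_max, self.points):
            dq = (hi - lo) / npt
            out.append(2.0 * np.pi * np.fft.fftfreq(npt, d=dq))
        return out

    @property
    def weight(self) -> float:
        """Quadrature weight (volume element) of one grid cell."""
        w = 1.0
        for lo, hi, npt in zip(self.q_min, self.q_max, self.points):
            w *= (hi - lo) / npt
        return w


def auto_grid(model: LVCModel, points: int = 256, margin: float = 10.0,
              dt_fs: float = 0.1, t_final_fs: float = 100.0) -> GridSpec:
    """Grid covering all diabatic minima plus a generous turning-point margin.

    The margin must exceed the classical turning amplitude on every surface
    by several units: an under-sized box lets the exponential tunneling
    tail wrap around the periodic boundary and contaminates populations
    long before the norm shows any drift.
    """
    if model.n_modes > MAX_MODES:
        raise ValueError(f"oracle limited to {MAX_MODES} modes")
    centers = np.stack([diabatic_minimum(model, n)[0]
                        for n in range(model.n_states)])
    lo = tuple(float(np.min(centers[:, i]) - margin) for i in range(model.n_modes))
    hi = tuple(float(np.max(centers[:, i]) + margin) for i in range(model.n_modes))
    return GridSpec(points=(points,) * model.n_modes, q_min=lo, q_max=hi,
                    dt_fs=dt_fs, t_final_fs=t_final_fs)


@dataclass
class WavePacket:
    """Complex grid amplitudes per diabatic state."""

    grid: GridSpec
    psi: np.ndarray  # (n_states, *points)
    t_fs: float = 0.0

    @property
    def norm(self) -> float:
        return float(np.sqrt(np.sum(np.abs(self.psi) ** 2) * self.grid.weight))

    def populations(self) -> np.ndarray:
        axes = tuple(range(1, self.psi.ndim))
        return np.sum(np.abs(self.psi) ** 2, axis=axes) * self.grid.weight


@dataclass
class PopulationTraces:
    t_fs: np.ndarray
    diabatic: np.ndarray  # (frames, n)
    adiabatic: np.ndarray  # (frames, n)
    norm: np.ndarray
    energy: np.ndarray
    autocorrelation: np.ndarray  # complex overlap with the initial packet


def initial_wavepacket(model: LVCModel, grid: GridSpec,
                       state: str | int) -> WavePacket:
    """Ground-state Gaussian of V0 placed on one diabatic state.

    In dimensionless coordinates the vibrational ground state has
    sigma_Q = 1/sqrt(2) per mode regardless of frequency.
    """
    if model.n_modes > MAX_MODES:
        raise ValueError(f"oracle limited to {MAX_MODES} modes")
    if model.n_states > MAX_STATES:
        raise ValueError(f"oracle limited to {MAX_STATES} states")
    idx = state if isinstance(state, (int, np.integer)) else model.basis.index(state)
    axes = grid.axes()
    gauss = [np.exp(-0.5 * q ** 2) / np.pi ** 0.25 for q in axes]
    if len(axes) == 1:
        packet = gauss[0]
    else:
        packet = np.multiply.outer(gauss[0], gauss[1])
    psi = np.zeros((model.n_states, *packet.shape), dtype=complex)
    psi[int(idx)] = packet
    wp = WavePacket(grid=grid, psi=psi)
    wp.psi /= wp.norm
    return wp


def _potential_propagators(model: LVCModel, grid: GridSpec, dt_half: float
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-grid-point exp(-i (W + V0) dt/2), U(Q) and V(Q) arrays."""
    axes = grid.axes()
    if len(axes) == 1:
        Qs = axes[0][:, None]
    else:
        g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
        Qs = np.column_stack([g0.ravel(), g1.ravel()])
    npts = Qs.shape[0]
    n = model.n_states
    W = np.empty((npts, n, n), dtype=complex)
    V0s = np.empty(npts)
    for j in range(npts):
        V0, Wj = evaluate_potential(model, Qs[j])
        W[j] = Wj + V0 * np.eye(n)
        V0s[j] = V0
    ev, Uv = np.linalg.eigh(W)  # batched
    phase = np.exp(-1j * ev * dt_half)
    prop = np.einsum("jab,jb,jcb->jac", Uv, phase, Uv.conj())
    return prop, Uv, ev


def split_operator_propagate(model: LVCModel, wp: WavePacket, grid: GridSpec,
                             output_stride: int = 1) -> PopulationTraces:
    """Propagate with second-order Strang splitting; returns populations.

    Aborts (with grid-refinement advice) if the norm drifts by more than
    1e-8 — the sign of a box too small or a step too large.
    """
    dt = units.fs_to_au(grid.dt_fs)
    n_steps = int(round(grid.t_final_fs / grid.dt_fs))
    n = model.n_states
    shape = wp.psi.shape[1:]
    npts = int(np.prod(shape))

    prop_half, Uv, ev_tot = _potential_propagators(model, grid, dt / 2.0)
    ks = grid.momenta()
    if len(ks) == 1:
        t_kin = 0.5 * model.omega[0] * ks[0] ** 2
    else:
        t_kin = (0.5 * model.omega[0] * ks[0][:, None] ** 2
                 + 0.5 * model.omega[1] * ks[1][None, :] ** 2)
    kin_phase = np.exp(-1j * t_kin * dt)

    psi = wp.psi.copy()
    psi0 = psi.copy()
    w_quad = grid.weight

    frames = list(range(0, n_steps + 1, output_stride))
    if frames[-1] != n_steps:
        frames.append(n_steps)
    t_out = np.array([k * grid.dt_fs for k in frames])
    dia = np.zeros((len(frames), n))
    adia = np.zeros((len(frames), n))
    norms = np.zeros(len(frames))
    energy = np.zeros(len(frames))
    auto = np.zeros(len(frames), dtype=complex)

    fft_axes = tuple(range(1, psi.ndim))

    def apply_V(p, flat_prop):
        flat = p.reshape(n, npts)
        return np.einsum("jab,bj->aj", flat_prop, flat).reshape(n, *shape)

    def measure(i, p):
        dens = np.abs(p) ** 2
        dia[i] = dens.reshape(n, npts).sum(axis=1) * w_quad
        flat = p.reshape(n, npts)
        phi = np.einsum("jba,bj->aj", Uv.conj(), flat)  # adiabatic components
        adia[i] = (np.abs(phi) ** 2).sum(axis=1) * w_quad
        norms[i] = np.sqrt(dens.sum() * w_quad)
        # potential part from the adiabatic representation, kinetic via FFT
        e_pot = float(np.sum(np.abs(phi) ** 2 * ev_tot.T) * w_quad)
        pk = np.fft.fftn(p, axes=fft_axes)
        nk = np.sum(np.abs(pk) ** 2)
        e_kin = float(np.sum(np.abs(pk) ** 2 * t_kin[None]) / nk) if nk > 0 else 0.0
        energy[i] = e_pot + e_kin * (dens.sum() * w_quad)
        auto[i] = np.sum(psi0.conj() * p) * w_quad

    frame_i = 0
    measure(0, psi)
    frame_i = 1
    for k in range(1, n_steps + 1):
        psi = apply_V(psi, prop_half)
        pk = np.fft.fftn(psi, axes=fft_axes)
        pk *= kin_phase[None]
        psi = np.fft.ifftn(pk, axes=fft_axes)
        psi = apply_V(psi, prop_half)
        if frame_i < len(frames) and k == frames[frame_i]:
            measure(frame_i, psi)
            if abs(norms[frame_i] - 1.0) > 1e-8:
                raise RuntimeError(
                    f"norm drifted to {norms[frame_i]:.2e} at t = "
                    f"{t_out[frame_i]:.2f} fs; enlarge the grid box or refine "
                    "the spacing/time step")
            frame_i += 1

    wp.psi = psi
    wp.t_fs = n_steps * grid.dt_fs
    return PopulationTraces(t_fs=t_out, diabatic=dia, adiabatic=adia,
                            norm=norms, energy=energy, autocorrelation=auto)


@dataclass
class ComparisonMetrics:
    max_abs_deviation: float
    mean_abs_deviation: float
    per_state_max: np.ndarray
    final_abs_deviation: np.ndarray


def compare_sh_qd(t_sh: np.ndarray, pop_sh: np.ndarray,
                  t_qd: np.ndarray, pop_qd: np.ndarray) -> ComparisonMetrics:
    """Population-deviation metrics between two trace sets.

    The second trace set is linearly interpolated onto the overlapping
    part of the first time grid; metrics are symmetric in the inputs and
    zero for identical traces.
    """
    t_lo = max(t_sh.min(), t_qd.min())
    t_hi = min(t_sh.max(), t_qd.max())
    if t_hi <= t_lo:
        raise ValueError("time ranges do not overlap")
    mask = (t_sh >= t_lo) & (t_sh <= t_hi)
    t = t_sh[mask]
    a = pop_sh[mask]
    b = np.column_stack([np.interp(t, t_qd, pop_qd[:, s])
                         for s in range(pop_qd.shape[1])])
    dev = np.abs(a - b)
    return ComparisonMetrics(
        max_abs_deviation=float(dev.max()),
        mean_abs_deviation=float(dev.mean()),
        per_state_max=dev.max(axis=0),
        final_abs_deviation=dev[-1],
    )
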