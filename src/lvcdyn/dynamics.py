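"""Fewest-switches surface hopping on vibronic coupling models.

Trajectories move classically on one adiabatic surface of the model
(velocity-Verlet in dimensionless coordinates, H = sum_i (omega_i/2)P_i^2
+ V_a(Q)), while complex electronic coefficients are propagated along the
path.  Stochastic surface switches are drawn from the fewest-switches
probability computed from the flux of active-state population through the
step propagator.  The protocol matrix covers the three classic ad hoc
ingredients:

* decoherence: none, the energy-based decoherence correction (EDC), or
  augmented FSSH (AFSSH) moment propagation with stochastic collapse;
* momentum rescaling after a hop: keep the momentum (``p``), rescale the
  full vector to conserve total energy (``E``), or adjust only the
  component along the gradient-difference (``Ep_g``) or non-adiabatic
  coupling (``Ep_h``) direction;
* frustrated hops (insufficient energy along the rescaling direction):
  leave the momentum untouched (``plus``) or reflect it along the
  direction when the target-surface force opposes the momentum component
  (``minus``).

All combinations are enumerable as presets, so one ensemble of initial
conditions can be propagated under every protocol and compared against an
exact wave-packet reference on the same potentials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import units
from .initial import InitialCondition, assign_initial_state
from .model import (
    DEFAULT_DEGENERACY_THRESHOLD,
    LVCModel,
    adiabatic_point,
    AdiabaticPoint,
    evaluate_potential,
)

__all__ = [
    "SHProtocol",
    "HopEvent",
    "TrajectoryLog",
    "EnsembleResult",
    "protocol_matrix",
    "kinetic_energy",
    "velocity_verlet_step",
    "propagate_electronic",
    "hop_probability",
    "rescale_momentum",
    "handle_frustrated",
    "apply_edc",
    "AFSSHMoments",
    "run_trajectory",
    "run_ensemble",
]

DECOHERENCE_OPTIONS = ("none", "edc", "afssh")
RESCALING_OPTIONS = ("p", "E", "Ep_g", "Ep_h")
FRUSTRATED_OPTIONS = ("plus", "minus")


@dataclass(frozen=True)
class SHProtocol:
    """One combination of surface-hopping options plus integrator settings."""

    decoherence: str = "edc"
    rescaling: str = "Ep_h"
    frustrated: str = "plus"
    dt_fs: float = 0.5
    substeps: int = 25
    edc_c: float = 0.1  # Hartree, EDC decoherence constant
    propagator: str = "interp"  # 'interp' or 'ld' (local diabatization)
    degeneracy_threshold: float = DEFAULT_DEGENERACY_THRESHOLD

    def __post_init__(self):
        if self.decoherence not in DECOHERENCE_OPTIONS:
            raise ValueError(f"decoherence must be one of {DECOHERENCE_OPTIONS}")
        if self.rescaling not in RESCALING_OPTIONS:
            raise ValueError(f"rescaling must be one of {RESCALING_OPTIONS}")
        if self.frustrated not in FRUSTRATED_OPTIONS:
            raise ValueError(f"frustrated must be one of {FRUSTRATED_OPTIONS}")
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.substeps < 1:
            raise ValueError("at least one electronic substep required")
        if self.propagator not in ("interp", "ld"):
            raise ValueError("propagator must be 'interp' or 'ld'")

    @property
    def name(self) -> str:
        sign = {"plus": "+", "minus": "-"}[self.frustrated]
        return f"{self.decoherence}/{self.rescaling}{sign}"


# The curated benchmark subset: every decoherence flavor crossed with the
# physically distinct rescaling/reflection choices, dropping reflection
# variants that cannot trigger (momentum-conserving hops are never
# frustrated) and near-redundant combinations.
_BENCHMARK_SET = [
    ("none", "p", "plus"),
    ("none", "E", "plus"),
    ("edc", "p", "plus"),
    ("edc", "E", "plus"),
    ("edc", "Ep_g", "plus"),
    ("edc", "Ep_g", "minus"),
    ("edc", "Ep_h", "plus"),
    ("edc", "Ep_h", "minus"),
    ("afssh", "p", "plus"),
    ("afssh", "E", "plus"),
    ("afssh", "Ep_g", "minus"),
    ("afssh", "Ep_h", "plus"),
    ("afssh", "Ep_h", "minus"),
]


def protocol_matrix(preset: str = "full", **kwargs) -> list[SHProtocol]:
    """Enumerate surface-hopping protocols.

    ``full`` is the complete 3 x 4 x 2 = 24 factorial; ``benchmark`` is a
    curated 13-member subset spanning the distinct physics.  Keyword
    arguments (dt_fs, substeps, ...) are applied to every protocol.
    """
    if preset == "full":
        combos = [
            (d, r, fr)
            for d in DECOHERENCE_OPTIONS
            for r in RESCALING_OPTIONS
            for fr in FRUSTRATED_OPTIONS
        ]
    elif preset == "benchmark":
        combos = list(_BENCHMARK_SET)
    else:
        raise ValueError(f"unknown preset {preset!r}; use 'full' or 'benchmark'")
    return [SHProtocol(decoherence=d, rescaling=r, frustrated=fr, **kwargs)
            for d, r, fr in combos]


@dataclass
class HopEvent:
    t_fs: float
    source: int
    target: int
    accepted: bool
    frustrated: bool
    reflected: bool
    delta_v: float


@dataclass
class TrajectoryLog:
    t_fs: np.ndarray  # (frames,)
    active: np.ndarray  # (frames,) int
    c: np.ndarray  # (frames, n) complex
    U: np.ndarray  # (frames, n, n) complex
    energy: np.ndarray  # (frames,) total energy, Hartree
    Q: np.ndarray  # (frames, f)
    P: np.ndarray  # (frames, f)
    hops: list[HopEvent]
    max_drift: float  # max |E - E0 - sum(expected jumps)| over the run
    seed: tuple[int, ...]
    failed: bool = False
    failure_reason: str = ""


def kinetic_energy(omega: np.ndarray, P: np.ndarray) -> float:
    return float(0.5 * np.dot(omega, P * P))


def velocity_verlet_step(model: LVCModel, Q: np.ndarray, P: np.ndarray,
                         point: AdiabaticPoint, active: int, dt: float,
                         degeneracy_threshold: float = DEFAULT_DEGENERACY_THRESHOLD,
                         ) -> tuple[np.ndarray, np.ndarray, AdiabaticPoint]:
    """One velocity-Verlet step on the active adiabatic surface.

    Hamilton's equations in dimensionless coordinates read dQ_i/dt =
    omega_i P_i and dP_i/dt = -dV_a/dQ_i.  Returns updated (Q, P) and the
    adiabatic point at the new geometry (phase-aligned to the old one).
    """
    w = model.omega
    grad = point.g[active]
    P_half = P - 0.5 * dt * grad
    Q_new = Q + dt * w * P_half
    new_pt = adiabatic_point(model, Q_new, U_ref=point.U,
                             degeneracy_threshold=degeneracy_threshold)
    P_new = P_half - 0.5 * dt * new_pt.g[active]
    if not (np.all(np.isfinite(Q_new)) and np.all(np.isfinite(P_new))):
        raise FloatingPointError("non-finite nuclear update")
    return Q_new, P_new, new_pt


def _coupling_matrix(point: AdiabaticPoint, Qdot: np.ndarray) -> np.ndarray:
    """Scalar NAC matrix sigma_ab = h_ab . Qdot (anti-Hermitian)."""
    return np.einsum("abf,f->ab", point.nac, Qdot)


def propagate_electronic(model: LVCModel, c: np.ndarray,
                         old: AdiabaticPoint, new: AdiabaticPoint,
                         P_old: np.ndarray, P_new: np.ndarray,
                         dt: float, substeps: int,
                         scheme: str = "interp") -> tuple[np.ndarray, np.ndarray]:
    """Propagate electronic coefficients across one nuclear step.

    ``interp``: exponential midpoint of the adiabatic effective
    Hamiltonian H = diag(V) - i sigma (sigma_ab = h_ab . Qdot), with V and
    sigma interpolated linearly across the step; each substep propagator
    is the exact unitary exp(-i H_mid dtau) from an eigendecomposition.

    ``ld``: local diabatization — the diabatic potential matrix is
    propagated along the linearly interpolated path and the result
    transformed with the endpoint eigenvector matrices; robust at narrowly
    avoided crossings where the NAC is sharply peaked.

    Returns (c_new, A) with A the accumulated step propagator
    (c_new = A c_old); the norm of c is preserved to machine precision.
    """
    n = c.size
    dtau = dt / substeps
    w = model.omega
    xs = (np.arange(substeps) + 0.5) / substeps
    if scheme == "interp":
        H0 = np.diag(old.V).astype(complex) - 1j * _coupling_matrix(old, w * P_old)
        H1 = np.diag(new.V).astype(complex) - 1j * _coupling_matrix(new, w * P_new)
        Hs = (1.0 - xs)[:, None, None] * H0 + xs[:, None, None] * H1
    elif scheme == "ld":
        Qs = (1.0 - xs)[:, None] * old.Q + xs[:, None] * new.Q
        Hs = np.empty((substeps, n, n), dtype=complex)
        for k in range(substeps):
            V0, W = evaluate_potential(model, Qs[k])
            Hs[k] = W + V0 * np.eye(n)
    else:
        raise ValueError(f"unknown electronic propagation scheme {scheme!r}")
    ev, V = np.linalg.eigh(Hs)  # batched over substeps
    props = np.einsum("sab,sb,scb->sac", V, np.exp(-1j * ev * dtau), V.conj())
    A = props[0]
    for k in range(1, substeps):
        A = props[k] @ A
    if scheme == "ld":
        A = new.U.conj().T @ A @ old.U
    return A @ c, A


def hop_probability(c_before: np.ndarray, c_after: np.ndarray,
                    A: np.ndarray, active: int) -> np.ndarray:
    """Fewest-switches hopping probabilities from the step propagator.

    The total probability of leaving the active state a over the step is
    1 - |c_a(t+dt)|^2 / |c_a(t)|^2 (clamped at zero); it is distributed
    over target states b proportionally to the population flux
    Re[c_b(t+dt) (A_ba c_a(t))*].  Because A is unitary these fluxes sum
    exactly to the survival deficit, so 1 - sum_b g_b equals the survival
    probability whenever no clamping occurs.
    """
    a = active
    pa = abs(c_before[a]) ** 2
    g = np.zeros(c_before.size)
    if pa < 1e-12:
        warnings.warn("active-state population below 1e-12; hop probabilities "
                      "set to zero", stacklevel=2)
        return g
    leave = 1.0 - abs(c_after[a]) ** 2 / pa
    if leave <= 0.0:
        return g
    denom = pa - np.real(c_after[a] * np.conj(A[a, a] * c_before[a]))
    if abs(denom) < 1e-300:
        return g
    for b in range(c_before.size):
        if b == a:
            continue
        flux = np.real(c_after[b] * np.conj(A[b, a] * c_before[a]))
        g[b] = max(0.0, leave * flux / denom)
    total = g.sum()
    if total > 1.0:
        g *= 1.0 / total
    return g


FRUSTRATED = "FRUSTRATED"


def rescale_momentum(omega: np.ndarray, P: np.ndarray, delta_v: float,
                     scheme: str, direction: np.ndarray | None = None
                     ) -> np.ndarray | str:
    """Adjust the momentum for a hop with energy gap delta_v = V_b - V_a.

    Returns the new momentum vector, or :data:`FRUSTRATED` when the
    requested scheme cannot conserve energy.  ``p`` leaves the momentum
    (total energy changes by delta_v); ``E`` rescales the full vector;
    ``Ep_g``/``Ep_h`` solve the quadratic for a shift along ``direction``
    only, leaving orthogonal components untouched.
    """
    if scheme == "p":
        return P.copy()
    T = kinetic_energy(omega, P)
    if scheme == "E":
        if delta_v > T:
            return FRUSTRATED
        if T <= 0.0:
            return P.copy() if abs(delta_v) < 1e-15 else FRUSTRATED
        return P * np.sqrt(1.0 - delta_v / T)
    if scheme in ("Ep_g", "Ep_h"):
        d = None if direction is None else np.asarray(direction, float)
        if d is None or np.linalg.norm(d) < 1e-12:
            warnings.warn(f"zero-length {scheme} direction; falling back to "
                          "uniform rescaling", stacklevel=2)
            return rescale_momentum(omega, P, delta_v, "E")
        a = 0.5 * np.dot(omega, d * d)
        b = np.dot(omega * P, d)
        disc = b * b - 4.0 * a * delta_v
        if disc < 0.0:
            return FRUSTRATED
        sq = np.sqrt(disc)
        roots = ((-b + sq) / (2 * a), (-b - sq) / (2 * a))
        beta = min(roots, key=abs)
        return P + beta * d
    raise ValueError(f"unknown rescaling scheme {scheme!r}")


def handle_frustrated(omega: np.ndarray, P: np.ndarray,
                      direction: np.ndarray | None, option: str,
                      force_target: np.ndarray | None = None
                      ) -> tuple[np.ndarray, bool]:
    """Momentum update after a frustrated hop.

    ``plus``: do nothing.  ``minus``: reflect the momentum component along
    ``direction`` (in the kinetic-energy metric, so |T| is preserved
    exactly) when the force on the target surface opposes the momentum
    component along that direction — otherwise leave the momentum alone.
    Returns (P', reflected?).
    """
    if option == "plus" or direction is None:
        return P.copy(), False
    d = np.asarray(direction, float)
    nd = np.dot(omega * d, d)
    if nd < 1e-300:
        return P.copy(), False
    p_par = np.dot(P, d)
    if force_target is not None:
        f_par = np.dot(force_target, d)
        if f_par * p_par >= 0.0:
            return P.copy(), False
    proj = np.dot(omega * P, d) / nd
    return P - 2.0 * proj * d, True


def apply_edc(c: np.ndarray, active: int, V: np.ndarray, e_kin: float,
              dt: float, C: float = 0.1) -> np.ndarray:
    """Energy-based decoherence: damp non-active amplitudes.

    tau_b = (1 / |V_b - V_a|) (1 + C / E_kin) in atomic units; the active
    amplitude is rescaled to restore the norm.  With zero kinetic energy
    or a vanishing gap the damping time diverges and the coefficient is
    left untouched.
    """
    if e_kin <= 0.0:
        return c.copy()
    out = c.copy()
    a = active
    damped = 0.0
    for b in range(c.size):
        if b == a:
            continue
        gap = abs(V[b] - V[a])
        if gap < 1e-300:
            damped += abs(out[b]) ** 2
            continue
        tau = (1.0 / gap) * (1.0 + C / e_kin)
        out[b] = out[b] * np.exp(-dt / tau)
        damped += abs(out[b]) ** 2
    pa = abs(out[a]) ** 2
    if pa > 0.0:
        out[a] *= np.sqrt(max(1.0 - damped, 0.0) / pa)
    return out


@dataclass
class AFSSHMoments:
    """Auxiliary position/momentum moments of augmented FSSH.

    One (state, mode) array each for the position and momentum deviations
    of the auxiliary wave-packet center on every surface relative to the
    active one.  Moments are reset on hops and on per-state collapse.
    """

    dR: np.ndarray  # (n, f)
    dP: np.ndarray  # (n, f)

    @classmethod
    def zeros(cls, n: int, f: int) -> "AFSSHMoments":
        return cls(dR=np.zeros((n, f)), dP=np.zeros((n, f)))

    def reset(self, state: int | None = None) -> None:
        if state is None:
            self.dR[:] = 0.0
            self.dP[:] = 0.0
        else:
            self.dR[state] = 0.0
            self.dP[state] = 0.0


def apply_afssh(c: np.ndarray, moments: AFSSHMoments, point: AdiabaticPoint,
                omega: np.ndarray, active: int, dt: float,
                rng: np.random.Generator) -> np.ndarray:
    """One AFSSH decoherence step (moment propagation + stochastic collapse).

    The auxiliary moments follow the population-weighted force difference
    between each surface and the active one; a non-active amplitude is
    collapsed onto the active state with probability
    dt * [(F_n - F_a).dR_n / 2 - 2 |F_na . dR_n|] (clamped at zero), and
    the moments alone are reset with the rate built from the opposite sign
    of the first term.  Collapses renormalize the coefficient vector.
    """
    n, f = moments.dR.shape
    F = -point.g  # (n, f) adiabatic forces
    dF = F - F[active]
    pop = np.abs(c) ** 2
    moments.dR += dt * (omega[None, :] * moments.dP)
    moments.dP += dt * dF * pop[:, None]
    moments.reset(active)
    out = c.copy()
    for s in range(n):
        if s == active:
            continue
        drift = 0.5 * float(np.dot(dF[s], moments.dR[s]))
        f_od = point.nac[s, active] * (point.V[active] - point.V[s])
        od = 2.0 * abs(complex(np.dot(f_od, moments.dR[s])))
        p_collapse = dt * max(0.0, drift - od)
        p_reset = dt * max(0.0, -drift)
        u = rng.random()
        if u < p_collapse:
            out[s] = 0.0
            norm = np.linalg.norm(out)
            if norm > 0:
                out /= norm
            moments.reset(s)
        elif u < p_collapse + p_reset:
            moments.reset(s)
    return out


def _hop_directions(point: AdiabaticPoint, a: int, b: int, scheme: str
                    ) -> np.ndarray | None:
    """Direction vector used for rescaling/reflection of an a->b hop."""
    if scheme == "Ep_g":
        return point.g[a] - point.g[b]
    if scheme == "Ep_h":
        h = np.real(point.nac[a, b])
        return h
    # p/E hops reflect along the NAC by convention
    h = np.real(point.nac[a, b])
    return h if np.linalg.norm(h) > 1e-12 else point.g[a] - point.g[b]


def run_trajectory(model: LVCModel, protocol: SHProtocol, ic: InitialCondition,
                   t_final_fs: float, stride: int = 1) -> TrajectoryLog:
    """Propagate a single surface-hopping trajectory.

    Each nuclear step alternates velocity-Verlet motion on the active
    surface, electronic propagation with ``protocol.substeps`` substeps,
    the fewest-switches hop decision, momentum rescaling or frustrated-hop
    handling, and the decoherence correction.  Frames are recorded every
    ``stride`` steps (plus t = 0).
    """
    rng = np.random.default_rng(ic.seed)
    dt = units.fs_to_au(protocol.dt_fs)
    n_steps = int(round(t_final_fs / protocol.dt_fs))
    w = model.omega
    n, f = model.n_states, model.n_modes

    active, c, _ = assign_initial_state(model, ic, rng)
    Q, P = ic.Q.copy(), ic.P.copy()
    point = adiabatic_point(model, Q,
                            degeneracy_threshold=protocol.degeneracy_threshold)
    moments = AFSSHMoments.zeros(n, f) if protocol.decoherence == "afssh" else None

    frames = [k for k in range(0, n_steps + 1) if k % stride == 0]
    if frames[-1] != n_steps:
        frames.append(n_steps)
    n_frames = len(frames)
    t_log = np.array([k * protocol.dt_fs for k in frames])
    act_log = np.zeros(n_frames, dtype=np.int64)
    c_log = np.zeros((n_frames, n), dtype=complex)
    U_log = np.zeros((n_frames, n, n), dtype=complex)
    e_log = np.zeros(n_frames)
    Q_log = np.zeros((n_frames, f))
    P_log = np.zeros((n_frames, f))
    hops: list[HopEvent] = []

    e0 = kinetic_energy(w, P) + point.V[active]
    expected_offset = 0.0  # accumulated DV of momentum-conserving hops
    max_drift = 0.0
    frame_i = 0

    def record(k):
        nonlocal frame_i
        act_log[frame_i] = active
        c_log[frame_i] = c
        U_log[frame_i] = point.U
        e_log[frame_i] = kinetic_energy(w, P) + point.V[active]
        Q_log[frame_i] = Q
        P_log[frame_i] = P
        frame_i += 1

    record(0)
    failed = False
    reason = ""
    try:
        for k in range(1, n_steps + 1):
            P_prev = P
            Q, P, new_pt = velocity_verlet_step(
                model, Q, P, point, active, dt,
                degeneracy_threshold=protocol.degeneracy_threshold)
            c_new, A = propagate_electronic(
                model, c, point, new_pt, P_prev, P, dt, protocol.substeps,
                scheme=protocol.propagator)
            g_hop = hop_probability(c, c_new, A, active)
            c = c_new
            point = new_pt
            zeta = rng.random()
            target = -1
            acc = 0.0
            for b in range(n):
                if b == active:
                    continue
                acc += g_hop[b]
                if zeta < acc:
                    target = b
                    break
            if target >= 0:
                dV = point.V[target] - point.V[active]
                direction = _hop_directions(point, active, target,
                                            protocol.rescaling)
                res = rescale_momentum(w, P, dV, protocol.rescaling, direction)
                if isinstance(res, str):  # FRUSTRATED
                    P, reflected = handle_frustrated(
                        w, P, direction, protocol.frustrated,
                        force_target=-point.g[target])
                    hops.append(HopEvent(k * protocol.dt_fs, active, target,
                                         False, True, reflected, dV))
                else:
                    P = res
                    if protocol.rescaling == "p":
                        expected_offset += dV
                    hops.append(HopEvent(k * protocol.dt_fs, active, target,
                                         True, False, False, dV))
                    active = target
                    if moments is not None:
                        moments.reset()
            if protocol.decoherence == "edc":
                c = apply_edc(c, active, point.V, kinetic_energy(w, P), dt,
                              C=protocol.edc_c)
            elif protocol.decoherence == "afssh":
                c = apply_afssh(c, moments, point, w, active, dt, rng)
            drift = abs(kinetic_energy(w, P) + point.V[active] - e0
                        - expected_offset)
            max_drift = max(max_drift, drift)
            if frame_i < n_frames and k == frames[frame_i]:
                record(k)
    except FloatingPointError as exc:
        failed = True
        reason = str(exc)

    return TrajectoryLog(t_fs=t_log[:frame_i], active=act_log[:frame_i],
                         c=c_log[:frame_i], U=U_log[:frame_i],
                         energy=e_log[:frame_i], Q=Q_log[:frame_i],
                         P=P_log[:frame_i], hops=hops, max_drift=max_drift,
                         seed=ic.seed, failed=failed, failure_reason=reason)


@dataclass
class EnsembleResult:
    """Aggregated swarm of surface-hopping trajectories.

    Per-frame arrays are stacked over trajectories; populations are
    derived quantities (active-state fractions for the adiabatic picture,
    transformation-based estimators for the diabatic one, see
    :mod:`lvcdyn.analysis`).
    """

    t_fs: np.ndarray  # (frames,)
    active: np.ndarray  # (ntraj, frames)
    c: np.ndarray  # (ntraj, frames, n)
    U: np.ndarray  # (ntraj, frames, n, n)
    energy: np.ndarray  # (ntraj, frames)
    seeds: list[tuple[int, ...]]
    hops: list[list[HopEvent]]
    max_drift: np.ndarray  # (ntraj,)
    state_labels: tuple[str, ...] = ()

    @property
    def n_traj(self) -> int:
        return self.active.shape[0]

    @property
    def n_states(self) -> int:
        return self.c.shape[2]

    def adiabatic_populations(self) -> np.ndarray:
        """Active-state fractions, shape (frames, n)."""
        n = self.n_states
        counts = np.zeros((self.t_fs.size, n))
        for s in range(n):
            counts[:, s] = np.mean(self.active == s, axis=0)
        return counts

    def hop_statistics(self) -> dict[tuple[int, int], dict[str, int]]:
        stats: dict[tuple[int, int], dict[str, int]] = {}
        for traj in self.hops:
            for h in traj:
                key = (h.source, h.target)
                d = stats.setdefault(key, {"accepted": 0, "frustrated": 0,
                                           "reflected": 0})
                if h.accepted:
                    d["accepted"] += 1
                if h.frustrated:
                    d["frustrated"] += 1
                if h.reflected:
                    d["reflected"] += 1
        return stats

    @classmethod
    def merge(cls, parts: list["EnsembleResult"]) -> "EnsembleResult":
        """Concatenate disjoint sub-ensembles (same time grid)."""
        first = parts[0]
        for p in parts[1:]:
            if not np.array_equal(p.t_fs, first.t_fs):
                raise ValueError("cannot merge ensembles with different time grids")
        return cls(
            t_fs=first.t_fs,
            active=np.concatenate([p.active for p in parts]),
            c=np.concatenate([p.c for p in parts]),
            U=np.concatenate([p.U for p in parts]),
            energy=np.concatenate([p.energy for p in parts]),
            seeds=[s for p in parts for s in p.seeds],
            hops=[h for p in parts for h in p.hops],
            max_drift=np.concatenate([p.max_drift for p in parts]),
            state_labels=first.state_labels,
        )


def run_ensemble(model: LVCModel, protocol: SHProtocol,
                 ics: list[InitialCondition], t_final_fs: float,
                 stride: int = 1) -> EnsembleResult:
    """Propagate an ensemble of independent trajectories.

    Results are deterministic given the per-trajectory seeds and invariant
    under execution order.  Failed trajectories are dropped with a
    warning; an all-failed ensemble is a hard error.
    """
    if not ics:
        raise ValueError("at least one initial condition required")
    logs = [run_trajectory(model, protocol, ic, t_final_fs, stride=stride)
            for ic in ics]
    good = [lg for lg in logs if not lg.failed]
    if not good:
        raise RuntimeError("every trajectory in the ensemble failed: "
                           + "; ".join(lg.failure_reason for lg in logs[:3]))
    if len(good) < len(logs):
        warnings.warn(f"dropped {len(logs) - len(good)} failed trajectories",
                      stacklevel=2)
    return EnsembleResult(
        t_fs=good[0].t_fs,
        active=np.stack([lg.active for lg in good]),
        c=np.stack([lg.c for lg in good]),
        U=np.stack([lg.U for lg in good]),
        energy=np.stack([lg.energy for lg in good]),
        seeds=[lg.seed for lg in good],
        hops=[lg.hops for lg in good],
        max_drift=np.array([lg.max_drift for lg in good]),
        state_labels=model.basis.labels,
    )
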