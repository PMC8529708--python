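"""Population analysis, diagnostics, model reduction, and kinetic fits.

The tools here mirror the workflow used to audit vibronic-coupling
dynamics: diabatic population traces from the well-defined adiabatic-to-
diabatic transformation carried by every trajectory frame; a Wigner-
sampled density-of-states scan that flags spurious below-reference
states; per-mode coupling-strength rankings driving dimensionality
reduction; and first-order kinetic-network / exponential-decay fits of
population traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .dynamics import EnsembleResult
from .initial import wigner_sample
from .model import LVCModel, adiabatic_point, diabatic_minimum

__all__ = [
    "diabatic_populations",
    "DOSHistogram",
    "dos_from_wigner",
    "ModeImportanceTable",
    "mode_importance",
    "reduce_model",
    "KineticModel",
    "fit_kinetic_model",
    "DecayFit",
    "fit_decay_times",
]


def diabatic_populations(ensemble: EnsembleResult,
                         mode: str = "active-projector") -> np.ndarray:
    """Diabatic population traces from a surface-hopping ensemble.

    ``active-projector``: P_n(t) = < |U_{n,a}|^2 > with a the active
    surface — each trajectory contributes the diabatic composition of its
    occupied adiabat.  ``coefficient``: P_n(t) = < |(U c)_n|^2 >, the
    diabatic populations of the coherent electronic wavefunction.  Both
    sum to one per frame by unitarity.
    """
    if ensemble.U.size == 0:
        raise ValueError("ensemble carries no transformation matrices")
    nt, nf, n, _ = ensemble.U.shape
    if mode == "active-projector":
        rows = np.abs(ensemble.U) ** 2  # (nt, nf, n_dia, n_adia)
        idx = ensemble.active[..., None, None]  # (nt, nf, 1, 1)
        picked = np.take_along_axis(rows, np.broadcast_to(idx, (nt, nf, n, 1)),
                                    axis=3)[..., 0]
        return picked.mean(axis=0)
    if mode == "coefficient":
        dia = np.einsum("tfnm,tfm->tfn", ensemble.U, ensemble.c)
        return (np.abs(dia) ** 2).mean(axis=0)
    raise ValueError("mode must be 'active-projector' or 'coefficient'")


@dataclass
class DOSHistogram:
    """Wigner-sampled adiabatic density of states, grouped by character."""

    bin_edges: np.ndarray
    groups: tuple[str, ...]
    counts: np.ndarray  # (n_groups, n_bins)
    n_samples: int
    negative_flags: np.ndarray  # sample indices with a spurious state below 0
    reference: float

    @property
    def n_negative(self) -> int:
        return int(self.negative_flags.size)


def dos_from_wigner(model: LVCModel, n_samples: int, seed: int,
                    reference: float = 0.0, bins: int = 60) -> DOSHistogram:
    """Histogram adiabatic energies over the ground-state Wigner cloud.

    Each sampled geometry is adiabatized; every adiabat is assigned the
    group tag of its dominant diabatic character (|U_na|^2), and energies
    are collected per group relative to ``reference`` — by construction
    the reference-geometry ground minimum sits at zero for models whose
    first diabat is undisplaced.  A sample is flagged when an adiabat of
    *excited* character (dominant diabat other than the first) lies below
    the reference: the signature of a spuriously displaced state that
    will act as an artificial population trap.  Classification by
    character rather than energy order matters — a diving state ends up
    as the *lowest* eigenvalue and would otherwise escape notice.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n = model.n_states
    group_of_state = [s.group or s.label for s in model.basis.states]
    groups = tuple(dict.fromkeys(group_of_state))
    pairs = wigner_sample(model.modes, n_samples, seed)
    energies = np.empty((n_samples, n))
    char = np.empty((n_samples, n), dtype=int)  # dominant diabat per adiabat
    for j, (Q, _) in enumerate(pairs):
        pt = adiabatic_point(model, Q, derivatives=False)
        energies[j] = pt.V - reference
        char[j] = np.argmax(np.abs(pt.U) ** 2, axis=0)
    spurious = (energies < 0.0) & (char != 0)
    flags = np.flatnonzero(np.any(spurious, axis=1))
    lo = min(energies.min(), 0.0)
    hi = energies.max()
    edges = np.linspace(lo, hi, bins + 1)
    counts = np.zeros((len(groups), bins), dtype=int)
    gidx = {g: i for i, g in enumerate(groups)}
    for gi in range(len(groups)):
        mask = np.array([gidx[group_of_state[c]] == gi
                         for c in char.ravel()]).reshape(char.shape)
        counts[gi] = np.histogram(energies[mask], bins=edges)[0]
    return DOSHistogram(bin_edges=edges, groups=groups, counts=counts,
                        n_samples=n_samples, negative_flags=flags,
                        reference=reference)


@dataclass
class ModeImportanceTable:
    """Per-mode coupling-strength ranking.

    ``score`` is the plain absolute coupling sum
    sum_n |kappa_i^(n)| + sum_{n<m} |lambda_i^(nm)|;
    ``reorganization`` holds the omega-weighted variant kappa^2/(2 omega)
    per (state, mode), whose large values flag modes able to create
    low-energy displaced minima.
    """

    order: np.ndarray  # mode indices, descending score
    score: np.ndarray  # (f,), aligned with `order`
    kappa_abs: np.ndarray  # (n, f), original mode order
    lambda_abs: np.ndarray  # (f,), summed over pairs, original order
    reorganization: np.ndarray  # (n, f), original order


def mode_importance(model: LVCModel) -> ModeImportanceTable:
    kappa_abs = np.abs(model.kappa)
    iu = np.triu_indices(model.n_states, k=1)
    lambda_abs = np.abs(model.lam[iu]).sum(axis=0)
    score = kappa_abs.sum(axis=0) + lambda_abs
    reorg = model.kappa ** 2 / (2.0 * model.omega[None, :])
    order = np.argsort(-score, kind="stable")
    return ModeImportanceTable(order=order, score=score[order],
                               kappa_abs=kappa_abs, lambda_abs=lambda_abs,
                               reorganization=reorg)


def reduce_model(model: LVCModel, keep_modes: list[int] | None = None,
                 keep_states: list[str] | None = None) -> LVCModel:
    """Sub-model with only the given modes and multiplets retained.

    ``keep_states`` names multiplets; all spin components of a named
    multiplet are kept, and asking for an individual component of a
    larger multiplet is an error (multiplets are removed atomically).
    The eta sub-block, kappa/lambda slices and basis metadata carry over
    unchanged, so evaluation on the kept coordinates is identical to the
    parent model with the removed coordinates pinned at zero.
    """
    from dataclasses import replace

    from .model import BasisSpec, ModeSet

    f = model.n_modes
    modes_idx = list(range(f)) if keep_modes is None else sorted(set(keep_modes))
    if not modes_idx:
        raise ValueError("keep_modes must not be empty")
    if any(not 0 <= i < f for i in modes_idx):
        raise ValueError("mode index out of range")

    if keep_states is None:
        state_idx = list(range(model.n_states))
        basis = model.basis
    else:
        names = list(dict.fromkeys(keep_states))
        if not names:
            raise ValueError("keep_states must not be empty")
        available = set(model.basis.multiplet_names)
        component_labels = set(model.basis.labels)
        state_idx = []
        for nm in names:
            if nm in available:
                state_idx.extend(model.basis.multiplet_indices(nm))
            elif nm in component_labels:
                st = model.basis.states[model.basis.index(nm)]
                if int(round(2 * st.spin + 1)) > 1:
                    raise ValueError(
                        f"{nm!r} is a single component of multiplet "
                        f"{st.multiplet!r}; multiplets are removed atomically")
                state_idx.append(model.basis.index(nm))
            else:
                raise KeyError(f"unknown state or multiplet {nm!r}")
        state_idx = sorted(set(state_idx))
        basis = BasisSpec(tuple(model.basis.states[i] for i in state_idx))

    modes = ModeSet(frequencies=model.omega[modes_idx],
                    labels=tuple(model.modes.labels[i] for i in modes_idx))
    sub = np.ix_(state_idx, state_idx)
    return replace(
        model,
        modes=modes,
        basis=basis,
        E=model.E[state_idx],
        eta=model.eta[sub],
        kappa=model.kappa[np.ix_(state_idx, modes_idx)],
        lam=model.lam[np.ix_(state_idx, state_idx, modes_idx)],
        gamma=None if model.gamma is None
        else model.gamma[np.ix_(state_idx, modes_idx)],
    )


@dataclass
class KineticModel:
    """First-order kinetic network fitted to population traces."""

    labels: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]  # directed (source, sink)
    rates: np.ndarray  # 1/fs, aligned with `edges`
    covariance: np.ndarray | None
    residual: float

    def rate_matrix(self) -> np.ndarray:
        n = len(self.labels)
        K = np.zeros((n, n))
        for (src, dst), k in zip(self.edges, self.rates):
            K[dst, src] += k
            K[src, src] -= k
        return K

    def populations(self, t_fs: np.ndarray, p0: np.ndarray) -> np.ndarray:
        K = self.rate_matrix()
        return np.stack([scipy.linalg.expm(K * t) @ p0 for t in t_fs])


def fit_kinetic_model(t_fs: np.ndarray, traces: np.ndarray,
                      edges: list[tuple[int, int]],
                      labels: tuple[str, ...] | None = None,
                      p0: np.ndarray | None = None) -> KineticModel:
    """Globally fit a first-order rate network to population traces.

    The population model is P(t) = expm(K t) P(0) with K assembled from
    non-negative directed rates on ``edges``; all states and frames enter
    one least-squares objective.  Ill-conditioned (non-identifiable)
    topologies are reported through a warning and the covariance.
    """
    t_fs = np.asarray(t_fs, float)
    traces = np.asarray(traces, float)
    n = traces.shape[1]
    labels = labels or tuple(f"state{i}" for i in range(n))
    p_init = traces[0] if p0 is None else np.asarray(p0, float)
    span = max(t_fs[-1] - t_fs[0], 1e-12)

    def model_pop(rates):
        K = np.zeros((n, n))
        for (src, dst), k in zip(edges, rates):
            K[dst, src] += k
            K[src, src] -= k
        return np.stack([scipy.linalg.expm(K * t) @ p_init for t in t_fs])

    def resid(rates):
        return (model_pop(rates) - traces).ravel()

    x0 = np.full(len(edges), 1.0 / span)
    sol = scipy.optimize.least_squares(resid, x0, bounds=(0.0, np.inf),
                                       xtol=1e-14, ftol=1e-14, gtol=1e-14)
    J = sol.jac
    dof = max(sol.fun.size - len(edges), 1)
    s2 = float(np.sum(sol.fun ** 2)) / dof
    JTJ = J.T @ J
    cov = None
    try:
        cov = np.linalg.inv(JTJ) * s2
        cond = np.linalg.cond(JTJ)
        if cond > 1e12:
            warnings.warn(
                f"kinetic topology is poorly identifiable (condition number "
                f"{cond:.1e}); inspect the covariance", stacklevel=2)
    except np.linalg.LinAlgError:
        warnings.warn("singular Jacobian: kinetic topology not identifiable "
                      "from these traces", stacklevel=2)
    return KineticModel(labels=labels, edges=tuple(edges), rates=sol.x,
                        covariance=cov, residual=float(np.sum(sol.fun ** 2)))


@dataclass
class DecayFit:
    tau_fs: float
    tau_stderr_fs: float
    amplitude: float
    offset: float
    converged: bool
    diverged: bool  # flat trace: no finite decay time


def fit_decay_times(t_fs: np.ndarray, trace: np.ndarray,
                    with_offset: bool = True) -> DecayFit:
    """Fit a single-exponential decay a * exp(-t/tau) + c to one trace.

    Standard errors come from the fit covariance.  A trace without
    discernible decay (fitted tau beyond ~100x the time span, or a
    singular fit) is flagged ``diverged`` rather than silently filled.
    """
    t_fs = np.asarray(t_fs, float)
    y = np.asarray(trace, float)
    span = max(t_fs[-1] - t_fs[0], 1e-12)
    if np.ptp(y) < 1e-12:
        return DecayFit(np.inf, np.inf, 0.0, float(y.mean()),
                        converged=False, diverged=True)

    if with_offset:
        def f(t, a, tau, c):
            return a * np.exp(-t / tau) + c
        p0 = [y[0] - y[-1], span / 3.0, y[-1]]
    else:
        def f(t, a, tau):
            return a * np.exp(-t / tau)
        p0 = [y[0], span / 3.0]
    try:
        popt, pcov = scipy.optimize.curve_fit(f, t_fs, y, p0=p0, maxfev=20000)
    except (RuntimeError, scipy.optimize.OptimizeWarning):
        return DecayFit(np.nan, np.nan, np.nan, np.nan,
                        converged=False, diverged=False)
    tau = float(popt[1])
    tau_err = float(np.sqrt(np.abs(pcov[1, 1])))
    diverged = not np.isfinite(tau) or tau > 100.0 * span
    return DecayFit(tau_fs=tau, tau_stderr_fs=tau_err, amplitude=float(popt[0]),
                    offset=float(popt[2]) if with_offset else 0.0,
                    converged=True, diverged=diverged)
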