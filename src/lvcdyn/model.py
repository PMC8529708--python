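"""Vibronic coupling model Hamiltonians and their adiabatization.

The potential is a Taylor expansion around a reference geometry in
dimensionless mass-frequency-weighted normal coordinates Q:

    H = T + V0(Q) * 1 + W(Q)
    V0(Q) = sum_i (omega_i / 2) Q_i^2
    W_nn(Q) = E_n + sum_i kappa_i^(n) Q_i  [+ (1/2) gamma_i^(n) Q_i^2]
    W_nm(Q) = eta_nm + sum_i lambda_i^(nm) Q_i      (n != m)

with kinetic energy T = sum_i (omega_i / 2) P_i^2.  ``eta`` carries
geometry-independent couplings such as spin-orbit matrix elements and may
be complex (Hermitian); ``kappa`` are intrastate gradients, ``lambda``
linear interstate couplings, and the optional diagonal-in-mode ``gamma``
adds per-state second-order (quadratic vibronic coupling) curvature.

Adiabatic surfaces are the eigenvalues of W(Q) + V0(Q); gradients and
non-adiabatic coupling (NAC) vectors follow analytically from the
Hellmann-Feynman theorem, which makes these models attractive test beds
for trajectory surface hopping against exact wave-packet references.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

__all__ = [
    "ModeSet",
    "ElectronicState",
    "BasisSpec",
    "LVCModel",
    "AdiabaticPoint",
    "evaluate_potential",
    "adiabatize",
    "model_derivatives",
    "adiabatic_point",
    "diabatic_minimum",
    "ModelValidationError",
    "DegeneracyWarning",
]

DEFAULT_DEGENERACY_THRESHOLD = 1e-8  # Hartree


class ModelValidationError(ValueError):
    """Raised when model data violates a structural invariant."""


class DegeneracyWarning(UserWarning):
    """Emitted when NAC vectors are evaluated inside a degenerate block."""


@dataclass(frozen=True)
class ModeSet:
    """Set of harmonic normal modes.

    Frequencies are stored in Hartree (energy equivalent, hbar*omega with
    hbar = 1); wavenumber input is converted at the I/O layer.
    """

    frequencies: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        freq = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        object.__setattr__(self, "frequencies", freq)
        if freq.ndim != 1 or freq.size < 1:
            raise ModelValidationError("frequencies must be a non-empty 1-D array")
        if not np.all(np.isfinite(freq)) or np.any(freq <= 0):
            raise ModelValidationError("all mode frequencies must be finite and > 0")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"mode{i + 1}" for i in range(freq.size))
            )
        elif len(self.labels) != freq.size:
            raise ModelValidationError("labels length does not match frequencies")

    @property
    def count(self) -> int:
        return int(self.frequencies.size)

    def __len__(self) -> int:
        return self.count


@dataclass(frozen=True)
class ElectronicState:
    """One diabatic basis state (a single spin component of a multiplet)."""

    label: str
    spin: float = 0.0  # total spin quantum number S
    ms: float = 0.0  # spin projection M_S
    group: str = ""  # free-form tag used in character analysis

    def __post_init__(self):
        two_s = Fraction(self.spin).limit_denominator(2) * 2
        if two_s.denominator != 1 or self.spin < 0:
            raise ModelValidationError(f"spin must be a non-negative half-integer, got {self.spin}")
        if abs(self.ms) > self.spin + 1e-12:
            raise ModelValidationError(f"|M_S| must not exceed S for state {self.label!r}")

    @property
    def multiplet(self) -> str:
        """Multiplet identity: the label stripped of any M_S suffix."""
        return self.label.split("@")[0]


@dataclass(frozen=True)
class BasisSpec:
    """Ordered diabatic electronic basis.

    Each multiplet of spin S must appear with all 2S+1 components; the
    component labels are `name` for singlets and `name@ms` otherwise.
    """

    states: tuple[ElectronicState, ...]

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ModelValidationError("state labels must be unique")
        # multiplet completeness: every (multiplet, S) needs 2S+1 distinct M_S
        groups: dict[tuple[str, float], set[float]] = {}
        for s in self.states:
            groups.setdefault((s.multiplet, s.spin), set()).add(s.ms)
        for (name, spin), ms_set in groups.items():
            expected = int(round(2 * spin + 1))
            if len(ms_set) != expected:
                raise ModelValidationError(
                    f"multiplet {name!r} (S={spin}) has {len(ms_set)} components, expected {expected}"
                )

    @classmethod
    def from_multiplets(cls, multiplets: list[tuple[str, float, str]]) -> "BasisSpec":
        """Expand (name, S, group) triples into individual spin components."""
        states = []
        for name, spin, group in multiplets:
            n_comp = int(round(2 * spin + 1))
            if n_comp == 1:
                states.append(ElectronicState(name, spin, 0.0, group))
            else:
                for k in range(n_comp):
                    ms = -spin + k
                    states.append(ElectronicState(f"{name}@{ms:g}", spin, ms, group))
        return cls(tuple(states))

    @classmethod
    def singlets(cls, n: int, group: str = "") -> "BasisSpec":
        return cls.from_multiplets([(f"S{i}", 0.0, group or "S") for i in range(n)])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    @property
    def multiplet_names(self) -> tuple[str, ...]:
        seen = []
        for s in self.states:
            if s.multiplet not in seen:
                seen.append(s.multiplet)
        return tuple(seen)

    def multiplet_indices(self, name: str) -> list[int]:
        return [i for i, s in enumerate(self.states) if s.multiplet == name]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown state label {label!r}; available: {', '.join(self.labels)}"
            ) from None

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class LVCModel:
    """A (linear, optionally quadratic) vibronic coupling model.

    Shapes: with n states and f modes, ``E`` is (n,), ``eta`` (n, n)
    complex Hermitian with zero diagonal, ``kappa`` (n, f), ``lam``
    (n, n, f) real, symmetric in the state pair with zero diagonal, and
    the optional ``gamma`` (n, f) holds per-state diagonal second-order
    coefficients.  All energies in Hartree.
    """

    modes: ModeSet
    basis: BasisSpec
    E: np.ndarray
    eta: np.ndarray | None = None
    kappa: np.ndarray | None = None
    lam: np.ndarray | None = None
    gamma: np.ndarray | None = None

    def __post_init__(self):
        n, f = len(self.basis), self.modes.count
        E = np.asarray(self.E, dtype=float).reshape(n)
        eta = (
            np.zeros((n, n), dtype=complex)
            if self.eta is None
            else np.asarray(self.eta, dtype=complex)
        )
        kappa = (
            np.zeros((n, f))
            if self.kappa is None
            else np.asarray(self.kappa, dtype=float)
        )
        lam = (
            np.zeros((n, n, f))
            if self.lam is None
            else np.asarray(self.lam, dtype=float)
        )
        for name, arr, shape in [
            ("E", E, (n,)),
            ("eta", eta, (n, n)),
            ("kappa", kappa, (n, f)),
            ("lam", lam, (n, n, f)),
        ]:
            if arr.shape != shape:
                raise ModelValidationError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ModelValidationError(f"{name} contains non-finite entries")
        if not np.allclose(eta, eta.conj().T, atol=1e-12):
            raise ModelValidationError("eta must be Hermitian")
        if np.any(np.abs(np.diagonal(eta)) > 1e-14):
            raise ModelValidationError("eta must have zero diagonal")
        if not np.allclose(lam, np.swapaxes(lam, 0, 1), atol=1e-14):
            raise ModelValidationError("lambda must be symmetric in the state pair")
        if np.any(np.abs(np.einsum("nnf->nf", lam)) > 1e-14):
            raise ModelValidationError("lambda must have zero state diagonal")
        gamma = self.gamma
        if gamma is not None:
            gamma = np.asarray(gamma, dtype=float)
            if gamma.shape != (n, f):
                raise ModelValidationError(f"gamma has shape {gamma.shape}, expected {(n, f)}")
            if not np.all(np.isfinite(gamma)):
                raise ModelValidationError("gamma contains non-finite entries")
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "kappa", kappa)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "gamma", gamma)

    @property
    def n_states(self) -> int:
        return len(self.basis)

    @property
    def n_modes(self) -> int:
        return self.modes.count

    @property
    def omega(self) -> np.ndarray:
        return self.modes.frequencies

    def with_(self, **kwargs) -> "LVCModel":
        return replace(self, **kwargs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LVCModel):
            return NotImplemented
        ga, gb = self.gamma, other.gamma
        return (
            np.array_equal(self.omega, other.omega)
            and self.basis == other.basis
            and np.array_equal(self.E, other.E)
            and np.array_equal(self.eta, other.eta)
            and np.array_equal(self.kappa, other.kappa)
            and np.array_equal(self.lam, other.lam)
            and ((ga is None) == (gb is None))
            and (ga is None or np.array_equal(ga, gb))
        )


@dataclass
class AdiabaticPoint:
    """Adiabatic electronic structure of the model at one geometry.

    ``V`` holds the total adiabatic energies (eigenvalues of W plus the
    harmonic backbone V0) in ascending order; the columns of the unitary
    ``U`` express the adiabatic states in the diabatic basis.  ``g`` are
    the adiabatic energy gradients, ``nac`` the first-order derivative
    coupling vectors h_ab; pairs inside ``degenerate_pairs`` were closer
    than the degeneracy threshold and their NAC entries are zeroed rather
    than divided through.
    """

    Q: np.ndarray
    V0: float
    V: np.ndarray
    U: np.ndarray
    g: np.ndarray | None = None
    nac: np.ndarray | None = None
    degenerate_pairs: list[tuple[int, int]] = field(default_factory=list)


def _check_Q(model: LVCModel, Q) -> np.ndarray:
    Q = np.atleast_1d(np.asarray(Q, dtype=float))
    if Q.shape != (model.n_modes,):
        raise ModelValidationError(
            f"coordinate vector has shape {Q.shape}, expected ({model.n_modes},)"
        )
    if not np.all(np.isfinite(Q)):
        raise ModelValidationError("coordinates contain non-finite entries")
    return Q


def evaluate_potential(model: LVCModel, Q) -> tuple[float, np.ndarray]:
    """Evaluate the harmonic backbone V0(Q) and the diabatic matrix W(Q)."""
    Q = _check_Q(model, Q)
    w = model.omega
    V0 = float(0.5 * np.dot(w, Q * Q))
    W = model.eta + model.lam @ Q
    diag = model.E + model.kappa @ Q
    if model.gamma is not None:
        diag = diag + 0.5 * (model.gamma @ (Q * Q))
    W = W + np.diag(diag.astype(complex))
    return V0, W


def dW_dQ(model: LVCModel, Q=None) -> np.ndarray:
    """Derivative tensor dW/dQ_i, shape (f, n, n).

    Constant for a pure LVC model; Q only matters with quadratic terms.
    """
    n, f = model.n_states, model.n_modes
    d = np.transpose(model.lam, (2, 0, 1)).astype(complex).copy()
    idx = np.arange(n)
    d[:, idx, idx] += model.kappa.T
    if model.gamma is not None:
        Q = _check_Q(model, Q if Q is not None else np.zeros(f))
        d[:, idx, idx] += model.gamma.T * Q[:, None]
    return d


def _align_columns(U: np.ndarray, V: np.ndarray, U_ref: np.ndarray,
                   deg_tol: float = 1e-10) -> np.ndarray:
    """Phase/sign-align eigenvector columns to a reference unitary.

    Non-degenerate columns get the phase maximizing Re(U_ref_k^dag U_k);
    degenerate blocks are rotated onto the reference by the unitary factor
    of the polar decomposition of the overlap block, which is the global
    maximizer of Re tr(U_ref^dag U X) over unitary X.
    """
    U = U.copy()
    n = U.shape[1]
    # cluster eigenvalues
    clusters: list[list[int]] = []
    for k in range(n):
        if clusters and V[k] - V[clusters[-1][-1]] < deg_tol:
            clusters[-1].append(k)
        else:
            clusters.append([k])
    for cl in clusters:
        block = U[:, cl]
        A = U_ref[:, cl].conj().T @ block
        if len(cl) == 1:
            a = A[0, 0]
            if abs(a) > 1e-14:
                block = block * (a.conjugate() / abs(a))
        else:
            Wm, _, Vh = np.linalg.svd(A)
            block = block @ (Wm @ Vh).conj().T
        U[:, cl] = block
    return U


def adiabatize(W: np.ndarray, V0: float = 0.0, U_ref: np.ndarray | None = None,
               check: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Diagonalize W and return total adiabatic energies and the unitary U.

    Energies come back ascending as eigenvalues(W) + V0.  When ``U_ref``
    is given the eigenvector phases (and degenerate subspaces) are aligned
    to it for smooth propagation; otherwise phases are fixed so the
    largest-magnitude component of each column is real positive.
    """
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ModelValidationError("W must be a square matrix")
    if check and not np.allclose(W, W.conj().T, atol=1e-12):
        raise ModelValidationError("W must be Hermitian to 1e-12")
    ev, U = np.linalg.eigh(W)
    if U_ref is not None:
        U = _align_columns(U, ev, np.asarray(U_ref))
    else:
        for k in range(U.shape[1]):
            j = int(np.argmax(np.abs(U[:, k])))
            a = U[j, k]
            if abs(a) > 0:
                U[:, k] *= a.conjugate() / abs(a)
    return ev + V0, U


def model_derivatives(
    model: LVCModel,
    Q,
    V: np.ndarray,
    U: np.ndarray,
    degeneracy_threshold: float = DEFAULT_DEGENERACY_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Analytic adiabatic gradients and NAC vectors at one geometry.

    Hellmann-Feynman:  g_a,i = omega_i Q_i + [U^dag dW/dQ_i U]_aa and
    h_ab,i = [U^dag dW/dQ_i U]_ab / (V_b - V_a).  State pairs with
    |V_b - V_a| below ``degeneracy_threshold`` are flagged and their NAC
    entries set to zero — never silently divided.

    Returns (g, nac, degenerate_pairs) with g shape (n, f) real and nac
    shape (n, n, f) complex, antisymmetric under (a, b) swap together with
    complex conjugation.
    """
    Q = _check_Q(model, Q)
    n, f = model.n_states, model.n_modes
    d = dW_dQ(model, Q)  # (f, n, n)
    A = np.einsum("pa,fpq,qb->fab", U.conj(), d, U)  # (f, n, n)
    g = model.omega[None, :] * Q[None, :] + np.real(np.einsum("faa->af", A))
    nac = np.zeros((n, n, f), dtype=complex)
    degenerate: list[tuple[int, int]] = []
    for a in range(n):
        for b in range(a + 1, n):
            gap = V[b] - V[a]
            if abs(gap) < degeneracy_threshold:
                degenerate.append((a, b))
                continue
            h = A[:, a, b] / gap
            nac[a, b] = h
            nac[b, a] = -h.conjugate()
    return g, nac, degenerate


def adiabatic_point(
    model: LVCModel,
    Q,
    U_ref: np.ndarray | None = None,
    degeneracy_threshold: float = DEFAULT_DEGENERACY_THRESHOLD,
    derivatives: bool = True,
) -> AdiabaticPoint:
    """Evaluate, adiabatize and (optionally) differentiate in one call."""
    Q = _check_Q(model, Q)
    V0, W = evaluate_potential(model, Q)
    V, U = adiabatize(W, V0, U_ref=U_ref, check=False)  # Hermitian by construction
    pt = AdiabaticPoint(Q=Q, V0=V0, V=V, U=U)
    if derivatives:
        pt.g, pt.nac, pt.degenerate_pairs = model_derivatives(
            model, Q, V, U, degeneracy_threshold
        )
    return pt


def diabatic_minimum(model: LVCModel, n: int) -> tuple[np.ndarray, float]:
    """Minimum of the isolated diabatic surface n (pure LVC closed form).

    Q_min,i = -kappa_i^(n) / omega_i and
    E_min = E_n - sum_i kappa_i^(n)^2 / (2 omega_i); the subtracted term
    is the reorganization energy of the displaced harmonic minimum.
    """
    if model.gamma is not None:
        raise NotImplementedError(
            "diabatic_minimum supports pure LVC models only (no quadratic terms)"
        )
    k = model.kappa[n]
    w = model.omega
    Q_min = -k / w
    E_min = float(model.E[n] - np.sum(k * k / (2.0 * w)))
    return Q_min, E_min
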