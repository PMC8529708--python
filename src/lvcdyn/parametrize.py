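"""Building LVC models from ab initio point data.

Two routes are supported:

* the *one-shot* route: a single calculation at the reference geometry
  providing vertical energies, Cartesian gradients and (optionally)
  non-adiabatic coupling vectors.  Intrastate gradients kappa are the
  mode-projected gradients; interstate couplings follow from
  lambda = (E_m - E_n) * h at the reference point, where h is the
  mode-projected NAC vector — exact for the LVC form, since at Q = 0 the
  adiabatic and diabatic bases coincide for non-degenerate states.

* the *finite-difference* route: pre-diabatized potential matrices
  W(+/- delta e_i) for every mode, from which central differences give
  kappa and lambda.  Central differences are exact for linear potentials
  and cancel any quadratic contamination.

Cartesian quantities are converted to dimensionless normal coordinates by
mass weighting and frequency scaling; the mode matrix is expected to hold
Cartesian displacement columns whose mass-weighted forms are orthonormal
(the usual normalization of quantum-chemistry normal-mode output; small
deviations are re-normalized, large ones rejected).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import units
from .model import BasisSpec, LVCModel, ModeSet, ModelValidationError

__all__ = [
    "AbInitioPoint",
    "DisplacementSet",
    "cartesian_to_mode",
    "build_lvc_one_shot",
    "build_lvc_finite_difference",
    "read_point",
    "write_point",
    "read_molden_frequencies",
    "LOW_FREQUENCY_CUTOFF_CM1",
]

LOW_FREQUENCY_CUTOFF_CM1 = 50.0


@dataclass
class AbInitioPoint:
    """Single-point electronic-structure data at the reference geometry.

    Units: geometry bohr, masses amu, frequencies cm^-1, energies Hartree,
    gradients Hartree/bohr, NAC vectors 1/bohr, SOC matrix cm^-1.
    ``gradients`` maps state index -> (n_atoms, 3); ``nacs`` maps ordered
    pairs (n, m) with n < m -> (n_atoms, 3).  Missing entries are simply
    absent from the dictionaries.
    """

    geometry: np.ndarray  # (n_atoms, 3), bohr
    masses: np.ndarray  # (n_atoms,), amu
    modes: np.ndarray  # (3*n_atoms, f) Cartesian displacements per mode
    frequencies_cm1: np.ndarray  # (f,)
    energies: np.ndarray  # (n_states,), Hartree (relative to reference)
    gradients: dict[int, np.ndarray]
    nacs: dict[tuple[int, int], np.ndarray]
    soc_cm1: np.ndarray | None = None  # (n_states, n_states) complex
    basis: BasisSpec | None = None

    def __post_init__(self):
        self.geometry = np.asarray(self.geometry, float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, float)
        self.modes = np.asarray(self.modes, float)
        self.frequencies_cm1 = np.asarray(self.frequencies_cm1, float)
        self.energies = np.asarray(self.energies, float)
        n_at = self.geometry.shape[0]
        if self.masses.shape != (n_at,):
            raise ModelValidationError("masses do not match atom count")
        if self.modes.shape[0] != 3 * n_at:
            raise ModelValidationError("mode matrix rows must equal 3*n_atoms")
        if self.modes.shape[1] != self.frequencies_cm1.size:
            raise ModelValidationError("mode matrix columns must match frequencies")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_states(self) -> int:
        return self.energies.size


@dataclass
class DisplacementSet:
    """Diabatic potential matrices at symmetric displacements.

    ``w_plus[i]`` / ``w_minus[i]`` are the Hermitian diabatic matrices at
    +delta e_i / -delta e_i (dimensionless step ``delta``) for each
    parametrized mode i.
    """

    delta: float
    w_plus: list[np.ndarray]
    w_minus: list[np.ndarray]

    def __post_init__(self):
        if self.delta <= 0:
            raise ModelValidationError("finite-difference step delta must be > 0")
        if len(self.w_plus) != len(self.w_minus):
            raise ModelValidationError("both signs required for every mode")
        for i, (wp, wm) in enumerate(zip(self.w_plus, self.w_minus)):
            for tag, w in (("+", wp), ("-", wm)):
                if not np.allclose(w, np.asarray(w).conj().T, atol=1e-10):
                    raise ModelValidationError(
                        f"W({tag}delta e_{i + 1}) is not Hermitian"
                    )


def _mass_weighted_modes(point_modes: np.ndarray, masses_amu: np.ndarray
                         ) -> np.ndarray:
    """Orthonormal mass-weighted mode matrix L (3N, f)."""
    sqm = np.sqrt(np.repeat(masses_amu * units.AMU_TO_ME, 3))
    L = point_modes * sqm[:, None]
    norms = np.linalg.norm(L, axis=0)
    if np.any(norms < 1e-12):
        raise ModelValidationError("mode matrix contains a null column")
    L = L / norms
    gram = L.T @ L
    if not np.allclose(gram, np.eye(L.shape[1]), atol=1e-6):
        raise ModelValidationError(
            "mass-weighted normal modes are not orthonormal (max deviation "
            f"{np.max(np.abs(gram - np.eye(L.shape[1]))):.2e})"
        )
    return L


def cartesian_to_mode(vectors: np.ndarray, modes: np.ndarray,
                      masses_amu: np.ndarray, frequencies_cm1: np.ndarray,
                      kind: str = "gradient") -> np.ndarray:
    """Project Cartesian per-atom vectors onto dimensionless mode coordinates.

    ``kind='displacement'`` transforms geometry displacements (bohr):
    Q_i = sqrt(omega_i) * L_i . (sqrt(m) x), so a displacement along one
    mode's Cartesian pattern of one dimensionless unit maps to a unit
    vector on that mode.  ``kind='gradient'`` transforms derivative
    vectors (Hartree/bohr or 1/bohr): v_i = (L_i . (v / sqrt(m))) /
    sqrt(omega_i), the covariant counterpart.
    """
    vec = np.asarray(vectors, float).reshape(-1)
    L = _mass_weighted_modes(modes, masses_amu)
    omega = units.cm1_to_hartree(np.asarray(frequencies_cm1, float))
    sqm = np.sqrt(np.repeat(np.asarray(masses_amu, float) * units.AMU_TO_ME, 3))
    if kind == "displacement":
        return np.sqrt(omega) * (L.T @ (sqm * vec))
    if kind == "gradient":
        return (L.T @ (vec / sqm)) / np.sqrt(omega)
    raise ValueError(f"kind must be 'displacement' or 'gradient', got {kind!r}")


def build_lvc_one_shot(point: AbInitioPoint, states: list[int] | None = None,
                       basis: BasisSpec | None = None,
                       low_freq_cutoff_cm1: float = LOW_FREQUENCY_CUTOFF_CM1,
                       ) -> LVCModel:
    """Parametrize an LVC model from a single reference-point calculation.

    Modes below ``low_freq_cutoff_cm1`` are dropped entirely (they are the
    usual source of spurious low-energy states and are poorly harmonic).
    Missing NAC pairs yield lambda = 0 with a warning; missing gradients
    are an error naming the state.
    """
    sel = list(range(point.n_states)) if states is None else list(states)
    keep = np.flatnonzero(point.frequencies_cm1 >= low_freq_cutoff_cm1)
    if keep.size < point.n_modes:
        warnings.warn(
            f"excluding {point.n_modes - keep.size} mode(s) below "
            f"{low_freq_cutoff_cm1:g} cm^-1 from parametrization",
            stacklevel=2,
        )
    if keep.size == 0:
        raise ModelValidationError("no modes remain above the frequency cutoff")
    freqs = point.frequencies_cm1[keep]
    mode_mat = point.modes[:, keep]
    modes = ModeSet(frequencies=units.cm1_to_hartree(freqs))

    n = len(sel)
    f = keep.size
    E = point.energies[sel] - point.energies[sel].min()
    kappa = np.zeros((n, f))
    for a, st in enumerate(sel):
        if st not in point.gradients:
            raise ModelValidationError(
                f"gradient missing for state {st}; cannot parametrize kappa"
            )
        kappa[a] = cartesian_to_mode(point.gradients[st], mode_mat,
                                     point.masses, freqs, kind="gradient")
    lam = np.zeros((n, n, f))
    for a in range(n):
        for b in range(a + 1, n):
            key = (min(sel[a], sel[b]), max(sel[a], sel[b]))
            if key not in point.nacs:
                warnings.warn(
                    f"NAC missing for state pair {key}; setting lambda = 0",
                    stacklevel=2,
                )
                continue
            h = cartesian_to_mode(point.nacs[key], mode_mat, point.masses,
                                  freqs, kind="gradient")
            dE = point.energies[max(sel[a], sel[b])] - point.energies[min(sel[a], sel[b])]
            lam[a, b] = lam[b, a] = dE * h
    eta = None
    if point.soc_cm1 is not None:
        soc = np.asarray(point.soc_cm1)[np.ix_(sel, sel)].astype(complex)
        eta = units.cm1_to_hartree(soc)
        np.fill_diagonal(eta, 0.0)
    if basis is None:
        basis = point.basis if point.basis is not None else BasisSpec.singlets(n)
    return LVCModel(modes=modes, basis=basis, E=E, eta=eta, kappa=kappa, lam=lam)


def build_lvc_finite_difference(disp: DisplacementSet, modes: ModeSet,
                                E_el: np.ndarray,
                                eta: np.ndarray | None = None,
                                basis: BasisSpec | None = None,
                                ) -> tuple[LVCModel, int]:
    """Parametrize kappa and lambda by central differences of W.

    Returns the model together with the number of displaced evaluations
    consumed (2 f).  Exact for LVC inputs; quadratic contamination cancels
    in the central difference.
    """
    f = modes.count
    if len(disp.w_plus) != f:
        raise ModelValidationError(
            f"displacement set covers {len(disp.w_plus)} modes, model has {f}"
        )
    E_el = np.asarray(E_el, float)
    n = E_el.size
    kappa = np.zeros((n, f))
    lam = np.zeros((n, n, f))
    for i in range(f):
        dW = (np.asarray(disp.w_plus[i]) - np.asarray(disp.w_minus[i])) / (2 * disp.delta)
        if dW.shape != (n, n):
            raise ModelValidationError(
                f"W matrices for mode {i + 1} have shape {dW.shape}, expected {(n, n)}"
            )
        kappa[:, i] = np.real(np.diag(dW))
        off = np.real(dW - np.diag(np.diag(dW)))
        lam[:, :, i] = 0.5 * (off + off.T)
    if basis is None:
        basis = BasisSpec.singlets(n)
    model = LVCModel(modes=modes, basis=basis, E=E_el, eta=eta, kappa=kappa, lam=lam)
    return model, 2 * f


# ---------------------------------------------------------------------------
# file formats


def write_point(point: AbInitioPoint, path) -> None:
    """Serialize an AbInitioPoint to the documented JSON schema."""
    d = {
        "format": "lvcdyn-point",
        "version": 1,
        "geometry_bohr": point.geometry.tolist(),
        "masses_amu": point.masses.tolist(),
        "modes": point.modes.tolist(),
        "frequencies_cm1": point.frequencies_cm1.tolist(),
        "energies": point.energies.tolist(),
        "gradients": {str(k): v.tolist() for k, v in point.gradients.items()},
        "nacs": {f"{a},{b}": v.tolist() for (a, b), v in point.nacs.items()},
    }
    if point.soc_cm1 is not None:
        d["soc_cm1_re"] = np.real(point.soc_cm1).tolist()
        d["soc_cm1_im"] = np.imag(point.soc_cm1).tolist()
    Path(path).write_text(json.dumps(d) + "\n")


def read_point(path) -> AbInitioPoint:
    d = json.loads(Path(path).read_text())
    if d.get("format") != "lvcdyn-point":
        raise ModelValidationError("not an lvcdyn point document")
    soc = None
    if "soc_cm1_re" in d:
        soc = np.asarray(d["soc_cm1_re"], float) + 1j * np.asarray(
            d.get("soc_cm1_im", np.zeros_like(d["soc_cm1_re"])), float)
    return AbInitioPoint(
        geometry=np.asarray(d["geometry_bohr"], float),
        masses=np.asarray(d["masses_amu"], float),
        modes=np.asarray(d["modes"], float),
        frequencies_cm1=np.asarray(d["frequencies_cm1"], float),
        energies=np.asarray(d["energies"], float),
        gradients={int(k): np.asarray(v, float) for k, v in d["gradients"].items()},
        nacs={tuple(map(int, k.split(","))): np.asarray(v, float)
              for k, v in d["nacs"].items()},
        soc_cm1=soc,
    )


def read_molden_frequencies(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse [FREQ], [FR-COORD] and [FR-NORM-COORD] blocks of a MOLDEN file.

    Returns (frequencies_cm1, geometry_bohr (n_atoms, 3), modes (3N, f)).
    Zero-frequency (translation/rotation) entries are dropped.
    """
    text = Path(path).read_text().splitlines()
    freqs: list[float] = []
    coords: list[list[float]] = []
    vib: list[list[float]] = []
    section = None
    current: list[float] | None = None
    for raw in text:
        s = raw.strip()
        if not s:
            continue
        low = s.lower()
        if low.startswith("["):
            if low.startswith("[freq]"):
                section = "freq"
            elif low.startswith("[fr-coord]"):
                section = "coord"
            elif low.startswith("[fr-norm-coord]"):
                section = "norm"
            else:
                section = None
            continue
        if section == "freq":
            freqs.append(float(s.split()[0]))
        elif section == "coord":
            parts = s.split()
            coords.append([float(x) for x in parts[1:4]])
        elif section == "norm":
            if low.startswith("vibration"):
                current = []
                vib.append(current)
            elif current is not None:
                current.extend(float(x) for x in s.split())
    if not freqs or not vib:
        raise ModelValidationError("no [FREQ]/[FR-NORM-COORD] data found")
    freqs_arr = np.asarray(freqs)
    modes = np.asarray(vib).T  # (3N, n_vib)
    keep = np.abs(freqs_arr) > 1e-6
    return freqs_arr[keep], np.asarray(coords), modes[:, keep]
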