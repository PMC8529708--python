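"""Parametrization from point data: round trips and finite differences."""

import numpy as np
import pytest

from lvcdyn import units
from lvcdyn.model import BasisSpec, LVCModel, ModeSet, adiabatic_point
from lvcdyn.parametrize import (
    AbInitioPoint,
    DisplacementSet,
    build_lvc_finite_difference,
    build_lvc_one_shot,
    cartesian_to_mode,
    read_molden_frequencies,
    read_point,
    write_point,
)
from lvcdyn.model import ModelValidationError
from conftest import random_lvc


def synthetic_molecule(n_atoms=3, seed=4):
    """Random masses and an orthonormal mass-weighted mode basis."""
    rng = np.random.default_rng(seed)
    masses = rng.uniform(1.0, 30.0, size=n_atoms)
    f = 3 * n_atoms - 6 if n_atoms > 2 else 3 * n_atoms - 5
    raw = rng.normal(size=(3 * n_atoms, f))
    L, _ = np.linalg.qr(raw)  # orthonormal in the mass-weighted space
    sqm = np.sqrt(np.repeat(masses * units.AMU_TO_ME, 3))
    cart_modes = L / sqm[:, None]
    freqs = np.sort(rng.uniform(300.0, 1800.0, size=f))
    return masses, cart_modes, freqs


def point_from_model(model, masses, cart_modes, freqs_cm1, seed=0):
    """Analytic gradients/NACs of a known LVC model at Q = 0, pushed back
    to Cartesian space — the inverse of the one-shot construction."""
    sqm = np.sqrt(np.repeat(masses * units.AMU_TO_ME, 3))
    omega = units.cm1_to_hartree(freqs_cm1)
    pt = adiabatic_point(model, np.zeros(model.n_modes))
    # at Q=0 adiabatic == diabatic when E values are distinct and eta = 0
    grads = {}
    nacs = {}
    for n in range(model.n_states):
        v_modes = model.kappa[n]  # dW_nn/dQ at Q=0
        # invert kind='gradient': v_i = (L_i . (vec/sqm))/sqrt(w)
        cart = (cart_modes * sqm[:, None] ** 2) @ (v_modes * np.sqrt(omega))
        grads[n] = cart.reshape(-1, 3)
    for a in range(model.n_states):
        for b in range(a + 1, model.n_states):
            dE = model.E[b] - model.E[a]
            h_modes = model.lam[a, b] / dE
            cart = (cart_modes * sqm[:, None] ** 2) @ (h_modes * np.sqrt(omega))
            nacs[(a, b)] = cart.reshape(-1, 3)
    return AbInitioPoint(
        geometry=np.zeros((masses.size, 3)),
        masses=masses,
        modes=cart_modes,
        frequencies_cm1=freqs_cm1,
        energies=model.E.copy(),
        gradients=grads,
        nacs=nacs,
    )


class TestCartesianToMode:
    def test_zero_vector_maps_to_zero(self):
        masses, cart_modes, freqs = synthetic_molecule()
        out = cartesian_to_mode(np.zeros(cart_modes.shape[0]), cart_modes,
                                masses, freqs)
        np.testing.assert_allclose(out, 0.0)

    def test_unit_mode_displacement_maps_to_basis_vector(self):
        masses, cart_modes, freqs = synthetic_molecule()
        omega = units.cm1_to_hartree(freqs)
        # Cartesian pattern of one dimensionless unit along mode 1
        x = cart_modes[:, 1] / np.sqrt(omega[1])
        q = cartesian_to_mode(x, cart_modes, masses, freqs, kind="displacement")
        expected = np.zeros(freqs.size)
        expected[1] = 1.0
        np.testing.assert_allclose(q, expected, atol=1e-10)

    def test_displacement_round_trip(self):
        masses, cart_modes, freqs = synthetic_molecule(seed=8)
        rng = np.random.default_rng(1)
        q_in = rng.normal(size=freqs.size)
        omega = units.cm1_to_hartree(freqs)
        x = cart_modes @ (q_in / np.sqrt(omega))
        q_out = cartesian_to_mode(x, cart_modes, masses, freqs,
                                  kind="displacement")
        np.testing.assert_allclose(q_out, q_in, atol=1e-10)

    def test_rejects_degenerate_mode_matrix(self):
        masses, cart_modes, freqs = synthetic_molecule()
        cart_modes = cart_modes.copy()
        cart_modes[:, 0] = cart_modes[:, 1]
        with pytest.raises(ModelValidationError):
            cartesian_to_mode(np.ones(cart_modes.shape[0]), cart_modes,
                              masses, freqs)


class TestOneShot:
    def test_zero_gradients_give_zero_kappa(self):
        masses, cart_modes, freqs = synthetic_molecule()
        model0 = random_lvc(2, freqs.size, seed=2)
        point = point_from_model(model0, masses, cart_modes, freqs)
        for k in point.gradients:
            point.gradients[k] = np.zeros_like(point.gradients[k])
        rebuilt = build_lvc_one_shot(point)
        np.testing.assert_allclose(rebuilt.kappa, 0.0, atol=1e-15)

    def test_missing_nac_warns_and_zeroes_lambda(self):
        masses, cart_modes, freqs = synthetic_molecule()
        model0 = random_lvc(2, freqs.size, seed=2)
        point = point_from_model(model0, masses, cart_modes, freqs)
        point.nacs.clear()
        with pytest.warns(UserWarning, match="NAC missing"):
            rebuilt = build_lvc_one_shot(point)
        np.testing.assert_allclose(rebuilt.lam, 0.0)

    def test_missing_gradient_names_state(self):
        masses, cart_modes, freqs = synthetic_molecule()
        model0 = random_lvc(2, freqs.size, seed=2)
        point = point_from_model(model0, masses, cart_modes, freqs)
        del point.gradients[1]
        with pytest.raises(ModelValidationError, match="state 1"):
            build_lvc_one_shot(point)

    @pytest.mark.parametrize("n_states,seed", [(2, 0), (5, 3)])
    def test_round_trip_parameter_recovery(self, n_states, seed):
        masses, cart_modes, freqs = synthetic_molecule(n_atoms=4, seed=seed)
        model0 = random_lvc(n_states, freqs.size, seed=seed)
        model0 = model0.with_(E=model0.E - model0.E.min())  # ground state at 0
        point = point_from_model(model0, masses, cart_modes, freqs)
        rebuilt = build_lvc_one_shot(point)
        np.testing.assert_allclose(rebuilt.E, model0.E, atol=1e-8)
        np.testing.assert_allclose(rebuilt.kappa, model0.kappa, atol=1e-8)
        np.testing.assert_allclose(rebuilt.lam, model0.lam, atol=1e-8)
        np.testing.assert_allclose(
            units.hartree_to_cm1(rebuilt.omega),
            freqs, atol=1e-8)

    def test_point_file_round_trip(self, tmp_path):
        masses, cart_modes, freqs = synthetic_molecule()
        model0 = random_lvc(2, freqs.size, seed=2)
        point = point_from_model(model0, masses, cart_modes, freqs)
        path = tmp_path / "point.json"
        write_point(point, path)
        back = read_point(path)
        np.testing.assert_allclose(back.modes, point.modes)
        np.testing.assert_allclose(back.gradients[0], point.gradients[0])
        np.testing.assert_allclose(back.nacs[(0, 1)], point.nacs[(0, 1)])


class TestFiniteDifference:
    @staticmethod
    def displacement_set(model, delta=0.05, quad=0.0):
        from lvcdyn.model import evaluate_potential

        wp, wm = [], []
        f = model.n_modes
        for i in range(f):
            e = np.zeros(f)
            e[i] = delta
            _, Wp = evaluate_potential(model, e)
            _, Wm = evaluate_potential(model, -e)
            if quad:
                Wp = Wp + quad * delta ** 2 * np.eye(model.n_states)
                Wm = Wm + quad * delta ** 2 * np.eye(model.n_states)
            wp.append(Wp)
            wm.append(Wm)
        return DisplacementSet(delta=delta, w_plus=wp, w_minus=wm)

    def test_exact_recovery_for_linear_potentials(self):
        model0 = random_lvc(3, 4, seed=6)
        disp = self.displacement_set(model0)
        rebuilt, n_evals = build_lvc_finite_difference(
            disp, model0.modes, model0.E, basis=model0.basis)
        assert n_evals == 8
        np.testing.assert_allclose(rebuilt.kappa, model0.kappa, atol=1e-12)
        np.testing.assert_allclose(rebuilt.lam, model0.lam, atol=1e-12)

    def test_constant_matrices_give_zero_couplings(self):
        model0 = random_lvc(2, 3, seed=1)
        W = np.diag(model0.E).astype(complex)
        disp = DisplacementSet(delta=0.05, w_plus=[W] * 3, w_minus=[W] * 3)
        rebuilt, _ = build_lvc_finite_difference(disp, model0.modes, model0.E)
        np.testing.assert_allclose(rebuilt.kappa, 0.0)
        np.testing.assert_allclose(rebuilt.lam, 0.0)

    def test_quadratic_contamination_cancels(self):
        model0 = random_lvc(2, 3, seed=5)
        disp = self.displacement_set(model0, quad=0.01)
        rebuilt, _ = build_lvc_finite_difference(disp, model0.modes, model0.E)
        np.testing.assert_allclose(rebuilt.kappa, model0.kappa, atol=1e-12)

    def test_agrees_with_one_shot_on_pure_lvc(self):
        masses, cart_modes, freqs = synthetic_molecule(seed=12)
        model0 = random_lvc(2, freqs.size, seed=12)
        point = point_from_model(model0, masses, cart_modes, freqs)
        one_shot = build_lvc_one_shot(point)
        disp = self.displacement_set(model0)
        fd, _ = build_lvc_finite_difference(disp, model0.modes, model0.E)
        np.testing.assert_allclose(one_shot.kappa, fd.kappa, atol=1e-10)
        np.testing.assert_allclose(one_shot.lam, fd.lam, atol=1e-10)


class TestMolden:
    def test_reads_frequency_blocks(self, tmp_path):
        text = """[Molden Format]
[FREQ]
0.0
523.1
1210.5
[FR-COORD]
O 0.0 0.0 0.0
H 0.0 0.0 1.8
[FR-NORM-COORD]
vibration 1
0.0 0.0 0.0
0.0 0.0 0.0
vibration 2
0.1 0.0 0.0
-0.1 0.0 0.0
vibration 3
0.0 0.1 0.0
0.0 -0.1 0.0
"""
        path = tmp_path / "freq.molden"
        path.write_text(text)
        freqs, geom, modes = read_molden_frequencies(path)
        np.testing.assert_allclose(freqs, [523.1, 1210.5])
        assert geom.shape == (2, 3)
        assert modes.shape == (6, 2)
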