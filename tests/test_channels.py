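"""Hole/particle densities, potential channels, and the ε channel.

The Coulomb part of the potential channel is cross-checked against a
real-space quadrature oracle: the electrostatic potential of the density
is evaluated in closed form per primitive Gaussian pair (erf kernels) and
the MO matrix elements are integrated numerically on a dense uniform grid
— a route fully independent of the analytic two-electron integrals.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erf

from molorbimage import (DensityMatrix, OrbitalSet, epsilon_channel,
                         effective_potential_matrix, hole_density,
                         particle_density)
from molorbimage.channels import boltzmann_weights

BETAS = (0.0, 1.0, 10.0, 100.0, 1e6)


# -- density normalization and limits ------------------------------------

class TestDensities:
    @pytest.mark.parametrize("beta", BETAS)
    def test_trace_normalization(self, pool_scf_orbitals, beta):
        """Tr(D^H S) = Tr(D^P S) = 2 for every molecule and beta."""
        for orbs in pool_scf_orbitals.values():
            s = orbs.overlap
            for dm in (hole_density(orbs, beta), particle_density(orbs, beta)):
                assert abs(np.trace(dm.matrix @ s) - 2.0) < 1e-8

    def test_large_beta_collapses_onto_homo_lumo(self, h2o_scf):
        from molorbimage.orbitals import frontier_indices
        homo, lumo = frontier_indices(h2o_scf)
        c = h2o_scf.coefficients
        dh = hole_density(h2o_scf, 1e6).matrix
        dp = particle_density(h2o_scf, 1e6).matrix
        assert np.max(np.abs(dh - 2.0 * np.outer(c[:, homo], c[:, homo]))) < 1e-10
        assert np.max(np.abs(dp - 2.0 * np.outer(c[:, lumo], c[:, lumo]))) < 1e-10

    def test_zero_beta_is_uniform_average(self, h2o_scf):
        n_occ = h2o_scf.n_occupied
        dh = hole_density(h2o_scf, 0.0).matrix
        np.testing.assert_allclose(dh, h2o_scf.ground_density() / n_occ,
                                   atol=1e-12)

    def test_single_virtual_is_beta_independent(self, h2_scf):
        c = h2_scf.coefficients[:, 1]
        for beta in (0.0, 5.0, 1e4):
            dp = particle_density(h2_scf, beta).matrix
            np.testing.assert_allclose(dp, 2.0 * np.outer(c, c), atol=1e-12)

    def test_two_level_hole_weights(self):
        """Two occupied MOs 0.1 Hartree apart at beta=10 weight as
        (1, e^-1)/(1+e^-1) = (0.7311, 0.2689)."""
        w = boltzmann_weights(np.array([-0.6, -0.5]), -0.5, 10.0, sign=-1.0)
        np.testing.assert_allclose(w, [0.2689, 0.7311], atol=1e-4)

    def test_three_virtual_particle_weights(self):
        """Virtuals at gaps (0, 0.05, 0.2) Hartree above the LUMO at
        beta=100 weight as normalized (1, e^-5, e^-20)."""
        w = boltzmann_weights(np.array([0.1, 0.15, 0.3]), 0.1, 100.0, sign=1.0)
        np.testing.assert_allclose(w, [0.99331, 0.00669, 2.04e-9],
                                   atol=1e-5)

    def test_negative_beta_rejected(self, h2_scf):
        with pytest.raises(ValueError):
            hole_density(h2_scf, -1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-2.0, 0.0), min_size=2, max_size=10,
                    unique=True),
           st.floats(0.01, 200.0))
    def test_hole_weights_monotone_in_energy_gap(self, energies, beta):
        """w_i never increases as ε_HOMO − ε_i grows (any beta > 0)."""
        eps = np.sort(np.array(energies))
        w = boltzmann_weights(eps, eps[-1], beta, sign=-1.0)
        assert np.all(np.diff(w) >= -1e-15)  # ascending ε → ascending w
        assert abs(w.sum() - 1.0) < 1e-12


# -- potential channel ----------------------------------------------------

class TestPotentialChannel:
    def test_zero_density_gives_zero_channel(self, h2o_scf):
        zero = DensityMatrix(np.zeros((h2o_scf.n_ao,) * 2), kind="ground")
        v = effective_potential_matrix(zero, h2o_scf)
        assert np.all(v.values == 0.0)

    def test_symmetric_and_nonnegative(self, h2o_scf):
        v = effective_potential_matrix(hole_density(h2o_scf, 10.0), h2o_scf)
        assert np.all(v.values >= 0.0)
        np.testing.assert_allclose(v.values, v.values.T, atol=1e-8)

    def test_phase_flip_invariance(self, h2o_scf):
        """Flipping the sign of an MO column leaves |<p|V|q>| unchanged."""
        flipped = OrbitalSet(
            coefficients=h2o_scf.coefficients * np.array(
                [(-1.0 if p == 2 else 1.0) for p in range(h2o_scf.n_mo)]),
            energies=h2o_scf.energies, occupations=h2o_scf.occupations,
            overlap=h2o_scf.overlap, n_electrons=h2o_scf.n_electrons,
            source_tag=h2o_scf.source_tag, context=h2o_scf.context)
        for orbs in (h2o_scf,):
            v0 = effective_potential_matrix(hole_density(orbs, 10.0), orbs)
            v1 = effective_potential_matrix(hole_density(flipped, 10.0), flipped)
            np.testing.assert_allclose(v0.values, v1.values, atol=1e-10)

    def test_coulomb_part_matches_grid_quadrature(self, h2_scf):
        """MO-basis Coulomb elements for H2 agree with dense-grid numerical
        integration of ∫ρ(r')|r−r'|⁻¹ within 1e-4 Hartree."""
        dm = DensityMatrix(h2_scf.ground_density(), kind="ground")
        analytic = effective_potential_matrix(dm, h2_scf,
                                              include_exchange=False).values
        numeric = _coulomb_mo_quadrature(h2_scf, dm.matrix)
        np.testing.assert_allclose(analytic, np.abs(numeric), atol=1e-4)


def _coulomb_mo_quadrature(orbitals, dm, spacing=0.15, extent=6.0):
    """Grid oracle: V_rho from closed-form Gaussian potentials (erf), outer
    integral by uniform-grid quadrature. s-type AOs only."""
    from molorbimage.integrals import ao_values
    basis = orbitals.context.basis
    centers = np.array([f.center for f in basis.functions])
    origin = centers.mean(axis=0)
    ax = np.arange(-extent, extent + spacing / 2, spacing)
    X, Y, Z = np.meshgrid(*(origin[i] + ax for i in range(3)), indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    v = np.zeros(len(pts))
    nbf = basis.n_functions
    for lam in range(nbf):
        fl = basis.functions[lam]
        assert fl.powers == (0, 0, 0)
        for mu in range(nbf):
            fm = basis.functions[mu]
            d_lm = dm[lam, mu]
            if d_lm == 0.0:
                continue
            ab2 = float(np.sum((fl.center - fm.center) ** 2))
            for ca, aa in zip(fl.coefficients, fl.exponents):
                for cb, bb in zip(fm.coefficients, fm.exponents):
                    p = aa + bb
                    q_tot = ca * cb * np.exp(-aa * bb / p * ab2) \
                        * (np.pi / p) ** 1.5
                    P = (aa * fl.center + bb * fm.center) / p
                    r = np.linalg.norm(pts - P[None, :], axis=1)
                    pot = np.where(r > 1e-10,
                                   erf(np.sqrt(p) * np.maximum(r, 1e-10)) /
                                   np.maximum(r, 1e-10),
                                   2.0 * np.sqrt(p / np.pi))
                    v += d_lm * q_tot * pot
    ao = ao_values(basis, pts)
    mo = orbitals.coefficients.T @ ao
    h3 = spacing ** 3
    return h3 * np.einsum("pg,g,qg->pq", mo, v, mo, optimize=True)


# -- epsilon channel ------------------------------------------------------

class TestEpsilonChannel:
    def test_diagonal_values_and_bitwise_zero_offdiagonals(self):
        orbs = _synthetic_orbitals([-0.5, -0.3, 0.1, 0.4], [2, 2, 0, 0])
        ch = epsilon_channel(orbs, np.arange(4))
        np.testing.assert_array_equal(np.diag(ch.values),
                                      [-0.5, -0.3, 0.1, 0.4])
        off = ch.values[~np.eye(4, dtype=bool)]
        assert np.all(off == 0.0)  # bitwise

    def test_degenerate_permutation_invariance(self):
        """Swapping a 2-fold degenerate pair leaves the channel unchanged
        (brute force over both orderings)."""
        for order in ([0, 1, 2, 3], [0, 2, 1, 3]):
            orbs = _synthetic_orbitals(
                np.array([-0.5, -0.3, -0.3, 0.4])[order].tolist(),
                [2, 2, 2, 0])
            ch = epsilon_channel(orbs, np.arange(4))
            np.testing.assert_array_equal(np.diag(ch.values),
                                          [-0.5, -0.3, -0.3, 0.4])

    def test_empty_window_rejected(self, h2_scf):
        with pytest.raises(ValueError):
            epsilon_channel(h2_scf, np.arange(0))


def _synthetic_orbitals(energies, occupations):
    n = len(energies)
    return OrbitalSet(coefficients=np.eye(n),
                      energies=np.array(energies, dtype=float),
                      occupations=np.array(occupations, dtype=float),
                      overlap=np.eye(n), n_electrons=int(sum(occupations)),
                      source_tag="tight_binding")
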