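"""Restricted SCF driver, atomic densities, and the SAD orbital source.

Two orbital sources live here:

``run_scf``
    Conventional restricted self-consistent-field calculation (DIIS
    accelerated) with a hybrid-exchange effective potential.

``sad_guess``
    Superposition of atomic densities promoted to an orbital source: a
    block-diagonal guess density D0 is assembled from converged,
    spherically-averaged atomic densities, one Fock matrix is built at D0
    and diagonalized once — no further iteration.

The supported effective potential is the hybrid exact-exchange family

    V_eff[D] = J[D] − ½·x_HF·K[D]

with x_HF = 1 ("hf", the default). Semilocal exchange–correlation terms
are outside this backend; ``exchange_fraction``/``include_exchange`` expose
the exchange term for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .basis import BasisSet, build_basis
from .integrals import IntegralContext
from .molecule import Molecule
from .orbitals import OrbitalSet

__all__ = ["run_scf", "sad_guess", "atomic_density", "SCFResult",
           "effective_potential", "exchange_fraction_for"]

_FUNCTIONALS = {
    # name -> exact-exchange fraction of the hybrid effective potential
    "hf": 1.0,
    "rhf": 1.0,
}


def exchange_fraction_for(functional: str) -> float:
    key = functional.strip().lower()
    if key not in _FUNCTIONALS:
        raise ValueError(
            f"functional {functional!r} is not supported; available: "
            f"{sorted(set(_FUNCTIONALS))} (hybrid exact-exchange family)")
    return _FUNCTIONALS[key]


def effective_potential(context: IntegralContext, dm: np.ndarray,
                        functional: str = "hf",
                        include_exchange: bool = True) -> np.ndarray:
    """AO-basis effective potential V_eff[D] = J[D] − ½·x·K[D]."""
    x = exchange_fraction_for(functional)
    v = context.coulomb(dm)
    if include_exchange and x != 0.0:
        v = v - 0.5 * x * context.exchange(dm)
    return v


class SCFConvergenceError(RuntimeError):
    def __init__(self, cycles: int, error: float):
        super().__init__(
            f"SCF did not converge in {cycles} cycles (DIIS error {error:.2e})")
        self.cycles = cycles


@dataclass
class SCFResult:
    orbitals: OrbitalSet
    energy: float          # total electronic + nuclear energy, Hartree
    n_cycles: int
    converged: bool


def _solve_fock(fock: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Generalized symmetric eigenproblem F C = S C ε (ascending, stable)."""
    energies, coeffs = scipy.linalg.eigh(fock, s)
    return energies, coeffs


def _aufbau_fractional(energies: np.ndarray, n_electrons: float,
                       degeneracy_tol: float = 1e-6) -> np.ndarray:
    """Fill electrons bottom-up, averaging over (near-)degenerate groups.

    Isolated open-shell atoms get spherically symmetric densities this way
    (e.g. oxygen's 2p shell carries 4/3 electrons per component).
    """
    n_mo = len(energies)
    occ = np.zeros(n_mo)
    remaining = float(n_electrons)
    i = 0
    while i < n_mo and remaining > 1e-12:
        j = i + 1
        while j < n_mo and energies[j] - energies[j - 1] < degeneracy_tol:
            j += 1
        g = j - i
        fill = min(remaining, 2.0 * g)
        occ[i:j] = fill / g
        remaining -= fill
        i = j
    if remaining > 1e-12:
        raise ValueError("more electrons than basis functions can hold")
    return occ


def _scf_loop(context: IntegralContext, n_electrons: float, functional: str,
              fractional: bool, max_cycles: int, conv_tol: float
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int]:
    s = context.overlap()
    hcore = context.core_hamiltonian()
    # Core-Hamiltonian start
    energies, coeffs = _solve_fock(hcore, s)
    occ = _aufbau_fractional(energies, n_electrons) if fractional else \
        _aufbau_closed_shell(energies, n_electrons)
    dm = (coeffs * occ) @ coeffs.T
    diis_focks: list[np.ndarray] = []
    diis_errs: list[np.ndarray] = []
    last_energy = 0.0
    for cycle in range(1, max_cycles + 1):
        fock = hcore + effective_potential(context, dm, functional)
        err = fock @ dm @ s - s @ dm @ fock
        diis_focks.append(fock)
        diis_errs.append(err)
        if len(diis_focks) > 8:
            diis_focks.pop(0)
            diis_errs.pop(0)
        if len(diis_focks) > 1:
            fock = _diis_extrapolate(diis_focks, diis_errs)
        energies, coeffs = _solve_fock(fock, s)
        occ = _aufbau_fractional(energies, n_electrons) if fractional else \
            _aufbau_closed_shell(energies, n_electrons)
        dm_new = (coeffs * occ) @ coeffs.T
        e_elec = 0.5 * float(np.sum(dm_new * (hcore + fock)))
        delta_d = np.max(np.abs(dm_new - dm))
        delta_e = abs(e_elec - last_energy)
        dm, last_energy = dm_new, e_elec
        if delta_d < conv_tol and delta_e < conv_tol and cycle > 2:
            return energies, coeffs, occ, e_elec, cycle
    raise SCFConvergenceError(max_cycles, float(np.max(np.abs(diis_errs[-1]))))


def _aufbau_closed_shell(energies: np.ndarray, n_electrons: float) -> np.ndarray:
    n = int(round(n_electrons))
    if n % 2 != 0:
        raise ValueError("closed-shell filling needs an even electron count")
    occ = np.zeros(len(energies))
    occ[: n // 2] = 2.0
    return occ


def _diis_extrapolate(focks: list[np.ndarray], errs: list[np.ndarray]) -> np.ndarray:
    n = len(focks)
    b = -np.ones((n + 1, n + 1))
    b[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            b[i, j] = float(np.sum(errs[i] * errs[j]))
    rhs = np.zeros(n + 1)
    rhs[n] = -1.0
    try:
        coef = np.linalg.solve(b, rhs)[:n]
    except np.linalg.LinAlgError:
        return focks[-1]
    return sum(c * f for c, f in zip(coef, focks))


def run_scf(molecule: Molecule, basis: str | BasisSet = "STO-3G",
            functional: str = "hf", max_cycles: int = 100,
            conv_tol: float = 1e-10) -> OrbitalSet:
    """Converged restricted-SCF orbitals for a closed-shell molecule."""
    molecule.require_closed_shell()
    bas = basis if isinstance(basis, BasisSet) else build_basis(molecule, basis)
    context = IntegralContext(molecule, bas)
    energies, coeffs, occ, e_elec, cycles = _scf_loop(
        context, molecule.n_electrons, functional, fractional=False,
        max_cycles=max_cycles, conv_tol=conv_tol)
    orbs = OrbitalSet(coefficients=coeffs, energies=energies, occupations=occ,
                      overlap=context.overlap(),
                      n_electrons=molecule.n_electrons,
                      source_tag="scf_converged", context=context,
                      molecule_id=molecule.name)
    orbs.total_energy = e_elec + molecule.nuclear_repulsion()
    orbs.n_cycles = cycles
    return orbs


def scf_total_energy(molecule: Molecule, basis: str | BasisSet = "STO-3G",
                     functional: str = "hf") -> float:
    return run_scf(molecule, basis, functional).total_energy


# -- SAD ------------------------------------------------------------------

_ATOMIC_DENSITY_CACHE: dict[tuple[str, str, str], np.ndarray] = {}


def atomic_density(symbol: str, basis_name: str = "STO-3G",
                   functional: str = "hf") -> np.ndarray:
    """Converged spherically-averaged density of a neutral isolated atom.

    Restricted SCF with fractional occupation over degenerate shells; the
    result is cached by (element, basis, functional).
    """
    key = (symbol, basis_name.strip().lower(), functional.strip().lower())
    if key in _ATOMIC_DENSITY_CACHE:
        return _ATOMIC_DENSITY_CACHE[key]
    atom = Molecule([symbol], np.zeros((1, 3)), name=symbol)
    bas = build_basis(atom, basis_name)
    context = IntegralContext(atom, bas)
    energies, coeffs, occ, _, _ = _scf_loop(
        context, atom.n_electrons, functional, fractional=True,
        max_cycles=200, conv_tol=1e-10)
    dm = (coeffs * occ) @ coeffs.T
    _ATOMIC_DENSITY_CACHE[key] = dm
    return dm


def sad_guess(molecule: Molecule, basis: str | BasisSet = "STO-3G",
              functional: str = "hf") -> OrbitalSet:
    """Superposition-of-atomic-densities orbitals via one diagonalization.

    Builds the block-diagonal guess density D0 from converged atomic
    densities, assembles F = H_core + V_eff[D0] with the named hybrid
    functional, solves F C = S C ε once, and occupies by aufbau. The
    returned occupied orbitals define an idempotent closed-shell density
    even though D0 itself is not idempotent.
    """
    molecule.require_closed_shell()
    basis_name = basis if isinstance(basis, str) else basis.name
    bas = basis if isinstance(basis, BasisSet) else build_basis(molecule, basis)
    context = IntegralContext(molecule, bas)
    nbf = bas.n_functions
    d0 = np.zeros((nbf, nbf))
    for sl, symbol in zip(bas.atom_slices(molecule.n_atoms), molecule.symbols):
        d0[sl, sl] = atomic_density(symbol, basis_name, functional)
    fock = context.core_hamiltonian() + effective_potential(context, d0, functional)
    energies, coeffs = _solve_fock(fock, context.overlap())
    occ = _aufbau_closed_shell(energies, molecule.n_electrons)
    return OrbitalSet(coefficients=coeffs, energies=energies, occupations=occ,
                      overlap=context.overlap(),
                      n_electrons=molecule.n_electrons, source_tag="sad_guess",
                      context=context, molecule_id=molecule.name)
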