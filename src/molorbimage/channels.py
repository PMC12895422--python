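"""The ε, V^H and V^P channels of the MolOrbImage descriptor.

The hole and particle densities are Boltzmann-weighted sums over occupied
and virtual MOs,

    D^H = Σ_i 2 C_i C_iᵀ · w_i,   w_i ∝ exp[−β (ε_HOMO − ε_i)],
    D^P = Σ_a 2 C_a C_aᵀ · w_a,   w_a ∝ exp[ β (ε_LUMO − ε_a)],

with the weights normalized to one, so Tr(D S) = 2 for both. The inverse
temperature β (Hartree⁻¹) steers how sharply the densities concentrate on
the frontier orbitals: β → ∞ collapses them onto HOMO/LUMO, β = 0 averages
uniformly over the whole occupied/virtual space.

The V channels are |⟨p|V_eff[D]|q⟩| with the hybrid-exchange effective
potential evaluated at D^H / D^P; the ε channel is the diagonal matrix of
MO energies. All values are in Hartree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .orbitals import OrbitalSet, frontier_indices
from .scf import effective_potential

__all__ = ["DensityMatrix", "ChannelMatrix", "hole_density",
           "particle_density", "effective_potential_matrix",
           "epsilon_channel", "boltzmann_weights"]

DENSITY_KINDS = ("hole", "particle", "ground")
CHANNEL_NAMES = ("epsilon", "v_hole", "v_particle", "v_ground")


@dataclass
class DensityMatrix:
    """An AO-basis symmetric density with provenance tag."""

    matrix: np.ndarray
    kind: str
    beta: Optional[float] = None  # Hartree^-1; absent for ground densities

    def __post_init__(self) -> None:
        if self.kind not in DENSITY_KINDS:
            raise ValueError(f"unknown density kind {self.kind!r}")
        self.matrix = np.asarray(self.matrix, dtype=float)
        asym = np.max(np.abs(self.matrix - self.matrix.T))
        if asym > 1e-10:
            raise ValueError(f"density not symmetric (max asymmetry {asym:.2e})")


@dataclass
class ChannelMatrix:
    """An N×N non-negative matrix for one channel, values in Hartree."""

    values: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.values = np.asarray(self.values, dtype=float)


def boltzmann_weights(energies: np.ndarray, reference: float, beta: float,
                      sign: float) -> np.ndarray:
    """Normalized exp[sign·β·(reference − ε)] with the max-shift trick.

    ``sign=-1`` with reference ε_HOMO gives hole weights; ``sign=+1`` with
    reference ε_LUMO gives particle weights. Weights below 1e-300 flush to
    exact zero.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    arg = sign * beta * (reference - energies)
    arg = arg - np.max(arg)
    w = np.exp(arg)
    w[w < 1e-300] = 0.0
    return w / w.sum()


def hole_density(orbitals: OrbitalSet, beta: float) -> DensityMatrix:
    """Boltzmann-weighted hole density D^H (Tr(D^H S) = 2)."""
    homo, _ = frontier_indices(orbitals)
    occ_idx = np.arange(homo + 1)
    w = boltzmann_weights(orbitals.energies[occ_idx],
                          orbitals.energies[homo], beta, sign=-1.0)
    c = orbitals.coefficients[:, occ_idx]
    dm = 2.0 * (c * w) @ c.T
    return DensityMatrix(matrix=dm, kind="hole", beta=beta)


def particle_density(orbitals: OrbitalSet, beta: float) -> DensityMatrix:
    """Boltzmann-weighted particle density D^P (Tr(D^P S) = 2)."""
    _, lumo = frontier_indices(orbitals)
    if lumo is None:
        raise ValueError("no virtual orbitals: particle density undefined")
    virt_idx = np.arange(lumo, orbitals.n_mo)
    w = boltzmann_weights(orbitals.energies[virt_idx],
                          orbitals.energies[lumo], beta, sign=+1.0)
    c = orbitals.coefficients[:, virt_idx]
    dm = 2.0 * (c * w) @ c.T
    return DensityMatrix(matrix=dm, kind="particle", beta=beta)


def effective_potential_matrix(density: DensityMatrix, orbitals: OrbitalSet,
                               functional: str = "hf",
                               include_exchange: bool = True) -> ChannelMatrix:
    """MO-basis potential channel V_pq = |⟨p|V_eff[D]|q⟩| over all MOs.

    The effective potential is Coulomb plus the hybrid's scaled exact
    exchange evaluated at the given density; ``include_exchange=False``
    drops the exchange term (Coulomb-only ablation, also the hook for the
    grid-quadrature oracle). Output is symmetric and entrywise non-negative.
    """
    if orbitals.context is None:
        raise ValueError("OrbitalSet carries no integral context")
    if density.matrix.shape != (orbitals.n_ao, orbitals.n_ao):
        raise ValueError("density and orbitals do not share one AO basis")
    v_ao = effective_potential(orbitals.context, density.matrix, functional,
                               include_exchange=include_exchange)
    c = orbitals.coefficients
    v_mo = np.abs(c.T @ v_ao @ c)
    v_mo = 0.5 * (v_mo + v_mo.T)  # symmetrize away eigensolver round-off
    kind = {"hole": "v_hole", "particle": "v_particle",
            "ground": "v_ground"}[density.kind]
    return ChannelMatrix(values=v_mo, channel=kind)


def epsilon_channel(orbitals: OrbitalSet,
                    window: np.ndarray | slice | None = None) -> ChannelMatrix:
    """Diagonal matrix of MO energies over ``window`` (off-diagonals exact 0)."""
    if window is None:
        window = np.arange(orbitals.n_mo)
    eps = orbitals.energies[window]
    if eps.size == 0:
        raise ValueError("empty MO window")
    return ChannelMatrix(values=np.diag(eps), channel="epsilon")
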