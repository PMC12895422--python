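"""The OrbitalSet container — common currency of all orbital sources."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["OrbitalSet", "frontier_indices"]

SOURCE_TAGS = ("scf_converged", "sad_guess", "tight_binding")


@dataclass
class OrbitalSet:
    """Molecular orbitals from any source behind one uniform contract.

    Attributes
    ----------
    coefficients : (n_ao, n_mo) array
        MO coefficients C_{λp}, columns S-orthonormal.
    energies : (n_mo,) array
        MO energies ε_p in Hartree, ascending (stable order within
        degeneracies, as delivered by the eigensolver).
    occupations : (n_mo,) array
        0 or 2 per MO (closed shell).
    overlap : (n_ao, n_ao) array
        AO overlap matrix S.
    n_electrons : int
        Electrons represented: all-electron for SCF/SAD sources,
        valence-only for tight-binding MOLDEN files.
    source_tag : str
        One of ``scf_converged``, ``sad_guess``, ``tight_binding``.
    context : optional
        The :class:`~molorbimage.integrals.IntegralContext` that can build
        Coulomb/exchange matrices in this AO basis (needed by the potential
        channels).
    """

    coefficients: np.ndarray
    energies: np.ndarray
    occupations: np.ndarray
    overlap: np.ndarray
    n_electrons: int
    source_tag: str
    context: Optional[object] = None
    molecule_id: str = field(default="")

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.occupations = np.asarray(self.occupations, dtype=float)
        self.overlap = np.asarray(self.overlap, dtype=float)
        if self.source_tag not in SOURCE_TAGS:
            raise ValueError(f"unknown source_tag {self.source_tag!r}")

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_ao(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_mo(self) -> int:
        return self.coefficients.shape[1]

    @property
    def n_occupied(self) -> int:
        return int(np.sum(self.occupations > 0))

    @property
    def n_virtual(self) -> int:
        return self.n_mo - self.n_occupied

    def ground_density(self) -> np.ndarray:
        """D0_{λμ} = Σ_p f_p C_{λp} C_{μp}."""
        return (self.coefficients * self.occupations) @ self.coefficients.T

    # -- invariants -------------------------------------------------------

    def validate(self, tol: float = 1e-8) -> None:
        """Check the OrbitalSet contract; raise ValueError on violation."""
        c, s = self.coefficients, self.overlap
        ortho = c.T @ s @ c
        err = np.max(np.abs(ortho - np.eye(self.n_mo)))
        if err > tol:
            raise ValueError(f"MO orthonormality violated: max|C'SC - I| = {err:.3e}")
        if np.any(np.diff(self.energies) < -1e-10):
            raise ValueError("MO energies are not ascending")
        if abs(float(np.sum(self.occupations)) - self.n_electrons) > 1e-8:
            raise ValueError("sum of occupations does not equal n_electrons")
        occ = self.occupations > 0
        if occ.any() and not np.all(occ[: int(occ.sum())]):
            raise ValueError("occupations are not aufbau-contiguous")


def frontier_indices(orbitals: OrbitalSet) -> tuple[int, Optional[int]]:
    """HOMO and LUMO indices (0-based).

    The HOMO is the highest-energy occupied MO under the stable ascending
    ordering; the LUMO is the next MO, or ``None`` when every MO is occupied
    (image assembly then zero-pads the whole particle block).
    """
    occ = np.flatnonzero(orbitals.occupations > 0)
    if len(occ) == 0:
        raise ValueError("no occupied orbitals")
    homo = int(occ[-1])
    lumo = homo + 1 if homo + 1 < orbitals.n_mo else None
    return homo, lumo
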