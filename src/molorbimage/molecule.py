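"""Molecular geometries.

Coordinates are stored in Ångström (the XYZ convention) and converted to
Bohr only inside the integral engine. Only closed-shell molecules
(spin multiplicity 1) are accepted downstream: the hole/particle density
formulas carry a restricted-spin factor of 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ANGSTROM_TO_BOHR = 1.8897259886
HARTREE_TO_EV = 27.2114

#: Atomic numbers for the elements the built-in basis table covers (H–Ne),
#: plus a few more so XYZ files parse with a clear downstream error instead
#: of a KeyError here.
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}


@dataclass
class Molecule:
    """A molecular geometry with charge and spin state.

    Parameters
    ----------
    symbols : list of str
        Element symbols, one per atom.
    coordinates : (n_atoms, 3) array
        Cartesian positions in Ångström.
    charge : int
        Net charge.
    spin_multiplicity : int
        2S+1; must be 1 for every orbital source in this package.
    """

    symbols: list[str]
    coordinates: np.ndarray
    charge: int = 0
    spin_multiplicity: int = 1
    name: str = field(default="")

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.symbols) == 0:
            raise ValueError("molecule must contain at least one atom")
        if self.coordinates.shape != (len(self.symbols), 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{len(self.symbols)} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        unknown = [s for s in self.symbols if s not in ATOMIC_NUMBERS]
        if unknown:
            raise ValueError(f"unknown element symbols: {unknown}")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.symbols], dtype=int)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    @property
    def coordinates_bohr(self) -> np.ndarray:
        return self.coordinates * ANGSTROM_TO_BOHR

    def require_closed_shell(self) -> None:
        if self.spin_multiplicity != 1:
            raise ValueError(
                "open-shell molecules are not supported (restricted-spin "
                "hole/particle densities require multiplicity 1)"
            )
        if self.n_electrons % 2 != 0:
            raise ValueError(
                f"odd electron count ({self.n_electrons}) is not closed-shell"
            )

    def nuclear_repulsion(self) -> float:
        """Nuclear–nuclear repulsion energy in Hartree."""
        z = self.atomic_numbers.astype(float)
        r = self.coordinates_bohr
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e

    # -- XYZ I/O ----------------------------------------------------------

    @classmethod
    def from_xyz(cls, path: str | Path, charge: int = 0,
                 spin_multiplicity: int = 1) -> "Molecule":
        """Read a single-geometry XYZ file (Ångström)."""
        lines = Path(path).read_text().splitlines()
        n = int(lines[0].split()[0])
        name = lines[1].strip()
        symbols, coords = [], []
        for line in lines[2:2 + n]:
            parts = line.split()
            symbols.append(parts[0].capitalize())
            coords.append([float(x) for x in parts[1:4]])
        return cls(symbols, np.array(coords), charge=charge,
                   spin_multiplicity=spin_multiplicity, name=name)

    def to_xyz(self, path: str | Path) -> None:
        lines = [str(self.n_atoms), self.name]
        for s, (x, y, z) in zip(self.symbols, self.coordinates):
            lines.append(f"{s:<3s} {x:18.12f} {y:18.12f} {z:18.12f}")
        Path(path).write_text("\n".join(lines) + "\n")
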