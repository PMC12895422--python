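"""MOLDEN orbital file I/O.

Tight-binding orbitals enter the pipeline as MOLDEN files written by an
external code (e.g. ``xtb``). The reader takes the basis verbatim from the
``[GTO]`` section, recomputes the AO overlap in that basis with the
package's own integral engine, and re-checks MO orthonormality and the
electron count — a failed check raises a dialect-mismatch error instead
of being silently ignored.

Dialect: s and p shells (and Cartesian d); contraction coefficients refer
to normalized primitives, p components ordered x, y, z. Files carrying
spherical-harmonic d/f sections ([5D]/[7F]) are rejected explicitly, as are
files without occupation numbers. Occupations are kept as stored, so a
valence-only tight-binding file yields a valence-only electron count.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .basis import BasisSet, Shell, SHELL_L, SHELL_LETTERS
from .integrals import IntegralContext
from .molecule import ANGSTROM_TO_BOHR, Molecule
from .orbitals import OrbitalSet

__all__ = ["read_molden", "write_molden"]


class MoldenError(ValueError):
    """Malformed or unsupported MOLDEN content."""


def write_molden(orbitals: OrbitalSet, path: str | Path,
                 title: str = "molorbimage") -> None:
    """Write an OrbitalSet (with its molecule/basis context) to MOLDEN."""
    if orbitals.context is None:
        raise ValueError("OrbitalSet has no integral context to serialize")
    mol: Molecule = orbitals.context.molecule
    basis: BasisSet = orbitals.context.basis
    lines = ["[Molden Format]", "[Title]", f" {title}", "[Atoms] Angs"]
    for i, (sym, xyz) in enumerate(zip(mol.symbols, mol.coordinates), start=1):
        z = mol.atomic_numbers[i - 1]
        lines.append(f"{sym:<3s} {i:4d} {z:4d} "
                     f"{xyz[0]:18.12f} {xyz[1]:18.12f} {xyz[2]:18.12f}")
    lines.append("[GTO]")
    for ia in range(mol.n_atoms):
        lines.append(f"  {ia + 1} 0")
        for shell in basis.shells:
            if shell.atom_index != ia:
                continue
            lines.append(f" {SHELL_LETTERS[shell.l]} {len(shell.exponents):3d} 1.00")
            for e, c in zip(shell.exponents, shell.coefficients):
                lines.append(f"  {e:20.10e} {c:20.10e}")
        lines.append("")
    lines.append("[MO]")
    for p in range(orbitals.n_mo):
        lines.append(" Sym= A")
        lines.append(f" Ene= {orbitals.energies[p]:.12e}")
        lines.append(" Spin= Alpha")
        lines.append(f" Occup= {orbitals.occupations[p]:.8f}")
        for mu in range(orbitals.n_ao):
            lines.append(f" {mu + 1:4d} {orbitals.coefficients[mu, p]:20.12e}")
    Path(path).write_text("\n".join(lines) + "\n")


def _split_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.rstrip()
        stripped = line.strip()
        if stripped.startswith("["):
            tag = stripped[1:stripped.index("]")].lower()
            current = tag
            sections[current] = [stripped[stripped.index("]") + 1:].strip()]
        elif current is not None:
            sections[current].append(line)
    return sections


def read_molden(path: str | Path, check_tol: float = 1e-6) -> OrbitalSet:
    """Parse a MOLDEN file into a tight-binding-tagged OrbitalSet.

    The AO overlap is computed from the declared basis; the MO set is
    checked for S-orthonormality (tolerance 1e-6 on |C'SC − I|) and the
    trace condition Tr(D S) = Σ occupations within ``check_tol``.
    """
    text = Path(path).read_text()
    sections = _split_sections(text)
    for bad in ("5d", "7f", "5d7f", "5d10f", "9g"):
        if bad in sections:
            raise MoldenError(
                "spherical-harmonic shells ([5D]/[7F]) are not supported; "
                "re-export with Cartesian functions")
    if "atoms" not in sections or "gto" not in sections or "mo" not in sections:
        raise MoldenError("missing [Atoms], [GTO] or [MO] section")

    unit = sections["atoms"][0].strip().lower()
    to_angstrom = 1.0 if unit.startswith("angs") else 1.0 / ANGSTROM_TO_BOHR
    symbols, coords = [], []
    for line in sections["atoms"][1:]:
        parts = line.split()
        if len(parts) < 6:
            continue
        symbols.append(parts[0].capitalize())
        coords.append([float(x) * to_angstrom for x in parts[3:6]])
    if not symbols:
        raise MoldenError("no atoms parsed")
    molecule = Molecule(symbols, np.array(coords), name=Path(path).stem)

    shells = _parse_gto(sections["gto"], molecule)
    basis = BasisSet(shells=shells, name="molden_declared")
    context = IntegralContext(molecule, basis)
    s = context.overlap()

    energies, occupations, columns = _parse_mo(sections["mo"], basis.n_functions)
    order = np.argsort(energies, kind="stable")
    energies = energies[order]
    occupations = occupations[order]
    coeffs = np.stack(columns, axis=1)[:, order]

    n_electrons = float(np.sum(occupations))
    if abs(n_electrons - round(n_electrons)) > 1e-6:
        raise MoldenError(f"non-integer total occupation {n_electrons}")
    orbs = OrbitalSet(coefficients=coeffs, energies=energies,
                      occupations=occupations, overlap=s,
                      n_electrons=int(round(n_electrons)),
                      source_tag="tight_binding", context=context,
                      molecule_id=molecule.name)
    dm = orbs.ground_density()
    tr = float(np.trace(dm @ s))
    if abs(tr - orbs.n_electrons) > check_tol:
        raise MoldenError(
            f"Tr(D S) = {tr:.8f} differs from the stored electron count "
            f"{orbs.n_electrons} beyond {check_tol:g}: basis-dialect mismatch")
    ortho_err = float(np.max(np.abs(coeffs.T @ s @ coeffs - np.eye(orbs.n_mo))))
    if ortho_err > 1e-4:
        raise MoldenError(
            f"MOs are not orthonormal in the declared basis "
            f"(max deviation {ortho_err:.2e}): basis-dialect mismatch")
    return orbs


def _parse_gto(lines: list[str], molecule: Molecule) -> list[Shell]:
    shells: list[Shell] = []
    coords = molecule.coordinates_bohr
    i = 1  # skip the tag-line remainder
    n = len(lines)
    while i < n:
        stripped = lines[i].strip()
        if not stripped:
            i += 1
            continue
        parts = stripped.split()
        atom_index = int(parts[0]) - 1
        if atom_index < 0 or atom_index >= molecule.n_atoms:
            raise MoldenError(f"GTO block references atom {parts[0]}")
        i += 1
        while i < n and lines[i].strip():
            head = lines[i].split()
            letter = head[0].lower()
            if letter not in SHELL_L:
                raise MoldenError(f"unsupported shell type {head[0]!r}")
            nprim = int(head[1])
            exps, coefs = [], []
            for k in range(nprim):
                i += 1
                e_str, c_str = lines[i].split()[:2]
                exps.append(float(e_str.replace("D", "E").replace("d", "e")))
                coefs.append(float(c_str.replace("D", "E").replace("d", "e")))
            shells.append(Shell(SHELL_L[letter], np.array(exps),
                                np.array(coefs), coords[atom_index].copy(),
                                atom_index))
            i += 1
    if not shells:
        raise MoldenError("no shells parsed from [GTO]")
    return shells


def _parse_mo(lines: list[str], n_ao: int
              ) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    energies: list[float] = []
    occupations: list[float] = []
    columns: list[np.ndarray] = []
    current: np.ndarray | None = None
    has_occup = False
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        low = stripped.lower()
        if low.startswith("sym="):
            continue
        if low.startswith("ene="):
            current = np.zeros(n_ao)
            columns.append(current)
            energies.append(float(stripped.split("=")[1]))
            occupations.append(np.nan)
        elif low.startswith("spin="):
            if "beta" in low:
                raise MoldenError("unrestricted (beta-spin) files not supported")
        elif low.startswith("occup="):
            occupations[-1] = float(stripped.split("=")[1])
            has_occup = True
        else:
            parts = stripped.split()
            if current is None or len(parts) < 2:
                raise MoldenError(f"unparseable [MO] line: {line!r}")
            current[int(parts[0]) - 1] = float(parts[1])
    if not columns:
        raise MoldenError("no MOs parsed")
    if not has_occup or np.any(np.isnan(occupations)):
        raise MoldenError("occupation numbers missing — refusing to guess")
    return np.array(energies), np.array(occupations), columns
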