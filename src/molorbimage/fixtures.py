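"""Desk-scale fixture generation: toy molecules, orbitals, surrogate targets.

Stands in for the large external quantum-chemistry datasets: a pool of
small closed-shell species is geometry-jittered, orbitals are produced by
a chosen source, images are assembled, and six surrogate excited-state
targets are derived from the frontier-orbital gap,

    E_Sn = a_n · (ε_LUMO − ε_HOMO) · 27.2114 + b_n + noise,
    E_Tn = E_Sn(noiseless) − g_n + noise,          g_n > 0,

so the targets are learnable from the images (the gap sits in the central
ε pixels), singlet lies above triplet in expectation, and the
perturbation machinery has a known dominant feature. The surrogate form
is an artifact of the test harness, not a physical excitation model; its
coefficients are chosen so typical targets land in the 2–10 eV window of
real low-lying excitations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image import ImageDataset, assemble_image
from .molecule import HARTREE_TO_EV, Molecule
from .orbitals import OrbitalSet, frontier_indices
from .scf import run_scf, sad_guess

__all__ = ["FixtureSpec", "generate_fixtures", "MOLECULE_POOL",
           "DEFAULT_TRAIN_POOL", "pool_molecule", "surrogate_targets"]

#: Reference geometries (Å) of the closed-shell fixture pool.
MOLECULE_POOL: dict[str, tuple[tuple[str, ...], list]] = {
    "H2": (("H", "H"), [[0, 0, 0], [0, 0, 0.74]]),
    "He": (("He",), [[0, 0, 0]]),
    "LiH": (("Li", "H"), [[0, 0, 0], [0, 0, 1.595]]),
    "HF": (("H", "F"), [[0, 0, 0], [0, 0, 0.917]]),
    "H2O": (("O", "H", "H"),
            [[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692],
             [0.0, -0.7572, -0.4692]]),
    "NH3": (("N", "H", "H", "H"),
            [[0.0, 0.0, 0.1173], [0.0, 0.9377, -0.2737],
             [0.8121, -0.4689, -0.2737], [-0.8121, -0.4689, -0.2737]]),
    "CH2O": (("C", "O", "H", "H"),
             [[0, 0, 0], [0, 0, 1.205], [0.943, 0, -0.587],
              [-0.943, 0, -0.587]]),
    "C2H4": (("C", "C", "H", "H", "H", "H"),
             [[0, 0, 0.667], [0, 0, -0.667], [0, 0.923, 1.238],
              [0, -0.923, 1.238], [0, 0.923, -1.238], [0, -0.923, -1.238]]),
}

#: Species used for dataset generation by default: light (fast integrals)
#: and all with at least one virtual orbital in the minimal basis, which
#: the surrogate targets require. He (no STO-3G virtual) stays available
#: for boundary-condition tests.
DEFAULT_TRAIN_POOL = ("H2", "LiH", "HF", "H2O", "NH3")


def pool_molecule(name: str) -> Molecule:
    symbols, coords = MOLECULE_POOL[name]
    return Molecule(list(symbols), np.array(coords, dtype=float), name=name)


@dataclass
class FixtureSpec:
    """Everything that determines a fixture dataset (seed-reproducible)."""

    n_molecules: int = 16
    molecule_pool: tuple[str, ...] = DEFAULT_TRAIN_POOL
    beta: float = 10.0            # Hartree^-1
    n_mo: int = 8
    orbital_source: str = "sad"   # scf | sad
    basis: str = "STO-3G"
    functional: str = "hf"
    jitter_sigma: float = 0.02    # Å, per Cartesian component
    jitter_max: float = 0.05      # Å, hard clip
    target_slopes: tuple[float, float, float] = (0.20, 0.22, 0.24)
    target_offsets: tuple[float, float, float] = (1.0, 1.5, 2.0)   # eV
    singlet_triplet_gaps: tuple[float, float, float] = (0.5, 0.6, 0.7)  # eV
    noise_sigma: float = 0.02     # eV
    seed: int = 0


def surrogate_targets(gap_ev: float, spec: FixtureSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Six-vector (S1, S2, S3, T1, T2, T3) in eV for one molecule."""
    a = np.asarray(spec.target_slopes)
    b = np.asarray(spec.target_offsets)
    g = np.asarray(spec.singlet_triplet_gaps)
    singlets_clean = a * gap_ev + b
    triplets_clean = singlets_clean - g
    noise = rng.normal(0.0, spec.noise_sigma, size=6) \
        if spec.noise_sigma > 0 else np.zeros(6)
    return np.concatenate([singlets_clean, triplets_clean]) + noise


def _orbitals_for(molecule: Molecule, spec: FixtureSpec) -> OrbitalSet:
    if spec.orbital_source == "scf":
        return run_scf(molecule, spec.basis, spec.functional)
    if spec.orbital_source == "sad":
        return sad_guess(molecule, spec.basis, spec.functional)
    raise ValueError(f"unknown orbital_source {spec.orbital_source!r}")


def generate_fixtures(spec: FixtureSpec
                      ) -> tuple[list[Molecule], ImageDataset]:
    """Generate jittered molecules, their images, and surrogate targets.

    The same seed yields bitwise-identical output. Molecules whose SCF
    fails on a jittered geometry are skipped with a warning and replaced.
    """
    rng = np.random.default_rng(spec.seed)
    molecules: list[Molecule] = []
    images = []
    gaps = []
    attempts = 0
    while len(molecules) < spec.n_molecules:
        if attempts > 10 * spec.n_molecules + 10:
            raise RuntimeError("too many failed fixture geometries")
        name = spec.molecule_pool[attempts % len(spec.molecule_pool)]
        attempts += 1
        base = pool_molecule(name)
        jitter = rng.normal(0.0, spec.jitter_sigma, size=base.coordinates.shape)
        jitter = np.clip(jitter, -spec.jitter_max, spec.jitter_max)
        mol = Molecule(base.symbols, base.coordinates + jitter,
                       name=f"{name}_{len(molecules):03d}")
        try:
            orbs = _orbitals_for(mol, spec)
        except Exception as exc:  # SCF failure on a jittered geometry
            warnings.warn(f"skipping {mol.name}: {exc}")
            continue
        homo, lumo = frontier_indices(orbs)
        if lumo is None:
            raise ValueError(
                f"{name} has no virtual orbital in basis {spec.basis}; "
                "surrogate targets need a frontier gap — use a pool species "
                "with virtuals")
        gaps.append((orbs.energies[lumo] - orbs.energies[homo]) * HARTREE_TO_EV)
        images.append(assemble_image(orbs, spec.beta, spec.n_mo,
                                     spec.functional))
        molecules.append(mol)
    targets = np.stack([surrogate_targets(g, spec, rng) for g in gaps])
    dataset = ImageDataset(images=images, targets=targets, beta=spec.beta,
                           orbital_source=spec.orbital_source,
                           metadata={"basis": spec.basis,
                                     "functional": spec.functional,
                                     "seed": spec.seed})
    return molecules, dataset
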