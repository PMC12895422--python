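"""Assembly and serialization of 3-channel MolOrbImages.

An image is an N_MO×N_MO grid of MO-pair pixels with channels (ε, V^H, V^P).
The window holds up to N_MO/2 occupied and N_MO/2 virtual MOs around the
Fermi level; molecules with fewer orbitals on either side are zero-padded.

Padding convention: the HOMO pixel sits at row/column N_MO/2 − 1 and the
LUMO at N_MO/2 (0-based) in *every* image, with missing occupied slots
padded toward index 0 and missing virtual slots toward index N_MO − 1.
Fixing the frontier pixels at the image center makes pixel positions
comparable across molecules — the precondition for element-wise
perturbation bookkeeping and for attributing importance to HOMO/LUMO
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .channels import (effective_potential_matrix, epsilon_channel,
                       hole_density, particle_density)
from .orbitals import OrbitalSet, frontier_indices

__all__ = ["MolOrbImage", "ImageDataset", "assemble_image",
           "write_dataset", "read_dataset"]

CHANNEL_ORDER = ("epsilon", "v_hole", "v_particle")
_FORMAT_VERSION = 1

TARGET_COLUMNS = ("E_S1", "E_S2", "E_S3", "E_T1", "E_T2", "E_T3")


@dataclass
class MolOrbImage:
    """One stacked 3×N_MO×N_MO descriptor with padding metadata."""

    pixels: np.ndarray          # (3, n_mo, n_mo), Hartree
    n_occ_used: int
    n_virt_used: int
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 3 \
                or self.pixels.shape[1] != self.pixels.shape[2]:
            raise ValueError(f"bad pixel shape {self.pixels.shape}")
        if self.n_mo % 2 != 0:
            raise ValueError("n_mo must be even")

    @property
    def n_mo(self) -> int:
        return self.pixels.shape[1]

    @property
    def homo_pixel(self) -> int:
        return self.n_mo // 2 - 1

    @property
    def lumo_pixel(self) -> int:
        return self.n_mo // 2


@dataclass
class ImageDataset:
    """An ordered image collection with optional six-state targets (eV)."""

    images: list[MolOrbImage]
    targets: Optional[np.ndarray] = None  # (n, 6): S1..3, T1..3 in eV
    beta: float = 0.0
    orbital_source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.images:
            n_mo = self.images[0].n_mo
            if any(im.n_mo != n_mo for im in self.images):
                raise ValueError("all images must share one n_mo")
        if self.targets is not None:
            self.targets = np.asarray(self.targets, dtype=float)
            if self.targets.shape != (len(self.images), 6):
                raise ValueError(
                    f"targets shape {self.targets.shape} != ({len(self.images)}, 6)")
            if not np.all(np.isfinite(self.targets)):
                raise ValueError("targets must be finite")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_mo(self) -> int:
        return self.images[0].n_mo

    def pixel_array(self) -> np.ndarray:
        """(n, 3, n_mo, n_mo) stack of all images."""
        return np.stack([im.pixels for im in self.images])

    def subset(self, indices: np.ndarray) -> "ImageDataset":
        idx = np.asarray(indices, dtype=int)
        return ImageDataset(
            images=[self.images[i] for i in idx],
            targets=None if self.targets is None else self.targets[idx],
            beta=self.beta, orbital_source=self.orbital_source,
            metadata=dict(self.metadata))

    def copy(self) -> "ImageDataset":
        return ImageDataset(
            images=[MolOrbImage(im.pixels.copy(), im.n_occ_used,
                                im.n_virt_used, im.molecule_id)
                    for im in self.images],
            targets=None if self.targets is None else self.targets.copy(),
            beta=self.beta, orbital_source=self.orbital_source,
            metadata=dict(self.metadata))


def assemble_image(orbitals: OrbitalSet, beta: float, n_mo: int,
                   functional: str = "hf",
                   include_exchange: bool = True) -> MolOrbImage:
    """Build one ε/V^H/V^P image from an OrbitalSet.

    Selects up to ``n_mo/2`` occupied MOs below and ``n_mo/2`` virtuals
    above the Fermi level, computes the three channels over that window,
    and zero-pads the remaining pixels under the centered HOMO/LUMO
    alignment. Evaluation order is fixed, so repeated assembly is
    bitwise-deterministic.
    """
    if n_mo < 2 or n_mo % 2 != 0:
        raise ValueError("n_mo must be an even integer >= 2")
    half = n_mo // 2
    homo, lumo = frontier_indices(orbitals)

    n_occ_used = min(homo + 1, half)
    occ_idx = np.arange(homo + 1 - n_occ_used, homo + 1)
    if lumo is None:
        n_virt_used = 0
        virt_idx = np.arange(0)
    else:
        n_virt_used = min(orbitals.n_mo - lumo, half)
        virt_idx = np.arange(lumo, lumo + n_virt_used)
    window = np.concatenate([occ_idx, virt_idx])
    start = half - n_occ_used
    stop = half + n_virt_used
    block = slice(start, stop)

    pixels = np.zeros((3, n_mo, n_mo))
    eps = epsilon_channel(orbitals, window)
    pixels[0, block, block] = eps.values

    v_h = effective_potential_matrix(hole_density(orbitals, beta), orbitals,
                                     functional, include_exchange)
    pixels[1][np.ix_(range(start, stop), range(start, stop))] = \
        v_h.values[np.ix_(window, window)]
    if lumo is not None:
        v_p = effective_potential_matrix(particle_density(orbitals, beta),
                                         orbitals, functional, include_exchange)
        pixels[2][np.ix_(range(start, stop), range(start, stop))] = \
            v_p.values[np.ix_(window, window)]
    return MolOrbImage(pixels=pixels, n_occ_used=n_occ_used,
                       n_virt_used=n_virt_used,
                       molecule_id=orbitals.molecule_id)


def write_dataset(dataset: ImageDataset, path: str | Path) -> None:
    """Lossless single-file HDF5 serialization of an ImageDataset.

    Layout: ``/pixels`` (n, 3, n_mo, n_mo, float64), ``/n_occ_used``,
    ``/n_virt_used``, ``/molecule_ids`` (utf-8), optional ``/targets``
    (n, 6, eV); root attributes ``version``, ``n_mo``, ``beta``,
    ``orbital_source``, ``channel_order``.
    """
    with h5py.File(path, "w") as f:
        f.attrs["version"] = _FORMAT_VERSION
        f.attrs["n_mo"] = dataset.n_mo if dataset.images else 0
        f.attrs["beta"] = dataset.beta
        f.attrs["orbital_source"] = dataset.orbital_source
        f.attrs["channel_order"] = ",".join(CHANNEL_ORDER)
        f.create_dataset("pixels", data=dataset.pixel_array())
        f.create_dataset("n_occ_used",
                         data=np.array([im.n_occ_used for im in dataset.images]))
        f.create_dataset("n_virt_used",
                         data=np.array([im.n_virt_used for im in dataset.images]))
        f.create_dataset(
            "molecule_ids",
            data=np.array([im.molecule_id for im in dataset.images],
                          dtype=h5py.string_dtype()))
        if dataset.targets is not None:
            f.create_dataset("targets", data=dataset.targets)


def read_dataset(path: str | Path) -> ImageDataset:
    """Read a dataset written by :func:`write_dataset` (bitwise lossless)."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs["version"])
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported dataset version {version}")
        pixels = f["pixels"][...]
        n_occ = f["n_occ_used"][...]
        n_virt = f["n_virt_used"][...]
        ids = [s.decode() if isinstance(s, bytes) else str(s)
               for s in f["molecule_ids"][...]]
        targets = f["targets"][...] if "targets" in f else None
        images = [MolOrbImage(pixels[i], int(n_occ[i]), int(n_virt[i]), ids[i])
                  for i in range(pixels.shape[0])]
        return ImageDataset(images=images, targets=targets,
                            beta=float(f.attrs["beta"]),
                            orbital_source=str(f.attrs["orbital_source"]))
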