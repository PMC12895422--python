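"""Gaussian basis sets.

A built-in STO-3G table covers H–Ne, which is enough for the desk-scale
molecule pool; MOLDEN files may declare any s/p/d basis and are taken
verbatim. Contraction coefficients are stored for *normalized* primitives
(the convention of every standard basis-set exchange and of MOLDEN writers)
and each contracted Cartesian function is renormalized to unit self-overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molecule import Molecule


def _double_factorial(n: int) -> float:
    """n!! with the (-1)!! = 1 convention the Gaussian norms rely on."""
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out

# STO-3G exponents (Hartree-atomic units).  Contraction coefficients are
# universal across the row: the same 1s/2s/2p fit coefficients are combined
# with element-scaled exponents.
_STO3G_COEF_1S = (0.15432897, 0.53532814, 0.44463454)
_STO3G_COEF_2S = (-0.09996723, 0.39951283, 0.70011547)
_STO3G_COEF_2P = (0.15591627, 0.60768372, 0.39195739)

_STO3G_EXPONENTS = {
    # element: (1s exps, 2sp exps or None)
    "H": ((3.42525091, 0.62391373, 0.16885540), None),
    "He": ((6.36242139, 1.15892300, 0.31364979), None),
    "Li": ((16.1195750, 2.9362007, 0.7946505),
           (0.6362897, 0.1478601, 0.0480887)),
    "Be": ((30.1678710, 5.4951153, 1.4871927),
           (1.3148331, 0.3055389, 0.0993707)),
    "B": ((48.7911130, 8.8873622, 2.4052670),
          (2.2369561, 0.5198205, 0.1690618)),
    "C": ((71.6168370, 13.0450960, 3.5305122),
          (2.9412494, 0.6834831, 0.2222899)),
    "N": ((99.1061690, 18.0523120, 4.8856602),
          (3.7804559, 0.8784966, 0.2857144)),
    "O": ((130.7093200, 23.8088610, 6.4436083),
          (5.0331513, 1.1695961, 0.3803890)),
    "F": ((166.6791300, 30.3608120, 8.2168207),
          (6.4648032, 1.5022812, 0.4885885)),
    "Ne": ((207.0156100, 37.7081510, 9.8540695),
           (8.2463151, 1.9162662, 0.6232326)),
}

#: Cartesian component ordering per angular momentum; p follows the MOLDEN
#: (x, y, z) convention.
CARTESIAN_POWERS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
}

SHELL_LETTERS = {0: "s", 1: "p", 2: "d"}
SHELL_L = {v: k for k, v in SHELL_LETTERS.items()}


def primitive_norm(alpha: float, lx: int, ly: int, lz: int) -> float:
    """Normalization constant of a primitive Cartesian Gaussian."""
    l = lx + ly + lz
    num = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)
    den = np.sqrt(_double_factorial(2 * lx - 1) * _double_factorial(2 * ly - 1)
                  * _double_factorial(2 * lz - 1))
    return num / den


@dataclass
class Shell:
    """One contracted shell: shared exponents, one angular momentum."""

    l: int
    exponents: np.ndarray
    coefficients: np.ndarray  # for normalized primitives
    center: np.ndarray        # Bohr
    atom_index: int

    @property
    def n_functions(self) -> int:
        return len(CARTESIAN_POWERS[self.l])


@dataclass
class BasisFunction:
    """A contracted Cartesian Gaussian (internal currency of the integrals)."""

    center: np.ndarray
    powers: tuple[int, int, int]
    exponents: np.ndarray
    coefficients: np.ndarray  # primitive norms and contraction norm folded in
    atom_index: int
    shell_index: int


def _contracted_self_overlap(exps: np.ndarray, coefs: np.ndarray,
                             powers: tuple[int, int, int]) -> float:
    """⟨g|g⟩ for a contracted Cartesian Gaussian at a single center."""
    lx, ly, lz = powers
    l = lx + ly + lz
    dfac = (_double_factorial(2 * lx - 1) * _double_factorial(2 * ly - 1)
            * _double_factorial(2 * lz - 1))
    s = 0.0
    for ci, ai in zip(coefs, exps):
        for cj, aj in zip(coefs, exps):
            p = ai + aj
            s += ci * cj * dfac / (2.0 * p) ** l * (np.pi / p) ** 1.5
    return s


@dataclass
class BasisSet:
    """All shells and expanded Cartesian basis functions for one molecule."""

    shells: list[Shell]
    name: str = ""
    functions: list[BasisFunction] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.functions:
            self.functions = self._expand()

    def _expand(self) -> list[BasisFunction]:
        funcs = []
        for si, shell in enumerate(self.shells):
            for powers in CARTESIAN_POWERS[shell.l]:
                coefs = shell.coefficients * np.array(
                    [primitive_norm(a, *powers) for a in shell.exponents])
                norm = _contracted_self_overlap(shell.exponents, coefs, powers)
                coefs = coefs / np.sqrt(norm)
                funcs.append(BasisFunction(
                    center=shell.center, powers=powers,
                    exponents=np.asarray(shell.exponents, dtype=float),
                    coefficients=coefs, atom_index=shell.atom_index,
                    shell_index=si))
        return funcs

    @property
    def n_functions(self) -> int:
        return len(self.functions)

    def atom_slices(self, n_atoms: int) -> list[slice]:
        """AO index ranges per atom (functions are emitted atom-ordered)."""
        starts = [0] * (n_atoms + 1)
        for f in self.functions:
            starts[f.atom_index + 1] += 1
        for i in range(n_atoms):
            starts[i + 1] += starts[i]
        return [slice(starts[i], starts[i + 1]) for i in range(n_atoms)]


def build_basis(molecule: Molecule, name: str = "STO-3G") -> BasisSet:
    """Build the named basis for a molecule.

    Only the built-in STO-3G table (aliases ``sto-3g``, ``minimal``) is
    available by name; other bases enter through MOLDEN files.
    """
    key = name.strip().lower()
    if key not in ("sto-3g", "sto3g", "minimal"):
        raise ValueError(
            f"basis {name!r} is not in the built-in table (STO-3G, H–Ne); "
            "use a MOLDEN file to supply another basis")
    shells: list[Shell] = []
    coords = molecule.coordinates_bohr
    for ia, symbol in enumerate(molecule.symbols):
        if symbol not in _STO3G_EXPONENTS:
            raise ValueError(f"element {symbol} not in the STO-3G table (H–Ne)")
        exps_1s, exps_2sp = _STO3G_EXPONENTS[symbol]
        shells.append(Shell(0, np.array(exps_1s), np.array(_STO3G_COEF_1S),
                            coords[ia].copy(), ia))
        if exps_2sp is not None:
            shells.append(Shell(0, np.array(exps_2sp),
                                np.array(_STO3G_COEF_2S), coords[ia].copy(), ia))
            shells.append(Shell(1, np.array(exps_2sp),
                                np.array(_STO3G_COEF_2P), coords[ia].copy(), ia))
    return BasisSet(shells=shells, name="STO-3G")
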