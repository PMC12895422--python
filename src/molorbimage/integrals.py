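"""Analytic one- and two-electron integrals over contracted Cartesian Gaussians.

McMurchie–Davidson scheme: products of Gaussians are expanded in Hermite
Gaussians (E coefficients); Coulomb-type integrals reduce to Hermite Coulomb
tensors R built from Boys functions. Angular momenta up to d are supported,
which covers the built-in STO-3G table and typical valence MOLDEN files.

The :class:`IntegralContext` caches the AO matrices (S, T, V_ne, ERI) per
molecule/basis and exposes Coulomb/exchange builds used by the SCF driver
and the potential channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import hyp1f1

from .basis import BasisFunction, BasisSet
from .molecule import Molecule

__all__ = ["IntegralContext", "boys", "ao_values"]


def boys(n_max: int, t: np.ndarray) -> np.ndarray:
    """Boys functions F_0..F_{n_max} evaluated at ``t`` (any shape).

    The highest order is evaluated with Kummer's confluent hypergeometric
    function and the rest by stable downward recursion.
    """
    t = np.asarray(t, dtype=float)
    out = np.empty((n_max + 1,) + t.shape)
    out[n_max] = hyp1f1(n_max + 0.5, n_max + 1.5, -t) / (2 * n_max + 1)
    et = np.exp(-t)
    for n in range(n_max, 0, -1):
        out[n - 1] = (2.0 * t * out[n] + et) / (2 * n - 1)
    return out


def _hermite_e(la: int, lb: int, a: float, b: float, ab: float) -> np.ndarray:
    """1D Hermite expansion coefficients E_t^{ij}, shape (la+1, lb+1, la+lb+1)."""
    p = a + b
    mu = a * b / p
    # P - A and P - B along this axis; ab = A - B
    pa = -b / p * ab
    pb = a / p * ab
    tmax = la + lb
    E = np.zeros((la + 1, lb + 1, tmax + 2))  # one slot of slack for t+1 reads
    E[0, 0, 0] = np.exp(-mu * ab * ab)
    for i in range(1, la + 1):
        for t in range(i + 1):
            E[i, 0, t] = ((E[i - 1, 0, t - 1] / (2 * p) if t > 0 else 0.0)
                          + pa * E[i - 1, 0, t]
                          + (t + 1) * E[i - 1, 0, t + 1])
    for j in range(1, lb + 1):
        for i in range(la + 1):
            for t in range(i + j + 1):
                E[i, j, t] = ((E[i, j - 1, t - 1] / (2 * p) if t > 0 else 0.0)
                              + pb * E[i, j - 1, t]
                              + (t + 1) * E[i, j - 1, t + 1])
    return E[:, :, :tmax + 1]


def _hermite_r(tuv_max: tuple[int, int, int], alpha: np.ndarray,
               pq: np.ndarray) -> dict[tuple[int, int, int], np.ndarray]:
    """Hermite Coulomb tensor R_{tuv}(alpha, PQ), batched over leading axes.

    ``alpha``: (...,), ``pq``: (..., 3).  Returns arrays of shape (...).
    """
    tmax, umax, vmax = tuv_max
    n_max = tmax + umax + vmax
    t2 = alpha * np.einsum("...i,...i->...", pq, pq)
    fn = boys(n_max, t2)
    base = {}
    scale = np.ones_like(alpha)
    for n in range(n_max + 1):
        base[n] = scale * fn[n]
        scale = scale * (-2.0 * alpha)
    cache: dict[tuple[int, int, int, int], np.ndarray] = {}

    def r(n: int, t: int, u: int, v: int) -> np.ndarray:
        if t < 0 or u < 0 or v < 0:
            return 0.0
        key = (n, t, u, v)
        if key in cache:
            return cache[key]
        if t == u == v == 0:
            val = base[n]
        elif t >= 1:
            val = (t - 1) * r(n + 1, t - 2, u, v) + pq[..., 0] * r(n + 1, t - 1, u, v)
        elif u >= 1:
            val = (u - 1) * r(n + 1, t, u - 2, v) + pq[..., 1] * r(n + 1, t, u - 1, v)
        else:
            val = (v - 1) * r(n + 1, t, u, v - 2) + pq[..., 2] * r(n + 1, t, u, v - 1)
        cache[key] = val
        return val

    return {(t, u, v): r(0, t, u, v)
            for t in range(tmax + 1)
            for u in range(umax + 1)
            for v in range(vmax + 1)}


@dataclass
class _PairData:
    """Precomputed primitive-pair quantities for one basis-function pair."""

    p: np.ndarray        # (np,) combined exponents
    P: np.ndarray        # (np, 3) product centers
    lam: np.ndarray      # (np, tx, ty, tz) contracted Hermite coefficients
    dims: tuple[int, int, int]


def _pair_data(fa: BasisFunction, fb: BasisFunction) -> _PairData:
    ab = fa.center - fb.center
    la, lb = fa.powers, fb.powers
    dims = tuple(la[d] + lb[d] + 1 for d in range(3))
    n_pairs = len(fa.exponents) * len(fb.exponents)
    p = np.empty(n_pairs)
    P = np.empty((n_pairs, 3))
    lam = np.empty((n_pairs,) + dims)
    k = 0
    for ca, aa in zip(fa.coefficients, fa.exponents):
        for cb, bb in zip(fb.coefficients, fb.exponents):
            pk = aa + bb
            p[k] = pk
            P[k] = (aa * fa.center + bb * fb.center) / pk
            exs = [_hermite_e(la[d], lb[d], aa, bb, ab[d]) for d in range(3)]
            e0 = exs[0][la[0], lb[0]]
            e1 = exs[1][la[1], lb[1]]
            e2 = exs[2][la[2], lb[2]]
            lam[k] = (ca * cb) * np.einsum("t,u,v->tuv", e0, e1, e2)
            k += 1
    return _PairData(p=p, P=P, lam=lam, dims=dims)


def _overlap_kinetic(basis: BasisSet) -> tuple[np.ndarray, np.ndarray]:
    nbf = basis.n_functions
    S = np.zeros((nbf, nbf))
    T = np.zeros((nbf, nbf))
    funcs = basis.functions
    for i in range(nbf):
        for j in range(i + 1):
            fa, fb = funcs[i], funcs[j]
            ab = fa.center - fb.center
            s_ij = 0.0
            t_ij = 0.0
            for ca, aa in zip(fa.coefficients, fa.exponents):
                for cb, bb in zip(fb.coefficients, fb.exponents):
                    p = aa + bb
                    pref = ca * cb * (np.pi / p) ** 1.5
                    s1 = np.empty(3)
                    k1 = np.empty(3)
                    for d in range(3):
                        la, lb = fa.powers[d], fb.powers[d]
                        E = _hermite_e(la, lb + 2, aa, bb, ab[d])
                        s1[d] = E[la, lb, 0]
                        term = bb * (2 * lb + 1) * E[la, lb, 0]
                        term -= 2.0 * bb * bb * E[la, lb + 2, 0]
                        if lb >= 2:
                            term -= 0.5 * lb * (lb - 1) * E[la, lb - 2, 0]
                        k1[d] = term
                    s_ij += pref * s1[0] * s1[1] * s1[2]
                    t_ij += pref * (k1[0] * s1[1] * s1[2]
                                    + s1[0] * k1[1] * s1[2]
                                    + s1[0] * s1[1] * k1[2])
            S[i, j] = S[j, i] = s_ij
            T[i, j] = T[j, i] = t_ij
    return S, T


def _nuclear_attraction(basis: BasisSet, charges: np.ndarray,
                        centers: np.ndarray) -> np.ndarray:
    nbf = basis.n_functions
    V = np.zeros((nbf, nbf))
    funcs = basis.functions
    for i in range(nbf):
        for j in range(i + 1):
            pair = _pair_data(funcs[i], funcs[j])
            dims = pair.dims
            v_ij = 0.0
            for zc, C in zip(charges, centers):
                pq = pair.P - C[None, :]
                R = _hermite_r((dims[0] - 1, dims[1] - 1, dims[2] - 1),
                               pair.p, pq)
                acc = np.zeros(len(pair.p))
                for t in range(dims[0]):
                    for u in range(dims[1]):
                        for v in range(dims[2]):
                            acc += pair.lam[:, t, u, v] * R[(t, u, v)]
                v_ij += -zc * np.sum(2.0 * np.pi / pair.p * acc)
            V[i, j] = V[j, i] = v_ij
    return V


def _eri_tensor(basis: BasisSet) -> np.ndarray:
    nbf = basis.n_functions
    funcs = basis.functions
    pairs = []
    pair_index = {}
    for i in range(nbf):
        for j in range(i + 1):
            pair_index[(i, j)] = len(pairs)
            pairs.append((i, j, _pair_data(funcs[i], funcs[j])))
    eri = np.zeros((nbf, nbf, nbf, nbf))
    two_pi_52 = 2.0 * np.pi ** 2.5
    for a, (i, j, pa) in enumerate(pairs):
        da = pa.dims
        for b in range(a + 1):
            k, l, pb = pairs[b]
            db = pb.dims
            p = pa.p[:, None]
            q = pb.p[None, :]
            alpha = p * q / (p + q)
            pq = pa.P[:, None, :] - pb.P[None, :, :]
            R = _hermite_r((da[0] + db[0] - 2, da[1] + db[1] - 2,
                            da[2] + db[2] - 2), alpha, pq)
            val = np.zeros_like(alpha)
            for t in range(da[0]):
                for u in range(da[1]):
                    for v in range(da[2]):
                        l1 = pa.lam[:, t, u, v][:, None]
                        for tt in range(db[0]):
                            for uu in range(db[1]):
                                for vv in range(db[2]):
                                    sign = -1.0 if (tt + uu + vv) % 2 else 1.0
                                    val += (sign * l1 * pb.lam[:, tt, uu, vv][None, :]
                                            * R[(t + tt, u + uu, v + vv)])
            integral = float(np.sum(two_pi_52 / (p * q * np.sqrt(p + q)) * val))
            for (x, y) in ((i, j), (j, i)):
                for (z, w) in ((k, l), (l, k)):
                    eri[x, y, z, w] = integral
                    eri[z, w, x, y] = integral
    return eri


def ao_values(basis: BasisSet, points: np.ndarray) -> np.ndarray:
    """Evaluate all contracted AOs on ``points`` (Bohr); shape (nbf, npts)."""
    points = np.asarray(points, dtype=float)
    out = np.empty((basis.n_functions, len(points)))
    for n, f in enumerate(basis.functions):
        d = points - f.center[None, :]
        r2 = np.einsum("pi,pi->p", d, d)
        poly = (d[:, 0] ** f.powers[0] * d[:, 1] ** f.powers[1]
                * d[:, 2] ** f.powers[2])
        rad = np.zeros(len(points))
        for c, a in zip(f.coefficients, f.exponents):
            rad += c * np.exp(-a * r2)
        out[n] = poly * rad
    return out


class IntegralContext:
    """Cached AO integrals for one molecule/basis combination."""

    def __init__(self, molecule: Molecule, basis: BasisSet):
        self.molecule = molecule
        self.basis = basis
        self._s = None
        self._t = None
        self._vne = None
        self._eri = None

    @property
    def n_basis(self) -> int:
        return self.basis.n_functions

    def overlap(self) -> np.ndarray:
        if self._s is None:
            self._s, self._t = _overlap_kinetic(self.basis)
        return self._s

    def kinetic(self) -> np.ndarray:
        if self._t is None:
            self._s, self._t = _overlap_kinetic(self.basis)
        return self._t

    def nuclear(self) -> np.ndarray:
        if self._vne is None:
            self._vne = _nuclear_attraction(
                self.basis, self.molecule.atomic_numbers.astype(float),
                self.molecule.coordinates_bohr)
        return self._vne

    def core_hamiltonian(self) -> np.ndarray:
        return self.kinetic() + self.nuclear()

    def eri(self) -> np.ndarray:
        if self._eri is None:
            self._eri = _eri_tensor(self.basis)
        return self._eri

    def coulomb(self, dm: np.ndarray) -> np.ndarray:
        """J[D]_{λμ} = Σ_{νσ} (λμ|νσ) D_{νσ}."""
        return np.einsum("pqrs,rs->pq", self.eri(), dm, optimize=True)

    def exchange(self, dm: np.ndarray) -> np.ndarray:
        """K[D]_{λμ} = Σ_{νσ} (λν|μσ) D_{νσ}."""
        return np.einsum("prqs,rs->pq", self.eri(), dm, optimize=True)
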