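"""Shared fixtures and independent test oracles.

The ``gauss_oracle`` fixture exposes a self-contained evaluator for integrals
over *multi-center* contracted s-Gaussian functions, written directly from
the textbook primitive formulas.  It is deliberately independent of the
package's integral code paths (which never form explicit multi-center
contractions) and serves as the reference for the vertex-condensation
checks: a condensed block must equal the direct integral over the explicitly
summed, renormalized orbital.
"""

import math
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.special import erf

from chemion.molecule import build_chain, build_monofocal
from chemion.sto import build_anchor_integrals


def _boys0(t):
    if t < 1e-13:
        return 1.0 - t / 3.0
    return 0.5 * math.sqrt(math.pi / t) * erf(math.sqrt(t))


class GFunction:
    """A contracted s-Gaussian with per-primitive centers."""

    def __init__(self, alphas, coeffs, centers):
        self.alphas = np.asarray(alphas, dtype=float)
        self.coeffs = np.asarray(coeffs, dtype=float)
        self.centers = np.asarray(centers, dtype=float)

    @classmethod
    def from_orbital(cls, orb, scale=1.0):
        centers = np.repeat(orb.center[None, :], len(orb.alphas), axis=0)
        return cls(orb.alphas, scale * orb.coeffs, centers)

    @classmethod
    def summed(cls, orbitals, scale):
        alphas = np.concatenate([o.alphas for o in orbitals])
        coeffs = np.concatenate([scale * o.coeffs for o in orbitals])
        centers = np.concatenate(
            [np.repeat(o.center[None, :], len(o.alphas), axis=0) for o in orbitals])
        return cls(alphas, coeffs, centers)


def _prim_overlap(a, A, b, B):
    p = a + b
    d = A - B
    return (math.pi / p) ** 1.5 * math.exp(-a * b / p * float(d @ d))


def _prim_kinetic(a, A, b, B):
    p = a + b
    mu = a * b / p
    d = A - B
    r2 = float(d @ d)
    return mu * (3.0 - 2.0 * mu * r2) * _prim_overlap(a, A, b, B)


def _prim_attraction(a, A, b, B, C):
    p = a + b
    d = A - B
    P = (a * A + b * B) / p
    pref = 2.0 * math.pi / p * math.exp(-a * b / p * float(d @ d))
    return pref * _boys0(p * float((P - C) @ (P - C)))


def _prim_eri(a, A, b, B, c, C, d, D):
    p, q = a + b, c + d
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    k1 = math.exp(-a * b / p * float((A - B) @ (A - B)))
    k2 = math.exp(-c * d / q * float((C - D) @ (C - D)))
    t = p * q / (p + q) * float((P - Q) @ (P - Q))
    return (2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
            * k1 * k2 * _boys0(t))


def g_overlap(f, g):
    return sum(ci * cj * _prim_overlap(ai, Ai, aj, Aj)
               for ai, ci, Ai in zip(f.alphas, f.coeffs, f.centers)
               for aj, cj, Aj in zip(g.alphas, g.coeffs, g.centers))


def g_kinetic(f, g):
    return sum(ci * cj * _prim_kinetic(ai, Ai, aj, Aj)
               for ai, ci, Ai in zip(f.alphas, f.coeffs, f.centers)
               for aj, cj, Aj in zip(g.alphas, g.coeffs, g.centers))


def g_attraction(f, g, C):
    C = np.asarray(C, dtype=float)
    return sum(ci * cj * _prim_attraction(ai, Ai, aj, Aj, C)
               for ai, ci, Ai in zip(f.alphas, f.coeffs, f.centers)
               for aj, cj, Aj in zip(g.alphas, g.coeffs, g.centers))


def g_eri(f, g, h, k):
    total = 0.0
    for ai, ci, Ai in zip(f.alphas, f.coeffs, f.centers):
        for aj, cj, Aj in zip(g.alphas, g.coeffs, g.centers):
            for ak, ck, Ak in zip(h.alphas, h.coeffs, h.centers):
                for al, cl, Al in zip(k.alphas, k.coeffs, k.centers):
                    total += ci * cj * ck * cl * _prim_eri(ai, Ai, aj, Aj,
                                                          ak, Ak, al, Al)
    return total


@pytest.fixture(scope="session")
def gauss_oracle():
    return SimpleNamespace(GFunction=GFunction, overlap=g_overlap,
                           kinetic=g_kinetic, attraction=g_attraction,
                           eri=g_eri)


@pytest.fixture(scope="session")
def methane():
    return build_monofocal("C")


@pytest.fixture(scope="session")
def water():
    return build_monofocal("O")


@pytest.fixture(scope="session")
def ethane():
    return build_chain(1, "CH3")


@pytest.fixture(scope="session")
def methane_integrals(methane):
    return build_anchor_integrals(methane, order=4)


@pytest.fixture(scope="session")
def ethane_integrals(ethane):
    return build_anchor_integrals(ethane, order=3)


def random_mo_integrals(chp, rng):
    """Random symmetric one-chemion matrix and 8-fold-symmetric repulsions."""
    from chemion.fci import MOIntegrals
    nv = chp + 1
    h = rng.normal(size=(nv, nv))
    h = (h + h.T) / 2
    eri = rng.normal(size=(nv,) * 4)
    eri = eri + eri.transpose(1, 0, 2, 3)
    eri = eri + eri.transpose(0, 1, 3, 2)
    eri = eri + eri.transpose(2, 3, 0, 1)
    return MOIntegrals(h=h, eri=eri, chp=chp)


@pytest.fixture(scope="session")
def mo_factory():
    return random_mo_integrals
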