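"""Full configuration interaction in the molecular-orbital basis.

Because every topology chart obeys #vtx = #chp + 1, a converged RHF reference
leaves exactly one virtual orbital r.  The full many-chemion space then
consists of the reference, the singles a→r, the paired doubles aa→rr and the
unpaired doubles ab→rr, giving the compact spin blocks

    #sing = (#chp+1)(#chp+2)/2,      #trip = (#chp+1)#chp/2.

Both symmetric blocks are assembled element-by-element from closed formulas
over the MO integrals (with their √2 cross factors between singly- and
doubly-excited configurations), diagonalized densely, and the chemionic
ground energy is the lower of the two lowest eigenvalues, the singlet winning
ties.  M_S = ±1 triplet blocks are identical to the M_S = 0 block and are not
stored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .condense import one_chemion_matrix
from .molecule import ChemionEnsemble, MoleculeGraph, nuclear_repulsion
from .sto import AnchorIntegralSet

__all__ = ["MOIntegrals", "CIMatrix", "transform_integrals", "build_singlet",
           "build_triplet", "build_ci", "chemionic_energy", "total_energy",
           "singlet_dimension", "triplet_dimension"]


class CIStructureError(ValueError):
    """Raised when the orbital layout leaves other than one virtual orbital."""


def singlet_dimension(chp: int) -> int:
    return (chp + 1) * (chp + 2) // 2


def triplet_dimension(chp: int) -> int:
    return (chp + 1) * chp // 2


@dataclass
class MOIntegrals:
    """One- and two-chemion integrals over molecular orbitals.

    ``h`` is the one-chemion matrix C^T (K − V_ε) C; ``eri`` the chemists'-
    notation tensor (ab|cd).  Orbitals 0..chp−1 are occupied, r = chp is the
    unique virtual.
    """

    h: np.ndarray
    eri: np.ndarray
    chp: int

    def __post_init__(self):
        nv = self.h.shape[0]
        if nv != self.chp + 1:
            raise CIStructureError(
                f"expected exactly one virtual orbital: basis {nv}, chp {self.chp}")

    @property
    def r(self) -> int:
        return self.chp


def transform_integrals(integrals: AnchorIntegralSet, C: np.ndarray,
                        z_prop: np.ndarray, chp: int) -> MOIntegrals:
    """Four-index transform of H_ε and R to the molecular-orbital basis."""
    _, H = one_chemion_matrix(integrals.K, integrals.U, z_prop)
    h = C.T @ H @ C
    eri = np.einsum("pa,qb,rc,sd,pqrs->abcd", C, C, C, C, integrals.R,
                    optimize=True)
    return MOIntegrals(h=h, eri=eri, chp=chp)


def _aux(mo: MOIntegrals):
    """J, K, orbital energies and the generalized Fock sums F^m_kl of the
    closed formulas.  Sums written "n ≠ m" run over every orbital except m
    (with one virtual, "n ≠ r" is exactly the occupied set)."""
    h, eri, r = mo.h, mo.eri, mo.r
    nv = h.shape[0]
    occ = list(range(mo.chp))
    J = np.einsum("aabb->ab", eri)
    K = np.einsum("abba->ab", eri)
    eps = np.array([h[k, k] + sum(2 * J[k, n] - K[k, n] for n in occ)
                    for k in range(nv)])

    def F(k, l, m):
        return h[k, l] + sum(2 * eri[k, l, n, n] - eri[k, n, n, l]
                             for n in range(nv) if n != m)

    e0 = sum(2 * h[m, m] + sum(2 * J[m, n] - K[m, n] for n in occ) for m in occ)
    return J, K, eps, F, e0


def _singlet_basis(chp: int):
    """Fixed ordering: reference, singles, paired doubles, unpaired doubles."""
    basis = [("ref",)]
    basis += [("s", a) for a in range(chp)]
    basis += [("dp", a) for a in range(chp)]
    basis += [("du", a, b) for a in range(chp) for b in range(a + 1, chp)]
    return basis


def build_singlet(mo: MOIntegrals) -> np.ndarray:
    """Singlet CI block over [Ψ0, Ψ_a^r, Ψ_aa^rr, Ψ_ab^rr], as printed."""
    J, K, eps, F, e0 = _aux(mo)
    eri, h, r = mo.eri, mo.h, mo.r
    nv = h.shape[0]
    basis = _singlet_basis(mo.chp)
    dim = len(basis)
    M = np.zeros((dim, dim))
    rt2 = np.sqrt(2.0)

    def brace(k, l, excl_a, excl_b):
        """h_kl + Σ_{n≠excl_a}(kl|nn) + Σ_{n≠excl_b}[(kl|nn) − (kn|nl)]."""
        s = h[k, l]
        s += sum(eri[k, l, n, n] for n in range(nv) if n != excl_a)
        s += sum(eri[k, l, n, n] - eri[k, n, n, l]
                 for n in range(nv) if n != excl_b)
        return s

    for i, bi in enumerate(basis):
        for j in range(i, dim):
            bj = basis[j]
            ti, tj = bi[0], bj[0]
            val = 0.0
            if ti == "ref" and tj == "ref":
                val = e0
            elif ti == "ref" and tj == "s":
                val = rt2 * F(bj[1], r, r)
            elif ti == "ref" and tj == "dp":
                a = bj[1]
                val = K[a, r]
            elif ti == "ref" and tj == "du":
                a, b = bj[1], bj[2]
                val = rt2 * eri[a, r, b, r]
            elif ti == "s" and tj == "s":
                a, b = bi[1], bj[1]
                if a == b:
                    val = e0 + F(r, r, r) - F(a, a, r) - J[a, r] + 2 * K[a, r]
                else:
                    val = -F(a, b, r) - eri[a, b, r, r] + 2 * eri[a, r, r, b]
            elif ti == "s" and tj == "dp":
                a, b = bi[1], bj[1]
                if a == b:
                    val = rt2 * F(a, r, a)
                else:
                    # ⟨Ψ_bb^rr|H|Ψ_a^r⟩ with the printed roles (a↔pair, b↔single)
                    val = -rt2 * eri[b, a, b, r]
            elif ti == "s" and tj == "du":
                a = bi[1]
                pair = (bj[1], bj[2])
                if a in pair:
                    b = pair[0] if pair[1] == a else pair[1]
                    val = brace(b, r, a, r) - eri[a, b, a, r]
                else:
                    b, c = pair
                    val = -eri[a, b, c, r] - eri[a, c, b, r]
            elif ti == "dp" and tj == "dp":
                a, b = bi[1], bj[1]
                if a == b:
                    val = (e0 + 2 * (eps[r] - eps[a]) + J[r, r] + J[a, a]
                           - 4 * J[a, r] + 2 * K[a, r])
                else:
                    # paired aa→rr vs bb→rr: a same-spin double replacement in
                    # both spin channels, Coulomb-only element (ab|ab).
                    val = eri[a, b, a, b]
            elif ti == "dp" and tj == "du":
                a = bi[1]
                pair = (bj[1], bj[2])
                if a in pair:
                    b = pair[0] if pair[1] == a else pair[1]
                    val = -rt2 * F(a, b, a)
                else:
                    b, c = pair
                    val = rt2 * eri[a, b, a, c]
            elif ti == "du" and tj == "du":
                if i == j:
                    a, b = bi[1], bi[2]
                    val = (e0 + 2 * eps[r] - eps[a] - eps[b] + J[r, r]
                           + J[a, b] - 2 * J[a, r] - 2 * J[b, r]
                           + K[a, b] + K[a, r] + K[b, r])
                else:
                    p, q = set(bi[1:]), set(bj[1:])
                    shared = p & q
                    if len(shared) == 1:
                        # pairs sharing one member: symmetric in the two
                        # unique indices u, v around the shared s
                        s = shared.pop()
                        u = (p - {s}).pop()
                        v = (q - {s}).pop()
                        val = (-F(u, v, r) - 2 * eri[u, v, r, r]
                               + eri[u, r, r, v] + eri[u, v, s, s]
                               + eri[u, s, s, v])
                    else:
                        a, b = bi[1], bi[2]
                        c, d = bj[1], bj[2]
                        val = eri[a, c, b, d] + eri[a, d, b, c]
            M[i, j] = M[j, i] = val
    return M


def build_triplet(mo: MOIntegrals) -> np.ndarray:
    """Triplet (M_S = 0) CI block via the printed singlet-to-triplet corrections."""
    if mo.chp < 1:
        raise CIStructureError("triplet block needs at least one chemion pair")
    J, K, eps, F, e0 = _aux(mo)
    eri, h, r = mo.eri, mo.h, mo.r
    nv = h.shape[0]
    basis = [("s", a) for a in range(mo.chp)]
    basis += [("du", a, b) for a in range(mo.chp) for b in range(a + 1, mo.chp)]
    singlet = build_singlet(mo)
    s_index = {b: i for i, b in enumerate(_singlet_basis(mo.chp))}
    dim = len(basis)
    M = np.zeros((dim, dim))
    # The unpaired triplet configuration is antisymmetric in its pair label
    # (Ψ_ba = −Ψ_ab); elements over the canonically sorted pairs therefore
    # carry orientation signs wherever a formula assumes the shared member in
    # a fixed slot.
    for i, bi in enumerate(basis):
        for j in range(i, dim):
            bj = basis[j]
            base = singlet[s_index[bi], s_index[bj]]
            ti, tj = bi[0], bj[0]
            if ti == "s" and tj == "s":
                a, b = bi[1], bj[1]
                val = base - (2 * K[a, r] if a == b else 2 * eri[a, r, r, b])
            elif ti == "s" and tj == "du":
                a = bi[1]
                pair = (bj[1], bj[2])
                if a in pair:
                    b = pair[0] if pair[1] == a else pair[1]
                    orient = 1.0 if pair[0] == a else -1.0
                    val = orient * (base + 2 * eri[a, b, a, r])
                else:
                    b, c = pair
                    val = base + 2 * eri[a, c, b, r]
            else:
                p, q = set(bi[1:]), set(bj[1:])
                shared = p & q
                if len(shared) == 2:
                    a, b = bi[1], bi[2]
                    val = base - 2 * K[a, b]
                elif len(shared) == 1:
                    s = shared.pop()
                    u = (p - {s}).pop()
                    v = (q - {s}).pop()
                    orient = ((1.0 if bi[1] == u else -1.0)
                              * (1.0 if bj[1] == s else -1.0))
                    val = orient * (-base + 2 * eri[u, s, s, v])
                else:
                    a, b = bi[1], bi[2]
                    c, d = bj[1], bj[2]
                    val = base - 2 * eri[a, d, b, c]
            M[i, j] = M[j, i] = val
    return M


@dataclass
class CIMatrix:
    singlet: np.ndarray
    triplet: np.ndarray
    singlet_energies: np.ndarray
    triplet_energies: np.ndarray


def build_ci(mo: MOIntegrals) -> CIMatrix:
    singlet = build_singlet(mo)
    triplet = build_triplet(mo)
    return CIMatrix(singlet=singlet, triplet=triplet,
                    singlet_energies=np.linalg.eigvalsh(singlet),
                    triplet_energies=np.linalg.eigvalsh(triplet))


def chemionic_energy(singlet_spectrum, triplet_spectrum,
                     degeneracy_tol: float = 1e-9) -> tuple[float, str]:
    """Lowest of the two ground eigenvalues; the singlet wins exact ties."""
    e1 = float(np.min(singlet_spectrum))
    e3 = float(np.min(triplet_spectrum)) if len(triplet_spectrum) else np.inf
    if abs(e1 - e3) < degeneracy_tol:
        return e1, "degenerate"
    if e1 <= e3:
        return e1, "singlet"
    return e3, "triplet"


def total_energy(ensemble: ChemionEnsemble, graph: MoleculeGraph,
                 e_chem: float) -> float:
    """Ground energy E_0 = E_nucl(ε) + E_chem(ε), hartree."""
    return nuclear_repulsion(ensemble, graph) + e_chem
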