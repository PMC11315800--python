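"""Determinant-space full CI with Slater–Condon rules, spin-resolved.

This is an independent route to the CI spectra: the many-chemion Hamiltonian
is represented over all Slater determinants of the M_S = 0 sector (2·#chp
chemions in #chp+1 spatial orbitals), built element-by-element from the
Slater–Condon rules, and diagonalized inside the exact S² eigenspaces.  It
shares nothing with the closed-formula configuration blocks it arbitrates —
no basis ordering, no spin-adapted matrix elements, no √2 factors — and is
used by the validation suite to cross-check their singlet and triplet
spectra.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .fci import MOIntegrals

__all__ = ["determinant_spectra", "determinant_hamiltonian"]


def _phase_single(det: tuple, p: int, q: int) -> int:
    """Sign of replacing occupied p by q in an ordered determinant."""
    i = det.index(p)
    rest = [o for o in det if o != p]
    j = sum(1 for o in rest if o < q)
    return -1 if (i + j) % 2 else 1


def _excitation(d1: tuple, d2: tuple):
    """(degree, removed, added) between two same-length ordered determinants."""
    s1, s2 = set(d1), set(d2)
    removed = sorted(s1 - s2)
    added = sorted(s2 - s1)
    return len(removed), removed, added


def _spin_orbital_lists(alpha: tuple, beta: tuple, n_orb: int):
    """Global spin-orbital labels: spatial p as p (α) and p + n_orb (β)."""
    return tuple(alpha) + tuple(b + n_orb for b in beta)


def _sc_element(d1: tuple, d2: tuple, h_so, eri_so) -> float:
    """⟨D1|H|D2⟩ over ordered spin-orbital determinants (Slater–Condon)."""
    deg, rem, add = _excitation(d1, d2)
    if deg > 2:
        return 0.0
    if deg == 0:
        one = sum(h_so(p, p) for p in d1)
        two = 0.5 * sum(eri_so(p, p, q, q) - eri_so(p, q, q, p)
                        for p in d1 for q in d1)
        return one + two
    if deg == 1:
        p, q = rem[0], add[0]
        sign = _phase_single(d1, p, q)
        val = h_so(p, q) + sum(eri_so(p, q, o, o) - eri_so(p, o, o, q)
                               for o in d1 if o != p)
        return sign * val
    p1, p2 = rem
    q1, q2 = add
    i1, i2 = d1.index(p1), d1.index(p2)
    j1, j2 = d2.index(q1), d2.index(q2)
    sign = -1 if (i1 + i2 + j1 + j2) % 2 else 1
    return sign * (eri_so(p1, q1, p2, q2) - eri_so(p1, q2, p2, q1))


def determinant_hamiltonian(mo: MOIntegrals):
    """H and S² matrices over the M_S = 0 determinant basis."""
    n_orb = mo.chp + 1
    n_pair = mo.chp
    h, eri = mo.h, mo.eri

    def h_so(p, q):
        sp, ssp = p % n_orb, p // n_orb
        sq, ssq = q % n_orb, q // n_orb
        return h[sp, sq] if ssp == ssq else 0.0

    def eri_so(p, q, r, s):
        # chemists' notation over spin orbitals: (pq|rs) δ(σp,σq) δ(σr,σs)
        if p // n_orb != q // n_orb or r // n_orb != s // n_orb:
            return 0.0
        return eri[p % n_orb, q % n_orb, r % n_orb, s % n_orb]

    spatial = list(range(n_orb))
    dets = [(a, b) for a in combinations(spatial, n_pair)
            for b in combinations(spatial, n_pair)]
    so_dets = [_spin_orbital_lists(a, b, n_orb) for a, b in dets]
    dim = len(dets)

    H = np.zeros((dim, dim))
    for i in range(dim):
        for j in range(i, dim):
            H[i, j] = H[j, i] = _sc_element(so_dets[i], so_dets[j], h_so, eri_so)

    # S² = S_z(S_z + 1) + S_- S_+ ; in the M_S = 0 sector S_z terms vanish and
    # S_- S_+ = P^T P with P the matrix of S_+ into the M_S = 1 sector.
    up_dets = {}
    rows = []
    for i, (a, b) in enumerate(dets):
        terms = []
        for p in b:
            if p in a:
                continue
            na = tuple(sorted(a + (p,)))
            nb = tuple(o for o in b if o != p)
            # sign from reordering the global α…β string after the move
            src = _spin_orbital_lists(a, b, n_orb)
            dst = _spin_orbital_lists(na, nb, n_orb)
            moved = p + n_orb
            # remove β_p then create α_p: count crossings in the source string
            k = src.index(moved)
            sign1 = (-1) ** k
            k2 = sum(1 for o in dst[:dst.index(p)] if True)
            sign2 = (-1) ** k2
            key = (na, nb)
            if key not in up_dets:
                up_dets[key] = len(up_dets)
            terms.append((up_dets[key], sign1 * sign2))
        rows.append(terms)
    P = np.zeros((len(up_dets), dim))
    for i, terms in enumerate(rows):
        for col, sign in terms:
            P[col, i] += sign
    S2 = P.T @ P
    return H, S2, dets


def determinant_spectra(mo: MOIntegrals, tol: float = 1e-8):
    """Exact singlet (S=0) and triplet (S=1) spectra from determinant FCI.

    S² is diagonalized first; H is projected into each spin eigenspace and
    diagonalized there, so degenerate H eigenvalues of mixed spin cannot leak
    between the sectors.
    """
    H, S2, _ = determinant_hamiltonian(mo)
    evals, evecs = np.linalg.eigh(S2)
    out = {}
    for label, s2_target in (("singlet", 0.0), ("triplet", 2.0)):
        mask = np.abs(evals - s2_target) < tol
        if not mask.any():
            out[label] = np.array([])
            continue
        V = evecs[:, mask]
        out[label] = np.linalg.eigvalsh(V.T @ H @ V)
    return out["singlet"], out["triplet"]
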