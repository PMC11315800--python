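"""Vertex condensation: recursion orbitals, condensed blocks, integral budgets.

A *recursion orbital* replaces a group of vertex orbitals by their normalized
sum,

    φ_ω = N_ω Σ_p φ_p,    N_ω = {Σ_p Σ_q S(p,q)}^(−1/2),

so a whole fragment enters higher levels as a single vertex.  Condensing any
integral family is then the normalized double (or quadruple) sum of the
precursor blocks — equivalently a congruence with the aggregation matrix
T[p, g] = N_g for p in group g.  Because the sums are linear, condensing
condensed blocks equals condensing the anchors in one shot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sto import AnchorIntegralSet

__all__ = [
    "RecursionOrbital", "condense_normalization", "aggregation_matrix",
    "condense_integrals", "one_chemion_matrix", "condense_fock_block",
    "condense_fock", "integral_budget",
]


class CondensationError(ValueError):
    """Raised for pathological member sets (non-positive overlap sums)."""


@dataclass
class RecursionOrbital:
    """A condensed orbital: member ids at the previous level and its norm."""

    level: int
    members: tuple[int, ...]
    norm: float


def condense_normalization(members, S_prev: np.ndarray) -> float:
    """Normalization N = {Σ_p Σ_q S(p,q)}^(−1/2) over a member set."""
    idx = np.asarray(list(members), dtype=int)
    total = float(S_prev[np.ix_(idx, idx)].sum())
    if total <= 0.0:
        raise CondensationError(
            f"overlap sum {total:.3e} over members {tuple(members)} is not positive"
        )
    return total ** -0.5


def aggregation_matrix(groups, S_prev: np.ndarray) -> np.ndarray:
    """T with T[p, g] = N_g for p in group g, zero elsewhere."""
    nv = S_prev.shape[0]
    flat = [i for g in groups for i in g]
    if sorted(flat) != sorted(set(flat)):
        raise CondensationError("condensation groups must be disjoint")
    T = np.zeros((nv, len(groups)))
    for g, members in enumerate(groups):
        T[list(members), g] = condense_normalization(members, S_prev)
    return T


def condense_integrals(aset: AnchorIntegralSet, groups,
                       level: int = 1) -> tuple[AnchorIntegralSet, list[RecursionOrbital]]:
    """Condense all four integral families over the given vertex groups.

    Each condensed value is the product of member normalizations times the
    double (or quadruple) sum of precursor values.  Returns the condensed
    block set (one vertex per group; the nucleus axis is untouched) and the
    recursion orbitals.
    """
    T = aggregation_matrix(groups, aset.S)
    S = T.T @ aset.S @ T
    K = T.T @ aset.K @ T
    U = np.einsum("pa,qb,pqc->abc", T, T, aset.U, optimize=True)
    R = np.einsum("pa,qb,rc,sd,pqrs->abcd", T, T, T, T, aset.R, optimize=True)
    orbitals = [RecursionOrbital(level=level, members=tuple(g), norm=float(T[g[0], i]))
                for i, g in enumerate(groups)]
    out = AnchorIntegralSet(S=S, K=K, U=U, R=R, mode=aset.mode,
                            expansion_order=aset.expansion_order)
    return out, orbitals


def one_chemion_matrix(K: np.ndarray, U: np.ndarray,
                       z_prop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Charge-weighted attraction V = Σ_C Z_prop(C) U(·,·,C) and H = K − V."""
    z = np.asarray(z_prop, dtype=float)
    if U.shape[2] != z.shape[0]:
        raise ValueError("charge vector length must match the nucleus axis of U")
    V = np.einsum("mnc,c->mn", U, z)
    return V, K - V


def condense_fock_block(F_prev: np.ndarray, groups, S_prev: np.ndarray) -> np.ndarray:
    """Condense a precursor Fock block: F(α,β) = N_α N_β Σ Σ F_prev(m,n)."""
    T = aggregation_matrix(groups, S_prev)
    return T.T @ F_prev @ T


def condense_fock(bank, fragment_key: str, groups=None):
    """The "if available" branch: condense a Fock block stored in the bank.

    Returns the condensed block, or None ("not available") when the bank holds
    no block under this exact key — the caller then falls back to the fresh
    Roothaan build.  Reuse never crosses ensemble labels or geometry hashes
    because both are part of the key.
    """
    entry = bank.load(fragment_key)
    if entry is None or "F" not in entry.blocks or "S" not in entry.blocks:
        return None
    if groups is None:
        return entry.blocks["F"].copy()
    return condense_fock_block(entry.blocks["F"], groups, entry.blocks["S"])


def integral_budget(n=None, include_loves: bool = True, n_love: int = 0) -> dict:
    """New-integral counts for one prolongation step of the chain growth.

    For the anchor chart H–XV3 (``n`` None or "anchor") all 5 vertices are
    new: 5² overlaps/kinetics, ≤5³ attractions, 5⁴ repulsions.  For chain step
    n ≥ 0 the molecule has a = 3n+8 vertices of which the reused precursor
    fragment covers b = 3n+4, so only entries touching the 4 new vertices are
    fresh: #S = #K = a²−b², #U ≤ a³−b³, #R = a⁴−b⁴.  The attraction bound
    carries "≤" semantics (the nucleus axis is shorter whenever lone pairs are
    present).  With ``include_loves`` False the ``n_love`` lone-pair vertices
    of the terminal are excluded from both vertex totals.
    """
    if n is None or n == "anchor" or (isinstance(n, int) and n < 0):
        a, b = 5, 0
    else:
        a, b = 3 * n + 8, 3 * n + 4
    if not include_loves:
        a, b = a - n_love, max(b - n_love, 0)
    return {
        "S": a * a - b * b,
        "K": a * a - b * b,
        "U_bound": a ** 3 - b ** 3,
        "R": a ** 4 - b ** 4,
        "a": a,
        "b": b,
    }
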