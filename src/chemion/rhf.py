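"""Restricted Hartree–Fock in the vertex basis for one chemion ensemble.

The Roothaan generalized eigenproblem F C = S C E is iterated with the
closed-shell density D = 2 Σ_o C(:,o) C(:,o)^T built from the #chp lowest
orbitals, until the RMS density change

    σ(i) = { #vtx^−2 Σ_mn [D_mn(i) − D_mn(i−1)]² }^(1/2)

falls below the threshold (1e-4 by default; tightened for CI input).  The
Fock matrix is F = H + W_cou − ½ W_exc with the symmetrized exchange kernel
½{R(αγ|βδ) + R(αδ|γβ)}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .condense import one_chemion_matrix
from .molecule import ChemionEnsemble
from .sto import AnchorIntegralSet, LinearDependenceError

__all__ = ["SCFState", "density_matrix", "build_fock", "solve_roothaan",
           "scf", "electronic_energy"]


@dataclass
class SCFState:
    """Converged (or flagged) self-consistent-field result."""

    C: np.ndarray
    E_orb: np.ndarray
    D: np.ndarray
    F: np.ndarray
    H: np.ndarray
    S: np.ndarray
    chp: int
    energy: float                     # electronic energy E_0^RHF, hartree
    iterations: int
    sigma_history: list = field(default_factory=list)
    energy_history: list = field(default_factory=list)
    converged: bool = False


def density_matrix(C: np.ndarray, chp: int) -> np.ndarray:
    """Closed-shell density from the chp lowest-energy occupied columns."""
    if C.shape[1] < chp:
        raise ValueError(f"need at least {chp} orbitals, got {C.shape[1]}")
    occ = C[:, :chp]
    return 2.0 * occ @ occ.T


def build_fock(H: np.ndarray, R: np.ndarray, D: np.ndarray) -> np.ndarray:
    """F = H + W_cou − ½ W_exc, with the symmetrized exchange as printed."""
    w_cou = np.einsum("abgd,gd->ab", R, D, optimize=True)
    w_exc = 0.5 * (np.einsum("agbd,gd->ab", R, D, optimize=True)
                   + np.einsum("adgb,gd->ab", R, D, optimize=True))
    return H + w_cou - 0.5 * w_exc


def solve_roothaan(F: np.ndarray, S: np.ndarray,
                   s_min_eig: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Generalized symmetric eigenpairs of F C = S C E.

    Solved via symmetric (Löwdin) orthogonalization; eigenvalues ascending,
    column phases fixed so the largest-magnitude coefficient is positive.
    """
    s_eig = np.linalg.eigvalsh(S)
    if s_eig[0] < s_min_eig:
        raise LinearDependenceError(
            f"overlap matrix near-singular (eigenvalue {s_eig[0]:.3e})")
    e, c = scipy.linalg.eigh(F, S)
    for k in range(c.shape[1]):
        lead = np.argmax(np.abs(c[:, k]))
        if c[lead, k] < 0:
            c[:, k] = -c[:, k]
    return c, e


def electronic_energy(D: np.ndarray, H: np.ndarray, F: np.ndarray) -> float:
    """E_0^RHF in trace form: ½ Σ D (H + F)."""
    return 0.5 * float(np.einsum("mn,mn->", D, H + F))


def scf(integrals: AnchorIntegralSet, ensemble: ChemionEnsemble, *,
        scf_tol: float = 1e-4, max_iter: int = 200, damping: float = 0.0,
        guess: str = "core") -> SCFState:
    """Iterate Fock build → Roothaan solve → density until σ < scf_tol.

    A non-converged run returns a flagged state rather than raising.  With a
    damping factor λ the new density is (1−λ) D_new + λ D_old, which makes the
    electronic energy descend monotonically on oscillatory cases.
    """
    nv = integrals.n_vtx
    chp = ensemble.chp
    if chp >= nv:
        raise ValueError(f"#chp={chp} must be below the basis size {nv}")
    _, H = one_chemion_matrix(integrals.K, integrals.U, ensemble.z_prop)
    S, R = integrals.S, integrals.R

    if guess == "core":
        D = np.zeros((nv, nv))
    elif guess == "huckel":
        C0, _ = solve_roothaan(H, S)
        D = density_matrix(C0, chp)
    else:
        raise ValueError(f"unknown initial guess {guess!r}")

    sigma_history: list[float] = []
    energy_history: list[float] = []
    C = np.eye(nv)
    E_orb = np.zeros(nv)
    F = H.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        F = build_fock(H, R, D)
        C, E_orb = solve_roothaan(F, S)
        D_new = density_matrix(C, chp)
        if damping > 0.0 and it > 1:
            D_new = (1.0 - damping) * D_new + damping * D
        sigma = float(np.sqrt(((D_new - D) ** 2).sum()) / nv)
        sigma_history.append(sigma)
        D = D_new
        energy_history.append(electronic_energy(D, H, build_fock(H, R, D)))
        if sigma < scf_tol:
            converged = True
            break

    F = build_fock(H, R, D)
    return SCFState(C=C, E_orb=E_orb, D=D, F=F, H=H, S=S, chp=chp,
                    energy=electronic_energy(D, H, F),
                    iterations=it, sigma_history=sigma_history,
                    energy_history=energy_history, converged=converged)
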