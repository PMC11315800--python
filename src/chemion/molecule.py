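"""Euler-vertex topologies and standard tetrahedral model geometries.

A molecule is a graph of *vertices* — bonding sites in the sense of Euler's
topology rule: central atoms, hydrogen ligands, and lone-pair positions
("loves").  Every singly-bound topology built here satisfies

    #vtx = #chp + 1

where #chp counts shared chemion (electron) pairs: one per bond plus one per
lone pair.  Geometries are ideal tetrahedra: one bond angle arccos(−1/3), one
dihedral 2π/3, bond lengths from a configurable table, and lone pairs at one
Bohr radius from their parent atom.  All coordinates are in bohr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import (
    BOHR_ANGSTROM,
    CENTRAL_ELEMENTS,
    LONE_PAIR_DISTANCE,
    LONE_PAIRS,
    N_VAL,
    TERMINAL_ELEMENT,
    TETRA_ANGLE,
    DIHEDRAL_ANGLE,
    Z_VAL,
    bond_length_bohr,
)


class TopologyError(ValueError):
    """Raised for malformed or unsupported molecular topologies."""


class GeometryError(ValueError):
    """Raised for degenerate geometries (e.g. coincident nuclei)."""


#: The four ideal tetrahedron directions from a center.
TETRA_DIRECTIONS = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / math.sqrt(3.0)


@dataclass
class Vertex:
    """One Euler vertex: a bonding site carrying exactly one basis orbital.

    ``z_val``/``n_val`` follow the periodic-table column/row indices; a
    lone-pair vertex inherits both from its parent atom (it shares the parent's
    valence shell) but carries no nuclear charge.  The default orbital exponent
    is the ratio zeta = z_val / n_val.
    """

    label: str
    kind: str  # "central-atom" | "hydrogen-ligand" | "lone-pair"
    element: str
    position: np.ndarray
    z_val: int = 0
    n_val: int = 0
    zeta: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not self.z_val:
            self.z_val = Z_VAL[self.element]
        if not self.n_val:
            self.n_val = N_VAL[self.element]
        if not self.zeta:
            self.zeta = self.z_val / self.n_val


@dataclass
class Torsion:
    """A rotatable backbone bond with its dihedral bookkeeping.

    ``bond`` joins two tetrahedral centers; the dihedral is measured between
    ``ref_prox`` and ``ref_dist`` (the first-listed ligand on each side,
    IUPAC sign convention) and rotating sets the angle by rigidly turning
    every vertex in ``distal`` about the bond axis.
    """

    bond: tuple[int, int]
    ref_prox: int
    ref_dist: int
    distal: tuple[int, ...]


@dataclass
class MoleculeGraph:
    vertices: list[Vertex]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    torsions: list[Torsion] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def nuclei(self) -> list[int]:
        """Indices of vertices carrying a nucleus (lone pairs never do)."""
        return [i for i, v in enumerate(self.vertices) if v.kind != "lone-pair"]

    @property
    def n_vtx(self) -> int:
        return len(self.vertices)

    @property
    def n_chp(self) -> int:
        n_love = sum(1 for v in self.vertices if v.kind == "lone-pair")
        return len(self.bonds) + n_love

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.position for v in self.vertices])

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(
            vertices=[replace(v, position=v.position.copy()) for v in self.vertices],
            bonds=list(self.bonds),
            torsions=list(self.torsions),
            meta=dict(self.meta),
        )


def euler_counts(graph: MoleculeGraph) -> tuple[int, int, int]:
    """Return (#vtx, #chp, #nuc) and enforce the Euler rule #vtx = #chp + 1."""
    n_vtx, n_chp, n_nuc = graph.n_vtx, graph.n_chp, len(graph.nuclei)
    if n_vtx != n_chp + 1:
        raise TopologyError(
            f"Euler rule violated: #vtx={n_vtx} but #chp+1={n_chp + 1}"
        )
    return n_vtx, n_chp, n_nuc


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 (IUPAC right-hand convention), radians."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    c12, c23 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(c12, c23), b2) / np.linalg.norm(b2)
    x = np.dot(c12, c23)
    return math.atan2(y, x)


def _orthonormal_frame(axis: np.ndarray, hint: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis``; e1 along ``hint``'s normal part."""
    u = axis / np.linalg.norm(axis)
    if hint is None or np.linalg.norm(hint - np.dot(hint, u) * u) < 1e-10:
        hint = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(hint, u)) > 0.9:
            hint = np.array([0.0, 1.0, 0.0])
    e1 = hint - np.dot(hint, u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _make_vertex(element: str, kind: str, label: str, position) -> Vertex:
    return Vertex(label=label, kind=kind, element=element, position=np.asarray(position))


def build_monofocal(element: str, bond_lengths: dict | None = None) -> MoleculeGraph:
    """Build one of the eight anchor hydrides as a 5-vertex tetrahedral chart.

    The central atom sits at the origin; the four peripheral tetrahedron slots
    are filled left-to-right with hydrogen ligands first, then lone pairs at
    one Bohr radius.  #vtx = 5, #chp = 4 for every anchor.
    """
    if element not in CENTRAL_ELEMENTS:
        raise TopologyError(f"unknown monofocal element {element!r}; "
                            f"expected one of {CENTRAL_ELEMENTS}")
    n_love = LONE_PAIRS[element]
    n_h = 4 - n_love
    lam_h = bond_length_bohr(element, "H", bond_lengths)
    vertices = [_make_vertex(element, "central-atom", element, np.zeros(3))]
    bonds = []
    for k in range(4):
        direction = TETRA_DIRECTIONS[k]
        if k < n_h:
            vertices.append(_make_vertex("H", "hydrogen-ligand", f"H{k + 1}",
                                         lam_h * direction))
            bonds.append((0, len(vertices) - 1))
        else:
            lp = _make_vertex(element, "lone-pair", f"lp{k - n_h + 1}",
                              LONE_PAIR_DISTANCE * direction)
            vertices.append(lp)
    graph = MoleculeGraph(vertices=vertices, bonds=bonds,
                          meta={"family": "monofocal", "element": element})
    euler_counts(graph)
    return graph


def _place_substituents(center: np.ndarray, parent: np.ndarray,
                        n_subs: int, ref_point: np.ndarray | None,
                        tau: float | None) -> list[np.ndarray]:
    """Unit directions of ``n_subs`` tetrahedral substituents of a center.

    Directions make the tetrahedron angle with the center→parent bond and are
    spaced 120° apart in azimuth about it.  If ``tau`` is given, the azimuth of
    the *first* substituent is chosen so that the dihedral
    ref_point – parent – center – first_sub equals ``tau`` exactly.
    """
    u = center - parent
    u /= np.linalg.norm(u)
    e1, e2 = _orthonormal_frame(u, None if ref_point is None
                                else np.asarray(ref_point) - parent)
    a = math.pi - TETRA_ANGLE

    def direction(phi):
        return math.cos(a) * u + math.sin(a) * (math.cos(phi) * e1 + math.sin(phi) * e2)

    phi0 = 0.0
    if tau is not None and ref_point is not None:
        # The dihedral is linear in the azimuth; fix offset and sign numerically.
        d0 = dihedral(ref_point, parent, center, center + direction(0.0))
        d1 = dihedral(ref_point, parent, center, center + direction(0.1))
        sign = 1.0 if math.remainder(d1 - d0, 2 * math.pi) > 0 else -1.0
        phi0 = sign * (tau - d0)
    return [direction(phi0 + k * DIHEDRAL_ANGLE) for k in range(n_subs)]


def build_chain(n: int, terminal: str, torsions=None,
                bond_lengths: dict | None = None) -> MoleculeGraph:
    """Build the explicit-vertex chain H–(CH2)n–X with X a terminal group.

    ``torsions`` (radians, length n) are the dihedrals of the n backbone bonds
    between consecutive tetrahedral centers, index k for the bond joining
    center k and center k+1 (the terminal heavy atom is the last center).
    Vertex count is 3n + 5 plus one vertex per lone pair of the terminal.
    """
    if n < 0:
        raise TopologyError("chain length n must be >= 0")
    if terminal not in TERMINAL_ELEMENT:
        raise TopologyError(f"unsupported terminal group {terminal!r}; "
                            f"expected one of {tuple(TERMINAL_ELEMENT)}")
    torsions = [0.0] * n if torsions is None else [float(t) for t in torsions]
    if len(torsions) != n:
        raise TopologyError(f"expected {n} torsion angles, got {len(torsions)}")

    x_elem = TERMINAL_ELEMENT[terminal]
    chain_elems = ["C"] * n + [x_elem]          # heavy centers
    vertices = [_make_vertex("H", "hydrogen-ligand", "H0", np.zeros(3))]
    bonds: list[tuple[int, int]] = []
    torsion_records: list[Torsion] = []

    lam0 = bond_length_bohr("H", chain_elems[0], bond_lengths)
    pos0 = np.array([0.0, 0.0, lam0])
    vertices.append(_make_vertex(chain_elems[0], "central-atom",
                                 f"{chain_elems[0]}1", pos0))
    bonds.append((0, 1))

    heavy_idx = [1]                 # vertex indices of the heavy centers
    parent_idx = [0]                # chain predecessor of each heavy center
    first_sub_idx: list[int | None] = []

    for k, elem in enumerate(chain_elems):
        c_idx = heavy_idx[k]
        center = vertices[c_idx].position
        parent = vertices[parent_idx[k]].position
        is_last = k == n
        n_love = LONE_PAIRS[elem] if is_last else 0
        n_h = (4 - 1 - n_love) if is_last else 2
        n_subs = (0 if is_last else 1) + n_h + n_love

        ref_point = None
        tau = None
        if k > 0:
            ref_point = vertices[parent_idx[k - 1]].position
            tau = torsions[k - 1]
        dirs = _place_substituents(center, parent, n_subs, ref_point, tau)

        sub_indices = []
        d_iter = iter(dirs)
        if not is_last:
            nxt = chain_elems[k + 1]
            lam = bond_length_bohr(elem, nxt, bond_lengths)
            pos = center + lam * next(d_iter)
            vertices.append(_make_vertex(nxt, "central-atom", f"{nxt}{k + 2}", pos))
            j = len(vertices) - 1
            bonds.append((c_idx, j))
            sub_indices.append(j)
            heavy_idx.append(j)
            parent_idx.append(c_idx)
        lam_h = bond_length_bohr(elem, "H", bond_lengths)
        for h in range(n_h):
            pos = center + lam_h * next(d_iter)
            vertices.append(_make_vertex("H", "hydrogen-ligand",
                                         f"H{c_idx}.{h + 1}", pos))
            j = len(vertices) - 1
            bonds.append((c_idx, j))
            sub_indices.append(j)
        for lv in range(n_love):
            pos = center + LONE_PAIR_DISTANCE * next(d_iter)
            vertices.append(_make_vertex(elem, "lone-pair",
                                         f"lp{c_idx}.{lv + 1}", pos))
            sub_indices.append(len(vertices) - 1)
        first_sub_idx.append(sub_indices[0] if sub_indices else None)

    graph = MoleculeGraph(vertices=vertices, bonds=bonds,
                          meta={"family": "chain", "n": n, "terminal": terminal,
                                "heavy_idx": list(heavy_idx)})

    # Torsion records: bond k joins heavy center k and k+1.
    adjacency = _adjacency(graph)
    for k in range(n):
        i, j = heavy_idx[k], heavy_idx[k + 1]
        distal = _component_beyond(adjacency, i, j)
        torsion_records.append(Torsion(bond=(i, j),
                                       ref_prox=parent_idx[k],
                                       ref_dist=first_sub_idx[k + 1],
                                       distal=tuple(sorted(distal))))
    graph.torsions = torsion_records
    euler_counts(graph)
    return graph


def build_diatomic(element_a: str, element_b: str,
                   torsion: float = 0.0,
                   bond_lengths: dict | None = None) -> MoleculeGraph:
    """Two bonded tetrahedral centers with their hydrogens and lone pairs.

    Covers the axially symmetric halogen pairs (F2, Cl2, FCl …) whose
    vertex bases nevertheless produce a torsion dependence — a known
    artifact of placing lone pairs at discrete tetrahedron slots.  The
    torsion is measured between the first peripheral vertex on each side.
    """
    for el in (element_a, element_b):
        if el not in CENTRAL_ELEMENTS:
            raise TopologyError(f"unknown central element {el!r}")
    lam = bond_length_bohr(element_a, element_b, bond_lengths)
    pos_a = np.zeros(3)
    pos_b = np.array([0.0, 0.0, lam])
    vertices = [_make_vertex(element_a, "central-atom", element_a, pos_a),
                _make_vertex(element_b, "central-atom", element_b, pos_b)]
    bonds = [(0, 1)]

    def add_peripherals(center_idx, other_pos, elem, ref_point, tau):
        center = vertices[center_idx].position
        n_love = LONE_PAIRS[elem]
        n_h = 3 - n_love
        dirs = _place_substituents(center, other_pos, 3, ref_point, tau)
        lam_h = bond_length_bohr(elem, "H", bond_lengths) if n_h else 0.0
        first = None
        for k, d in enumerate(dirs):
            if k < n_h:
                vertices.append(_make_vertex("H", "hydrogen-ligand",
                                             f"H{center_idx}.{k + 1}",
                                             center + lam_h * d))
                bonds.append((center_idx, len(vertices) - 1))
            else:
                vertices.append(_make_vertex(elem, "lone-pair",
                                             f"lp{center_idx}.{k - n_h + 1}",
                                             center + LONE_PAIR_DISTANCE * d))
            if first is None:
                first = len(vertices) - 1
        return first

    ref_a = add_peripherals(0, pos_b, element_a, None, None)
    ref_b = add_peripherals(1, pos_a, element_b,
                            vertices[ref_a].position, float(torsion))
    graph = MoleculeGraph(vertices=vertices, bonds=bonds,
                          meta={"family": "diatomic",
                                "elements": (element_a, element_b),
                                "heavy_idx": [0, 1]})
    adjacency = _adjacency(graph)
    distal = _component_beyond(adjacency, 0, 1)
    graph.torsions = [Torsion(bond=(0, 1), ref_prox=ref_a, ref_dist=ref_b,
                              distal=tuple(sorted(distal)))]
    euler_counts(graph)
    return graph


def _adjacency(graph: MoleculeGraph) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(graph.n_vtx)}
    for i, j in graph.bonds:
        adj[i].add(j)
        adj[j].add(i)
    # Lone pairs hang off their parent atom (nearest central atom).
    for i, v in enumerate(graph.vertices):
        if v.kind == "lone-pair":
            parent = min(
                (j for j, w in enumerate(graph.vertices) if w.kind == "central-atom"),
                key=lambda j: np.linalg.norm(graph.vertices[j].position - v.position),
            )
            adj[i].add(parent)
            adj[parent].add(i)
    return adj


def _component_beyond(adjacency, i: int, j: int) -> set[int]:
    """Vertices on j's side of the bond (i, j), including j."""
    seen = {i, j}
    stack = [j]
    while stack:
        for nb in adjacency[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    seen.discard(i)
    return seen


def get_torsion(graph: MoleculeGraph, index: int) -> float:
    """Current dihedral of backbone bond ``index``, radians in [0, 2π)."""
    t = graph.torsions[index]
    pos = graph.positions
    val = dihedral(pos[t.ref_prox], pos[t.bond[0]], pos[t.bond[1]], pos[t.ref_dist])
    return val % (2 * math.pi)


def set_torsion(graph: MoleculeGraph, index: int, tau: float) -> MoleculeGraph:
    """Return a copy with backbone torsion ``index`` set to ``tau`` (radians).

    The distal fragment is rotated rigidly about the bond axis; bond lengths
    and angles are preserved exactly.
    """
    if not 0 <= index < len(graph.torsions):
        raise TopologyError(f"invalid torsion index {index}")
    out = graph.copy()
    t = out.torsions[index]
    current = get_torsion(out, index)
    delta = tau - current
    i, j = t.bond
    axis = out.vertices[j].position - out.vertices[i].position
    axis /= np.linalg.norm(axis)
    # A right-hand rotation of the distal side about the i→j axis by +ψ
    # increases the IUPAC dihedral by +ψ.
    rot = Rotation.from_rotvec(axis * delta)
    pivot = out.vertices[j].position.copy()
    for k in t.distal:
        v = out.vertices[k]
        v.position = pivot + rot.apply(v.position - pivot)
    return out


def subgraph(graph: MoleculeGraph, indices) -> MoleculeGraph:
    """Vertex-subset graph (a fragment), keeping bonds internal to the subset.

    Fragments with dangling bonds are legitimate here — they only serve as
    integral carriers, not as standalone Euler charts.
    """
    indices = list(indices)
    remap = {old: new for new, old in enumerate(indices)}
    return MoleculeGraph(
        vertices=[replace(graph.vertices[i], position=graph.vertices[i].position.copy())
                  for i in indices],
        bonds=[(remap[i], remap[j]) for i, j in graph.bonds
               if i in remap and j in remap],
        meta={"family": "fragment", "parent_indices": indices},
    )


# ---------------------------------------------------------------------------
# Chemion ensembles and proportional nuclear charges
# ---------------------------------------------------------------------------

@dataclass
class ChemionEnsemble:
    """A chemion subset ε with its pair count and proportional nuclear charges.

    The ε-dependent charges distribute the ensemble's total chemion charge
    2·#chp(ε) over all nuclei in proportion to their valence charges, so that
    Σ_C Z_prop(C) = 2·#chp(ε) for every ensemble.
    """

    kind: str  # "full-molecule" | "off-diagonal-ab" | "diagonal-aa" | "diagonal-bb"
    member_vertices: tuple[int, ...]
    chp: int
    z_prop: np.ndarray


def proportional_charges(chp: int, graph: MoleculeGraph) -> np.ndarray:
    """Proportional valence charges: Z_val(C) · 2·#chp / Σ_D Z_val(D), per nucleus."""
    nuclei = graph.nuclei
    if not nuclei:
        raise TopologyError("graph has no nuclei")
    if chp < 1:
        raise ValueError("ensemble must contain at least one chemion pair")
    z_val = np.array([graph.vertices[i].z_val for i in nuclei], dtype=float)
    total = z_val.sum()
    if total <= 0:
        raise ValueError("zero total valence charge")
    return z_val * (2.0 * chp / total)


def full_molecule_ensemble(graph: MoleculeGraph) -> ChemionEnsemble:
    chp = graph.n_chp
    return ChemionEnsemble(kind="full-molecule",
                           member_vertices=tuple(range(graph.n_vtx)),
                           chp=chp, z_prop=proportional_charges(chp, graph))


def chain_bond_ensemble(graph: MoleculeGraph, torsion_index: int = 0) -> ChemionEnsemble:
    """The single chemion pair of one backbone bond (#chp = 1)."""
    if not graph.torsions:
        raise TopologyError("graph has no backbone torsion bonds")
    if not 0 <= torsion_index < len(graph.torsions):
        raise TopologyError(f"invalid torsion index {torsion_index}")
    return ChemionEnsemble(kind="off-diagonal-ab",
                           member_vertices=tuple(range(graph.n_vtx)),
                           chp=1, z_prop=proportional_charges(1, graph))


def fragment_ensemble(graph: MoleculeGraph, members, chp: int,
                      kind: str = "diagonal-aa") -> ChemionEnsemble:
    return ChemionEnsemble(kind=kind, member_vertices=tuple(members),
                           chp=chp, z_prop=proportional_charges(chp, graph))


def nuclear_repulsion(ensemble: ChemionEnsemble, graph: MoleculeGraph) -> float:
    """Pairwise Coulomb repulsion of the proportional point charges, hartree."""
    nuclei = graph.nuclei
    pos = np.array([graph.vertices[i].position for i in nuclei])
    z = ensemble.z_prop
    energy = 0.0
    for a in range(len(nuclei)):
        for b in range(a + 1, len(nuclei)):
            r = np.linalg.norm(pos[a] - pos[b])
            if r < 1e-10:
                raise GeometryError(f"coincident nuclei {nuclei[a]} and {nuclei[b]}")
            energy += z[a] * z[b] / r
    return energy


# ---------------------------------------------------------------------------
# Fragment splits for vertex condensation
# ---------------------------------------------------------------------------

def bond_split(graph: MoleculeGraph, torsion_index: int) -> tuple[list[int], list[int]]:
    """Split the vertex set at a backbone bond into (proximal, distal) groups.

    The proximal group holds the methyl-side fragment, the distal group the
    rest of the chain — the two recursion-orbital member sets of the two-vertex
    chain chart (#vtx = 2, #chp = 1).
    """
    t = graph.torsions[torsion_index]
    distal = set(t.distal)
    prox = [i for i in range(graph.n_vtx) if i not in distal]
    return prox, sorted(distal)


def functional_group_partition(graph: MoleculeGraph) -> list[list[int]]:
    """Partition a chain into its n+2 functional groups: H, n×CH2, terminal.

    This is the condensed chart at the functional-group level, where the Euler
    rule reads #vtx = n + 2 = #chp + 1.
    """
    if graph.meta.get("family") != "chain":
        raise TopologyError("functional-group partition is defined for chains")
    heavy = graph.meta["heavy_idx"]
    adjacency = _adjacency(graph)
    groups = [[0]]
    for k, c in enumerate(heavy):
        members = [c] + sorted(
            nb for nb in adjacency[c]
            if nb != 0 and nb not in heavy
        )
        groups.append(members)
    return groups
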