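"""Molecule specs (YAML) and XYZ geometry I/O.

Geometries are exchanged in plain XYZ with coordinates in ångström; the
comment line records the chain spec, current torsions (degrees) and,
optionally, the ensemble kind.  Lone-pair vertices are emitted with the
dummy symbol "X" when requested (they are model bookkeeping, not atoms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import BOHR_ANGSTROM
from .molecule import MoleculeGraph, TopologyError, build_chain, build_monofocal

__all__ = ["MoleculeSpec", "write_xyz", "read_xyz"]


@dataclass
class MoleculeSpec:
    """Structured description of a buildable molecule.

    ``terminal`` + ``n`` select the chain H–(CH2)n–X; ``monofocal`` selects an
    anchor hydride instead.  ``torsions_deg`` are the backbone dihedrals.
    """

    terminal: str = "CH3"
    n: int = 1
    torsions_deg: list = field(default_factory=list)
    bond_lengths: dict = field(default_factory=dict)
    exponent_rule: str = "ratio"
    monofocal: str | None = None

    def __post_init__(self):
        if self.exponent_rule != "ratio":
            raise TopologyError(
                f"unsupported exponent rule {self.exponent_rule!r} (only 'ratio')")

    @classmethod
    def from_yaml(cls, text: str) -> "MoleculeSpec":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "MoleculeSpec":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def build(self) -> MoleculeGraph:
        if self.monofocal is not None:
            return build_monofocal(self.monofocal, self.bond_lengths or None)
        torsions = [math.radians(t) for t in self.torsions_deg] or None
        return build_chain(self.n, self.terminal, torsions,
                           self.bond_lengths or None)

    def key_dict(self) -> dict:
        return {"terminal": self.terminal, "n": self.n,
                "monofocal": self.monofocal,
                "bond_lengths": {("-".join(k) if not isinstance(k, str) else k): v
                                 for k, v in self.bond_lengths.items()},
                "exponent_rule": self.exponent_rule}


def write_xyz(graph: MoleculeGraph, path, comment: str = "",
              include_loves: bool = False) -> None:
    """Write standard XYZ (Å); lone pairs appear as symbol "X" if requested."""
    lines = []
    for v in graph.vertices:
        if v.kind == "lone-pair" and not include_loves:
            continue
        sym = "X" if v.kind == "lone-pair" else v.element
        x, y, z = v.position * BOHR_ANGSTROM
        lines.append(f"{sym:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    with open(path, "w") as fh:
        fh.write(f"{len(lines)}\n{comment}\n")
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> tuple[list[str], np.ndarray, str]:
    """Read standard XYZ; returns (symbols, positions in bohr, comment)."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    count = int(raw[0].strip())
    comment = raw[1] if len(raw) > 1 else ""
    symbols, coords = [], []
    for line in raw[2:2 + count]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return symbols, np.array(coords) / BOHR_ANGSTROM, comment
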