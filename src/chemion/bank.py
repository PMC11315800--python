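"""The fragment bank: a persistent keyed store of condensed blocks.

Precomputed fragment quantities (S, K, U, R, F, H blocks) are stored on disk
in an HDF5 file, keyed by everything that could change an integral: element
sequence, bond-length table, exponent rule, torsion grid values (rounded to
1e-9 rad), evaluation mode, expansion order, condensation level and ensemble
label, plus a hash of the fragment's internal geometry.  A lookup only hits
when the whole key matches, so a stored block is never silently reused for a
different geometry or ensemble.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .molecule import MoleculeGraph

__all__ = ["FragmentBank", "fragment_key", "geometry_hash", "BankEntry"]


def geometry_hash(graph: MoleculeGraph, members=None) -> str:
    """Hash of a fragment's internal geometry (pairwise distances, 1e-9 bohr).

    Pairwise distances make the hash invariant under rigid motion of the
    fragment — exactly the invariance of its internal integrals.
    """
    idx = list(range(graph.n_vtx)) if members is None else list(members)
    pos = np.array([graph.vertices[i].position for i in idx])
    labels = ",".join(f"{graph.vertices[i].element}:{graph.vertices[i].kind}"
                      for i in idx)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    rounded = np.round(d[np.triu_indices(len(idx), k=1)], 9)
    h = hashlib.sha256()
    h.update(labels.encode())
    h.update(rounded.tobytes())
    return h.hexdigest()[:32]


def fragment_key(graph: MoleculeGraph, members=None, *, level: int = 0,
                 ensemble_kind: str = "none", torsion: float | None = None,
                 mode: str = "exact", order: int = 6,
                 exponent_rule: str = "ratio",
                 bond_lengths: dict | None = None) -> str:
    """Deterministic bank key for a fragment's condensed blocks."""
    meta = {
        "geometry": geometry_hash(graph, members),
        "level": level,
        "ensemble": ensemble_kind,
        "torsion": None if torsion is None else round(float(torsion), 9),
        "mode": mode,
        "order": order,
        "exponent_rule": exponent_rule,
        "bond_lengths": sorted(
            ("-".join(k) if not isinstance(k, str) else k, float(v))
            for k, v in (bond_lengths or {}).items()
        ),
    }
    digest = hashlib.sha256(json.dumps(meta, sort_keys=True).encode()).hexdigest()
    return digest[:40]


@dataclass
class BankEntry:
    blocks: dict[str, np.ndarray]
    attrs: dict = field(default_factory=dict)


class FragmentBank:
    """HDF5-backed store: one group per fragment key, one dataset per block.

    Retrieval returns blocks bit-identical to what was stored (float64 is
    kept exact); ``hits``/``misses`` count lookups for the budget accounting.
    """

    def __init__(self, path):
        self.path = str(path)
        self.hits = 0
        self.misses = 0
        # Create the file eagerly so that reads on a cold bank are well defined.
        with h5py.File(self.path, "a"):
            pass

    def __contains__(self, key: str) -> bool:
        with h5py.File(self.path, "r") as f:
            return key in f

    def store(self, key: str, blocks: dict[str, np.ndarray],
              attrs: dict | None = None) -> None:
        with h5py.File(self.path, "a") as f:
            if key in f:
                del f[key]
            grp = f.create_group(key)
            for name, arr in blocks.items():
                grp.create_dataset(name, data=np.asarray(arr, dtype=float))
            for name, val in (attrs or {}).items():
                grp.attrs[name] = val

    def load(self, key: str) -> BankEntry | None:
        with h5py.File(self.path, "r") as f:
            if key not in f:
                self.misses += 1
                return None
            grp = f[key]
            self.hits += 1
            return BankEntry(
                blocks={name: grp[name][()] for name in grp},
                attrs=dict(grp.attrs),
            )

    def keys(self) -> list[str]:
        with h5py.File(self.path, "r") as f:
            return list(f.keys())
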