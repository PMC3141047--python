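"""Graph and geometry molecular descriptors: LP1, SIC1, principal moments.

Only the interpretable descriptors that need nothing beyond a molecular
graph (atoms + bonds) or 3D coordinates are computed here:

* **LP1** — the Lovász–Pelikán index, the leading eigenvalue of the
  adjacency matrix; a measure of molecular branching (chain graphs score
  lowest, stars highest at fixed atom count).
* **SIC1** — first-order structural information content: the Shannon
  entropy of atom equivalence classes defined by each atom's element and
  the multiset of its neighbours' elements, normalised by log2(n).
* **Principal moments of inertia** (IA <= IB <= IC, amu·Å²) from masses and
  coordinates; the largest, IC, is reported as the mass-distribution
  descriptor PMIC.

Descriptors needing leverage matrices, dipole-weighted edge adjacency or a
quantum-chemistry wavefunction (GETAWAY, EEig09d, electron-repulsion and
Fukui-index descriptors) are out of scope.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

# Standard atomic weights (amu), enough for common organic chemistry.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Fe": 55.845,
    "Zn": 65.38, "Se": 78.971, "Br": 79.904, "I": 126.90,
}

HYDROGEN_POLICIES = ("heavy-only", "explicit")


@dataclass
class Atom:
    element: str
    mass: float | None = None
    coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.element = str(self.element)
        if self.mass is None:
            self.mass = ATOMIC_MASSES.get(self.element)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (3,):
                raise ValidationError("atom coordinates must be length-3 (x, y, z)")


@dataclass
class MolecularGraph:
    """Atoms and bonds, optionally with 3D coordinates and masses.

    ``hydrogen_policy`` controls which atoms enter the *topological*
    descriptors (LP1, SIC1): ``"heavy-only"`` (default, the common
    convention for topological indices) skips hydrogens, ``"explicit"``
    keeps them.  The inertia tensor always uses every atom present.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    hydrogen_policy: str = "heavy-only"

    def __post_init__(self) -> None:
        if self.hydrogen_policy not in HYDROGEN_POLICIES:
            raise ValidationError(
                f"hydrogen_policy must be one of {HYDROGEN_POLICIES}"
            )
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        norm_bonds: list[tuple[int, int]] = []
        for i, j in self.bonds:
            i, j = int(i), int(j)
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bond ({i}, {j}) out of range for {n} atoms")
            if i == j:
                raise ValidationError(f"self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValidationError(f"duplicate bond {key}")
            seen.add(key)
            norm_bonds.append(key)
        self.bonds = norm_bonds

    # -- views -------------------------------------------------------------
    def topological_indices(self) -> list[int]:
        """Atom indices entering LP1/SIC1 under the hydrogen policy."""
        if self.hydrogen_policy == "explicit":
            return list(range(len(self.atoms)))
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def adjacency_matrix(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """Symmetric 0/1 adjacency over ``indices`` (default: policy atoms)."""
        if indices is None:
            indices = self.topological_indices()
        pos = {a: k for k, a in enumerate(indices)}
        A = np.zeros((len(indices), len(indices)))
        for i, j in self.bonds:
            if i in pos and j in pos:
                A[pos[i], pos[j]] = A[pos[j], pos[i]] = 1.0
        return A


def lp1(graph: MolecularGraph) -> float:
    """Leading eigenvalue of the adjacency matrix (Lovász–Pelikán index)."""
    idx = graph.topological_indices()
    if not idx:
        raise ValidationError("graph has no atoms under the hydrogen policy")
    if len(idx) == 1:
        return 0.0
    A = graph.adjacency_matrix(idx)
    return float(np.linalg.eigvalsh(A)[-1])


def sic1(graph: MolecularGraph) -> float:
    """First-order structural information content, normalised to [0, 1].

    Atoms are partitioned into equivalence classes by (own element,
    multiset of neighbour elements); the result is the Shannon entropy of
    the class sizes divided by log2(n).
    """
    idx = graph.topological_indices()
    n = len(idx)
    if n < 2:
        raise ValidationError("SIC1 needs at least 2 atoms (log2(1) = 0)")
    members = set(idx)
    neighbours: dict[int, list[str]] = {i: [] for i in idx}
    for i, j in graph.bonds:
        if i in members and j in members:
            neighbours[i].append(graph.atoms[j].element)
            neighbours[j].append(graph.atoms[i].element)
    classes = Counter(
        (graph.atoms[i].element, tuple(sorted(neighbours[i]))) for i in idx
    )
    sizes = np.array(list(classes.values()), dtype=float)
    probs = sizes / n
    entropy = float(-(probs * np.log2(probs)).sum())
    return entropy / np.log2(n)


def principal_moments(graph: MolecularGraph) -> tuple[float, float, float]:
    """Principal moments of inertia (IA <= IB <= IC) in amu·Å².

    Coordinates are translated to the centre of mass and the 3x3 inertia
    tensor is diagonalised.  Every atom in the graph contributes,
    regardless of the hydrogen policy.
    """
    if not graph.atoms:
        raise ValidationError("empty graph")
    coords, masses = [], []
    for k, atom in enumerate(graph.atoms):
        if atom.coords is None:
            raise ValidationError(f"atom {k} ({atom.element}) has no coordinates")
        if atom.mass is None:
            raise ValidationError(f"atom {k} ({atom.element}) has no known mass")
        coords.append(atom.coords)
        masses.append(atom.mass)
    r = np.asarray(coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    d = r - com
    # I = sum_i m_i (|d_i|^2 E - d_i d_i^T)
    sq = (d**2).sum(axis=1)
    tensor = np.diag([float((m * sq).sum())] * 3) - np.einsum("i,ij,ik->jk", m, d, d)
    moments = np.linalg.eigvalsh(tensor)
    moments = np.clip(moments, 0.0, None)
    return float(moments[0]), float(moments[1]), float(moments[2])


def pmic(graph: MolecularGraph) -> float:
    """Principal moment of inertia about the C axis (largest moment)."""
    return principal_moments(graph)[2]


# ---------------------------------------------------------------------------
# minimal connection-table format
#
#   # comment lines and blank lines ignored
#   atoms
#   1 C 0.000 0.000 0.000     <- index element [x y z]
#   2 N
#   bonds
#   1 2                       <- one-based atom indices
#


def read_connection_table(path: str | Path, hydrogen_policy: str = "heavy-only") -> MolecularGraph:
    """Parse the whitespace-delimited connection-table format above."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    atoms: dict[int, Atom] = {}
    bonds: list[tuple[int, int]] = []
    section = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        low = line.lower()
        if low in ("atoms", "bonds"):
            section = low
            continue
        parts = line.split()
        if section == "atoms":
            if len(parts) not in (2, 5):
                raise ValidationError(
                    f"line {lineno}: atom lines are 'index element [x y z]'"
                )
            idx = int(parts[0])
            coords = np.array([float(v) for v in parts[2:5]]) if len(parts) == 5 else None
            if idx in atoms:
                raise ValidationError(f"line {lineno}: duplicate atom index {idx}")
            atoms[idx] = Atom(element=parts[1], coords=coords)
        elif section == "bonds":
            if len(parts) != 2:
                raise ValidationError(f"line {lineno}: bond lines are 'i j'")
            bonds.append((int(parts[0]), int(parts[1])))
        else:
            raise ValidationError(
                f"line {lineno}: content before an 'atoms'/'bonds' section header"
            )
    if not atoms:
        raise ValidationError(f"no atoms in {path}")
    order = sorted(atoms)
    remap = {orig: k for k, orig in enumerate(order)}
    try:
        bond_idx = [(remap[i], remap[j]) for i, j in bonds]
    except KeyError as exc:
        raise ValidationError(f"bond references unknown atom index {exc}") from None
    return MolecularGraph(
        atoms=[atoms[i] for i in order],
        bonds=bond_idx,
        hydrogen_policy=hydrogen_policy,
    )
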