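"""Molecular graphs with 3D coordinates, internal-coordinate geometry, and I/O.

The central container is :class:`MolecularGraph`: per-atom feature rows, 3D
Cartesian coordinates in Å, and an undirected bond list.  Geometry primitives
(pairwise distances, bond angles via the normalized-dot arccos, signed
dihedrals via the two-plane arctan2 convention) operate on plain coordinate
arrays and are reused by the regularization losses in differentiable form.

SDF (V2000) files are read and written through RDKit; XYZ files are parsed
directly, with bonds inferred by a covalent-radius distance criterion.
Internally atom indices are 0-based; units are Å and radians throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularGraph",
    "GeometryReference",
    "ELEMENTS",
    "COVALENT_RADII",
    "atom_features",
    "pairwise_distances",
    "bond_angle",
    "dihedral",
    "extract_geometry_reference",
    "read_structures",
    "write_structures",
    "radius_of_gyration",
]

# Feature vocabulary: the elements the synthetic generator and typical organic
# SDF inputs contain.  Unknown elements map to the trailing "other" slot.
ELEMENTS = ["H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"]

# Covalent radii in Å (Cordero et al. consensus values), used for XYZ bond
# inference and the steric-clash filter.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_DEFAULT_RADIUS = 0.75

FEATURE_DIM = len(ELEMENTS) + 1 + 4 + 1  # one-hot(+other) + degree-bucket + charge


def atom_features(symbol: str, degree: int, formal_charge: int = 0) -> np.ndarray:
    """Featurize one atom: element one-hot, degree one-hot (1..4+), charge."""
    x = np.zeros(FEATURE_DIM)
    try:
        x[ELEMENTS.index(symbol)] = 1.0
    except ValueError:
        x[len(ELEMENTS)] = 1.0
    x[len(ELEMENTS) + 1 + min(max(degree, 1), 4) - 1] = 1.0
    x[-1] = float(formal_charge)
    return x


@dataclass
class MolecularGraph:
    """A molecule as (atoms, bonds, features X, coordinates R).

    Attributes
    ----------
    atom_features : (n, d_in) float array
        One row per atom (element one-hot, degree, formal charge).
    coords : (n, 3) float array
        Cartesian positions in Å.
    bonds : list of (i, j, order)
        Each undirected bond stored once with ``i < j``.
    symbols : list of str
        Element symbols, parallel to the rows of ``atom_features``.
    name : str
    meta : dict
        Free-form provenance (e.g. the torsion alphabet a synthetic
        conformer was built from).
    """

    atom_features: np.ndarray
    coords: np.ndarray
    bonds: list
    symbols: list
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.atom_features = np.asarray(self.atom_features, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------------
    def validate(self):
        n = self.atom_count
        if self.atom_features.shape[0] != n:
            raise ValueError("atom_features and coords row counts differ")
        if self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        seen = set()
        norm_bonds = []
        for i, j, *rest in self.bonds:
            order = rest[0] if rest else 1
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond references atom {max(i, j)} of {n}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm_bonds.append((key[0], key[1], order))
        self.bonds = norm_bonds
        if len(self.symbols) != n:
            raise ValueError("symbols length mismatch")

    @property
    def atom_count(self) -> int:
        return self.coords.shape[0]

    def adjacency(self) -> list:
        """Neighbor lists (0-based)."""
        adj = [[] for _ in range(self.atom_count)]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def copy_with_coords(self, coords: np.ndarray) -> "MolecularGraph":
        return MolecularGraph(
            self.atom_features.copy(), np.asarray(coords, float).copy(),
            list(self.bonds), list(self.symbols), self.name, dict(self.meta),
        )


@dataclass
class GeometryReference:
    """Reference internal coordinates extracted from one conformer.

    ``distances`` maps bonded pairs (i, j) with i<j to d_ij in Å; ``angles``
    maps bonded paths (i, j, k) with j central to θ in [0, π]; ``torsions``
    maps bonded paths (i, j, k, l) to the signed dihedral in (−π, π].
    """

    distances: dict
    angles: dict
    torsions: dict

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("kind\ti\tj\tk\tl\tvalue\n")
            for (i, j), v in sorted(self.distances.items()):
                fh.write(f"distance\t{i}\t{j}\t\t\t{v:.10f}\n")
            for (i, j, k), v in sorted(self.angles.items()):
                fh.write(f"angle\t{i}\t{j}\t{k}\t\t{v:.10f}\n")
            for (i, j, k, l), v in sorted(self.torsions.items()):
                fh.write(f"torsion\t{i}\t{j}\t{k}\t{l}\t{v:.10f}\n")

    @classmethod
    def from_tsv(cls, path) -> "GeometryReference":
        d, a, t = {}, {}, {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                kind, i, j, k, l, v = line.rstrip("\n").split("\t")
                if kind == "distance":
                    d[(int(i), int(j))] = float(v)
                elif kind == "angle":
                    a[(int(i), int(j), int(k))] = float(v)
                else:
                    t[(int(i), int(j), int(k), int(l))] = float(v)
        return cls(d, a, t)


# -- geometry primitives ------------------------------------------------------

def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix in Å."""
    coords = np.asarray(coords, float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return d


_CLAMP = 1.0 - 1e-9


def bond_angle(r_i, r_j, r_k) -> float:
    """Angle at the central atom j, in [0, π].

    arccos of the normalized dot product of the two arm vectors; the argument
    is clamped to ±(1−1e−9) so the angle (and its gradient, in the
    differentiable version) stays finite near collinearity.
    """
    u = np.asarray(r_i, float) - np.asarray(r_j, float)
    v = np.asarray(r_k, float) - np.asarray(r_j, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("degenerate angle")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.arccos(np.clip(c, -_CLAMP, _CLAMP)))


def dihedral(r_i, r_j, r_k, r_l) -> float:
    """Signed torsion about the j–k axis, in (−π, π].

    Uses the two-plane convention: n1 = (r_i−r_j)×(r_j−r_k),
    n2 = (r_j−r_k)×(r_k−r_l), u = (r_j−r_k)/‖r_j−r_k‖, and
    φ = arctan2((n1×n2)·u, n1·n2).
    """
    r_i, r_j, r_k, r_l = (np.asarray(p, float) for p in (r_i, r_j, r_k, r_l))
    b1 = r_i - r_j
    b2 = r_j - r_k
    b3 = r_k - r_l
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise ValueError("undefined torsion")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("undefined torsion")
    u = b2 / nb2
    phi = float(np.arctan2(np.dot(np.cross(n1, n2), u), np.dot(n1, n2)))
    if phi <= -np.pi:  # canonical representative of the branch point
        phi = np.pi
    return phi


def radius_of_gyration(coords: np.ndarray) -> float:
    coords = np.asarray(coords, float)
    c = coords - coords.mean(0)
    return float(np.sqrt((c**2).sum(-1).mean()))


def _angle_triples(graph: MolecularGraph):
    adj = graph.adjacency()
    for j in range(graph.atom_count):
        nb = sorted(adj[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                yield (nb[a], j, nb[b])


def _torsion_quads(graph: MolecularGraph):
    adj = graph.adjacency()
    seen = set()
    for j, k, _ in graph.bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                quad = (i, j, k, l)
                canon = min(quad, quad[::-1])
                if canon not in seen:
                    seen.add(canon)
                    yield canon


def extract_geometry_reference(graph: MolecularGraph) -> GeometryReference:
    """Internal coordinates over bonded paths of the graph.

    Distances for every bond, angles for every bonded path i–j–k (j central),
    torsions for every bonded path i–j–k–l (each stored once in a canonical
    orientation).  Torsions whose inner triples are collinear are skipped.
    """
    R = graph.coords
    dists = {
        (i, j): float(np.linalg.norm(R[i] - R[j])) for i, j, _ in graph.bonds
    }
    angles = {t: bond_angle(R[t[0]], R[t[1]], R[t[2]]) for t in _angle_triples(graph)}
    torsions = {}
    for q in _torsion_quads(graph):
        try:
            torsions[q] = dihedral(R[q[0]], R[q[1]], R[q[2]], R[q[3]])
        except ValueError:
            continue
    return GeometryReference(dists, angles, torsions)


# -- file I/O -----------------------------------------------------------------

def infer_bonds(symbols, coords, scale: float = 1.2) -> list:
    """Bond inference by distance: bonded iff d < scale × (r_cov_i + r_cov_j)."""
    coords = np.asarray(coords, float)
    n = len(symbols)
    d = pairwise_distances(coords)
    bonds = []
    for i in range(n):
        ri = COVALENT_RADII.get(symbols[i], _DEFAULT_RADIUS)
        for j in range(i + 1, n):
            rj = COVALENT_RADII.get(symbols[j], _DEFAULT_RADIUS)
            if d[i, j] < scale * (ri + rj):
                bonds.append((i, j, 1))
    return bonds


def _graph_from_rdkit(mol, name: str, record: int) -> MolecularGraph:
    from rdkit import Chem

    conf = mol.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(a).x, conf.GetAtomPosition(a).y, conf.GetAtomPosition(a).z]
         for a in range(mol.GetNumAtoms())]
    )
    if mol.GetNumAtoms() >= 2 and (not conf.Is3D()) and np.allclose(coords[:, 2], 0.0):
        raise ValueError(f"record {record}: missing 3D coordinates (2D-only SDF)")
    if np.allclose(coords, 0.0) and mol.GetNumAtoms() >= 2:
        raise ValueError(f"record {record}: missing 3D coordinates")
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    feats = np.array(
        [atom_features(a.GetSymbol(), a.GetDegree(), a.GetFormalCharge())
         for a in mol.GetAtoms()]
    )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    return MolecularGraph(feats, coords, bonds, symbols, name=name)


def read_structures(path, format: str | None = None) -> list:
    """Read molecules from an SDF (V2000) or XYZ file.

    SDF parsing goes through RDKit (1-based file indices converted to 0-based
    by the parser); multi-record XYZ is supported and bonds are inferred by
    the covalent-radius criterion.  2D-only SDF records (all-zero coordinates)
    are rejected.  Malformed records raise ``ValueError`` naming the record.
    """
    path = str(path)
    if format is None:
        format = "xyz" if path.lower().endswith(".xyz") else "sdf"
    if format == "sdf":
        return _read_sdf(path)
    if format == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown format: {format}")


def _read_sdf(path) -> list:
    from rdkit import Chem

    # pre-validate bond blocks so out-of-range indices raise a named error
    # rather than being silently dropped by RDKit
    _validate_sdf_counts(path)
    supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=False)
    graphs = []
    for rec, mol in enumerate(supplier, start=1):
        if mol is None:
            raise ValueError(f"record {rec}: malformed SDF record")
        try:
            Chem.SanitizeMol(
                mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
            )
        except Exception:
            pass  # keep raw valences; geometry is what matters here
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{rec}"
        graphs.append(_graph_from_rdkit(mol, name, rec))
    if not graphs:
        logger.warning("no records found in %s", path)
    return graphs


def _validate_sdf_counts(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    rec = 1
    idx = 0
    while idx < len(lines):
        block_end = None
        for j in range(idx, len(lines)):
            if lines[j].strip() == "$$$$":
                block_end = j
                break
        block = lines[idx: block_end if block_end is not None else len(lines)]
        if not any(ln.strip() for ln in block):
            break
        if len(block) < 4:
            raise ValueError(f"record {rec}: truncated SDF record")
        counts = block[3]
        try:
            natoms, nbonds = int(counts[0:3]), int(counts[3:6])
        except ValueError as exc:
            raise ValueError(f"record {rec}: bad counts line") from exc
        bond_lines = block[4 + natoms: 4 + natoms + nbonds]
        for bl in bond_lines:
            a, b = int(bl[0:3]), int(bl[3:6])
            if a > natoms or b > natoms or a < 1 or b < 1:
                raise ValueError(
                    f"record {rec}: bond references atom {max(a, b)} of {natoms}"
                )
        if block_end is None:
            break
        idx = block_end + 1
        rec += 1


def _read_xyz(path) -> list:
    graphs = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    rec = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        rec += 1
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"record {rec}: bad atom count line") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        body = lines[pos + 2: pos + 2 + n]
        if len(body) < n:
            raise ValueError(f"record {rec}: expected {n} atom lines")
        symbols, coords = [], []
        for ln in body:
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"record {rec}: malformed atom line: {ln!r}")
            symbols.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        coords = np.array(coords)
        bonds = infer_bonds(symbols, coords)
        adj_deg = np.zeros(n, int)
        for i, j, _ in bonds:
            adj_deg[i] += 1
            adj_deg[j] += 1
        feats = np.array(
            [atom_features(s, int(adj_deg[i])) for i, s in enumerate(symbols)]
        )
        graphs.append(
            MolecularGraph(feats, coords, bonds, symbols, name=comment.strip() or f"mol{rec}")
        )
        pos += 2 + n
    if not graphs:
        logger.warning("no records found in %s", path)
    return graphs


def write_structures(graphs, path, format: str | None = None):
    """Write molecules to SDF (via RDKit) or XYZ."""
    path = str(path)
    if format is None:
        format = "xyz" if path.lower().endswith(".xyz") else "sdf"
    if isinstance(graphs, MolecularGraph):
        graphs = [graphs]
    if format == "xyz":
        with open(path, "w") as fh:
            for g in graphs:
                fh.write(f"{g.atom_count}\n{g.name}\n")
                for s, (x, y, z) in zip(g.symbols, g.coords):
                    fh.write(f"{s} {x:.8f} {y:.8f} {z:.8f}\n")
        return
    if format != "sdf":
        raise ValueError(f"unknown format: {format}")
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(path)
    try:
        for g in graphs:
            em = Chem.RWMol()
            for s in g.symbols:
                em.AddAtom(Chem.Atom(s))
            for i, j, order in g.bonds:
                em.AddBond(
                    i, j,
                    {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE}.get(order, Chem.BondType.SINGLE),
                )
            mol = em.GetMol()
            conf = Chem.Conformer(g.atom_count)
            for a, (x, y, z) in enumerate(g.coords):
                conf.SetAtomPosition(a, Point3D(float(x), float(y), float(z)))
            mol.AddConformer(conf)
            mol.SetProp("_Name", g.name)
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                mol.UpdatePropertyCache(strict=False)
            writer.write(mol)
    finally:
        writer.close()
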