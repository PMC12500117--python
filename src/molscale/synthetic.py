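"""Synthetic ideal-geometry conformers: the offline test corpus.

Three families, all built from exact internal coordinates so every bond
length, angle and torsion of the result is known by construction:

* ``alkane_chain`` — united-atom carbon chains, C–C 1.54 Å, tetrahedral
  109.47° backbone angles, backbone torsions drawn from a discrete alphabet
  (anti/gauche by default).
* ``cycloalkane`` — planar regular rings with side 1.54 Å (interior angle
  (n−2)π/n by construction).
* ``decorated_scaffold`` — an alkane backbone with O/N substituents at ideal
  bond lengths, giving heterogeneous feature rows.

Generation is deterministic per (spec, seed).  Real conformers have vibrating
bond lengths, puckered rings and correlated torsions; these do not — they are
a controlled geometry source, not a conformational ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .molgraph import MolecularGraph, atom_features

__all__ = ["SyntheticSpec", "make_synthetic", "make_corpus",
           "CC_BOND", "CCC_ANGLE_DEG", "DEFAULT_TORSIONS"]

CC_BOND = 1.54            # Å
CO_BOND = 1.43
CN_BOND = 1.47
CCC_ANGLE_DEG = 109.47    # tetrahedral backbone angle
DEFAULT_TORSIONS = (180.0, 60.0, -60.0)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic conformer."""

    family: str = "alkane_chain"          # alkane_chain | cycloalkane | decorated_scaffold
    size: int = 8                          # chain length or ring size (atoms)
    torsion_set: tuple = DEFAULT_TORSIONS  # degrees, each in (−180, 180]
    seed: int = 0

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("size must be ≥ 2")
        for t in self.torsion_set:
            if not (-180.0 < t <= 180.0):
                raise ValueError(f"torsion {t} outside (−180, 180]")


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position a fourth atom D from atoms A,B,C and internal coordinates.

    ``bond`` is |CD| in Å, ``angle`` the B–C–D angle and ``torsion`` the
    signed A–B–C–D dihedral, both in radians, under the same sign convention
    as :func:`molscale.molgraph.dihedral`.
    """
    a, b, c = np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.cos(torsion) * math.sin(angle),
        -bond * math.sin(torsion) * math.sin(angle),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_chain(n: int, bond: float, angle_deg: float, torsions_deg) -> np.ndarray:
    """Backbone coordinates for an n-atom chain with given internal coords."""
    theta = math.radians(angle_deg)
    coords = np.zeros((n, 3))
    coords[0] = (0.0, 0.0, 0.0)
    if n >= 2:
        coords[1] = (bond, 0.0, 0.0)
    if n >= 3:
        coords[2] = coords[1] + (
            bond * math.cos(math.pi - theta),
            bond * math.sin(math.pi - theta),
            0.0,
        )
    for idx in range(3, n):
        phi = math.radians(torsions_deg[idx - 3])
        coords[idx] = place_atom(
            coords[idx - 3], coords[idx - 2], coords[idx - 1], bond, theta, phi
        )
    return coords


def make_synthetic(spec: SyntheticSpec) -> MolecularGraph:
    """Build the conformer a :class:`SyntheticSpec` describes.

    Deterministic: the same spec (including seed) always yields identical
    coordinates.  The drawn backbone torsions and the torsion alphabet are
    recorded in ``graph.meta`` for downstream augmentation.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.family == "alkane_chain":
        return _make_alkane(spec, rng)
    if spec.family == "cycloalkane":
        return _make_ring(spec)
    if spec.family == "decorated_scaffold":
        return _make_decorated(spec, rng)
    raise ValueError(f"unsupported family: {spec.family}")


def _finish(symbols, coords, bonds, name, meta) -> MolecularGraph:
    deg = np.zeros(len(symbols), int)
    for i, j, _ in bonds:
        deg[i] += 1
        deg[j] += 1
    feats = np.array([atom_features(s, int(deg[i])) for i, s in enumerate(symbols)])
    return MolecularGraph(feats, np.asarray(coords), bonds, symbols, name=name, meta=meta)


def _make_alkane(spec: SyntheticSpec, rng) -> MolecularGraph:
    n = spec.size
    n_tors = max(n - 3, 0)
    torsions = [float(spec.torsion_set[rng.integers(len(spec.torsion_set))])
                for _ in range(n_tors)]
    coords = _build_chain(n, CC_BOND, CCC_ANGLE_DEG, torsions)
    bonds = [(i, i + 1, 1) for i in range(n - 1)]
    meta = {"family": "alkane_chain", "torsion_set": tuple(spec.torsion_set),
            "backbone_torsions": torsions}
    return _finish(["C"] * n, coords, bonds, f"alkane{n}", meta)


def _make_ring(spec: SyntheticSpec) -> MolecularGraph:
    n = spec.size
    if n < 3:
        raise ValueError("ring size must be ≥ 3")
    # planar regular n-gon with side length CC_BOND
    radius = CC_BOND / (2.0 * math.sin(math.pi / n))
    coords = np.array([
        (radius * math.cos(2 * math.pi * i / n),
         radius * math.sin(2 * math.pi * i / n), 0.0)
        for i in range(n)
    ])
    bonds = [(i, (i + 1) % n, 1) for i in range(n)]
    bonds = [(min(i, j), max(i, j), o) for i, j, o in bonds]
    meta = {"family": "cycloalkane", "ring_angle": math.pi * (n - 2) / n,
            "torsion_set": tuple(spec.torsion_set)}
    return _finish(["C"] * n, coords, bonds, f"ring{n}", meta)


def _make_decorated(spec: SyntheticSpec, rng) -> MolecularGraph:
    base = _make_alkane(SyntheticSpec("alkane_chain", spec.size, spec.torsion_set,
                                      spec.seed), rng)
    symbols = list(base.symbols)
    coords = [c for c in base.coords]
    bonds = list(base.bonds)
    n = spec.size
    # decorate interior backbone atoms with O or N at ideal bond lengths,
    # placed off-backbone along a torsion chosen from the alphabet
    n_dec = max(1, n // 4)
    sites = rng.choice(np.arange(1, n - 1), size=min(n_dec, n - 2), replace=False)
    theta = math.radians(CCC_ANGLE_DEG)
    for site in sorted(int(s) for s in sites):
        elem = "O" if rng.random() < 0.5 else "N"
        bond_len = CO_BOND if elem == "O" else CN_BOND
        # place relative to (site−1, site) arm with a +120° offset torsion so
        # the substituent leaves the backbone plane
        anchor_prev = coords[site - 1]
        anchor = coords[site]
        anchor_next = coords[site + 1]
        pos = place_atom(anchor_next, anchor_prev, anchor, bond_len, theta,
                         math.radians(120.0))
        coords.append(pos)
        bonds.append((site, len(coords) - 1, 1))
        symbols.append(elem)
    meta = dict(base.meta)
    meta["family"] = "decorated_scaffold"
    return _finish(symbols, np.array(coords), bonds, f"deco{n}", meta)


def make_corpus(n_molecules: int, seed: int = 0, size_range=(6, 14),
                families=("alkane_chain", "cycloalkane", "decorated_scaffold"),
                weights=(0.5, 0.2, 0.3)) -> list:
    """A mixed corpus of synthetic conformers, deterministic per seed."""
    rng = np.random.default_rng(seed)
    corpus = []
    for idx in range(n_molecules):
        fam = rng.choice(families, p=weights)
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if fam == "cycloalkane":
            size = max(size, 3)
        corpus.append(make_synthetic(
            SyntheticSpec(str(fam), size, DEFAULT_TORSIONS, seed=int(rng.integers(2**31)))
        ))
    return corpus
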