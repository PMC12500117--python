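"""Scale-specific positive-view generation for contrastive pre-training.

Three augmentations, one per geometric scale, each preserving the structure
that its scale contrasts on:

* scale 1 — :func:`atomic_jitter`: independent atomic displacements, uniform
  in a ball of radius ≤ 0.1 Å, leaving local geometry almost unchanged;
* scale 2 — :func:`group_perturb`: bounded rotations about rotatable bonds,
  preserving every bond length and bond angle exactly;
* scale 3 — :func:`conformer_resample`: full torsion resampling accepted only
  when the global shape survives (radius-of-gyration band) and no nonbonded
  pair clashes sterically — a dependency-light proxy for energy-aware
  conformer sampling.

All augmentations keep atom count, ordering, features and bonds fixed; only
coordinates change.  Randomness comes from ``numpy.random.default_rng(seed)``
(PCG64), so views are reproducible across platforms for a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .molgraph import (
    MolecularGraph, COVALENT_RADII, _DEFAULT_RADIUS,
    dihedral, pairwise_distances, radius_of_gyration,
)

__all__ = [
    "AugmentedPair", "atomic_jitter", "group_perturb", "conformer_resample",
    "rotatable_bonds", "rotate_about_bond", "augment_for_scale",
]


@dataclass
class AugmentedPair:
    """An (original, positive-view) conformer pair for one scale."""

    original: MolecularGraph
    positive: MolecularGraph
    scale: int
    seed: int
    perturbation_log: dict = field(default_factory=dict)

    def log_json(self) -> str:
        return json.dumps({"scale": self.scale, "seed": self.seed,
                           **self.perturbation_log})


def _uniform_ball(rng, n: int, radius: float) -> np.ndarray:
    """n points uniform in the 3-ball of given radius."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def atomic_jitter(graph: MolecularGraph, max_disp: float = 0.1,
                  seed: int = 0) -> AugmentedPair:
    """Scale-1 view: per-atom displacement uniform in a ball of radius ≤ max_disp Å."""
    if max_disp < 0:
        raise ValueError("max_disp must be nonnegative")
    rng = np.random.default_rng(seed)
    disp = _uniform_ball(rng, graph.atom_count, max_disp) if max_disp > 0 else 0.0
    pos = graph.copy_with_coords(graph.coords + disp)
    return AugmentedPair(graph, pos, 1, seed,
                         {"kind": "atomic_jitter", "max_disp": max_disp})


def _ring_edges(graph: MolecularGraph) -> set:
    """Edges that lie on a cycle (removal does not disconnect their ends)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.atom_count))
    g.add_edges_from((i, j) for i, j, _ in graph.bonds)
    return {tuple(sorted(e)) for e in g.edges} - {
        tuple(sorted(e)) for e in nx.bridges(g)
    }


def rotatable_bonds(graph: MolecularGraph) -> list:
    """Acyclic bonds whose endpoints both have degree ≥ 2."""
    deg = np.zeros(graph.atom_count, int)
    for i, j, _ in graph.bonds:
        deg[i] += 1
        deg[j] += 1
    rings = _ring_edges(graph)
    return [
        (i, j) for i, j, _ in graph.bonds
        if deg[i] >= 2 and deg[j] >= 2 and (i, j) not in rings
    ]


def _side_atoms(graph: MolecularGraph, i: int, j: int) -> list:
    """Atoms on the j side after cutting bond (i, j)."""
    adj = graph.adjacency()
    seen = {i, j}
    stack = [j]
    side = []
    while stack:
        a = stack.pop()
        side.append(a)
        for b in adj[a]:
            if b not in seen:
                seen.add(b)
                stack.append(b)
    return side


def rotate_about_bond(coords: np.ndarray, graph: MolecularGraph, i: int, j: int,
                      angle_rad: float) -> np.ndarray:
    """Rotate the j-side of bond (i, j) about the i→j axis (Rodrigues)."""
    coords = np.array(coords, float)
    axis = coords[j] - coords[i]
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)
    side = _side_atoms(graph, i, j)
    moving = [a for a in side if a != j]
    coords[moving] = (coords[moving] - coords[j]) @ R.T + coords[j]
    return coords


def group_perturb(graph: MolecularGraph, max_torsion_deg: float = 30.0,
                  seed: int = 0) -> AugmentedPair:
    """Scale-2 view: rotations about rotatable bonds only.

    Bond lengths, bond angles and all 1-2/1-3 distances are preserved
    exactly; each rotated dihedral shifts by at most ``max_torsion_deg``.
    Molecules with no rotatable bond return an identity pair.
    """
    bonds = rotatable_bonds(graph)
    rng = np.random.default_rng(seed)
    if not bonds or max_torsion_deg == 0:
        return AugmentedPair(graph, graph.copy_with_coords(graph.coords), 2, seed,
                             {"kind": "group_perturb", "note": "identity",
                              "rotated": []})
    coords = np.array(graph.coords, float)
    rotated = []
    for (i, j) in bonds:
        delta = float(rng.uniform(-max_torsion_deg, max_torsion_deg))
        coords = rotate_about_bond(coords, graph, i, j, math.radians(delta))
        rotated.append({"bond": [i, j], "delta_deg": delta})
    pos = graph.copy_with_coords(coords)
    return AugmentedPair(graph, pos, 2, seed,
                         {"kind": "group_perturb", "rotated": rotated})


def _reference_quad(graph: MolecularGraph, i: int, j: int):
    """A torsion-defining quadruple (a, i, j, b) for bond (i, j)."""
    adj = graph.adjacency()
    a = next((x for x in sorted(adj[i]) if x != j), None)
    b = next((x for x in sorted(adj[j]) if x != i), None)
    if a is None or b is None:
        return None
    return (a, i, j, b)


def set_torsion(coords: np.ndarray, graph: MolecularGraph, i: int, j: int,
                target_rad: float) -> np.ndarray:
    """Rotate the j-side so the (a, i, j, b) dihedral equals ``target_rad``."""
    quad = _reference_quad(graph, i, j)
    if quad is None:
        return np.array(coords, float)
    a, _, _, b = quad
    try:
        current = dihedral(coords[a], coords[i], coords[j], coords[b])
    except ValueError:
        return np.array(coords, float)
    return rotate_about_bond(coords, graph, i, j, -(target_rad - current))


def _min_clash_ratio(graph: MolecularGraph, coords: np.ndarray) -> float:
    """min over nonbonded pairs of d_ij / (r_i + r_j); large = no clash."""
    n = graph.atom_count
    if n < 3:
        return np.inf
    d = pairwise_distances(coords)
    radii = np.array([COVALENT_RADII.get(s, _DEFAULT_RADIUS) for s in graph.symbols])
    ssum = radii[:, None] + radii[None, :]
    bonded = np.zeros((n, n), bool)
    for i, j, _ in graph.bonds:
        bonded[i, j] = bonded[j, i] = True
    adj = graph.adjacency()
    for j in range(n):  # 1-3 pairs are constrained by angles, not sterics
        for a in adj[j]:
            for b in adj[j]:
                if a != b:
                    bonded[a, b] = True
    mask = ~bonded
    np.fill_diagonal(mask, False)
    if not mask.any():
        return np.inf
    return float((d[mask] / ssum[mask]).min())


def conformer_resample(graph: MolecularGraph, seed: int = 0,
                       rg_tolerance: float = 0.15, max_tries: int = 50,
                       kappa: float = 2.0) -> AugmentedPair:
    """Scale-3 view: resample all rotatable torsions, keep the global shape.

    Torsion targets come from the molecule's torsion alphabet when it was
    built synthetically (``meta['torsion_set']``), otherwise from a von Mises
    proposal centred on the current torsion (concentration ``kappa``).  A
    candidate is accepted only if its radius of gyration is within
    ±``rg_tolerance`` of the original and no nonbonded pair comes closer
    than 0.8 × the sum of covalent radii.  After ``max_tries`` rejections the
    least-clashing candidate is returned with a warning note in the log.
    """
    if not (0.0 < rg_tolerance < 1.0):
        raise ValueError("rg_tolerance must be in (0, 1)")
    bonds = rotatable_bonds(graph)
    if not bonds:
        return AugmentedPair(graph, graph.copy_with_coords(graph.coords), 3, seed,
                             {"kind": "conformer_resample", "note": "identity"})
    rng = np.random.default_rng(seed)
    rg0 = radius_of_gyration(graph.coords)
    alphabet = graph.meta.get("torsion_set")
    best, best_ratio = None, -np.inf
    for attempt in range(max_tries):
        coords = np.array(graph.coords, float)
        for (i, j) in bonds:
            if alphabet:
                target = math.radians(float(alphabet[rng.integers(len(alphabet))]))
            else:
                quad = _reference_quad(graph, i, j)
                if quad is None:
                    continue
                cur = dihedral(*[coords[q] for q in quad])
                target = float(rng.vonmises(cur, kappa))
            coords = set_torsion(coords, graph, i, j, target)
        ratio = _min_clash_ratio(graph, coords)
        rg_ok = abs(radius_of_gyration(coords) / rg0 - 1.0) <= rg_tolerance
        if ratio > best_ratio and rg_ok:
            best, best_ratio = coords, ratio
        if rg_ok and ratio >= 0.8:
            pos = graph.copy_with_coords(coords)
            return AugmentedPair(graph, pos, 3, seed,
                                 {"kind": "conformer_resample",
                                  "attempts": attempt + 1, "accepted": True})
    if best is None:
        best = np.array(graph.coords, float)
    pos = graph.copy_with_coords(best)
    return AugmentedPair(graph, pos, 3, seed,
                         {"kind": "conformer_resample", "attempts": max_tries,
                          "accepted": False,
                          "warning": "returned least-clashing candidate"})


def augment_for_scale(graph: MolecularGraph, scale: int, seed: int,
                      max_disp: float = 0.1, max_torsion_deg: float = 30.0,
                      rg_tolerance: float = 0.15) -> AugmentedPair:
    """Dispatch the scale-appropriate augmentation."""
    if scale == 1:
        return atomic_jitter(graph, max_disp, seed)
    if scale == 2:
        return group_perturb(graph, max_torsion_deg, seed)
    if scale == 3:
        return conformer_resample(graph, seed, rg_tolerance)
    raise ValueError(f"unknown scale: {scale}")
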