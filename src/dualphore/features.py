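"""Pharmacophore feature perception on 3D small molecules.

Three ligand-side annotation point kinds are derived, mirroring the feature
classes of a donor/aromatic/hydrophobic pharmacophore model:

* **donor** — every N or O bearing at least one explicitly bonded hydrogen,
  the point placed on the heavy atom (no directionality);
* **aromatic** — the centroid of each 5-7 membered ring whose bonds all
  carry the SDF aromatic flag, or, when none of its bonds are flagged,
  whose atoms fit a least-squares plane within a tolerance (0.10 A
  default);
* **hydrophobic** — the centroid of each maximal connected cluster of at
  least ``min_cluster_size`` carbon/halogen atoms, none of which is bonded
  to N, O or a formally charged atom.

These rules are a documented, deterministic approximation of the
(unpublished) typing schemes in commercial modelling suites; they are
format-driven and contain no electronic-structure model.  Acceptor and
charged-group features are deliberately not implemented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .chem import Molecule3D

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("donor", "aromatic", "hydrophobic")

_HYDROPHOBIC_ELEMENTS = {"C", "F", "Cl", "Br", "I"}


@dataclass(frozen=True)
class AnnotationPoint:
    """A ligand-side feature location that may satisfy a query feature."""

    kind: str
    position: tuple[float, float, float]
    source_atoms: frozenset[int]

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.source_atoms:
            raise ValueError("annotation point needs at least one source atom")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite annotation point position")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass(frozen=True)
class PerceptionRules:
    """Tunable perception parameters (config-exposed)."""

    min_cluster_size: int = 3
    planarity_tol: float = 0.10  # Angstrom, max out-of-plane deviation
    ring_size_min: int = 5
    ring_size_max: int = 7


DEFAULT_RULES = PerceptionRules()


def _bond_graph(mol: Molecule3D) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from((b.i, b.j) for b in mol.bonds)
    return g


def _order_cycle(nodes: list[int], graph: nx.Graph) -> tuple[int, ...]:
    """Return the cycle's atoms in traversal order starting from the smallest index."""
    node_set = set(nodes)
    start = min(nodes)
    order = [start]
    prev = None
    current = start
    while len(order) < len(nodes):
        nxt = sorted(
            n for n in graph.neighbors(current) if n in node_set and n != prev
        )
        nxt = [n for n in nxt if n not in order]
        if not nxt:
            return tuple(sorted(nodes))  # chorded/ambiguous: fall back to sorted
        prev, current = current, nxt[0]
        order.append(current)
    return tuple(order)


def ring_perception(mol: Molecule3D) -> list[tuple[int, ...]]:
    """Smallest set of smallest rings (minimum cycle basis of the bond graph).

    Rings are returned in deterministic order (sorted by smallest member
    index, then length, then contents); an acyclic molecule yields an empty
    list.
    """
    g = _bond_graph(mol)
    cycles = nx.minimum_cycle_basis(g)
    ordered = [_order_cycle(c, g) for c in cycles]
    return sorted(ordered, key=lambda ring: (min(ring), len(ring), ring))


def _plane_deviation(coords: np.ndarray) -> float:
    """Max distance of points from their least-squares plane."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    return float(np.max(np.abs(centered @ normal)))


def perceive_features(
    mol: Molecule3D,
    rules: PerceptionRules = DEFAULT_RULES,
    warn_missing_h: bool = True,
) -> list[AnnotationPoint]:
    """Derive donor/aromatic/hydrophobic annotation points from a molecule.

    An empty list is a valid result.  Donor perception needs explicit
    hydrogens; a molecule with N/O atoms but no hydrogens at all is
    processed with a warning (its donor features will be absent).  Bulk
    callers that summarise per-library set ``warn_missing_h`` to False.
    """
    adj = mol.adjacency()
    elements = [a.element for a in mol.atoms]
    coords = mol.coords
    points: list[AnnotationPoint] = []

    if (
        warn_missing_h
        and any(e in ("N", "O") for e in elements)
        and not mol.has_explicit_hydrogens()
    ):
        logger.warning(
            "molecule %s has N/O atoms but no explicit hydrogens; "
            "donor features cannot be perceived",
            mol.id,
        )

    # donors: N/O with >= 1 bonded hydrogen, point on the heavy atom
    for idx, e in enumerate(elements):
        if e in ("N", "O") and any(elements[n] == "H" for n in adj[idx]):
            points.append(
                AnnotationPoint("donor", tuple(coords[idx]), frozenset({idx}))
            )

    # aromatic ring centroids
    bond_aromatic = {}
    for b in mol.bonds:
        bond_aromatic[(min(b.i, b.j), max(b.i, b.j))] = b.aromatic
    for ring in ring_perception(mol):
        size = len(ring)
        if not (rules.ring_size_min <= size <= rules.ring_size_max):
            continue
        ring_set = set(ring)
        flags = [
            flag
            for (i, j), flag in bond_aromatic.items()
            if i in ring_set and j in ring_set
        ]
        if all(flags):
            aromatic = True
        elif not any(flags):
            aromatic = _plane_deviation(coords[list(ring)]) <= rules.planarity_tol
        else:
            aromatic = False  # partially flagged ring is not aromatic
        if aromatic:
            centroid = coords[list(ring)].mean(axis=0)
            points.append(
                AnnotationPoint("aromatic", tuple(centroid), frozenset(ring_set))
            )

    # hydrophobic clusters: maximal connected sets of eligible C/halogen atoms
    charged = {i for i, a in enumerate(mol.atoms) if a.formal_charge != 0}
    eligible = set()
    for idx, e in enumerate(elements):
        if e not in _HYDROPHOBIC_ELEMENTS or idx in charged:
            continue
        if any(elements[n] in ("N", "O") or n in charged for n in adj[idx]):
            continue
        eligible.add(idx)
    g = _bond_graph(mol).subgraph(eligible)
    for component in sorted(nx.connected_components(g), key=min):
        if len(component) >= rules.min_cluster_size:
            centroid = coords[sorted(component)].mean(axis=0)
            points.append(
                AnnotationPoint(
                    "hydrophobic", tuple(centroid), frozenset(component)
                )
            )

    return points
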