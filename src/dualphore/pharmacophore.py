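"""Pharmacophore query model and the RMSD-based feature matcher.

A query is an ordered set of typed tolerance spheres (donor / aromatic /
hydrophobic, centre + radius in Angstrom).  A molecule matches when *all*
features can be assigned distinct, type-compatible ligand annotation
points whose RMSD to the feature centres — after optimal proper-rotation
superposition (``superpose`` mode, the default) or on the raw coordinates
(``in_place`` mode) — is below the cutoff, with every assigned point lying
inside its feature's tolerance sphere.  Partial matches are rejected.

The matcher enumerates every injective type-compatible assignment and
returns the minimum-RMSD qualifying one (ties broken by lexicographically
smallest mapping), so results are exact, not heuristic.  A configurable
combinatorial ceiling guards against pathological inputs.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chem import Molecule3D
from .features import (
    FEATURE_KINDS,
    AnnotationPoint,
    PerceptionRules,
    DEFAULT_RULES,
    perceive_features,
)
from .geometry import apply_rigid, kabsch_superpose, raw_rmsd

logger = logging.getLogger(__name__)


class CapacityError(RuntimeError):
    """Raised when the assignment enumeration would exceed the ceiling."""


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.radius > 0:
            raise ValueError("feature radius must be > 0")
        if not np.all(np.isfinite(self.center)):
            raise ValueError("non-finite feature center")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class PharmacophoreQuery:
    name: str
    features: list[PharmacophoreFeature]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("query needs at least one feature")

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features], dtype=float)

    @classmethod
    def from_dict(cls, payload: dict) -> "PharmacophoreQuery":
        feats = [
            PharmacophoreFeature(
                kind=f["kind"], center=tuple(f["center"]), radius=float(f["radius"])
            )
            for f in payload["features"]
        ]
        return cls(name=payload["name"], features=feats)

    @classmethod
    def from_json(cls, path: str | Path) -> "PharmacophoreQuery":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "features": [
                {"kind": f.kind, "center": list(f.center), "radius": f.radius}
                for f in self.features
            ],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True)
class MatcherSettings:
    mode: str = "superpose"  # or "in_place"
    rmsd_cutoff: float = 1.0  # Angstrom
    assignment_ceiling: int = 10**6

    def __post_init__(self) -> None:
        if self.mode not in ("superpose", "in_place"):
            raise ValueError(f"unknown matcher mode {self.mode!r}")
        if not self.rmsd_cutoff > 0:
            raise ValueError("rmsd_cutoff must be > 0")


@dataclass
class MatchResult:
    """Outcome of matching one molecule's annotation points against a query."""

    compound_id: str
    matched: bool
    rmsd: float | None = None
    mapping: tuple[int, ...] | None = None  # feature index -> point index
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None


_CONTAINMENT_EPS = 1e-9


def _assignment_count(per_kind: dict[str, tuple[int, int]]) -> float:
    total = 1.0
    for m, k in per_kind.values():
        total *= math.perm(m, k)
    return total


def match_query(
    query: PharmacophoreQuery,
    points: Sequence[AnnotationPoint],
    mode: str = "superpose",
    rmsd_cutoff: float = 1.0,
    assignment_ceiling: int = 10**6,
    compound_id: str = "",
) -> MatchResult:
    """Match annotation points against a query; all features are required.

    Enumerates every injective type-compatible assignment; each is scored
    by RMSD after proper-rotation superposition onto the feature centres
    (``superpose``) or on raw coordinates (``in_place``).  The minimal-RMSD
    assignment satisfying both the cutoff and per-feature sphere
    containment wins; ties go to the lexicographically smallest mapping.

    Raises :class:`CapacityError` if the assignment count would exceed
    ``assignment_ceiling`` (never silently truncates).
    """
    settings = MatcherSettings(mode, rmsd_cutoff, assignment_ceiling)

    kinds = sorted({f.kind for f in query.features})
    feat_idx_by_kind = {
        k: [i for i, f in enumerate(query.features) if f.kind == k] for k in kinds
    }
    pt_idx_by_kind = {
        k: [i for i, p in enumerate(points) if p.kind == k] for k in kinds
    }
    for k in kinds:
        if len(pt_idx_by_kind[k]) < len(feat_idx_by_kind[k]):
            return MatchResult(compound_id, matched=False)

    count = _assignment_count(
        {k: (len(pt_idx_by_kind[k]), len(feat_idx_by_kind[k])) for k in kinds}
    )
    if count > settings.assignment_ceiling:
        raise CapacityError(
            f"{compound_id or 'molecule'}: {count:.0f} candidate assignments "
            f"exceed the ceiling of {settings.assignment_ceiling}"
        )

    centers = query.centers
    radii = np.array([f.radius for f in query.features])
    pt_coords = np.array([p.xyz for p in points], dtype=float)
    n_feat = len(query.features)

    best: tuple[float, tuple[int, ...]] | None = None
    best_rt: tuple[np.ndarray, np.ndarray] | None = None

    per_kind_perms = [
        itertools.permutations(pt_idx_by_kind[k], len(feat_idx_by_kind[k]))
        for k in kinds
    ]
    for combo in itertools.product(*per_kind_perms):
        mapping_arr = [0] * n_feat
        for k, perm in zip(kinds, combo):
            for fi, pi in zip(feat_idx_by_kind[k], perm):
                mapping_arr[fi] = pi
        mapping = tuple(mapping_arr)
        lig = pt_coords[list(mapping)]
        if settings.mode == "superpose":
            rot, trans, rmsd = kabsch_superpose(lig, centers, allow_few_points=True)
            moved = apply_rigid(lig, rot, trans)
        else:
            rot = np.eye(3)
            trans = np.zeros(3)
            rmsd = raw_rmsd(lig, centers)
            moved = lig
        if rmsd > settings.rmsd_cutoff:
            continue
        dists = np.linalg.norm(moved - centers, axis=1)
        if np.any(dists > radii + _CONTAINMENT_EPS):
            continue
        key = (rmsd, mapping)
        if best is None or key < best:
            best = key
            best_rt = (rot, trans)

    if best is None:
        return MatchResult(compound_id, matched=False)
    rmsd, mapping = best
    rot, trans = best_rt  # type: ignore[misc]
    return MatchResult(
        compound_id,
        matched=True,
        rmsd=float(rmsd),
        mapping=mapping,
        rotation=rot,
        translation=trans,
    )


def screen_library(
    query: PharmacophoreQuery,
    mols: Iterable[Molecule3D],
    rules: PerceptionRules = DEFAULT_RULES,
    settings: MatcherSettings = MatcherSettings(),
) -> list[MatchResult]:
    """Screen a library, returning matched compounds in input order.

    Per-molecule capacity failures are logged and counted, never fatal; an
    empty library yields an empty hit list.
    """
    hits: list[MatchResult] = []
    failures = 0
    missing_h = 0
    for mol in mols:
        if not mol.has_explicit_hydrogens() and any(
            a.element in ("N", "O") for a in mol.atoms
        ):
            missing_h += 1
        points = perceive_features(mol, rules, warn_missing_h=False)
        try:
            result = match_query(
                query,
                points,
                mode=settings.mode,
                rmsd_cutoff=settings.rmsd_cutoff,
                assignment_ceiling=settings.assignment_ceiling,
                compound_id=mol.id,
            )
        except CapacityError as exc:
            failures += 1
            logger.debug("skipping %s: %s", mol.id, exc)
            continue
        if result.matched:
            hits.append(result)
    if missing_h:
        logger.warning(
            "%d molecule(s) have N/O atoms but no explicit hydrogens; "
            "their donor features were not perceived",
            missing_h,
        )
    if failures:
        logger.warning("%d molecule(s) skipped by the combinatorial guard", failures)
    return hits


def carm1_like_query() -> PharmacophoreQuery:
    """The packaged four-feature query fixture (donor, aromatic x2, hydrophobic).

    Synthetic coordinates in a tetrahedron-like arrangement (edges ~6 A);
    illustrative of a donor/aromatic/aromatic/hydrophobic binding-site
    model, not a reconstruction of any crystal structure.
    """
    ref = resources.files("dualphore.data").joinpath("carm1_like_query.json")
    return PharmacophoreQuery.from_dict(json.loads(ref.read_text()))
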