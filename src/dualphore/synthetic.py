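"""Synthetic input generators: planted screening libraries, docking score
tables, dose-response readouts and jittered trajectories.

Every generator is a pure function of its spec (including the seed):
identical specs give byte-identical outputs.  The constructions guarantee
their advertised properties rather than making them merely probable —
actives *realise* each query feature with a chemical fragment whose
annotation point lands at the feature centre (plus optional Gaussian
jitter), decoys *omit* a feature kind the query requires, planted score
passers are drawn strictly below their cutoff, and so on.

Chemistry here is geometric, not physical: fragments are idealised
hand-built motifs (regular benzene hexagon, 0.96 A hydroxyl, 1.54 A alkyl
spacing) chained through ether-oxygen bridges.  The ether bridge is load-
bearing: a carbon linker would merge neighbouring hydrophobic clusters
under the perception rules, while an ether oxygen breaks cluster
connectivity and contributes no hydrogen-bond donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import chi

from .bioassay import DoseResponseData, four_parameter_logistic
from .chem import Atom, Bond, Molecule3D, ScoreRecord
from .enrichment import ACTIVE, INACTIVE, LabeledLibrary
from .geometry import random_rotation
from .pharmacophore import PharmacophoreQuery
from .trajectory import AtomMeta, Trajectory

# priority used when choosing which feature kind a decoy must lack; aromatic
# rings themselves spawn hydrophobic cluster points, so dropping donor or
# aromatic is what structurally guarantees a non-match
_DROP_PRIORITY = ("donor", "aromatic", "hydrophobic")

_CONTAINMENT_QUANTILE = float(chi.ppf(0.95, 3))  # ~2.80 sigma for a 3D Gaussian


@dataclass(frozen=True)
class ScoreSpec:
    """Per-target cutoffs, spread, and the planted dual-passer sets."""

    cutoffs: dict = field(
        default_factory=lambda: {"CARM1": -11.3, "HDAC2": -11.7}
    )
    sd: float = 0.5
    margin: float = 0.05
    planted_passers: dict = field(default_factory=dict)  # target -> ids


@dataclass(frozen=True)
class DoseResponseSpec:
    ic50: float = 1e-8  # molar (10 nM)
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    noise_pct: float = 2.0  # sd as percent of (top - bottom)
    concentrations: tuple = tuple(np.logspace(-10, -6, 8))  # 0.1 nM - 1 uM
    n_replicates: int = 3


@dataclass(frozen=True)
class TrajectorySpec:
    n_atoms: int = 200  # one alpha carbon per residue
    n_frames: int = 100
    core_sigma: float = 0.3  # Angstrom, per coordinate
    terminal_multiplier: float = 5.0
    n_terminal_residues: int = 5
    frame_interval_ps: float = 10.0
    # frame 0 is the unjittered starting structure, like the minimised
    # initial frame of a production run; RMSD vs frame 0 then measures the
    # jitter directly
    first_frame_clean: bool = True


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs for the synthetic-input generators, with one shared seed."""

    seed: int = 0
    n_actives: int = 10
    n_decoys: int = 100
    feature_jitter: float = 0.2  # Angstrom per coordinate
    scores: ScoreSpec = field(default_factory=ScoreSpec)
    dose: DoseResponseSpec = field(default_factory=DoseResponseSpec)
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)

    def __post_init__(self) -> None:
        if self.feature_jitter < 0:
            raise ValueError("feature_jitter must be >= 0")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GeneratorSpec":
        kwargs = dict(payload)
        if "scores" in kwargs:
            kwargs["scores"] = ScoreSpec(**kwargs["scores"])
        if "dose" in kwargs:
            d = dict(kwargs["dose"])
            if "concentrations" in d:
                d["concentrations"] = tuple(d["concentrations"])
            kwargs["dose"] = DoseResponseSpec(**d)
        if "trajectory" in kwargs:
            kwargs["trajectory"] = TrajectorySpec(**kwargs["trajectory"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _rng(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator function."""
    return np.random.default_rng([abs(spec.seed), stream])


# ---------------------------------------------------------------------------
# fragment geometry (local frames anchored so the annotation point is at the
# origin); each returns (elements, charges, coords, bonds, attach_index)

_CC = 1.54  # sp3 carbon spacing, Angstrom
_AROM = 1.39  # aromatic C-C, Angstrom
_OH = 0.96  # O-H, Angstrom


def _fragment_donor():
    elements = ["O", "H"]
    coords = np.array([[0.0, 0.0, 0.0], [_OH, 0.0, 0.0]])
    bonds = [(0, 1, 1, False)]
    return elements, coords, bonds, 0


def _fragment_aromatic():
    angles = np.deg2rad(np.arange(6) * 60.0)
    coords = np.stack(
        [_AROM * np.cos(angles), _AROM * np.sin(angles), np.zeros(6)], axis=1
    )
    elements = ["C"] * 6
    bonds = [(i, (i + 1) % 6, 1, True) for i in range(6)]
    return elements, coords, bonds, 0


def _fragment_hydrophobic():
    # 3-carbon cluster (the annotation source) centred at the origin, plus an
    # attachment carbon that ends up excluded once bonded to a bridge oxygen
    r = _CC / np.sqrt(3.0)
    angles = np.deg2rad([90.0, 210.0, 330.0])
    tri = np.stack([r * np.cos(angles), r * np.sin(angles), np.zeros(3)], axis=1)
    attach = tri[0] + np.array([0.0, _CC, 0.0])
    coords = np.vstack([tri, attach[None, :]])
    elements = ["C"] * 4
    bonds = [(0, 1, 1, False), (1, 2, 1, False), (0, 3, 1, False)]
    return elements, coords, bonds, 3


_FRAGMENTS = {
    "donor": _fragment_donor,
    "aromatic": _fragment_aromatic,
    "hydrophobic": _fragment_hydrophobic,
}


def _assemble(
    mol_id: str,
    placements: Sequence[tuple[str, np.ndarray]],
    rng: np.random.Generator,
    properties: dict | None = None,
) -> Molecule3D:
    """Place one fragment per (kind, position), chained by ether-O bridges."""
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    attach_indices: list[int] = []
    for kind, pos in placements:
        elements, coords, frag_bonds, attach = _FRAGMENTS[kind]()
        rot = random_rotation(rng)
        placed = (rot @ coords.T).T + np.asarray(pos, dtype=float)
        offset = len(atoms)
        for e, xyz in zip(elements, placed):
            atoms.append(Atom(e, 0, tuple(float(v) for v in xyz)))
        for i, j, order, arom in frag_bonds:
            bonds.append(Bond(offset + i, offset + j, order, arom))
        attach_indices.append(offset + attach)
    for a, b in zip(attach_indices, attach_indices[1:]):
        mid = (np.array(atoms[a].xyz) + np.array(atoms[b].xyz)) / 2.0
        bridge = len(atoms)
        atoms.append(Atom("O", 0, tuple(float(v) for v in mid)))
        bonds.append(Bond(a, bridge, 1, False))
        bonds.append(Bond(bridge, b, 1, False))
    return Molecule3D(mol_id, atoms, bonds, properties or {})


def gen_labeled_library(
    query: PharmacophoreQuery, spec: GeneratorSpec
) -> LabeledLibrary:
    """Build a labelled screening library with planted actives and decoys.

    Actives carry one fragment per query feature, each fragment's
    annotation point landing at the feature centre plus per-coordinate
    Gaussian jitter of scale ``feature_jitter``.  Decoys omit every
    fragment of one feature kind the query requires (donor preferred, then
    aromatic) and scramble the remaining fragment positions, so they can
    never satisfy an all-features-required match.

    If the jitter is large enough that sphere containment can no longer be
    guaranteed for ~95% of points, ``jitter_warning`` is set on the
    returned library.
    """
    rng = _rng(spec, 1)
    query_kinds = [f.kind for f in query.features]
    drop_kind = next(k for k in _DROP_PRIORITY if k in query_kinds)

    centers = query.centers
    span = centers.max(axis=0) - centers.min(axis=0) + 10.0
    origin = centers.min(axis=0) - 5.0

    molecules: list[Molecule3D] = []
    labels: dict[str, str] = {}

    for i in range(spec.n_actives):
        placements = []
        for feat in query.features:
            jitter = rng.normal(0.0, spec.feature_jitter, 3) if spec.feature_jitter else 0.0
            placements.append((feat.kind, feat.xyz + jitter))
        mol = _assemble(
            f"ACT-{i + 1:03d}", placements, rng, {"activity": ACTIVE}
        )
        molecules.append(mol)
        labels[mol.id] = ACTIVE

    decoy_kinds = [k for k in query_kinds if k != drop_kind]
    for i in range(spec.n_decoys):
        placements = [
            (kind, origin + rng.random(3) * span) for kind in decoy_kinds
        ]
        if not placements:  # query made of a single kind: decoy is bare alkane pair
            placements = [("hydrophobic", origin + rng.random(3) * span)]
        mol = _assemble(
            f"DEC-{i + 1:03d}", placements, rng, {"activity": INACTIVE}
        )
        molecules.append(mol)
        labels[mol.id] = INACTIVE

    min_radius = min(f.radius for f in query.features)
    warning = spec.feature_jitter * _CONTAINMENT_QUANTILE > min_radius
    return LabeledLibrary(molecules, labels, jitter_warning=warning)


def gen_score_table(
    compound_ids: Sequence[str],
    targets: Sequence[str],
    spec: GeneratorSpec,
) -> list[ScoreRecord]:
    """Full-factorial compound x target score table with planted passers.

    Planted passers for a target draw energies strictly below its cutoff;
    all other compounds draw strictly above.  Requires every planted set
    to be a subset of ``compound_ids``.
    """
    rng = _rng(spec, 2)
    ss = spec.scores
    records: list[ScoreRecord] = []
    id_set = set(compound_ids)
    for target in targets:
        planted = set(ss.planted_passers.get(target, ()))
        if not planted <= id_set:
            raise ValueError(
                f"planted passers for {target!r} not all in compound_ids: "
                f"{sorted(planted - id_set)}"
            )
        cutoff = ss.cutoffs.get(target, -11.0)
        for cid in compound_ids:
            spread = abs(rng.normal(0.0, ss.sd))
            if cid in planted:
                energy = cutoff - ss.margin - spread
            else:
                energy = cutoff + ss.margin + spread
            records.append(ScoreRecord(cid, target, float(energy)))
    return records


def gen_dose_response(spec: GeneratorSpec) -> DoseResponseData:
    """Sample replicate responses from the 4PL curve with Gaussian noise.

    Noise sd is ``noise_pct`` percent of the curve's dynamic range
    (top - bottom); at zero noise the responses lie exactly on the curve
    and the response at c = IC50 equals (top + bottom) / 2.
    """
    rng = _rng(spec, 3)
    d = spec.dose
    conc = np.repeat(np.asarray(d.concentrations, dtype=float), d.n_replicates)
    clean = four_parameter_logistic(conc, d.ic50, d.hill, d.top, d.bottom)
    sd = d.noise_pct / 100.0 * (d.top - d.bottom)
    noise = rng.normal(0.0, sd, size=conc.shape) if sd > 0 else 0.0
    return DoseResponseData(conc, clean + noise)


def gen_trajectory(spec: GeneratorSpec) -> Trajectory:
    """Rigid-core / floppy-termini jittered trajectory of alpha carbons.

    The reference is an ideal helix of one CA per residue; each frame adds
    isotropic Gaussian jitter of per-coordinate scale ``core_sigma``,
    multiplied by ``terminal_multiplier`` for the first and last
    ``n_terminal_residues`` residues.  Zero jitter reproduces the
    reference in every frame.
    """
    rng = _rng(spec, 4)
    t = spec.trajectory
    n = t.n_atoms
    # alpha-helix-like reference: 100 deg turn, 1.5 A rise, 2.3 A radius
    theta = np.deg2rad(100.0) * np.arange(n)
    ref = np.stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(n)], axis=1
    )
    sigma = np.full(n, t.core_sigma)
    k = min(t.n_terminal_residues, n)
    if k:
        sigma[:k] = t.core_sigma * t.terminal_multiplier
        sigma[-k:] = t.core_sigma * t.terminal_multiplier
    meta = [AtomMeta("CA", i + 1, "ALA", True) for i in range(n)]
    if t.core_sigma > 0:
        noise = rng.normal(0.0, 1.0, size=(t.n_frames, n, 3)) * sigma[None, :, None]
    else:
        noise = np.zeros((t.n_frames, n, 3))
    if t.first_frame_clean:
        noise[0] = 0.0
    frames = ref[None, :, :] + noise
    return Trajectory(meta, frames, t.frame_interval_ps)
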