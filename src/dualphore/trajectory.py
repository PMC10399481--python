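"""Trajectory stability metrics: RMSD time series and per-residue RMSF.

Coordinates are handled internally in Angstrom; results are reported in
both Angstrom and nm (the convention of molecular-dynamics plots).  The
analysis operates on pre-computed trajectories (multi-model PDB or XYZ);
no simulation, solvation or periodic-boundary handling is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import apply_rigid, kabsch_superpose, raw_rmsd

A_PER_NM = 10.0


@dataclass(frozen=True)
class AtomMeta:
    name: str
    residue_index: int
    residue_name: str
    is_alpha_carbon: bool


@dataclass
class Trajectory:
    """Frames of coordinates (Angstrom) with per-atom residue metadata."""

    atom_meta: list[AtomMeta]
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval_ps: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != len(self.atom_meta):
            raise ValueError("frame atom count does not match atom_meta")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps


AtomPredicate = Callable[[AtomMeta], bool]


def alpha_carbons(meta: AtomMeta) -> bool:
    """Default selection: alpha carbons."""
    return meta.is_alpha_carbon


def _selection_indices(traj: Trajectory, selection: AtomPredicate) -> np.ndarray:
    idx = np.array(
        [i for i, m in enumerate(traj.atom_meta) if selection(m)], dtype=int
    )
    if idx.size == 0:
        raise ValueError("empty atom selection")
    return idx


def rmsd_series(
    traj: Trajectory,
    reference: int = 0,
    selection: AtomPredicate = alpha_carbons,
    superpose: bool = True,
) -> pd.DataFrame:
    """Per-frame RMSD versus a reference frame over the selection.

    Returns a DataFrame with columns ``time_ps``, ``rmsd_A``, ``rmsd_nm``.
    With ``superpose`` each frame is optimally superposed (proper rotation)
    onto the reference selection first; otherwise raw coordinates are
    compared.
    """
    idx = _selection_indices(traj, selection)
    if not (0 <= reference < traj.n_frames):
        raise IndexError(f"reference frame {reference} out of range")
    ref = traj.frames[reference][idx]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.frames[f][idx]
        if superpose:
            _, _, values[f] = kabsch_superpose(mob, ref)
        else:
            values[f] = raw_rmsd(mob, ref)
    return pd.DataFrame(
        {
            "time_ps": traj.times_ps(),
            "rmsd_A": values,
            "rmsd_nm": values / A_PER_NM,
        }
    )


def rmsf_per_residue(
    traj: Trajectory, selection: AtomPredicate = alpha_carbons
) -> pd.DataFrame:
    """Per-residue RMSF about the time-average structure of the selection.

    Every frame is superposed onto the mean structure, the mean being
    refined by a fixed two-iteration superposition pass (the provisional
    reference is the raw coordinate mean, so the result is independent of
    frame order) to avoid biasing the average toward an arbitrary frame.
    RMSF_i = sqrt(<|x_i(t) - <x_i>|^2>_t) per atom,
    then averaged over the selected atoms of each residue.

    Returns a DataFrame with columns ``residue_index``, ``rmsf_A``,
    ``rmsf_nm``.  Requires >= 2 frames.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    idx = _selection_indices(traj, selection)
    coords = traj.frames[:, idx, :]  # (F, n, 3)

    ref = coords.mean(axis=0)
    aligned = coords
    for _ in range(2):
        aligned = np.empty_like(coords)
        for f in range(traj.n_frames):
            rot, trans, _ = kabsch_superpose(coords[f], ref)
            aligned[f] = apply_rigid(coords[f], rot, trans)
        ref = aligned.mean(axis=0)

    mean = aligned.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))

    residues = np.array([traj.atom_meta[i].residue_index for i in idx])
    order = []
    sums: dict[int, list[float]] = {}
    for res, val in zip(residues, per_atom):
        if res not in sums:
            sums[res] = []
            order.append(res)
        sums[res].append(val)
    res_vals = np.array([np.mean(sums[r]) for r in order])
    return pd.DataFrame(
        {
            "residue_index": order,
            "rmsf_A": res_vals,
            "rmsf_nm": res_vals / A_PER_NM,
        }
    )


def _universe_to_trajectory(universe, frame_interval_ps: float) -> Trajectory:
    atoms = universe.atoms
    names = [str(n) for n in atoms.names]
    try:
        resids = [int(r) for r in atoms.resids]
    except Exception:  # topology without residue info
        resids = list(range(1, len(names) + 1))
    try:
        resnames = [str(r) for r in atoms.resnames]
    except Exception:
        resnames = ["UNK"] * len(names)
    meta = [
        AtomMeta(n, ri, rn, n.strip().upper() == "CA")
        for n, ri, rn in zip(names, resids, resnames)
    ]
    frames = np.array(
        [atoms.positions.copy() for _ in universe.trajectory], dtype=float
    )
    return Trajectory(meta, frames, frame_interval_ps)


def read_trajectory(path: str | Path, frame_interval_ps: float = 10.0) -> Trajectory:
    """Read a multi-model PDB or XYZ trajectory (format by extension)."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe(str(path))
        return _universe_to_trajectory(universe, frame_interval_ps)


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL per frame)."""
    import MDAnalysis as mda

    n = traj.n_atoms
    resids_all = [m.residue_index for m in traj.atom_meta]
    unique_res = sorted(set(resids_all))
    res_lookup = {r: i for i, r in enumerate(unique_res)}
    atom_resindex = [res_lookup[r] for r in resids_all]
    resnames = {}
    for m in traj.atom_meta:
        resnames.setdefault(m.residue_index, m.residue_name)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=len(unique_res),
            atom_resindex=atom_resindex,
            residue_segindex=[0] * len(unique_res),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [m.name for m in traj.atom_meta])
        u.add_TopologyAttr("resids", unique_res)
        u.add_TopologyAttr("resnames", [resnames[r] for r in unique_res])
        u.add_TopologyAttr("segids", ["A"])
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as writer:
            for frame in traj.frames:
                u.atoms.positions = frame
                writer.write(u.atoms)
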