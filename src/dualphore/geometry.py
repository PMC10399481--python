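"""Least-squares rigid superposition (Kabsch) and RMSD helpers.

The superposition is restricted to proper rotations (determinant +1):
reflections would silently erase chirality, which matters both for
pharmacophore matching and for trajectory analysis.
"""

from __future__ import annotations

import numpy as np


def raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """In-place RMSD between two paired coordinate sets (no superposition)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, *, allow_few_points: bool = False
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with the transform ``x -> R @ x + t`` applied to
    the mobile set minimising the summed squared deviation over proper
    rotations only (determinant +1; mirror images are never matched).

    Requires >= 3 points unless ``allow_few_points`` is set (the
    pharmacophore matcher legitimately superposes 1- or 2-feature queries,
    where the problem is underdetermined but the minimum is still attained).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("expected (n, 3) coordinate arrays")
    if mobile.shape[0] < 3 and not allow_few_points:
        raise ValueError("superposition requires at least 3 points")

    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    am = mobile - mu_m
    ar = reference - mu_r

    h = am.T @ ar
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:  # fully degenerate covariance; treat as proper
        d = 1.0
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_r - rot @ mu_m
    moved = (rot @ mobile.T).T + trans
    return rot, trans, raw_rmsd(moved, reference)


def apply_rigid(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    """Apply ``x -> R @ x + t`` to an (n, 3) array."""
    return (np.asarray(rot) @ np.asarray(coords, dtype=float).T).T + np.asarray(trans)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
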