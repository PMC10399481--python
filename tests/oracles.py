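"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: the
superposition here comes from scipy's ``Rotation.align_vectors``, the GH
formula is re-evaluated in exact rational arithmetic, and the matcher
oracle enumerates raw permutations.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
from scipy.spatial.transform import Rotation


def superpose_rmsd_scipy(mobile: np.ndarray, reference: np.ndarray):
    """Proper-rotation least-squares RMSD via scipy (independent of the package)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - mu_r, mobile - mu_m)
    moved = rot.apply(mobile - mu_m) + mu_r
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return moved, rmsd


def match_oracle(
    feature_kinds,
    centers,
    radii,
    point_kinds,
    point_coords,
    mode: str,
    cutoff: float,
):
    """Exhaustive-permutation matcher: returns (matched, best_rmsd).

    Scores every injective type-compatible assignment of points to
    features explicitly; no per-kind factorisation, no shared code with
    the implementation under test.
    """
    centers = np.asarray(centers, dtype=float)
    point_coords = np.asarray(point_coords, dtype=float)
    n_feat = len(feature_kinds)
    best = None
    for combo in itertools.permutations(range(len(point_kinds)), n_feat):
        if any(point_kinds[p] != feature_kinds[f] for f, p in enumerate(combo)):
            continue
        lig = point_coords[list(combo)]
        if mode == "superpose":
            moved, rmsd = superpose_rmsd_scipy(lig, centers)
        else:
            moved = lig
            rmsd = float(np.sqrt(np.mean(np.sum((lig - centers) ** 2, axis=1))))
        if rmsd > cutoff:
            continue
        dists = np.linalg.norm(moved - centers, axis=1)
        if np.any(dists > np.asarray(radii) + 1e-9):
            continue
        if best is None or rmsd < best:
            best = rmsd
    return (best is not None), best


def gh_fraction(D: int, A: int, Ht: int, Ha: int) -> Fraction:
    """The goodness-of-hit score in exact rational arithmetic."""
    first = Fraction(Ha * (3 * A + Ht), 4 * Ht * A)
    second = 1 - Fraction(Ht - Ha, D - A)
    return first * second


def grid_min_rmsd(mobile: np.ndarray, reference: np.ndarray, n: int, seed: int):
    """Minimum RMSD over a dense random sample of proper rotations."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    am = mobile - mobile.mean(axis=0)
    ar = reference - reference.mean(axis=0)
    mats = Rotation.random(n, rng=np.random.default_rng(seed)).as_matrix()
    rotated = np.einsum("nij,mj->nmi", mats, am)
    d = rotated - ar[None, :, :]
    rmsds = np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))
    return float(rmsds.min())
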