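"""RMSD pharmacophore matcher: exactness, invariances, screening."""

import numpy as np
import pytest

from dualphore.features import AnnotationPoint
from dualphore.geometry import apply_rigid, random_rotation
from dualphore.pharmacophore import (
    CapacityError,
    MatcherSettings,
    PharmacophoreFeature,
    PharmacophoreQuery,
    carm1_like_query,
    match_query,
    screen_library,
)
from dualphore.synthetic import GeneratorSpec, gen_labeled_library

from oracles import match_oracle

KINDS = ("donor", "aromatic", "hydrophobic")


def _point(kind, xyz):
    return AnnotationPoint(kind, tuple(np.asarray(xyz, dtype=float)), frozenset({0}))


def _points_at_centers(query):
    return [_point(f.kind, f.center) for f in query.features]


def _random_instance(rng, near_centers=False):
    """Random matcher instance; with ``near_centers`` the points are noisy
    permuted copies of the feature centres (plus extras), so the matched
    branch of the oracle comparison is exercised in both modes."""
    n_feat = int(rng.integers(2, 5))
    n_points = int(rng.integers(n_feat, 7))
    feat_kinds = [KINDS[k] for k in rng.integers(0, 3, n_feat)]
    centers = rng.uniform(-5, 5, (n_feat, 3))
    radii = rng.uniform(0.5, 3.0, n_feat)
    if near_centers:
        order = rng.permutation(n_feat)
        pt_kinds = [feat_kinds[i] for i in order]
        coords = centers[order] + rng.normal(0, 0.3, (n_feat, 3))
        for _ in range(n_points - n_feat):
            pt_kinds.append(KINDS[int(rng.integers(0, 3))])
            coords = np.vstack([coords, rng.uniform(-5, 5, 3)])
    else:
        pt_kinds = [KINDS[k] for k in rng.integers(0, 3, n_points)]
        coords = rng.uniform(-5, 5, (n_points, 3))
    cutoff = float(rng.uniform(0.5, 3.0))
    query = PharmacophoreQuery(
        "random",
        [
            PharmacophoreFeature(k, tuple(c), float(r))
            for k, c, r in zip(feat_kinds, centers, radii)
        ],
    )
    points = [_point(k, c) for k, c in zip(pt_kinds, coords)]
    return query, points, cutoff, (feat_kinds, centers, radii, pt_kinds, coords)


class TestMatchQuery:
    def test_points_at_centers_match_with_zero_rmsd(self, four_feature_query):
        result = match_query(four_feature_query, _points_at_centers(four_feature_query))
        assert result.matched
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        assert result.mapping == (0, 1, 2, 3)

    def test_rigid_motion_invariance(self, four_feature_query):
        points = _points_at_centers(four_feature_query)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90 deg
        trans = np.array([10.0, -3.0, 7.0])
        moved = [
            _point(p.kind, apply_rigid(p.xyz[None, :], rot, trans)[0]) for p in points
        ]
        result = match_query(four_feature_query, moved, mode="superpose")
        assert result.matched
        assert result.rmsd <= 1e-8

    def test_in_place_mode_uses_raw_coordinates(self, four_feature_query):
        points = _points_at_centers(four_feature_query)
        shifted = [_point(p.kind, p.xyz + np.array([5.0, 0.0, 0.0])) for p in points]
        assert match_query(four_feature_query, shifted, mode="superpose").matched
        assert not match_query(four_feature_query, shifted, mode="in_place").matched

    def test_all_features_required(self, four_feature_query):
        points = [
            p for p in _points_at_centers(four_feature_query) if p.kind != "donor"
        ]
        assert not match_query(four_feature_query, points).matched

    def test_tie_broken_by_lexicographic_mapping(self):
        # two aromatic features and two aromatic points exactly on them:
        # both assignments reach rmsd 0 under superposition (180 deg flip)
        query = PharmacophoreQuery(
            "pair",
            [
                PharmacophoreFeature("aromatic", (0.0, 0.0, 0.0), 1.0),
                PharmacophoreFeature("aromatic", (4.0, 0.0, 0.0), 1.0),
            ],
        )
        points = [_point("aromatic", (0.0, 0.0, 0.0)), _point("aromatic", (4.0, 0.0, 0.0))]
        result = match_query(query, points)
        assert result.matched
        assert result.mapping == (0, 1)

    def test_capacity_guard_raises(self):
        query = PharmacophoreQuery(
            "big",
            [PharmacophoreFeature("aromatic", (float(i), 0.0, 0.0), 1.0) for i in range(6)],
        )
        points = [_point("aromatic", (float(i), 0.1, 0.0)) for i in range(12)]
        with pytest.raises(CapacityError):
            match_query(query, points, assignment_ceiling=1000)

    @pytest.mark.parametrize("mode", ["superpose", "in_place"])
    def test_matches_exhaustive_permutation_oracle(self, mode):
        rng = np.random.default_rng(42)
        n_checked = 0
        for i in range(300):
            query, points, cutoff, raw = _random_instance(rng, near_centers=i % 2 == 0)
            feat_kinds, centers, radii, pt_kinds, coords = raw
            result = match_query(query, points, mode=mode, rmsd_cutoff=cutoff)
            expected_matched, expected_rmsd = match_oracle(
                feat_kinds, centers, radii, pt_kinds, coords, mode, cutoff
            )
            assert result.matched == expected_matched
            if expected_matched:
                assert result.rmsd == pytest.approx(expected_rmsd, abs=1e-8)
                n_checked += 1
        assert n_checked > 10  # the random instances do exercise the matched branch

    def test_monotone_in_radius_and_cutoff(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            query, points, cutoff, _ = _random_instance(rng)
            base = match_query(query, points, rmsd_cutoff=cutoff)
            if not base.matched:
                continue
            bigger = PharmacophoreQuery(
                query.name,
                [
                    PharmacophoreFeature(f.kind, f.center, f.radius + 1.0)
                    for f in query.features
                ],
            )
            assert match_query(bigger, points, rmsd_cutoff=cutoff + 1.0).matched


class TestScreenLibrary:
    def test_planted_actives_all_hit(self, four_feature_query):
        lib = gen_labeled_library(
            four_feature_query,
            GeneratorSpec(seed=5, n_actives=10, n_decoys=50, feature_jitter=0.0),
        )
        hits = screen_library(four_feature_query, lib.molecules)
        hit_ids = [h.compound_id for h in hits]
        actives = [m.id for m in lib.molecules if lib.labels[m.id] == "active"]
        assert set(actives) <= set(hit_ids)
        assert len(hit_ids) == len(set(hit_ids))
        # hit list preserves library order
        order = {m.id: i for i, m in enumerate(lib.molecules)}
        assert hit_ids == sorted(hit_ids, key=order.__getitem__)

    def test_empty_library_gives_empty_hit_list(self, four_feature_query):
        assert screen_library(four_feature_query, []) == []

    def test_decoys_only_no_hits(self, four_feature_query):
        lib = gen_labeled_library(
            four_feature_query,
            GeneratorSpec(seed=6, n_actives=0, n_decoys=40, feature_jitter=0.0),
        )
        assert screen_library(four_feature_query, lib.molecules) == []
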