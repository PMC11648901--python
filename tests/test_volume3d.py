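"""Label-volume interpolation, overlap resolution, meshing, repair."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from histoatlas.volume3d import (
    ClaimVolume,
    LabelVolume,
    RegionMesh,
    SmoothingConfig,
    build_claim_volume,
    extract_mesh,
    interpolate_region_pair,
    repair_mesh_overlaps,
    resolve_overlaps,
    smooth_mesh,
    voxelize_mesh,
)


def _disk(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return (yy - center[1]) ** 2 + (xx - center[0]) ** 2 <= radius**2


class TestInterpolateRegionPair:
    def test_identical_masks_unchanged(self):
        m = _disk((64, 64), (32, 32), 12)
        for inter in interpolate_region_pair(m, m, 4):
            assert np.array_equal(inter, m)

    def test_translated_disk_moves_linearly(self):
        a = _disk((96, 96), (34, 48), 14)
        b = _disk((96, 96), (58, 48), 14)
        inters = interpolate_region_pair(a, b, 3)
        for i, m in enumerate(inters, start=1):
            frac = i / 4
            expect_x = 34 + frac * 24
            ys, xs = np.nonzero(m)
            assert abs(xs.mean() - expect_x) <= 1.0
            assert abs(ys.mean() - 48) <= 1.0

    def test_extinction_monotone(self):
        a = _disk((64, 64), (32, 32), 14)
        b = np.zeros((64, 64), bool)
        inters = interpolate_region_pair(a, b, 5)
        areas = [m.sum() for m in inters]
        assert all(x >= y for x, y in zip(areas, areas[1:]))
        assert areas[0] < a.sum()

    def test_both_empty_flagged(self):
        e = np.zeros((32, 32), bool)
        with pytest.warns(UserWarning, match="both masks empty"):
            inters = interpolate_region_pair(e, e, 3)
        assert all(not m.any() for m in inters)


class TestBuildClaimVolume:
    def test_spacing_arithmetic(self):
        """100 µm sections to a 10 µm grid insert 9 intermediates."""
        a = np.where(_disk((48, 48), (24, 24), 10), 1, 0)
        claims = build_claim_volume([a, a], spacing_in=100.0, spacing_out=10.0)
        assert claims.shape[0] == 11  # (2-1)*10 + 1 planes
        assert claims.spacing[0] == 10.0

    def test_identical_slices_constant(self):
        a = np.where(_disk((48, 48), (24, 24), 10), 2, 0)
        claims = build_claim_volume([a, a], spacing_in=40.0, spacing_out=10.0)
        for p in range(claims.shape[0]):
            assert np.array_equal(claims.claims[2][p], a == 2)

    def test_region_on_single_slice_tapers_out(self):
        a = np.where(_disk((48, 48), (24, 24), 12), 5, 0)
        empty = np.zeros_like(a)
        claims = build_claim_volume([empty, a, empty], spacing_in=40.0, spacing_out=10.0)
        areas = claims.claims[5].sum(axis=(1, 2))
        assert areas[4] == (a == 5).sum()
        assert areas[0] == 0 and areas[-1] == 0
        assert all(areas[i] <= areas[i + 1] for i in range(4))
        assert all(areas[i] >= areas[i + 1] for i in range(4, 8))

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_claim_volume([np.zeros((8, 8), int)], 100.0, 10.0)

    def test_indivisible_spacing_rejected(self):
        a = np.zeros((8, 8), int)
        with pytest.raises(ValueError, match="divisible"):
            build_claim_volume([a, a], 100.0, 30.0)


class TestResolveOverlaps:
    def test_disjoint_claims_identity(self):
        a = np.zeros((8, 8, 8), bool)
        a[1:4] = True
        b = np.zeros((8, 8, 8), bool)
        b[5:7] = True
        vol = resolve_overlaps(ClaimVolume({1: a, 2: b}, (1, 1, 1)))
        assert np.array_equal(vol.labels == 1, a)
        assert np.array_equal(vol.labels == 2, b)

    def test_line_overlap_split_by_distance(self):
        """A claims [0..5], B claims [4..9] on a line: A keeps 4, B keeps 5."""
        a = np.zeros((1, 1, 10), bool)
        a[0, 0, 0:6] = True
        b = np.zeros((1, 1, 10), bool)
        b[0, 0, 4:10] = True
        vol = resolve_overlaps(ClaimVolume({1: a, 2: b}, (1, 1, 1)))
        assert vol.labels[0, 0, 4] == 1
        assert vol.labels[0, 0, 5] == 2

    def test_covers_claimed_union_only(self):
        rng = np.random.default_rng(0)
        claims = _random_claims(rng, shape=(24, 24, 24), n_regions=3)
        vol = resolve_overlaps(claims)
        union = np.zeros((24, 24, 24), bool)
        for m in claims.claims.values():
            union |= m
        assert not (vol.labels[~union] != 0).any()
        # every reachable claimed voxel is assigned
        assert (vol.labels[union] == 0).mean() < 0.01

    def test_matches_nearest_support_oracle(self):
        rng = np.random.default_rng(1)
        agree, total = 0, 0
        for _ in range(5):
            claims = _random_claims(rng, shape=(32, 32, 32), n_regions=3)
            got = resolve_overlaps(claims)
            want, contested = _nearest_support_oracle(claims)
            agree += (got.labels[contested] == want[contested]).sum()
            total += contested.sum()
        assert total > 0
        assert agree / total >= 0.99


def _random_claims(rng, shape, n_regions):
    """Overlapping random ellipsoid claims on a shared grid."""
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(float)
    claims = {}
    for rid in range(1, n_regions + 1):
        c = rng.uniform(0.35, 0.65, 3) * np.asarray(shape)
        semi = rng.uniform(0.15, 0.32, 3) * np.asarray(shape)
        claims[rid] = (
            ((zz - c[0]) / semi[0]) ** 2
            + ((yy - c[1]) / semi[1]) ** 2
            + ((xx - c[2]) / semi[2]) ** 2
        ) <= 1.0
    return ClaimVolume(claims, (1.0, 1.0, 1.0))


def _nearest_support_oracle(claims):
    """Brute force: each contested voxel goes to the claimant with the
    nearest post-unassignment support voxel (ties to the lower id)."""
    count = claims.claim_count()
    contested = count >= 2
    want = np.zeros(claims.shape, dtype=np.int32)
    for rid, m in claims.claims.items():
        want[m & (count == 1)] = rid
    pts = np.argwhere(contested)
    if len(pts) == 0:
        return want, contested
    best = np.full(len(pts), np.inf)
    winner = np.zeros(len(pts), dtype=np.int32)
    for rid in sorted(claims.claims):
        support = np.argwhere(claims.claims[rid] & ~contested)
        if len(support) == 0:
            continue
        claimed_here = claims.claims[rid][tuple(pts.T)]
        d = cdist(pts, support).min(axis=1)
        better = claimed_here & (d < best)
        best[better] = d[better]
        winner[better] = rid
    want[tuple(pts.T)] = winner
    return want, contested


class TestMeshing:
    def test_ball_volume(self):
        zz, yy, xx = np.mgrid[0:48, 0:48, 0:48].astype(float)
        mask = (zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2 <= 20**2
        vol = LabelVolume(np.where(mask, 1, 0), (1.0, 1.0, 1.0))
        mesh = extract_mesh(vol, 1)
        expect = 4 / 3 * np.pi * 20**3
        assert abs(mesh.enclosed_volume - expect) <= 0.05 * expect
        assert mesh.is_watertight

    def test_single_voxel(self):
        """A lone voxel meshes to the closed octahedron through its six
        face centers, whose volume is exactly 1/6 voxel."""
        labels = np.zeros((5, 5, 5), int)
        labels[2, 2, 2] = 1
        mesh = extract_mesh(LabelVolume(labels, (1.0, 1.0, 1.0)), 1)
        assert mesh.is_watertight
        assert np.isclose(mesh.enclosed_volume, 1.0 / 6.0)

    def test_absent_region_rejected(self):
        vol = LabelVolume(np.zeros((4, 4, 4), int), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="absent"):
            extract_mesh(vol, 3)

    def test_voxelize_round_trip(self):
        zz, yy, xx = np.mgrid[0:32, 0:32, 0:32].astype(float)
        mask = ((zz - 16) / 10) ** 2 + ((yy - 16) / 8) ** 2 + ((xx - 16) / 12) ** 2 <= 1
        vol = LabelVolume(np.where(mask, 1, 0), (1.0, 1.0, 1.0))
        mesh = extract_mesh(vol, 1)
        back = voxelize_mesh(mesh, vol)
        dice = 2 * (back & mask).sum() / (back.sum() + mask.sum())
        assert dice >= 0.98


class TestSmoothMesh:
    def test_zero_iterations_identity(self):
        labels = np.zeros((8, 8, 8), int)
        labels[2:6, 2:6, 2:6] = 1
        mesh = extract_mesh(LabelVolume(labels, (1.0, 1.0, 1.0)), 1)
        out = smooth_mesh(mesh, SmoothingConfig(iterations=0))
        assert np.array_equal(out.vertices, mesh.vertices)

    def test_single_umbrella_update(self):
        """One iteration, λ=0.5: vertex at the origin with neighbors at
        (1,0,0), (−1,0,0), (0,1,0) moves to (0, 1/6, 0)."""
        verts = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]
        )
        faces = np.array([[0, 1, 3], [0, 3, 2]])
        mesh = RegionMesh(verts, faces, 1)
        out = smooth_mesh(mesh, SmoothingConfig(lambda0=0.5, iterations=1))
        assert np.allclose(out.vertices[0], [0.0, 1.0 / 6.0, 0.0])

    def test_published_schedule_barely_moves(self):
        """λ=1e-4 for 100 iterations perturbs vertices by well under a voxel."""
        labels = np.zeros((16, 16, 16), int)
        labels[4:12, 4:12, 4:12] = 1
        mesh = extract_mesh(LabelVolume(labels, (1.0, 1.0, 1.0)), 1)
        out = smooth_mesh(mesh, SmoothingConfig())
        assert np.abs(out.vertices - mesh.vertices).max() < 0.05


class TestRepairMeshOverlaps:
    def _adjacent_cubes(self):
        labels = np.zeros((20, 20, 36), int)
        labels[4:16, 4:16, 4:18] = 1
        labels[4:16, 4:16, 18:32] = 2
        return LabelVolume(labels, (1.0, 1.0, 1.0))

    def test_disjoint_meshes_unchanged(self):
        vol = self._adjacent_cubes()
        meshes = [extract_mesh(vol, rid) for rid in (1, 2)]
        out = repair_mesh_overlaps(meshes, vol, SmoothingConfig())
        for a, b in zip(out, meshes):
            assert np.array_equal(a.vertices, b.vertices)

    def test_bulging_meshes_separated(self):
        """Meshes whose surfaces encroach on each other (here: two balls
        meshed from masks that overlap by a thin lens, the situation
        smoothing creates at region interfaces) come back pairwise
        disjoint in voxel space with near-conserved union volume."""
        zz, yy, xx = np.mgrid[0:28, 0:28, 0:44].astype(float)
        a = (zz - 14) ** 2 + (yy - 14) ** 2 + (xx - 15) ** 2 <= 10**2
        b = (zz - 14) ** 2 + (yy - 14) ** 2 + (xx - 28) ** 2 <= 10**2
        grid = LabelVolume(np.zeros((28, 28, 44), int), (1.0, 1.0, 1.0))
        meshes = [
            extract_mesh(LabelVolume(np.where(a, 1, 0), (1.0, 1.0, 1.0)), 1),
            extract_mesh(LabelVolume(np.where(b, 2, 0), (1.0, 1.0, 1.0)), 2),
        ]
        vox = [voxelize_mesh(m, grid) for m in meshes]
        overlap = (vox[0] & vox[1]).sum()
        assert overlap > 0
        union_before = (vox[0] | vox[1]).sum()
        cfg = SmoothingConfig(lambda0=1e-3, iterations=50, decay=0.5, max_cycles=8)
        out = repair_mesh_overlaps(meshes, grid, cfg)
        vox2 = [voxelize_mesh(m, grid) for m in out]
        assert not (vox2[0] & vox2[1]).any()
        union_after = (vox2[0] | vox2[1]).sum()
        assert abs(union_after - union_before) <= 0.02 * union_before
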