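from collections import deque
from itertools import product

import numpy as np
import pytest
from skimage.measure import marching_cubes

from tbprobe.segmentation import build_mesh, label_bone, remove_islands
from tbprobe.volume_io import CTVolume


def _volume(data, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(data, dtype=np.float32), np.asarray(spacing))


def _slab_volume(spacing=(0.5, 0.5, 0.5), shape=(24, 24, 24), lo=6, hi=18):
    data = np.full(shape, -1000.0, dtype=np.float32)
    data[lo:hi, lo:hi, lo:hi] = 1500.0
    return _volume(data, spacing), (lo, hi)


def bfs_components(mask):
    """Independent 26-connected component labeling (brute-force BFS)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    offsets = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            p = q.popleft()
            comp.append(p)
            for d in offsets:
                n = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if all(0 <= n[a] < mask.shape[a] for a in range(3)) \
                        and mask[n] and not seen[n]:
                    seen[n] = True
                    q.append(n)
        comps.append(comp)
    return comps


def test_threshold_labels_slab_exactly():
    vol, (lo, hi) = _slab_volume()
    label = label_bone(vol)
    expected = np.zeros(vol.shape, bool)
    expected[lo:hi, lo:hi, lo:hi] = True
    np.testing.assert_array_equal(label.mask, expected)


def test_threshold_boundary_is_inclusive_at_620():
    below = label_bone(_volume(np.full((4, 4, 4), 619.0)))
    at = label_bone(_volume(np.full((4, 4, 4), 620.0)))
    assert not below.mask.any()
    assert at.mask.all()


def test_air_cells_inside_bone_are_excluded():
    vol, (lo, hi) = _slab_volume()
    vol.data[10:12, 10:12, 10:12] = -800.0
    label = label_bone(vol)
    np.testing.assert_array_equal(label.mask, vol.data >= 620.0)
    assert not label.mask[10, 10, 10]


@pytest.mark.parametrize("n_voxels, survives", [(299, False), (300, True)])
def test_island_removal_boundary_at_300(n_voxels, survives):
    data = np.full((10, 10, 10), -1000.0, dtype=np.float32)
    flat = np.zeros(1000, bool)
    flat[:n_voxels] = True  # one connected raster-order blob
    data[flat.reshape(10, 10, 10, order="F")] = 1500.0
    label = remove_islands(label_bone(_volume(data)), 300)
    assert label.mask.any() == survives


def test_island_removal_matches_bruteforce_components(rng):
    data = np.full((20, 20, 20), -1000.0, dtype=np.float32)
    data[2:14, 2:14, 2:14] = 1500.0  # large slab
    for c in [(17, 3, 3), (3, 17, 17), (17, 17, 3)]:
        data[c[0]:c[0] + 2, c[1]:c[1] + 2, c[2]:c[2] + 2] = 1500.0  # 8-vox specks
    label = label_bone(_volume(data))
    cleaned = remove_islands(label, 300)
    comps = bfs_components(label.mask)
    expected = np.zeros_like(label.mask)
    for comp in comps:
        if len(comp) >= 300:
            for p in comp:
                expected[p] = True
    np.testing.assert_array_equal(cleaned.mask, expected)
    # every surviving component is large enough (re-check with oracle)
    assert all(len(c) >= 300 for c in bfs_components(cleaned.mask))


def test_island_removal_empty_and_idempotent():
    vol, _ = _slab_volume()
    empty = remove_islands(label_bone(_volume(np.full((5, 5, 5), -1000.0))), 300)
    assert not empty.mask.any()
    once = remove_islands(label_bone(vol), 300)
    twice = remove_islands(once, 300)
    np.testing.assert_array_equal(once.mask, twice.mask)


def test_mesh_bbox_matches_cuboid():
    vol, (lo, hi) = _slab_volume(spacing=(0.5, 0.5, 0.5))
    mesh = build_mesh(label_bone(vol), smoothing_mm=0.0)
    # mask voxel centers span [lo, hi-1]*s; surface extends half a voxel
    lo_mm, hi_mm = (lo - 0.5) * 0.5, (hi - 0.5) * 0.5
    np.testing.assert_allclose(mesh.vertices.min(axis=0), lo_mm, atol=0.5)
    np.testing.assert_allclose(mesh.vertices.max(axis=0), hi_mm, atol=0.5)


def test_slab_faces_have_opposite_outward_normals():
    data = np.full((30, 30, 20), -1000.0, dtype=np.float32)
    data[3:27, 3:27, 6:14] = 1500.0
    mesh = build_mesh(label_bone(_volume(data)), smoothing_mm=0.0)
    centers = mesh.vertices[mesh.triangles].mean(axis=1)
    zc = centers[:, 2]
    top = mesh.face_normals[zc > 13.2]
    bottom = mesh.face_normals[zc < 5.8]
    top_mean = top.mean(axis=0) / np.linalg.norm(top.mean(axis=0))
    bot_mean = bottom.mean(axis=0) / np.linalg.norm(bottom.mean(axis=0))
    assert top_mean @ bot_mean < -0.99
    assert top_mean[2] > 0.99  # outward = +z on the top face


def test_zero_smoothing_returns_raw_marching_cubes():
    vol, _ = _slab_volume()
    mesh = build_mesh(label_bone(vol), smoothing_mm=0.0)
    padded = np.pad(vol.data >= 620.0, 1).astype(np.float32)
    verts, _, _, _ = marching_cubes(padded, 0.5, spacing=tuple(vol.spacing))
    verts = verts - vol.spacing
    np.testing.assert_allclose(np.sort(mesh.vertices, axis=0),
                               np.sort(verts, axis=0), atol=1e-9)


def test_smoothed_sphere_area_near_analytic():
    r_vox = 12
    n = 2 * r_vox + 7
    c = (n - 1) / 2.0
    ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    mask = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= r_vox ** 2
    data = np.where(mask, 1500.0, -1000.0).astype(np.float32)
    mesh = build_mesh(label_bone(_volume(data, (1.0, 1.0, 1.0))),
                      smoothing_mm=4.0)
    area = mesh.trimesh.area
    assert area == pytest.approx(4 * np.pi * r_vox ** 2, rel=0.05)


def test_empty_label_is_hard_error():
    label = label_bone(_volume(np.full((4, 4, 4), -1000.0)))
    with pytest.raises(ValueError, match="empty"):
        build_mesh(label)
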