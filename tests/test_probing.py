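import numpy as np
import pytest
import trimesh

from tbprobe.frame import RetroauricularFrame
from tbprobe.phantom import PhantomSpec, generate_slab
from tbprobe.probing import (cortical_density, probe_point, project_probe,
                             sample_profile, thickness)
from tbprobe.segmentation import BoneMesh, build_mesh, label_bone
from tbprobe.volume_io import CTVolume

CANONICAL_FRAME = RetroauricularFrame(
    origin=np.zeros(3), x_axis=np.array([1.0, 0, 0]),
    y_axis=np.array([0, 1.0, 0]), z_axis=np.array([0, 0, 1.0]))


def _box_mesh(extents, center=(0, 0, 0), rotation=None):
    m = trimesh.creation.box(extents=extents)
    if rotation is not None:
        m.apply_transform(rotation)
    m.apply_translation(center)
    return BoneMesh(m.vertices, m.faces)


def test_flat_slab_probe_direction_is_medial():
    mesh = _box_mesh([30, 30, 10], center=(0, 0, -5))  # top face at z=0
    hit = project_probe((0.0, 0.0), mesh, CANONICAL_FRAME)
    assert hit is not None
    entry, direction = hit
    np.testing.assert_allclose(entry, [0, 0, 0], atol=1e-9)
    np.testing.assert_allclose(direction, -CANONICAL_FRAME.z_axis, atol=1e-6)


def test_probe_beyond_mesh_misses():
    mesh = _box_mesh([30, 30, 10], center=(0, 0, -5))
    assert project_probe((100.0, 0.0), mesh, CANONICAL_FRAME) is None


def test_tilted_slab_direction_matches_rotated_normal():
    rot = trimesh.transformations.rotation_matrix(np.deg2rad(30), [0, 1, 0])
    mesh = _box_mesh([40, 40, 10], center=(0, 0, -5), rotation=rot)
    _, direction = project_probe((0.0, 0.0), mesh, CANONICAL_FRAME)
    expected = -(rot[:3, :3] @ np.array([0.0, 0.0, 1.0]))
    np.testing.assert_allclose(direction, expected, atol=1e-3)


def test_thickness_of_box_probed_perpendicular_and_oblique():
    mesh = _box_mesh([40, 40, 10], center=(0, 0, -5))
    entry = np.array([0.0, 0.0, 0.0])
    down = np.array([0.0, 0.0, -1.0])
    assert thickness(mesh, entry, down) == pytest.approx(10.0, abs=1e-9)
    # 30 degrees incidence: path length 10/cos(30)
    d30 = np.array([np.sin(np.deg2rad(30)), 0, -np.cos(np.deg2rad(30))])
    assert thickness(mesh, entry, d30) == pytest.approx(
        10 / np.cos(np.deg2rad(30)), abs=1e-9)
    # 60 degrees: 20 mm path capped at 18
    d60 = np.array([np.sin(np.deg2rad(60)), 0, -np.cos(np.deg2rad(60))])
    assert thickness(mesh, entry, d60) == 18.0


def test_thickness_ignores_internal_cavity_surfaces():
    # nested boxes: outer surface plus an internal void's surface
    outer = trimesh.creation.box(extents=[40, 40, 10])
    inner = trimesh.creation.box(extents=[10, 10, 2])
    inner.invert()
    both = trimesh.util.concatenate([outer, inner])
    both.apply_translation([0, 0, -5])
    mesh = BoneMesh(both.vertices, both.faces)
    d = thickness(mesh, np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, -1.0]))
    assert d == pytest.approx(10.0, abs=1e-9)


def _uniform_volume(hu=1500.0, shape=(40, 40, 40), spacing=0.5):
    return CTVolume(np.full(shape, hu, dtype=np.float32),
                    np.full(3, spacing))


def test_uniform_volume_sampling_and_count():
    vol = _uniform_volume()
    entry = np.array([10.0, 10.0, 18.5])
    samples = sample_profile(vol, entry, np.array([0.0, 0.0, -1.0]))
    assert len(samples) == 121  # floor(18 / 0.15) + 1
    np.testing.assert_allclose(samples, 1500.0)


def test_sampling_depths_monotone_and_within_cap():
    vol = _uniform_volume()
    samples = sample_profile(vol, np.array([10.0, 10.0, 18.0]),
                             np.array([0.0, 0.0, -1.0]), delta_d=0.15,
                             d_max=18.0)
    depths = np.arange(len(samples)) * 0.15
    assert np.all(np.diff(depths) > 0)
    assert depths[-1] <= 18.0 + 1e-9


def test_sampling_stops_at_volume_boundary():
    vol = _uniform_volume(shape=(20, 20, 20), spacing=0.5)  # 10 mm cube
    samples = sample_profile(vol, np.array([5.0, 5.0, 9.0]),
                             np.array([0.0, 0.0, -1.0]))
    assert len(samples) < 121
    assert len(samples) == pytest.approx(9.0 / 0.15, abs=2)


def test_entry_outside_volume_is_hard_error():
    vol = _uniform_volume(shape=(10, 10, 10), spacing=0.5)
    with pytest.raises(ValueError, match="outside"):
        sample_profile(vol, np.array([50.0, 0.0, 0.0]),
                       np.array([0.0, 0.0, -1.0]))


def test_two_layer_profile_tracks_analytic_step():
    # 1500 HU for z in [18, 20) mm, 300 HU below: boundary at depth 2 mm
    data = np.full((40, 40, 48), -1000.0, dtype=np.float32)
    data[:, :, 36:40] = 1500.0
    data[:, :, 16:36] = 300.0
    vol = CTVolume(data, np.full(3, 0.5))
    entry = np.array([10.0, 10.0, 19.75])  # top voxel-center plane
    samples = sample_profile(vol, entry, np.array([0.0, 0.0, -1.0]))
    depths = np.arange(len(samples)) * 0.15
    assert samples[np.argmin(np.abs(depths - 1.5))] == pytest.approx(1500, abs=1)
    assert samples[np.argmin(np.abs(depths - 2.5))] == pytest.approx(300, abs=1)


def test_cortical_density_rules():
    assert cortical_density(np.full(40, 1200.0), 0.15) == 1200.0
    profile = np.array([500.0, 500.0] + [1100.0] * 30)
    assert cortical_density(profile, 0.15) == 1100.0
    assert cortical_density(np.full(40, 900.0), 0.15) is None


def test_cortical_density_matches_bruteforce_window(rng):
    delta_d = 0.15
    ramp = np.linspace(0.0, 2000.0, 80)  # crosses 1000 HU mid-profile
    got = cortical_density(ramp, delta_d)
    start = next(i for i, v in enumerate(ramp) if v >= 1000.0)
    window = [v for i, v in enumerate(ramp)
              if start <= i <= start + int(np.floor(1.5 / delta_d + 1e-9))]
    assert len(window) == 11
    assert got == pytest.approx(sum(window) / len(window), abs=1e-12)


@pytest.mark.parametrize("t_mm", [2.0, 6.0, 15.0])
def test_slab_thickness_recovered_via_pipeline(t_mm):
    spec = PhantomSpec(kind="slab", size_mm=(20, 20, t_mm + 8),
                       spacing_mm=(0.3, 0.3, 0.2), layers=[(t_mm, 1500.0)])
    vol, gt = generate_slab(spec)
    mesh = build_mesh(label_bone(vol), smoothing_mm=4.0)
    p = probe_point(vol, mesh, gt.frame, (0.0, 0.0))
    assert p.status == "ok"
    tol = float(np.linalg.norm(vol.spacing)) / 2
    assert p.d_tb == pytest.approx(gt.expected_thickness(), abs=tol)
    expected_n = int(np.floor(min(p.d_tb, 18.0) / 0.15 + 1e-9)) + 1
    assert len(p.samples) == expected_n


def test_probe_miss_reported_via_status():
    spec = PhantomSpec(kind="slab", size_mm=(14, 14, 12),
                       spacing_mm=(0.3, 0.3, 0.2), layers=[(4.0, 1500.0)])
    vol, gt = generate_slab(spec)
    mesh = build_mesh(label_bone(vol), smoothing_mm=0.0)
    p = probe_point(vol, mesh, gt.frame, (500.0, 0.0))
    assert p.status == "no_intersection"
    assert np.isnan(p.d_tb)
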