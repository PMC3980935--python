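"""Implicit field values, gradients, distance estimates and ray tracing."""

import numpy as np
import pytest

from cavigraph import fixtures as fx
from cavigraph.surface import (
    EPS_ISO,
    SurfaceField,
    SurfaceModel,
    evaluate_brute_force,
)
from conftest import make_frame, make_parallel_plates

SAS = SurfaceModel("sas", 1.4)


def test_sas_value_single_atom(lone_atom_field):
    f = lone_atom_field
    assert f.evaluate([0, 0, 0]) == pytest.approx(3.1)       # r + R at center
    assert f.evaluate([3.1, 0, 0]) == pytest.approx(0.0, abs=1e-12)
    assert f.evaluate([5, 0, 0]) == pytest.approx(-1.9)


def test_vdw_and_kernel_sign_conventions():
    frame, _ = fx.make_lone_atom()
    vdw = SurfaceField(SurfaceModel("vdw"), frame)
    assert vdw.evaluate([0, 0, 0]) == pytest.approx(1.7)
    assert vdw.evaluate([1.7, 0, 0]) == pytest.approx(0.0, abs=1e-12)
    kern = SurfaceField(SurfaceModel("kernel"), frame)
    assert kern.evaluate([0, 0, 0]) > 0          # inside positive
    assert kern.evaluate([10, 0, 0]) < 0


def test_union_is_max_of_single_atom_values():
    frame = make_frame([(0, 0, 0), (2.0, 0, 0)])
    both = SurfaceField(SAS, frame)
    a = SurfaceField(SAS, make_frame([(0, 0, 0)]))
    b = SurfaceField(SAS, make_frame([(2.0, 0, 0)]))
    for p in ([1.0, 0.5, 0], [0.5, 0, 0], [3.0, 1.0, -1.0]):
        assert both.evaluate(p) == pytest.approx(
            max(a.evaluate(p), b.evaluate(p))
        )


@pytest.mark.parametrize("kind", ["vdw", "sas", "kernel"])
def test_grid_equals_brute_force(kind, slab_pocket):
    """The voxel-accelerated field equals the all-atoms scan everywhere."""
    fixtures = [
        fx.make_lone_atom()[0],
        fx.make_convex_cluster(5)[0],
        slab_pocket[0],
        fx.make_hollow_shell()[0],
    ]
    model = SurfaceModel(kind)
    rng = np.random.default_rng(42)
    for frame in fixtures:
        field = SurfaceField(model, frame)
        lo, hi = frame.bounds
        pts = rng.uniform(lo - 8.0, hi + 8.0, size=(1000, 3))
        fast = field.evaluate_many(pts)
        slow = np.array([evaluate_brute_force(model, frame, p) for p in pts])
        if kind == "kernel":
            assert np.allclose(fast, slow, atol=1e-9)
        else:
            assert np.array_equal(fast, slow)
        # scalar path agrees with the batched path (kernel sums may differ
        # in float association order only)
        sub = pts[:25]
        scalar = np.array([field.evaluate(p) for p in sub])
        if kind == "kernel":
            assert np.allclose(scalar, field.evaluate_many(sub), atol=1e-12)
        else:
            assert np.array_equal(scalar, field.evaluate_many(sub))


def test_sign_inside_atoms_and_far_outside(slab_pocket):
    frame, _ = slab_pocket
    field = SurfaceField(SAS, frame)
    for i in range(0, len(frame), 37):
        assert field.evaluate(frame.coords[i]) > 0
    lo, hi = frame.bounds
    far = hi + (field.grid.radius_max + field.grid.probe_max + 1.0)
    assert field.evaluate(far) < 0


def test_gradient_single_atom_points_inward(lone_atom_field):
    g, mag = lone_atom_field.gradient([5.0, 0, 0])
    assert mag == pytest.approx(1.0)
    assert np.allclose(g, [-1, 0, 0])


def test_gradient_tie_breaks_to_lowest_atom_index():
    frame = make_frame([(-2.0, 0, 0), (2.0, 0, 0)])
    field = SurfaceField(SAS, frame)
    g, mag = field.gradient([0.0, 4.0, 0.0])  # equidistant from both atoms
    assert mag == pytest.approx(1.0)
    to_first = (frame.coords[0] - np.array([0.0, 4.0, 0.0]))
    assert np.allclose(g, to_first / np.linalg.norm(to_first))


def test_gradient_degenerate_at_center(lone_atom_field):
    g, mag = lone_atom_field.gradient([0.0, 0.0, 0.0])
    assert mag == 0.0


def test_kernel_gradient_matches_finite_difference():
    frame, _ = fx.make_lone_atom()
    field = SurfaceField(SurfaceModel("kernel"), frame)
    p = np.array([1.3, 0.7, -0.4])
    direction, mag = field.gradient(p)
    h = 1e-5
    numeric = np.array(
        [(field.evaluate(p + h * e) - field.evaluate(p - h * e)) / (2 * h)
         for e in np.eye(3)]
    )
    assert np.linalg.norm(direction * mag - numeric) < 1e-5


def test_distance_estimate_exact_for_single_sphere(lone_atom_field):
    # (r + R) - d with a unit gradient: exact Euclidean surface distance
    assert lone_atom_field.distance_estimate([5, 0, 0]) == pytest.approx(1.9)
    assert lone_atom_field.distance_estimate([3.1, 0, 0]) == pytest.approx(0.0, abs=1e-12)


def test_distance_estimate_lower_bounds_true_distance():
    """On a two-sphere union the estimate never exceeds the true distance
    (dense surface sampling as oracle)."""
    centers = np.array([[0.0, 0, 0], [2.5, 0, 0]])
    frame = make_frame(centers)
    field = SurfaceField(SAS, frame)
    # dense point cloud on both inflated spheres, keeping surface points only
    u = np.linspace(0, np.pi, 200)
    v = np.linspace(0, 2 * np.pi, 400)
    uu, vv = np.meshgrid(u, v)
    sphere = 3.1 * np.column_stack(
        [np.sin(uu.ravel()) * np.cos(vv.ravel()),
         np.sin(uu.ravel()) * np.sin(vv.ravel()),
         np.cos(uu.ravel())]
    )
    surf = np.concatenate([c + sphere for c in centers])
    surf = surf[field.evaluate_many(surf) > -1e-9]  # drop buried caps

    rng = np.random.default_rng(3)
    pts = rng.uniform(-7, 9, size=(100, 3))
    pts = pts[field.evaluate_many(pts) < 0][:60]
    for p in pts:
        true = np.min(np.linalg.norm(surf - p, axis=1))
        assert field.distance_estimate(p) <= true + 1e-6


def test_trace_ray_hits_sphere_at_inflated_radius(lone_atom_field):
    hit = lone_atom_field.trace_ray([6.0, 0, 0], [-1, 0, 0])
    assert hit is not None
    assert np.linalg.norm(hit - np.array([3.1, 0, 0])) < 1e-3


def test_trace_ray_away_from_lone_atom_misses(lone_atom_field):
    assert lone_atom_field.trace_ray([6.0, 0, 0], [1, 0, 0]) is None


def test_trace_ray_requires_outside_origin(lone_atom_field):
    with pytest.raises(ValueError):
        lone_atom_field.trace_ray([0, 0, 0], [1, 0, 0])


def test_trace_ray_parallel_walls_hits_facing_wall():
    gap = 12.0
    frame = make_parallel_plates(gap=gap)
    field = SurfaceField(SAS, frame)
    # straight up from the midplane over an atom column: surface plane of the
    # facing wall is z = gap - 3.1 exactly
    hit = field.trace_ray([0.0, 0.0, gap / 2], [0, 0, 1])
    assert hit is not None
    assert abs(hit[2] - (gap - 3.1)) < 1e-2
    assert abs(hit[0]) < 1e-9 and abs(hit[1]) < 1e-9


def test_trace_ray_never_overshoots_first_crossing():
    """The reported hit is the FIRST surface crossing along the ray (a
    0.01-A fine-sampling oracle finds no earlier sign change)."""
    frame = make_parallel_plates()
    field = SurfaceField(SAS, frame)
    rng = np.random.default_rng(11)
    origins = rng.uniform([-8, -8, 4.0], [8, 8, 8.0], size=(40, 3))
    origins = origins[field.evaluate_many(origins) < 0][:15]
    for origin in origins:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        hit = field.trace_ray(origin, d)
        if hit is None:
            continue
        assert abs(field.evaluate(hit)) < EPS_ISO
        t_hit = float(np.dot(hit - origin, d))
        ts = np.arange(0.0, t_hit - 5e-3, 0.01)
        if len(ts):
            f_before = field.evaluate_many(origin[None, :] + ts[:, None] * d)
            assert np.all(f_before < EPS_ISO)
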