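import numpy as np
import pytest
from shapely.geometry import Polygon

from azmap import (
    ASYNCHRONOUS,
    ECTOPIC,
    IN_AZ,
    SYNCHRONOUS,
    UNDEFINED,
    build_az,
    build_az_map,
    label_events,
    normalized_distance,
    radial_profile,
    ray_border_distance,
)
from azmap.errors import DegenerateGeometryError, InsufficientPointsError
from .conftest import make_dataset
from .oracles import ray_march_border


def test_square_hull_center_and_area():
    corners = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], float)
    az = build_az(corners)
    assert az.area_nm2 == pytest.approx(10000.0)
    np.testing.assert_allclose(az.center_nm, [50.0, 50.0])
    assert len(az.hull_vertices) == 4


def test_interior_point_changes_center_not_hull():
    pts = np.array([[0, 0], [100, 0], [100, 100], [0, 100], [50, 50]], float)
    az = build_az(pts)
    assert len(az.hull_vertices) == 4
    np.testing.assert_allclose(az.center_nm, [50.0, 50.0])


def test_centroid_option_differs_from_event_mean():
    # hull unchanged, but an off-center interior point shifts the event mean
    pts = np.array([[0, 0], [100, 0], [100, 100], [0, 100], [10, 10]], float)
    mean_az = build_az(pts, center="mean")
    cen_az = build_az(pts, center="centroid")
    np.testing.assert_allclose(cen_az.center_nm, [50.0, 50.0])
    assert mean_az.center_nm[0] < 50.0


def test_too_few_or_collinear_points_raise():
    with pytest.raises(InsufficientPointsError):
        build_az(np.array([[0, 0], [1, 1]], float))
    with pytest.raises(DegenerateGeometryError):
        build_az(np.array([[0, 0], [50, 50], [100, 100]], float))


def test_normalized_distance_on_worked_square(square_az):
    m = normalized_distance([50.0, 0.0], square_az, rim_nm=25.0)
    assert m.d_center_nm == pytest.approx(50.0)
    assert m.d_border_nm == pytest.approx(100.0)
    assert m.d_norm == pytest.approx(0.4)
    assert m.location_class == IN_AZ

    m = normalized_distance([150.0, 0.0], square_az, rim_nm=25.0)
    assert m.d_norm == pytest.approx(1.2)
    assert m.location_class == ECTOPIC

    m = normalized_distance([0.0, 0.0], square_az, rim_nm=25.0)
    assert m.d_norm == 0.0 and m.location_class == IN_AZ


def test_boundary_tie_classifies_inside(square_az):
    # d_norm exactly 1 (event at border + rim along +x) counts as in-AZ
    m = normalized_distance([125.0, 0.0], square_az, rim_nm=25.0)
    assert m.d_norm == pytest.approx(1.0)
    assert m.location_class == IN_AZ


def _random_convex_polygon(rng, n_min=4, n_max=10, r_mean=150.0):
    n = rng.integers(n_min, n_max + 1)
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = rng.uniform(0.4 * r_mean, 1.6 * r_mean, n)
    pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    return np.asarray(Polygon(pts).convex_hull.exterior.coords[:-1])


def test_border_distance_matches_ray_marching_on_random_polygons():
    """Analytic ray-edge intersection vs dense marching (reduced size; the
    full-size check runs in the acceptance suite)."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        verts = _random_convex_polygon(rng)
        az = build_az(verts)
        poly = Polygon(az.hull_vertices)
        theta = rng.uniform(0, 2 * np.pi, 10)
        dirs = np.column_stack([np.cos(theta), np.sin(theta)])
        analytic = ray_border_distance(az, dirs)
        marched = ray_march_border(poly, az.center_nm, dirs)
        np.testing.assert_allclose(analytic, marched, atol=0.1)


def test_scale_equivariance_of_normalized_distance(square_az):
    """Scaling coordinates and rim together leaves d_norm unchanged; with a
    fixed rim, d_norm = s*d_c / (s*d_b + rim) is strictly monotone in the
    scale s (the rim matters less as the AZ grows)."""
    base = normalized_distance([150.0, 0.0], square_az, rim_nm=25.0)
    for s in (0.5, 2.0, 5.0):
        scaled = build_az(square_az.hull_vertices * s)
        both = normalized_distance([150.0 * s, 0.0], scaled, rim_nm=25.0 * s)
        assert both.d_norm == pytest.approx(base.d_norm)
        fixed_rim = normalized_distance([150.0 * s, 0.0], scaled, rim_nm=25.0)
        if s > 1:
            assert fixed_rim.d_norm > base.d_norm
        else:
            assert fixed_rim.d_norm < base.d_norm


def test_hull_vertex_events_stay_inside_with_rim(square_az):
    for v in square_az.hull_vertices:
        m = normalized_distance(v, square_az, rim_nm=25.0)
        expected = m.d_border_nm / (m.d_border_nm + 25.0)
        assert m.d_norm == pytest.approx(expected)
        assert m.d_norm < 1


def test_radial_profile_composition_and_partition():
    rows = [
        ("A", -100, -100, 0, 1), ("A", 100, -100, 1, 1),
        ("A", 100, 100, 2, 1), ("A", -100, 100, 3, 1),
        ("A", 50, 0, 10, 2),    # in-AZ asynchronous
        ("A", 150, 0, 11, 2),   # ectopic asynchronous
    ]
    ds = label_events(make_dataset(rows))
    prof = radial_profile(ds)
    prof = prof.set_index("event_id")
    assert prof.loc["e4", "d_norm"] == pytest.approx(0.4)
    assert prof.loc["e5", "d_norm"] == pytest.approx(1.2)
    sync = prof[prof["release_class"] == SYNCHRONOUS]
    assert (sync["d_norm"] < 1).all()
    async_part = prof[prof["release_class"] == ASYNCHRONOUS]
    assert (async_part["location_class"] == IN_AZ).sum() + (
        async_part["location_class"] == ECTOPIC
    ).sum() == len(async_part)


def test_bouton_without_valid_az_flags_rows_undefined():
    rows = [("A", 0, 0, 0, 1), ("A", 10, 0, 1, 1), ("A", 5, 0, 10, 2)]
    ds = label_events(make_dataset(rows))  # only 2 sync events: no hull
    prof = radial_profile(ds)
    assert (prof["location_class"] == UNDEFINED).all()
    assert prof["d_norm"].isna().all()


def test_synthetic_synchronous_events_always_inside(small_synthetic):
    ds, _ = small_synthetic
    ds = label_events(ds.copy())
    prof = radial_profile(ds, build_az_map(ds))
    sync = prof[(prof["release_class"] == SYNCHRONOUS) & prof["d_norm"].notna()]
    assert (sync["d_norm"] < 1).all()
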