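"""Lattice packing, event location, transport rules and fICSD scoring."""

import math

import numpy as np
import pytest

from idkit import (
    SourceSphere,
    TransportRules,
    accumulate_ficsd,
    apply_pbc,
    build_cylinder_lattice,
    exclude_source_overlap,
    locate_event,
    locate_events,
    mean_source_path,
    primary_termination_budget,
    score_history,
    secondary_transport_decision,
)
from idkit.geometry import (
    InvalidGeometryError,
    fk_standard_error,
    locate_events_bruteforce,
)


def oracle_count(cube, d, length):
    """Independent enumeration of the uniform-count registration."""
    if d > cube or length > cube:
        return 0
    r = d / 2.0
    n_xy = sum(1 for i in range(1000) if (-cube / 2 + r) + i * d <= cube / 2 - r + 1e-12)
    n_z = sum(
        1
        for i in range(1000)
        if (-cube / 2 + length / 2) + i * length <= cube / 2 - length / 2 + 1e-12
    )
    return n_xy * n_xy * n_z


class TestPacking:
    @pytest.mark.parametrize("cube", [3.4, 6.0, 10.0, 13.7, 20.0])
    def test_count_matches_enumeration_oracle(self, cube):
        lat = build_cylinder_lattice(cube, 2.3, 3.4, 1.15)
        assert lat.count == oracle_count(cube, 2.3, 3.4)

    def test_single_and_zero_cylinder_cubes(self):
        assert build_cylinder_lattice(3.4, 2.3, 3.4, 1.15).count == 1
        assert build_cylinder_lattice(2.0, 2.3, 3.4, 1.15).count == 0

    def test_reference_geometry_count_and_fill(self):
        lat = build_cylinder_lattice(100, 2.3, 3.4, 1.15)
        assert lat.count == 53621
        assert round(100 * lat.fill_fraction) == 76

    def test_determinism(self):
        a = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        b = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_no_overlap_within_layer(self):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        layer = lat.centers[np.isclose(lat.centers[:, 2], lat.centers[0, 2])]
        xy = layer[:, :2]
        d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
        d2[np.diag_indices(len(xy))] = np.inf
        assert math.sqrt(d2.min()) >= lat.cyl_diameter - 1e-9

    def test_containment_with_shift_tolerance(self):
        # shifted-row end cylinders may overhang by at most the shift slack
        lat = build_cylinder_lattice(100, 2.3, 3.4, 1.15)
        h = lat.cube_side / 2
        over = np.max(np.abs(lat.centers[:, 0]) + lat.radius - h)
        assert over <= lat.row_shift + 1e-9
        # unshifted axes: strict containment
        assert np.max(np.abs(lat.centers[:, 1]) + lat.radius) <= h + 1e-9
        assert np.max(np.abs(lat.centers[:, 2]) + lat.cyl_length / 2) <= h + 1e-9

    def test_invalid_dimension_raises(self):
        with pytest.raises(InvalidGeometryError):
            build_cylinder_lattice(-1, 2.3, 3.4, 1.15)
        with pytest.raises(InvalidGeometryError):
            build_cylinder_lattice(10, 0.0, 3.4, 1.15)


class TestSourceExclusion:
    def test_zero_sphere_is_noop(self):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        assert exclude_source_overlap(lat, SourceSphere(diameter=0)).count == lat.count

    def test_sphere_covering_cube_removes_all(self):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        assert exclude_source_overlap(lat, SourceSphere(diameter=200)).count == 0

    def test_exclusion_matches_sampling_oracle(self):
        lat = build_cylinder_lattice(40, 2.3, 3.4, 1.15)
        sphere = SourceSphere(diameter=20)
        kept = exclude_source_overlap(lat, sphere)
        kept_set = {tuple(np.round(c, 9)) for c in kept.centers}
        # sample each cylinder solid on a cylindrical grid; compare with a
        # margin covering the sampling resolution
        rr = np.linspace(0, lat.radius, 6)
        th = np.linspace(0, 2 * math.pi, 16, endpoint=False)
        zz = np.linspace(-lat.cyl_length / 2, lat.cyl_length / 2, 9)
        R, TH, ZZ = np.meshgrid(rr, th, zz, indexing="ij")
        local = np.stack(
            [R * np.cos(TH), R * np.sin(TH), ZZ], axis=-1
        ).reshape(-1, 3)
        margin = 0.35  # > max sample spacing
        for c in lat.centers:
            pts = c + local
            dmin = np.min(np.linalg.norm(pts - np.asarray(sphere.center), axis=1))
            key = tuple(np.round(c, 9))
            if dmin < sphere.radius - margin:
                assert key not in kept_set  # certainly intersects
            elif dmin > sphere.radius + margin:
                assert key in kept_set  # certainly separate


class TestLocate:
    def test_center_and_gap_points(self):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        assert locate_event(lat.centers[7], lat) == 7
        # corner of the cube lies in no cylinder (registration leaves gaps)
        assert locate_event([9.99, 9.99, 9.99], lat) is None

    def test_hash_equals_linear_scan(self, rng):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        pts = rng.uniform(-10, 10, size=(10_000, 3))
        np.testing.assert_array_equal(
            locate_events(pts, lat), locate_events_bruteforce(pts, lat)
        )


class TestTransportRules:
    def test_termination_budget_worked_example(self):
        assert primary_termination_budget(15, 10, 0.01) == pytest.approx(0.05)
        assert primary_termination_budget(1.0, 0.9, 0.01) == pytest.approx(0.001)

    def test_budget_invalid_arguments(self):
        with pytest.raises(ValueError):
            primary_termination_budget(10, 15, 0.01)

    @pytest.mark.parametrize(
        "species,energy,expected",
        [
            ("e-", 0.04, "transport"),
            ("e-", 0.054, "terminate"),
            ("proton", 2.0, "terminate"),
            ("proton", 1.0, "transport"),
            ("He", 0.001, "terminate"),
            ("Ar", 500.0, "terminate"),
        ],
    )
    def test_secondary_decision(self, species, energy, expected):
        rules = TransportRules()
        assert secondary_transport_decision(species, energy, rules) == expected

    def test_unknown_species_raises(self):
        with pytest.raises(ValueError):
            secondary_transport_decision("muon", 1.0, TransportRules())

    def test_pbc_diametric_reentry(self):
        p, u, e = apply_pbc([50.0, 3.0, 7.0], [1.0, 0.0, 0.0], 5.0, 100.0)
        np.testing.assert_allclose(p, [-50.0, -3.0, -7.0])
        np.testing.assert_allclose(u, [1.0, 0.0, 0.0])
        assert e == 5.0

    def test_pbc_interior_point_rejected(self):
        with pytest.raises(ValueError):
            apply_pbc([0.0, 0.0, 0.0], [1.0, 0.0, 0.0], 5.0, 100.0)


class TestScoring:
    def test_hand_assigned_clusters(self):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        c0, c1 = lat.centers[0], lat.centers[40]
        events = np.vstack([np.tile(c0, (4, 1)), np.tile(c1, (2, 1))])
        sizes = score_history(events, lat, track_length=10.0)
        assert sorted(sizes) == [2, 4]

    def test_single_event_single_cluster(self):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        assert list(score_history(lat.centers[3], lat, 5.0)) == [1]

    def test_conservation_of_in_cylinder_events(self, rng):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        pts = rng.uniform(-10, 10, size=(2000, 3))
        sizes = score_history(pts, lat, 100.0)
        assert sizes.sum() == np.sum(locate_events(pts, lat) >= 0)

    def test_zero_track_length_with_events_raises(self):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        with pytest.raises(ValueError):
            score_history(lat.centers[0], lat, 0.0)


class TestFicsdAccumulation:
    def test_identical_histories_zero_se(self):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        hist = (np.tile(lat.centers[0], (3, 1)), 10.0)
        tally = accumulate_ficsd([hist] * 20, lat)
        np.testing.assert_allclose(tally.se, 0.0, atol=1e-15)
        assert tally.f[2] == pytest.approx(20 / 200.0)

    def test_f_is_intensive_under_duplication(self, rng):
        lat = build_cylinder_lattice(20, 2.3, 3.4, 1.15)
        hists = [
            (rng.uniform(-10, 10, size=(rng.integers(1, 30), 3)), 15.0)
            for _ in range(40)
        ]
        t1 = accumulate_ficsd(hists, lat)
        t2 = accumulate_ficsd(hists * 2, lat)
        np.testing.assert_allclose(t1.f, t2.f)

    def test_f1_matches_poisson_thinning_oracle(self):
        """Axial Poisson track vs. the closed-form cluster expectation."""
        from idkit.tracks import ToyTrackModel, generate_history

        lam, cube = 0.5, 20.0
        lat = build_cylinder_lattice(cube, 2.3, 3.4, 1.15)
        model = ToyTrackModel(primary_ionization_density=lam)
        src = SourceSphere(diameter=0.0)
        start = np.array([lat.centers[0, 0], lat.centers[0, 1], -9.999])
        rng = np.random.default_rng(77)
        hists = [
            generate_history(model, src, cube, rng, start=start, direction=[0, 0, 1])
            for _ in range(3000)
        ]
        tally = accumulate_ficsd(hists, lat)
        track_len = hists[0][1]
        # independent expectation: Poisson thinning per overlapped cylinder
        col = lat.centers[
            np.isclose(lat.centers[:, 0], start[0])
            & np.isclose(lat.centers[:, 1], start[1])
        ]
        exp_clusters = 0.0
        for cz in col[:, 2]:
            lo, hi = max(cz - 1.7, start[2]), min(cz + 1.7, cube / 2)
            if hi > lo:
                exp_clusters += -math.expm1(-lam * (hi - lo))
        f1_expected = exp_clusters / track_len
        f1 = tally.f.sum()
        se = fk_standard_error(tally, 1)
        assert abs(f1 - f1_expected) <= 3 * se + 1e-12


class TestMeanSourcePath:
    def test_closed_form_values(self):
        assert mean_source_path(17.0) == pytest.approx(12.75)
        assert mean_source_path(4.0) == pytest.approx(3.0)

    def test_monte_carlo_converges_to_3R_over_4(self):
        n = 200_000
        est = mean_source_path(17.0, n_samples=n, rng=3)
        # path-length std is ~0.49 R (numeric integration); 0.5 R is a bound
        se = 17.0 * 0.5 / math.sqrt(n)
        assert abs(est - 12.75) <= 3 * se
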