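"""Sensor site placement, channel construction, and array thinning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist

from megsim import make_head
from megsim.sensor_arrays import (
    array_from_frame,
    array_to_frame,
    build_opm_array,
    local_triad,
    place_opm_sites,
    remove_sensors,
)


class TestLocalTriad:
    def test_equator_site_recovers_cartesian_axes(self):
        tri = local_triad(np.array([0.09, 0, 0]), np.zeros(3))
        assert np.allclose(tri.e_nor, [1, 0, 0])
        assert np.allclose(tri.e_lat, [0, 1, 0])
        assert np.allclose(tri.e_lon, [0, 0, 1])

    @settings(max_examples=50, deadline=None)
    @given(
        st.tuples(
            st.floats(-1, 1), st.floats(-1, 1), st.floats(-0.95, 0.95)
        ).filter(lambda v: 0.1 < np.linalg.norm(v) and abs(v[2]) / max(np.linalg.norm(v), 1e-9) < 0.99)
    )
    def test_orthonormal_right_handed_everywhere(self, direction):
        site = 0.09 * np.asarray(direction) / np.linalg.norm(direction)
        tri = local_triad(site, np.zeros(3))
        gram = np.abs(
            [tri.e_nor @ tri.e_lat, tri.e_nor @ tri.e_lon, tri.e_lat @ tri.e_lon]
        ).sum()
        assert gram < 1e-12
        for e in (tri.e_nor, tri.e_lat, tri.e_lon):
            assert np.linalg.norm(e) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.cross(tri.e_nor, tri.e_lat), tri.e_lon, atol=1e-12)

    def test_pole_fallback_is_deterministic_and_orthonormal(self):
        a = local_triad(np.array([0, 0, 0.09]), np.zeros(3))
        b = local_triad(np.array([0, 0, 0.09]), np.zeros(3))
        assert np.array_equal(a.e_lat, b.e_lat)
        assert abs(a.e_nor @ a.e_lat) < 1e-12
        assert np.allclose(np.cross(a.e_nor, a.e_lat), a.e_lon)


@pytest.fixture(scope="module")
def full_heads():
    # default-resolution meshes at the extreme head sizes
    return [
        make_head(scalp_radius=r, subdivision=4, perturbation=0.02, seed=s)
        for r, s in [(0.087, 1), (0.096, 2)]
    ]


class TestPlaceOpmSites:
    def test_site_counts_span_reference_range(self, full_heads):
        counts = [len(place_opm_sites(h, seed=h.seed)[0]) for h in full_heads]
        assert all(71 <= c <= 93 for c in counts)
        assert counts[1] > counts[0]  # bigger head, more sensors

    def test_min_spacing_enforced(self, head, opm_sites):
        sites, _ = opm_sites
        assert pdist(sites).min() >= 0.015 - 1e-12

    def test_larger_footprint_reduces_count(self, head):
        small, _ = place_opm_sites(head, footprint=(0.010, 0.015), seed=1)
        large, _ = place_opm_sites(head, footprint=(0.020, 0.030), seed=1)
        assert len(large) < len(small)

    def test_deterministic_for_fixed_seed(self, head):
        a, _ = place_opm_sites(head, seed=9)
        b, _ = place_opm_sites(head, seed=9)
        assert np.array_equal(a, b)


class TestBuildOpmArray:
    def test_channel_count_is_sites_times_components(self, opm_sites, opm_all, opm_nor):
        sites, _ = opm_sites
        assert opm_all.n_channels == 3 * len(sites)
        assert opm_nor.n_channels == len(sites)

    def test_cell_centroid_at_standoff_above_site(self, opm_sites):
        sites, triads = opm_sites
        arr = build_opm_array(sites, triads, components=("NOR",))
        for ch, site, tri in zip(arr.channels, sites, triads):
            center = site + 0.0065 * tri.e_nor
            assert np.allclose(ch.points.mean(axis=0), center, atol=1e-12)
            assert np.allclose(ch.weights, 1 / 8)

    def test_all_integration_points_outside_scalp(self, head, opm_all):
        pts = np.concatenate([c.points for c in opm_all.channels])
        assert not head.scalp.contains(pts).any()

    def test_component_subsets_share_sites_and_ordering(self, opm_sites):
        sites, triads = opm_sites
        sub = build_opm_array(sites, triads, components=("NOR", "TAN-LAT"))
        full = build_opm_array(sites, triads)
        assert np.array_equal(sub.site_positions, full.site_positions)
        # site-major, component-minor: site index never decreases
        order = [c.site for c in full.channels]
        assert order == sorted(order)
        nor_sub = [c.label for c in sub.channels if c.label.endswith("NOR")]
        nor_full = [c.label for c in full.channels if c.label.endswith("NOR")]
        assert nor_sub == nor_full

    def test_empty_components_rejected(self, opm_sites):
        sites, triads = opm_sites
        with pytest.raises(ValueError):
            build_opm_array(sites, triads, components=())


class TestBuildSquidArrays:
    def test_gradiometer_layout(self, squid_arrays):
        grad = squid_arrays["SQUID-AXI-GRAD"]
        assert grad.n_channels == 125
        for ch in grad.channels:
            assert len(ch.points) == 8
            assert np.allclose(ch.weights, 1 / 4)
            assert np.array_equal(np.sign(ch.coil_signs), np.r_[np.ones(4), -np.ones(4)])

    def test_gradiometer_rejects_uniform_field(self, squid_arrays):
        grad = squid_arrays["SQUID-AXI-GRAD"]
        b = np.array([3e-12, -1e-12, 2e-12])
        for ch in grad.channels[::25]:
            resp = ch.signed_weights @ (np.tile(b, (8, 1)) @ ch.orientation)
            assert abs(resp) < 1e-25

    def test_magnetometer_equals_proximal_coil_term(self, head, squid_arrays):
        from megsim import Dipole, channel_response

        dip = Dipole([0.02, 0.01, 0.05], [5e-8, -3e-8, 0.0])
        grad = squid_arrays["SQUID-AXI-GRAD"]
        nor = squid_arrays["SQUID-NOR"]
        for k in (0, 40, 90):
            g, m = grad.channels[k], nor.channels[k]
            prox = m.weights @ (
                np.array(
                    [
                        channel_response(
                            type(m)(
                                kind=m.kind,
                                points=p[None, :],
                                weights=np.ones(1),
                                orientation=m.orientation,
                                label="pt",
                            ),
                            dip,
                            head.sphere_center,
                        )
                        for p in m.points
                    ]
                )
            )
            assert channel_response(m, dip, head.sphere_center) == pytest.approx(prox, rel=1e-12)
            # proximal term of the gradiometer = the NOR magnetometer reading
            prox_term = g.weights[:4] @ np.array(
                [
                    channel_response(
                        type(g)(
                            kind="squid_magnetometer",
                            points=p[None, :],
                            weights=np.ones(1),
                            orientation=g.orientation,
                            label="pt",
                        ),
                        dip,
                        head.sphere_center,
                    )
                    for p in g.points[:4]
                ]
            )
            assert prox_term == pytest.approx(
                channel_response(m, dip, head.sphere_center), rel=1e-12
            )

    def test_shared_sites_across_layouts(self, squid_arrays):
        ref = squid_arrays["SQUID-AXI-GRAD"].site_positions
        for name in ("SQUID-NOR", "SQUID-TAN-LAT", "SQUID-TAN-LON"):
            assert np.array_equal(squid_arrays[name].site_positions, ref)

    def test_coil_clearance(self, squid_arrays):
        sites = squid_arrays["SQUID-AXI-GRAD"].site_positions
        assert pdist(sites).min() >= 2 * 0.00775 - 1e-12


class TestRemoveSensors:
    def test_zero_fraction_is_identity(self, opm_all):
        assert remove_sensors(opm_all, 0.0) is opm_all

    def test_site_level_removal_arithmetic(self, opm_all):
        n = opm_all.n_sites
        thinned = remove_sensors(opm_all, 0.5, seed=1)
        assert thinned.n_sites == round(0.5 * n)
        assert thinned.n_channels == 3 * thinned.n_sites
        # all components of a retained site survive together
        per_site = {}
        for c in thinned.channels:
            per_site.setdefault(c.site, []).append(c.label)
        assert all(len(v) == 3 for v in per_site.values())

    def test_fraction_leaving_too_few_sites_rejected(self, opm_all):
        with pytest.raises(ValueError):
            remove_sensors(opm_all, 0.99, seed=0)

    def test_farthest_point_retention_beats_random_subsampling(self, opm_all):
        n_keep = round(0.25 * opm_all.n_sites)
        rng = np.random.default_rng(0)
        wins = 0
        for trial in range(20):
            kept = remove_sensors(opm_all, 0.75, seed=trial).site_positions
            rand = opm_all.site_positions[
                rng.choice(opm_all.n_sites, size=n_keep, replace=False)
            ]
            if pdist(kept).min() >= pdist(rand).min():
                wins += 1
        assert wins == 20


class TestTabularRoundTrip:
    @pytest.mark.parametrize("which", ["opm", "squid"])
    def test_lossless(self, opm_all, squid_arrays, which):
        arr = opm_all if which == "opm" else squid_arrays["SQUID-AXI-GRAD"]
        back = array_from_frame(array_to_frame(arr))
        assert back.n_channels == arr.n_channels
        assert back.configuration == arr.configuration
        for a, b in zip(arr.channels, back.channels):
            assert np.allclose(a.points, b.points, atol=0)
            assert np.allclose(a.signed_weights, b.signed_weights, atol=0)
            assert np.allclose(a.orientation, b.orientation, atol=0)
            assert a.label == b.label
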