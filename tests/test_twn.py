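"""TIP3P pair energies, hydrogen-bond graphs and ring detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import ideal_hbond_pair, make_water, random_frame, random_water
from oracles import (
    brute_force_frame_triangles,
    brute_force_triangles,
    tip3p_reference_energy,
)
import networkx as nx

from twn_rencod import (
    Tip3pParams,
    ValidationError,
    WaterFrame,
    detect_twns,
    find_three_rings,
    hbond_graph,
    pair_interaction_energy,
)

PARAMS = Tip3pParams()


def frame_from_waters(waters, box=None, frame_index=0):
    sites = np.stack(waters)
    return WaterFrame(frame_index, sites[:, 0], sites[:, 1:], box=box)


class TestPairInteractionEnergy:
    def test_matches_term_by_term_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            a, b = random_water(rng), random_water(rng)
            expected = tip3p_reference_energy(a, b)
            assert pair_interaction_energy(a, b, PARAMS) == pytest.approx(
                expected, rel=1e-12
            )

    def test_symmetric_in_arguments(self, rng):
        for _ in range(100):
            a, b = random_water(rng), random_water(rng)
            assert pair_interaction_energy(a, b, PARAMS) == pytest.approx(
                pair_interaction_energy(b, a, PARAMS), rel=1e-14
            )

    def test_ideal_hbond_dimer_clears_criterion(self):
        donor, acceptor = ideal_hbond_pair(r_oo=2.8)
        v = pair_interaction_energy(donor, acceptor, PARAMS)
        assert v == pytest.approx(tip3p_reference_energy(donor, acceptor), rel=1e-12)
        assert v <= PARAMS.hbond_criterion

    def test_vanishes_at_large_separation(self, rng):
        a = random_water(rng, oxygen=np.zeros(3))
        b = random_water(rng, oxygen=np.array([100.0, 0, 0]))
        assert abs(pair_interaction_energy(a, b, PARAMS)) < 0.01

    def test_coincident_oxygens_rejected(self, rng):
        a = random_water(rng, oxygen=np.zeros(3))
        b = random_water(rng, oxygen=np.zeros(3))
        with pytest.raises(ValidationError, match="oxygen"):
            pair_interaction_energy(a, b, PARAMS)

    def test_minimum_image_equals_unwrapped_nearest_copy(self, rng):
        # a pair straddling the boundary of a 20 A box: wrapped coordinates
        # with the box must give the unwrapped nearest-image energy
        box = np.array([20.0, 20.0, 20.0])
        a = random_water(rng, oxygen=np.array([0.5, 10.0, 10.0]))
        b_unwrapped = random_water(rng, oxygen=np.array([-2.3, 10.0, 10.0]))
        b_wrapped = b_unwrapped + np.array([20.0, 0.0, 0.0])
        v_box = pair_interaction_energy(a, b_wrapped, PARAMS, box=box)
        v_ref = pair_interaction_energy(a, b_unwrapped, PARAMS)
        assert v_box == pytest.approx(v_ref, rel=1e-12)
        assert v_box == pytest.approx(
            tip3p_reference_energy(a, b_wrapped, box=box), rel=1e-12
        )

    def test_invariant_under_rigid_motion(self, rng):
        a, b = random_water(rng), random_water(rng)
        v0 = pair_interaction_energy(a, b, PARAMS)
        # random rotation via QR, plus a translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-50, 50, size=3)
        assert pair_interaction_energy(a @ q.T + t, b @ q.T + t, PARAMS) == pytest.approx(
            v0, rel=1e-9
        )


class TestTip3pParams:
    def test_non_neutral_charges_rejected(self):
        with pytest.raises(ValidationError, match="neutral"):
            Tip3pParams(q_o=-0.8, q_h=0.417)

    def test_positive_criterion_rejected(self):
        with pytest.raises(ValidationError):
            Tip3pParams(hbond_criterion=1.0)


class TestHbondGraph:
    @pytest.mark.parametrize("n_waters", [0, 1])
    def test_tiny_frames_have_no_edges(self, rng, n_waters):
        frame = random_frame(rng, n_waters, box_edge=10.0)
        assert hbond_graph(frame, PARAMS).number_of_edges() == 0

    def test_ideal_pair_gives_one_edge(self):
        frame = frame_from_waters(ideal_hbond_pair())
        g = hbond_graph(frame, PARAMS)
        assert set(g.edges) == {(0, 1)}
        assert g.edges[0, 1]["energy"] <= PARAMS.hbond_criterion

    def test_six_angstrom_pair_gives_no_edge(self):
        donor, acceptor = ideal_hbond_pair(r_oo=6.0)
        frame = frame_from_waters([donor, acceptor])
        assert hbond_graph(frame, PARAMS.without_prescreen()).number_of_edges() == 0

    def test_borderline_energy_toggles_exactly_that_edge(self):
        # scale the dimer separation to bracket the criterion, then nudge
        donor, acceptor = ideal_hbond_pair(r_oo=2.8)

        def energy_at(r_oo):
            return tip3p_reference_energy(*ideal_hbond_pair(r_oo=r_oo))

        lo, hi = 2.8, 6.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if energy_at(mid) <= PARAMS.hbond_criterion:
                lo = mid
            else:
                hi = mid
        eps = 1e-4
        bonded = frame_from_waters(ideal_hbond_pair(r_oo=lo - eps))
        unbonded = frame_from_waters(ideal_hbond_pair(r_oo=hi + eps))
        assert energy_at(lo - eps) <= PARAMS.hbond_criterion
        assert energy_at(hi + eps) > PARAMS.hbond_criterion
        assert hbond_graph(bonded, PARAMS).number_of_edges() == 1
        assert hbond_graph(unbonded, PARAMS).number_of_edges() == 0


class TestFindThreeRings:
    def test_triangle_graph(self):
        g = nx.cycle_graph(3)
        assert find_three_rings(g) == [(0, 1, 2)]

    def test_complete_graph_on_four_vertices(self):
        assert len(find_three_rings(nx.complete_graph(4))) == 4

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 41))
            g = nx.gnp_random_graph(n, rng.uniform(0.05, 0.5),
                                    seed=int(rng.integers(2**31)))
            assert find_three_rings(g) == sorted(
                brute_force_triangles(n, set(g.edges))
            )


class TestDetectTwns:
    def test_centroid_is_mean_of_oxygens(self, rng):
        # oxygens on a 3-4-5 right triangle with cyclic donor orientations
        # (attractive pairs); a permissive criterion makes all three count
        # so the centroid arithmetic is exercised
        vertices = [np.array(o, float) for o in [(0, 0, 0), (3.0, 0, 0), (0, 3.0, 0)]]
        waters = []
        for k, o in enumerate(vertices):
            to_next = vertices[(k + 1) % 3] - o
            perp = np.cross(to_next, [0.0, 0.0, 1.0])
            hoh = np.radians(104.52)
            d2 = np.cos(hoh) * to_next / np.linalg.norm(to_next) + np.sin(hoh) * perp / np.linalg.norm(perp)
            waters.append(make_water(o, to_next, d2))
        params = Tip3pParams(hbond_criterion=-1e-6, oo_prescreen_cutoff=0.0)
        rings = detect_twns(frame_from_waters(waters), params)
        assert len(rings) == 1
        assert rings[0].water_indices == (0, 1, 2)
        np.testing.assert_allclose(rings[0].centroid, [1.0, 1.0, 0.0], atol=1e-12)

    def test_chain_without_cycle_yields_no_ring(self):
        # four waters in a line, each H-bonded to the next only
        waters = []
        for k in range(4):
            donor = make_water(
                (2.8 * k, 0, 0), (1, 0, 0),
                (np.cos(np.radians(104.52)), np.sin(np.radians(104.52)), 0),
            )
            waters.append(donor)
        rings = detect_twns(frame_from_waters(waters), PARAMS)
        assert rings == []

    def test_prescreen_equals_no_prescreen_equals_brute_force(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 41))
            frame = random_frame(rng, n, box_edge=3.1 * n ** (1 / 3))
            with_pre = detect_twns(frame, PARAMS)
            without_pre = detect_twns(frame, PARAMS.without_prescreen())
            brute = brute_force_frame_triangles(
                frame.all_sites(), criterion=PARAMS.hbond_criterion
            )
            assert [r.water_indices for r in with_pre] == brute
            assert [r.water_indices for r in without_pre] == brute

    def test_energies_stored_on_rings_meet_criterion(self, rng):
        frame = random_frame(rng, 30, box_edge=9.0)
        for ring in detect_twns(frame, PARAMS):
            assert all(e <= PARAMS.hbond_criterion for e in ring.pair_energies)
            i, j, k = ring.water_indices
            assert ring.pair_energies[0] == pytest.approx(
                tip3p_reference_energy(frame.water_sites(i), frame.water_sites(j)),
                rel=1e-10,
            )

    def test_adding_a_water_never_removes_rings(self, rng):
        for _ in range(20):
            frame = random_frame(rng, 25, box_edge=9.0)
            before = {r.water_indices for r in detect_twns(frame, PARAMS)}
            extra = random_water(rng, oxygen=rng.uniform(0, 9.0, size=3))
            grown = frame_from_waters(
                list(frame.all_sites()) + [extra], frame_index=frame.frame_index
            )
            after = {r.water_indices for r in detect_twns(grown, PARAMS)}
            assert before <= after

    def test_rigid_motion_moves_centroids_and_preserves_energies(self, rng):
        frame = random_frame(rng, 20, box_edge=8.0)
        rings = detect_twns(frame, PARAMS)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = np.array([5.0, -3.0, 11.0])
        moved_sites = frame.all_sites() @ q.T + t
        moved = frame_from_waters(list(moved_sites))
        moved_rings = detect_twns(moved, PARAMS)
        assert [r.water_indices for r in rings] == [r.water_indices for r in moved_rings]
        for r0, r1 in zip(rings, moved_rings):
            np.testing.assert_allclose(r1.centroid, r0.centroid @ q.T + t, atol=1e-8)
            np.testing.assert_allclose(r1.pair_energies, r0.pair_energies, rtol=1e-9)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_energy_symmetry_property(seed):
    """v(a, b) = v(b, a) for arbitrary random configurations."""
    local = np.random.default_rng(seed)
    a, b = random_water(local), random_water(local)
    assert pair_interaction_energy(a, b, PARAMS) == pytest.approx(
        pair_interaction_energy(b, a, PARAMS), rel=1e-14
    )
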