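"""Connectivity index: hand values, invariants and the brute-force oracle."""

import math

import numpy as np
import pytest

from meadowmrr.connectivity import (
    ConnectivityParams,
    connectivity,
    pairwise_patch_distance_km,
)
from meadowmrr.simulate import SimConfig, generate_patches


def brute_force_connectivity(patches, params, D):
    """Naive double loop, independent of the vectorized implementation."""
    out = []
    for j in range(len(patches)):
        s = 0.0
        for k in range(len(patches)):
            if k == j or D[j, k] > params.buffer_km:
                continue
            s += math.exp(-params.alpha * D[j, k]) * patches[k].area_m2**params.xi
        out.append(s)
    return np.array(out)


class TestDistances:
    def test_single_patch_zero_matrix(self, toy_patches):
        D = pairwise_patch_distance_km(toy_patches[:1])
        assert D.shape == (1, 1) and D[0, 0] == 0.0

    def test_centroids_one_km_apart(self, toy_patches):
        D = pairwise_patch_distance_km(toy_patches[:2], mode="centroid")
        assert D[0, 1] == pytest.approx(1.0, rel=1e-3)

    def test_symmetric_zero_diagonal(self, toy_patches):
        D = pairwise_patch_distance_km(toy_patches)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_edge_distance_shorter_than_centroid(self, toy_patches):
        Dc = pairwise_patch_distance_km(toy_patches[:2], mode="centroid")
        De = pairwise_patch_distance_km(toy_patches[:2], mode="edge")
        # two 100 m squares, centroids 1 km apart -> edges 900 m apart
        assert De[0, 1] == pytest.approx(0.9, rel=1e-3)
        assert De[0, 1] < Dc[0, 1]


class TestConnectivity:
    def test_isolated_patch_is_zero(self, toy_patches):
        params = ConnectivityParams(alpha=1.0, buffer_km=0.5)
        res = connectivity(toy_patches[:2], params)
        assert all(r.s_j == 0.0 and r.n_neighbours == 0 for r in res)

    def test_single_neighbour_hand_value(self, toy_patches):
        # one neighbour at 1 km with A=10,000 m^2, alpha=1, xi=0.5:
        # S = exp(-1) * 100
        params = ConnectivityParams(alpha=1.0, xi=0.5)
        res = connectivity(toy_patches[:2], params)
        assert res[0].s_j == pytest.approx(math.exp(-1.0) * 100.0, rel=1e-3)

    def test_xi_zero_drops_area_weighting(self, toy_patches):
        params = ConnectivityParams(alpha=2.0, xi=0.0)
        D = pairwise_patch_distance_km(toy_patches[:2])
        res = connectivity(toy_patches[:2], params, D)
        assert res[0].s_j == pytest.approx(math.exp(-2.0 * D[0, 1]), rel=1e-9)

    def test_monotone_in_alpha_and_neighbours(self, toy_patches):
        D = pairwise_patch_distance_km(toy_patches)
        weak = connectivity(toy_patches, ConnectivityParams(alpha=3.0), D)
        strong = connectivity(toy_patches, ConnectivityParams(alpha=1.0), D)
        for w, s in zip(weak, strong):
            assert s.s_j >= w.s_j
        # removing a patch never increases the others' connectivity
        D2 = pairwise_patch_distance_km(toy_patches[:2])
        fewer = connectivity(toy_patches[:2], ConnectivityParams(alpha=1.0), D2)
        assert fewer[0].s_j <= strong[0].s_j

    def test_area_doubling_scales_by_two_to_the_xi(self, proj, toy_patches):
        import dataclasses

        from tests.conftest import make_square

        centres = [(0.0, 0.0), (1000.0, 0.0), (250.0, 400.0)]
        side = 100.0 * math.sqrt(2.0)  # doubles every area
        doubled_patches = [
            dataclasses.replace(
                p,
                area_m2=2.0 * p.area_m2,
                polygon=make_square(cx, cy, side, proj),
            )
            for p, (cx, cy) in zip(toy_patches, centres)
        ]
        D = pairwise_patch_distance_km(toy_patches)
        for xi in (0.0, 0.5, 1.0):
            params = ConnectivityParams(alpha=1.0, xi=xi)
            base = connectivity(toy_patches, params, D)
            # same distance matrix: only the areas change
            doubled = connectivity(doubled_patches, params, D)
            for b, d in zip(base, doubled):
                assert d.s_j == pytest.approx(2**xi * b.s_j, rel=1e-9)

    def test_matches_brute_force_on_random_networks(self):
        for seed in (1, 2):
            cfg = SimConfig(seed=seed, n_patches=40)
            patches, _ = generate_patches(cfg)
            params = ConnectivityParams(alpha=5.0, xi=0.5, buffer_km=3.0)
            D = pairwise_patch_distance_km(patches)
            fast = np.array([r.s_j for r in connectivity(patches, params, D)])
            slow = brute_force_connectivity(patches, params, D)
            assert np.max(np.abs(fast - slow)) < 1e-10


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ConnectivityParams(alpha=0.0)
    with pytest.raises(ValueError):
        ConnectivityParams(alpha=1.0, xi=1.5)
    with pytest.raises(ValueError):
        ConnectivityParams(alpha=1.0, distance_mode="midpoint")
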