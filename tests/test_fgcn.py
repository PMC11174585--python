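"""Frequency-GCN layer operations against independent brute-force oracles."""

import numpy as np
import pytest

from gaitfreq import (
    FeatureMap,
    FGCNParams,
    SpectralTensor,
    TCNBaselineParams,
    apply_spectral_weights,
    build_skeleton_graph,
    fgcn_layer_forward,
    from_frequency,
    spatial_aggregate,
    tcn_baseline_forward,
    to_frequency,
)
from gaitfreq.fgcn import edge_weight_length, spectral_factors

from conftest import random_graph

RNG = np.random.default_rng(7)


def leaky(x, slope=0.01):
    return np.where(x >= 0, x, slope * x)


def aggregate_oracle(x, graph, weights, slope=0.01):
    """Explicit edge-loop implementation of the spatial aggregation."""
    c, t, v = x.shape
    out = np.zeros_like(x)
    n_bones = len(graph.edges)
    for i in range(v):
        acc = np.zeros((c, t))
        for k, (a, b) in enumerate(graph.edges):
            if a == i:
                acc += weights[k] * x[:, :, b]
            elif b == i:
                acc += weights[k] * x[:, :, a]
        acc += weights[n_bones + i] * x[:, :, i]
        out[:, :, i] = leaky(acc / graph.degrees[i], slope)
    return out


def dft2_oracle(xs):
    """O(N^2) direct 2D DFT with orthonormal scaling, temporal half-spectrum."""
    s, t = xs.shape
    f = t // 2 + 1
    out = np.zeros((s, f), dtype=complex)
    for ks in range(s):
        for kt in range(f):
            acc = 0.0j
            for a in range(s):
                for b in range(t):
                    acc += xs[a, b] * np.exp(-2j * np.pi * (ks * a / s + kt * b / t))
            out[ks, kt] = acc / np.sqrt(s * t)
    return out


class TestSpatialAggregate:
    def test_hand_computed_two_node_average(self):
        g = build_skeleton_graph([(0, 1)], 2)
        params = FGCNParams.identity(g, 1, 2)
        x = FeatureMap(np.array([[[2.0, 4.0], [2.0, 4.0]]]))  # joints hold 2 and 4
        out = spatial_aggregate(x, g, params)
        assert np.allclose(out.values[:, :, 0], 3.0)

    def test_zero_input_fixed_point(self, kinect_graph):
        params = FGCNParams.identity(kinect_graph, 2, 4)
        out = spatial_aggregate(FeatureMap(np.zeros((2, 4, 25))), kinect_graph, params)
        assert np.all(out.values == 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_edge_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, int(rng.integers(2, 6)))
        weights = rng.normal(size=edge_weight_length(g))
        params = FGCNParams(
            edge_weights=weights,
            spatial_mask=np.ones(2 * g.n_joints),
            temporal_mask=np.ones(3),
        )
        x = FeatureMap(rng.normal(size=(2, 4, g.n_joints)))
        out = spatial_aggregate(x, g, params)
        assert np.abs(out.values - aggregate_oracle(x.values, g, weights)).max() < 1e-12

    def test_shape_mismatch_rejected(self, kinect_graph):
        params = FGCNParams.identity(kinect_graph, 1, 4)
        with pytest.raises(ValueError):
            spatial_aggregate(FeatureMap(np.zeros((1, 4, 17))), kinect_graph, params)


class TestFourierTransforms:
    def test_constant_input_is_dc_only(self):
        c = 1.7
        x = FeatureMap(np.full((2, 8, 3), c))
        xf = to_frequency(x)
        s, t = 6, 8
        assert np.isclose(abs(xf.coeffs[0, 0]), c * np.sqrt(s * t))
        rest = np.abs(xf.coeffs).sum() - abs(xf.coeffs[0, 0])
        assert rest < 1e-9

    def test_pure_cosine_lands_in_its_bin(self):
        t, k = 32, 5
        wave = np.cos(2 * np.pi * k * np.arange(t) / t)
        x = FeatureMap(np.tile(wave[None, :, None], (1, 1, 4)))
        xf = to_frequency(x)
        mags = np.abs(xf.coeffs)
        temporal_energy = (mags**2).sum(axis=0)
        assert temporal_energy[k] > 0.99 * temporal_energy.sum()

    @pytest.mark.parametrize("shape", [(1, 5, 3), (2, 8, 4), (1, 7, 8)])
    def test_matches_naive_dft_oracle(self, shape):
        x = FeatureMap(RNG.normal(size=shape))
        xf = to_frequency(x)
        c, t, v = shape
        xs = x.values.transpose(0, 2, 1).reshape(c * v, t)
        assert np.abs(xf.coeffs - dft2_oracle(xs)).max() < 1e-10

    def test_round_trip_identity(self):
        x = FeatureMap(RNG.normal(size=(3, 31, 7)))
        back = from_frequency(to_frequency(x), x.shape)
        assert np.abs(back.values - x.values).max() < 1e-6

    def test_zero_spectrum_gives_zero_signal(self):
        xf = SpectralTensor(np.zeros((6, 5), dtype=complex), source_T=8)
        out = from_frequency(xf, (2, 8, 3))
        assert np.all(out.values == 0)

    def test_parseval_energy_equality(self):
        x = FeatureMap(RNG.normal(size=(2, 30, 5)))
        xf = to_frequency(x)
        dup = np.full(16, 2.0)
        dup[0] = dup[-1] = 1.0  # T = 30: DC and Nyquist bins are unpaired
        spec = ((np.abs(xf.coeffs) ** 2) * dup[None, :]).sum()
        time = (x.values**2).sum()
        assert abs(spec - time) / time < 1e-10

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            FeatureMap(np.array([[[np.nan]] * 2]))

    def test_inconsistent_inverse_shape_rejected(self):
        xf = to_frequency(FeatureMap(RNG.normal(size=(2, 8, 3))))
        with pytest.raises(ValueError):
            from_frequency(xf, (2, 8, 4))


class TestSpectralWeighting:
    def test_identity_masks_preserve_spectrum(self, kinect_graph):
        params = FGCNParams.identity(kinect_graph, 2, 16)
        x = FeatureMap(RNG.normal(size=(2, 16, 25)))
        xf = to_frequency(x)
        out = apply_spectral_weights(xf, params, kinect_graph)
        assert np.allclose(out.coeffs, xf.coeffs)

    def test_dc_only_temporal_mask_gives_temporal_mean(self, kinect_graph):
        params = FGCNParams.identity(kinect_graph, 1, 16)
        params.temporal_mask = np.zeros(9)
        params.temporal_mask[0] = 1.0
        x = FeatureMap(RNG.normal(size=(1, 16, 25)))
        out = from_frequency(
            apply_spectral_weights(to_frequency(x), params, kinect_graph), x.shape
        )
        expected = np.broadcast_to(x.values.mean(axis=1, keepdims=True), x.shape)
        assert np.abs(out.values - expected).max() < 1e-9

    def test_random_masks_match_scalar_loop_oracle(self, kinect_graph):
        c, t = 2, 12
        s, f = c * 25, 7
        params = FGCNParams(
            edge_weights=RNG.normal(size=edge_weight_length(kinect_graph)),
            spatial_mask=RNG.normal(size=s),
            temporal_mask=RNG.normal(size=f),
        )
        x = FeatureMap(RNG.normal(size=(c, t, 25)))
        xf = to_frequency(x)
        out = apply_spectral_weights(xf, params, kinect_graph)
        # scalar re-derivation of the documented factor formula
        edge_mean = leaky(params.edge_weights).mean()
        expected = np.empty_like(xf.coeffs)
        for si in range(s):
            mirrored = (s - si) % s
            a = 0.5 * (
                leaky(edge_mean * params.spatial_mask[si])
                + leaky(edge_mean * params.spatial_mask[mirrored])
            )
            for ti in range(f):
                b = leaky(params.temporal_mask[ti])
                expected[si, ti] = a * b * xf.coeffs[si, ti]
        assert np.abs(out.coeffs - expected).max() < 1e-12

    def test_mask_length_mismatch_rejected(self, kinect_graph):
        params = FGCNParams.identity(kinect_graph, 2, 16)
        xf = to_frequency(FeatureMap(RNG.normal(size=(3, 16, 25))))
        with pytest.raises(ValueError):
            apply_spectral_weights(xf, params, kinect_graph)


class TestLayerForward:
    def test_identity_configuration_reduces_to_activation(self):
        g = build_skeleton_graph([], 1)  # single joint, self-loop only
        params = FGCNParams.identity(g, 2, 16)
        x = FeatureMap(RNG.normal(size=(2, 16, 1)))
        out = fgcn_layer_forward(x, g, params)
        assert np.abs(out.values - leaky(x.values)).max() < 1e-9

    def test_circular_shift_equivariance(self, kinect_graph):
        params = FGCNParams(
            edge_weights=np.abs(RNG.normal(size=edge_weight_length(kinect_graph))),
            spatial_mask=RNG.normal(size=2 * 25),
            temporal_mask=RNG.normal(size=9),
        )
        x = FeatureMap(RNG.normal(size=(2, 16, 25)))
        shift = 5
        out = fgcn_layer_forward(x, kinect_graph, params)
        out_shifted = fgcn_layer_forward(
            FeatureMap(np.roll(x.values, shift, axis=1)), kinect_graph, params
        )
        assert np.abs(out_shifted.values - np.roll(out.values, shift, axis=1)).max() < 1e-9


class TestTCNBaseline:
    def test_unit_window_self_loop_identity(self):
        g = build_skeleton_graph([], 1)
        x = FeatureMap(RNG.normal(size=(2, 8, 1)))
        out = tcn_baseline_forward(x, g, TCNBaselineParams(np.ones((2, 1))))
        assert np.allclose(out.values, x.values)

    def test_constant_input_interior_frames(self):
        # middle node of a 3-path: degree 3 (two bones + self-loop)
        g = build_skeleton_graph([(0, 1), (1, 2)], 3)
        c = 0.5
        x = FeatureMap(np.full((1, 10, 3), c))
        out = tcn_baseline_forward(x, g, TCNBaselineParams(np.ones((1, 3))))
        interior = out.values[0, : 10 - 3 + 1, 1]
        assert np.allclose(interior, 3 * 3 * c)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, int(rng.integers(2, 6)))
        c, t, sd = 2, 7, 3
        kernel = rng.normal(size=(c, sd))
        x = FeatureMap(rng.normal(size=(c, t, g.n_joints)))
        out = tcn_baseline_forward(x, g, TCNBaselineParams(kernel))
        expected = np.zeros_like(x.values)
        for i in range(g.n_joints):
            neigh = [j for j in range(g.n_joints) if g.adjacency[i, j]]
            for ch in range(c):
                for tt in range(t):
                    acc = 0.0
                    for j in neigh:
                        for tau in range(sd):
                            if tt + tau < t:
                                acc += kernel[ch, tau] * x.values[ch, tt + tau, j]
                    expected[ch, tt, i] = acc
        assert np.abs(out.values - expected).max() < 1e-12

    def test_oversized_window_rejected(self, kinect_graph):
        x = FeatureMap(RNG.normal(size=(1, 4, 25)))
        with pytest.raises(ValueError):
            tcn_baseline_forward(x, kinect_graph, TCNBaselineParams(np.ones((1, 5))))


def test_spectral_factors_identity_at_init(kinect_graph):
    """Unit-initialized parameters make the layer's filter an exact identity."""
    params = FGCNParams.identity(kinect_graph, 2, 16)
    a_sym, b = spectral_factors(params, 50, 9)
    assert np.allclose(a_sym, 1.0) and np.allclose(b, 1.0)
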