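"""Pyramid assembly: fusion, ablation reductions, loss, and symmetries."""

import numpy as np
import pytest

from gaitfreq import (
    FeatureMap,
    FGCNParams,
    FPGCN,
    FusionParams,
    ModelConfig,
    TCNClassifier,
    build_skeleton_graph,
    cross_domain_fuse,
    fgcn_layer_forward,
    label_smoothed_loss,
    load_checkpoint,
    load_layout,
    pathway_graph,
    save_checkpoint,
)
from gaitfreq import autodiff as ad
from gaitfreq.graphs import PartitionScheme

RNG = np.random.default_rng(11)


def tiny_config(**kw):
    defaults = dict(
        num_classes=2, layout="kinect25", in_channels=2, frames=8,
        depth=1, widths=(4, 3, 2), dtype="float64",
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def tiny_graph_setup():
    """A 4-joint chain with a hand-made three-scale partition."""
    g = build_skeleton_graph([(0, 1), (1, 2), (2, 3)], 4)
    part = PartitionScheme(
        pathways=(
            (0, ((0, 1, 2, 3),)),
            (1, ((0, 1), (1, 2, 3))),
            (2, ((0,), (1, 2), (3,))),
        ),
        n_joints=4,
    )
    return g, part


class TestPathwayGraph:
    def test_global_pathway_keeps_all_bones(self, kinect_graph, kinect_partition):
        pg = pathway_graph(kinect_graph, kinect_partition.subsets(0))
        assert pg.edges == kinect_graph.edges

    def test_limb_pathway_cuts_cross_subset_bones(self, kinect_graph, kinect_partition):
        pg = pathway_graph(kinect_graph, kinect_partition.subsets(2))
        # bones bridging subsets (e.g. shoulder-to-spine) are masked out
        assert len(pg.edges) < len(kinect_graph.edges)
        assert pg.n_joints == 25
        assert np.all(pg.degrees >= 1)

    def test_subset_order_irrelevant(self, kinect_graph, kinect_partition):
        subsets = kinect_partition.subsets(2)
        a = pathway_graph(kinect_graph, subsets)
        b = pathway_graph(kinect_graph, tuple(reversed(subsets)))
        assert np.array_equal(a.adjacency, b.adjacency)


class TestCrossDomainFuse:
    def test_concatenated_width_is_sum(self):
        fine = RNG.normal(size=(2, 4, 6, 5))
        coarse = RNG.normal(size=(2, 7, 6, 5))
        params = FusionParams.passthrough(4, 7)
        out = cross_domain_fuse(fine, coarse, params)
        assert out.shape == (2, 4, 6, 5)
        assert params.w_proj.shape == (4, 4 + 7)

    def test_zero_coarse_with_passthrough_is_identity(self):
        fine = RNG.normal(size=(2, 4, 6, 5))
        coarse = np.zeros((2, 7, 6, 5))
        out = cross_domain_fuse(fine, coarse, FusionParams.passthrough(4, 7))
        assert np.abs(out.data - fine).max() < 1e-12

    def test_matches_concat_project_loop_oracle(self):
        fine = RNG.normal(size=(1, 3, 2, 2))
        coarse = RNG.normal(size=(1, 2, 2, 2))
        params = FusionParams(
            w_fine=ad.Tensor(RNG.normal(size=(3, 3))),
            w_coarse=ad.Tensor(RNG.normal(size=(2, 2))),
            w_proj=ad.Tensor(RNG.normal(size=(3, 5))),
            b_proj=ad.Tensor(RNG.normal(size=(3,))),
        )
        out = cross_domain_fuse(fine, coarse, params).data
        expected = np.zeros((1, 3, 2, 2))
        for v in range(2):
            for t in range(2):
                a = params.w_fine.data @ fine[0, :, v, t]
                b = params.w_coarse.data @ coarse[0, :, v, t]
                cat = np.concatenate([a, b])
                expected[0, :, v, t] = params.w_proj.data @ cat + params.b_proj.data
        assert np.abs(out - expected).max() < 1e-12

    def test_mismatched_joint_axes_rejected(self):
        with pytest.raises(ValueError):
            cross_domain_fuse(
                np.zeros((1, 3, 2, 4)), np.zeros((1, 2, 3, 4)),
                FusionParams.passthrough(3, 2),
            )


class TestForward:
    def test_global_pathway_preserves_joint_dimension(self):
        model = FPGCN(tiny_config(in_channels=3, frames=16, num_classes=3))
        x = RNG.normal(size=(2, 3, 16, 25))
        feat = model.pathway_forward(x, 0)
        assert feat.pathway_id == 0 and feat.width == 4
        assert feat.values.shape == (2, 4, 16, 25)

    def test_zero_input_zero_pathway_output(self):
        model = FPGCN(tiny_config(in_channels=3, frames=16))
        for ph in range(3):
            feat = model.pathway_forward(np.zeros((1, 3, 16, 25)), ph)
            assert np.all(feat.values == 0)

    def test_single_identity_layer_is_relu_of_aggregate(self):
        g, part = tiny_graph_setup()
        cfg = tiny_config(in_channels=2, frames=8, widths=(2, 2, 2))
        model = FPGCN(cfg, graph=g, partition=part)
        model.params["lift_w_0"].data = np.eye(2)
        x = RNG.normal(size=(2, 8, 4))
        feat = model.pathway_forward(x, 0).values[0]
        params = FGCNParams.identity(g, 2, 8, slope=cfg.slope)
        expected = np.maximum(fgcn_layer_forward(FeatureMap(x), g, params).values, 0)
        assert np.abs(feat - expected).max() < 1e-9

    def test_zero_head_gives_zero_scores(self):
        model = FPGCN(tiny_config(in_channels=3, frames=16))
        model.params["head_w"].data[:] = 0
        model.params["head_b"].data[:] = 0
        scores = model.forward(RNG.normal(size=(3, 3, 16, 25)))
        assert np.all(scores.data == 0)

    def test_batch_permutation_equivariance(self):
        model = FPGCN(tiny_config(in_channels=3, frames=16))
        x = RNG.normal(size=(5, 3, 16, 25))
        perm = np.array([3, 0, 4, 1, 2])
        s1 = model.forward(x).data
        s2 = model.forward(x[perm]).data
        assert np.abs(s1[perm] - s2).max() < 1e-9

    def test_mirror_symmetric_model_gives_identical_scores(self):
        """With the lateral channel ignored and default symmetric weights, a
        mirrored walker must receive exactly the same class scores."""
        layout = load_layout("kinect25")
        model = FPGCN(tiny_config(in_channels=3, frames=16))
        for ph in range(3):  # make lifts blind to the lateral coordinate
            model.params[f"lift_w_{ph}"].data[:, layout.lateral_channel] = 0
        x = RNG.normal(size=(1, 3, 16, 25))
        perm = layout.mirror_permutation()
        x_mirror = x[:, :, :, perm].copy()
        x_mirror[:, layout.lateral_channel] *= -1
        s = model.forward(x).data
        s_m = model.forward(x_mirror).data
        assert np.abs(s - s_m).max() < 1e-9

    def test_frame_count_mismatch_rejected(self):
        model = FPGCN(tiny_config(frames=16, in_channels=3))
        with pytest.raises(ValueError):
            model.forward(RNG.normal(size=(1, 3, 8, 25)))


class TestAblationReductions:
    def test_fgcn_only_is_plain_stacked_classifier(self):
        """The single-pathway variant must equal a hand-composed stack of
        functional F-GCN layers + channel mixes + pooling + head."""
        g, part = tiny_graph_setup()
        cfg = tiny_config(in_channels=2, frames=8, widths=(2, 2, 2),
                          depth=2, ablation="fgcn_only")
        model = FPGCN(cfg, graph=g, partition=part)
        rng = np.random.default_rng(3)
        for i in range(2):
            model.params[f"edge_{0}_{i}"].data = rng.normal(size=7) ** 2
            model.params[f"amask_{0}_{i}"].data = rng.normal(size=8)
            model.params[f"tmask_{0}_{i}"].data = rng.normal(size=5)
        model.params["lift_w_0"].data = np.eye(2)
        x = rng.normal(size=(2, 8, 4))
        scores = model.forward(x).data[0]
        h = FeatureMap(x)
        for i in range(2):
            params = FGCNParams(
                edge_weights=model.params[f"edge_0_{i}"].data,
                spatial_mask=model.params[f"amask_0_{i}"].data,
                temporal_mask=model.params[f"tmask_0_{i}"].data,
                slope=cfg.slope,
            )
            h = FeatureMap(np.maximum(fgcn_layer_forward(h, g, params).values, 0))
        emb = h.values.mean(axis=(1, 2))
        expected = model.params["head_w"].data @ emb + model.params["head_b"].data
        assert np.abs(scores - expected).max() < 1e-9

    def test_pgcn_only_equals_pyramid_with_identity_masks(self):
        g, part = tiny_graph_setup()
        cfg_p = tiny_config(in_channels=2, frames=8, widths=(3, 3, 2),
                            ablation="pgcn_only")
        cfg_f = tiny_config(in_channels=2, frames=8, widths=(3, 3, 2),
                            ablation="fpgcn")
        pgcn = FPGCN(cfg_p, graph=g, partition=part)
        fpgcn = FPGCN(cfg_f, graph=g, partition=part)
        # identical shared parameters; spectral masks stay at their unit init
        for k, t in pgcn.params.items():
            fpgcn.params[k].data = t.data.copy()
        assert not any(k.startswith(("amask", "tmask")) for k in pgcn.params)
        x = RNG.normal(size=(2, 2, 8, 4))
        assert np.abs(pgcn.forward(x).data - fpgcn.forward(x).data).max() < 1e-9

    def test_variant_parameter_surgery_contract(self):
        fgcn = FPGCN(tiny_config(ablation="fgcn_only"))
        assert fgcn.active == [0]
        assert not any(k.startswith("fuse") for k in fgcn.params)
        pgcn = FPGCN(tiny_config(ablation="pgcn_only"))
        assert pgcn.active == [0, 1, 2]
        assert not pgcn.spectral


class TestLoss:
    def test_zero_epsilon_reduces_to_cross_entropy(self):
        scores = RNG.normal(size=(6, 4))
        labels = np.array([0, 1, 2, 3, 1, 2])
        loss = label_smoothed_loss(scores, labels, 0.0)
        z = scores - scores.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        assert np.isclose(loss, -logp[np.arange(6), labels].mean())

    def test_uniform_scores_give_log_k(self):
        for k, eps in [(3, 0.0), (5, 0.2), (9, 0.05)]:
            loss = label_smoothed_loss(np.zeros((4, k)), np.zeros(4, dtype=int), eps)
            assert np.isclose(loss, np.log(k))

    def test_hand_computed_smoothed_example(self):
        # K = 3, scores (2, 0, 0), label 0, eps = 0.1
        z = np.array([2.0, 0.0, 0.0])
        logp = z - np.log(np.exp(z).sum())
        expected = -(0.9 * logp[0] + 0.05 * logp[1] + 0.05 * logp[2])
        assert np.isclose(label_smoothed_loss(np.array([[2.0, 0, 0]]), [0], 0.1), expected)

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            label_smoothed_loss(np.zeros((1, 2)), [0], 1.0)

    def test_one_sgd_step_decreases_loss_on_separable_batch(self):
        model = FPGCN(tiny_config(in_channels=3, frames=16, num_classes=2))
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3, 16, 25))
        x[4:] += 2.0
        y = np.array([0] * 4 + [1] * 4)
        loss0 = model.loss(x, y, 0.1)
        assert float(loss0.data) >= 0
        loss0.backward()
        for p in model.params.values():
            if p.grad is not None:
                p.data = p.data - 0.05 * p.grad
        loss1 = model.loss(x, y, 0.1)
        assert float(loss1.data) < float(loss0.data)


class TestCheckpoints:
    def test_round_trip_fpgcn(self, tmp_path):
        model = FPGCN(tiny_config(in_channels=3, frames=16))
        path = tmp_path / "model.npz"
        save_checkpoint(path, model)
        clone = load_checkpoint(path)
        x = RNG.normal(size=(2, 3, 16, 25))
        assert np.allclose(model.forward(x).data, clone.forward(x).data)

    def test_round_trip_tcn(self, tmp_path):
        cfg = tiny_config(in_channels=3, frames=16, tcn_window=4)
        model = TCNClassifier(cfg)
        path = tmp_path / "tcn.npz"
        save_checkpoint(path, model)
        clone = load_checkpoint(path)
        x = RNG.normal(size=(2, 3, 16, 25))
        assert np.allclose(model.forward(x).data, clone.forward(x).data)
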