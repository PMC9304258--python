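import numpy as np
import pytest

from eedn import nn
from eedn.eedn_core import (
    EEDN,
    UDDN,
    ModelConfig,
    build_model,
    compose_output,
    denoise,
    laplacian_edge_map,
    load_checkpoint,
    save_checkpoint,
)
from eedn.image_io import ImageFrame
from eedn.phantom import default_template, generate_phantom


def brute_force_laplacian(arr):
    """Direct stencil convolution with replicate borders (the oracle)."""
    rows, cols = arr.shape
    out = np.zeros_like(arr, dtype=float)
    for r in range(rows):
        for c in range(cols):
            up = arr[max(r - 1, 0), c]
            down = arr[min(r + 1, rows - 1), c]
            left = arr[r, max(c - 1, 0)]
            right = arr[r, min(c + 1, cols - 1)]
            out[r, c] = up + down + left + right - 4 * arr[r, c]
    return out


MICRO = ModelConfig(
    n_udbs_total=2, n_udbs_denoiser=1, n_udbs_edge=1, udb_layers=2,
    growth_channels=4, base_channels=8,
)


class TestLaplacian:
    def test_constant_frame_maps_to_zero(self):
        np.testing.assert_array_equal(laplacian_edge_map(np.full((5, 7), 9.0)), 0.0)

    def test_linear_ramp_has_zero_interior(self):
        yy, xx = np.mgrid[0:8, 0:8]
        lap = laplacian_edge_map(3.0 * xx + 2.0 * yy)
        np.testing.assert_allclose(lap[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_unit_impulse_reproduces_stencil(self):
        frame = np.zeros((5, 5))
        frame[2, 2] = 1.0
        lap = laplacian_edge_map(frame)
        expected = np.zeros((5, 5))
        expected[2, 2] = -4.0
        expected[1, 2] = expected[3, 2] = expected[2, 1] = expected[2, 3] = 1.0
        np.testing.assert_array_equal(lap[1:-1, 1:-1], expected[1:-1, 1:-1])

    def test_matches_brute_force_oracle_on_random_rasters(self, rng):
        for _ in range(50):
            arr = rng.normal(size=(16, 16)) * 100
            lap = laplacian_edge_map(arr)
            oracle = brute_force_laplacian(arr)
            np.testing.assert_allclose(lap, oracle, rtol=1e-6, atol=1e-9)

    def test_translation_covariance_on_interiors(self, rng):
        arr = rng.normal(size=(24, 24))
        shifted = np.roll(arr, (2, 3), axis=(0, 1))
        a = laplacian_edge_map(arr)
        b = laplacian_edge_map(shifted)
        np.testing.assert_allclose(
            np.roll(a, (2, 3), axis=(0, 1))[4:-4, 4:-4], b[4:-4, 4:-4], atol=1e-12
        )

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            laplacian_edge_map(np.zeros((2, 5)))


class TestComposeOutput:
    def test_identical_edge_maps_return_intermediate(self, rng):
        i = rng.normal(size=(6, 6))
        e = rng.normal(size=(6, 6))
        np.testing.assert_array_equal(compose_output(i, e, e), i)

    def test_elementwise_arithmetic(self):
        out = compose_output(
            np.array([[10.0, 20.0], [30.0, 40.0]]),
            np.array([[1.0, 0.0], [0.0, 1.0]]),
            np.array([[2.0, 0.0], [0.0, 3.0]]),
        )
        np.testing.assert_array_equal(out, [[11.0, 20.0], [30.0, 42.0]])

    def test_all_zero_inputs(self):
        np.testing.assert_array_equal(compose_output(*([np.zeros((3, 3))] * 3)), 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose_output(np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((2, 2)))


class TestBuildModel:
    def test_same_config_and_seed_give_identical_parameters(self):
        assert build_model(MICRO).checksum() == build_model(MICRO).checksum()

    def test_different_seed_changes_parameters(self):
        import dataclasses

        other = dataclasses.replace(MICRO, seed=99)
        assert build_model(MICRO).checksum() != build_model(other).checksum()

    def test_uddn_variant_stacks_all_udbs(self):
        model = build_model(ModelConfig(variant="uddn"))
        assert isinstance(model, UDDN)
        assert len(model.denoiser.udbs) == 6
        assert not hasattr(model, "edge")

    def test_eedn_splits_udbs_between_denoiser_and_edge_branch(self):
        model = build_model(ModelConfig())
        assert len(model.denoiser.udbs) == 3
        assert len(model.edge.udbs) == 3

    def test_inconsistent_udb_split_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_udbs_total=6, n_udbs_denoiser=2, n_udbs_edge=3)

    def test_parameter_counts_of_variants_are_comparable(self):
        # the edge-enhanced variant must not exceed the plain stack's cost
        # by more than 20% at equal growth
        eedn = build_model(ModelConfig()).num_parameters()
        uddn = build_model(ModelConfig(variant="uddn")).num_parameters()
        assert abs(eedn - uddn) / uddn < 0.20

    def test_attention_block_is_fixed_at_six_3x3_layers(self):
        with pytest.raises(ValueError):
            ModelConfig(attention_layers=4)
        model = build_model(ModelConfig())
        assert len(model.edge.attention.convs) == 6
        assert all(c.weight.shape[2:] == (3, 3) for c in model.edge.attention.convs)


class TestAttentionWeights:
    def test_weights_lie_strictly_inside_unit_interval(self, rng):
        model = build_model(MICRO)
        ce = MICRO.resolved_edge_channels()
        feats = nn.Tensor(rng.normal(size=(1, ce, 8, 8)).astype("f4"))
        w = model.attention_weights(feats)
        assert w.data.min() > 0.0 and w.data.max() < 1.0
        assert w.shape == feats.shape

    def test_zeroed_block_outputs_exactly_half(self, rng):
        model = build_model(MICRO)
        for conv in model.edge.attention.convs:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        ce = MICRO.resolved_edge_channels()
        feats = nn.Tensor(rng.normal(size=(1, ce, 6, 6)).astype("f4"))
        np.testing.assert_array_equal(model.attention_weights(feats).data, 0.5)

    def test_deterministic_given_seed_and_input(self, rng):
        feats = rng.normal(size=(1, MICRO.resolved_edge_channels(), 8, 8)).astype("f4")
        a = build_model(MICRO).attention_weights(nn.Tensor(feats)).data
        b = build_model(MICRO).attention_weights(nn.Tensor(feats)).data
        np.testing.assert_array_equal(a, b)


class TestDenoise:
    @pytest.mark.parametrize("shape", [(96, 96), (512, 512), (90, 70)])
    def test_output_shape_matches_input(self, shape):
        model = build_model(MICRO)
        frame = ImageFrame(np.full(shape, 100.0), 8)
        trace = denoise(model, frame)
        assert trace.i_output.shape == shape

    def test_composition_identity_holds_in_float32(self):
        model = build_model(MICRO)
        frame = generate_phantom(default_template(size=(128, 128)))
        trace = denoise(model, frame)
        assert trace.composition_error() <= 1e-4

    def test_edge_map_is_laplacian_of_intermediate(self):
        model = build_model(MICRO)
        frame = generate_phantom(default_template(size=(64, 64)))
        trace = denoise(model, frame)
        np.testing.assert_allclose(
            trace.i_edge, laplacian_edge_map(trace.i_inter), atol=5e-3
        )

    def test_forward_is_pure_function_of_parameters_and_input(self):
        frame = generate_phantom(default_template(size=(64, 64)))
        a = denoise(build_model(MICRO), frame).i_output
        b = denoise(build_model(MICRO), frame).i_output
        np.testing.assert_array_equal(a, b)

    def test_uddn_trace_satisfies_composition_with_zero_edges(self):
        import dataclasses

        cfg = dataclasses.replace(MICRO, variant="uddn", n_udbs_total=2)
        model = build_model(cfg)
        trace = denoise(model, ImageFrame(np.full((32, 32), 80.0), 8))
        assert trace.composition_error() == 0.0
        np.testing.assert_array_equal(trace.i_edge, 0.0)


def test_checkpoint_round_trip(tmp_path):
    model = build_model(MICRO)
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    assert restored.checksum() == model.checksum()
    assert restored.config == MICRO
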