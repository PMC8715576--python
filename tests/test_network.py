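"""Architecture builder: structural conformance, shape bookkeeping, backend."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmnet.metrics import PredictionBatch, tmse_grad, tmse_loss
from rhythmnet.network import (
    ArchitectureConfig,
    ArchitectureError,
    LayerSpec,
    build_architecture,
    instantiate,
    output_sequence_length,
    parameter_count,
)
from rhythmnet import backend


def kind_counts(specs):
    out = {}
    for s in specs:
        out[s.kind] = out.get(s.kind, 0) + 1
    return out


class TestBuildArchitecture:
    def test_default_conv_stack(self):
        specs = build_architecture()
        convs = [s for s in specs if s.kind == "conv1d"]
        assert len(convs) == 24
        assert all(s.params["kernel"] == 16 for s in convs)
        assert [s.params["filters"] for s in convs] == [32] * 8 + [64] * 8 + [128] * 8

    def test_default_support_layers(self):
        counts = kind_counts(build_architecture())
        assert counts["maxpool1d"] == 12
        assert counts["batchnorm"] == 24
        assert counts["dropout"] == 24
        assert counts["bilstm"] == 2
        assert counts["dense"] == 4
        assert counts["softmax"] == 1

    def test_bilstm_units_and_sequence_flags(self):
        lstms = [s for s in build_architecture() if s.kind == "bilstm"]
        assert [s.params["units"] for s in lstms] == [64, 128]
        assert [s.params["return_sequences"] for s in lstms] == [True, False]
        assert all(s.params["merge_mode"] == "concat" for s in lstms)

    def test_dense_head(self):
        dense = [s for s in build_architecture() if s.kind == "dense"]
        assert [s.params["width"] for s in dense] == [128, 64, 32, 4]

    def test_per_conv_layer_order(self):
        specs = build_architecture()
        kinds = [s.kind for s in specs]
        first_conv = kinds.index("conv1d")
        assert kinds[first_conv : first_conv + 4] == [
            "conv1d", "batchnorm", "activation", "dropout",
        ]

    def test_minimal_config(self):
        cfg = ArchitectureConfig(
            filters_per_block=(4,), conv_per_block=2, pool_every=2,
            dense_widths=(4,), bilstm_units=(3,), input_length=64,
        )
        counts = kind_counts(build_architecture(cfg))
        assert counts["conv1d"] == 2 and counts["maxpool1d"] == 1

    def test_inconsistent_config_lists_violations(self):
        cfg = ArchitectureConfig(conv_per_block=3, pool_every=2, dense_widths=(128, 5))
        with pytest.raises(ArchitectureError) as err:
            build_architecture(cfg)
        assert "divisible" in str(err.value) and "n_classes" in str(err.value)

    def test_relu_then_softmax_variant(self):
        cfg = ArchitectureConfig(final_activation="relu-then-softmax")
        tail = [s.kind for s in build_architecture(cfg)][-3:]
        assert tail == ["dense", "activation", "softmax"]

    def test_bilstm_merge_mode_is_concatenation(self):
        with pytest.raises(ArchitectureError):
            LayerSpec("bilstm", {"units": 8, "merge_mode": "sum"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n_blocks=st.integers(1, 4),
        conv_per_block=st.sampled_from([2, 4, 8]),
        pool_every=st.sampled_from([1, 2]),
        n_dense=st.integers(1, 4),
        n_lstm=st.integers(1, 3),
    )
    def test_structural_closed_forms(self, n_blocks, conv_per_block, pool_every, n_dense, n_lstm):
        if conv_per_block % pool_every:
            conv_per_block = pool_every * conv_per_block
        cfg = ArchitectureConfig(
            filters_per_block=tuple(8 * (i + 1) for i in range(n_blocks)),
            conv_per_block=conv_per_block,
            pool_every=pool_every,
            bilstm_units=tuple(4 * (i + 1) for i in range(n_lstm)),
            dense_widths=tuple([16] * (n_dense - 1) + [4]),
            input_length=2 ** (n_blocks * conv_per_block // pool_every + 2),
        )
        counts = kind_counts(build_architecture(cfg))
        n_convs = n_blocks * conv_per_block
        assert counts["conv1d"] == n_convs
        assert counts["batchnorm"] == n_convs
        assert counts["dropout"] == n_convs
        assert counts["maxpool1d"] == n_convs // pool_every
        assert counts["bilstm"] == n_lstm
        assert counts["dense"] == n_dense


class TestOutputSequenceLength:
    def test_default_9000_through_12_pools(self):
        assert output_sequence_length(ArchitectureConfig()) == 2

    def test_power_of_two_input(self):
        assert output_sequence_length(ArchitectureConfig(input_length=4096)) == 1

    def test_too_short_input_rejected(self):
        with pytest.raises(ArchitectureError):
            output_sequence_length(ArchitectureConfig(input_length=2048))


SMALL = ArchitectureConfig(
    filters_per_block=(4, 6), conv_per_block=2, kernel=5, pool_every=2,
    dropout=0.2, bilstm_units=(3, 4), dense_widths=(8, 4), input_length=60,
)


class TestInstantiate:
    def test_forward_rows_are_probabilities(self, rng):
        model = instantiate(build_architecture(SMALL), seed=0)
        x = rng.normal(size=(5, 1, 60)).astype(np.float32)
        p = model.forward(np.zeros_like(x))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        p2 = model.forward(x)
        assert np.allclose(p2.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p2 >= 0)

    def test_same_seed_identical_outputs(self, rng):
        x = rng.normal(size=(3, 1, 60)).astype(np.float32)
        a = instantiate(build_architecture(SMALL), seed=9).forward(x)
        b = instantiate(build_architecture(SMALL), seed=9).forward(x)
        assert np.array_equal(a, b)

    def test_parameter_count_matches_hand_computed_sum(self):
        # independently computed layer-by-layer for the default config:
        # conv blocks 115,968 + 493,056 + 1,969,152; BiLSTMs 98,816 + 263,168;
        # dense head 43,364
        model = instantiate(build_architecture(ArchitectureConfig()), seed=0)
        assert model.num_params == 2_983_524
        assert parameter_count(ArchitectureConfig()) == 2_983_524

    def test_parameter_count_closed_form_small(self):
        model = instantiate(build_architecture(SMALL), seed=1)
        assert model.num_params == parameter_count(SMALL)

    def test_one_optimizer_step_decreases_loss(self, rng):
        """Gradient flow: one Adam step on a singleton batch reduces that
        batch's TMSE for a freshly initialized default-config model."""
        model = instantiate(build_architecture(ArchitectureConfig()), seed=3)
        x = rng.normal(size=(1, 1, 9000)).astype(np.float32)
        y = np.zeros((1, 4), dtype=np.float32); y[0, 1] = 1.0
        loss_fn = lambda yt, p: tmse_loss(PredictionBatch(yt, np.clip(p, 0, 1)))  # noqa: E731
        loss_grad = lambda yt, p: tmse_grad(PredictionBatch(yt, np.clip(p, 0, 1)))  # noqa: E731
        opt = backend.Adam(lr=1e-3)
        before = model.train_step(x, y, loss_fn, loss_grad, opt)
        after = loss_fn(y, model.forward(x))
        assert after < before


class TestBackendPieces:
    def test_maxpool_backward_routes_to_argmax(self):
        pool = backend.MaxPool1D(2)
        x = np.array([[[1.0, 3.0, 2.0, 0.0]]])
        out = pool.forward(x, training=True)
        assert np.array_equal(out, [[[3.0, 2.0]]])
        dx = pool.backward(np.array([[[1.0, 1.0]]]))
        assert np.array_equal(dx, [[[0.0, 1.0, 1.0, 0.0]]])

    def test_bilstm_concatenates_directions(self, rng):
        lstm = backend.BiLSTM(2, 3, rng, return_sequences=True)
        x = rng.normal(size=(2, 5, 2)).astype(np.float32)
        out = lstm.forward(x)
        assert out.shape == (2, 5, 6)
        last = backend.BiLSTM(2, 3, rng, return_sequences=False)
        final = last.forward(x)
        assert final.shape == (2, 6)

    def test_dropout_inverted_scaling(self, rng):
        drop = backend.Dropout(0.5, rng)
        x = np.ones((200, 50), dtype=np.float32)
        out = drop.forward(x, training=True)
        assert out.mean() == pytest.approx(1.0, abs=0.05)
        assert np.array_equal(drop.forward(x, training=False), x)
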