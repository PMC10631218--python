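"""Math primitives, architecture assembly, catalog identity, training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from convboost.containers import LabeledDataset
from convboost.network import (
    ArchitectureSpec,
    bce_loss,
    build_network,
    load_network,
    predict,
    relu,
    save_network,
    sigmoid,
    softmax,
    train_network,
)
from convboost.recipes import activity_spec, genomic_spec, text_spec


class TestPrimitives:
    @pytest.mark.parametrize("x,expected", [(-2, 0), (3.5, 3.5), (0, 0)])
    def test_relu_cases(self, x, expected):
        assert relu(x) == expected

    def test_relu_elementwise(self):
        assert np.array_equal(relu(np.array([-1.0, 2.0])), [0.0, 2.0])

    def test_softmax_uniform_and_closed_form(self):
        assert np.allclose(softmax(np.zeros(3)), 1 / 3, atol=1e-12)
        assert np.allclose(softmax(np.array([0.0, np.log(3)])), [0.25, 0.75], atol=1e-12)

    def test_softmax_shift_invariance_and_overflow(self):
        z = np.array([1000.0, 1000.0])
        assert np.allclose(softmax(z), [0.5, 0.5])
        z = np.array([0.3, -1.2, 4.0])
        assert np.allclose(softmax(z), softmax(z + 123.4), atol=1e-12)

    def test_softmax_sums_to_one_many_random_vectors(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(scale=50, size=(10_000, 7))
        assert np.allclose(softmax(Z, axis=1).sum(axis=1), 1.0, atol=1e-9)

    def test_bce_closed_forms(self):
        assert bce_loss(1, 0.5) == pytest.approx(np.log(2), abs=1e-9)
        assert bce_loss(0, 0.5) == pytest.approx(np.log(2), abs=1e-9)
        assert bce_loss(1, 1.0) == pytest.approx(0.0, abs=1e-6)  # clipped at 1-eps

    @given(st.floats(0.01, 0.99), st.integers(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bce_nonnegative(self, p, y):
        assert bce_loss(y, p) >= 0

    def test_sigmoid_stable_at_extremes(self):
        assert sigmoid(np.array([-1000.0, 1000.0])).tolist() == [0.0, 1.0]


RECIPE_SPECS = [
    ("genomic-1", genomic_spec(n_blocks=1), 2),
    ("genomic-3", genomic_spec(n_blocks=3), 2),
    ("activity-1", activity_spec(n_blocks=1), 6),
    ("activity-2", activity_spec(n_blocks=2), 6),
    ("text-1", text_spec(vocab_size=50, n_blocks=1), 2),
]


class TestBuild:
    @pytest.mark.parametrize("name,spec,k", RECIPE_SPECS, ids=[r[0] for r in RECIPE_SPECS])
    def test_catalog_length_identity(self, name, spec, k):
        net, catalog = build_network(spec, n_classes=k)
        n_dense = len(spec.resolved_dense_sizes(k))
        assert len(catalog) == 3 * spec.n_blocks + 1 + n_dense
        assert [e.index for e in catalog] == list(range(1, len(catalog) + 1))

    def test_genomic_3_block_catalog_is_12(self):
        _, catalog = build_network(genomic_spec(n_blocks=3), n_classes=2)
        assert len(catalog) == 12

    def test_block_structure_per_block(self):
        _, catalog = build_network(genomic_spec(n_blocks=2), n_classes=2)
        kinds = [e.kind for e in catalog]
        assert kinds == ["conv", "conv", "pool"] * 2 + ["flatten", "dense", "dense"]

    def test_filter_counts_double(self):
        net, catalog = build_network(activity_spec(n_blocks=2), n_classes=6)
        assert catalog[1].output_shape[1] == 64     # block 1 convs: 64 filters
        assert catalog[4].output_shape[1] == 128    # block 2 convs doubled

    def test_same_padding_conserves_length_and_pool_floors(self):
        _, catalog = build_network(genomic_spec(n_blocks=3), n_classes=2)
        # block1: 57 -valid-> 55 -same-> 55 -pool2-> 27; then 25/25/12; then 10/10/5
        lengths = [e.output_shape[0] for e in catalog if e.kind in ("conv", "pool")]
        assert lengths == [55, 55, 27, 25, 25, 12, 10, 10, 5]

    def test_flatten_dim_after_three_pools(self):
        _, catalog = build_network(genomic_spec(n_blocks=3), n_classes=2)
        flatten = next(e for e in catalog if e.kind == "flatten")
        assert flatten.output_shape == (5 * 256,)

    def test_too_many_blocks_errors_advising_fewer(self):
        with pytest.raises(ValueError, match="fewer blocks|kernel"):
            build_network(genomic_spec(n_blocks=6), n_classes=2)

    def test_embedding_only_for_text(self):
        spec = text_spec(vocab_size=30, max_len=30, n_blocks=1)
        net, catalog = build_network(spec, n_classes=2)
        assert catalog[1].output_shape[0] < 30  # conv after embedding shrinks length


def _toy_dataset(n=120, seed=0):
    """Linearly separable two-class signal dataset."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 16, 2)) * 0.1
    X[y == 1] += 1.0
    return LabeledDataset(X, y, "timeseries", ["lo", "hi"])


def _toy_spec(**kw):
    base = dict(n_blocks=1, base_filters=8, kernel_size=3, pool_size=2,
                dense_sizes=(16, 1), output_activation="sigmoid",
                input_shape=(16, 2))
    base.update(kw)
    return ArchitectureSpec(**base)


class TestTraining:
    def test_fits_separable_data(self):
        ds = _toy_dataset()
        spec = _toy_spec()
        net, cat = build_network(spec, 2, seed=0)
        trained = train_network(net, cat, spec, ds, ds, max_epochs=15, seed=0)
        assert trained.history["train_acc"][-1] >= 0.95

    def test_zero_lr_constant_val_loss_stops_at_patience_plus_one(self):
        from convboost.layers import BatchNorm
        ds = _toy_dataset(n=40)
        spec = _toy_spec(learning_rate=0.0, dropout_rate=0.0)
        net, cat = build_network(spec, 2, seed=0)
        for op in net.ops:  # freeze running statistics so the network is fully static
            if isinstance(op, BatchNorm):
                op.momentum = 1.0
        trained = train_network(net, cat, spec, ds, ds, max_epochs=50, patience=10, seed=0)
        assert trained.stopped_epoch == 11
        assert len(set(np.round(trained.history["val_loss"], 12))) == 1

    def test_runs_to_max_epochs_when_patience_never_triggers(self):
        ds = _toy_dataset(n=60)
        spec = _toy_spec()
        net, cat = build_network(spec, 2, seed=1)
        trained = train_network(net, cat, spec, ds, ds, max_epochs=5, patience=10, seed=1)
        assert trained.stopped_epoch == 5
        assert len(trained.history["val_loss"]) == 5

    def test_best_weights_restored(self):
        ds = _toy_dataset(n=60)
        spec = _toy_spec()
        net, cat = build_network(spec, 2, seed=2)
        trained = train_network(net, cat, spec, ds, ds, max_epochs=12, seed=2)
        # evaluation after restore must match the best recorded val loss
        from convboost.network import _batched_eval
        loss, _ = _batched_eval(trained.net, ds.X, ds.y)
        assert loss == pytest.approx(min(trained.history["val_loss"]), abs=1e-9)

    def test_nan_loss_aborts_with_diagnostic(self):
        ds = _toy_dataset(n=40)
        spec = _toy_spec()
        net, cat = build_network(spec, 2, seed=0)
        net.ops[-1].params["W"][:] = np.nan  # corrupted weights -> NaN loss
        with pytest.raises(RuntimeError, match="non-finite"):
            train_network(net, cat, spec, ds, ds, max_epochs=5, seed=0)


@pytest.fixture(scope="module")
def trained():
    ds = _toy_dataset()
    spec = _toy_spec()
    net, cat = build_network(spec, 2, seed=3)
    return ds, train_network(net, cat, spec, ds, ds, max_epochs=8, seed=3)


class TestTextModality:
    def test_embedding_network_trains_on_biased_tokens(self):
        from convboost.synthetic_data import gen_token_sequences
        X, y = gen_token_sequences(120, vocab_size=40, max_len=24,
                                   class_token_bias=50.0, seed=6)
        ds = LabeledDataset(X, y, "text", ["neg", "pos"])
        spec = text_spec(vocab_size=40, max_len=24, embed_dim=8, n_blocks=1)
        spec = ArchitectureSpec(**{**spec.__dict__, "base_filters": 4,
                                   "dense_sizes": (8, 1)})
        net, cat = build_network(spec, 2, seed=6)
        tn = train_network(net, cat, spec, ds, ds, max_epochs=10, seed=6)
        assert tn.history["train_acc"][-1] > 0.7  # embedding gradients flow
        probs, labels = predict(tn, ds.X)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_extraction_from_embedding_network(self):
        from convboost.extraction import extract_features
        from convboost.network import TrainedNetwork
        spec = text_spec(vocab_size=30, max_len=20, embed_dim=4, n_blocks=1)
        spec = ArchitectureSpec(**{**spec.__dict__, "base_filters": 3, "dense_sizes": (4, 1)})
        net, cat = build_network(spec, 2, seed=0)
        tn = TrainedNetwork(net, spec, cat, {"val_loss": [1.0]}, 1)
        X = np.random.default_rng(0).integers(0, 30, size=(5, 20))
        fm = extract_features(tn, 1, X)
        assert fm.n == 5 and fm.values.min() >= 0  # post-ReLU conv activations


class TestPredict:

    def test_probabilities_in_range_and_consistent(self, trained):
        ds, tn = trained
        probs, labels = predict(tn, ds.X)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.array_equal(labels, (probs > 0.5).astype(int))

    def test_softmax_head_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        ds = LabeledDataset(rng.normal(size=(30, 16, 2)), rng.integers(0, 3, 30),
                            "timeseries", ["a", "b", "c"])
        spec = _toy_spec(output_activation="softmax", dense_sizes=(16,))
        net, cat = build_network(spec, 3, seed=0)
        tn = train_network(net, cat, spec, ds, ds, max_epochs=2, seed=0)
        probs, labels = predict(tn, ds.X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(labels, probs.argmax(axis=1))

    def test_inference_deterministic(self, trained):
        ds, tn = trained
        p1, _ = predict(tn, ds.X)
        p2, _ = predict(tn, ds.X)
        assert np.array_equal(p1, p2)

    def test_serialization_roundtrip(self, trained, tmp_path):
        ds, tn = trained
        path = tmp_path / "net.cbz"
        save_network(tn, path)
        back = load_network(path)
        p1, _ = predict(tn, ds.X)
        p2, _ = predict(back, ds.X)
        assert np.allclose(p1, p2, atol=1e-12)
        assert back.stopped_epoch == tn.stopped_epoch
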