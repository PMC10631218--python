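"""Windowing, encoding, tokenization, normalization, splitting and readers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from convboost.containers import LabeledDataset, RawSeries, SplitSpec
from convboost.data_io import (
    MinMaxNormalizer,
    Tokenizer,
    binarize_ratings,
    count_windows,
    normalize_features,
    one_hot_decode,
    one_hot_encode,
    read_promoter_file,
    read_sentiment_file,
    read_wisdm_csv,
    split_dataset,
    split_indices,
    tokenize_texts,
    window_time_series,
    write_promoter_file,
    write_sentiment_file,
    write_wisdm_csv,
)
from convboost.synthetic_data import (
    MotifGeneratorConfig,
    SignalGeneratorConfig,
    gen_activity_series,
    gen_motif_sequences,
)


def brute_force_window_count(T: int, period: int, step: int) -> int:
    """Independent oracle: enumerate every valid start offset."""
    return sum(1 for start in range(T + 1) if start % step == 0 and start + period <= T)


class TestWindowing:
    def test_window_feature_count_80x4(self, single_label_series):
        ds = window_time_series(single_label_series, time_period=80, time_step=40)
        assert ds.X.shape[1:] == (80, 4)
        assert ds.flat_features().shape[1] == 320

    def test_no_overlap_when_step_equals_period(self):
        s = RawSeries("a", np.arange(160.0), np.zeros((160, 2)),
                      np.array(["w"] * 160, dtype=object))
        ds = window_time_series([s], time_period=80, time_step=80)
        assert ds.n == 2

    def test_enumerated_starts(self):
        s = RawSeries("a", np.arange(200.0), np.random.default_rng(0).normal(size=(200, 3)),
                      np.array(["w"] * 200, dtype=object))
        ds = window_time_series([s], time_period=80, time_step=40)
        assert ds.n == 4  # starts 0, 40, 80, 120
        assert np.allclose(ds.X[1], s.channels[40:120])

    @given(T=st.integers(1, 400), period=st.integers(1, 100), step=st.integers(1, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_count_matches_brute_force(self, T, period, step):
        step = min(step, period)
        assert count_windows(T, period, step) == brute_force_window_count(T, period, step)

    def test_windows_never_span_subjects(self):
        mk = lambda sid, v: RawSeries(sid, np.arange(100.0), np.full((100, 1), v),
                                      np.array([sid] * 100, dtype=object))
        ds = window_time_series([mk("a", 0.0), mk("b", 1.0)], time_period=80, time_step=10)
        # every window is constant within one subject's value
        assert set(np.unique(ds.X).tolist()) == {0.0, 1.0}
        for w in ds.X:
            assert np.ptp(w) == 0.0

    def test_majority_label_tie_breaks_to_earliest(self):
        labels = np.array(["b"] * 40 + ["a"] * 40, dtype=object)
        s = RawSeries("x", np.arange(80.0), np.zeros((80, 1)), labels)
        ds = window_time_series([s], time_period=80, time_step=80,
                                class_names=["a", "b"])
        assert ds.class_names[ds.y[0]] == "b"  # tie: first-occurring wins

    def test_empty_and_nonnumeric_errors(self):
        with pytest.raises(ValueError, match="empty"):
            window_time_series([], 10, 5)
        ch = np.zeros((50, 2)); ch[7, 1] = np.nan
        s = RawSeries("a", np.arange(50.0), ch, np.array(["w"] * 50, dtype=object))
        with pytest.raises(ValueError, match="row 7"):
            window_time_series([s], 10, 5)


class TestOneHot:
    def test_alphabet_order(self):
        assert one_hot_encode(["a"]).tolist() == [[[1, 0, 0, 0]]]
        assert np.array_equal(one_hot_encode(["acgt"])[0], np.eye(4))

    def test_57mer_shape_and_row_sums(self):
        seqs, _ = gen_motif_sequences(MotifGeneratorConfig(n=4, seed=0))
        X = one_hot_encode(seqs)
        assert X.shape == (4, 57, 4)
        assert np.all(X.sum(axis=2) == 1)

    def test_decode_inverts_encode(self):
        seqs, _ = gen_motif_sequences(MotifGeneratorConfig(n=10, seed=1))
        assert one_hot_decode(one_hot_encode(seqs)) == seqs

    def test_case_insensitive(self):
        assert np.array_equal(one_hot_encode(["ACGT"]), one_hot_encode(["acgt"]))

    def test_error_cases(self):
        with pytest.raises(ValueError, match="ragged"):
            one_hot_encode(["ac", "acg"])
        with pytest.raises(ValueError, match="position 2"):
            one_hot_encode(["acnt"])


class TestTokenizer:
    def test_small_vocab_indices(self):
        ds, tok = tokenize_texts(["red fish blue fish", "red sky"], [0, 1], max_len=10)
        used = set(ds.X[ds.X > 0].tolist())
        assert used <= set(range(2, 6))  # 3 distinct words -> indices 2..4 (+OOV unused)

    def test_truncation_to_max_len(self):
        long = " ".join(f"w{i}" for i in range(150))
        ds, _ = tokenize_texts([long], [0], max_len=100)
        assert ds.X.shape == (1, 100)
        assert np.all(ds.X[0] > 0)

    def test_determinism_and_oov(self):
        tok = Tokenizer(vocab_size=100).fit(["alpha beta beta"])
        a = tok.encode(["alpha beta gamma"], max_len=5)
        b = tok.encode(["alpha beta gamma"], max_len=5)
        assert np.array_equal(a, b)
        assert a[0, 2] == 1  # unseen word -> OOV index

    def test_indices_below_vocab_size(self):
        texts = [" ".join(f"word{i}" for i in range(50))]
        tok = Tokenizer(vocab_size=20).fit(texts)
        enc = tok.encode(texts, max_len=60)
        assert enc.max() < 20

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError, match="empty corpus"):
            Tokenizer().fit([])


class TestBinarize:
    @pytest.mark.parametrize("rating,threshold,expected", [
        (3, 2.5, 1), (2, 2, 0), (2.5, 2.5, 0), (5, 2, 1), (1, 2.5, 0),
    ])
    def test_strict_threshold(self, rating, threshold, expected):
        assert binarize_ratings([rating], threshold)[0] == expected

    def test_out_of_scale_errors(self):
        with pytest.raises(ValueError, match="outside"):
            binarize_ratings([0.5], 2)


class TestNormalize:
    def test_minmax_and_constant_column(self):
        X = np.array([[0.0, 3.0], [5.0, 3.0], [10.0, 3.0]])
        Xn, norm = normalize_features(X)
        assert np.allclose(Xn[:, 0], [0, 0.5, 1])
        assert np.allclose(Xn[:, 1], 0)

    def test_fitted_transform_is_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        Xn, norm = normalize_features(X)
        assert np.array_equal(norm.transform(X), Xn)

    def test_stored_stats_applied_to_new_data(self):
        norm = MinMaxNormalizer().fit(np.array([[0.0], [10.0]]))
        assert norm.transform(np.array([[20.0]]))[0, 0] == 2.0  # extrapolates, no refit


class TestSplit:
    def test_sizes_n1000(self):
        tr, va, te = split_indices(1000, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (640, 160, 200)

    def test_sizes_n106_partition(self):
        tr, va, te = split_indices(106, SplitSpec(seed=4))
        assert len(tr) + len(va) + len(te) == 106
        assert abs(len(tr) - 67) <= 1 and abs(len(va) - 17) <= 1 and abs(len(te) - 22) <= 1
        assert len(set(tr) | set(va) | set(te)) == 106  # exact partition

    def test_seed_determinism(self):
        a = split_indices(500, SplitSpec(seed=9))
        b = split_indices(500, SplitSpec(seed=9))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        c = split_indices(500, SplitSpec(seed=10))
        assert not np.array_equal(a[0], c[0])

    @given(n=st.integers(10, 2000), seed=st.integers(0, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_property(self, n, seed):
        tr, va, te = split_indices(n, SplitSpec(seed=seed))
        combined = np.concatenate([tr, va, te])
        assert len(combined) == n and len(set(combined.tolist())) == n

    def test_split_dataset_warns_on_missing_class(self, caplog):
        X = np.zeros((10, 3)); y = np.array([0] * 9 + [1])
        ds = LabeledDataset(X, y, "flat", ["a", "b"])
        # try seeds until the single class-1 row lands outside training
        for seed in range(50):
            tr, _, _ = split_dataset(ds, SplitSpec(seed=seed))
            if 1 not in tr.y:
                assert any("absent" in r.message for r in caplog.records)
                return
        pytest.skip("class-1 row always sampled into training")


class TestReaders:
    def test_promoter_roundtrip_counts(self, tmp_path):
        seqs, y = gen_motif_sequences(MotifGeneratorConfig(n=106, seed=2))
        p = tmp_path / "prom.txt"
        write_promoter_file(p, seqs, y)
        rseqs, ry, _ = read_promoter_file(p)
        assert len(rseqs) == 106 and int(ry.sum()) == 53
        assert rseqs == seqs and np.array_equal(ry, y)

    def test_promoter_small_fixture(self, tmp_path):
        p = tmp_path / "ten.txt"
        seqs, y = gen_motif_sequences(MotifGeneratorConfig(n=10, length=12, motif="acgt", seed=3))
        write_promoter_file(p, seqs, y)
        rseqs, _, _ = read_promoter_file(p)
        assert len(rseqs) == 10

    def test_promoter_whitespace_tolerated(self, tmp_path):
        p = tmp_path / "w.txt"
        p.write_text("+, name1 ,\tac gt\n-,name2,ccgg\n")
        seqs, y, names = read_promoter_file(p)
        assert seqs == ["acgt", "ccgg"] and y.tolist() == [1, 0]

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(ValueError, match="no records"):
            read_promoter_file(p)
        with pytest.raises(ValueError, match="no records"):
            read_sentiment_file(p)

    def test_malformed_line_number_reported(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("+,n1,acgt\nnot a record\n")
        with pytest.raises(ValueError, match=":2"):
            read_promoter_file(p)

    def test_wisdm_roundtrip_and_magnitude(self, tmp_path):
        series = gen_activity_series(SignalGeneratorConfig(n_subjects=2, classes=2,
                                                           run_length=50, seed=5))
        p = tmp_path / "w.csv"
        write_wisdm_csv(p, series)
        back = read_wisdm_csv(p)
        assert len(back) == 2
        assert back[0].n_channels == 4
        xyz = back[0].channels[:, :3]
        assert np.allclose(back[0].channels[:, 3], np.linalg.norm(xyz, axis=1), atol=1e-5)

    def test_sentiment_roundtrip(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_sentiment_file(p, ["good film", "bad film"], np.array([1, 0]))
        texts, y = read_sentiment_file(p)
        assert texts == ["good film", "bad film"] and y.tolist() == [1, 0]
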