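"""Readers and preprocessing for the three supported modalities.

Covers sliding-window segmentation of sensor streams, one-hot encoding of
fixed-length DNA sequences, word-index tokenization of text, rating
binarization, min-max feature normalization and seeded train/val/test
splitting, plus flat-file readers for the promoter, accelerometer-CSV and
sentiment-TSV dialects.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .containers import LabeledDataset, RawSeries, SplitSpec

logger = logging.getLogger(__name__)

DNA_ALPHABET = "acgt"


# ---------------------------------------------------------------------------
# time-series windowing
# ---------------------------------------------------------------------------

def count_windows(T: int, time_period: int, time_step: int) -> int:
    """Number of sliding windows over a run of ``T`` steps.

    Equals ``floor((T - time_period) / time_step) + 1`` when ``T >= time_period``
    and 0 otherwise.
    """
    if T < time_period:
        return 0
    return (T - time_period) // time_step + 1


def _majority_label(window_labels: np.ndarray) -> object:
    """Majority class of a window; ties broken by earliest occurrence in the window."""
    counts = Counter(window_labels.tolist())
    best_count = max(counts.values())
    for lab in window_labels:  # first label reaching the max count wins
        if counts[lab] == best_count:
            return lab
    raise AssertionError("unreachable")


def window_time_series(
    series: list[RawSeries],
    time_period: int,
    time_step: int,
    class_names: list[str] | None = None,
) -> LabeledDataset:
    """Segment subject recordings into fixed-length overlapping windows.

    Windows of ``time_period`` steps are taken every ``time_step`` steps within
    each subject (never across subjects).  Each window keeps its full
    ``time_period x C`` channel block and is labeled with the majority class of
    its timesteps, ties broken by the earliest-occurring class in the window.
    """
    if not series:
        raise ValueError("empty input: no subject series to window")
    if time_period < 1:
        raise ValueError("time_period must be >= 1")
    if not 1 <= time_step <= time_period:
        raise ValueError("time_step must satisfy 1 <= time_step <= time_period")
    C = series[0].n_channels
    windows: list[np.ndarray] = []
    labels: list[object] = []
    for s in series:
        if s.n_channels != C:
            raise ValueError(
                f"subject {s.subject_id!r} has {s.n_channels} channels, expected {C}"
            )
        if not np.isfinite(s.channels).all():
            bad = int(np.argwhere(~np.isfinite(s.channels))[0][0])
            raise ValueError(
                f"subject {s.subject_id!r}: non-numeric channel value at row {bad}"
            )
        T = len(s)
        for w in range(count_windows(T, time_period, time_step)):
            start = w * time_step
            windows.append(s.channels[start : start + time_period])
            labels.append(_majority_label(s.labels[start : start + time_period]))
    if not windows:
        raise ValueError(
            f"no subject is long enough for time_period={time_period}"
        )
    if class_names is None:
        class_names = sorted({str(l) for l in labels})
    index = {c: i for i, c in enumerate(class_names)}
    y = np.array([index[str(l)] for l in labels], dtype=np.int64)
    X = np.stack(windows).astype(np.float64)
    logger.info(
        "windowed %d subjects into %d windows of %d x %d values; class histogram %s",
        len(series), len(windows), time_period, C, Counter(y.tolist()),
    )
    return LabeledDataset(X, y, "timeseries", class_names)


# ---------------------------------------------------------------------------
# DNA one-hot
# ---------------------------------------------------------------------------

def one_hot_encode(sequences: list[str]) -> np.ndarray:
    """One-hot encode equal-length DNA strings to ``(n, L, 4)``.

    Channel order is fixed alphabetically as ``(a, c, g, t)`` so downstream
    feature indices are stable.  Unknown characters (including ambiguity
    codes) are an error; case is ignored.
    """
    if len(sequences) == 0:
        raise ValueError("empty input: no sequences")
    L = len(sequences[0])
    lengths = {len(s) for s in sequences}
    if lengths != {L}:
        raise ValueError(f"ragged sequence lengths {sorted(lengths)}; all must equal {L}")
    lut = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(DNA_ALPHABET):
        lut[ord(ch)] = i
        lut[ord(ch.upper())] = i
    X = np.zeros((len(sequences), L, 4), dtype=np.float64)
    for i, seq in enumerate(sequences):
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        chan = lut[codes]
        if (chan < 0).any():
            pos = int(np.argwhere(chan < 0)[0][0])
            raise ValueError(
                f"sequence {i}: unknown character {seq[pos]!r} at position {pos}; "
                f"alphabet is {{a,c,g,t}}"
            )
        X[i, np.arange(L), chan] = 1.0
    return X


def one_hot_decode(X: np.ndarray) -> list[str]:
    """Invert :func:`one_hot_encode` (exact for valid one-hot input)."""
    idx = np.asarray(X).argmax(axis=-1)
    return ["".join(DNA_ALPHABET[c] for c in row) for row in idx]


# ---------------------------------------------------------------------------
# text tokenization
# ---------------------------------------------------------------------------

PAD_INDEX = 0
OOV_INDEX = 1


@dataclass
class Tokenizer:
    """Frequency-ranked word-index tokenizer.

    Index 0 is padding and index 1 the out-of-vocabulary token; real words
    occupy ``[2, vocab_size)`` ranked by training-corpus frequency.  Fit on the
    training split only, then applied unchanged to validation and test text.
    """

    vocab_size: int = 10_000
    word_index: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def _words(text: str) -> list[str]:
        return [w for w in "".join(c.lower() if c.isalnum() else " " for c in text).split() if w]

    def fit(self, texts: list[str]) -> "Tokenizer":
        if not texts or all(not self._words(t) for t in texts):
            raise ValueError("empty corpus: nothing to fit the tokenizer on")
        counts: Counter[str] = Counter()
        for t in texts:
            counts.update(self._words(t))
        # deterministic rank: by descending count then lexicographic
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        self.word_index = {
            w: i + 2 for i, (w, _) in enumerate(ranked) if i + 2 < self.vocab_size
        }
        return self

    def encode(self, texts: list[str], max_len: int) -> np.ndarray:
        if not self.word_index:
            raise RuntimeError("tokenizer must be fit before encoding")
        out = np.full((len(texts), max_len), PAD_INDEX, dtype=np.int64)
        for i, t in enumerate(texts):
            idx = [self.word_index.get(w, OOV_INDEX) for w in self._words(t)][:max_len]
            out[i, : len(idx)] = idx
        return out


def tokenize_texts(
    texts: list[str],
    labels: np.ndarray | list[int],
    vocab_size: int = 10_000,
    max_len: int = 100,
    tokenizer: Tokenizer | None = None,
    class_names: list[str] | None = None,
) -> tuple[LabeledDataset, Tokenizer]:
    """Tokenize texts into a padded integer ``LabeledDataset``.

    If ``tokenizer`` is None a new one is fit on ``texts`` (which should then
    be the training split); otherwise the already-fitted tokenizer is applied.
    """
    if tokenizer is None:
        tokenizer = Tokenizer(vocab_size=vocab_size).fit(texts)
    X = tokenizer.encode(texts, max_len)
    y = np.asarray(labels, dtype=np.int64)
    if class_names is None:
        class_names = [str(c) for c in range(int(y.max()) + 1)]
    return LabeledDataset(X, y, "text", class_names), tokenizer


# ---------------------------------------------------------------------------
# rating binarization
# ---------------------------------------------------------------------------

def binarize_ratings(ratings: np.ndarray | list[float], threshold: float) -> np.ndarray:
    """Map 1-5 star ratings to binary labels: 1 iff rating > threshold (strict)."""
    r = np.asarray(ratings, dtype=float)
    if ((r < 1) | (r > 5)).any():
        bad = float(r[(r < 1) | (r > 5)][0])
        raise ValueError(f"rating {bad} outside the 1-5 scale")
    return (r > threshold).astype(np.int64)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class MinMaxNormalizer:
    """Per-feature min-max scaling to [0, 1], fit on the training split only.

    Constant features map to 0.  Stored statistics are reused verbatim on
    validation/test data, so re-applying the fitted transform is idempotent.
    """

    lo: np.ndarray | None = None
    span: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        flat = X.reshape(X.shape[0], -1)
        self.lo = flat.min(axis=0)
        span = flat.max(axis=0) - self.lo
        span[span == 0] = 1.0  # constant columns -> (x - lo)/1 = 0
        self.span = span
        self._shape = X.shape[1:]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise RuntimeError("normalizer must be fit before transform")
        X = np.asarray(X, dtype=float)
        flat = X.reshape(X.shape[0], -1)
        return ((flat - self.lo) / self.span).reshape(X.shape)


def normalize_features(X: np.ndarray, method: str = "minmax") -> tuple[np.ndarray, MinMaxNormalizer]:
    """Fit the named normalizer on ``X`` and return (transformed, fitted)."""
    if method != "minmax":
        raise ValueError(f"unknown normalization method {method!r}")
    norm = MinMaxNormalizer().fit(X)
    return norm.transform(X), norm


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_indices(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed-deterministic (train, val, test) index partition of ``range(n)``."""
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train_total = round(n * spec.train_frac)
    n_val = round(n_train_total * spec.val_frac_of_train)
    n_train = n_train_total - n_val
    return perm[:n_train], perm[n_train:n_train_total], perm[n_train_total:]


def split_dataset(
    ds: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Randomly split into train/val/test per ``spec`` (plain random, not stratified).

    Sizes are ``round(n*train_frac*(1-val_frac))`` / ``round(n*train_frac*val_frac)``
    / remainder; the three index sets form an exact partition and are
    reproducible from ``spec.seed``.  A warning is logged if a class is absent
    from the training split.
    """
    tr, va, te = split_indices(ds.n, spec)
    train = ds.subset(tr)
    present = set(train.y.tolist())
    for c in range(ds.n_classes):
        if c not in present:
            logger.warning("class %r absent from the training split", ds.class_names[c])
    return train, ds.subset(va), ds.subset(te)


# ---------------------------------------------------------------------------
# flat-file readers / writers
# ---------------------------------------------------------------------------

def read_promoter_file(path: str) -> tuple[list[str], np.ndarray, list[str]]:
    """Read the promoter flat dialect: ``class,name,sequence`` per line.

    Class is ``+`` (promoter, label 1) or ``-`` (non-promoter, label 0);
    whitespace and tabs inside fields are tolerated; sequences are lowercase
    acgt.  Returns (sequences, labels, names).
    """
    seqs: list[str] = []
    labels: list[int] = []
    names: list[str] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n_lines += 1
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'class,name,sequence'")
            cls, name, seq = (p.strip().replace("\t", "") for p in parts)
            if cls not in "+-" or not cls:
                raise ValueError(f"{path}:{lineno}: class must be '+' or '-', got {cls!r}")
            seq = "".join(seq.split()).lower()
            if not seq:
                raise ValueError(f"{path}:{lineno}: empty sequence")
            seqs.append(seq)
            labels.append(1 if cls == "+" else 0)
            names.append(name)
    if not seqs:
        raise ValueError(f"{path}: no records found")
    y = np.asarray(labels, dtype=np.int64)
    logger.info(
        "read %d promoter records from %s (%d '+', %d '-')",
        len(seqs), path, int(y.sum()), int((1 - y).sum()),
    )
    return seqs, y, names


def read_wisdm_csv(path: str) -> list[RawSeries]:
    """Read accelerometer rows ``user,activity,timestamp,x,y,z;`` into per-subject series.

    A trailing semicolon is tolerated.  Rows are grouped by user in file
    order; timestamps must be strictly increasing within a user.  Returns one
    :class:`RawSeries` per subject with C=4 channels (x, y, z, magnitude), the
    magnitude channel being ``sqrt(x^2+y^2+z^2)``.
    """
    per_user: dict[str, list[tuple[float, float, float, float, str]]] = {}
    order: list[str] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            row = line.strip().rstrip(";").strip()
            if not row:
                dropped += 1
                continue
            parts = [p.strip() for p in row.split(",")]
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 comma-separated fields")
            user, activity, ts, x, y, z = parts
            try:
                rec = (float(ts), float(x), float(y), float(z), activity)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if user not in per_user:
                per_user[user] = []
                order.append(user)
            per_user[user].append(rec)
    if not per_user:
        raise ValueError(f"{path}: no records found")
    series = []
    hist: Counter[str] = Counter()
    for user in order:
        recs = per_user[user]
        ts = np.array([r[0] for r in recs])
        xyz = np.array([[r[1], r[2], r[3]] for r in recs])
        mag = np.linalg.norm(xyz, axis=1, keepdims=True)
        labs = np.array([r[4] for r in recs], dtype=object)
        hist.update(labs.tolist())
        series.append(RawSeries(user, ts, np.hstack([xyz, mag]), labs))
    logger.info(
        "read %d rows (%d subjects) from %s; dropped %d blank lines; class histogram %s",
        sum(len(v) for v in per_user.values()), len(series), path, dropped, dict(hist),
    )
    return series


def read_sentiment_file(path: str) -> tuple[list[str], np.ndarray]:
    """Read ``sentence<TAB>label`` lines, label in {0, 1}."""
    texts: list[str] = []
    labels: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: missing tab separator")
            text, _, lab = line.rstrip("\n").rpartition("\t")
            lab = lab.strip()
            if lab not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
            texts.append(text)
            labels.append(int(lab))
    if not texts:
        raise ValueError(f"{path}: no records found")
    y = np.asarray(labels, dtype=np.int64)
    logger.info(
        "read %d sentiment lines from %s (%d positive)", len(texts), path, int(y.sum())
    )
    return texts, y


def write_promoter_file(path: str, sequences: list[str], labels: np.ndarray) -> None:
    with open(path, "w") as fh:
        for i, (seq, lab) in enumerate(zip(sequences, labels)):
            fh.write(f"{'+' if lab == 1 else '-'},S{i:05d},{seq}\n")


def write_wisdm_csv(path: str, series: list[RawSeries]) -> None:
    # emits the 3 raw axes only; the reader reconstructs the magnitude channel
    with open(path, "w") as fh:
        for s in series:
            for t in range(len(s)):
                x, y, z = s.channels[t, :3]
                fh.write(f"{s.subject_id},{s.labels[t]},{s.timestamps[t]:.6f},{x:.6f},{y:.6f},{z:.6f};\n")


def write_sentiment_file(path: str, texts: list[str], labels: np.ndarray) -> None:
    with open(path, "w") as fh:
        for text, lab in zip(texts, labels):
            fh.write(f"{text}\t{int(lab)}\n")
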