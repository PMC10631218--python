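"""Core data containers shared across the package.

A :class:`LabeledDataset` is the single in-memory currency of the pipeline:
a dense numeric tensor ``X`` whose trailing dimensions depend on the data
modality, integer class labels ``y``, and the ordered class names.  The four
modalities are

``timeseries``
    windowed sensor signals, ``X`` of shape ``(n, window_len, channels)``;
``sequence``
    one-hot encoded DNA, ``X`` of shape ``(n, L, 4)`` with channel order
    ``(a, c, g, t)``;
``text``
    tokenized documents, ``X`` of shape ``(n, max_len)`` holding integer
    token indices;
``flat``
    a plain feature table, ``X`` of shape ``(n, d)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("timeseries", "sequence", "text", "flat")


@dataclass
class RawSeries:
    """A single subject's multichannel recording with per-timestep labels.

    Parameters
    ----------
    subject_id
        Opaque subject identifier; windows never cross subjects.
    timestamps
        Strictly increasing times in seconds, one per timestep.
    channels
        Array of shape ``(T, C)`` with sensor readings.
    labels
        Length-``T`` sequence of class strings, one per timestep.
    """

    subject_id: object
    timestamps: np.ndarray
    channels: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        T = self.timestamps.shape[0]
        if self.channels.shape[0] != T or self.labels.shape[0] != T:
            raise ValueError(
                f"subject {self.subject_id!r}: timestamps ({T}), channels "
                f"({self.channels.shape[0]}) and labels ({self.labels.shape[0]}) "
                "must have equal length"
            )
        if T > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError(
                f"subject {self.subject_id!r}: timestamps must be strictly increasing"
            )

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]

    def __len__(self) -> int:
        return self.timestamps.shape[0]


@dataclass
class LabeledDataset:
    """Dense examples plus integer labels for one modality."""

    X: np.ndarray
    y: np.ndarray
    modality: str
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.X.shape[0] < 1:
            raise ValueError("dataset must contain at least one example")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must be a vector aligned with the rows of X")
        if not self.class_names:
            self.class_names = [str(c) for c in range(int(self.y.max()) + 1 if self.y.size else 0)]
        k = len(self.class_names)
        if self.y.min() < 0 or self.y.max() >= k:
            raise ValueError(f"labels must lie in [0, {k}); got range [{self.y.min()}, {self.y.max()}]")
        if self.modality == "sequence":
            sums = self.X.sum(axis=-1)
            if not np.allclose(sums, 1.0):
                raise ValueError("one-hot sequence rows must each sum to exactly 1")
        if self.modality == "text":
            if not np.issubdtype(self.X.dtype, np.integer):
                raise ValueError("text modality requires integer token indices")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def input_shape(self) -> tuple[int, ...]:
        return tuple(self.X.shape[1:])

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        """Row-subset preserving modality and class names."""
        idx = np.asarray(idx)
        return LabeledDataset(self.X[idx], self.y[idx], self.modality, list(self.class_names))

    def flat_features(self) -> np.ndarray:
        """Examples flattened to ``(n, d)`` in row-major (position, channel) order."""
        return self.X.reshape(self.n, -1)


@dataclass(frozen=True)
class SplitSpec:
    """Random train/validation/test split specification.

    ``train_frac`` of the data is drawn for training and ``val_frac_of_train``
    of that is held back for validation; the remainder is the test set.
    """

    train_frac: float = 0.8
    val_frac_of_train: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie strictly between 0 and 1")
        if not 0.0 <= self.val_frac_of_train < 1.0:
            raise ValueError("val_frac_of_train must lie in [0, 1)")
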