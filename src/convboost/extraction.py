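"""Re-express data as the activations of an internal network layer.

The trained network defines, for each catalog layer, a deterministic map from
an input example to that layer's post-activation output (dropout disabled,
batch-norm using its learned population statistics).  Extraction evaluates
this truncated forward pass and flattens any multi-axis output in row-major
(position, channel) order, so feature ``j`` of a conv/pool layer with ``C``
channels corresponds to position ``j // C`` and channel ``j % C``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np

from .network import TrainedNetwork


@dataclass
class FeatureMatrix:
    """``(n, d)`` feature values with their extraction-layer provenance."""

    values: np.ndarray
    layer_index: int
    layer_name: str
    source: str = ""
    n_extracted: int | None = None  # columns from the network; the rest are handcrafted

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.n_extracted is None:
            self.n_extracted = self.values.shape[1]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def column_coordinate(self, j: int, channels: int | None = None) -> str:
        """Human-readable layer coordinate of feature column ``j``."""
        if j >= self.n_extracted:
            return f"handcrafted[{j - self.n_extracted}]"
        if channels:
            return f"{self.layer_name}[pos={j // channels},ch={j % channels}]"
        return f"{self.layer_name}[{j}]"


def extract_features(trained: TrainedNetwork, layer: int, X: np.ndarray,
                     batch_size: int = 512) -> FeatureMatrix:
    """Activations of catalog layer ``layer`` (1-based) for every row of ``X``.

    Runs in inference mode, so repeated calls are byte-identical.  Raises an
    error listing the catalog if ``layer`` is out of range.
    """
    entry = trained.catalog[layer]  # raises IndexError with the catalog listing
    n = np.asarray(X).shape[0]
    chunks = []
    for s in range(0, n, batch_size):
        act = trained.net.forward_capture(X[s : s + batch_size], layer)
        chunks.append(act.reshape(act.shape[0], -1))
    values = np.vstack(chunks)
    return FeatureMatrix(values, layer_index=layer, layer_name=entry.name,
                         source=f"{trained.spec.n_blocks}-block network, seed {trained.seed}")


def concat_handcrafted(fm: FeatureMatrix, handcrafted: np.ndarray) -> FeatureMatrix:
    """Column-concatenate handcrafted features after the extracted ones."""
    handcrafted = np.atleast_2d(np.asarray(handcrafted, dtype=float))
    if handcrafted.shape[1] == 0:
        return FeatureMatrix(fm.values.copy(), fm.layer_index, fm.layer_name,
                             fm.source, fm.n_extracted)
    if handcrafted.shape[0] != fm.n:
        raise ValueError(
            f"row mismatch: {fm.n} extracted rows vs {handcrafted.shape[0]} handcrafted rows"
        )
    values = np.hstack([fm.values, handcrafted])
    return FeatureMatrix(values, fm.layer_index, fm.layer_name,
                         fm.source + " + handcrafted", n_extracted=fm.n_extracted)


@dataclass(frozen=True)
class OverfitReport:
    n: int
    d: int
    sqrt_n: float
    at_risk: bool

    def __str__(self) -> str:
        verdict = "overfit risk" if self.at_risk else "no overfit risk"
        return f"d={self.d} vs sqrt(n)={self.sqrt_n:.1f} (n={self.n}): {verdict}"


def overfit_diagnostic(n: int, d: int) -> OverfitReport:
    """Rule-of-thumb dimensionality check: flags risk whenever ``d >= sqrt(n)``.

    Keeping the feature count below the square root of the sample size is a
    common heuristic for avoiding overfit in small-sample classification;
    datasets violating it benefit most from a compact learned representation.
    """
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    root = float(np.sqrt(n))
    return OverfitReport(n=n, d=d, sqrt_n=root, at_risk=d >= root)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def save_feature_matrix(fm: FeatureMatrix, path: str) -> None:
    """Write a gzip TSV: a # header naming the layer, then one row per example."""
    with gzip.open(path, "wt") as fh:
        fh.write(f"# layer_index={fm.layer_index}\tlayer_name={fm.layer_name}"
                 f"\tn_extracted={fm.n_extracted}\tsource={fm.source}\n")
        fh.write("\t".join(f"f{j}" for j in range(fm.d)) + "\n")
        for row in fm.values:
            fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")


def load_feature_matrix(path: str) -> FeatureMatrix:
    with gzip.open(path, "rt") as fh:
        header = fh.readline().lstrip("# ").rstrip("\n")
        meta = dict(kv.split("=", 1) for kv in header.split("\t"))
        fh.readline()  # column names
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return FeatureMatrix(values, int(meta["layer_index"]), meta["layer_name"],
                         meta.get("source", ""), int(meta["n_extracted"]))
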