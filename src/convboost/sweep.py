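"""Experimental protocol: block growing, layer sweeps, baselines, learning curves.

The central loop trains a ``b``-block network, re-expresses the data at every
catalog layer, fits the boosted-tree classifier on each representation, and
grows ``b`` until the best-over-layers accuracy no longer improves.  Accuracy
is always reported on the held-out test partition; by default the best
(blocks, layer) configuration is *selected* on the validation split, with
``selection="test"`` available to reproduce protocols that select directly on
the test set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .boosted import evaluate_accuracy, fit_trees
from .containers import LabeledDataset
from .extraction import extract_features
from .network import ArchitectureSpec, TrainedNetwork, build_network, predict, train_network

logger = logging.getLogger(__name__)


def _child_seed(seed: int, *branch: int) -> int:
    """Deterministic sub-seed below 2**31 for one branch of the protocol."""
    h = seed & 0x7FFFFFFF
    for b in branch:
        h = (h * 1_000_003 + b + 1) % (2**31 - 1)
    return h


@dataclass
class SweepResult:
    """Accuracy grid over (n_blocks, layer) plus the selected configuration."""

    grid: dict[tuple[int, int], float]          # selection-split accuracy
    test_grid: dict[tuple[int, int], float]     # held-out test accuracy
    dl_alone: dict[int, float]                  # n_blocks -> DL-alone test accuracy
    ml_raw: float                               # trees on raw features, test accuracy
    best: tuple[int, int, float]                # (n_blocks, layer, grid accuracy)
    best_test_accuracy: float
    selection: str
    layer_names: dict[tuple[int, int], str] = field(default_factory=dict)
    seed: int = 0

    def recompute_best(self) -> tuple[int, int, float]:
        """Best config from the stored grid: max accuracy, ties -> fewer blocks, then shallower layer."""
        best_acc = max(self.grid.values())
        for key in sorted(self.grid):
            if self.grid[key] == best_acc:
                return (key[0], key[1], best_acc)
        raise AssertionError("empty grid")


@dataclass
class LearningCurveResult:
    sample_sizes: list[int]
    hybrid_acc: list[float]                     # mean over replicates per size
    dl_acc: list[float]
    hybrid_replicates: dict[int, list[float]]
    dl_replicates: dict[int, list[float]]
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.sample_sizes, self.sample_sizes[1:])):
            raise ValueError("sample_sizes must be strictly increasing")


def train_for_blocks(
    spec: ArchitectureSpec,
    train: LabeledDataset,
    val: LabeledDataset,
    seed: int,
    max_epochs: int = 100,
    patience: int = 10,
    batch_size: int = 32,
) -> TrainedNetwork:
    """Build and train one network from scratch for ``spec.n_blocks`` blocks."""
    net, catalog = build_network(spec, train.n_classes, seed=seed)
    return train_network(net, catalog, spec, train, val,
                         max_epochs=max_epochs, patience=patience,
                         batch_size=batch_size, seed=seed)


def run_layer_sweep(
    trained: TrainedNetwork,
    train: LabeledDataset,
    eval_set: LabeledDataset,
    seed: int = 0,
) -> dict[int, float]:
    """Accuracy of trees on every catalog layer's features, evaluated on ``eval_set``."""
    out: dict[int, float] = {}
    for entry in trained.catalog:
        fm_tr = extract_features(trained, entry.index, train.X)
        fm_ev = extract_features(trained, entry.index, eval_set.X)
        model = fit_trees(fm_tr, train.y, seed=_child_seed(seed, entry.index))
        out[entry.index] = evaluate_accuracy(model, fm_ev, eval_set.y)
    return out


def _layer_sweep_two_splits(
    trained: TrainedNetwork,
    train: LabeledDataset,
    val: LabeledDataset,
    test: LabeledDataset,
    seed: int,
) -> dict[int, tuple[float, float]]:
    """Per layer (val accuracy, test accuracy) with a single tree fit per layer."""
    out: dict[int, tuple[float, float]] = {}
    for entry in trained.catalog:
        fm_tr = extract_features(trained, entry.index, train.X)
        model = fit_trees(fm_tr, train.y, seed=_child_seed(seed, entry.index))
        va = evaluate_accuracy(model, extract_features(trained, entry.index, val.X), val.y)
        ta = evaluate_accuracy(model, extract_features(trained, entry.index, test.X), test.y)
        out[entry.index] = (va, ta)
    return out


def run_block_sweep(
    train: LabeledDataset,
    val: LabeledDataset,
    test: LabeledDataset,
    base_spec: ArchitectureSpec,
    max_blocks: int = 5,
    seed: int = 0,
    selection: str = "val",
    max_epochs: int = 100,
    patience: int = 10,
    batch_size: int = 32,
) -> SweepResult:
    """Grow blocks, sweep layers, stop when best-over-layers accuracy stops improving.

    For each block count the network is retrained from scratch.  Growth stops
    when the best-over-layers selection accuracy at ``b`` is <= the best at
    ``b - 1``, at ``max_blocks``, or when the input is too small for another
    block.  Ties for the overall best break toward fewer blocks, then the
    shallower layer.
    """
    if max_blocks < 1:
        raise ValueError("max_blocks must be >= 1")
    if selection not in ("val", "test"):
        raise ValueError("selection must be 'val' or 'test'")
    grid: dict[tuple[int, int], float] = {}
    test_grid: dict[tuple[int, int], float] = {}
    dl_alone: dict[int, float] = {}
    layer_names: dict[tuple[int, int], str] = {}
    best_per_block: dict[int, float] = {}

    raw_model = fit_trees(train.flat_features(), train.y, seed=_child_seed(seed, 0))
    ml_raw = evaluate_accuracy(raw_model, test.flat_features(), test.y)

    for b in range(1, max_blocks + 1):
        spec_b = base_spec.with_blocks(b)
        try:
            trained = train_for_blocks(spec_b, train, val, seed=_child_seed(seed, b),
                                       max_epochs=max_epochs, patience=patience,
                                       batch_size=batch_size)
        except ValueError as exc:
            logger.info("stopping block growth at b=%d: %s", b, exc)
            break
        _, pred = predict(trained, test.X)
        dl_alone[b] = float((pred == test.y).mean())
        per_layer = _layer_sweep_two_splits(trained, train, val, test, seed)
        for layer, (va, ta) in per_layer.items():
            grid[(b, layer)] = va if selection == "val" else ta
            test_grid[(b, layer)] = ta
            layer_names[(b, layer)] = trained.catalog[layer].name
        best_per_block[b] = max(grid[(b, l)] for l in per_layer)
        logger.info("block %d: best-over-layers %s accuracy %.4f, DL-alone test %.4f",
                    b, selection, best_per_block[b], dl_alone[b])
        if b > 1 and best_per_block[b] <= best_per_block[b - 1]:
            break

    if not grid:
        raise ValueError("no block count could be trained on this input")
    result = SweepResult(grid=grid, test_grid=test_grid, dl_alone=dl_alone, ml_raw=ml_raw,
                         best=(0, 0, 0.0), best_test_accuracy=0.0, selection=selection,
                         layer_names=layer_names, seed=seed)
    result.best = result.recompute_best()
    result.best_test_accuracy = test_grid[(result.best[0], result.best[1])]
    return result


def run_baselines(
    train: LabeledDataset,
    val: LabeledDataset,
    test: LabeledDataset,
    spec: ArchitectureSpec,
    seed: int = 0,
    handcrafted: tuple[np.ndarray, np.ndarray] | None = None,
    max_epochs: int = 100,
    patience: int = 10,
    batch_size: int = 32,
) -> tuple[float, float]:
    """(DL-alone test accuracy, trees-on-raw test accuracy) for one architecture.

    ``handcrafted`` optionally supplies (train, test) feature tables to use in
    place of the flattened raw tensors for the tree baseline.
    """
    trained = train_for_blocks(spec, train, val, seed=_child_seed(seed, 900),
                               max_epochs=max_epochs, patience=patience, batch_size=batch_size)
    _, pred = predict(trained, test.X)
    dl_acc = float((pred == test.y).mean())
    if handcrafted is not None:
        Xtr, Xte = handcrafted
    else:
        Xtr, Xte = train.flat_features(), test.flat_features()
    model = fit_trees(Xtr, train.y, seed=_child_seed(seed, 901))
    ml_acc = evaluate_accuracy(model, Xte, test.y)
    return dl_acc, ml_acc


def stratified_subsample(y: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Class-stratified index sample of ``size`` rows (every class represented)."""
    n = y.shape[0]
    if size > n:
        raise ValueError(f"requested size {size} exceeds available {n}")
    classes, counts = np.unique(y, return_counts=True)
    fractions = size * counts / n
    alloc = np.floor(fractions).astype(int)
    alloc[alloc == 0] = 1
    while alloc.sum() > size:
        alloc[np.argmax(alloc)] -= 1
    order = np.argsort(-(fractions - alloc))
    for i in range(size - alloc.sum()):
        alloc[order[i % len(classes)]] += 1
    idx = []
    for c, a in zip(classes, alloc):
        pool = np.flatnonzero(y == c)
        idx.append(rng.choice(pool, size=min(a, pool.size), replace=False))
    return np.concatenate(idx)


def run_learning_curve(
    pool: LabeledDataset,
    val: LabeledDataset,
    test: LabeledDataset,
    spec: ArchitectureSpec,
    sizes: list[int],
    replicates: int = 5,
    seed: int = 0,
    max_epochs: int = 100,
    patience: int = 10,
    batch_size: int = 32,
) -> LearningCurveResult:
    """Hybrid vs DL-alone accuracy as the training-set size grows.

    For each size and replicate a class-stratified subsample of ``pool``
    trains the network from scratch; the hybrid accuracy is the best over all
    extraction layers (trees refit per layer) on the test set, mirroring the
    report-the-best-layer protocol, and the DL-alone accuracy is the same
    network's own test accuracy.
    """
    if any(s > pool.n for s in sizes):
        raise ValueError(f"a requested size exceeds the available pool of {pool.n}")
    hybrid_reps: dict[int, list[float]] = {s: [] for s in sizes}
    dl_reps: dict[int, list[float]] = {s: [] for s in sizes}
    for si, size in enumerate(sizes):
        for rep in range(replicates):
            sub_seed = _child_seed(seed, si, rep)
            rng = np.random.default_rng(sub_seed)
            sub = pool.subset(stratified_subsample(pool.y, size, rng))
            trained = train_for_blocks(spec, sub, val, seed=sub_seed,
                                       max_epochs=max_epochs, patience=patience,
                                       batch_size=batch_size)
            _, pred = predict(trained, test.X)
            dl_reps[size].append(float((pred == test.y).mean()))
            per_layer = run_layer_sweep(trained, sub, test, seed=sub_seed)
            hybrid_reps[size].append(max(per_layer.values()))
        logger.info("size %d: hybrid %.4f, DL-alone %.4f (means over %d replicates)",
                    size, float(np.mean(hybrid_reps[size])), float(np.mean(dl_reps[size])),
                    replicates)
    return LearningCurveResult(
        sample_sizes=list(sizes),
        hybrid_acc=[float(np.mean(hybrid_reps[s])) for s in sizes],
        dl_acc=[float(np.mean(dl_reps[s])) for s in sizes],
        hybrid_replicates=hybrid_reps,
        dl_replicates=dl_reps,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tidy exports
# ---------------------------------------------------------------------------

def sweep_to_tsv(result: SweepResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("n_blocks\tlayer_index\tlayer_name\taccuracy\ttest_accuracy\n")
        for (b, l) in sorted(result.grid):
            fh.write(f"{b}\t{l}\t{result.layer_names.get((b, l), '')}"
                     f"\t{result.grid[(b, l)]:.6f}\t{result.test_grid[(b, l)]:.6f}\n")


def sweep_summary_json(result: SweepResult, path: str) -> None:
    b, l, acc = result.best
    with open(path, "w") as fh:
        json.dump({
            "best_n_blocks": b,
            "best_layer_index": l,
            "best_layer_name": result.layer_names.get((b, l), ""),
            "best_selection_accuracy": acc,
            "best_test_accuracy": result.best_test_accuracy,
            "selection": result.selection,
            "dl_alone": {str(k): v for k, v in result.dl_alone.items()},
            "ml_raw": result.ml_raw,
            "seed": result.seed,
        }, fh, indent=2)


def curve_to_tsv(result: LearningCurveResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("size\tmethod\treplicate\taccuracy\n")
        for s in result.sample_sizes:
            for r, a in enumerate(result.hybrid_replicates[s]):
                fh.write(f"{s}\thybrid\t{r}\t{a:.6f}\n")
            for r, a in enumerate(result.dl_replicates[s]):
                fh.write(f"{s}\tdl_alone\t{r}\t{a:.6f}\n")
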