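"""Named architecture and preprocessing recipes for the benchmark tasks.

Each recipe bundles the per-modality architecture variant: kernel 3 with Adam
for activity signals and genomic sequences (pool 2), kernel 5 with an
embedding layer, pool 3, a sigmoid head and RMSprop for text.  Recipes return
fresh :class:`ArchitectureSpec` objects; the input shape is filled in from
the data at build time.
"""

from __future__ import annotations

from .network import ArchitectureSpec


def genomic_spec(length: int = 57, n_blocks: int = 1) -> ArchitectureSpec:
    """Promoter-style one-hot DNA: kernel 3, pool 2, dense 64 -> 1 sigmoid, Adam."""
    return ArchitectureSpec(
        n_blocks=n_blocks, kernel_size=3, pool_size=2, dense_sizes=(64, 1),
        output_activation="sigmoid", optimizer="adam", input_shape=(length, 4),
    )


def activity_spec(window_len: int = 80, channels: int = 4, n_blocks: int = 1) -> ArchitectureSpec:
    """Windowed sensor signals: kernel 3, pool 2, dense 256/128, softmax, Adam."""
    return ArchitectureSpec(
        n_blocks=n_blocks, kernel_size=3, pool_size=2, dense_sizes=(256, 128),
        output_activation="softmax", optimizer="adam", input_shape=(window_len, channels),
    )


def text_spec(vocab_size: int = 10_000, max_len: int = 100, embed_dim: int = 64,
              n_blocks: int = 1) -> ArchitectureSpec:
    """Tokenized text: embedding, kernel 5, pool 3, dense 64 -> 1 sigmoid, RMSprop."""
    return ArchitectureSpec(
        n_blocks=n_blocks, kernel_size=5, pool_size=3, dense_sizes=(64, 1),
        output_activation="sigmoid", optimizer="rmsprop",
        embedding=(vocab_size, embed_dim), input_shape=(max_len,),
    )


def flat_spec(d: int, n_classes: int = 2, n_blocks: int = 1) -> ArchitectureSpec:
    """Precomputed feature tables treated as a length-d single-channel signal."""
    return ArchitectureSpec(
        n_blocks=n_blocks, kernel_size=3, pool_size=2, dense_sizes=(256, 128),
        output_activation="softmax" if n_classes > 2 else "sigmoid",
        optimizer="adam", input_shape=(d, 1),
    )


RECIPES = {
    "promoter": lambda: genomic_spec(),
    "wisdm": lambda: activity_spec(),
    "har": lambda: flat_spec(561, n_classes=6),
    "amazon": lambda: text_spec(),
    "imdb": lambda: text_spec(),
    "yelp": lambda: text_spec(),
}

# dataset-specific preprocessing constants
RATING_THRESHOLDS = {"amazon": 2.0, "imdb": 2.5, "yelp": 2.5}
WISDM_TIME_PERIOD = 80
WISDM_TIME_STEP = 40
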