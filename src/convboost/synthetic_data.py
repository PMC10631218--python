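"""Seeded synthetic datasets with known, recoverable structure.

Three generators emulate the pipeline's three modalities:

* :func:`gen_motif_sequences` — balanced two-class DNA sequences where the
  positive class carries one (possibly mutated) copy of a planted motif, at a
  fixed or random position, over an i.i.d. background.  Random placement is
  the default: it is the regime where position-invariant convolutional
  features should beat trees on the raw one-hot encoding, while fixed
  placement gives trees on raw features a directly visible signal — the two
  controlled sides of the hybrid-vs-baseline comparison.
* :func:`gen_activity_series` — per-subject multichannel sinusoid recordings
  whose frequency signature is class-conditioned, plus Gaussian noise; after
  sliding-window segmentation the windows are learnable.
* :func:`gen_token_sequences` — integer token sequences where the positive
  class over-samples a marked token subset by a configurable bias factor.

Every generator is a pure function of its config (same seed, same output) and
can emit files in the exact dialects the readers parse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import RawSeries
from .data_io import DNA_ALPHABET

DEFAULT_MOTIF = "tataatgca"[:8]  # 8-base TATA-like planted motif


@dataclass
class MotifGeneratorConfig:
    """Planted-motif DNA generator settings (promoter-task scale by default)."""

    n: int = 106
    length: int = 57
    motif: str = DEFAULT_MOTIF
    mutation_prob: float = 0.15
    placement: str = "random"  # "fixed" (position 20) or "random"
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    fixed_position: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.motif) > self.length:
            raise ValueError("motif longer than sequence length")
        if not 0.0 <= self.mutation_prob < 1.0:
            raise ValueError("mutation_prob must lie in [0, 1)")
        if self.placement not in ("fixed", "random"):
            raise ValueError("placement must be 'fixed' or 'random'")
        if abs(sum(self.background) - 1.0) > 1e-9 or any(p < 0 for p in self.background):
            raise ValueError("background base frequencies must be non-negative and sum to 1")
        if any(c not in DNA_ALPHABET for c in self.motif.lower()):
            raise ValueError("motif must be over {a,c,g,t}")


def gen_motif_sequences(cfg: MotifGeneratorConfig) -> tuple[list[str], np.ndarray]:
    """Balanced sequences + binary labels; positives carry the planted motif.

    Positives number ``ceil(n/2)`` and negatives ``floor(n/2)``.  Each
    positive receives one copy of the motif whose bases are independently
    mutated to a uniformly-drawn different base with ``mutation_prob``;
    negatives are pure background.
    """
    rng = np.random.default_rng(cfg.seed)
    bases = np.array(list(DNA_ALPHABET))
    n_pos = (cfg.n + 1) // 2
    motif_codes = np.array([DNA_ALPHABET.index(c) for c in cfg.motif.lower()])
    m = len(motif_codes)
    seqs: list[str] = []
    labels = np.concatenate([np.ones(n_pos, dtype=np.int64),
                             np.zeros(cfg.n - n_pos, dtype=np.int64)])
    for i in range(cfg.n):
        codes = rng.choice(4, size=cfg.length, p=cfg.background)
        if labels[i] == 1:
            inserted = motif_codes.copy()
            mutate = rng.random(m) < cfg.mutation_prob
            # mutated base is always a *different* base
            shift = rng.integers(1, 4, size=m)
            inserted[mutate] = (inserted[mutate] + shift[mutate]) % 4
            if cfg.placement == "fixed":
                start = min(cfg.fixed_position, cfg.length - m)
            else:
                start = int(rng.integers(0, cfg.length - m + 1))
            codes[start : start + m] = inserted
        seqs.append("".join(bases[codes]))
    return seqs, labels


@dataclass
class SignalGeneratorConfig:
    """Class-conditioned sinusoid activity generator.

    Each subject performs every activity for ``run_length`` consecutive
    timesteps at ``sample_hz``.  Activity ``k`` oscillates at
    ``base_freq + k * freq_step`` Hz with amplitude ``base_amp + k * amp_step``;
    channels differ by phase, and i.i.d. Gaussian noise of ``noise_sd`` is
    added throughout.
    """

    n_subjects: int = 6
    classes: int = 6
    channels: int = 4
    run_length: int = 400
    sample_hz: float = 20.0
    base_freq: float = 0.5
    freq_step: float = 0.45
    base_amp: float = 1.0
    amp_step: float = 0.15
    noise_sd: float = 0.3
    class_names: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.class_names:
            self.class_names = tuple(f"activity{k}" for k in range(self.classes))


def gen_activity_series(cfg: SignalGeneratorConfig) -> list[RawSeries]:
    """One :class:`RawSeries` per subject: all activities in consecutive runs."""
    rng = np.random.default_rng(cfg.seed)
    series = []
    dt = 1.0 / cfg.sample_hz
    for s in range(cfg.n_subjects):
        order = rng.permutation(cfg.classes)
        T = cfg.classes * cfg.run_length
        t = np.arange(T) * dt
        channels = np.zeros((T, cfg.channels))
        labels = np.empty(T, dtype=object)
        phases = rng.uniform(0, 2 * np.pi, size=cfg.channels)
        for run, k in enumerate(order):
            sl = slice(run * cfg.run_length, (run + 1) * cfg.run_length)
            f = cfg.base_freq + k * cfg.freq_step
            a = cfg.base_amp + k * cfg.amp_step
            for c in range(cfg.channels):
                channels[sl, c] = a * np.sin(2 * np.pi * f * t[sl] + phases[c])
            labels[sl] = cfg.class_names[k]
        channels += rng.normal(0, cfg.noise_sd, size=channels.shape)
        series.append(RawSeries(f"subject{s}", t, channels, labels))
    return series


def fft_magnitude_features(X: np.ndarray) -> np.ndarray:
    """Handcrafted per-window features: FFT magnitudes of each channel.

    ``X`` of shape ``(n, T, C)`` maps to ``(n, (T//2+1) * C)`` — the classic
    frequency-domain summary used as the handcrafted baseline for
    activity-signal windows.
    """
    mags = np.abs(np.fft.rfft(X, axis=1))
    return mags.reshape(X.shape[0], -1)


def gen_token_sequences(
    n: int,
    vocab_size: int = 1000,
    max_len: int = 100,
    class_token_bias: float = 4.0,
    marked_frac: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer token sequences where class 1 over-samples a marked token subset.

    Tokens are drawn from ``[2, vocab_size)`` (0 = pad, 1 = OOV are never
    generated).  A fraction ``marked_frac`` of the vocabulary is marked; class
    1 draws marked tokens with probability multiplied by ``class_token_bias``
    (renormalized).  ``class_token_bias = 1`` yields identical class
    distributions (accuracy at chance for any classifier); large bias drives
    the classes toward disjoint token support.
    """
    if class_token_bias <= 0:
        raise ValueError("class_token_bias must be > 0")
    rng = np.random.default_rng(seed)
    n_real = vocab_size - 2
    base = 1.0 / (np.arange(1, n_real + 1))  # Zipf-like background frequencies
    base /= base.sum()
    n_marked = max(1, int(round(marked_frac * n_real)))
    marked = rng.choice(n_real, size=n_marked, replace=False)
    pos = base.copy()
    pos[marked] *= class_token_bias
    pos /= pos.sum()
    n_pos = (n + 1) // 2
    labels = np.concatenate([np.ones(n_pos, dtype=np.int64), np.zeros(n - n_pos, dtype=np.int64)])
    X = np.empty((n, max_len), dtype=np.int64)
    for i in range(n):
        p = pos if labels[i] == 1 else base
        X[i] = rng.choice(n_real, size=max_len, p=p) + 2
    return X, labels
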