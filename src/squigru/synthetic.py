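"""Self-contained synthetic study data: pore model, sequences, target signals.

Real supervised data for the signal-processing network needs flowcell reads
plus the vendor's 6-mer table.  This module generates a stand-in for all of
it so the whole pipeline can be exercised and tested offline:

* a synthetic pore model assigning every 6-mer a reproducible level in
  [60, 120] pA;
* uniform random nucleotide sequences;
* "real-like" target signals built from the ground truth by smoothing *only
  the level transitions* (short triangular kernel) and adding Gaussian noise
  in normalized units.

Smoothing only the transitions encodes the qualitative difference between a
real pore trace and a square wave: within a 6-mer the level is flat, while
the change-over between 6-mers is gradual.  A global low-pass filter cannot
reproduce that, so a network trained on these data has something genuine to
learn - which is exactly what makes the filter-vs-network comparison
meaningful on synthetic data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ValidationError
from .pore_model import ExpectedSignal, PoreModel, expected_signal
from .synthesis import (
    DEFAULT_REPEAT_MODEL,
    GroundTruthSignal,
    NormStats,
    RepeatModel,
    assemble_ground_truth,
    sample_repeat_counts,
    zscore_normalize,
)
from .training import TrainingPair

_BASES = "ACGT"
LEVEL_RANGE_PA = (60.0, 120.0)


def synthetic_pore_model(seed: int) -> PoreModel:
    """All 4096 6-mers mapped to uniform pseudo-random levels in [60, 120] pA."""
    rng = np.random.default_rng(seed)
    kmers = ["".join(p) for p in itertools.product(_BASES, repeat=6)]
    lo, hi = LEVEL_RANGE_PA
    levels = rng.uniform(lo, hi, size=len(kmers))
    return PoreModel(levels=dict(zip(kmers, levels)))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform i.i.d. nucleotide string over {A, C, G, T}."""
    if length < 6:
        raise ValidationError(f"sequence length must be >= 6, got {length}")
    idx = rng.integers(0, 4, size=length)
    return "".join(_BASES[i] for i in idx)


def _triangular_kernel(taps: int) -> np.ndarray:
    if taps < 1 or taps % 2 == 0:
        raise ValidationError(f"edge_smooth_taps must be an odd integer >= 1, got {taps}")
    half = taps // 2
    k = 1.0 - np.abs(np.arange(taps) - half) / (half + 1.0)
    return k / k.sum()


def synthesize_real_like(
    ground_truth: GroundTruthSignal | np.ndarray,
    edge_smooth_taps: int = 5,
    noise_std: float = 0.15,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Target signal: transition-smoothed square wave plus Gaussian noise.

    The triangular kernel has unit sum, so flat stretches pass unchanged and
    only the samples around level changes move.  Length is preserved via edge
    replication.
    """
    values = ground_truth.values if isinstance(ground_truth, GroundTruthSignal) else np.asarray(ground_truth, dtype=float)
    kernel = _triangular_kernel(edge_smooth_taps)
    half = edge_smooth_taps // 2
    if half:
        padded = np.pad(values, half, mode="edge")
        smoothed = np.convolve(padded, kernel, mode="valid")
    else:
        smoothed = values.copy()
    if noise_std < 0:
        raise ValidationError("noise_std must be >= 0")
    if noise_std > 0:
        if rng is None:
            rng = np.random.default_rng()
        smoothed = smoothed + rng.normal(0.0, noise_std, size=smoothed.shape)
    return smoothed


@dataclass(frozen=True)
class DatasetConfig:
    """Generation knobs for :func:`make_dataset` (noise in normalized units)."""

    edge_smooth_taps: int = 5
    noise_std: float = 0.15
    repeat_model: RepeatModel = field(default=DEFAULT_REPEAT_MODEL)
    pore_model_seed: int = 20_001


DEFAULT_DATASET_CONFIG = DatasetConfig()


@dataclass(frozen=True)
class SyntheticRead:
    """One generated read with every intermediate kept for evaluation."""

    sequence: str
    expected: ExpectedSignal
    repeats: np.ndarray
    ground_truth: GroundTruthSignal
    stats: NormStats
    input: np.ndarray   # z-scored ground truth
    target: np.ndarray  # transition-smoothed input + noise

    def pair(self, provenance: str = "") -> TrainingPair:
        return TrainingPair(input=self.input, target=self.target, provenance=provenance)


def generate_reads(
    n_reads: int,
    seq_length: int,
    config: DatasetConfig = DEFAULT_DATASET_CONFIG,
    seed: int = 0,
) -> list[SyntheticRead]:
    """Full simulation chain per read, deterministic in ``seed``."""
    if n_reads < 1:
        raise ValidationError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    pore = synthetic_pore_model(config.pore_model_seed)
    reads = []
    for _ in range(n_reads):
        seq = random_sequence(seq_length, rng)
        exp = expected_signal(seq, pore)
        repeats = sample_repeat_counts(len(exp), config.repeat_model, rng)
        gt = assemble_ground_truth(exp, repeats)
        normalized, stats = zscore_normalize(gt.values)
        target = synthesize_real_like(
            normalized, config.edge_smooth_taps, config.noise_std, rng
        )
        reads.append(
            SyntheticRead(
                sequence=seq,
                expected=exp,
                repeats=repeats,
                ground_truth=gt,
                stats=stats,
                input=normalized,
                target=target,
            )
        )
    return reads


def make_dataset(
    n_reads: int,
    seq_length: int = 500,
    config: DatasetConfig = DEFAULT_DATASET_CONFIG,
    seed: int = 0,
) -> tuple[list[TrainingPair], dict]:
    """Normalized training pairs plus a manifest that regenerates them exactly."""
    reads = generate_reads(n_reads, seq_length, config, seed)
    pairs = [r.pair(provenance=f"synthetic:{seed}:{i}") for i, r in enumerate(reads)]
    manifest = {
        "generator": "squigru.synthetic.make_dataset",
        "seed": seed,
        "n_reads": n_reads,
        "seq_length": seq_length,
        "edge_smooth_taps": config.edge_smooth_taps,
        "noise_std": config.noise_std,
        "pore_model_seed": config.pore_model_seed,
        "repeat_model": {
            "components": [asdict(c) for c in config.repeat_model.components],
            "min_repeat": config.repeat_model.min_repeat,
            "max_repeat": config.repeat_model.max_repeat,
        },
        "level_range_pa": list(LEVEL_RANGE_PA),
    }
    return pairs, manifest
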