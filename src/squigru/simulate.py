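"""End-to-end squiggle simulation: sequence -> expected -> ground truth ->
filtered signal -> noisy raw signal.

The filter stage is selectable: the trained BiGRU network (applied on the
z-scored ground truth and mapped back to pA with the same stats), the
windowed-sinc low-pass baseline, or no filtering at all.  Gaussian noise
(default std 2.0 pA) is added last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bigru import BiGRUNetwork, load_checkpoint, network_forward
from .errors import ValidationError
from .io import SimulationConfig
from .lowpass import FilterSpec, lowpass_filter
from .pore_model import ExpectedSignal, PoreModel, expected_signal
from .synthesis import (
    DEFAULT_REPEAT_MODEL,
    GroundTruthSignal,
    RepeatModel,
    add_gaussian_noise,
    assemble_ground_truth,
    denormalize,
    sample_repeat_counts,
    zscore_normalize,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulatedRead:
    """All stages of one simulated read, ground truth included."""

    read_id: str
    sequence: str
    expected: ExpectedSignal
    ground_truth: GroundTruthSignal
    filtered: np.ndarray
    signal: np.ndarray  # filtered + noise: the final simulated raw signal


def apply_filter(
    ground_truth: GroundTruthSignal,
    config: SimulationConfig,
    net: BiGRUNetwork | None = None,
) -> np.ndarray:
    """Post-process a ground-truth signal according to ``config.filter_mode``."""
    values = ground_truth.values
    if config.filter_mode == "none":
        return values.copy()
    if config.filter_mode == "lowpass":
        spec = FilterSpec(
            cutoff_hz=config.cutoff_hz,
            sample_rate_hz=config.sample_rate_hz,
            kernel_length=config.kernel_length,
        )
        return lowpass_filter(values, spec)
    if net is None:
        if not config.model_checkpoint_path:
            raise ValidationError("bigru filtering needs a network or checkpoint path")
        net = load_checkpoint(config.model_checkpoint_path)
    normalized, stats = zscore_normalize(values)
    filtered = network_forward(net, normalized)
    return denormalize(filtered, stats)


def simulate_read(
    sequence: str,
    pore_model: PoreModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    net: BiGRUNetwork | None = None,
    repeat_model: RepeatModel = DEFAULT_REPEAT_MODEL,
    read_id: str = "read",
) -> SimulatedRead:
    """Simulate the raw current signal for one nucleotide sequence."""
    exp = expected_signal(sequence, pore_model)
    repeats = sample_repeat_counts(len(exp), repeat_model, rng)
    gt = assemble_ground_truth(exp, repeats)
    filtered = apply_filter(gt, config, net=net)
    signal = add_gaussian_noise(filtered, config.noise_std, rng)
    logger.info(
        "simulated read %s: %d bases -> %d samples (filter=%s, noise_std=%g)",
        read_id, len(sequence), len(signal), config.filter_mode, config.noise_std,
    )
    return SimulatedRead(
        read_id=read_id,
        sequence=sequence,
        expected=exp,
        ground_truth=gt,
        filtered=filtered,
        signal=signal,
    )


def simulate_reads(
    records: list[tuple[str, str]],
    pore_model: PoreModel,
    config: SimulationConfig,
    repeat_model: RepeatModel = DEFAULT_REPEAT_MODEL,
) -> list[SimulatedRead]:
    """Simulate every (id, sequence) record with one seeded generator."""
    rng = np.random.default_rng(config.seed)
    net = None
    if config.filter_mode == "bigru":
        net = load_checkpoint(config.model_checkpoint_path)
    logger.info("simulation config: %s", config)
    return [
        simulate_read(
            seq, pore_model, config, rng, net=net,
            repeat_model=repeat_model, read_id=rid,
        )
        for rid, seq in records
    ]
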