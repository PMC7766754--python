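"""Ground-truth squiggle assembly: repeat-time sampling, expansion, noise, scaling.

With the R9.4 chemistry DNA translocates at roughly 450 bases/s while the
current is sampled at 4 kHz, so each 6-mer dwells for 8-9 samples on average.
The dwell (repeat) time is modelled as a two-component mixture of
alpha-distributed variables, rounded to the nearest integer and clamped to
``[min_repeat, max_repeat]``.  Repeating each expected level for its sampled
dwell yields the piecewise-constant *ground-truth signal*; adding i.i.d.
Gaussian noise yields a simulated raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .pore_model import ExpectedSignal


@dataclass(frozen=True)
class AlphaComponent:
    """One mixture component: an alpha distribution with shape/location/scale."""

    weight: float
    shape: float
    location: float
    scale: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValidationError(f"component weight must be in (0, 1], got {self.weight}")
        if self.shape <= 0:
            raise ValidationError(f"alpha shape must be > 0, got {self.shape}")
        if self.scale <= 0:
            raise ValidationError(f"alpha scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class RepeatModel:
    """Mixture-alpha model of samples-per-6-mer (dwell time in raw samples)."""

    components: tuple[AlphaComponent, ...]
    min_repeat: int = 1
    max_repeat: int = 40

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("repeat model needs at least one component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"component weights must sum to 1, got {total}")
        if self.min_repeat < 1:
            raise ValidationError("min_repeat must be >= 1")
        if self.min_repeat > self.max_repeat:
            raise ValidationError("min_repeat must be <= max_repeat")


# Calibrated so the clamped-and-rounded mean dwell lands at ~8.8 samples per
# 6-mer, consistent with 450 bp/s translocation sampled at 4 kHz.
DEFAULT_REPEAT_MODEL = RepeatModel(
    components=(
        AlphaComponent(weight=0.7, shape=4.0, location=1.0, scale=28.5),
        AlphaComponent(weight=0.3, shape=6.0, location=2.0, scale=41.0),
    ),
    min_repeat=1,
    max_repeat=40,
)


@dataclass(frozen=True)
class NormStats:
    """Center/spread used to z-score a signal; kept for exact inversion."""

    center: float
    spread: float

    def __post_init__(self) -> None:
        if not self.spread > 0:
            raise ValidationError(f"spread must be > 0, got {self.spread}")


@dataclass(frozen=True)
class GroundTruthSignal:
    """Piecewise-constant signal: one block per expected-signal position."""

    values: np.ndarray
    repeats: np.ndarray
    expected: ExpectedSignal | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        repeats = np.asarray(self.repeats, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "repeats", repeats)
        if len(values) != int(repeats.sum()):
            raise ValidationError(
                f"ground-truth length {len(values)} != sum of repeats {int(repeats.sum())}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def transition_indices(self) -> np.ndarray:
        """Raw-sample indices where a new 6-mer block starts (excluding 0)."""
        return np.cumsum(self.repeats)[:-1]


def sample_repeat_counts(
    n_positions: int,
    model: RepeatModel = DEFAULT_REPEAT_MODEL,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one integer dwell time per expected-signal position.

    Component chosen by weight, a continuous alpha draw taken from it, rounded
    to the nearest integer (ties to even) and clamped to the model bounds.
    """
    if n_positions < 1:
        raise ValidationError("n_positions must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    weights = np.array([c.weight for c in model.components])
    which = rng.choice(len(model.components), size=n_positions, p=weights)
    draws = np.empty(n_positions, dtype=float)
    for k, comp in enumerate(model.components):
        mask = which == k
        n_k = int(mask.sum())
        if n_k:
            draws[mask] = stats.alpha.rvs(
                comp.shape, loc=comp.location, scale=comp.scale,
                size=n_k, random_state=rng,
            )
    counts = np.clip(np.rint(draws), model.min_repeat, model.max_repeat)
    return counts.astype(int)


def assemble_ground_truth(
    expected: ExpectedSignal, repeats: Sequence[int] | np.ndarray
) -> GroundTruthSignal:
    """Expand each expected level into a block of ``repeats[i]`` raw samples."""
    repeats = np.asarray(repeats, dtype=int)
    if len(repeats) != len(expected.values):
        raise ValidationError(
            f"got {len(repeats)} repeat counts for {len(expected.values)} "
            "expected-signal positions"
        )
    if np.any(repeats < 1):
        raise ValidationError("every repeat count must be >= 1")
    values = np.repeat(expected.values, repeats)
    return GroundTruthSignal(values=values, repeats=repeats, expected=expected)


def add_gaussian_noise(
    signal: Sequence[float] | np.ndarray,
    std: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of standard deviation ``std``."""
    if std < 0:
        raise ValidationError(f"noise std must be >= 0, got {std}")
    signal = np.asarray(signal, dtype=float)
    if rng is None:
        rng = np.random.default_rng()
    return signal + rng.normal(0.0, std, size=signal.shape)


def zscore_normalize(signal: Sequence[float] | np.ndarray) -> tuple[np.ndarray, NormStats]:
    """Z-score a signal; returns the stats needed to undo the transform."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise ValidationError("need at least 2 samples to normalize")
    center = float(signal.mean())
    spread = float(signal.std())
    if spread == 0.0:
        raise DegenerateInputError("cannot z-score a constant signal (zero spread)")
    return (signal - center) / spread, NormStats(center=center, spread=spread)


def denormalize(signal: Sequence[float] | np.ndarray, stats_: NormStats) -> np.ndarray:
    """Invert :func:`zscore_normalize`."""
    return np.asarray(signal, dtype=float) * stats_.spread + stats_.center
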