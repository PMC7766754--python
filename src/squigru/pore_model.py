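"""6-mer pore model: k-mer -> expected current level (pA), and sequence conversion.

The pore model maps every 6-base window occupying the nanopore to the mean
ionic current it is expected to produce.  Converting a nucleotide sequence of
length ``T`` through the model yields the *expected signal*: one level per
overlapping 6-mer window, i.e. ``T - 5`` values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import AlphabetError, MissingKmerError, ParseError, ValidationError

KMER_LENGTH = 6
ALPHABET = frozenset("ACGT")
N_KMERS = 4 ** KMER_LENGTH  # 4096


def _validate_kmer(kmer: str) -> None:
    if len(kmer) != KMER_LENGTH:
        raise ValidationError(
            f"k-mer {kmer!r} has length {len(kmer)}, expected {KMER_LENGTH}"
        )
    if not ALPHABET.issuperset(kmer):
        bad = sorted(set(kmer) - ALPHABET)
        raise ValidationError(f"k-mer {kmer!r} contains invalid characters {bad}")


@dataclass(frozen=True)
class PoreModel:
    """Lookup table from 6-mer to expected current level in pA.

    A complete model has exactly 4096 entries (one per 6-mer over ACGT); a
    partial model is valid but can only convert sequences whose windows it
    covers.
    """

    levels: Mapping[str, float]
    kmer_length: int = field(default=KMER_LENGTH)

    def __post_init__(self) -> None:
        if self.kmer_length != KMER_LENGTH:
            raise ValidationError(f"only {KMER_LENGTH}-mer models are supported")
        for kmer, level in self.levels.items():
            _validate_kmer(kmer)
            if not math.isfinite(level):
                raise ValidationError(f"level for {kmer!r} is not finite: {level}")

    def __len__(self) -> int:
        return len(self.levels)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.levels

    def __getitem__(self, kmer: str) -> float:
        return self.levels[kmer]

    @property
    def is_complete(self) -> bool:
        return len(self.levels) == N_KMERS

    def to_tsv(self, path: str | Path) -> None:
        """Write the model as a two-column TSV (k-mer, level mean)."""
        with open(path, "w") as fh:
            fh.write("#kmer\tlevel_mean\n")
            for kmer in sorted(self.levels):
                fh.write(f"{kmer}\t{self.levels[kmer]:.6f}\n")


@dataclass(frozen=True)
class ExpectedSignal:
    """Per-window expected current levels for a source sequence.

    ``values`` has one entry per overlapping 6-mer window, so its length is
    ``source_length - 5``.
    """

    values: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValidationError("expected-signal values must be 1-D")
        if len(values) != self.source_length - (KMER_LENGTH - 1):
            raise ValidationError(
                f"expected {self.source_length - KMER_LENGTH + 1} values for a "
                f"{self.source_length}-base sequence, got {len(values)}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("expected-signal values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def load_pore_model(path: str | Path) -> PoreModel:
    """Parse a pore-model TSV: ``KMER<TAB>level`` per line.

    Lines starting with ``#`` and blank lines are ignored; a first line whose
    second column is not numeric is treated as a header.  Columns beyond the
    second (e.g. level stdv) are read but ignored.  Duplicate k-mers are an
    error.
    """
    levels: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 tab-separated "
                    f"columns, got {len(fields)}"
                )
            kmer = fields[0].strip().upper()
            try:
                level = float(fields[1])
            except ValueError:
                if lineno == 1 or (not levels and kmer in {"KMER", "K-MER"}):
                    continue  # header row
                raise ParseError(
                    f"{path}:{lineno}: cannot parse level {fields[1]!r}"
                ) from None
            _validate_kmer(kmer)
            if kmer in levels:
                raise ValidationError(f"{path}:{lineno}: duplicate k-mer {kmer!r}")
            levels[kmer] = level
    return PoreModel(levels=levels)


def expected_signal(sequence: str, model: PoreModel) -> ExpectedSignal:
    """Convert a nucleotide sequence into its expected signal sequence.

    ``values[i]`` is the model level of the 6-mer starting at position ``i``
    (0-based internally; positions are reported 1-based in error messages).
    """
    sequence = sequence.upper()
    if not ALPHABET.issuperset(sequence):
        bad = sorted(set(sequence) - ALPHABET)
        raise AlphabetError(
            f"sequence contains non-ACGT characters {bad}; "
            "ambiguity codes are not expanded"
        )
    T = len(sequence)
    if T < KMER_LENGTH:
        raise ValidationError(
            f"sequence length {T} is shorter than the k-mer length {KMER_LENGTH}"
        )
    levels = model.levels
    values = np.empty(T - KMER_LENGTH + 1, dtype=float)
    for i in range(T - KMER_LENGTH + 1):
        kmer = sequence[i : i + KMER_LENGTH]
        try:
            values[i] = levels[kmer]
        except KeyError:
            raise MissingKmerError(
                f"6-mer {kmer!r} at position {i + 1} is absent from the pore model"
            ) from None
    return ExpectedSignal(values=values, source_length=T)
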