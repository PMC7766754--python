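"""File formats: FASTA input, signal TSV/HDF5 output, simulation config."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
from Bio import SeqIO

from .errors import ValidationError


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """FASTA records in file order as (id, uppercased sequence)."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_signal(
    path: str | Path,
    read_id: str,
    signal: np.ndarray,
    format: str = "tsv",
    metadata: dict[str, Any] | None = None,
) -> None:
    """Persist one signal as TSV (one float per line) or fast5-inspired HDF5.

    The HDF5 layout stores floats in pA under ``Raw/Reads/Read_<id>/Signal``
    with metadata as attributes; it is not a bit-exact vendor fast5 (those
    store DAC integers with channel calibration).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 1:
        raise ValidationError("cannot write an empty signal")
    metadata = metadata or {}
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# read_id={read_id}\n")
            for key, value in metadata.items():
                fh.write(f"# {key}={value}\n")
            for v in signal:
                fh.write(f"{v:.6f}\n")
    elif format == "hdf5":
        with h5py.File(path, "a") as fh:
            group = fh.require_group(f"Raw/Reads/Read_{read_id}")
            if "Signal" in group:
                del group["Signal"]
            ds = group.create_dataset("Signal", data=signal)
            for key, value in metadata.items():
                ds.attrs[key] = value
    else:
        raise ValidationError(f"unknown signal format {format!r}")


def read_signal(path: str | Path, read_id: str | None = None) -> tuple[np.ndarray, dict]:
    """Load a signal written by :func:`write_signal`; format by extension."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5", ".fast5"}:
        with h5py.File(path, "r") as fh:
            reads = fh["Raw/Reads"]
            if read_id is None:
                read_id = sorted(reads.keys())[0].removeprefix("Read_")
            ds = reads[f"Read_{read_id}"]["Signal"]
            return np.asarray(ds, dtype=float), dict(ds.attrs)
    metadata: dict[str, Any] = {}
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
                continue
            values.append(float(line.split("\t")[0]))
    return np.asarray(values, dtype=float), metadata


@dataclass(frozen=True)
class SimulationConfig:
    """End-to-end simulation settings; defaults follow the 4 kHz / R9.4 setup."""

    pore_model_path: str | None = None
    filter_mode: str = "lowpass"  # one of {"bigru", "lowpass", "none"}
    model_checkpoint_path: str | None = None
    cutoff_hz: float = 950.0
    noise_std: float = 2.0
    sample_rate_hz: float = 4000.0
    seed: int = 0
    output_format: str = "tsv"
    kernel_length: int = 129
    repeat_seed_offset: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self.filter_mode not in {"bigru", "lowpass", "none"}:
            raise ValidationError(f"unknown filter_mode {self.filter_mode!r}")
        if self.filter_mode == "bigru" and not self.model_checkpoint_path:
            raise ValidationError("filter_mode 'bigru' requires model_checkpoint_path")
        if self.noise_std < 0:
            raise ValidationError("noise_std must be >= 0")
        if self.output_format not in {"tsv", "hdf5"}:
            raise ValidationError(f"unknown output format {self.output_format!r}")
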