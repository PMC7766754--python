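"""Simulate a raw nanopore current signal for a random DNA sequence.

Builds a synthetic 6-mer pore model, draws a 300-base sequence, expands it
into a ground-truth square wave with realistic dwell times, applies the
windowed-sinc low-pass baseline (950 Hz at 4 kHz) and adds 2.0 pA of
Gaussian noise.
"""

import numpy as np

import squigru as sq

pore = sq.synthetic_pore_model(seed=1)
rng = np.random.default_rng(1)
sequence = sq.random_sequence(300, rng)

config = sq.SimulationConfig(filter_mode="lowpass", noise_std=2.0, seed=1)
read = sq.simulate_read(sequence, pore, config, rng, read_id="demo")

print(f"sequence length:        {len(read.sequence)} bases")
print(f"expected signal length: {len(read.expected)} levels (= bases - 5)")
print(f"mean dwell time:        {read.ground_truth.repeats.mean():.2f} samples per 6-mer")
print(f"raw signal length:      {len(read.signal)} samples at 4 kHz")
print(f"first five samples:     {np.round(read.signal[:5], 2)} pA")
# Each 6-mer occupying the pore contributes ~8-9 current samples; the final
# signal is the filtered square wave of per-6-mer levels plus sensor noise.
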