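# Methods

## Signal model

A nanopore read is modelled in four stages.

**Pore model.**  Each 6-mer over {A,C,G,T} maps to one expected current
level in pA.  Converting a sequence of length T yields T − 5 levels, one per
overlapping window.  Ambiguity codes are rejected rather than sampled: no
principled expansion exists without a base-composition prior, and silent
sampling would make simulations irreproducible across inputs.  The vendor's
table is not redistributed here; `load_pore_model` reads any ONT-style TSV
(k-mer, level mean, further columns ignored), and `synthetic_pore_model`
provides a complete stand-in with levels uniform in [60, 120] pA — the
span of typical R9.4 level tables.

**Dwell times.**  With ~450 bases/s translocation sampled at 4 kHz, a 6-mer
dwells for 8–9 samples on average, with a heavy right tail from motor-protein
stalling.  Dwell is modelled as a mixture of two alpha-distributed
components, rounded to the nearest integer (ties to even) and clamped to
[1, 40].  Defaults: weights (0.7, 0.3), shapes (4, 6), locations (1, 2),
scales (28.5, 41).  The mixture family and the 8–9 mean are the modelling
targets; the remaining degrees of freedom were calibrated once so the
clamped-rounded mean sits near 8.8 and then frozen.  The clamp at 40 bounds
the tail (the unclamped alpha distribution has no finite mean).

**Filtering.**  The baseline is a linear-phase FIR low-pass: sinc kernel,
Blackman window, 129 taps, unit DC gain, 950 Hz cutoff at 4 kHz (the firwin
convention puts the half-amplitude point at the cutoff; the kernel-design
test checks exactly that).  Edges are handled by replication so output
length equals input length and constant signals pass unchanged.  The
learned alternative is the BiGRU network below.

**Noise.**  I.i.d. zero-mean Gaussian noise, default std 2.0 pA, added to
every sample of the filtered signal.  No temporal correlation, baseline
drift, or stall artifacts are modelled.

## BiGRU signal-processing network

Three stacked bidirectional GRU layers and a per-time-step scalar linear
head.  The candidate state is computed *without* a bias term, matching the
gate equations as stated; a `candidate_bias` switch restores the
framework-standard cell for users who want it.  Hidden size is configurable
(default 64 per direction; the bundled experiments use 16 — see problem
sizes below).  Initial hidden states are zero at both ends.  Inputs are
per-read z-scored signals; simulation output is mapped back to pA with the
same read's statistics.

The forward pass, backpropagation through time and Adam are written
directly against these equations in numpy.  Implementation notes:

* input-side weight products are hoisted out of the sequential scan into
  one large matrix product per gate; only the (d × d) recurrent products
  run per time step, and all parameter-gradient products are batched over
  time after the backward scan;
* glibc's malloc trim/mmap thresholds are raised once at training start so
  the ~100 MB of per-step BPTT caches are reused instead of being returned
  to the OS and faulted back every step;
* everything runs in float64; gradients are verified against central finite
  differences in the test suite, and the full forward pass against an
  independently coded scalar-loop implementation.

## Training

Loss: Log-Cosh, `Σ log cosh(o_i − r_i)`, computed as
`logaddexp(x, −x) − log 2` so it is exact and overflow-safe at any
magnitude.  The optimizer minimizes the *mean* per valid position so the
window length does not rescale the learning rate; the raw sum is exposed
unchanged for per-read reporting.  Initialization is Xavier-uniform
(bound √(6/(n_in + n_out))) for all weight matrices, zeros for biases.
Adam uses lr 1e-4 (β₁ 0.9, β₂ 0.999, ε 1e-8), batch 128, 1000 iterations by
default; "iterations" means optimizer steps.  Reads are cut into
non-overlapping windows (default 512 samples); a final remainder shorter
than half a window is discarded, otherwise zero-padded under a mask the
loss ignores.  Windows are shuffled with the config seed; two runs with the
same config are bitwise identical.

## Labeling (supervised pair construction)

Raw reads are mapped onto their expected signal with exact dynamic time
warping (local cost |a_i − b_j|, steps (1,0), (0,1), (1,1)), both signals
z-scored first.  Ties prefer the diagonal, then the raw-consuming step, so
paths are deterministic.  When a raw sample matches several expected
positions, the first is kept.  An optional band restricts the search to a
radius around the length-rescaled diagonal (engaged automatically above
50k samples, radius 1000); a radius below 1 cannot connect the grid
corners and is an error.  The dynamic program is numba-compiled and stores
the full cost matrix, so memory is O(n·m) — adequate at desk scale, not
for warping two multi-hour reads against each other.

Because the raw read's z-score moments are dwell-weighted while the
expected signal's are not, the two scales disagree slightly, occasionally
pushing an entire dwell block onto an adjacent 6-mer of nearly equal
level.  One refinement pass — least-squares fit of the matched expected
values onto the raw scale, then re-warp — removes almost all such swaps
(exact per-sample level recovery on synthetic expansions: ~99.9% noiseless,
~96% at noise std 0.1 in normalized units).

The upstream steps used with real data (basecalling, aligning the read to
a reference to obtain the matching fragment) are external tools and are
not reimplemented; `label_read` assumes the fragment is known.

## Evaluation metrics

**Normalized DTW** = warp cost divided by warp-path length, on z-scored
signals, making reads of different lengths comparable and the measure
invariant to affine rescaling of either input.

**CWT spectra** use a Morlet wavelet with angular center frequency ω₀ = 6
(complex Morlet with bandwidth 2 and center frequency ω₀/2π in pywt's
parametrization), 64 scales log-spaced so pseudo-frequencies span
[f_s/length, f_s/2].  The signal is de-meaned first: at the smallest scales
the discretized wavelet is too coarse to cancel a large DC offset exactly.
Spectra are compared by Pearson correlation of the magnitude matrices,
overall and split at 450 Hz — the base-translocation rate, separating
level-structure content from within-dwell detail.  Bitwise-identical
spectra short-circuit to a correlation of exactly 1.  Note that
neighbouring spectrogram cells are strongly correlated, so the correlation
between two *independent* noise spectra is small but not 3/√cells-small;
the suite checks |PCC| < 0.3 for that case.

## Synthetic study data

The generator emulates the supervised setting end to end: random uniform
sequences → synthetic pore model → dwell expansion → per-read z-scoring →
"real-like" target.  The target smooths *only the level transitions*
(triangular kernel, default 5 taps, unit sum — flat stretches pass
unchanged) and adds Gaussian noise in normalized units (default std 0.15).
This encodes the qualitative feature that distinguishes real reads from
square waves — gradual 6-mer change-overs with flat dwells — and it is
precisely what a global low-pass filter cannot reproduce, so the trained
network has a genuine, testable advantage.  What the generator does *not*
emulate: sequence-dependent dwell, heteroscedastic per-k-mer noise, drift,
stalls, adapter signal.  Passing the synthetic end-to-end tests therefore
demonstrates that the architecture, training loop and metrics work as
designed, not that the defaults reproduce any particular flowcell.

## Problem sizes

The bundled end-to-end experiment uses 200 reads of 500 bases (≈4,300
samples each), 150 for training and 50 held out; hidden size 16 per
direction; 300 Adam steps at batch 128, windows of 512.  These sizes give a
clear learning signal — held-out Log-Cosh well below both the identity map
and 0.6× the initial loss, and a normalized-DTW win over the raw square
wave on essentially all held-out reads — while a full training run stays in
the minutes range on one CPU.  The defaults (hidden 64, 1000 iterations)
are the recommended starting point for real data.

## Known limitations

* The full multi-scale (continuous-wavelet-seeded) DTW used for labeling
  very long reads is replaced by exact banded DTW; fine at desk scale,
  quadratic beyond it.
* The HDF5 output is fast5-inspired (float pA signal plus attributes), not
  a bit-exact vendor fast5 (no DAC integers or channel calibration).
* 6-mer models only; no RNA tables, no per-k-mer level spreads.
* Changing the noise std is the only signal-quality knob.
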