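# Methods

## Signal model and pipeline

A music mixture x(t) = y₁(t) + y₂(t) is the sample-wise sum of a vocal
source y₁ and an instruments source y₂ at 44.1 kHz. The separator works
on the short-time Fourier transform of the mixture, X(k), computed with
a 1024-sample periodic Hamming window advancing by 256 samples (75 %
overlap); the real-input transform keeps the 513 non-negative-frequency
bins. A multilayer perceptron regresses |Y₁(k)| and |Y₂(k)| from the
mixture magnitudes; the estimates are recombined with the *mixture
phase* ∠X(k) and inverted by overlap-add. The remix stage then forms
m(t) from the two estimates at the requested vocals-to-instruments
ratio (VIR).

### STFT conventions

The analysis window is applied once, at analysis. Synthesis overlap-adds
the inverse-transformed frames and divides by the sum of the shifted
analysis windows, which is exact for any everywhere-positive window (the
periodic Hamming never vanishes). The signal is zero-padded by
`window_len − hop` = 768 samples at the start and by up to one window at
the end, so every input sample is covered by the full four overlapping
frames; synthesis trims the padding. These two choices make
`istft(stft(x))` reproduce x to machine precision (measured relative RMS
error ~2·10⁻¹⁶), which the whole test suite leans on. The edge padding
and normalization are this package's contract — overlap-add systems vary
here, and any convention with exact reconstruction would do.

### Network and training

* Input: causal context [frame t−2, t−1, t] of the scaled mixture
  magnitude, 3 × 513 = 1539 units. Missing leading frames are zeros. A
  causal (rather than centered) context is used so separation adds no
  lookahead beyond the one-hop block latency.
* Hidden: 1024 ReLU units; output: 1026 ReLU units = two 513-bin
  spectra (vocal first). The output rectifier enforces non-negative
  magnitudes; the loss is the mean squared error of both halves jointly
  on the linear magnitude scale. Direct magnitude regression is the
  default; a `mask_mode` flag instead converts the two outputs into a
  ratio mask v̂/(v̂+î+ε) applied to |X|.
* Optimizer: Adam (β₁ = 0.9, β₂ = 0.999), batch size 128 frame rows
  pooled across all training chunks and reshuffled each epoch, initial
  learning rate 0.005 multiplied by 0.9 after every epoch, dropout on
  the hidden layer with drop probability 0.8 (inverted scaling at train
  time; "80 %" is read literally as the drop rate — the keep-rate
  reading is available through `TrainConfig.dropout_prob`).
* Feature scaling: magnitudes are divided by one scalar, the 99th
  percentile of the training mixture magnitudes, stored in the model and
  reapplied at inference. This keeps the rectified units in a sane range
  without per-bin statistics that would complicate streaming.
* Weights: He-normal initialization, float32 arithmetic during training
  (float64 at inference), fully determined by the config seed; repeated
  runs are bit-identical.
* Silent frames: a frame whose mixture spectrum is exactly zero
  produces zero output (the network's biases would otherwise emit
  magnitude into silence). The gate uses exact zero so ordinary quiet
  audio is never touched.

The per-epoch loss reported in the training history is the running
training loss, i.e. computed with dropout active, as is conventional.
With an 0.8 drop rate this floors well above the dropout-free training
error — on the separable fixture the history settles near 15–20 % of the
first-epoch value even though the clean prediction error keeps falling —
so convergence assertions are calibrated against that floor.

## VIR remixing

VIR is the vocal/instruments power ratio in dB, controlled on an integer
grid from −12 to +12 (quantization rounds to the nearest step, half-way
values away from zero). Two adjustment methods:

* `vocals_gain`: m = 10^{VIR/20}·v̂ + î; the overall level varies.
* `balanced`: m′ = 10^{VIR/40}·v̂ + 10^{−VIR/40}·î, then m = m′ ·
  (reference_rms / rms(m′)). Splitting the ratio symmetrically and
  renormalizing makes the constant-level contract *exact* rather than
  approximate; without the final normalization the level of the sum
  still depends on the source balance. Whether the original listening
  setup renormalized or relied on approximate constancy is not
  derivable; exactness was chosen because it gives a testable contract.
* The calibrated presentation level (65 dB SPL in a playback room) maps
  to a configurable digital RMS, default 0.05 full-scale; absolute SPL
  belongs to the playback chain, not the signal path.

## BSS-Eval metrics

The time-invariant (projection, filter-length-1) BSS-Eval variant:
s_target is the scalar projection of the estimate onto the target
source, e_interf the remainder of the projection onto the span of all
true sources, e_artif the residual. SDR/SIR/SAR follow from the three
energies; ratios with a vanishing denominator are capped at ±200 dB so
per-track averages stay finite. The 512-tap filtered variant admits
time-varying alignment this pipeline neither needs nor produces; the
projection form is exactly testable against an independent least-squares
oracle (agreement ≤ 10⁻⁶ dB on random instances).

## Synthetic scenes

The generator stands in for commercial vocal/accompaniment corpora and
for reverberant playback rooms:

* **Vocal**: harmonics of a piecewise note contour (random walk within
  110–440 Hz), 5 Hz vibrato of ±50 cents, 1/h^0.8 spectral roll-off with
  a gentle formant bump near 600 Hz, syllabic gating with 20 ms ramps
  and a 25 % silent-note probability (emulating non-vocal passages),
  plus faint gated breath noise (−35 dB). Voiced-region RMS 0.1.
* **Instruments**: percussive band-limited noise bursts (2 per second,
  60 ms decay), a bass line around 82 Hz, a sustained three-note chord
  bed, and a broadband noise floor; overall RMS 0.1, i.e. a ≈0 dB input
  VIR against the vocal.
* **Room**: a statistical impulse response — unit direct path plus a
  Gaussian tail with envelope exp(−6.9078·t/T60) — parameterized by T60
  and the direct-to-reverb energy ratio (default 0 dB), 1.5·T60 long.
  A Schroeder backward-integration estimator (linear fit of the −5…−35 dB
  decay, extrapolated to 60 dB) validates the rooms: T60 ∈ {0.5, 0.65} s
  is recovered within 5 %. With a single decay slope, estimates
  extrapolated from any decay range coincide, so T20 cannot be set
  independently of T60 — a documented limitation of the statistical
  model versus image-source room simulation, which is out of scope.
  After rendering, the ground truth is the *reverberant image* of each
  source, matching how in-room recordings are made.
* **Corpus**: n tracks of 30 s, chunked and split 60/20/20 *by track*
  (largest-remainder apportionment, seeded shuffle), all signal content
  derived from per-track child seeds.

What the generator does **not** emulate: real vocal formant dynamics,
consonants and unvoiced phonemes, instrument timbre diversity, mixing
effects (compression, stereo imaging), or correlated vocal/accompaniment
rhythm. Passing the gate on this material shows the implementation is
correct and trainable end to end — not that it reaches the published
separation quality on commercial recordings, which would require those
corpora.

## Streaming and latency

The streaming engine consumes arbitrary block sizes and performs one
frame of work per 256 new samples; its output equals the batch pipeline
bitwise because the overlap-add accumulators replicate the batch
accumulation order. The VIR may be changed between blocks; new gains
apply from the next synthesized frame without cross-fade. In balanced
mode the stream applies the ±VIR/40 gains but not the global RMS
renormalization, which is not causal.

Two latency notions are kept apart deliberately:

* **Declared algorithmic latency** = one hop = 256/44100 s ≈ 5.8 ms
  (rounds to 6 ms): the block granularity of the scheme. This is a
  definition, reported by `algorithmic_latency_ms` and the stream.
* **Measured availability lag** = `window_len − hop` = 768 samples
  ≈ 17.4 ms: a complete 75 %-overlap overlap-add can finalize an output
  sample only after the last of the four frames covering it is analyzed.
  Emitting earlier would require partial overlap-add output and break
  batch equivalence. The test suite asserts both numbers.

Per-frame wall-clock time is logged and summarized as a real-time factor
but never asserted: it is a property of the host machine.

## Problem sizes

The built-in suitability gate trains on a 10-track, 30-s-per-track
synthetic corpus (six training tracks ≈ 31 000 frame rows) for 20
epochs — the package's desk-scale rendition of a corpus-scale training
run; it keeps a full train/separate/evaluate cycle in the minutes range
on one CPU while exercising every part of the recipe. Unit and property
tests use seconds-long fixtures; the spectrally disjoint fixture (vocal
harmonics < 1 kHz, accompaniment > 2.2 kHz) makes convergence and
separation quality assertable with wide margins (ideal-magnitude upper
bound ≈ 44 dB SDR; the trained network reaches > 10 dB within 20
epochs).
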