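# vocalmix

Real-time singing-voice separation and remixing for cochlear-implant (CI)
music enhancement.

CI listeners receive a coarse electrical representation of sound and
typically enjoy pop music more when the lead vocal is boosted relative to
the accompaniment. `vocalmix` implements the complete signal path such a
music-enhancement front end needs:

1. **Separation** — an STFT-domain multilayer perceptron estimates the
   magnitude spectra of the vocal and the instruments from the mixture.
   Analysis uses a 1024-sample periodic Hamming window with 75 % overlap
   (513 bins per frame); the network maps a causal context of three
   consecutive frames (513 × 3 = 1539 inputs) through one 1024-unit ReLU
   hidden layer to a 1026-unit output (two 513-bin spectra). Estimates
   are resynthesized with the **mixture phase** and overlap-add.
2. **Remixing** — the vocals-to-instruments ratio (VIR), the power ratio
   of vocal to accompaniment in dB, is applied on an integer slider from
   −12 to +12 dB, either by scaling the vocals alone (`vocals_gain`) or
   by scaling both sources in opposite directions and renormalizing to a
   calibrated RMS so the presentation level stays constant (`balanced`).
3. **Evaluation** — time-invariant BSS-Eval: each estimate is decomposed
   into target, interference and artifact parts by orthogonal projection
   onto the true sources, giving SDR, SIR and SAR in dB. Separators with
   mean SDR > 0.69 dB and SAR > 4.42 dB are considered transparent to CI
   listeners; that gate is built in.
4. **Streaming** — a frame-by-frame engine whose output is numerically
   identical to the batch pipeline for any input block schedule, with a
   declared algorithmic latency of one hop (256 / 44100 s ≈ 6 ms).
5. **Synthetic scenes** — generators for vocal-like sources (pitch
   contour, vibrato, syllabic gaps), accompaniment (percussion, bass,
   chords) and statistical room responses at a chosen reverberation time
   T60, so training and evaluation run without any external corpus.

Training follows the published recipe: mean-squared error on magnitude
spectra, Adam, batch size 128, initial learning rate 0.005 multiplied by
0.9 after each epoch, dropout 0.8 on the hidden layer, data reshuffled
every epoch; corpora are chopped into 30-s chunks and split 60/20/20 by
track.

## Worked example

```python
from vocalmix import benchmark, remix, separator

report, model = benchmark.run_benchmark(seed=0, n_tracks=10,
                                        duration=30.0, epochs=20)
print(f"mean test vocal SDR {report.mean_vocal_sdr_db:.2f} dB")
print(f"mean test vocal SAR {report.mean_vocal_sar_db:.2f} dB")
print(f"gate passed: {report.passes}")
```

On the default synthetic corpus this prints

```
mean test vocal SDR 3.92 dB
mean test vocal SAR 5.55 dB
gate passed: True
```

i.e. the vocal estimates on held-out mixtures carry ~4 dB more target
than distortion energy — comfortably above the 0.69 dB SDR / 4.42 dB SAR
suitability bounds for CI remixing. The trained model can then remix at
any slider position:

```python
est = separator.separate(model, mixture)          # mixture: AudioSignal
louder_vocals = remix.apply_vir(
    est.vocal, est.instruments,
    remix.VIRSetting(vir_db=8, mode="balanced"),  # +8 dB VIR, level held
)
```

The same workflow is available from the shell:

```sh
vocalmix simulate --out-dir corpus --n-tracks 10 --seed 0
vocalmix train --manifest corpus/manifest.json --checkpoint model.npz --epochs 20
vocalmix evaluate --checkpoint model.npz --manifest corpus/manifest.json --report report.csv
vocalmix stream --checkpoint model.npz --mixture song.wav --out remix.wav --vir-db 8
```

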