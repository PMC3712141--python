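# stochvoc

A stochastic-undersampling vocoder and analysis toolkit. Sounds are split
through a bank of contiguous Butterworth band-pass filters (log-spaced edges,
100 Hz–10 kHz by default). In each band, N independent per-sample Bernoulli
"spike" samplers fire with probability equal to the rectified band amplitude;
the N spike trains are OR-aggregated, multiplied back onto the band signal,
re-filtered through the same band filter, and summed across bands. Small N
degrades low-amplitude and fast-varying waveform features — in noise more than
in quiet — while the output converges to the plain analysis–synthesis rendering
("control" condition) as N grows.

The package also ships the synthetic stimuli needed to exercise the vocoder
(log-frequency chirp, ramped tones, white/pink/speech-shaped noise, a broadband
word-like token), SNR mixing and rms equalization, and the analysis tools:
Welch magnitude-squared coherence, maximum lag-normalized temporal correlation
R ∈ [0, 1], correlation maps over SNR × sampler-count grids at several signal
levels, and band-count sweeps at a matched total sampler budget.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the headline acceptance criteria
(convergence at large N, optimal-condition correlation, the analytic
aggregated-firing oracle, monotonicity, frequency asymmetry, and the
band-count comparisons); the other files are per-module unit and property
tests.

## CLI

One entry point with subcommands:

```sh
# generate stimuli
stochvoc gen --kind chirp --fs 44100 --dur 1.0 --peak 0.1 --out chirp.wav
stochvoc gen --kind noise --noise-kind pink --dur 1.0 --rms 0.07 --seed 3 --out pink.wav

# vocode a WAV file (N samplers per band; --control bypasses the sampling stage)
stochvoc vocode --in chirp.wav --out voc.wav --bands 10 --n 300 --seed 1 --equalize-rms

# compare control vs vocoded
stochvoc coherence --control ctrl.wav --vocoded voc.wav --out coherence.csv

# correlation map over SNR x N, and band-count sweep at matched total budget
stochvoc corrmap --rms 0.01 --reps 10 --seed 1 --out map.csv
stochvoc sweep --rms 0.01 --band-counts 20,5,1 --out-dir sweep/

# regenerate the built-in demonstration figures (PNG + CSV tables)
stochvoc figures --which fig5 --seed 1 --out-dir figures/
```

Every command writes a JSON manifest (parameters, seeds, output hashes) next
to its outputs; runs with an explicit seed are bit-reproducible.

## Python API

```python
from stochvoc import (
    make_word_like, make_noise, mix_at_snr, rms_equalize,
    VocoderConfig, control_config, vocode, temporal_correlation,
)

word = rms_equalize(make_word_like(0.5, 22050.0, seed=0), 0.01)
noise = make_noise("white", 0.5, 22050.0, rms=0.01, seed=1)
mix = mix_at_snr(word, noise, snr_db=20.0)

cfg = VocoderConfig(n_samplers=1000, n_bands=10, seed=0)
vocoded = vocode(mix, cfg)
control = vocode(word, control_config(cfg))
print(temporal_correlation(control, vocoded))  # ~0.996
```

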