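# embryoflow

Automated motion phenotyping of embryos from video. Developing embryos —
zebrafish, *Xenopus*, pond snails and others — produce rich, stage- and
stressor-specific movement: ciliary rotation, muscle twitches, tail
flicks. `embryoflow` turns a time-lapse image sequence of a single embryo
into a compact behavioural fingerprint and tests whether groups of
embryos (developmental stages, treatments) move differently, without any
hand scoring.

The pipeline has three stages, each usable on its own:

1. **Sparse optic flow.** Shi-Tomasi corners are detected on the embryo
   and registered frame to frame with pyramidal Lucas-Kanade tracking;
   unreliably tracked corners are dropped by the variance of their recent
   speeds. Each frame transition is summarised by four parameters: the
   mean clockwise and anti-clockwise angular steps of the corners about
   their centroid (`pos_angle`, `neg_angle`, radians — feasible as two
   separate signals because embryos are gelatinous and deform), and the
   centroid's own displacement in polar form (`com_rho` pixels,
   `com_theta` radians). These series persist to CSV.
2. **Spectral fingerprint.** Each series is mean-centred and passed
   through the DFT; for a series of length *N* at *f* Hz, coefficient
   *k* carries period *N*/(*k·f*) seconds and energy (2/*N*²)|*X_k*|².
   Energies are summed into preset period bins (three published presets:
   two 18-bin sets and one 30-bin set spanning 598–0.1 s) and the four
   binned vectors are concatenated and log(x+1)-transformed — 72 features
   per individual for an 18-bin preset.
3. **Group comparison.** Bray-Curtis dissimilarity
   d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) between fingerprints, non-metric MDS for
   ordination, and ANOSIM for inference:
   R = (r̄_between − r̄_within) / (n(n−1)/4) on dissimilarity ranks, with
   an exact permutation p-value (all distinct group partitions are
   enumerated for small designs, e.g. 462 for two groups of six) or a
   seeded Monte-Carlo approximation, plus pairwise tables with
   conventional significance stars.

A `synthetic` module generates ground truth for every stage: rendered
videos of a textured disc spinning/drifting inside a capsule ring with
the true motion record attached, and motion time series with controlled
oscillation periods, Poisson-timed "tail-flick" bursts and noise.

## Worked example

```python
from embryoflow import (VideoSpec, synth_embryo_video, analyze_sequence)

seq, truth = synth_embryo_video(
    VideoSpec(n_frames=60, spin_profile=0.035, fps=7.5, seed=42))
record = analyze_sequence(seq)
print(record.pos_angle.mean())   # 0.0345 — the true spin is 0.035 rad/frame
print(record.neg_angle.mean())   # 0.0000 — no anti-clockwise motion
```

The tracker recovers the planted clockwise spin to 1.4% while the
anti-clockwise channel stays at zero. Running
`examples/03_group_comparison.py` (two simulated cohorts of six whose
rotation rhythms differ in period, 8 s vs 20 s) prints

```
global ANOSIM: R = 1.000, p = 0.0022 (exact, 462 permutations)
  fast_rhythm vs slow_rhythm: R = 1.000, p = 0.0022 [**]
nMDS stress-1 = 0.0008
```

R = 1 means every between-group dissimilarity outranks every
within-group one; p = 1/462 is the smallest value an exact test on this
design can produce; the near-zero stress says the 2-D ordination
faithfully separates the groups. The other scripts in `examples/` cover
tracking, fingerprinting and the shell pipeline
(`simulate → spectra → compare` via the `embryoflow` command).

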