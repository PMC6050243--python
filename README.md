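# spitrain

Statistics of pulse-train communication signals in mormyrid weakly electric
fish.

Mormyrids emit brief, stereotyped electric organ discharges (EODs) whose
*timing* — the sequence of pulse intervals (SPI) — is under volitional
control and carries behavioural information. `spitrain` implements a
complete analysis pipeline for such pulse trains, together with calibrated
synthetic generators so that every stage can be exercised and validated
without access to animal recordings:

- **Inter-pulse intervals.** From event times `t_i` (seconds), the interval
  `IPI_i = t_i − t_{i−1}` (milliseconds); relative-frequency histograms at
  2-ms resolution with population mean/SEM/STD.
- **Five-variable SPI features** per 120-s analysis window: total EOD
  count, number of runs (maximal streaks of increasing / decreasing /
  constant intervals, as in the classical runs test), mode IPI (tallest
  2-ms histogram bin), and the longest and shortest interval.
- **Serial correlation with a permutation chance level.** For lag `i`,

      SC_i = ( ⟨IPI_k · IPI_{k+i}⟩_k − ⟨IPI⟩² ) / VAR(IPI)

  with the chance level built from 250 random permutations of the interval
  sequence (one-sided 99% normal bound per lag, averaged over lags). The
  **SC duration** — first sub-chance lag × median IPI — is a scalar measure
  of how far pulse-timing memory extends; renewal surrogates (scrambled
  interval order, identical interval distribution) decorrelate at lag 1.
- **PCA of feature tables** (log10 + standardize + SVD, deterministic sign
  convention), Pearson correlation matrices, and standard group tests.
- **Playback preference analysis.** For two-choice playback sessions the
  strength of preference `SOP = (t_B − t_D)/(t_B + t_D)` over
  side-unswapped preference-zone times, one-sample tests against SOP = 0,
  repeated-measures ANOVA across playback conditions with Tukey HSD, and
  responsiveness comparisons.
- **Synthetic generators**: renewal mixtures, sticky-state (semi-Markov
  burst/pause) chains, AR(1)-on-log-interval processes, two calibrated
  species presets, and simulated playback cohorts with known preference.

## Worked example

```python
from spitrain import (species_preset, simulate_spi, compute_ipis,
                      extract_features, compute_correlogram, scramble_ipis)

preset = species_preset("bimodal_burster")          # fast, bursty profile
train = simulate_spi(preset.config, seed=1)          # 120-s pulse train
feats = extract_features(train)
seq = compute_ipis(train)
cg = compute_correlogram(seq, seed=2)                # SC + chance band
surrogate = compute_correlogram(scramble_ipis(seq, seed=3), seed=4)
```

prints (via the obvious f-strings):

```
events in 120 s : 3303
runs            : 2059
mode IPI        : 13 ms
range           : 10.2 - 689.3 ms
chance level    : 0.0410
SC duration     : 144 ms (first sub-chance lag 7)
scrambled       : SC duration 21 ms (lag 1)
```

The burster preset emits ~3300 pulses in 120 s with its histogram mode near
14 ms; its serial correlation stays above the 0.041 chance level out to lag
7 (≈ 144 ms of timing memory), while the scrambled surrogate — same
intervals, random order — is indistinguishable from a renewal process and
drops below chance immediately.

The same pipeline is available from the shell:

```
spitrain simulate --preset bimodal_burster --seed 1 -o train.txt
spitrain features train.txt -o features.csv
spitrain sercorr --seed 2 train.txt -o sc.csv
spitrain simulate-cohort --n 12 --preference 0.4 --seed 5 -o sessions.csv
spitrain sop sessions.csv -o sop.csv
```

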