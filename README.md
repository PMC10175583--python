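# napqeeg

Sleep–cognition analysis for afternoon-nap polysomnography (PSG) in senior
dogs: from multichannel signals (EEG Fz/Cz/F3/F4, bipolar EOG and EMG at
400 Hz) through behavioral-state staging and sleep macrostructure, to
quantitative EEG — spectral power, interhemispheric/intrahemispheric
coherence, Lempel–Ziv complexity — and cohort-level correlation screening
against age and cognitive measures (dementia-scale score, working memory,
inhibitory control, detour problem-solving, sustained gaze).

It is written for researchers quantifying sleep changes in canine cognitive
dysfunction (an analog of Alzheimer's disease), but every stage is generic
PSG methodology. Because raw recordings of such studies are rarely
deposited, the package ships a synthetic-cohort generator that reproduces
the statistical structure the analysis assumes, so the entire pipeline is
testable end to end.

## Methods at a glance

- **Staging**: 3-s epochs over {W, Drow, NREM, REM}, scored by explicit
  rules on EMG tone, relative delta power and EOG event rate (wake: high
  EMG + frequent eye movements; drowsiness: reduced EMG, fast EEG; NREM:
  delta-dominant, low EMG; REM: atonia, fast EEG, rapid eye movements),
  followed by 3-epoch majority smoothing. Macrostructure: state latencies,
  state percentages, and sleep efficiency
  (time in NREM + time in REM) / total recorded time.
- **Spectra**: Welch power for Fz and Cz on a 0.25 Hz grid from 0.5–50 Hz
  (1-s Hamming windows, 50 % overlap, zero-padded to 4 s), relative power
  `P_rel(f) = P(f) / Σ_f P(f)`; bands delta (1–4), theta (4–8), alpha
  (8–12), sigma (12–16), beta (16–30), gamma (30–45 Hz).
- **Coherence**: magnitude-squared coherence
  `MSC(f) = |S_xy(f)|² / (S_xx(f)·S_yy(f))` for F3–F4 and Fz–Cz from
  pooled averaged cross/auto-spectra, Fisher-z transformed
  (`z = atanh(√MSC)`).
- **Complexity**: LZ76 phrase count of median-binarized 3-s epochs after an
  order-5 Butterworth 1–50 Hz prefilter, normalized as `c·log₂(n)/n` and
  averaged per state.
- **Screening**: Spearman rank correlations of sleep variables vs
  covariates with two-stage adaptive Benjamini–Krieger–Yekutieli FDR at
  0.05 per results table; bin-to-bin Spearman screens of power/coherence
  with Rüger's-areas cluster significance (a maximal run of p < 0.05 bins
  is significant iff ≥ 1/2 of its p-values are < 0.025 and ≥ 1/3 are
  < 0.0167).

## Worked example

Run the numbered drivers in `analysis/` (outputs land under `results/`), or
use the `napqeeg` CLI (`simulate`, `score`, `macro`, `qeeg`, `screen`,
`run-study`, `report`). Per-state quantitative EEG of one synthetic 2-h
nap:

```bash
$ python analysis/03_qeeg_features.py --seed 1
subject dog001, selected epochs: {'W': 356, 'D': 202, 'N': 1497, 'R': 228}
state  delta  theta  alpha  sigma  beta  gamma  msc_F3F4  lzc_Fz
    W  0.099  0.161  0.263  0.168 0.212  0.079     0.349   0.437
    D  0.187  0.228  0.265  0.133 0.118  0.047     0.352   0.377
    N  0.673  0.187  0.042  0.033 0.018  0.008     0.448   0.208
    R  0.103  0.215  0.211  0.126 0.210  0.117     0.300   0.454
```

Reading the table: NREM is delta-dominant (0.67 of total power 0.5–50 Hz)
with the lowest complexity (0.21), wake and REM are fast-frequency with
high complexity (0.44–0.45), and the interhemispheric coherence plateau is
highest in NREM — the state-dependence the downstream screens rely on.
Staging the same cohort against its ground truth
(`analysis/02_stage_macrostructure.py`) reports ~99.6 % epoch agreement,
and the full study driver (`analysis/04_cohort_screens.py`) writes the
three correlation tables (macrostructure, LZC at Fz, LZC at Cz) and all
96 bin-wise screens with their Rüger areas, plus a hash manifest.

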