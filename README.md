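# revspeech

An in-silico pipeline for studying speech intelligibility in noise under
reverberation, for normal-hearing (NH) and hearing-impaired (HI)
listeners. The package simulates every stage of such a study on
synthetic data: virtual-room acoustics, masker/stimulus construction, a
synthetic listener cohort, psychometric-function fitting with RAU-domain
statistics, default-prior Bayes factors, and a sequential Bayes-factor
design analysis.

## Modules

| Module | What it does |
| --- | --- |
| `revspeech.room` | Shoebox RIR simulation (frequency-dependent image-source model with a diffuse-decay hybrid attenuation), Schroeder T30, DRR, energy normalization. |
| `revspeech.stimuli` | Noise-vocoded speech-modulated maskers, phase-randomized stationary noise, FIR spectral matching, envelope modulation spectra (1–16 Hz octave bands), calibrated reverberant trial assembly. |
| `revspeech.cohort` | Synthetic NH/HI listeners: audiograms, 4FAHL, NAL-RP gains, latent psychometric truths per condition, binomial word-scoring trial simulation. |
| `revspeech.psychofit` | Maximum-likelihood psychometric fitting (logistic, lapse-rate bounded), RAU transform, group mean curves, optimal-SNR rule, dip-listening benefit, SRT. |
| `revspeech.bayes` | JZS t-test Bayes factors (quadrature) and mixed-design ANOVA interaction Bayes factors (g-priors, Cauchy scale 1/2; Laplace + importance sampling, plus a fast BIC surrogate). |
| `revspeech.design` | SBF+maxN sequential design analysis by Monte Carlo. |
| `revspeech.studydesign` / `revspeech.experiment` | Condition bookkeeping (14 combos / 70 cells), matrix-vocabulary sentence lists, session timing, and the end-to-end synthetic replication with its hypothesis battery. |

## CLI

```bash
revspeech room simulate --rt-target 0.8 --out rir.wav     # WAV + JSON sidecar
revspeech room metrics rir.wav
revspeech stimuli build --n-sentences 20 --out stimdir/   # manifest.csv + WAVs
revspeech design run --reps 200 --seed 1 --out bfda.json
revspeech replicate run --seed 7 --n-per-group 16 --out results/
```

`replicate run` writes `trials.csv`, `fits.csv` and `report.json`
(optimal SNRs, benefit-maximizing SNRs, and Bayes factors with evidence
categories for hypotheses H1, H1-1, H1-2, H2, H3-1, H3-2-a/b, each at
the optimal and the benefit-maximizing SNR where applicable).

## Notes

- Audio is synthetic throughout: the real matrix-test recordings are
  copyrighted, so targets/maskers are built from speech-shaped noise
  tokens with syllabic envelopes (`stimuli.synthetic_corpus`).
- The room simulator defaults to 16 kHz and a hybrid attenuation rule
  (exact specular attenuation for the direct path and first-order
  reflections, diffuse expected-hit attenuation beyond) so the late
  field decays at the Eyring rate, as a scattering ray-tracer would.
  The tabulated absorption vectors for the 0.15 s and 1.5 s rooms are
  approximate transcriptions.
- The SBF+maxN generating means/SDs are caller-supplied
  (`design.EffectModel`); `design.example_effect_model()` is a
  documented example configuration, not a claim about any particular
  dataset.
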