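# dualpop

Analysis pipeline for asymmetric functional influence between two
simultaneously recorded neural populations during reaching. Every stage is
driven by a synthetic-data generator with known ground truth (shared
delayed latents, directed pairwise coupling, inactivation effect sizes,
reach onsets), so the full pipeline is verifiable offline.

## Modules

| Subpackage | Purpose |
| --- | --- |
| `dualpop.synthetic_data` | Two-region sessions with known ground truth: smooth shared latents at configurable delays, Poisson spiking with optional alpha-function pairwise coupling, reach-locked EMG bursts, interleaved control/light trials, network-fitting target traces. |
| `dualpop.preprocess` | EMG conditioning (1 kHz, 250 Hz high-pass, rectify, 10 ms Gaussian), double-threshold reach-onset detection, outlier-trial exclusion, ISI/depth/waveform unit curation, pathological-channel exclusion, kernel rate estimation, circular-shift muscle-correlation tests. |
| `dualpop.perturbation` | Chance-corrected inactivation-effect time series for EMG and firing, pre-onset outlier masks, per-neuron z-scored effects, and a modified spike-latency (SALT-style) test with uniform null p-values. |
| `dualpop.population_geometry` | 1600-row concatenated trial-average matrices, CCA and PLS-SVD alignment with orthogonalized variance capture, lag scans, shifted-time controls, population/neuron activity-onset timing, pre-movement variance fractions. |
| `dualpop.delayed_latents` | Two-population latent factor model with per-latent continuous delays (EM with squared-exponential latent priors), bootstrap delay significance, variance-capture and lag summaries. |
| `dualpop.predictivity` | Directed pair metrics: delayed transfer entropy, point-process Granger causality with exogenous trial-time modulation, convergent cross mapping with simplex-projection embedding choice; pair selection and rate matching; circular-permutation nulls; false-null-fraction estimation. |
| `dualpop.network_model` | 2x500-unit excitatory/inhibitory rate network with Dale and sparsity constraints, trained by BPTT to reproduce muscle and per-region activity under control and inactivation conditions; across-region input and within-region inhibition analyses. |

## Command line

```bash
dualpop synth make --config cfg.yaml --seed 1 --out session.h5 [--light]
dualpop preprocess run --in session.h5 --out pre/
dualpop perturb run --in session.h5 --out effects/
dualpop geometry align --in session.h5 --out geo/ --lags -30:30
dualpop latents fit --in session.h5 --out latents.csv --across 4 --within 4
dualpop predict run --in session.h5 --out te.csv --metric te
dualpop dualnet train --out net.json --instances 30 --symmetric
```

`cfg.yaml` keys mirror `dualpop.synthetic_data.SynthConfig` fields.

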