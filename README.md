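# edamic

A desk-scale, fully synthetic virtual microscope for **event-driven hybrid
acquisition**: gentle label-free (phase-contrast) surveillance of living
samples, neural-network detection of rare organelle events, and automatic
switching to correlative phase + fluorescence bursts only while something
interesting happens — cutting the light dose, and therefore phototoxicity,
by roughly an order of magnitude per captured event.

Everything runs on one CPU with no deep-learning framework: the detector
networks (plain and stateful U-Nets) train on a small purpose-built numpy
autodiff engine.

## What is in the box

| Module | Purpose |
| --- | --- |
| `edamic.synthsample` | Synthetic phase/fluorescence time-lapses: moving tubular and spherical organelles, scripted transient contacts (~20 s, ~1 per 3.1 min) and divisions with pre-constrictions (~1 per 3.2 min), membrane-ruffle distractors, a light-dose viability model, and the virtual microscope the controller drives. |
| `edamic.detector` | Gaussian-heatmap labels (last five frames of each event), single-frame / multi-frame / stateful (ConvLSTM-bottleneck) U-Net detectors, BCE and soft focal losses, training loop, and the 36 % consistency label-refinement filter. |
| `edamic.evalkit` | Peak extraction, optimal detection–event matching, F_beta scoring (beta = 0.1 prioritizes precision), threshold optimization, best-model selection. |
| `edamic.edacontrol` | The two-state acquisition machine (analyzer → interpreter with memory and thresholding → scheduler), closed-loop runs, duty-cycle/capture statistics. |
| `edamic.downstream` | SYTOX/Hoechst death scoring and exponential survival fits, duty-cycle arithmetic (186 / 192 frames per event under continuous 1 Hz imaging), image-quality metrics, DRP1 daughter-tip ratios, TMRE tracking with 1.5 µm contact classification and flicker detection. |
| `edamic.io`, `edamic.cli`, `edamic.experiment` | ImageJ-style TIFF + CSV formats, YAML configs, run manifests, and the command-line surface. |
| `edamic.benchmarks` | Scaled-down architecture-trend experiments (time points × loss × statefulness). |

## CLI

```sh
# simulate a movie (per-channel TIFFs + events.csv + manifest)
edamic simulate --config sim.yaml --seed 1 --out out/sim

# train seeded detector runs, keep the best-F_0.1 model
edamic train --config train.yaml --data out/sim --runs 5 --out out/model

# optimize the detection threshold, report P/R/F_0.1
edamic evaluate --model out/model/model --data out/sim --out out/eval

# closed-loop smart acquisition (omit --model for the ground-truth oracle)
edamic run-eda --sim sim.yaml --model out/model/model --seed 1 --out out/eda

# downstream quantifications
edamic analyze dutycycle --interval 3.1 --out out/dc
edamic analyze survival --in survival.csv --out out/surv
```

A config YAML holds nested `sim` / `train` / `controller` / `analysis`
sections plus a master `seed`; unknown keys are rejected and every run
writes a manifest with the config hash and seeds used.

```yaml
seed: 1
channels: [phase, mito_fluo]
sim:
  height: 256
  width: 256
  duration: 600.0
  contact_rate: 0.3226   # 1 per 3.1 min
  contact_duration: 20.0
controller:
  score_threshold_up: 0.5
  min_correlative_frames: 20
  correlative_channels: [mito_fluo]
```

## Notes

- Determinism: every simulator/training output is a pure function of
  (config, seed); randomness is keyed per concern (geometry, events, noise,
  death) so toggling one does not perturb the others.
- Acquired EDA movies are written per channel with zero-filled gaps at
  time points where that channel was not exposed.
- Non-goals: real microscope hardware control, rigorous phase-contrast
  optics, GPU training, and reproduction of real-data benchmark scores.
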