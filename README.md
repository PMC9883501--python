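# spikebright

A two-layer stochastic winner-take-all (k-WTA) spiking network for
simulating how surrounding distractors modulate brightness perception of
a fixed gray target.

Grayscale square stimuli (a 0.5-gray 20×20 target on 0.2/0.8
backgrounds, with optional corner distractors of configurable gray
value, size and distance) are encoded by a grid of Difference-of-
Gaussians afferent neurons emitting Poisson spikes.  A second layer of
excitatory and inhibitory neurons with fixed random inhibitory pathways
and plastic feedforward/lateral weights responds stochastically
(logistic spiking from membrane potentials built on double-exponential
synaptic traces, absolute refractoriness).  The network identifies the
presented stimulus every timestep by comparing its excitatory spike
vector to per-stimulus FIFO clustering sets through energy distances;
correct identifications emit a reward that gates eligibility-trace
weight updates.  After learning, images are reconstructed from averaged
responses through the learned weights; pooled-normalized target-region
means quantify perceived brightness, and contextual modulation is
measured by per-neuron CMI histograms and zero-lag cross-correlation
differences.

## Layout

| module | contents |
| --- | --- |
| `spikebright.stimuli` | parametric stimulus images (SBC pair, split backgrounds, corner distractors, anchoring set), PNG + JSON sidecar I/O |
| `spikebright.encoding` | DoG receptive-field grid, stimulus-driven rates, Poisson spikes, double-exponential traces |
| `spikebright.dynamics` | second-layer circuit: connectivity sampling, membrane potentials, stochastic spiking, refractoriness |
| `spikebright.plasticity` | discounted eligibility traces, reward-gated updates, (0,1) clipping |
| `spikebright.identification` | energy distances, resampled acceptance thresholds, softmax actions, FIFO clustering sets |
| `spikebright.analysis` | image reconstruction, pooled normalization, CMI, cross-correlation differences, rate maps |
| `spikebright.experiments` | learning/testing protocol, seed hierarchy, report export |
| `spikebright.cli` | `spikebright` command-line interface |

## Running experiments

Six named experiments are available: `sbc`, `combined`, `anchoring`,
`distance`, `grayscale`, `size`.  Two profiles exist: `paper`
(K=100, J=50, 200 learning / 100 testing simulations, 200 timesteps per
stimulus) and `desk` (K=30, J=15, 50/30, 100 — minutes on a laptop).

```sh
spikebright generate-stimuli distance --outdir stimuli/
spikebright run sbc --profile desk --seed 0 --outdir runs/
spikebright train sbc --profile desk --seed 0 --outdir runs/
spikebright test runs/sbc_desk_seed0_model.npz --outdir runs/
spikebright analyze runs/sbc_desk_seed0_model.npz runs/sbc_desk_seed0_test.npz --outdir runs/report
```

`run` writes a manifest (full config, seed, weight hash), the stimulus
PNGs, a target-means table, per-neuron CMI values and an `arrays.npz`
with weights, rasters, rate maps and cross-correlation differences.
Every run is a pure function of (config, master seed); the master seed
spawns independent streams for receptive-field parameters, connectivity,
excitabilities, initial weights, afferent spikes, network sampling,
identification resampling and stimulus shuffling.

A YAML file passed via `--config` can override any experiment field,
including nested configs:

```yaml
n_learn: 20
network: {N: 900, K: 30, J: 15, rate_max: 0.2}
learning: {eta: 0.01}
```

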