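"""End-to-end experiment orchestration.

Protocol per experiment: build the stimulus set, seed the clustering
sets in a brief labeled warm-up, run ``n_learn`` learning simulations
(stimuli in random order, identification / reward / weight update at
every timestep), then ``n_test`` testing simulations with weights and
clustering sets frozen, and finally compute the perceptual and
modulation readouts.

Everything is a pure function of (spec, master seed): the master seed
spawns independent streams for DoG parameters, connectivity masks,
excitabilities, initial weights, afferent spikes, second-layer
sampling, identification resampling and stimulus shuffling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .dynamics import (
    Connectivity,
    NetworkConfig,
    NetworkState,
    init_weights,
    sample_connectivity,
)
from .encoding import AfferentPopulation, build_grid, stimulus_rates
from .identification import Identifier, IdentificationConfig
from .plasticity import LearningConfig, OnlineLearner
from .stimuli import (
    StimulusImage,
    make_anchoring_set,
    make_combined_background_pair,
    make_distractor_image,
    make_sbc_pair,
    write_png,
)

EXPERIMENT_NAMES = ("sbc", "combined", "anchoring", "distance", "grayscale", "size")

#: network/protocol sizes for the published scale and a desk (CI) scale
PROFILES: dict[str, dict] = {
    "paper": dict(K=100, J=50, n_learn=200, n_test=100, T=200),
    "desk": dict(K=30, J=15, n_learn=50, n_test=30, T=100),
}


class UsageError(ValueError):
    pass


def build_stimuli(name: str, image_size: int = 60) -> list[StimulusImage]:
    """Stimulus sets for the six named experiments.

    The three distractor experiments share the split-background pair as
    stimuli 1/2 (the no-distractor references) and vary one distractor
    property between stimuli 3 and 4: distance to the target (corner
    inset 0 vs 5 px), gray value (0.9 vs 1.0) or size (5 vs 10 px).
    """
    if name == "sbc":
        return make_sbc_pair(image_size=image_size)
    if name == "combined":
        return make_combined_background_pair(image_size=image_size)
    if name == "anchoring":
        return make_anchoring_set(image_size=image_size)
    if name in ("distance", "grayscale", "size"):
        pair = make_combined_background_pair(image_size=image_size, labels=(1, 2))
        variants = {
            "distance": [dict(distractor_inset=0), dict(distractor_inset=5)],
            "grayscale": [dict(distractor_value=0.9), dict(distractor_value=1.0)],
            "size": [dict(distractor_size=5), dict(distractor_size=10)],
        }[name]
        extra = [
            make_distractor_image(image_size=image_size, label=3 + i, **kw)
            for i, kw in enumerate(variants)
        ]
        return pair + extra
    raise UsageError(f"unknown experiment {name!r}; choose from {EXPERIMENT_NAMES}")


@dataclass
class ExperimentSpec:
    """Complete, reproducible description of one experiment run."""

    name: str
    stimuli: list[StimulusImage]
    n_learn: int = 200
    n_test: int = 100
    T_per_stimulus: int = 200
    image_size: int = 60
    spacing: int = 2
    network: NetworkConfig = field(default_factory=NetworkConfig)
    learning: LearningConfig = field(default_factory=LearningConfig)
    ident: IdentificationConfig = field(default_factory=IdentificationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learn < 1 or self.n_test < 1 or self.T_per_stimulus < 1:
            raise UsageError("n_learn, n_test and T_per_stimulus must be >= 1")

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)


def make_spec(
    name: str,
    profile: str = "desk",
    seed: int = 0,
    image_size: int = 60,
    **overrides,
) -> ExperimentSpec:
    if profile not in PROFILES:
        raise UsageError(f"unknown profile {profile!r}")
    prof = PROFILES[profile]
    stimuli = build_stimuli(name, image_size=image_size)
    n_afferent = (image_size // overrides.get("spacing", 2)) ** 2
    network = NetworkConfig(N=n_afferent, K=prof["K"], J=prof["J"])
    spec = ExperimentSpec(
        name=name,
        stimuli=stimuli,
        n_learn=prof["n_learn"],
        n_test=prof["n_test"],
        T_per_stimulus=prof["T"],
        image_size=image_size,
        network=network,
        seed=seed,
    )
    builders = {"network": NetworkConfig, "learning": LearningConfig, "ident": IdentificationConfig}
    for key, value in overrides.items():
        if key in builders and isinstance(value, dict):
            value = builders[key](**value)
        setattr(spec, key, value)
    spec.__post_init__()  # re-validate after overrides
    return spec


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("dog", "connectivity", "excitability", "weights",
             "afferent", "network", "ident", "shuffle")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class TrainedModel:
    spec: ExperimentSpec
    population: AfferentPopulation
    connectivity: Connectivity
    W: np.ndarray
    V: np.ndarray
    identifier: Identifier
    rates: dict[int, np.ndarray]  # per-stimulus afferent firing probabilities

    def weight_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.W.tobytes())
        h.update(self.V.tobytes())
        for members in self.identifier.snapshot():
            h.update(np.ascontiguousarray(members).tobytes())
        return h.hexdigest()


@dataclass
class LearningLog:
    """Per-simulation mean reward over all timesteps and stimuli."""

    reward_rate: np.ndarray  # (n_learn,)


@dataclass
class TestResult:
    z_rasters: dict[int, np.ndarray]  # label -> (n_test, K, T) bool
    x_mean: dict[int, np.ndarray]  # label -> (N,) mean afferent spike rate
    rewards: dict[int, np.ndarray]  # label -> (n_test, T) bool

    @property
    def reward_rate(self) -> float:
        return float(np.mean([r.mean() for r in self.rewards.values()]))


def _prepare(spec: ExperimentSpec, rngs) -> TrainedModel:
    population = build_grid(spec.image_size, spec.spacing, seed=rngs["dog"])
    if population.n_neurons != spec.network.N:
        raise UsageError(
            f"network.N={spec.network.N} but the grid has {population.n_neurons} afferents"
        )
    conn = sample_connectivity(spec.network, rngs["connectivity"], rngs["excitability"])
    W, V = init_weights(spec.network, rngs["weights"])
    rates = {
        stim.label: stimulus_rates(
            population, stim.pixels, spec.network.rate_max, spec.network.rate_sharpness
        )
        for stim in spec.stimuli
    }
    identifier = Identifier(spec.n_stimuli, spec.ident)
    return TrainedModel(spec, population, conn, W, V, identifier, rates)


def _seed_clusters(model: TrainedModel, state: NetworkState, rngs) -> None:
    """Labeled warm-up pass: collect n_seed response vectors per stimulus."""
    spec = model.spec
    T = spec.T_per_stimulus
    pick = np.unique(np.linspace(T // 2, T - 1, spec.ident.n_seed).astype(int))
    for stim in spec.stimuli:
        state.reset_transient()
        x = rngs["afferent"].random((spec.network.N, T)) < model.rates[stim.label][:, None]
        for t in range(T):
            z, _, _ = state.step(x[:, t], rngs["network"])
            if t in pick:
                model.identifier.seed_vector(stim.label, z.astype(float))


def run_learning(spec: ExperimentSpec) -> tuple[TrainedModel, LearningLog]:
    """Warm-up seeding followed by ``n_learn`` shuffled learning simulations."""
    rngs = _spawn_rngs(spec.seed)
    model = _prepare(spec, rngs)
    state = NetworkState(spec.network, model.connectivity, model.W, model.V)
    _seed_clusters(model, state, rngs)

    learner = OnlineLearner(spec.learning, spec.network.K, spec.network.N)
    T = spec.T_per_stimulus
    reward_rate = np.zeros(spec.n_learn)
    for sim in range(spec.n_learn):
        order = rngs["shuffle"].permutation(spec.n_stimuli)
        n_reward = 0
        for si in order:
            stim = spec.stimuli[si]
            state.reset_transient()
            learner.reset()
            x = rngs["afferent"].random((spec.network.N, T)) < model.rates[stim.label][:, None]
            for t in range(T):
                z, _, traces = state.step(x[:, t], rngs["network"])
                _, r, _ = model.identifier.step(
                    z.astype(float), stim.label, rngs["ident"], update=True
                )
                learner.observe(z, traces.x, traces.z, model.W, model.V)
                if r:
                    learner.apply(model.W, model.V, r)
                    n_reward += 1
        reward_rate[sim] = n_reward / (spec.n_stimuli * T)
    return model, LearningLog(reward_rate=reward_rate)


def run_testing(spec: ExperimentSpec, model: TrainedModel) -> TestResult:
    """``n_test`` frozen simulations; weights and clusters must not move."""
    rngs = _spawn_rngs(spec.seed + 1_000_003)  # independent of the learning streams
    state = NetworkState(spec.network, model.connectivity, model.W, model.V)
    T, K, N = spec.T_per_stimulus, spec.network.K, spec.network.N
    before = model.weight_hash()

    z_rasters = {s.label: np.zeros((spec.n_test, K, T), dtype=bool) for s in spec.stimuli}
    rewards = {s.label: np.zeros((spec.n_test, T), dtype=bool) for s in spec.stimuli}
    x_sum = {s.label: np.zeros(N) for s in spec.stimuli}
    for sim in range(spec.n_test):
        for stim in spec.stimuli:
            state.reset_transient()
            x = rngs["afferent"].random((N, T)) < model.rates[stim.label][:, None]
            x_sum[stim.label] += x.mean(axis=1)
            for t in range(T):
                z, _, _ = state.step(x[:, t], rngs["network"])
                z_rasters[stim.label][sim, :, t] = z
                _, r, _ = model.identifier.step(
                    z.astype(float), stim.label, rngs["ident"], update=False
                )
                rewards[stim.label][sim, t] = r

    after = model.weight_hash()
    if before != after:
        raise RuntimeError("testing mutated weights or clustering sets")
    x_mean = {label: s / spec.n_test for label, s in x_sum.items()}
    return TestResult(z_rasters=z_rasters, x_mean=x_mean, rewards=rewards)


@dataclass
class ExperimentReport:
    """Summary readouts of one trained-and-tested experiment."""

    name: str
    seed: int
    target_means: dict[int, float]  # label -> normalized target-region mean
    reconstructions: dict[int, analysis.Reconstruction]
    cmi: dict[int, analysis.CmiResult]  # label -> CMI vs stimulus 1
    xcorr_diff: dict[int, np.ndarray]  # label -> correlation difference vs stimulus 1
    rate_maps: dict[int, tuple[np.ndarray, np.ndarray]]
    spike_counts: dict[int, np.ndarray]
    test_reward_rate: float
    learning_reward_rate: np.ndarray

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stimulus": label,
                "normalized_target_mean": mean,
                "total_spikes": int(self.spike_counts[label].sum()),
            }
            for label, mean in sorted(self.target_means.items())
        ]
        return pd.DataFrame(rows)


def analyze(
    spec: ExperimentSpec, model: TrainedModel, test: TestResult, log: LearningLog
) -> ExperimentReport:
    recs = {}
    for stim in spec.stimuli:
        mean_z = test.z_rasters[stim.label].mean(axis=(0, 2))
        recs[stim.label] = analysis.reconstruct(
            stim, model.W, mean_z, test.x_mean[stim.label], model.population
        )
    ordered = [recs[s.label] for s in spec.stimuli]
    analysis.normalize_set(ordered)
    target_means = {
        s.label: recs[s.label].target_mean(s) for s in spec.stimuli
    }
    counts = {
        label: rast.sum(axis=(0, 2)).astype(int) for label, rast in test.z_rasters.items()
    }
    ref = spec.stimuli[0].label
    cmi = {
        s.label: analysis.cmi(counts[ref], counts[s.label])
        for s in spec.stimuli
        if s.label != ref
    }
    ref_rasters = list(test.z_rasters[ref])
    xdiff = {
        s.label: analysis.xcorr_diff(ref_rasters, list(test.z_rasters[s.label]))
        for s in spec.stimuli
        if s.label != ref
    }
    maps = {label: analysis.rate_map(list(rast)) for label, rast in test.z_rasters.items()}
    return ExperimentReport(
        name=spec.name,
        seed=spec.seed,
        target_means=target_means,
        reconstructions=recs,
        cmi=cmi,
        xcorr_diff=xdiff,
        rate_maps=maps,
        spike_counts=counts,
        test_reward_rate=test.reward_rate,
        learning_reward_rate=log.reward_rate,
    )


def run_experiment(
    name: str,
    profile: str = "desk",
    seed: int = 0,
    outdir: str | Path | None = None,
    **overrides,
) -> ExperimentReport:
    """Full pipeline: stimuli -> learning -> frozen testing -> readouts."""
    spec = make_spec(name, profile=profile, seed=seed, **overrides)
    model, log = run_learning(spec)
    test = run_testing(spec, model)
    report = analyze(spec, model, test, log)
    if outdir is not None:
        export_report(spec, model, test, report, Path(outdir), profile)
    return report


def save_model(model: TrainedModel, path: str | Path, profile: str = "desk") -> Path:
    """Checkpoint a trained model (weights + clusters + provenance).

    The afferent grid, connectivity and stimulus set are not stored:
    they are pure functions of (experiment name, profile, seed) and are
    re-derived on load.
    """
    path = Path(path)
    spec = model.spec
    meta = {
        "experiment": spec.name,
        "profile": profile,
        "seed": spec.seed,
        "weight_hash": model.weight_hash(),
    }
    clusters = {
        f"cluster_{c.label}": np.asarray(c._members, dtype=float)
        for c in model.identifier.clusters
        if len(c)
    }
    np.savez_compressed(path, W=model.W, V=model.V, meta=json.dumps(meta), **clusters)
    return path


def load_model(path: str | Path) -> tuple[TrainedModel, str]:
    """Rebuild a :class:`TrainedModel` from a checkpoint; returns (model, profile)."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        spec = make_spec(meta["experiment"], profile=meta["profile"], seed=meta["seed"])
        rngs = _spawn_rngs(spec.seed)
        model = _prepare(spec, rngs)
        model.W[:] = data["W"]
        model.V[:] = data["V"]
        for cluster in model.identifier.clusters:
            key = f"cluster_{cluster.label}"
            if key in data:
                for row in data[key]:
                    cluster.add(row)
    if model.weight_hash() != meta["weight_hash"]:
        raise RuntimeError("checkpoint hash mismatch after reload")
    return model, meta["profile"]


def export_report(
    spec: ExperimentSpec,
    model: TrainedModel,
    test: TestResult,
    report: ExperimentReport,
    outdir: Path,
    profile: str,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for stim in spec.stimuli:
        write_png(stim, outdir / f"stimulus_{stim.label}.png")
    report.summary_frame().to_csv(outdir / "target_means.csv", index=False)
    cmi_frame = pd.DataFrame(
        {f"cmi_vs1_sti{label}": res.values for label, res in report.cmi.items()}
    )
    cmi_frame.to_csv(outdir / "cmi.csv", index_label="neuron")
    np.savez_compressed(
        outdir / "arrays.npz",
        W=model.W,
        V=model.V,
        **{f"xcorr_diff_sti{label}": m for label, m in report.xcorr_diff.items()},
        **{f"rate_map_sti{label}": m for label, (m, _) in report.rate_maps.items()},
        **{f"z_raster_sti{label}": r for label, r in test.z_rasters.items()},
    )
    manifest = {
        "experiment": spec.name,
        "profile": profile,
        "seed": spec.seed,
        "n_learn": spec.n_learn,
        "n_test": spec.n_test,
        "T_per_stimulus": spec.T_per_stimulus,
        "network": asdict(spec.network),
        "learning": asdict(spec.learning),
        "identification": asdict(spec.ident),
        "weight_hash": model.weight_hash(),
        "test_reward_rate": report.test_reward_rate,
        "normalized_target_means": {str(k): v for k, v in report.target_means.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
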