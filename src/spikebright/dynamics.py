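"""Second-layer circuit dynamics.

K excitatory and J inhibitory neurons with Bernoulli-sampled fixed
connectivity on the inhibitory pathways and plastic weights W (feed-
forward) and V (lateral excitatory).  Excitatory neurons spike
stochastically through a logistic function of their membrane potential;
inhibitory neurons fire Poisson spikes from a rectified-linear rate.
Both carry absolute refractory periods, during which traces keep
decaying but no spike can be emitted.

Within-timestep order: traces are advanced first (so all potentials see
spikes strictly before t), then excitatory spikes are sampled, then
inhibitory spikes, then refractory counters are updated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.special import expit

from .encoding import TraceFilter


class StructuralError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, connection probabilities, fixed weights and time constants."""

    N: int = 900
    K: int = 100
    J: int = 50
    p_EI: float = 0.6
    p_IE: float = 0.575
    p_II: float = 0.55
    v_EI: float = 0.5
    v_IE: float = 0.5
    v_II: float = 0.5
    tau_r: float = 1.0
    tau_f: float = 10.0
    refrac_E: int = 5
    refrac_I: int = 3
    rate_max: float = 0.2
    #: exponent applied to the max-normalized afferent responses; > 1
    #: sparsifies the afferent code onto the strongest edge responses
    rate_sharpness: float = 5.0
    #: lateral E->E input is averaged over the K-1 presynaptic partners
    #: instead of summed; with summed input the recurrent excitation of a
    #: (0,1)-uniform V exceeds the maximum inhibition the fixed pathways
    #: can produce and the network locks into all-fire saturation.
    lateral_fanin_norm: bool = True

    def __post_init__(self) -> None:
        for name in ("p_EI", "p_IE", "p_II"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise StructuralError(f"{name}={p} outside [0, 1]")
        for name in ("v_EI", "v_IE", "v_II"):
            if getattr(self, name) < 0:
                raise StructuralError(f"{name} must be nonnegative")
        if self.refrac_E < 0 or self.refrac_I < 0:
            raise StructuralError("refractory periods must be nonnegative")

    def scaled(self, **overrides) -> "NetworkConfig":
        return replace(self, **overrides)


@dataclass(frozen=True)
class Connectivity:
    """Fixed Bernoulli masks and excitabilities, immutable after sampling."""

    m_ei: np.ndarray  # (K, J) inhibitory -> excitatory
    m_ie: np.ndarray  # (J, K) excitatory -> inhibitory
    m_ii: np.ndarray  # (J, J) inhibitory -> inhibitory, zero diagonal
    b: np.ndarray  # (K,) excitabilities

    def __post_init__(self) -> None:
        for m in (self.m_ei, self.m_ie, self.m_ii, self.b):
            m.setflags(write=False)


def sample_connectivity(
    config: NetworkConfig,
    seed: int | np.random.Generator,
    b_seed: int | np.random.Generator | None = None,
) -> Connectivity:
    """Independent Bernoulli masks for the inhibitory pathways, b ~ U(0, 1).

    ``b_seed`` lets the excitabilities come from their own stream so the
    masks can be varied independently of ``b``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if b_seed is None:
        b_rng = rng
    else:
        b_rng = b_seed if isinstance(b_seed, np.random.Generator) else np.random.default_rng(b_seed)
    K, J = config.K, config.J
    m_ei = rng.random((K, J)) < config.p_EI
    m_ie = rng.random((J, K)) < config.p_IE
    m_ii = rng.random((J, J)) < config.p_II
    np.fill_diagonal(m_ii, False)  # no self-inhibition
    b = b_rng.uniform(0.0, 1.0, size=K)
    return Connectivity(m_ei.astype(float), m_ie.astype(float), m_ii.astype(float), b)


def init_weights(
    config: NetworkConfig, seed: int | np.random.Generator, low: float = 0.001, high: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Plastic weights sampled independently from U(low, high); V has zero diagonal."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W = rng.uniform(low, high, size=(config.K, config.N))
    V = rng.uniform(low, high, size=(config.K, config.K))
    np.fill_diagonal(V, 0.0)
    return W, V


class Traces(NamedTuple):
    x: np.ndarray
    z: np.ndarray
    y: np.ndarray


@dataclass
class SpikeRaster:
    """Binary spike records for one simulation."""

    z: np.ndarray  # (K, T) excitatory
    y: np.ndarray  # (J, T) inhibitory
    x: np.ndarray | None = None  # (N, T) afferent, optional

    @property
    def T(self) -> int:
        return self.z.shape[1]

    def save(self, path, **metadata) -> None:
        arrays = {"z": self.z, "y": self.y}
        if self.x is not None:
            arrays["x"] = self.x
        np.savez_compressed(path, **arrays, **metadata)

    @classmethod
    def load(cls, path) -> "SpikeRaster":
        with np.load(path) as data:
            return cls(z=data["z"], y=data["y"], x=data["x"] if "x" in data else None)


def excitatory_potential(
    W, V, conn: Connectivity, traces: Traces, v_EI: float, lateral_scale: float = 1.0
) -> np.ndarray:
    """Membrane potentials of all excitatory neurons at the current timestep."""
    return (
        W @ traces.x
        + lateral_scale * (V @ traces.z)
        - v_EI * (conn.m_ei @ traces.y)
        + conn.b
    )


def excitatory_spike_probability(u: np.ndarray) -> np.ndarray:
    """Logistic spike probability exp(u) / (1 + exp(u))."""
    return expit(u)


def inhibitory_rate(conn: Connectivity, traces: Traces, v_IE: float, v_II: float) -> np.ndarray:
    """Rectified-linear instantaneous rates of all inhibitory neurons."""
    u = v_IE * (conn.m_ie @ traces.z) - v_II * (conn.m_ii @ traces.y)
    return np.clip(u, 0.0, None)


class NetworkState:
    """Mutable simulation state: weights, traces, refractory counters."""

    def __init__(
        self,
        config: NetworkConfig,
        connectivity: Connectivity,
        W: np.ndarray,
        V: np.ndarray,
    ):
        if W.shape != (config.K, config.N) or V.shape != (config.K, config.K):
            raise StructuralError("weight shapes inconsistent with config")
        self.config = config
        self.conn = connectivity
        self.W = W
        self.V = V
        self._tr_x = TraceFilter(config.N, config.tau_r, config.tau_f)
        self._tr_z = TraceFilter(config.K, config.tau_r, config.tau_f)
        self._tr_y = TraceFilter(config.J, config.tau_r, config.tau_f)
        self.refrac_z = np.zeros(config.K, dtype=int)
        self.refrac_y = np.zeros(config.J, dtype=int)
        self.lateral_scale = (
            1.0 / max(config.K - 1, 1) if config.lateral_fanin_norm else 1.0
        )
        self.t = 0

    def reset_transient(self) -> None:
        """Clear traces and refractory counters (weights untouched)."""
        for tr in (self._tr_x, self._tr_z, self._tr_y):
            tr.reset()
        self.refrac_z[:] = 0
        self.refrac_y[:] = 0
        self.t = 0

    def step(
        self, afferent_spikes_t: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, Traces]:
        """Advance one timestep; returns (z_t, y_t, traces used at t)."""
        cfg = self.config
        if afferent_spikes_t.shape != (cfg.N,):
            raise StructuralError("afferent spike vector has wrong length")
        traces = Traces(self._tr_x.advance(), self._tr_z.advance(), self._tr_y.advance())

        u = excitatory_potential(
            self.W, self.V, self.conn, traces, cfg.v_EI, self.lateral_scale
        )
        p_z = expit(u)
        z = (rng.random(cfg.K) < p_z) & (self.refrac_z == 0)

        rho = inhibitory_rate(self.conn, traces, cfg.v_IE, cfg.v_II)
        p_y = -np.expm1(-rho)  # Poisson, at most one spike per timestep
        y = (rng.random(cfg.J) < p_y) & (self.refrac_y == 0)

        np.subtract(self.refrac_z, 1, out=self.refrac_z, where=self.refrac_z > 0)
        np.subtract(self.refrac_y, 1, out=self.refrac_y, where=self.refrac_y > 0)
        self.refrac_z[z] = cfg.refrac_E
        self.refrac_y[y] = cfg.refrac_I

        self._tr_x.record(afferent_spikes_t.astype(float))
        self._tr_z.record(z.astype(float))
        self._tr_y.record(y.astype(float))
        self.t += 1
        return z, y, traces


def simulate(
    state: NetworkState,
    afferent_spikes: np.ndarray,
    rng: np.random.Generator,
    on_step=None,
) -> SpikeRaster:
    """Run ``T`` timesteps driven by an ``(N, T)`` afferent raster.

    ``on_step(t, z_t, y_t, traces)`` is invoked after each timestep and
    may implement identification and plasticity.
    """
    cfg = state.config
    if afferent_spikes.shape[0] != cfg.N:
        raise StructuralError("afferent raster has wrong neuron count")
    T = afferent_spikes.shape[1]
    z_rast = np.zeros((cfg.K, T), dtype=bool)
    y_rast = np.zeros((cfg.J, T), dtype=bool)
    for t in range(T):
        z, y, traces = state.step(afferent_spikes[:, t], rng)
        z_rast[:, t] = z
        y_rast[:, t] = y
        if on_step is not None:
            on_step(t, z, y, traces)
    return SpikeRaster(z=z_rast, y=y_rast, x=afferent_spikes.astype(bool))


def check_refractory(raster: np.ndarray, refrac: int) -> bool:
    """True when no neuron spikes twice within ``refrac`` timesteps."""
    spikes = np.asarray(raster, dtype=bool)
    for row in spikes:
        times = np.flatnonzero(row)
        if times.size > 1 and np.diff(times).min() <= refrac:
            return False
    return True
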