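"""First-layer afferent encoding.

Difference-of-Gaussians (DoG) receptive fields sit on a regular grid
covering the image.  A stimulus drives per-neuron firing probabilities
(rectified, max-normalized filter responses), spikes are Bernoulli per
timestep, and spike trains feed double-exponential synaptic traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


class ParameterError(ValueError):
    pass


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class ReceptiveField:
    """Isotropic center-surround DoG filter.

    ``value(x) = exp(-d^2 / sigma_c^2) - ratio * exp(-d^2 / sigma_s^2)``
    with ``d`` the Euclidean distance from ``center``.
    """

    center: tuple[float, float]
    sigma_c: float
    sigma_s: float
    ratio: float

    def __post_init__(self) -> None:
        if not (self.sigma_s > self.sigma_c > 0):
            raise ParameterError("need sigma_s > sigma_c > 0")
        if self.ratio < 0:
            raise ParameterError("surround ratio must be nonnegative")


def dog_filter_value(point: tuple[float, float], field: ReceptiveField) -> float:
    """Evaluate a DoG filter at a single point."""
    d2 = (point[0] - field.center[0]) ** 2 + (point[1] - field.center[1]) ** 2
    return float(
        np.exp(-d2 / field.sigma_c**2) - field.ratio * np.exp(-d2 / field.sigma_s**2)
    )


def default_rf_sampler(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Default DoG parameter draws: sigma_c ~ U(1.5, 3), sigma_s = 2 sigma_c.

    The surround ratio is the balanced value ``(sigma_c / sigma_s)**2``,
    which makes every filter integrate to ~0 over the plane: uniform
    luminance evokes no response and only local contrast drives rates.
    A larger ratio (surround-dominated) would make the response to any
    nonnegative image negative everywhere and silence the population.
    """
    sigma_c = rng.uniform(1.5, 3.0, size=n)
    sigma_s = 2.0 * sigma_c
    return {"sigma_c": sigma_c, "sigma_s": sigma_s, "ratio": (sigma_c / sigma_s) ** 2}


class AfferentPopulation:
    """Grid of DoG receptive fields over a square image.

    Parameters are sampled once at construction and then fixed; the
    per-pixel filter bank is computed lazily and cached.
    """

    def __init__(self, fields: list[ReceptiveField], image_size: int, spacing: int):
        self.fields = fields
        self.image_size = int(image_size)
        self.spacing = int(spacing)
        self._bank: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.fields)

    @property
    def n_neurons(self) -> int:
        return len(self.fields)

    def filter_bank(self) -> np.ndarray:
        """``(N, H*W)`` matrix of filter values at every pixel center."""
        if self._bank is None:
            s = self.image_size
            rr, cc = np.meshgrid(np.arange(s, dtype=float), np.arange(s, dtype=float),
                                 indexing="ij")
            pts_r, pts_c = rr.ravel(), cc.ravel()
            centers = np.array([f.center for f in self.fields])
            sig_c = np.array([f.sigma_c for f in self.fields])[:, None]
            sig_s = np.array([f.sigma_s for f in self.fields])[:, None]
            ratio = np.array([f.ratio for f in self.fields])[:, None]
            d2 = (pts_r[None, :] - centers[:, :1]) ** 2 + (pts_c[None, :] - centers[:, 1:]) ** 2
            self._bank = np.exp(-d2 / sig_c**2) - ratio * np.exp(-d2 / sig_s**2)
        return self._bank

    def filter_responses(self, image: np.ndarray) -> np.ndarray:
        """Per-neuron inner products between the image and each filter."""
        image = np.asarray(image, dtype=float)
        if image.shape != (self.image_size, self.image_size):
            raise GridError(
                f"image shape {image.shape} does not match grid extent "
                f"({self.image_size}, {self.image_size})"
            )
        return self.filter_bank() @ image.ravel()


def build_grid(
    image_size: int,
    spacing: int,
    rf_param_sampler: Callable[[np.random.Generator, int], dict[str, np.ndarray]] | None = None,
    seed: int | np.random.Generator = 0,
) -> AfferentPopulation:
    """Place one receptive field per grid point.

    ``spacing`` must divide ``image_size``; the grid then has
    ``(image_size / spacing)**2`` fields with centers at the middle of
    each ``spacing x spacing`` block.
    """
    if image_size % spacing != 0:
        raise GridError(f"spacing {spacing} does not divide image size {image_size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = rf_param_sampler or default_rf_sampler
    side = image_size // spacing
    n = side * side
    params = sampler(rng, n)
    offset = (spacing - 1) / 2.0
    fields = []
    i = 0
    for r in range(side):
        for c in range(side):
            fields.append(
                ReceptiveField(
                    center=(r * spacing + offset, c * spacing + offset),
                    sigma_c=float(params["sigma_c"][i]),
                    sigma_s=float(params["sigma_s"][i]),
                    ratio=float(params["ratio"][i]),
                )
            )
            i += 1
    return AfferentPopulation(fields, image_size, spacing)


def stimulus_rates(
    population: AfferentPopulation,
    image: np.ndarray,
    rate_max: float = 0.05,
    sharpness: float = 1.0,
) -> np.ndarray:
    """Per-timestep firing probabilities for one stimulus.

    Rectified filter responses, normalized by their maximum, raised to
    ``sharpness`` and scaled by ``rate_max``; all-zero when no response
    is positive.  ``sharpness > 1`` concentrates the code on the most
    strongly driven afferents (the normalized responses are in [0, 1],
    so the exponent preserves image-scale invariance).
    """
    if not 0.0 < rate_max <= 1.0:
        raise ParameterError("rate_max must be a per-timestep probability in (0, 1]")
    if sharpness <= 0:
        raise ParameterError("sharpness must be positive")
    a = population.filter_responses(image)
    rect = np.clip(a, 0.0, None)
    peak = rect.max()
    if peak <= 0.0:
        return np.zeros_like(rect)
    return rate_max * (rect / peak) ** sharpness


def generate_afferent_spikes(
    rates: np.ndarray, T: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli(rate) spikes: boolean ``(N, T)`` raster."""
    if T < 1:
        raise ParameterError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=float)
    return rng.random((rates.size, T)) < rates[:, None]


# ---------------------------------------------------------------------------
# double-exponential synaptic traces

def trace_kernel(delta: np.ndarray | float, tau_r: float = 1.0, tau_f: float = 10.0):
    """Causal double-exponential kernel ``exp(-d/tau_f) - exp(-d/tau_r)`` for d >= 0."""
    if tau_f <= tau_r:
        raise ParameterError("need tau_f > tau_r")
    delta = np.asarray(delta, dtype=float)
    out = np.where(delta >= 0, np.exp(-delta / tau_f) - np.exp(-delta / tau_r), 0.0)
    return float(out) if out.ndim == 0 else out


def kernel_peak_time(tau_r: float = 1.0, tau_f: float = 10.0) -> float:
    """Lag at which the trace kernel is maximal."""
    return tau_r * tau_f * np.log(tau_f / tau_r) / (tau_f - tau_r)


class TraceFilter:
    """Recursive two-exponential state equivalent to the kernel sum.

    ``advance()`` moves the state one timestep forward and returns the
    trace vector for the new timestep; ``record(spikes)`` adds spikes
    emitted at the current timestep (they contribute 0 now, per the
    kernel value at lag 0, and decay in later).
    """

    def __init__(self, n: int, tau_r: float = 1.0, tau_f: float = 10.0):
        if tau_f <= tau_r:
            raise ParameterError("need tau_f > tau_r")
        self._decay_r = np.exp(-1.0 / tau_r)
        self._decay_f = np.exp(-1.0 / tau_f)
        self._state_r = np.zeros(n)
        self._state_f = np.zeros(n)

    def reset(self) -> None:
        self._state_r[:] = 0.0
        self._state_f[:] = 0.0

    def advance(self) -> np.ndarray:
        self._state_r *= self._decay_r
        self._state_f *= self._decay_f
        return self._state_f - self._state_r

    def record(self, spikes: np.ndarray) -> None:
        self._state_r += spikes
        self._state_f += spikes


def update_traces(
    raster_history: np.ndarray, t: int, tau_r: float = 1.0, tau_f: float = 10.0
) -> np.ndarray:
    """Trace vector at timestep ``t`` from a ``(N, T)`` spike raster.

    Explicit kernel-sum form; the recursive :class:`TraceFilter` must
    agree with this to numerical precision.
    """
    raster = np.asarray(raster_history)
    if not 0 <= t < raster.shape[1]:
        raise ParameterError(f"t={t} outside raster history of length {raster.shape[1]}")
    lags = t - np.arange(t + 1, dtype=float)
    kern = trace_kernel(lags, tau_r, tau_f)
    return raster[:, : t + 1].astype(float) @ kern
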