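"""Perceptual and modulation readouts.

Brightness perception is operationalized as a linear reconstruction of
the image from mean network responses through the learned feedforward
weights and the afferent filter bank; compared reconstructions share one
pooled mean/SD for normalization.  Response modulation between two
conditions is quantified per neuron by the contextual modulation index
(CMI) and per neuron pair by differences of zero-lag Pearson
correlations of spike trains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import AfferentPopulation
from .stimuli import StimulusImage


class DegenerateInputError(ValueError):
    pass


@dataclass
class Reconstruction:
    """A reconstructed image grid, optionally with its pooled-normalized form."""

    values: np.ndarray
    normalized: np.ndarray | None = None

    def target_mean(self, stim: StimulusImage, normalized: bool = True) -> float:
        grid = self.normalized if normalized else self.values
        if grid is None:
            raise DegenerateInputError("reconstruction not normalized yet")
        return float(grid[stim.target_region.slices].mean())


def reconstruct(
    image: StimulusImage | np.ndarray,
    W: np.ndarray,
    mean_rates_z: np.ndarray,
    mean_rates_x: np.ndarray,
    population: AfferentPopulation,
) -> Reconstruction:
    """Linear readout ``I_rec(x) = sum_{k,n} zbar_k w_kn xbar_n a_n f_n(x)``.

    ``a_n`` is the filter response of neuron ``n`` to the stimulus
    itself and ``f_n`` its spatial filter; ``zbar`` / ``xbar`` are mean
    firing rates of second-layer excitatory and afferent neurons.
    """
    pixels = image.pixels if isinstance(image, StimulusImage) else np.asarray(image)
    a = population.filter_responses(pixels)
    coeff = (np.asarray(mean_rates_z) @ W) * np.asarray(mean_rates_x) * a
    flat = coeff @ population.filter_bank()
    return Reconstruction(values=flat.reshape(pixels.shape))


def normalize_set(reconstructions: list[Reconstruction]) -> list[Reconstruction]:
    """Z-score every grid with the single mean/SD pooled over the whole set."""
    if len(reconstructions) < 2:
        raise DegenerateInputError("need at least two reconstructions to compare")
    pooled = np.concatenate([r.values.ravel() for r in reconstructions])
    mu, sd = pooled.mean(), pooled.std()
    if sd == 0.0:
        raise DegenerateInputError("pooled standard deviation is zero")
    for r in reconstructions:
        r.normalized = (r.values - mu) / sd
    return reconstructions


@dataclass
class CmiResult:
    values: np.ndarray  # NaN where excluded
    excluded: np.ndarray  # boolean mask of 0/0 neurons

    @property
    def defined(self) -> np.ndarray:
        return self.values[~self.excluded]


def cmi(counts_1: np.ndarray, counts_2: np.ndarray) -> CmiResult:
    """Contextual modulation index ``(r1 - r2) / (r1 + r2)`` per neuron.

    Neurons silent under both conditions (0/0) are flagged excluded.
    """
    r1 = np.asarray(counts_1, dtype=float)
    r2 = np.asarray(counts_2, dtype=float)
    if np.any(r1 < 0) or np.any(r2 < 0):
        raise ValueError("spike counts must be nonnegative")
    total = r1 + r2
    excluded = total == 0
    values = np.full(r1.shape, np.nan)
    np.divide(r1 - r2, total, out=values, where=~excluded)
    return CmiResult(values=values, excluded=excluded)


def zero_lag_correlation(raster: np.ndarray) -> np.ndarray:
    """K x K zero-lag Pearson correlations of binary spike trains.

    Pairs involving a constant train are undefined and set to 0; the
    diagonal is 1 for non-constant trains.
    """
    X = np.asarray(raster, dtype=float)
    sd = X.std(axis=1)
    ok = sd > 0
    corr = np.zeros((X.shape[0], X.shape[0]))
    if ok.sum() >= 1:
        sub = np.corrcoef(X[ok])
        sub = np.atleast_2d(sub)
        corr[np.ix_(ok, ok)] = sub
    return corr


def mean_correlation(rasters: list[np.ndarray]) -> np.ndarray:
    """Per-pair correlations averaged over simulations (constant trains count 0)."""
    if not rasters:
        raise ValueError("need at least one raster")
    return np.mean([zero_lag_correlation(r) for r in rasters], axis=0)


def xcorr_diff(
    raster_pairs_condA: list[np.ndarray], raster_pairs_condB: list[np.ndarray]
) -> np.ndarray:
    """Difference (A - B) of simulation-averaged zero-lag correlation matrices."""
    a = mean_correlation(raster_pairs_condA)
    b = mean_correlation(raster_pairs_condB)
    if a.shape != b.shape:
        raise ValueError("conditions have different neuron counts")
    return a - b


def rate_map(rasters: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean spike indicator per (neuron, timestep), rows sorted by total response.

    Returns ``(map, order)`` with ``order`` the original neuron indices
    in descending responsiveness.
    """
    if not rasters:
        raise ValueError("need at least one raster")
    mean = np.mean([np.asarray(r, dtype=float) for r in rasters], axis=0)
    order = np.argsort(-mean.sum(axis=1), kind="stable")
    return mean[order], order
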