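"""Reward-gated plasticity.

Weight-update directions are discounted sums over the spike history of
``z_post * (pre_trace - h(w))`` where ``h(w) = 1 - 1/w + 1/(e^w - 1)``
repels weights from the boundaries of (0, 1).  The discounted sums are
realized as per-synapse eligibility accumulators that decay by the
discount factor each timestep; an update is applied only on rewarded
timesteps, and weights are clipped to stay strictly inside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class LearningConfig:
    gamma: float = 0.9
    eta: float = 0.01
    clip_eps: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ParameterError("gamma must lie in (0, 1)")
        if self.eta <= 0:
            raise ParameterError("eta must be positive")
        if not 0.0 < self.clip_eps < 0.5:
            raise ParameterError("clip_eps must lie in (0, 0.5)")


def subsequence_weight(T: int, gamma: float) -> float:
    """Discounted contribution ``(1 - gamma) * gamma**(T - 1)`` of a T-step sub-sequence."""
    if T < 1:
        raise ParameterError("sub-sequence length must be >= 1")
    return (1.0 - gamma) * gamma ** (T - 1)


def weight_penalty(w):
    """Boundary term ``h(w) = 1 - 1/w + 1/(e^w - 1)`` on (0, 1).

    Monotone increasing; diverges to -inf as w -> 0+, keeping weights
    away from zero once subtracted from the presynaptic trace.
    """
    w = np.asarray(w, dtype=float)
    if np.any((w <= 0.0) | (w >= 1.0)):
        raise ParameterError("weights must lie strictly in (0, 1)")
    out = 1.0 - 1.0 / w + 1.0 / np.expm1(w)
    return float(out) if out.ndim == 0 else out


def _penalty_masked(M: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """h(M) with excluded entries (e.g. the V diagonal) forced to 0."""
    out = np.zeros_like(M)
    if mask is None:
        return weight_penalty(M)
    valid = ~mask
    out[valid] = 1.0 - 1.0 / M[valid] + 1.0 / np.expm1(M[valid])
    return out


class EligibilityState:
    """Discounted accumulators E_W (K x N) and E_V (K x K)."""

    def __init__(self, K: int, N: int):
        self.E_W = np.zeros((K, N))
        self.E_V = np.zeros((K, K))
        self._diag = np.eye(K, dtype=bool)

    def reset(self) -> None:
        self.E_W[:] = 0.0
        self.E_V[:] = 0.0

    def accumulate(
        self,
        spikes_z_t: np.ndarray,
        traces_x_t: np.ndarray,
        traces_z_t: np.ndarray,
        W: np.ndarray,
        V: np.ndarray,
        gamma: float,
    ) -> None:
        """One recursive step ``E <- gamma * E + z_t (x) (pre_trace - h(w))``.

        Equivalent to the explicit discounted sum over the history with
        the penalty evaluated at the weights current at each timestep.
        """
        z = np.asarray(spikes_z_t, dtype=float)
        self.E_W *= gamma
        self.E_V *= gamma
        active = z > 0
        if active.any():
            self.E_W[active] += traces_x_t[None, :] - weight_penalty(W[active])
            self.E_V[active] += traces_z_t[None, :] - _penalty_masked(
                V, self._diag
            )[active]
            self.E_V[self._diag] = 0.0


def apply_update(
    W: np.ndarray,
    V: np.ndarray,
    elig: EligibilityState,
    r_t: int,
    eta: float,
    clip_eps: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient-ascent step gated by the binary reward (in place).

    ``r_t = 0`` leaves the weights bitwise unchanged; ``r_t = 1`` moves
    each weight by ``eta`` times its eligibility and clips into
    ``[clip_eps, 1 - clip_eps]``.  The V diagonal stays zero.
    """
    if r_t not in (0, 1):
        raise ParameterError("reward must be binary")
    if r_t:
        np.clip(W + eta * elig.E_W, clip_eps, 1.0 - clip_eps, out=W)
        np.clip(V + eta * elig.E_V, clip_eps, 1.0 - clip_eps, out=V)
        np.fill_diagonal(V, 0.0)
    return W, V


class OnlineLearner:
    """Per-timestep learning loop helper bound to one (W, V) pair."""

    def __init__(self, config: LearningConfig, K: int, N: int):
        self.config = config
        self.elig = EligibilityState(K, N)

    def reset(self) -> None:
        self.elig.reset()

    def observe(self, z_t, traces_x_t, traces_z_t, W, V) -> None:
        self.elig.accumulate(z_t, traces_x_t, traces_z_t, W, V, self.config.gamma)

    def apply(self, W, V, r_t: int) -> None:
        apply_update(W, V, self.elig, r_t, self.config.eta, self.config.clip_eps)
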