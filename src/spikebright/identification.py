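"""Unsupervised stimulus identification.

At every timestep the K-dimensional excitatory spike vector is compared
to per-stimulus FIFO clustering sets through energy distances.  A
leave-one-out resampling scheme turns each cluster into an acceptance
threshold; the common (minimum) threshold converts bootstrap energy
distances into membership probabilities, a softmax over those draws the
action, and a correct action emits reward 1 and appends the vector to
its cluster (evicting from the front past capacity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class StateError(RuntimeError):
    pass


@dataclass(frozen=True)
class IdentificationConfig:
    alpha_sig: float = 0.05
    R: int = 50
    n_cluster: int = 20
    n_seed: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_sig < 1.0:
            raise ValueError("alpha_sig must lie in (0, 1)")
        if self.R < 1:
            raise ValueError("R must be >= 1")


def _linear_quantile(values: np.ndarray, q: float) -> float:
    """Empirical quantile with linear interpolation (as ``np.quantile`` default)."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = q * (v.size - 1)
    lo = int(pos)
    hi = min(lo + 1, v.size - 1)
    frac = pos - lo
    return float(v[lo] + frac * (v[hi] - v[lo]))


def energy_distance(z: np.ndarray, members: np.ndarray) -> float:
    """Energy distance between the singleton {z} and a member set.

    ``e = (2/m) sum_i ||z - c_i|| - (1/m^2) sum_ij ||c_i - c_j||``;
    nonnegative, zero iff every member equals z.
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    m = members.shape[0]
    if m == 0:
        raise StateError("cluster is empty; seed it before querying")
    z = np.asarray(z, dtype=float)
    term1 = 2.0 * np.linalg.norm(members - z, axis=1).mean()
    diffs = members[:, None, :] - members[None, :, :]
    term2 = np.sqrt((diffs**2).sum(-1)).sum() / m**2
    return float(term1 - term2)


class ClusteringSet:
    """FIFO store of accepted binary response vectors for one stimulus.

    Caches the pairwise member-distance matrix and the leave-one-out
    energy distances, recomputed whenever membership changes.
    """

    def __init__(self, label: int, capacity: int = 20):
        self.label = int(label)
        self.capacity = int(capacity)
        self._members: list[np.ndarray] = []
        self._dirty = True
        self._pairwise: np.ndarray | None = None
        self._loo: np.ndarray | None = None
        self.version = 0  # bumped on every membership change

    def __len__(self) -> int:
        return len(self._members)

    @property
    def members(self) -> np.ndarray:
        if not self._members:
            raise StateError(f"cluster {self.label} is empty")
        return np.asarray(self._members, dtype=float)

    def add(self, z: np.ndarray) -> None:
        """Append at the end; evict from the front while over capacity."""
        self._members.append(np.asarray(z, dtype=float).copy())
        while len(self._members) > self.capacity:
            self._members.pop(0)
        self._dirty = True
        self.version += 1

    def _refresh(self) -> None:
        if not self._dirty:
            return
        M = self.members
        m = M.shape[0]
        diffs = M[:, None, :] - M[None, :, :]
        D = np.sqrt((diffs**2).sum(-1))
        self._pairwise = D
        if m >= 2:
            row = D.sum(axis=1)
            total = D.sum()
            # energy distance of member i to the remaining m-1 members
            self._loo = 2.0 * row / (m - 1) - (total - 2.0 * row) / (m - 1) ** 2
        else:
            self._loo = None
        self._dirty = False

    def energy_distance(self, z: np.ndarray) -> float:
        self._refresh()
        M = self.members
        term1 = 2.0 * np.linalg.norm(M - np.asarray(z, dtype=float), axis=1).mean()
        return float(term1 - self._pairwise.sum() / M.shape[0] ** 2)

    def loo_distances(self) -> np.ndarray:
        self._refresh()
        if self._loo is None:
            raise StateError("need at least 2 members for leave-one-out distances")
        return self._loo

    def acceptance_threshold(
        self, alpha_sig: float, R: int, rng: np.random.Generator
    ) -> float:
        """(1 - alpha) quantile of R leave-one-out resampled distances."""
        loo = self.loo_distances()
        picks = rng.integers(len(self._members), size=R)
        return _linear_quantile(loo[picks], 1.0 - alpha_sig)

    def bootstrap_membership(
        self, z: np.ndarray, threshold: float, R: int, rng: np.random.Generator
    ) -> float:
        """Fraction of R with-replacement resamples with e(z, resample) <= threshold.

        Each resample of indices enters through its count vector ``c``:
        ``e = 2 (c . dz) / m - (c^T D c) / m^2``, identical to summing
        over resampled members explicitly.
        """
        self._refresh()
        M = self.members
        m = M.shape[0]
        dz = np.sqrt(((M - np.asarray(z, dtype=float)) ** 2).sum(axis=1))
        idx = rng.integers(m, size=(R, m))
        counts = np.bincount(
            (np.arange(R)[:, None] * m + idx).ravel(), minlength=R * m
        ).reshape(R, m).astype(float)
        term1 = 2.0 * (counts @ dz) / m
        term2 = ((counts @ self._pairwise) * counts).sum(axis=1) / m**2
        return float(np.mean(term1 - term2 <= threshold))


def acceptance_threshold(
    cluster: ClusteringSet, alpha_sig: float, R: int, seed: int | np.random.Generator
) -> float:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(cluster) < 2:
        raise StateError("cluster too small for threshold estimation")
    return cluster.acceptance_threshold(alpha_sig, R, rng)


def membership_probability(
    z: np.ndarray,
    clusters: list[ClusteringSet],
    alpha_sig: float,
    R: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Per-stimulus membership probabilities under the common threshold.

    The common threshold is the minimum of the per-cluster acceptance
    thresholds; draws happen cluster by cluster in list order (first all
    thresholds, then all bootstrap resamples).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    thresholds = [c.acceptance_threshold(alpha_sig, R, rng) for c in clusters]
    common = min(thresholds)
    return np.array([c.bootstrap_membership(z, common, R, rng) for c in clusters])


def _batched_membership(
    z: np.ndarray,
    clusters: list["ClusteringSet"],
    alpha_sig: float,
    R: int,
    rng: np.random.Generator,
    cache: dict | None = None,
) -> np.ndarray:
    """Vectorized :func:`membership_probability` for equal-size clusters.

    Consumes the random stream in exactly the same order as the
    reference implementation (all threshold picks cluster by cluster,
    then all bootstrap index blocks cluster by cluster); only the
    arithmetic is batched.  ``cache`` optionally carries the stacked
    member arrays between calls, keyed by the cluster versions.
    """
    S = len(clusters)
    m = len(clusters[0])
    key = tuple(c.version for c in clusters)
    if cache is not None and cache.get("key") == key:
        loo, members, D = cache["loo"], cache["members"], cache["D"]
    else:
        loo = np.stack([c.loo_distances() for c in clusters])
        members = np.stack([c.members for c in clusters])  # (S, m, K)
        D = np.stack([c._pairwise for c in clusters])
        if cache is not None:
            cache.update(key=key, loo=loo, members=members, D=D)

    picks = rng.integers(m, size=(S, R))
    vals = np.sort(np.take_along_axis(loo, picks, axis=1), axis=1)
    pos = (1.0 - alpha_sig) * (R - 1)
    lo = int(pos)
    hi = min(lo + 1, R - 1)
    frac = pos - lo
    thresholds = vals[:, lo] + frac * (vals[:, hi] - vals[:, lo])
    common = thresholds.min()

    dz = np.sqrt(((members - np.asarray(z, dtype=float)) ** 2).sum(-1))  # (S, m)
    idx = rng.integers(m, size=(S, R, m))
    flat = (np.arange(S * R)[:, None] * m + idx.reshape(S * R, m)).ravel()
    counts = np.bincount(flat, minlength=S * R * m).reshape(S, R, m).astype(float)
    term1 = 2.0 * np.einsum("srm,sm->sr", counts, dz) / m
    term2 = ((counts @ D) * counts).sum(-1) / m**2
    return ((term1 - term2) <= common).mean(axis=1)


def sample_action(p_vector: np.ndarray, seed: int | np.random.Generator) -> int:
    """Draw a 1-based action from the softmax of the membership probabilities."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_vector = np.asarray(p_vector, dtype=float)
    w = np.exp(p_vector)
    cum = np.cumsum(w)
    u = rng.random() * cum[-1]
    return int(np.searchsorted(cum, u, side="right")) + 1


def reward_and_update(
    a_t: int,
    true_label: int,
    z: np.ndarray,
    clusters: list[ClusteringSet],
    update: bool = True,
) -> int:
    """Binary reward; on a correct identification append z to its cluster (FIFO)."""
    r_t = int(a_t == true_label)
    if r_t and update:
        for c in clusters:
            if c.label == true_label:
                c.add(z)
                break
        else:
            raise StateError(f"no cluster with label {true_label}")
    return r_t


class Identifier:
    """Stateful per-timestep identification loop over S clustering sets."""

    def __init__(self, n_stimuli: int, config: IdentificationConfig | None = None):
        self.config = config or IdentificationConfig()
        self.clusters = [
            ClusteringSet(s, self.config.n_cluster) for s in range(1, n_stimuli + 1)
        ]
        self._cache: dict = {}

    def cluster(self, label: int) -> ClusteringSet:
        return self.clusters[label - 1]

    def seed_vector(self, label: int, z: np.ndarray) -> None:
        """Warm-up seeding: append without reward bookkeeping."""
        self.cluster(label).add(z)

    @property
    def seeded(self) -> bool:
        return all(len(c) >= 2 for c in self.clusters)

    def step(
        self,
        z_t: np.ndarray,
        true_label: int,
        rng: np.random.Generator,
        update: bool = True,
    ) -> tuple[int, int, np.ndarray]:
        """One identification: returns (action, reward, membership probabilities)."""
        cfg = self.config
        sizes = {len(c) for c in self.clusters}
        if len(sizes) == 1 and min(sizes) >= 2:
            p = _batched_membership(
                z_t, self.clusters, cfg.alpha_sig, cfg.R, rng, cache=self._cache
            )
        else:
            p = membership_probability(z_t, self.clusters, cfg.alpha_sig, cfg.R, rng)
        a = sample_action(p, rng)
        r = reward_and_update(a, true_label, z_t, self.clusters, update=update)
        return a, r, p

    def snapshot(self) -> list[np.ndarray]:
        """Copies of all member arrays (for immutability assertions)."""
        return [np.asarray(c._members, dtype=float).copy() if len(c) else np.empty((0,))
                for c in self.clusters]
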