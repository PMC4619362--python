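"""Histogram representation layer for sequential signals.

Continuous frame trajectories (MFCC-like vectors, joint angles, ...) are
turned into fixed-length nonnegative vectors in three steps: delayed
derivatives add velocity-like streams, k-means codebooks quantize frames into
discrete events, and (co-)occurrence counting removes most of the temporal
structure.  Counting makes the representations additive: the histogram of a
concatenation of two segments is the sum of the segments' histograms up to a
small boundary deficit, which is exactly the mixture structure the NMF layer
assumes.

The lagged co-occurrence histograms (HAC — histograms of acoustic
co-occurrences) concatenate, per event stream and lag, the k² counts of event
pairs (e_t, e_{t+lag}).  For the three-stream acoustic setup with codebooks
of 150/150/100 and two lags, the vector has 2 + 2·(150² + 150² + 100²) =
110002 entries.

The per-degree-of-freedom angle–velocity histograms quantize (angle,
delayed-velocity) pairs with one codebook per DOF and concatenate the
occurrence counts; 9 DOFs with 50-cell codebooks give the 450-dimensional
motion representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "Codebook",
    "delayed_derivative",
    "learn_codebook",
    "quantize",
    "occurrence_histogram",
    "cooccurrence_histogram",
    "hac_dimension",
    "build_hac",
    "angle_velocity_histogram",
]

#: default frame period in seconds, making lags 2 and 5 equal 20 ms and 50 ms
FRAME_PERIOD = 0.01


@dataclass(frozen=True)
class Codebook:
    """k-means centroids mapping continuous frames to discrete events."""

    centroids: np.ndarray  # k × p
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, float)
        if c.ndim == 1:
            c = c[:, None]
        object.__setattr__(self, "centroids", c)
        if self.centroids.shape[0] < 1:
            raise ValueError("codebook must have at least one centroid")

    @property
    def size(self) -> int:
        return self.centroids.shape[0]


def delayed_derivative(seq, d: int):
    """Delayed difference x_t − x_{t−d}; output length L − d.

    Applied to angle trajectories it yields velocities; iterated on acoustic
    frames it yields the Δ and ΔΔ streams.
    """
    seq = np.asarray(seq, dtype=float)
    if d < 1:
        raise ValueError("delay must be a positive integer")
    if d >= len(seq):
        raise ValueError(f"delay {d} must be smaller than sequence length {len(seq)}")
    return seq[d:] - seq[:-d]


def learn_codebook(frames, k: int, seed: int = 0) -> Codebook:
    """Fit a k-means codebook on training frames (rows)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 1:
        frames = frames[:, None]
    if len(np.unique(frames, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct frames to learn a size-{k} codebook")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(frames)
    return Codebook(centroids=km.cluster_centers_, seed=seed)


def quantize(seq, codebook: Codebook) -> np.ndarray:
    """Map each frame to its nearest centroid index (Euclidean, ties to the
    lowest index); empty input gives an empty event sequence."""
    seq = np.asarray(seq, dtype=float)
    if seq.size == 0:
        return np.empty(0, dtype=int)
    if seq.ndim == 1:
        seq = seq[:, None]
    d2 = ((seq[:, None, :] - codebook.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def occurrence_histogram(events, k: int) -> np.ndarray:
    """Counts of each event value; length-k vector."""
    events = np.asarray(events, dtype=int)
    if events.size and (events.min() < 0 or events.max() >= k):
        raise ValueError(f"events must lie in [0, {k})")
    return np.bincount(events, minlength=k).astype(float)


def cooccurrence_histogram(events, k: int, lag: int) -> np.ndarray:
    """Lagged pair counts: entry a·k + b counts positions t with
    events[t] = a and events[t+lag] = b.  Sums to max(0, L − lag)."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    events = np.asarray(events, dtype=int)
    if events.size and (events.min() < 0 or events.max() >= k):
        raise ValueError(f"events must lie in [0, {k})")
    hist = np.zeros(k * k)
    if len(events) > lag:
        pairs = events[:-lag] * k + events[lag:]
        np.add.at(hist, pairs, 1.0)
    return hist


def hac_dimension(codebook_sizes, lags: int, extra: int = 0) -> int:
    """Length of the concatenated co-occurrence vector:
    extra + lags · Σ_i size_i²."""
    sizes = [int(s) for s in codebook_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("codebook sizes must be >= 1")
    return int(extra) + int(lags) * sum(s * s for s in sizes)


def build_hac(
    streams: list[np.ndarray],
    codebook_sizes: list[int],
    lags: tuple[int, ...] = (2, 5),
    extra: int = 0,
) -> np.ndarray:
    """Concatenated lagged co-occurrence histograms over event streams.

    Blocks follow a fixed stream-major, lag-minor order and are prefixed by
    ``extra`` zero-initialized entries; total length equals
    :func:`hac_dimension`.  Counting makes the result additive over time
    partitions up to a boundary deficit of at most ``lag`` pairs per cut and
    stream.
    """
    if not streams:
        raise ValueError("need at least one event stream")
    if len(streams) != len(codebook_sizes):
        raise ValueError("one codebook size per stream is required")
    blocks = [np.zeros(int(extra))]
    for events, k in zip(streams, codebook_sizes):
        for lag in lags:
            blocks.append(cooccurrence_histogram(events, k, lag))
    return np.concatenate(blocks)


def angle_velocity_histogram(
    dof_trajectories: list[np.ndarray],
    codebooks: list[Codebook],
    delay: int = 2,
) -> np.ndarray:
    """Concatenated per-DOF histograms over the joint (angle, velocity) space.

    For each degree of freedom, pairs (x_t, x_t − x_{t−delay}) are quantized
    by that DOF's 2-D codebook and counted; per-DOF histograms are
    concatenated in DOF order.  A static pose puts all mass in zero-velocity
    cells.  Additive over time partitions like every counting representation
    here.
    """
    if len(dof_trajectories) != len(codebooks):
        raise ValueError("one codebook per degree of freedom is required")
    parts = []
    for traj, cb in zip(dof_trajectories, codebooks):
        traj = np.asarray(traj, dtype=float).ravel()
        vel = delayed_derivative(traj, delay)
        pairs = np.column_stack([traj[delay:], vel])
        events = quantize(pairs, cb)
        parts.append(occurrence_histogram(events, cb.size))
    return np.concatenate(parts)
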