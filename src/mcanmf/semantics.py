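"""Post-hoc analysis of a trained multimodal model.

Two questions about what the learner has internalized:

* **Where in a sequence does the meaning live?**  Sliding windows (default
  0.5 s wide, shifted by 0.05 s) are cut from a test sequence, featurized
  exactly like training data, coded into the internal representation, and
  scored against reference examples of each concept.  The resulting
  similarity profile peaks on the windows that overlap the concept-bearing
  segment (the keyword).

* **Do single coefficients specialize on concepts?**  Each coefficient of
  the internal representation is quantized into a small number of bins and
  its plug-in mutual information (in nats) with each concept's indicator
  variable is computed.  A Kuhn–Munkres (Hungarian) assignment then aligns
  one coefficient to each concept, maximizing total MI.  For calibration:
  with uniform ten-class labels, a coefficient that is a deterministic
  function of one class indicator carries
  −(0.1·ln 0.1 + 0.9·ln 0.9) ≈ 0.325 nats about that class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import mutual_info_score

from .evaluation import ComparisonMode, Metric, cosine_similarity, _score
from .multimodal import MCAModel, internal_representation
from .nmf import FitConfig

__all__ = [
    "WindowSpec",
    "SimilarityProfile",
    "MIMatrix",
    "sliding_windows",
    "similarity_profile",
    "concept_coefficient_mi",
    "align_concepts",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds."""

    width: float = 0.5
    shift: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.shift <= self.width:
            raise ValueError("need 0 < shift <= width")


@dataclass
class SimilarityProfile:
    """Window-by-reference similarity matrix with window center times (s)."""

    center_times: np.ndarray
    reference_classes: np.ndarray
    similarities: np.ndarray  # windows × references

    def peak_window(self, reference_index: int) -> int:
        return int(np.argmax(self.similarities[:, reference_index]))


@dataclass
class MIMatrix:
    """Concept × coefficient mutual information, in nats."""

    values: np.ndarray  # C × k
    concepts: np.ndarray
    n_bins: int


def sliding_windows(seq, spec: WindowSpec, frame_rate: float = 100.0):
    """Cut overlapping windows from a frame or event sequence.

    Windows start at t = 0; their count is floor((T − width)/shift) + 1 for a
    duration-T sequence.  A sequence shorter than the width yields a single
    full-sequence window with a warning.  Returns (window, center time in s)
    pairs.
    """
    seq = np.asarray(seq)
    n = len(seq)
    width_frames = int(round(spec.width * frame_rate))
    shift_frames = max(1, int(round(spec.shift * frame_rate)))
    if n < width_frames:
        warnings.warn("sequence shorter than the window width; returning it whole", stacklevel=2)
        return [(seq, n / (2.0 * frame_rate))]
    count = (n - width_frames) // shift_frames + 1
    out = []
    for i in range(count):
        start = i * shift_frames
        out.append((seq[start : start + width_frames], (start + width_frames / 2.0) / frame_rate))
    return out


def similarity_profile(
    model: MCAModel,
    seq,
    spec: WindowSpec,
    references: list[dict[str, np.ndarray]],
    reference_classes,
    featurize,
    frame_rate: float = 100.0,
    mode: ComparisonMode = ComparisonMode.INTERNAL,
    metric: Metric = Metric.COSINE,
    config: FitConfig | None = None,
) -> SimilarityProfile:
    """Score each sliding window of ``seq`` against reference examples.

    ``featurize`` maps a window of the raw sequence to a raw-unit observation
    (a dict of modality vectors) using the same featurizer as training — same
    codebooks and lags, no per-window renormalization, since window mass is
    informative.  References are raw-unit observations in other modalities.
    Windows whose features are all zero get a zero code and similarity 0.
    """
    config = config or model.config
    windows = sliding_windows(seq, spec, frame_rate)
    ref_codes = [
        internal_representation(model, model.scale_observation(r), config)[:, 0]
        for r in references
    ]
    sims = np.zeros((len(windows), len(references)))
    centers = np.zeros(len(windows))
    for i, (win, center) in enumerate(windows):
        centers[i] = center
        obs = model.scale_observation(featurize(win))
        if all(np.all(np.asarray(v) == 0) for v in obs.values()):
            warnings.warn(f"window {i} produced no events; similarity set to 0", stacklevel=2)
            continue
        h = internal_representation(model, obs, config)[:, 0]
        for j, hr in enumerate(ref_codes):
            if metric is Metric.COSINE and (not h.any() or not hr.any()):
                sims[i, j] = 0.0
            else:
                sims[i, j] = _score(h, hr, metric)
    return SimilarityProfile(
        center_times=centers,
        reference_classes=np.asarray(reference_classes),
        similarities=sims,
    )


def _quantize_coefficient(y: np.ndarray, n_bins: int, strategy: str) -> np.ndarray:
    lo, hi = float(y.min()), float(y.max())
    if hi <= lo:
        return np.zeros(len(y), dtype=int)  # constant coefficient: one bin, MI 0
    if strategy == "width":
        edges = np.linspace(lo, hi, n_bins + 1)
    elif strategy == "frequency":
        edges = np.quantile(y, np.linspace(0, 1, n_bins + 1))
    else:
        raise ValueError(f"unknown binning strategy {strategy!r}")
    return np.clip(np.digitize(y, edges[1:-1]), 0, n_bins - 1)


def concept_coefficient_mi(
    h: np.ndarray,
    labels,
    n_bins: int = 10,
    strategy: str = "width",
) -> MIMatrix:
    """Plug-in mutual information between concept indicators and quantized
    coefficients.

    For each concept l, X_l indicates whether sample i carries label l; each
    coefficient row of ``h`` is quantized into ``n_bins`` bins over its
    observed range (equal-width by default, equal-frequency optional).  The
    MI of each (X_l, Y_j) pair is estimated from empirical joint frequencies,
    in nats.  Entries are nonnegative and bounded by min(H(X_l), ln n_bins).
    """
    h = np.asarray(h, dtype=float)
    if (h < 0).any():
        raise ValueError("coefficients must be nonnegative")
    labels = np.asarray(labels)
    if len(labels) != h.shape[1]:
        raise ValueError("one label per coefficient column is required")
    concepts = np.unique(labels)
    k = h.shape[0]
    values = np.zeros((len(concepts), k))
    quantized = [_quantize_coefficient(h[j], n_bins, strategy) for j in range(k)]
    for li, concept in enumerate(concepts):
        x = (labels == concept).astype(int)
        for j in range(k):
            values[li, j] = mutual_info_score(x, quantized[j])
    return MIMatrix(values=values, concepts=concepts, n_bins=n_bins)


def align_concepts(mi: MIMatrix) -> np.ndarray:
    """Order coefficients so concept-specialized ones come first.

    A Hungarian assignment on −MI picks one coefficient per concept
    maximizing total mutual information; the remaining coefficients follow in
    descending order of their best MI with any concept (ties toward the
    lowest index).  Returns the permutation of coefficient indices (assigned
    coefficients first, in concept order).
    """
    values = mi.values
    n_concepts, k = values.shape
    if k < n_concepts:
        warnings.warn(
            f"only {k} coefficients for {n_concepts} concepts; partial assignment",
            stacklevel=2,
        )
    rows, cols = linear_sum_assignment(-values)
    assigned = [int(c) for _, c in sorted(zip(rows, cols))]
    remaining = sorted(
        (j for j in range(k) if j not in set(assigned)),
        key=lambda j: (-values[:, j].max(), j),
    )
    return np.array(assigned + remaining, dtype=int)
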