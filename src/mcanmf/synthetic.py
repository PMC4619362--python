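"""Synthetic cross-situational multimodal data.

The generator emulates the statistical structure the learner is designed to
exploit: every scene carries exactly one semantic concept, expressed
simultaneously in every modality, buried among modality-specific distractor
components — meaningful and meaningless elements are mixed in each channel
and only the concept co-occurs across channels.

At the histogram level each sample in each modality is

    v = α · prototype_concept + (1 − α) · Σ_j λ_j · distractor_j + noise,

with Dirichlet(1) convex weights λ over that modality's distractor pool and
truncated-Gaussian (clipped at 0) noise of level σ.  Keeping the distractor
mass at (1 − α) holds the mean sample 1-norm roughly constant across σ and D
so that per-modality normalization does not mask effects.  A
``shuffle_associations`` switch draws the concept independently per modality,
destroying the cross-modal statistics while preserving all marginals — the
negative control under which recognition must fall to chance.

At the event level, "sentences" are distractor event streams with exactly one
concept-specific event n-gram (the keyword) inserted at a recorded span,
providing ground truth for sliding-window localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .multimodal import MultimodalDataset
from .representations import build_hac

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "sample_dataset",
    "sample_event_sentences",
    "sample_localization_corpus",
]

_MAX_COSINE = 0.9  # concept prototypes must be pairwise distinct below this
_MAX_RETRIES = 200


@dataclass
class GroundTruth:
    """Generative parameters: per-modality concept prototypes and distractors."""

    n_concepts: int
    n_distractors: int
    prototypes: dict[str, np.ndarray]  # name -> dim × C
    distractors: dict[str, np.ndarray]  # name -> dim × D
    concept_weight: float  # α, mass of the concept component
    noise_level: float  # σ of the truncated-Gaussian noise
    seed: int

    @property
    def modality_names(self) -> list[str]:
        return list(self.prototypes)


def _pairwise_max_cosine(mat: np.ndarray) -> float:
    norms = np.linalg.norm(mat, axis=0)
    normed = mat / np.where(norms == 0, 1.0, norms)
    gram = normed.T @ normed
    np.fill_diagonal(gram, -1.0)
    return float(gram.max())


def make_ground_truth(
    n_concepts: int = 10,
    n_distractors: int = 5,
    dims: dict[str, int] | None = None,
    sparsity: float = 0.3,
    concept_weight: float = 0.5,
    noise_level: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Draw sparse nonnegative concept prototypes and distractors per modality.

    ``sparsity`` is the expected fraction of nonzero entries per prototype.
    Prototypes are resampled (bounded retries) until pairwise cosine
    similarity stays below 0.9, so concepts are genuinely distinct; each
    prototype is scaled to unit 1-norm.  Deterministic given the seed.
    """
    if n_concepts < 2:
        raise ValueError("need at least two concepts")
    dims = dims or {"mod1": 40, "mod2": 40, "mod3": 40}
    for name, dim in dims.items():
        if dim < n_concepts:
            raise ValueError(f"modality {name!r} dim {dim} < number of concepts {n_concepts}")
    rng = np.random.default_rng(seed)

    def draw(dim: int, count: int) -> np.ndarray:
        for _ in range(_MAX_RETRIES):
            mask = rng.random((dim, count)) < sparsity
            mat = rng.random((dim, count)) * mask
            # guarantee at least one nonzero entry per column
            empty = ~mat.any(axis=0)
            if empty.any():
                mat[rng.integers(dim, size=empty.sum()), np.flatnonzero(empty)] = rng.random(
                    empty.sum()
                )
            mat /= mat.sum(axis=0)
            if count == 1 or _pairwise_max_cosine(mat) < _MAX_COSINE:
                return mat
        raise RuntimeError(
            f"could not draw {count} prototypes of dim {dim} with pairwise cosine < "
            f"{_MAX_COSINE}; increase dims or lower sparsity"
        )

    prototypes = {name: draw(dim, n_concepts) for name, dim in dims.items()}
    distractors = {
        name: draw(dim, n_distractors) if n_distractors else np.zeros((dim, 0))
        for name, dim in dims.items()
    }
    return GroundTruth(
        n_concepts=n_concepts,
        n_distractors=n_distractors,
        prototypes=prototypes,
        distractors=distractors,
        concept_weight=concept_weight,
        noise_level=noise_level,
        seed=seed,
    )


def sample_dataset(
    gt: GroundTruth,
    n: int,
    class_probs=None,
    seed: int = 0,
    shuffle_associations: bool = False,
) -> MultimodalDataset:
    """Draw n labeled multimodal samples from the generative model.

    Per sample one concept is drawn from ``class_probs`` (uniform by default)
    and expressed in every modality, mixed with per-modality independent
    Dirichlet-weighted distractors and clipped Gaussian noise.  With
    ``shuffle_associations`` the concept is redrawn independently per
    modality (the returned label comes from the first modality), so no
    cross-modal association survives.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    C = gt.n_concepts
    probs = np.full(C, 1.0 / C) if class_probs is None else np.asarray(class_probs, float)
    probs = probs / probs.sum()
    labels = rng.choice(C, size=n, p=probs)

    modalities: dict[str, np.ndarray] = {}
    alpha = gt.concept_weight
    for name in gt.modality_names:
        proto = gt.prototypes[name]
        concepts = rng.choice(C, size=n, p=probs) if shuffle_associations else labels
        v = alpha * proto[:, concepts]
        if gt.n_distractors:
            lam = rng.dirichlet(np.ones(gt.n_distractors), size=n)  # n × D
            v = v + (1 - alpha) * (gt.distractors[name] @ lam.T)
        if gt.noise_level > 0:
            v = np.clip(v + rng.normal(0.0, gt.noise_level, size=v.shape), 0.0, None)
        modalities[name] = v
    return MultimodalDataset(modalities, labels=labels)


def sample_event_sentences(
    gt: GroundTruth,
    n: int,
    word_length: int = 6,
    sentence_length: int = 30,
    codebook_size: int = 8,
    seed: int = 0,
):
    """Generate event "sentences", each embedding exactly one keyword.

    Every concept owns a fixed event n-gram of ``word_length`` symbols drawn
    from a size-``codebook_size`` alphabet (derived deterministically from
    the ground truth's seed); a sentence is uniform distractor events with
    that n-gram inserted at a random position.  Returns
    ``(sentences, labels, spans)`` where spans are (start, stop) frame
    indices of the inserted keyword.
    """
    if word_length >= sentence_length:
        raise ValueError("word length must be smaller than the sentence length")
    word_rng = np.random.default_rng((gt.seed, codebook_size, word_length))
    words = word_rng.integers(codebook_size, size=(gt.n_concepts, word_length))
    rng = np.random.default_rng(seed)
    sentences, labels, spans = [], [], []
    for _ in range(n):
        c = int(rng.integers(gt.n_concepts))
        events = rng.integers(codebook_size, size=sentence_length)
        start = int(rng.integers(sentence_length - word_length + 1))
        events[start : start + word_length] = words[c]
        sentences.append(events)
        labels.append(c)
        spans.append((start, start + word_length))
    return sentences, np.asarray(labels), spans


def sample_localization_corpus(
    n_concepts: int = 10,
    n_train: int = 200,
    n_test: int = 20,
    word_length: int = 50,
    sentence_length: int = 200,
    codebook_size: int = 8,
    lags: tuple[int, ...] = (1, 2),
    image_dim: int = 40,
    seed: int = 0,
):
    """Bundle a paired sound/image corpus for localization experiments.

    Training samples pair the lagged co-occurrence histogram of a whole event
    sentence (sound) with the concept's image histogram; test sentences come
    with keyword spans for ground truth.  At the default 0.01 s frame period
    the sentences last 2 s and keywords 0.5 s, matching the canonical
    0.5 s / 0.05 s sliding-window geometry.  Returns a dict with the train
    dataset, test sentences/labels/spans, per-class image references, and the
    ``featurize`` closure that maps an event window to a sound observation
    with the training configuration (same codebook size and lags).
    """
    gt = make_ground_truth(
        n_concepts=n_concepts,
        n_distractors=0,
        dims={"image": image_dim},
        seed=seed,
    )
    train_sent, train_labels, _ = sample_event_sentences(
        gt, n_train, word_length, sentence_length, codebook_size, seed=seed + 1
    )
    test_sent, test_labels, test_spans = sample_event_sentences(
        gt, n_test, word_length, sentence_length, codebook_size, seed=seed + 2
    )

    def featurize(events) -> dict[str, np.ndarray]:
        return {"sound": build_hac([np.asarray(events, int)], [codebook_size], lags)}

    sound = np.column_stack([featurize(s)["sound"] for s in train_sent])
    image = gt.prototypes["image"][:, train_labels]
    train = MultimodalDataset({"sound": sound, "image": image}, labels=train_labels)
    references = [{"image": gt.prototypes["image"][:, c]} for c in range(n_concepts)]
    return {
        "ground_truth": gt,
        "train": train,
        "test_sentences": test_sent,
        "test_labels": test_labels,
        "test_spans": test_spans,
        "references": references,
        "reference_classes": np.arange(n_concepts),
        "featurize": featurize,
    }
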