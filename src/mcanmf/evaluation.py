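"""Cross-modal classification protocol.

A trained learner observes a *test example* in one set of modalities and must
pick, among reference examples observed in disjoint modalities, the one that
shares its semantic concept.  Three comparison modes are supported:

INTERNAL
    code test and references into coefficient vectors and compare those;
REFERENCE_MODALITY
    code the test example, reconstruct its expected perception in the
    reference modalities, and compare with the raw references;
TEST_MODALITY
    code each reference, reconstruct into the test modalities, and compare
    with the raw test example.

Comparisons use Euclidean distance, the I-divergence (forward, reversed, or
symmetrized) or cosine similarity.  ``evaluate`` runs the full recognition
protocol: per trial one reference per concept class is drawn from a held-out
pool and the recognition is correct iff the chosen reference's class matches
the test example's class; the success rate is averaged over stratified folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .multimodal import MCAModel, MultimodalDataset, internal_representation, reconstruct_modality
from .nmf import FitConfig, i_divergence

__all__ = [
    "ComparisonMode",
    "Metric",
    "EvaluationResult",
    "cosine_similarity",
    "compare",
    "evaluate",
]


class ComparisonMode(Enum):
    INTERNAL = "internal"
    REFERENCE_MODALITY = "reference_modality"
    TEST_MODALITY = "test_modality"


class Metric(Enum):
    EUCLIDEAN = "euclidean"
    I_DIV_FORWARD = "i_div"
    I_DIV_REVERSED = "i_div_reversed"
    I_DIV_SYMMETRIZED = "i_div_symmetrized"
    COSINE = "cosine"

    @property
    def maximize(self) -> bool:
        return self is Metric.COSINE


def cosine_similarity(x, y) -> float:
    """(x·y)/(‖x‖‖y‖); zero vectors score 0 with a warning.

    Ranges over [−1, 1] in general and over [0, 1] on nonnegative vectors.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        warnings.warn("cosine similarity with a zero vector defined as 0", stacklevel=2)
        return 0.0
    return float(x @ y / (nx * ny))


def _score(x: np.ndarray, y: np.ndarray, metric: Metric) -> float:
    """Score a (test-side, reference-side) vector pair; lower is better
    except for cosine.  The forward I-divergence runs from the test side to
    the reference side."""
    if metric is Metric.EUCLIDEAN:
        return float(np.linalg.norm(x - y))
    if metric is Metric.COSINE:
        return cosine_similarity(x, y)
    if metric is Metric.I_DIV_FORWARD:
        return i_divergence(x[:, None], y[:, None])
    if metric is Metric.I_DIV_REVERSED:
        return i_divergence(y[:, None], x[:, None])
    if metric is Metric.I_DIV_SYMMETRIZED:
        return 0.5 * (
            i_divergence(x[:, None], y[:, None]) + i_divergence(y[:, None], x[:, None])
        )
    raise ValueError(f"unknown metric {metric}")


def _argbest(scores: np.ndarray, metric: Metric) -> int:
    # ties resolve to the lowest index via argmin/argmax semantics
    return int(np.argmax(scores) if metric.maximize else np.argmin(scores))


def _stack_obs(observation: dict[str, np.ndarray], names: list[str]) -> np.ndarray:
    cols = []
    for n in names:
        v = np.asarray(observation[n], float)
        cols.append(v[:, None] if v.ndim == 1 else v)
    return np.vstack(cols)


def compare(
    model: MCAModel,
    test: dict[str, np.ndarray],
    references: list[dict[str, np.ndarray]],
    mode: ComparisonMode = ComparisonMode.INTERNAL,
    metric: Metric = Metric.COSINE,
    config: FitConfig | None = None,
) -> int:
    """Pick the best-matching reference for a test example.

    ``test`` maps the test modalities to single-sample vectors; each entry of
    ``references`` maps the (disjoint) reference modalities likewise.  All
    observations are expected in model units.  Returns the argbest index,
    ties broken toward the lowest index.
    """
    if not references:
        raise ValueError("need at least one reference example")
    test_names = [n for n in model.schema.names if n in test]
    ref_names = [n for n in model.schema.names if n in references[0]]
    if set(test_names) & set(ref_names):
        raise ValueError("test and reference modalities must be disjoint")
    config = config or model.config

    if mode is ComparisonMode.INTERNAL:
        h_test = internal_representation(model, test, config)[:, 0]
        scores = np.array(
            [
                _score(h_test, internal_representation(model, r, config)[:, 0], metric)
                for r in references
            ]
        )
    elif mode is ComparisonMode.REFERENCE_MODALITY:
        h_test = internal_representation(model, test, config)
        expected = np.vstack([reconstruct_modality(model, h_test, n) for n in ref_names])[:, 0]
        scores = np.array(
            [_score(expected, _stack_obs(r, ref_names)[:, 0], metric) for r in references]
        )
    elif mode is ComparisonMode.TEST_MODALITY:
        raw_test = _stack_obs(test, test_names)[:, 0]
        scores = []
        for r in references:
            h_ref = internal_representation(model, r, config)
            expected = np.vstack(
                [reconstruct_modality(model, h_ref, n) for n in test_names]
            )[:, 0]
            scores.append(_score(raw_test, expected, metric))
        scores = np.array(scores)
    else:
        raise ValueError(f"unknown mode {mode}")
    return _argbest(scores, metric)


@dataclass
class EvaluationResult:
    """Outcome of the recognition protocol."""

    success_rate: float
    trials: list[dict]
    fold_assignments: np.ndarray
    seed: int
    mode: ComparisonMode | None
    metric: Metric | None

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _batch_scores(test_cols: np.ndarray, ref_cols: np.ndarray, metric: Metric) -> np.ndarray:
    """Score matrix (n_test × n_ref) between column sets, vectorized where
    the metric allows."""
    if metric is Metric.EUCLIDEAN:
        d = test_cols[:, :, None] - ref_cols[:, None, :]
        return np.sqrt((d**2).sum(axis=0))
    if metric is Metric.COSINE:
        tn = np.linalg.norm(test_cols, axis=0)
        rn = np.linalg.norm(ref_cols, axis=0)
        out = test_cols.T @ ref_cols
        safe_t = np.where(tn == 0, 1.0, tn)
        safe_r = np.where(rn == 0, 1.0, rn)
        out /= safe_t[:, None]
        out /= safe_r[None, :]
        out[tn == 0, :] = 0.0
        out[:, rn == 0] = 0.0
        return out
    n_t, n_r = test_cols.shape[1], ref_cols.shape[1]
    out = np.empty((n_t, n_r))
    for i in range(n_t):
        for j in range(n_r):
            out[i, j] = _score(test_cols[:, i], ref_cols[:, j], metric)
    return out


def evaluate(
    model: MCAModel,
    dataset: MultimodalDataset,
    test_modalities: list[str],
    reference_modalities: list[str],
    mode: ComparisonMode = ComparisonMode.INTERNAL,
    metric: Metric | None = Metric.COSINE,
    n_folds: int = 10,
    seed: int = 0,
    config: FitConfig | None = None,
    fixed_referents: bool = False,
    prescaled: bool = False,
) -> EvaluationResult:
    """Run the full cross-modal recognition protocol on a labeled test set.

    The set is split into stratified folds; samples of each fold serve as
    test trials while references are drawn from the remaining folds (the
    held-out pool), one per concept class.  By default referents are redrawn
    per trial; ``fixed_referents`` draws them once per fold instead.
    ``metric=None`` replaces the comparison by a uniform-random choice, which
    serves as the chance baseline (expected success 1/C).

    Raw-unit datasets are scaled by the model's stored training scales unless
    ``prescaled`` is set.
    """
    if dataset.labels is None:
        raise ValueError("evaluation requires a labeled dataset")
    if set(test_modalities) & set(reference_modalities):
        raise ValueError("test and reference modalities must be disjoint")
    config = config or model.config
    labels = np.asarray(dataset.labels)
    classes = np.unique(labels)
    n = dataset.n_samples
    rng = np.random.default_rng(seed)

    mods = dataset.modalities if prescaled else model.scale_observation(dataset.modalities)
    test_raw = np.vstack([mods[m] for m in model.schema.names if m in test_modalities])
    ref_raw = np.vstack([mods[m] for m in model.schema.names if m in reference_modalities])

    # batch-code / reconstruct every sample once; trials then only index
    if metric is not None:
        if mode is ComparisonMode.INTERNAL:
            test_side = internal_representation(
                model, {m: mods[m] for m in test_modalities}, config
            )
            ref_side = internal_representation(
                model, {m: mods[m] for m in reference_modalities}, config
            )
        elif mode is ComparisonMode.REFERENCE_MODALITY:
            h = internal_representation(model, {m: mods[m] for m in test_modalities}, config)
            test_side = np.vstack(
                [
                    reconstruct_modality(model, h, m)
                    for m in model.schema.names
                    if m in reference_modalities
                ]
            )
            ref_side = ref_raw
        elif mode is ComparisonMode.TEST_MODALITY:
            h = internal_representation(
                model, {m: mods[m] for m in reference_modalities}, config
            )
            test_side = test_raw
            ref_side = np.vstack(
                [
                    reconstruct_modality(model, h, m)
                    for m in model.schema.names
                    if m in test_modalities
                ]
            )
        else:
            raise ValueError(f"unknown mode {mode}")
        score_matrix = _batch_scores(test_side, ref_side, metric)

    n_folds = min(n_folds, int(np.bincount(np.searchsorted(classes, labels)).min()))
    if n_folds < 2:
        raise ValueError("need at least two samples per class for held-out references")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assignments = np.empty(n, dtype=int)
    trials: list[dict] = []
    for fold_id, (pool_idx, trial_idx) in enumerate(skf.split(np.zeros(n), labels)):
        fold_assignments[trial_idx] = fold_id
        pool_by_class = {c: pool_idx[labels[pool_idx] == c] for c in classes}
        for c, pool in pool_by_class.items():
            if len(pool) == 0:
                raise ValueError(f"concept class {c} has no held-out reference sample")
        if fixed_referents:
            fold_refs = np.array([rng.choice(pool_by_class[c]) for c in classes])
        for i in trial_idx:
            if fixed_referents:
                refs = fold_refs
            else:
                refs = np.array([rng.choice(pool_by_class[c]) for c in classes])
            if metric is None:
                chosen = int(rng.integers(len(refs)))
            else:
                chosen = _argbest(score_matrix[i, refs], metric)
            trials.append(
                {
                    "test_id": int(i),
                    "chosen_reference_id": int(refs[chosen]),
                    "true_concept": labels[i].item(),
                    "chosen_concept": classes[chosen].item(),
                    "fold": fold_id,
                    "correct": bool(classes[chosen] == labels[i]),
                }
            )
    success = float(np.mean([t["correct"] for t in trials]))
    return EvaluationResult(
        success_rate=success,
        trials=trials,
        fold_assignments=fold_assignments,
        seed=seed,
        mode=mode if metric is not None else None,
        metric=metric,
    )
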