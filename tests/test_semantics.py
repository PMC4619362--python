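import itertools
import warnings

import numpy as np
import pytest

from mcanmf import (
    FitConfig,
    MIMatrix,
    WindowSpec,
    align_concepts,
    concept_coefficient_mi,
    fit_mca,
    sample_localization_corpus,
    similarity_profile,
    sliding_windows,
)


def brute_force_mi(x, y) -> float:
    """Plug-in MI (nats) as an explicit double sum over the empirical joint
    table; independent of the library implementation."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    mi = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy == 0:
                continue
            px, py = np.mean(x == xv), np.mean(y == yv)
            mi += pxy * np.log(pxy / (px * py))
    return mi


class TestSlidingWindows:
    def test_window_count_formula(self):
        seq = np.zeros(200)  # 2.0 s at 100 fps
        wins = sliding_windows(seq, WindowSpec(width=0.5, shift=0.05), frame_rate=100)
        assert len(wins) == 31  # floor((2.0 − 0.5)/0.05) + 1
        assert all(len(w) == 50 for w, _ in wins)
        assert wins[0][1] == pytest.approx(0.25)  # center of [0, 0.5)

    def test_duration_equal_to_width_gives_one_window(self):
        wins = sliding_windows(np.zeros(50), WindowSpec(width=0.5, shift=0.05), 100)
        assert len(wins) == 1

    def test_shift_equal_width_tiles_without_overlap(self):
        wins = sliding_windows(np.zeros(100), WindowSpec(width=0.2, shift=0.2), 100)
        assert len(wins) == 5
        starts = [round((t - 0.1) * 100) for _, t in wins]
        assert starts == [0, 20, 40, 60, 80]

    def test_short_sequence_returned_whole_with_warning(self):
        with pytest.warns(UserWarning):
            wins = sliding_windows(np.zeros(10), WindowSpec(width=0.5, shift=0.05), 100)
        assert len(wins) == 1 and len(wins[0][0]) == 10

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(width=0.5, shift=0.0)
        with pytest.raises(ValueError):
            WindowSpec(width=0.1, shift=0.2)


class TestConceptCoefficientMI:
    def test_deterministic_indicator_reaches_class_entropy(self):
        """A coefficient that deterministically encodes one of ten uniform
        classes carries −(0.1 ln 0.1 + 0.9 ln 0.9) ≈ 0.325 nats about it."""
        labels = np.arange(1000) % 10
        h = np.zeros((2, 1000))
        h[0] = (labels == 3).astype(float)  # perfect detector of class 3
        h[1] = 0.5  # constant, carries nothing
        mi = concept_coefficient_mi(h, labels, n_bins=10)
        expected = -(0.1 * np.log(0.1) + 0.9 * np.log(0.9))
        assert mi.values[3, 0] == pytest.approx(expected, abs=1e-12)
        assert mi.values[:, 1] == pytest.approx(0.0)

    def test_independent_coefficient_has_vanishing_mi(self):
        rng = np.random.default_rng(0)
        n = 20000
        labels = rng.integers(4, size=n)
        h = rng.random((1, n))
        mi = concept_coefficient_mi(h, labels, n_bins=10)
        assert mi.values.max() < 0.005  # → 0 as n grows

    def test_matches_brute_force_double_sum(self):
        """Oracle equivalence at small n: plug-in MI equals the explicit sum
        over the empirical joint table."""
        rng = np.random.default_rng(1)
        n = 60
        labels = rng.integers(3, size=n)
        h = rng.random((4, n)) * (1 + labels)  # label-dependent scale
        mi = concept_coefficient_mi(h, labels, n_bins=5)
        from mcanmf.semantics import _quantize_coefficient

        for li, concept in enumerate(mi.concepts):
            x = (labels == concept).astype(int)
            for j in range(4):
                y = _quantize_coefficient(h[j], 5, "width")
                assert mi.values[li, j] == pytest.approx(brute_force_mi(x, y), abs=1e-12)

    def test_printed_joint_table(self):
        """2×2 joint counts {(0,0):45, (0,1):5, (1,0):5, (1,1):45} give
        0.9·ln 1.8 + 0.1·ln 0.2 ≈ 0.36806 nats (computed by the brute-force
        oracle)."""
        labels = np.repeat([0, 0, 1, 1], [45, 5, 5, 45])
        y = np.repeat([0, 1, 0, 1], [45, 5, 5, 45])
        assert brute_force_mi(labels, y) == pytest.approx(
            0.9 * np.log(1.8) + 0.1 * np.log(0.2), abs=1e-12
        )
        h = np.repeat([0.0, 1.0, 0.0, 1.0], [45, 5, 5, 45])[None, :]
        mi = concept_coefficient_mi(h, labels, n_bins=2)
        assert mi.values[0, 0] == pytest.approx(0.368064, abs=1e-5)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(3, size=200)
        h = rng.random((3, 200))
        mi = concept_coefficient_mi(h, labels, n_bins=6)
        assert (mi.values >= 0).all()
        assert (mi.values <= np.log(6) + 1e-12).all()

    def test_equal_frequency_binning_option(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(2, size=300)
        h = rng.exponential(size=(2, 300))
        mi = concept_coefficient_mi(h, labels, n_bins=4, strategy="frequency")
        assert mi.values.shape == (2, 2)
        with pytest.raises(ValueError):
            concept_coefficient_mi(h, labels, strategy="nope")


class TestAlignConcepts:
    def _mi(self, values):
        values = np.asarray(values, float)
        return MIMatrix(values=values, concepts=np.arange(values.shape[0]), n_bins=10)

    def test_diagonal_dominant_is_identity(self):
        values = np.eye(4) + 0.01
        perm = align_concepts(self._mi(values))
        np.testing.assert_array_equal(perm, np.arange(4))

    def test_row_permuted_diagonal_recovers_inverse(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = rng.permutation(5)
            values = np.eye(5)[p]  # concept l peaks at coefficient p^-1[l]... rows permuted
            perm = align_concepts(self._mi(values))
            # assigned coefficient for concept l is argmax of its row
            np.testing.assert_array_equal(perm[:5], np.argmax(values, axis=1))

    def test_matches_exhaustive_search(self):
        """Hungarian total MI equals brute force over all permutations for
        up to six concepts."""
        rng = np.random.default_rng(5)
        for c in range(2, 7):
            values = rng.random((c, c))
            perm = align_concepts(self._mi(values))[:c]
            best = max(
                itertools.permutations(range(c)),
                key=lambda p: sum(values[i, p[i]] for i in range(c)),
            )
            got = sum(values[i, perm[i]] for i in range(c))
            want = sum(values[i, best[i]] for i in range(c))
            assert got == pytest.approx(want)

    def test_all_equal_resolves_to_lowest_indices(self):
        perm = align_concepts(self._mi(np.ones((3, 5))))
        np.testing.assert_array_equal(perm[:3], [0, 1, 2])

    def test_remaining_coefficients_ordered_by_peak_mi(self):
        values = np.array([[1.0, 0.0, 0.2, 0.8], [0.0, 1.0, 0.6, 0.1]])
        perm = align_concepts(self._mi(values))
        np.testing.assert_array_equal(perm, [0, 1, 3, 2])  # 0.8 > 0.6 among leftovers

    def test_fewer_coefficients_than_concepts_warns(self):
        with pytest.warns(UserWarning, match="partial"):
            align_concepts(self._mi(np.ones((4, 2))))


@pytest.fixture(scope="module")
def corpus_and_model():
    corpus = sample_localization_corpus(n_concepts=5, n_train=120, n_test=12, seed=61)
    model, _ = fit_mca(corpus["train"], FitConfig(k=15, max_iter=50, seed=62))
    return corpus, model


class TestLocalization:

    def test_similarity_peaks_on_keyword_span(self, corpus_and_model):
        """The true concept's similarity curve must attain its maximum on a
        window overlapping the embedded keyword, for most sentences."""
        corpus, model = corpus_and_model
        spec = WindowSpec(width=0.5, shift=0.05)
        hits = 0
        n = len(corpus["test_sentences"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for sent, lab, (a, b) in zip(
                corpus["test_sentences"], corpus["test_labels"], corpus["test_spans"]
            ):
                prof = similarity_profile(
                    model, sent, spec, corpus["references"],
                    corpus["reference_classes"], corpus["featurize"],
                )
                w = prof.peak_window(int(lab))
                start = int(round((prof.center_times[w] - spec.width / 2) * 100))
                hits += start < b and a < start + 50
        assert hits / n > 0.8

    def test_profile_shape_and_range(self, corpus_and_model):
        corpus, model = corpus_and_model
        spec = WindowSpec(width=0.5, shift=0.05)
        prof = similarity_profile(
            model, corpus["test_sentences"][0], spec, corpus["references"],
            corpus["reference_classes"], corpus["featurize"],
        )
        assert prof.similarities.shape == (31, 5)
        assert (prof.similarities >= -1e-12).all()
        assert (prof.similarities <= 1 + 1e-12).all()
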