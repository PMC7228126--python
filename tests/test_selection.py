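import math

import numpy as np
import pytest

from pseterm import (
    Dataset,
    SequenceRecord,
    binomial_confidence,
    f_scores,
    incremental_selection,
    kmer_class_preference,
    pearson_matrix,
)


# ---------------------------------------------------------------------------
# Pearson correlation diagnostic


def pearson_oracle(x, y):
    """Textbook two-pass covariance correlation."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / len(x)
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / len(x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / len(y))
    return cov / (sx * sy)


def test_pearson_duplicate_and_negated_features():
    rng = np.random.default_rng(0)
    f = rng.normal(size=20)
    X = np.column_stack([f, f, -f])
    corr = pearson_matrix(X)
    assert corr[0, 1] == pytest.approx(1.0)
    assert corr[0, 2] == pytest.approx(-1.0)
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diag(corr), 1.0)


def test_pearson_matches_two_pass_oracle():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(20, 3))
    corr = pearson_matrix(X)
    for i in range(3):
        for j in range(3):
            assert corr[i, j] == pytest.approx(
                pearson_oracle(X[:, i], X[:, j]), abs=1e-12
            )


def test_pearson_constant_feature_reports_zero():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.warns(UserWarning, match="constant"):
        corr = pearson_matrix(X)
    assert corr[0, 1] == 0.0 and corr[0, 0] == 0.0


def test_pearson_needs_two_samples():
    with pytest.raises(ValueError):
        pearson_matrix(np.ones((1, 3)))


# ---------------------------------------------------------------------------
# F-score ranking


def fscore_oracle(pos, neg):
    m = np.mean(np.concatenate([pos, neg]))
    mp, mn = np.mean(pos), np.mean(neg)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = sum((v - mp) ** 2 for v in pos) / (len(pos) - 1) + sum(
        (v - mn) ** 2 for v in neg
    ) / (len(neg) - 1)
    return num / den


def test_fscore_hand_fixture():
    X = np.array([[2.0], [4.0], [0.0], [2.0]])
    y = [1, 1, 0, 0]
    ranking = f_scores(X, y)
    assert ranking.scores[0] == pytest.approx(0.5)


def test_fscore_identical_distribution_is_zero():
    X = np.array([[1.0], [2.0], [1.0], [2.0]])
    assert f_scores(X, [1, 1, 0, 0]).scores[0] == pytest.approx(0.0)


def test_fscore_matches_oracle_on_random_features():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(40, 50))
    y = np.array([1] * 20 + [0] * 20)
    scores = f_scores(X, y).scores
    for j in range(50):
        assert scores[j] == pytest.approx(
            fscore_oracle(X[:20, j], X[20:, j]), abs=1e-10
        )


def test_fscore_singleton_class_errors():
    with pytest.raises(ValueError, match="at least 2"):
        f_scores(np.ones((3, 1)), [1, 0, 0])


def test_fscore_zero_variance_separated_means_ranks_first():
    X = np.column_stack([[1, 1, 0, 0], np.random.default_rng(0).normal(size=4)])
    ranking = f_scores(X, [1, 1, 0, 0])
    assert np.isinf(ranking.scores[0])
    assert ranking.order[0] == 0


def test_ranking_tie_break_is_stable():
    X = np.array([[1.0, 1.0], [2.0, 2.0], [0.0, 0.0], [1.0, 1.0]])
    ranking = f_scores(X, [1, 1, 0, 0])
    assert list(ranking.order) == [0, 1]


# ---------------------------------------------------------------------------
# Binomial confidence ranking


def binomial_tail_oracle(n, N, q):
    """Exact upper-tail enumeration of the binomial pmf."""
    return sum(math.comb(N, m) * q**m * (1 - q) ** (N - m) for m in range(n, N + 1))


def test_binomial_all_occurrences_in_positives():
    # one count feature occurring 10 times, all in the positive class
    X = np.zeros((20, 1))
    X[:5, 0] = 2.0  # 10 occurrences in positives
    y = [1] * 10 + [0] * 10
    ranking = binomial_confidence(X, y)
    assert ranking.scores[0] == pytest.approx(1 - 1 / 1024, abs=1e-12)


def test_binomial_class_prior():
    # 1000 samples, 400 positive: q_pos = 0.4; CL computed from that prior
    rng = np.random.default_rng(3)
    X = rng.integers(0, 3, size=(1000, 1)).astype(float)
    y = np.array([1] * 400 + [0] * 600)
    n_pos = X[:400].sum()
    total = X.sum()
    expected = max(
        1 - binomial_tail_oracle(int(n_pos), int(total), 0.4),
        1 - binomial_tail_oracle(int(total - n_pos), int(total), 0.6),
    )
    assert binomial_confidence(X, y).scores[0] == pytest.approx(expected, abs=1e-9)


def test_binomial_matches_exact_enumeration():
    rng = np.random.default_rng(23)
    X = rng.integers(0, 3, size=(12, 8)).astype(float)
    y = np.array([1] * 5 + [0] * 7)
    scores = binomial_confidence(X, y).scores
    q_pos, q_neg = 5 / 12, 7 / 12
    for j in range(8):
        n_pos = int(X[:5, j].sum())
        n_neg = int(X[5:, j].sum())
        total = n_pos + n_neg
        expected = max(
            1 - binomial_tail_oracle(n_pos, total, q_pos),
            1 - binomial_tail_oracle(n_neg, total, q_neg),
        )
        assert scores[j] == pytest.approx(expected, abs=1e-12)


def test_binomial_rejects_real_valued_features():
    with pytest.raises(TypeError, match="count features"):
        binomial_confidence(np.array([[0.5], [1.0], [0.0], [1.0]]), [1, 1, 0, 0])


def test_binomial_sample_order_invariance():
    rng = np.random.default_rng(8)
    X = rng.integers(0, 4, size=(16, 5)).astype(float)
    y = np.array([1] * 8 + [0] * 8)
    perm = rng.permutation(16)
    a = binomial_confidence(X, y).scores
    b = binomial_confidence(X[perm], y[perm]).scores
    assert np.allclose(a, b)


# ---------------------------------------------------------------------------
# Incremental feature selection


def test_ifs_perfect_feature_wins_at_size_one():
    rng = np.random.default_rng(4)
    y = np.array([1] * 15 + [0] * 15)
    X = np.column_stack([y.astype(float), rng.normal(size=(30, 20))])
    ranking = f_scores(X, y)
    assert ranking.order[0] == 0

    def evaluator(Xs, ys):  # simple resubstitution separability check
        from sklearn.tree import DecisionTreeClassifier

        clf = DecisionTreeClassifier(max_depth=2, random_state=0).fit(Xs, ys)
        return float((clf.predict(Xs) == ys).mean())

    result = incremental_selection(X, y, ranking, evaluator)
    assert result.curve[0] == 1.0
    assert result.best_size == 1
    assert len(result.best_features) == 1


def test_ifs_monotone_evaluators():
    X = np.random.default_rng(0).normal(size=(10, 6))
    y = np.array([1, 0] * 5)
    ranking = f_scores(X, y)
    inc = incremental_selection(X, y, ranking, lambda Xs, ys: Xs.shape[1] / 10)
    assert inc.best_size == 6
    dec = incremental_selection(X, y, ranking, lambda Xs, ys: -Xs.shape[1] / 10)
    assert dec.best_size == 1


def test_ifs_stride_agrees_on_shared_prefixes():
    X = np.random.default_rng(1).normal(size=(12, 9))
    y = np.array([1, 0] * 6)
    ranking = f_scores(X, y)
    ev = lambda Xs, ys: float(np.sin(Xs.shape[1]))  # deterministic in prefix size
    full = incremental_selection(X, y, ranking, ev, stride=1)
    strided = incremental_selection(X, y, ranking, ev, stride=2)
    lookup = dict(zip(full.sizes.tolist(), full.curve.tolist()))
    for s, v in zip(strided.sizes.tolist(), strided.curve.tolist()):
        assert v == lookup[s]


def test_ifs_requires_full_ranking():
    X = np.zeros((4, 3))
    y = [1, 1, 0, 0]
    from pseterm import FeatureRanking

    bad = FeatureRanking("fscore", np.zeros(2), np.array([0, 1]))
    with pytest.raises(ValueError, match="cover"):
        incremental_selection(X, y, bad, lambda a, b: 0.0)


# ---------------------------------------------------------------------------
# k-mer class preference


def test_kmer_preference_polyt_fixture():
    ds = Dataset(
        [
            SequenceRecord("p", "TTTTTT", "positive"),
            SequenceRecord("n", "ACACAC", "negative"),
        ]
    )
    prefs = kmer_class_preference(ds, 5)
    assert prefs.loc["TTTTT", "positive"] == pytest.approx(1.0)
    assert prefs.loc["TTTTT", "negative"] == pytest.approx(0.0)
    assert prefs.index[0] == "TTTTT"  # most positively skewed pentamer


def test_kmer_preference_symmetric_classes():
    ds = Dataset(
        [
            SequenceRecord("p", "ACGTACGT", "positive"),
            SequenceRecord("n", "ACGTACGT", "negative"),
        ]
    )
    prefs = kmer_class_preference(ds, 3)
    assert np.allclose(prefs["positive"], prefs["negative"])


def test_kmer_preference_occurrence_shares_sum_to_one():
    ds = Dataset(
        [
            SequenceRecord("p1", "TTTTTTACGT", "positive"),
            SequenceRecord("p2", "ACGTACGTAC", "positive"),
            SequenceRecord("n1", "GGGGCCCCAA", "negative"),
        ]
    )
    prefs = kmer_class_preference(ds, 2, mode="occurrence")
    assert prefs["positive"].sum() == pytest.approx(1.0)
    assert prefs["negative"].sum() == pytest.approx(1.0)


def test_kmer_preference_errors():
    ds = Dataset([SequenceRecord("p", "ACGT", "positive")])
    with pytest.raises(ValueError, match="both classes"):
        kmer_class_preference(ds, 2)
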