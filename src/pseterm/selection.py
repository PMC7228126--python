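"""Two-step feature selection: rank (F-score or binomial confidence), then IFS.

The F-score of a feature is the squared separation of its class means
over the sum of its unbiased within-class variances; the binomial
confidence level asks how surprising a count feature's concentration in
one class is under the class prior.  Incremental feature selection (IFS)
then evaluates a classifier on growing prefixes of the ranked list and
keeps the prefix with the highest cross-validated accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix, count_kmers
from .seqio import Dataset

__all__ = [
    "FeatureRanking",
    "IFSResult",
    "pearson_matrix",
    "f_scores",
    "binomial_confidence",
    "incremental_selection",
    "kmer_class_preference",
]

#: Sentinel score for a feature with zero within-class variance but
#: separated class means: infinitely informative, ranked first.
PERFECT_SEPARATION = np.inf


@dataclass(frozen=True)
class FeatureRanking:
    """Per-feature scores and the descending-score feature order.

    Ties are broken by ascending original index, so rankings are stable.
    """

    method: str
    scores: np.ndarray
    order: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.order) != len(self.scores):
            raise ValueError("order must be a permutation of all feature indices")

    def top(self, n: int) -> np.ndarray:
        return self.order[:n]


def _make_order(scores: np.ndarray) -> np.ndarray:
    # stable sort on -scores keeps ascending original index among ties
    return np.argsort(-scores, kind="stable")


def pearson_matrix(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Feature-feature Pearson correlation; constant features give 0 rows.

    Used as a redundancy diagnostic before selection.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples to correlate features")
    sd = values.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); their correlations are reported as 0",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, sd)
    z = (values - values.mean(axis=0)) / safe
    corr = z.T @ z / values.shape[0]
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, np.where(constant, 0.0, 1.0))
    return np.clip(corr, -1.0, 1.0)


def _split_classes(X, y):
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos = values[y == 1]
    neg = values[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return values, pos, neg


def f_scores(X: FeatureMatrix | np.ndarray, y: Sequence[int]) -> FeatureRanking:
    """Fisher-style F-score per feature.

    F = ((m+ - m)^2 + (m- - m)^2) / (s+^2-sum + s-^2-sum) with unbiased
    per-class variance sums.  Zero variance with separated means scores
    the ``PERFECT_SEPARATION`` sentinel; with equal means, 0.
    """
    values, pos, neg = _split_classes(X, y)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 samples (variance undefined)")
    m = values.mean(axis=0)
    mp, mn = pos.mean(axis=0), neg.mean(axis=0)
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = ((pos - mp) ** 2).sum(axis=0) / (len(pos) - 1) + ((neg - mn) ** 2).sum(
        axis=0
    ) / (len(neg) - 1)
    scores = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    scores = np.where((den == 0) & (num > 0), PERFECT_SEPARATION, scores)
    names = tuple(X.feature_names) if isinstance(X, FeatureMatrix) else ()
    return FeatureRanking("fscore", scores, _make_order(scores), names)


def binomial_confidence(X: FeatureMatrix | np.ndarray, y: Sequence[int]) -> FeatureRanking:
    """Binomial confidence level per count feature.

    With class prior q_i (class share of samples), the upper binomial
    tail P = P[Binom(N_j, q_i) >= n_ij] measures how likely feature j's
    observed concentration n_ij of its N_j total occurrences in class i
    is by chance; CL_j = max over the two classes of 1 - P.  Only defined
    for nonnegative integer count features.
    """
    values, pos, neg = _split_classes(X, y)
    if np.any(values < 0) or not np.allclose(values, np.round(values)):
        names = X.feature_names if isinstance(X, FeatureMatrix) else None
        bad = np.where((values < 0) | ~np.isclose(values, np.round(values)))[1][0]
        label = names[bad] if names else f"column {bad}"
        raise TypeError(
            f"binomial ranking needs nonnegative integer count features; {label} is not"
        )
    counts = np.round(values)
    q_pos = len(pos) / len(values)
    q_neg = len(neg) / len(values)
    n_pos = counts[np.asarray(y) == 1].sum(axis=0)
    n_neg = counts[np.asarray(y) == 0].sum(axis=0)
    total = n_pos + n_neg
    # P[Binom(N, q) >= n] = sf(n - 1); features never observed get CL 0
    with np.errstate(invalid="ignore"):
        cl_pos = 1.0 - stats.binom.sf(n_pos - 1, total, q_pos)
        cl_neg = 1.0 - stats.binom.sf(n_neg - 1, total, q_neg)
    scores = np.where(total > 0, np.maximum(cl_pos, cl_neg), 0.0)
    names = tuple(X.feature_names) if isinstance(X, FeatureMatrix) else ()
    return FeatureRanking("binomial", scores, _make_order(scores), names)


@dataclass(frozen=True)
class IFSResult:
    """Accuracy over ranked-feature prefixes and the winning prefix."""

    sizes: np.ndarray
    curve: np.ndarray
    best_size: int
    best_features: tuple[str, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_features": self.sizes, "accuracy": self.curve})


def incremental_selection(
    X: FeatureMatrix | np.ndarray,
    y: Sequence[int],
    ranking: FeatureRanking,
    evaluator: Callable[[np.ndarray, np.ndarray], float],
    stride: int = 1,
    max_features: int | None = None,
) -> IFSResult:
    """Evaluate growing prefixes of the ranked features; keep the best.

    ``evaluator(X_subset, y) -> accuracy`` is typically a seeded
    cross-validation run.  ``stride`` evaluates every s-th prefix size
    (the full width is always included); the smallest size wins ties.
    """
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = values.shape[1]
    if len(ranking.order) != n:
        raise ValueError("ranking does not cover all features")
    limit = min(n, max_features) if max_features else n
    sizes = list(range(1, limit + 1, max(stride, 1)))
    if sizes[-1] != limit:
        sizes.append(limit)
    curve = np.array([evaluator(values[:, ranking.order[:s]], y) for s in sizes])
    best_i = int(np.argmax(curve))  # argmax returns the first (smallest) maximizer
    best_size = int(sizes[best_i])
    if ranking.feature_names:
        best = tuple(ranking.feature_names[j] for j in ranking.order[:best_size])
    elif isinstance(X, FeatureMatrix):
        best = tuple(X.feature_names[j] for j in ranking.order[:best_size])
    else:
        best = tuple(str(j) for j in ranking.order[:best_size])
    return IFSResult(np.array(sizes), curve, best_size, best)


def kmer_class_preference(
    dataset: Dataset,
    k: int,
    kmers: Sequence[str] | None = None,
    mode: str = "presence",
) -> pd.DataFrame:
    """Per-k-mer class preference ratios (e.g. pentamer poly-T enrichment).

    ``presence`` mode reports, per class, the fraction of sequences
    containing the k-mer at least once; ``occurrence`` mode the k-mer's
    share of all k-mer windows in that class.  Returns a frame indexed by
    k-mer with ``positive``/``negative`` ratio columns, sorted by the
    positive-negative difference.
    """
    if mode not in ("presence", "occurrence"):
        raise ValueError("mode must be 'presence' or 'occurrence'")
    pos = [r for r in dataset if r.label == "positive"]
    neg = [r for r in dataset if r.label == "negative"]
    if not pos or not neg:
        raise ValueError("dataset must contain both classes")
    if k > min(len(r) for r in dataset):
        raise ValueError(f"k={k} exceeds the shortest sequence length")

    def ratios(records) -> dict[str, float]:
        if mode == "presence":
            hits: dict[str, float] = {}
            for r in records:
                for m in count_kmers(r, k):
                    hits[m] = hits.get(m, 0.0) + 1.0
            return {m: c / len(records) for m, c in hits.items()}
        totals: dict[str, float] = {}
        grand = 0.0
        for r in records:
            for m, c in count_kmers(r, k).items():
                totals[m] = totals.get(m, 0.0) + c
                grand += c
        return {m: c / grand for m, c in totals.items()}

    rp, rn = ratios(pos), ratios(neg)
    keys = list(kmers) if kmers is not None else sorted(set(rp) | set(rn))
    df = pd.DataFrame(
        {
            "positive": [rp.get(m, 0.0) for m in keys],
            "negative": [rn.get(m, 0.0) for m in keys],
        },
        index=pd.Index(keys, name="kmer"),
    )
    df["difference"] = df["positive"] - df["negative"]
    return df.sort_values("difference", ascending=False)
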