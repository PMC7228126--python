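"""DNA feature encoders: K-pwm, base content, Nucleotidepro, PseKNC I/II.

Five encoders turn an A/C/G/T sequence into a fixed-length numeric
vector:

* **K-pwm** — a length-normalized position-weight-matrix log-odds score:
  the mean over sites of ln(site-specific k-tuple probability over the
  uniform background 1/4^k).  One scalar feature per k.
* **Base content** — atContent, gcContent, atgcRatio, gcSkew, atSkew.
* **Nucleotidepro** — a 47 x L_max per-position encoding: 3 binary
  chemical properties of the base at each position, 32 standardized
  dinucleotide property values of the step starting there, and 12
  trinucleotide values, zero-padded on the right to a fixed width.
* **PseKNC-I (parallel correlation)** — normalized K-tuple frequencies
  plus lambda pseudo-components, each the mean squared physicochemical
  distance between dinucleotides lambda steps apart, averaged over a
  property set.
* **PseKNC-II (series correlation)** — as above but with one correlation
  tier per property per gap, so the pseudo block has Lambda*lambda
  entries.

All encoders are pure functions of (sequence, configuration, table).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .properties import HELIX_PROPERTIES, PropertyTable
from .seqio import Dataset, SequenceRecord

__all__ = [
    "FeatureMatrix",
    "PositionWeightModel",
    "PseKNCConfig",
    "BaseContent",
    "count_kmers",
    "build_pwm",
    "pwm_score",
    "base_content",
    "chemical_encoding",
    "physico_encoding",
    "nucleotidepro",
    "pseknc",
    "extract_group",
    "TABLE_GROUPS",
    "FAMILIES",
]

FAMILIES = ("kpwm", "basecontent", "nucleotidepro", "pseknc1", "pseknc2")

#: Named feature-group presets (family compositions of the standard
#: combinations benchmarked for this problem; ``group8`` is the default
#: predictor's feature set).
TABLE_GROUPS: dict[str, tuple[str, ...]] = {
    "group1": ("pseknc1:5", "pseknc2:5"),
    "group2": ("kpwm:1", "kpwm:6"),
    "group3": ("pseknc1:5", "kpwm:1", "kpwm:6"),
    "group4": ("pseknc2:5", "kpwm:1", "kpwm:6"),
    "group5": ("pseknc1:5", "pseknc2:5", "kpwm:1", "kpwm:6"),
    "group6": ("pseknc1:5", "pseknc2:5", "kpwm:1", "kpwm:6", "basecontent"),
    "group7": ("kpwm:1", "kpwm:6", "nucleotidepro"),
    "group8": ("pseknc1:5", "pseknc2:5", "nucleotidepro"),
    "group9": ("pseknc1:5", "pseknc2:5", "kpwm:1", "kpwm:6", "nucleotidepro"),
}


def _encode(bases: str) -> np.ndarray:
    """Base string -> integer array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.shape, dtype=np.int64)
    out[arr == ord("A")] = 0
    out[arr == ord("C")] = 1
    out[arr == ord("G")] = 2
    out[arr == ord("T")] = 3
    return out


def _kmer_indices(code: np.ndarray, k: int) -> np.ndarray:
    """Lexicographic index of the k-mer starting at each of L-k+1 positions."""
    n = code.size - k + 1
    idx = np.zeros(n, dtype=np.int64)
    for t in range(k):
        idx = idx * 4 + code[t : t + n]
    return idx


def _kmer_names(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


def _bases_of(seq: SequenceRecord | str) -> str:
    return seq.bases if isinstance(seq, SequenceRecord) else seq


# ---------------------------------------------------------------------------
# K-mer counting and the K-pwm encoder


def count_kmers(seq: SequenceRecord | str, k: int) -> dict[str, int]:
    """Counts over the L-k+1 overlapping k-mer windows (zero counts omitted)."""
    bases = _bases_of(seq)
    if k < 1 or k > len(bases):
        raise ValueError(f"k={k} out of range for sequence of length {len(bases)}")
    idx = _kmer_indices(_encode(bases), k)
    names = _kmer_names(k)
    uniq, cnt = np.unique(idx, return_counts=True)
    return {names[u]: int(c) for u, c in zip(uniq, cnt)}


@dataclass(frozen=True)
class PositionWeightModel:
    """Site-wise k-tuple log-odds weights against the uniform background.

    ``weights[x, i] = ln(p_xi / p0)`` with ``p0 = 1/4^k`` and ``p_xi`` the
    additively smoothed probability of k-tuple ``x`` starting at site
    ``i`` among training sequences long enough to reach that site.  With
    pseudocount 0, never-seen (x, i) cells are ``-inf`` and scoring
    substitutes ``floor_logodds``.
    """

    k: int
    n_sites: int
    weights: np.ndarray  # (4^k, n_sites)
    pseudocount: float
    floor_logodds: float

    @property
    def p0(self) -> float:
        return 1.0 / 4**self.k

    @property
    def has_unseen_cells(self) -> bool:
        return bool(np.isneginf(self.weights).any())


def build_pwm(
    train: Dataset | Sequence[str],
    k: int,
    pseudocount: float = 0.25,
    floor_prob: float = 1e-3,
) -> PositionWeightModel:
    """Fit the position weight model on training sequences.

    ``n_sites`` is the largest number of k-mer windows any training
    sequence offers; at each site the denominator counts only sequences
    long enough to reach it, so mixed-length training sets are handled
    without padding.
    """
    seqs = [_bases_of(s) for s in train]
    if not seqs:
        raise ValueError("cannot build a position weight model from an empty dataset")
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if any(len(s) < k for s in seqs):
        raise ValueError(f"all training sequences must be at least {k} bp for k={k}")
    n_sites = max(len(s) - k + 1 for s in seqs)
    m = 4**k
    counts = np.zeros((m, n_sites), dtype=np.float64)
    site_totals = np.zeros(n_sites, dtype=np.float64)
    for s in seqs:
        idx = _kmer_indices(_encode(s), k)
        counts[idx, np.arange(idx.size)] += 1.0
        site_totals[: idx.size] += 1.0
    p = (counts + pseudocount) / (site_totals + m * pseudocount)
    with np.errstate(divide="ignore"):
        weights = np.log(p * m)  # ln(p / p0), p0 = 1/m
    return PositionWeightModel(
        k=k,
        n_sites=n_sites,
        weights=weights,
        pseudocount=pseudocount,
        floor_logodds=float(np.log(floor_prob * m)),
    )


def pwm_score(seq: SequenceRecord | str, pwm: PositionWeightModel) -> float:
    """Length-normalized log-odds score: mean site weight over scored windows.

    Sequences longer than the model score their first ``n_sites`` windows;
    shorter ones score all of their own, so the statistic is comparable
    across lengths.
    """
    bases = _bases_of(seq)
    if len(bases) < pwm.k:
        raise ValueError(
            f"sequence of length {len(bases)} is shorter than k={pwm.k}"
        )
    idx = _kmer_indices(_encode(bases), pwm.k)
    n = min(idx.size, pwm.n_sites)
    w = pwm.weights[idx[:n], np.arange(n)]
    w = np.where(np.isneginf(w), pwm.floor_logodds, w)
    return float(w.mean())


# ---------------------------------------------------------------------------
# Base content


BASECONTENT_NAMES = ("atContent", "gcContent", "atgcRatio", "gcSkew", "atSkew")


@dataclass(frozen=True)
class BaseContent:
    """The five strand-composition statistics of one sequence.

    Ratios with an empty denominator (e.g. gcSkew of an all-A/T sequence)
    are reported as 0 and listed in ``degenerate`` rather than raising.
    """

    at_content: float
    gc_content: float
    atgc_ratio: float
    gc_skew: float
    at_skew: float
    degenerate: frozenset[str] = frozenset()

    def values(self) -> np.ndarray:
        return np.array(
            [self.at_content, self.gc_content, self.atgc_ratio, self.gc_skew, self.at_skew]
        )


def base_content(seq: SequenceRecord | str) -> BaseContent:
    bases = _bases_of(seq)
    L = len(bases)
    a, c, g, t = (bases.count(b) for b in "ACGT")
    at, gc = a + t, g + c
    degenerate = set()

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.add(name)
            return 0.0
        return num / den

    return BaseContent(
        at_content=at / L,
        gc_content=gc / L,
        atgc_ratio=ratio(at, gc, "atgcRatio"),
        gc_skew=ratio(g - c, gc, "gcSkew"),
        at_skew=ratio(a - t, at, "atSkew"),
        degenerate=frozenset(degenerate),
    )


# ---------------------------------------------------------------------------
# Nucleotidepro: 47 properties x position


def chemical_encoding(seq: SequenceRecord | str, table: PropertyTable) -> np.ndarray:
    """3 x L binary matrix: ring structure / hydrogen bond / functional group."""
    code = _encode(_bases_of(seq))
    chem = table.chemical.to_numpy(dtype=float)  # 3 x 4, columns A,C,G,T
    return chem[:, code]


def physico_encoding(seq: SequenceRecord | str, table: PropertyTable) -> np.ndarray:
    """44 x L matrix of dinucleotide (32) and trinucleotide (12) property values.

    Column i of a dinucleotide row holds the value of the step starting at
    i; the final column is 0 (no step starts there).  Trinucleotide rows
    end in two zero columns analogously.
    """
    bases = _bases_of(seq)
    if len(bases) < 3:
        raise ValueError("physico_encoding needs sequences of at least 3 bp")
    code = _encode(bases)
    L = code.size
    di = table.dinucleotide.to_numpy(dtype=float)
    tri = table.trinucleotide.to_numpy(dtype=float)
    out = np.zeros((di.shape[0] + tri.shape[0], L))
    di_idx = _kmer_indices(code, 2)
    tri_idx = _kmer_indices(code, 3)
    out[: di.shape[0], : L - 1] = di[:, di_idx]
    out[di.shape[0] :, : L - 2] = tri[:, tri_idx]
    return out


def nucleotidepro(
    seq: SequenceRecord | str, table: PropertyTable, L_max: int = 82
) -> np.ndarray:
    """47 * L_max flat vector: chemical over physicochemical rows, padded.

    Sequences shorter than ``L_max`` are right zero-padded; longer ones
    are an error (raise ``L_max``).  Flattening is row-major, so the
    vector groups by property, then position.
    """
    bases = _bases_of(seq)
    if len(bases) > L_max:
        raise ValueError(
            f"sequence of {len(bases)} bp exceeds L_max={L_max}; "
            "raise L_max to at least the longest sequence"
        )
    block = np.zeros((table.n_properties, L_max))
    stacked = np.vstack(
        [chemical_encoding(bases, table), physico_encoding(bases, table)]
    )
    block[:, : len(bases)] = stacked
    return block.ravel()


def nucleotidepro_names(table: PropertyTable, L_max: int = 82) -> list[str]:
    return [f"{prop}@{pos}" for prop in table.names for pos in range(L_max)]


# ---------------------------------------------------------------------------
# PseKNC


@dataclass(frozen=True)
class PseKNCConfig:
    """Pseudo K-tuple nucleotide composition settings.

    ``K`` is the tuple size (4-6), ``lam`` the number of correlation
    tiers, ``w`` the pseudo-component weight, ``mode`` parallel (type I)
    or series (type II), ``props`` the dinucleotide property subset
    (default: the six helical step parameters).  ``correlation`` picks the
    series-tier statistic: mean squared per-property difference
    (default; keeps every component nonnegative and zero on homopolymers)
    or mean per-property product.
    """

    K: int = 5
    lam: int = 5
    w: float = 0.1
    mode: str = "parallel"
    props: tuple[str, ...] = HELIX_PROPERTIES
    correlation: str = "sq_diff"

    def __post_init__(self) -> None:
        if self.K not in (4, 5, 6):
            raise ValueError(f"K must be 4, 5 or 6, got {self.K}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.w < 0:
            raise ValueError(f"w must be >= 0, got {self.w}")
        if self.mode not in ("parallel", "series"):
            raise ValueError(f"mode must be 'parallel' or 'series', got {self.mode!r}")
        if self.correlation not in ("sq_diff", "product"):
            raise ValueError(f"correlation must be 'sq_diff' or 'product'")

    @property
    def n_features(self) -> int:
        tiers = self.lam if self.mode == "parallel" else self.lam * len(self.props)
        return 4**self.K + tiers

    def feature_names(self) -> list[str]:
        tag = "p1" if self.mode == "parallel" else "p2"
        names = [f"{tag}k{self.K}:{m}" for m in _kmer_names(self.K)]
        if self.mode == "parallel":
            names += [f"{tag}k{self.K}:theta{j}" for j in range(1, self.lam + 1)]
        else:
            names += [
                f"{tag}k{self.K}:tau{j}.{p}"
                for j in range(1, self.lam + 1)
                for p in self.props
            ]
        return names


def _property_profile(code: np.ndarray, cfg: PseKNCConfig, table: PropertyTable) -> np.ndarray:
    """Lambda x (L-1) matrix of property values of the step at each position."""
    prof = table.dinucleotide_profile(cfg.props).to_numpy(dtype=float)
    return prof[:, _kmer_indices(code, 2)]


def pseknc(
    seq: SequenceRecord | str, cfg: PseKNCConfig, table: PropertyTable
) -> np.ndarray:
    """Pseudo K-tuple nucleotide composition vector (sums to 1).

    First 4^K entries are weighted K-mer frequencies; the remaining
    entries are the weighted correlation tiers.  All components share the
    denominator ``1 + w * sum(tiers)``, so the vector is normalized.
    """
    bases = _bases_of(seq)
    L = len(bases)
    if L - cfg.K < cfg.lam or (cfg.lam > 0 and L - 1 - cfg.lam < 1):
        raise ValueError(
            f"sequence of {L} bp is too short for K={cfg.K}, lam={cfg.lam}"
        )
    code = _encode(bases)
    counts = np.bincount(_kmer_indices(code, cfg.K), minlength=4**cfg.K).astype(float)
    f = counts / counts.sum()

    if cfg.lam == 0:
        tiers = np.empty(0)
    else:
        P = _property_profile(code, cfg, table)  # Lambda x (L-1)
        n_steps = P.shape[1]
        if cfg.mode == "parallel":
            tiers = np.array(
                [
                    np.mean((P[:, : n_steps - j] - P[:, j:]) ** 2)
                    for j in range(1, cfg.lam + 1)
                ]
            )
        else:
            rows = []
            for j in range(1, cfg.lam + 1):
                if cfg.correlation == "sq_diff":
                    rows.append(np.mean((P[:, : n_steps - j] - P[:, j:]) ** 2, axis=1))
                else:
                    rows.append(np.mean(P[:, : n_steps - j] * P[:, j:], axis=1))
            tiers = np.concatenate(rows)

    denom = 1.0 + cfg.w * tiers.sum()
    return np.concatenate([f, cfg.w * tiers]) / denom


# ---------------------------------------------------------------------------
# Feature matrices and group assembly


@dataclass
class FeatureMatrix:
    """Samples x named features, with a family tag per feature."""

    values: np.ndarray
    feature_names: list[str]
    families: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n, d = self.values.shape
        if len(self.feature_names) != d or len(self.families) != d:
            raise ValueError("feature_names/families length must match column count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match row count")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    def select(self, columns: Sequence[int]) -> "FeatureMatrix":
        cols = list(columns)
        return FeatureMatrix(
            self.values[:, cols],
            [self.feature_names[j] for j in cols],
            [self.families[j] for j in cols],
            self.sample_ids,
        )

    def rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            self.values[idx],
            self.feature_names,
            self.families,
            [self.sample_ids[i] for i in idx],
        )

    @staticmethod
    def hstack(blocks: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        ids = blocks[0].sample_ids
        for b in blocks[1:]:
            if b.sample_ids != ids:
                raise ValueError("cannot hstack matrices over different samples")
        return FeatureMatrix(
            np.hstack([b.values for b in blocks]),
            sum((b.feature_names for b in blocks), []),
            sum((b.families for b in blocks), []),
            ids,
        )


def _parse_family(spec: str) -> tuple[str, int | None]:
    name, _, arg = spec.partition(":")
    name = name.strip().lower()
    if name not in FAMILIES:
        raise ValueError(f"unknown feature family {name!r}; known: {FAMILIES}")
    if name in ("kpwm", "pseknc1", "pseknc2"):
        if not arg:
            raise ValueError(f"family {name!r} needs a k argument, e.g. '{name}:5'")
        return name, int(arg)
    return name, None


def extract_group(
    dataset: Dataset,
    group: str | Iterable[str],
    table: PropertyTable,
    pwms: Mapping[int, PositionWeightModel] | None = None,
    L_max: int = 82,
    lam: int = 5,
    w: float = 0.1,
) -> FeatureMatrix:
    """Assemble a named feature-group matrix for a dataset.

    ``group`` is a preset name (``group1`` .. ``group9``) or an iterable
    of family specs (``kpwm:1``, ``basecontent``, ``nucleotidepro``,
    ``pseknc1:5``, ``pseknc2:5``).  K-pwm families require fitted
    position weight models passed in ``pwms`` (keyed by k) — build them
    on training positives only.
    """
    if isinstance(group, str):
        group = TABLE_GROUPS.get(group.lower(), (group,))
    specs = [_parse_family(s) for s in group]
    ids = dataset.ids
    blocks: list[FeatureMatrix] = []
    for name, arg in specs:
        if name == "kpwm":
            if pwms is None or arg not in pwms:
                raise ValueError(f"kpwm:{arg} requested but no fitted model for k={arg} given")
            col = np.array([[pwm_score(r, pwms[arg])] for r in dataset])
            blocks.append(FeatureMatrix(col, [f"kpwm{arg}"], ["kpwm"], ids))
        elif name == "basecontent":
            vals = np.array([base_content(r).values() for r in dataset])
            blocks.append(
                FeatureMatrix(vals, list(BASECONTENT_NAMES), ["basecontent"] * 5, ids)
            )
        elif name == "nucleotidepro":
            vals = np.array([nucleotidepro(r, table, L_max) for r in dataset])
            names = nucleotidepro_names(table, L_max)
            blocks.append(FeatureMatrix(vals, names, ["nucleotidepro"] * len(names), ids))
        else:
            mode = "parallel" if name == "pseknc1" else "series"
            cfg = PseKNCConfig(K=arg, lam=lam, w=w, mode=mode)
            vals = np.array([pseknc(r, cfg, table) for r in dataset])
            names = cfg.feature_names()
            blocks.append(FeatureMatrix(vals, names, [name] * len(names), ids))
    return FeatureMatrix.hstack(blocks)
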