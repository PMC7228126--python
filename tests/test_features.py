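import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pseterm import (
    Dataset,
    PseKNCConfig,
    SequenceRecord,
    base_content,
    build_pwm,
    chemical_encoding,
    count_kmers,
    extract_group,
    nucleotidepro,
    physico_encoding,
    pseknc,
    pwm_score,
)

dna = st.text(alphabet="ACGT", min_size=8, max_size=40)


# ---------------------------------------------------------------------------
# k-mer counting


def test_count_kmers_examples():
    assert count_kmers("ACGT", 2) == {"AC": 1, "CG": 1, "GT": 1}
    assert count_kmers("AAAA", 1) == {"A": 4}


@settings(max_examples=30, derandomize=True)
@given(dna, st.integers(1, 6))
def test_count_kmers_conservation(seq, k):
    counts = count_kmers(seq, k)
    assert sum(counts.values()) == len(seq) - k + 1


def test_count_kmers_rejects_large_k():
    with pytest.raises(ValueError):
        count_kmers("ACG", 4)


# ---------------------------------------------------------------------------
# Position weight model


def pwm_score_oracle(train, k, pseudocount, seq, floor_prob=1e-3):
    """Brute-force site-wise smoothed log-odds, independent of the package."""
    n_sites = max(len(s) - k + 1 for s in train)
    p0 = 0.25**k
    n = min(len(seq) - k + 1, n_sites)
    total = 0.0
    for i in range(n):
        x = seq[i : i + k]
        n_xi = sum(1 for s in train if len(s) - k + 1 > i and s[i : i + k] == x)
        big_n = sum(1 for s in train if len(s) - k + 1 > i)
        p = (n_xi + pseudocount) / (big_n + 4**k * pseudocount)
        total += math.log(floor_prob / p0) if p == 0 else math.log(p / p0)
    return total / n


def test_pwm_repeated_sequence_scores_ln4():
    pwm = build_pwm(["AA", "AA"], k=1, pseudocount=0.0)
    assert pwm_score("AA", pwm) == pytest.approx(math.log(4), abs=1e-12)


def test_pwm_uniform_training_gives_zero_logodds():
    pwm = build_pwm(["AAAA", "CCCC", "GGGG", "TTTT"], k=1, pseudocount=0.0)
    assert np.allclose(pwm.weights, 0.0)
    assert pwm_score("ACGT", pwm) == pytest.approx(0.0)


def test_pwm_background_probability():
    pwm = build_pwm(["ACGTACGT"], k=3)
    assert pwm.p0 == pytest.approx(1 / 64)


def test_pwm_smoothed_score_matches_oracle():
    pwm = build_pwm(["AA", "AA"], k=1, pseudocount=0.25)
    assert pwm_score("CC", pwm) == pytest.approx(
        pwm_score_oracle(["AA", "AA"], 1, 0.25, "CC"), abs=1e-12
    )


def test_pwm_oracle_equivalence_random_8mers():
    rng = np.random.default_rng(17)
    train = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(10)]
    for k, pc in [(1, 0.25), (2, 0.5), (3, 1.0)]:
        pwm = build_pwm(train, k, pseudocount=pc)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(k, 12))))
            assert pwm_score(seq, pwm) == pytest.approx(
                pwm_score_oracle(train, k, pc, seq), abs=1e-10
            )


def test_pwm_unseen_cells_flagged_and_floored():
    pwm = build_pwm(["AA", "AA"], k=1, pseudocount=0.0)
    assert pwm.has_unseen_cells
    assert pwm_score("CC", pwm) == pytest.approx(math.log(1e-3 * 4), abs=1e-12)


def test_pwm_variable_length_scores_min_windows():
    pwm = build_pwm(["ACGT"], k=1, pseudocount=0.25)
    assert pwm.n_sites == 4
    long_score = pwm_score("ACGTACGT", pwm)  # only first 4 windows scored
    assert long_score == pytest.approx(pwm_score("ACGT", pwm))


def test_pwm_rejects_short_sequence():
    pwm = build_pwm(["ACGT"], k=2)
    with pytest.raises(ValueError):
        pwm_score("A", pwm)


# ---------------------------------------------------------------------------
# Base content


def test_base_content_atgc():
    bc = base_content("ATGC")
    assert np.allclose(bc.values(), [0.5, 0.5, 1.0, 0.0, 0.0])
    assert not bc.degenerate


def test_base_content_homopolymer_t():
    bc = base_content("TTTT")
    assert bc.at_content == 1.0 and bc.gc_content == 0.0
    assert bc.at_skew == pytest.approx(-1.0)
    assert bc.gc_skew == 0.0 and "gcSkew" in bc.degenerate
    assert bc.atgc_ratio == 0.0 and "atgcRatio" in bc.degenerate


def test_base_content_homopolymer_g():
    bc = base_content("GGGG")
    assert bc.gc_content == 1.0 and bc.gc_skew == pytest.approx(1.0)
    assert bc.atgc_ratio == 0.0 and not {"atgcRatio"} & bc.degenerate


@settings(max_examples=40, derandomize=True)
@given(dna)
def test_base_content_identities(seq):
    bc = base_content(seq)
    assert bc.at_content + bc.gc_content == pytest.approx(1.0)
    assert -1.0 <= bc.at_skew <= 1.0 and -1.0 <= bc.gc_skew <= 1.0
    if bc.gc_content > 0:
        assert bc.atgc_ratio == pytest.approx(bc.at_content / bc.gc_content)


# ---------------------------------------------------------------------------
# Nucleotidepro


@pytest.mark.parametrize(
    "base,expected",
    [("A", (0, 1, 0)), ("C", (1, 0, 0)), ("G", (0, 0, 1)), ("T", (1, 1, 1))],
)
def test_chemical_encoding_per_base(base, expected, table):
    col = chemical_encoding(base, table)[:, 0]
    assert tuple(col) == expected


def test_physico_placement_dinucleotide_rows(table):
    mat = physico_encoding("AAA", table)
    v = table.dinucleotide.loc[table.dinucleotide.index[0], "AA"]
    assert mat[0, 0] == pytest.approx(v) and mat[0, 1] == pytest.approx(v)
    assert mat[0, 2] == 0.0  # no dinucleotide starts at the last position


def test_physico_placement_trinucleotide_rows(table):
    mat = physico_encoding("ACGT", table)
    tri_rows = mat[32:, :]
    assert np.all(tri_rows[:, 2:] == 0.0)
    assert np.any(tri_rows[:, :2] != 0.0)


def test_physico_is_deterministic(table):
    a = physico_encoding("ACGTACGT", table)
    b = physico_encoding("ACGTACGT", table)
    assert np.array_equal(a, b)


def test_nucleotidepro_padding_and_length(table):
    seq = "ACGT" * 12 + "AC"  # 50 bp
    vec = nucleotidepro(seq, table, L_max=82)
    assert vec.size == 47 * 82
    block = vec.reshape(47, 82)
    assert np.all(block[:, 50:] == 0.0)


def test_nucleotidepro_first_position_chemical_values(table):
    block = nucleotidepro("CAA", table, L_max=10).reshape(47, 10)
    assert tuple(block[:3, 0]) == (1, 0, 0)  # C: pyrimidine, strong, amino


def test_nucleotidepro_rejects_overlong_sequence(table):
    with pytest.raises(ValueError, match="L_max"):
        nucleotidepro("A" * 83, table, L_max=82)


# ---------------------------------------------------------------------------
# PseKNC


@settings(max_examples=25, derandomize=True)
@given(
    st.text(alphabet="ACGT", min_size=15, max_size=40),
    st.integers(4, 5),
    st.integers(0, 4),
    st.floats(0.0, 2.0),
    st.sampled_from(["parallel", "series"]),
)
def test_pseknc_is_probability_vector(table, seq, K, lam, w, mode):
    vec = pseknc(seq, PseKNCConfig(K=K, lam=lam, w=w, mode=mode), table)
    assert vec.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(vec >= -1e-12)
    cfg = PseKNCConfig(K=K, lam=lam, w=w, mode=mode)
    assert vec.size == cfg.n_features


def test_pseknc_homopolymer_parallel_collapses(table):
    vec = pseknc("AAAAAAAA", PseKNCConfig(K=5, lam=1, mode="parallel"), table)
    assert vec[0] == pytest.approx(1.0)  # AAAAA is the first lexicographic 5-mer
    assert np.all(vec[1:] == 0.0)


def test_pseknc_homopolymer_series_tiers_zero(table):
    vec = pseknc("A" * 12, PseKNCConfig(K=4, lam=2, mode="series"), table)
    assert np.all(vec[256:] == 0.0)


def test_pseknc_series_product_mode_constant_tiers(table):
    cfg = PseKNCConfig(K=4, lam=3, mode="series", correlation="product")
    vec = pseknc("A" * 14, cfg, table)
    tiers = vec[256:].reshape(3, 6)
    assert np.allclose(tiers, tiers[0])  # same value at every gap on a homopolymer


def test_pseknc_w_zero_reduces_to_kmer_frequencies(table):
    seq = "ACGTTACGGTACACGT"
    vec = pseknc(seq, PseKNCConfig(K=4, lam=3, w=0.0), table)
    counts = count_kmers(seq, 4)
    total = len(seq) - 3
    for i, kmer in enumerate(
        "".join(t) for t in __import__("itertools").product("ACGT", repeat=4)
    ):
        assert vec[i] == pytest.approx(counts.get(kmer, 0) / total)
    assert np.all(vec[256:] == 0.0)


def test_pseknc_too_short_sequence_errors(table):
    with pytest.raises(ValueError, match="too short"):
        pseknc("ACGTA", PseKNCConfig(K=5, lam=3), table)


# ---------------------------------------------------------------------------
# Group assembly


def _ds(*seqs):
    return Dataset([SequenceRecord(f"s{i}", b, "positive") for i, b in enumerate(seqs)])


def test_group_basecontent_has_five_columns(table):
    X = extract_group(_ds("ACGTACGTACGTACGT"), ["basecontent"], table)
    assert X.shape == (1, 5)
    assert X.families == ["basecontent"] * 5


def test_group_two_pwm_columns(table):
    ds = _ds("ACGTACGTACGTACGT", "ACGTTTTTACGTACGT")
    pwms = {1: build_pwm(ds, 1), 6: build_pwm(ds, 6)}
    X = extract_group(ds, ["kpwm:1", "kpwm:6"], table, pwms=pwms)
    assert X.shape == (2, 2)
    assert X.feature_names == ["kpwm1", "kpwm6"]


def test_group8_dimension_accounting(table, synthetic_small):
    lam, L_max = 5, 82
    X = extract_group(synthetic_small, "group8", table, L_max=L_max, lam=lam)
    expected = (4**5 + lam) + (4**5 + 6 * lam) + 47 * L_max
    assert X.shape == (len(synthetic_small), expected)
    fams = set(X.families)
    assert fams == {"pseknc1", "pseknc2", "nucleotidepro"}


def test_group_unknown_family_errors(table):
    with pytest.raises(ValueError, match="unknown feature family"):
        extract_group(_ds("ACGTACGT"), ["wavelet"], table)


def test_group_kpwm_requires_models(table):
    with pytest.raises(ValueError, match="no fitted model"):
        extract_group(_ds("ACGTACGT"), ["kpwm:1"], table)
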