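"""RSA ranking: exact hypergeometric tails, gene p-values, hit calling.

The enumeration oracle computes tail probabilities by brute force over all
C(N, n) draws in exact rational arithmetic, independent of the binomial-
coefficient formula used by the implementation.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sslscreen import rsa
from sslscreen.errors import ConfigurationError, ValidationError


def enumerate_upper_tail(N: int, K: int, n: int, i: int) -> Fraction:
    """Oracle: fraction of all n-subsets of {1..N} containing >= i of the
    first K items, by exhaustive enumeration."""
    marked = set(range(K))
    hits = sum(
        1 for draw in combinations(range(N), n) if len(marked & set(draw)) >= i
    )
    return Fraction(hits, comb(N, n))


def brute_force_rsa(ranks, N):
    """Oracle: min over i of the enumerated tail at cut r_i."""
    rs = sorted(ranks)
    best = Fraction(2)
    best_i = 0
    for i, r in enumerate(rs, start=1):
        p = enumerate_upper_tail(N, len(rs), r, i)
        if p < best:
            best, best_i = p, i
    return best, best_i


@pytest.mark.parametrize(
    "N, K, n, i, expected",
    [
        (6, 2, 1, 1, Fraction(1, 3)),
        (6, 2, 2, 2, Fraction(1, 15)),
        (6, 2, 2, 0, Fraction(1)),
    ],
)
def test_upper_tail_known_values(N, K, n, i, expected):
    assert rsa.hypergeom_upper_tail(N, K, n, i) == float(expected)


def test_upper_tail_matches_enumeration_small_grid():
    """Exact agreement with the draw-enumeration oracle on a small grid."""
    for N in (4, 6, 8):
        for K in range(0, min(4, N) + 1):
            for n in range(0, N + 1):
                for i in range(0, min(K, n) + 1):
                    got = rsa.hypergeom_upper_tail(N, K, n, i)
                    assert got == float(enumerate_upper_tail(N, K, n, i))


def test_upper_tail_matches_scipy():
    """Independent cross-check against scipy's hypergeometric survival fn."""
    for N, K, n, i in [(621, 3, 10, 2), (100, 4, 25, 3), (50, 2, 5, 1)]:
        assert rsa.hypergeom_upper_tail(N, K, n, i) == pytest.approx(
            stats.hypergeom.sf(i - 1, N, K, n), rel=1e-12
        )


def test_upper_tail_rejects_inconsistent_parameters():
    with pytest.raises(ValidationError):
        rsa.hypergeom_upper_tail(5, 6, 2, 1)
    with pytest.raises(ValidationError):
        rsa.hypergeom_upper_tail(6, 2, 2, 3)


def test_rsa_gene_pvalue_examples():
    p, best_i = rsa.rsa_gene_pvalue([1, 2], N=6)
    assert p == float(Fraction(1, 15)) and best_i == 2
    p, best_i = rsa.rsa_gene_pvalue([6], N=6)   # single siRNA ranked last
    assert p == 1.0
    p, _ = rsa.rsa_gene_pvalue([1, 2, 3], N=621)
    assert p == pytest.approx(1 / comb(621, 3), rel=1e-12)


def test_rsa_gene_pvalue_matches_brute_force_grid():
    for N in (6, 9):
        for k in (1, 2, 3):
            for ranks in combinations(range(1, N + 1), k):
                p, best_i = rsa.rsa_gene_pvalue(ranks, N)
                exp_p, exp_i = brute_force_rsa(ranks, N)
                assert p == float(exp_p), (ranks, N)
                assert best_i == exp_i, (ranks, N)


def test_rsa_gene_pvalue_rejects_duplicates():
    with pytest.raises(ValidationError):
        rsa.rsa_gene_pvalue([2, 2], N=6)


@settings(max_examples=60, deadline=None)
@given(st.data())
def test_rsa_pvalue_monotone_in_rank_improvement(data):
    """Moving any single siRNA to a better rank never worsens the gene p."""
    N = data.draw(st.integers(6, 25))
    k = data.draw(st.integers(1, 3))
    ranks = sorted(data.draw(
        st.lists(st.integers(1, N), min_size=k, max_size=k, unique=True)
    ))
    j = data.draw(st.integers(0, k - 1))
    improved = data.draw(st.integers(1, ranks[j]))
    new_ranks = set(ranks) - {ranks[j]} | {improved}
    if len(new_ranks) < k:
        return  # collision with an existing rank; not a valid move
    p_old, _ = rsa.rsa_gene_pvalue(ranks, N)
    p_new, _ = rsa.rsa_gene_pvalue(sorted(new_ranks), N)
    assert p_new <= p_old + 1e-15


def test_rank_sirnas_sort_and_ties():
    eps = pd.DataFrame({
        "sirna_id": ["s3", "s1", "s2"],
        "gene": ["G3", "G1", "G2"],
        "bio_rep": ["aggregate"] * 3,
        "v_a": [1.0] * 3, "v_b": [1.0] * 3, "v_ab": [1.0] * 3,
        "epsilon": [0.2, -0.3, -0.1],
    })
    ranked = rsa.rank_sirnas(eps)
    assert ranked["sirna_id"].tolist() == ["s1", "s2", "s3"]
    assert ranked["rank"].tolist() == [1, 2, 3]

    eps["epsilon"] = 0.0  # all tied -> lexical sirna order
    ranked = rsa.rank_sirnas(eps)
    assert ranked["sirna_id"].tolist() == ["s1", "s2", "s3"]


def test_rank_sirnas_empty_is_error():
    with pytest.raises(ValidationError):
        rsa.rank_sirnas(pd.DataFrame(columns=["sirna_id", "gene", "epsilon"]))


def test_call_hits_strict_cutoff():
    scores = pd.DataFrame({
        "gene": ["A", "B", "C"],
        "n_sirnas": [3] * 3,
        "sirna_ids": ["a"] * 3,
        "epsilons": ["-0.1"] * 3,
        "best_rank_index": [1] * 3,
        "rsa_p": [0.0499, 0.05, 1.0],
    })
    hits = rsa.call_hits(scores, cutoff=0.05)
    assert hits.set_index("gene")["is_hit"].to_dict() == {
        "A": True, "B": False, "C": False
    }


def test_call_hits_rejects_bad_cutoff():
    with pytest.raises(ConfigurationError):
        rsa.call_hits(pd.DataFrame({"rsa_p": [0.5]}), cutoff=0.0)


def test_benjamini_hochberg_matches_direct_formula():
    p = pd.Series([0.01, 0.04, 0.03, 0.5])
    q = rsa.benjamini_hochberg(p)
    assert q[0] == pytest.approx(0.04)
    assert q[3] == pytest.approx(0.5)
    assert (q >= p - 1e-15).all()
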