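"""Redundant siRNA activity (RSA) gene ranking.

RSA turns a ranked list of per-siRNA scores into per-gene p-values that
reward genes whose multiple independent siRNAs all rank well, which makes
hit calling robust to single-oligo off-target effects.

siRNAs are ranked ascending by interaction score (most synthetic-sick
first). For a gene with k siRNAs at ranks r_1 < ... < r_k out of N ranked
siRNAs, the statistic scans the cut at each r_i and asks how surprising it
is that at least i of the gene's k siRNAs fall within the top r_i under a
random rank assignment — the upper tail of a hypergeometric distribution.
The gene's RSA p-value is the minimum tail probability over i = 1..k.

Tail probabilities are computed in exact rational arithmetic with binomial
coefficients and converted to float at the end, so small-N values agree
exactly with exhaustive enumeration.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pandas as pd

from .errors import ConfigurationError, ValidationError

GENE_HIT_COLUMNS = ["gene", "n_sirnas", "sirna_ids", "epsilons",
                    "best_rank_index", "rsa_p", "is_hit"]


def hypergeom_upper_tail(N: int, K: int, n: int, i: int) -> float:
    """P(X >= i) for X ~ Hypergeometric(N, K, n).

    The population has N items of which K are marked; n are drawn without
    replacement; X counts marked items among the draws.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= i):
        raise ValidationError(f"inconsistent parameters N={N} K={K} n={n} i={i}")
    if i > min(K, n):
        raise ValidationError(f"i={i} exceeds min(K={K}, n={n})")
    if i == 0:
        return 1.0
    total = comb(N, n)
    acc = sum(comb(K, x) * comb(N - K, n - x) for x in range(i, min(K, n) + 1))
    return float(Fraction(acc, total))


def rsa_gene_pvalue(ranks, N: int) -> tuple[float, int]:
    """RSA p-value for one gene: min over i of the hypergeometric tail.

    ``ranks`` are the gene's siRNA ranks (1 = best) within the N ranked
    siRNAs; they must be distinct. Returns ``(p, best_i)`` where best_i is
    the 1-based index into the sorted ranks achieving the minimum (smallest
    i on ties).
    """
    rs = sorted(int(r) for r in ranks)
    if len(rs) == 0:
        raise ValidationError("gene has no ranked siRNAs")
    if len(set(rs)) != len(rs):
        raise ValidationError(f"duplicate ranks {rs}")
    if rs[0] < 1 or rs[-1] > N:
        raise ValidationError(f"ranks {rs} outside 1..{N}")
    best_p, best_i = 2.0, 0
    for i, r in enumerate(rs, start=1):
        p = hypergeom_upper_tail(N, len(rs), r, i)
        if p < best_p:
            best_p, best_i = p, i
    return best_p, best_i


def rank_sirnas(aggregate_epsilons: pd.DataFrame) -> pd.DataFrame:
    """Rank siRNAs ascending by aggregate epsilon (most sick first).

    Ties are broken by sirna_id lexical order so ranking is deterministic.
    Input needs columns ``sirna_id, gene, epsilon`` (aggregate rows only);
    returns the same rows with an added ``rank`` column, 1..N.
    """
    df = aggregate_epsilons
    if len(df) == 0:
        raise ValidationError("nothing to rank")
    if df["epsilon"].isna().any():
        df = df[df["epsilon"].notna()]
        if len(df) == 0:
            raise ValidationError("all epsilon scores are missing")
    out = df.sort_values(
        ["epsilon", "sirna_id"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


def score_genes(ranked: pd.DataFrame) -> pd.DataFrame:
    """Per-gene RSA p-values from a ranked siRNA table.

    Returns one row per gene: gene, n_sirnas, sirna_ids (comma-joined in
    rank order), epsilons (comma-joined, matching order), best_rank_index,
    rsa_p.
    """
    N = len(ranked)
    rows = []
    for gene, grp in ranked.groupby("gene", observed=True):
        grp = grp.sort_values("rank")
        p, best_i = rsa_gene_pvalue(grp["rank"].tolist(), N)
        rows.append({
            "gene": gene,
            "n_sirnas": len(grp),
            "sirna_ids": ",".join(grp["sirna_id"]),
            "epsilons": ",".join(f"{e:.6g}" for e in grp["epsilon"]),
            "best_rank_index": best_i,
            "rsa_p": p,
        })
    return pd.DataFrame(rows)


def call_hits(gene_scores: pd.DataFrame, cutoff: float = 0.05) -> pd.DataFrame:
    """Flag candidate hits at rsa_p < cutoff (strict, no multiplicity correction).

    Rows are sorted ascending by rsa_p, ties by gene symbol.
    """
    if not 0 < cutoff <= 1:
        raise ConfigurationError(f"cutoff must be in (0, 1], got {cutoff}")
    out = gene_scores.copy()
    out["is_hit"] = out["rsa_p"] < cutoff
    return out.sort_values(
        ["rsa_p", "gene"], kind="mergesort"
    ).reset_index(drop=True)[GENE_HIT_COLUMNS]


def benjamini_hochberg(pvalues: pd.Series) -> pd.Series:
    """BH-adjusted q-values, offered for reuse beyond the strict-cutoff default."""
    import numpy as np

    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    q[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return pd.Series(np.clip(q, 0, 1), index=pvalues.index)
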