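"""Multiplicative-model genetic interaction (epsilon) scores.

Under the multiplicative null model, the viability of cells carrying two
perturbations is the product of the single-perturbation viabilities,
V_ab = V_a * V_b. The interaction score

    epsilon = V_ab - V_a * V_b

measures deviation from that expectation; negative epsilon is the
synthetic sick/lethal direction, positive epsilon is alleviating.

Here perturbation *a* is a library siRNA and *b* is the screen-wide query
knockdown (the depleted arm). All three V's live on a shared scale: the
query-proficient arm's negative-control median (so the depleted arm is NOT
re-normalized to its own controls, which would cancel V_b and break the
model — use ``normalize_screen(..., reference="proficient")`` upstream).

epsilon is computed per biological replicate (technical replicates
averaged first, since they share a transfection) and then aggregated
across biological replicates.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .model import NEGATIVE_CONTROLS, SiRNALibrary

logger = logging.getLogger(__name__)

EPSILON_COLUMNS = ["sirna_id", "gene", "bio_rep", "v_a", "v_b", "v_ab", "epsilon"]


def epsilon_score(v_ab: float, v_a: float, v_b: float) -> float:
    """epsilon = V_ab - V_a * V_b for one siRNA."""
    for name, v in (("v_ab", v_ab), ("v_a", v_a), ("v_b", v_b)):
        if not math.isfinite(v):
            raise ValidationError(f"{name} is not finite: {v}")
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    return v_ab - v_a * v_b


def estimate_single_effect(viabilities) -> float:
    """V_a: mean normalized viability of one siRNA's wells (one bio rep).

    Returns NaN (missing) for an empty collection; the siRNA is then
    dropped from that replicate with a warning upstream.
    """
    v = np.asarray(list(viabilities), dtype=float)
    if v.size == 0:
        return float("nan")
    return float(v.mean())


def estimate_query_effect(control_viabilities) -> float:
    """V_b: median of query-arm negative-control viabilities.

    The inputs must already be on the query-proficient control scale; the
    median is then a direct estimate of the query knockdown's own effect.
    """
    v = np.asarray(list(control_viabilities), dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ConfigurationError(
            "no query-arm negative-control wells; supply v_b as a constant"
        )
    return float(np.median(v))


def epsilon_table(
    normalized_shared: pd.DataFrame,
    library: SiRNALibrary,
    v_b: float | None = None,
    negative_roles: tuple[str, ...] = NEGATIVE_CONTROLS,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Per-siRNA epsilon scores, per biological replicate and aggregated.

    Parameters
    ----------
    normalized_shared
        Output of ``normalize_screen(..., reference="proficient")``: both
        arms on the query-proficient control scale.
    library
        Maps siRNA identifiers to genes.
    v_b
        Optional constant query effect. By default V_b is estimated per
        biological replicate as the median of that replicate's query-arm
        negative-control viabilities.
    aggregation
        ``mean`` (default) or ``median`` across biological replicates.

    Returns a DataFrame with columns ``sirna_id, gene, bio_rep, v_a, v_b,
    v_ab, epsilon``; aggregate rows carry ``bio_rep == "aggregate"``.
    siRNAs with no surviving replicate are dropped with a warning.
    """
    if aggregation not in ("mean", "median"):
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    df = normalized_shared
    gene_map = dict(zip(library.entries["sirna_id"], library.entries["gene"]))

    samples = df[df["role"] == "sample"]
    bio_reps = sorted(df["bio_rep"].unique())

    # V_b per biological replicate (a screen-wide constant for the arm)
    v_b_by_rep: dict[int, float] = {}
    for b in bio_reps:
        if v_b is not None:
            v_b_by_rep[b] = float(v_b)
        else:
            ctrl = df[
                (df["arm"] == "query_depleted")
                & (df["bio_rep"] == b)
                & df["role"].isin(negative_roles)
            ]["viability"]
            v_b_by_rep[b] = estimate_query_effect(ctrl)

    per_arm = (
        samples.groupby(["content", "bio_rep", "arm"], observed=True)["viability"]
        .mean()
        .unstack("arm")
    )
    rows = []
    for (sirna, b), vals in per_arm.iterrows():
        v_a = vals.get("query_proficient", float("nan"))
        v_ab = vals.get("query_depleted", float("nan"))
        if np.isnan(v_a) or np.isnan(v_ab):
            continue
        vb = v_b_by_rep[b]
        rows.append({
            "sirna_id": sirna,
            "gene": gene_map.get(sirna, sirna),
            "bio_rep": b,
            "v_a": v_a,
            "v_b": vb,
            "v_ab": v_ab,
            "epsilon": epsilon_score(v_ab, v_a, vb),
        })
    per_rep = pd.DataFrame(rows, columns=EPSILON_COLUMNS)

    dropped = set(samples["content"].unique()) - set(per_rep["sirna_id"])
    if dropped:
        logger.warning(
            "%d siRNA(s) had no complete replicate and were dropped: %s",
            len(dropped), sorted(dropped)[:5],
        )
    if per_rep.empty:
        raise ValidationError("no siRNA has a complete replicate")

    agg_fn = "mean" if aggregation == "mean" else "median"
    agg = (
        per_rep.groupby(["sirna_id", "gene"], observed=True)[
            ["v_a", "v_b", "v_ab", "epsilon"]
        ]
        .agg(agg_fn)
        .reset_index()
    )
    agg["bio_rep"] = "aggregate"
    out = pd.concat([per_rep, agg[EPSILON_COLUMNS]], ignore_index=True)
    out = out.sort_values(
        ["sirna_id", "bio_rep"], key=lambda s: s.astype(str), kind="mergesort"
    ).reset_index(drop=True)
    return out


def aggregate_epsilon(per_rep: pd.DataFrame, aggregation: str = "mean") -> pd.DataFrame:
    """Aggregate per-replicate epsilon rows for ranking (bio_rep == "aggregate")."""
    if aggregation not in ("mean", "median"):
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    reps = per_rep[per_rep["bio_rep"] != "aggregate"]
    agg = (
        reps.groupby(["sirna_id", "gene"], observed=True)[
            ["v_a", "v_b", "v_ab", "epsilon"]
        ]
        .agg(aggregation)
        .reset_index()
    )
    agg["bio_rep"] = "aggregate"
    return agg[EPSILON_COLUMNS]


def write_epsilon_table(table: pd.DataFrame, path) -> None:
    table[EPSILON_COLUMNS].to_csv(path, sep="\t", index=False)
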