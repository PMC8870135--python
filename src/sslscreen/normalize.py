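"""Count transformation, plate normalization, and screen quality control.

Raw nucleus counts are square-root transformed (the classical variance
stabilizer for Poisson-distributed object counts) and expressed as a
fraction of the within-plate median of the negative-control wells
("percent of control"). Note that after the sqrt transform a normalized
value is the square root of the count-scale survival fraction; the
multiplicative interaction model is unaffected because the square root
distributes over products.

Two normalization references are supported:

``within``
    every physical plate (plate x arm x bio_rep x tech_rep) is divided by
    its own negative-control median; control medians are 1.0 by
    construction. This is the reference used for QC.
``proficient``
    both arms are divided by the negative-control median of the matching
    query-proficient plate, putting the query-depleted arm on the shared
    scale the multiplicative interaction score requires (the depleted arm's
    control median then estimates the query effect V_b instead of being
    forced to 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import QCError, ValidationError
from .model import NEGATIVE_CONTROLS

PLATE_KEY = ["plate_id", "arm", "bio_rep", "tech_rep"]


def sqrt_transform(count: float) -> float:
    """Square-root transform one nonnegative count."""
    if count < 0:
        raise ValidationError(f"negative count {count}")
    return math.sqrt(count)


def percent_of_control(
    values: pd.Series, is_negative_control: pd.Series
) -> pd.Series:
    """Normalize one plate's transformed values to its negative-control median.

    ``values`` are sqrt-transformed counts for every well of one physical
    plate; ``is_negative_control`` is an aligned boolean mask.
    """
    ctrl = values[is_negative_control]
    if len(ctrl) == 0:
        raise QCError("plate has no negative-control wells")
    med = float(ctrl.median())
    if med <= 0:
        raise QCError("negative-control median is zero")
    return values / med


def normalize_screen(
    measurements: pd.DataFrame,
    negative_roles: tuple[str, ...] = NEGATIVE_CONTROLS,
    reference: str = "within",
) -> pd.DataFrame:
    """sqrt-transform and plate-normalize a validated measurement table.

    Returns the table with added columns ``sqrt_count`` and ``viability``.
    ``reference`` selects the normalization scale (see module docstring).
    """
    if reference not in ("within", "proficient"):
        raise ValidationError(f"unknown normalization reference {reference!r}")
    df = measurements.copy()
    if (df["nuclei_count"] < 0).any():
        raise ValidationError("negative nuclei_count")
    df["sqrt_count"] = np.sqrt(df["nuclei_count"].astype(float))

    is_neg = df["role"].isin(negative_roles)
    medians = (
        df[is_neg]
        .groupby(PLATE_KEY, observed=True)["sqrt_count"]
        .median()
        .rename("ctrl_median")
    )

    if reference == "within":
        ref_key = PLATE_KEY
        ref_medians = medians
    else:
        # shared scale: every plate divided by the control median of the
        # query-proficient plate with the same (plate_id, bio_rep, tech_rep)
        prof = medians.reset_index()
        prof = prof[prof["arm"] == "query_proficient"]
        ref_key = ["plate_id", "bio_rep", "tech_rep"]
        ref_medians = prof.set_index(ref_key)["ctrl_median"]

    merged = df.join(ref_medians, on=ref_key)
    if merged["ctrl_median"].isna().any():
        bad = merged.loc[merged["ctrl_median"].isna(), PLATE_KEY].iloc[0]
        raise QCError(
            f"no negative-control reference for plate {tuple(bad)}"
        )
    if (merged["ctrl_median"] <= 0).any():
        raise QCError("a plate's negative-control median is zero")
    merged["viability"] = merged["sqrt_count"] / merged["ctrl_median"]
    return merged.drop(columns="ctrl_median")


def ssmd(positive_values, negative_values) -> float:
    """Strictly standardized mean difference between two groups.

    (mean_pos - mean_neg) / sqrt(var_pos + var_neg) with sample (ddof=1)
    variances. A healthy assay window between a cytotoxic positive control
    and the negative controls gives a strongly negative value. If both
    variances are zero the window is degenerate and a signed infinity is
    returned (0.0 when the means also coincide).
    """
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("ssmd needs >= 2 values per group")
    diff = pos.mean() - neg.mean()
    denom = math.sqrt(pos.var(ddof=1) + neg.var(ddof=1))
    if denom == 0:
        if diff == 0:
            return 0.0
        return math.copysign(math.inf, diff)
    return diff / denom


def ssmd_robust(positive_values, negative_values) -> float:
    """Median/MAD variant of SSMD (scaled MAD, consistent for normal data)."""
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("ssmd needs >= 2 values per group")
    diff = np.median(pos) - np.median(neg)
    s2 = stats.median_abs_deviation(pos, scale="normal") ** 2 + \
        stats.median_abs_deviation(neg, scale="normal") ** 2
    if s2 == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / math.sqrt(s2))


def replicate_correlation(rep_a: pd.Series, rep_b: pd.Series) -> float:
    """Pearson correlation between two replicates' per-siRNA viabilities.

    Series are aligned on their index (siRNA identifiers); only shared
    siRNAs enter. Returns NaN when fewer than 3 shared siRNAs or when
    either vector has zero variance.
    """
    joined = pd.concat([rep_a, rep_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        return float("nan")
    a, b = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def cytotoxicity_filter(
    per_gene_viability: pd.Series,
    overall_median: float,
    threshold_fraction: float = 0.20,
) -> tuple[set[str], set[str]]:
    """Split genes into (retained, excluded) by intrinsic cytotoxicity.

    A gene is excluded when its summary viability in the query-proficient
    arm falls strictly below ``threshold_fraction`` of the overall median
    viability — i.e. its knockdown alone kills so many cells that an
    interaction cannot be measured on top of it. A gene exactly at the
    threshold is retained.
    """
    if len(per_gene_viability) == 0:
        return set(), set()
    if overall_median <= 0:
        raise ValidationError("overall median must be positive")
    if not 0 < threshold_fraction < 1:
        raise ValidationError("threshold_fraction must be in (0, 1)")
    cutoff = threshold_fraction * overall_median
    excluded = set(per_gene_viability.index[per_gene_viability < cutoff])
    retained = set(per_gene_viability.index) - excluded
    return retained, excluded


@dataclass
class QCReport:
    """Per-plate and per-replicate quality metrics for one screen."""

    plate_ssmd: pd.DataFrame            # PLATE_KEY + ssmd
    replicate_correlations: pd.DataFrame  # arm, rep pair, pearson_r, n
    overall_median: dict[str, float]    # per arm, over sample wells
    excluded_genes: set[str] = field(default_factory=set)
    retained_genes: set[str] = field(default_factory=set)


def qc_report(
    normalized: pd.DataFrame,
    negative_roles: tuple[str, ...] = NEGATIVE_CONTROLS,
    cytotoxicity_threshold: float = 0.20,
) -> QCReport:
    """Compute the screen QC report from a within-plate-normalized table.

    - per-plate SSMD between cytotoxic-positive and negative-control wells;
    - Pearson correlation of per-siRNA viabilities (technical replicates
      averaged) between every pair of biological replicates, per arm;
    - the cytotoxicity exclusion, evaluated on the query-proficient arm
      against that arm's overall sample-well median.
    """
    rows = []
    for key, grp in normalized.groupby(PLATE_KEY, observed=True):
        pos = grp.loc[grp["role"] == "cytotoxic_positive", "viability"]
        neg = grp.loc[grp["role"].isin(negative_roles), "viability"]
        value = ssmd(pos, neg) if len(pos) >= 2 and len(neg) >= 2 else float("nan")
        rows.append(dict(zip(PLATE_KEY, key)) | {"ssmd": value})
    plate_ssmd = pd.DataFrame(rows)

    samples = normalized[normalized["role"] == "sample"]
    per_rep = (
        samples.groupby(["arm", "bio_rep", "content"], observed=True)["viability"]
        .mean()
    )
    corr_rows = []
    for arm in samples["arm"].unique():
        reps = sorted(samples.loc[samples["arm"] == arm, "bio_rep"].unique())
        for i, ra in enumerate(reps):
            for rb in reps[i + 1:]:
                a = per_rep.loc[(arm, ra)]
                b = per_rep.loc[(arm, rb)]
                corr_rows.append({
                    "arm": arm, "rep_a": ra, "rep_b": rb,
                    "pearson_r": replicate_correlation(a, b),
                    "n_sirnas": len(a.index.intersection(b.index)),
                })
    correlations = pd.DataFrame(corr_rows)

    overall = {
        arm: float(samples.loc[samples["arm"] == arm, "viability"].median())
        for arm in samples["arm"].unique()
    }

    retained: set[str] = set()
    excluded: set[str] = set()
    # the exclusion needs a gene column; callers attach it by mapping
    # content -> gene from the library before requesting the report
    prof = samples[samples["arm"] == "query_proficient"]
    if len(prof) and "gene" in prof.columns:
        per_gene = prof.groupby("gene")["viability"].mean()
        retained, excluded = cytotoxicity_filter(
            per_gene, overall["query_proficient"], cytotoxicity_threshold
        )
    return QCReport(plate_ssmd, correlations, overall, excluded, retained)
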