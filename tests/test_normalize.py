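"""Normalization, SSMD, replicate correlation, and the cytotoxicity filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sslscreen import normalize, simulate
from sslscreen.errors import QCError, ValidationError


@pytest.mark.parametrize("count, expected", [(0, 0.0), (100, 10.0), (2, math.sqrt(2))])
def test_sqrt_transform(count, expected):
    assert normalize.sqrt_transform(count) == pytest.approx(expected)


def test_sqrt_transform_rejects_negative():
    with pytest.raises(ValidationError):
        normalize.sqrt_transform(-1)


def test_percent_of_control_ratio():
    values = pd.Series([8.0, 10.0, 10.0, 10.0])
    is_neg = pd.Series([False, True, True, True])
    out = normalize.percent_of_control(values, is_neg)
    assert out.iloc[0] == pytest.approx(0.80)
    assert out[is_neg].median() == pytest.approx(1.0)


def test_percent_of_control_without_controls_is_qc_error():
    values = pd.Series([8.0, 9.0])
    with pytest.raises(QCError):
        normalize.percent_of_control(values, pd.Series([False, False]))


def test_normalize_screen_control_median_is_one(mini_screen):
    """Within-plate normalization pins every plate's negative-control median at 1."""
    measurements, _ = mini_screen
    norm = normalize.normalize_screen(measurements, reference="within")
    neg = norm[norm["role"].isin(normalize.NEGATIVE_CONTROLS)]
    medians = neg.groupby(normalize.PLATE_KEY)["viability"].median()
    assert np.allclose(medians, 1.0, atol=1e-12)


def test_normalize_screen_shared_scale_exposes_query_effect(mini_screen, mini_config):
    """On the shared (proficient) scale the depleted arm's control median
    estimates sqrt of the query effect instead of being forced to 1."""
    measurements, _ = mini_screen
    norm = normalize.normalize_screen(measurements, reference="proficient")
    neg = norm[
        norm["role"].isin(normalize.NEGATIVE_CONTROLS)
        & (norm["arm"] == "query_depleted")
    ]
    est = neg["viability"].median() ** 2
    assert est == pytest.approx(mini_config.query_effect, abs=0.1)


def test_ssmd_closed_form():
    # means 2 and 10, both sample variances 2 -> (2-10)/sqrt(4) = -4
    assert normalize.ssmd([1, 3], [9, 11]) == pytest.approx(-4.0)


def test_ssmd_degenerate_zero_variance():
    assert normalize.ssmd([2, 2], [10, 10]) == -math.inf
    assert normalize.ssmd([10, 10], [2, 2]) == math.inf
    assert normalize.ssmd([5, 7], [5, 7]) == pytest.approx(0.0)


def test_ssmd_needs_two_values_per_group():
    with pytest.raises(ValidationError):
        normalize.ssmd([1], [2, 3])


@settings(max_examples=50, deadline=None)
@given(
    pos=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=10),
    neg=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=10),
)
def test_ssmd_antisymmetric(pos, neg):
    a = normalize.ssmd(pos, neg)
    b = normalize.ssmd(neg, pos)
    if math.isfinite(a):
        assert a == pytest.approx(-b)
    else:
        assert a == -b


def test_replicate_correlation_exact_cases():
    a = pd.Series([0.5, 0.7, 0.9], index=["s1", "s2", "s3"])
    assert normalize.replicate_correlation(a, a) == pytest.approx(1.0)
    assert normalize.replicate_correlation(a, -a + 1.4) == pytest.approx(-1.0)


def test_replicate_correlation_derived_value():
    # direct Pearson formula: r = 3 / sqrt(2 * 14/3) = sqrt(27/28)
    a = pd.Series([1.0, 2.0, 3.0], index=list("xyz"))
    b = pd.Series([1.0, 2.0, 4.0], index=list("xyz"))
    assert normalize.replicate_correlation(a, b) == pytest.approx(
        math.sqrt(27 / 28), abs=1e-12
    )


def test_replicate_correlation_zero_variance_is_missing():
    a = pd.Series([1.0, 1.0, 1.0], index=list("xyz"))
    b = pd.Series([1.0, 2.0, 3.0], index=list("xyz"))
    assert math.isnan(normalize.replicate_correlation(a, b))


def test_cytotoxicity_filter_thresholds():
    v = pd.Series({"toxic": 0.10, "borderline": 0.20, "healthy": 1.0})
    retained, excluded = normalize.cytotoxicity_filter(v, overall_median=1.0)
    assert excluded == {"toxic"}          # strictly below 0.2 x median
    assert "borderline" in retained       # exactly at threshold stays


def test_cytotoxicity_filter_none_excluded_when_all_healthy():
    v = pd.Series({"a": 1.0, "b": 1.0})
    retained, excluded = normalize.cytotoxicity_filter(v, 1.0)
    assert excluded == set() and retained == {"a", "b"}


@settings(max_examples=30, deadline=None)
@given(
    values=st.dictionaries(
        st.text(alphabet="ABCDEFG", min_size=1, max_size=3),
        st.floats(0, 2, allow_nan=False),
        min_size=1, max_size=10,
    )
)
def test_cytotoxicity_filter_partitions_gene_set(values):
    v = pd.Series(values)
    retained, excluded = normalize.cytotoxicity_filter(v, 1.0)
    assert retained | excluded == set(v.index)
    assert retained & excluded == set()


def test_qc_report_structure(mini_screen, mini_library):
    measurements, _ = mini_screen
    norm = normalize.normalize_screen(measurements)
    gene_map = dict(zip(mini_library.entries["sirna_id"], mini_library.entries["gene"]))
    norm["gene"] = norm["content"].map(gene_map)
    report = normalize.qc_report(norm)
    assert (report.plate_ssmd["ssmd"] < 0).all()
    assert report.replicate_correlations["pearson_r"].between(-1, 1).all()
    assert report.retained_genes | report.excluded_genes == set(
        mini_library.genes
    )
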