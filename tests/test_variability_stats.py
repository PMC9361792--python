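"""Adjusted CV, bounded transforms, gated condition comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modvar.synthetic_data import gen_condition_table
from modvar.variability_stats import (
    adjusted_cv,
    bounded_transform,
    condition_comparison,
    dunn_test,
    sample_sd,
    variability_report,
)


def test_adjusted_cv_examples():
    assert adjusted_cv([5.0, 5.0, 5.0]) == 0.0
    # SD([8,10,12]) = 2, mean 10 -> CV 0.2, adjusted by (1 + 1/12)
    assert adjusted_cv([8.0, 10.0, 12.0]) == pytest.approx(0.2 * (1 + 1 / 12))
    assert np.isnan(adjusted_cv([-1.0, 1.0]))  # zero mean undefined
    assert np.isnan(adjusted_cv([3.0]))  # n < 2


@given(
    c=st.floats(0.1, 50.0),
    vals=st.lists(st.floats(1.0, 100.0), min_size=3, max_size=12),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_adjusted_cv_scale_and_sign_invariance(c, vals):
    x = np.asarray(vals)
    if x.mean() == 0:
        return
    base = adjusted_cv(x)
    assert adjusted_cv(c * x) == pytest.approx(base, rel=1e-9)
    assert adjusted_cv(-x) == pytest.approx(base, rel=1e-9)


def test_bounded_transforms():
    # 10^(−1.0969) ≈ 0.0800 s: the log latency scale
    assert bounded_transform([0.08], "log")[0] == pytest.approx(-1.0969, abs=1e-4)
    assert 10 ** bounded_transform([0.08], "log")[0] == pytest.approx(0.08)
    assert bounded_transform([0.0], "arctan_pi")[0] == 0.0
    x = np.array([0.1, 0.5, 0.9])
    back = np.tan(bounded_transform(x, "arctan_pi")) / np.pi
    assert back == pytest.approx(x, abs=1e-12)
    with pytest.raises(ValueError) as exc:
        bounded_transform([0.1, -0.5, 0.2], "log")
    assert "1" in str(exc.value)  # offending row listed


def test_condition_comparison_null_case():
    rng = np.random.default_rng(0)
    base = rng.normal(10.0, 1.0, size=12)
    groups = {c: base.copy() for c in ("ctrl", "Proc", "ProcCCAP", "wash")}
    rep = condition_comparison(groups, "a")
    assert rep.statistic == pytest.approx(0.0, abs=1e-9)
    assert rep.p > 0.99
    assert not any(pair["significant"] for pair in rep.posthoc)


def test_condition_comparison_large_separation_detected():
    """A five-SD mean shift at n=16 is detected essentially surely, and
    every pair against the shifted group is significant post hoc."""
    rng = np.random.default_rng(1)
    groups = {
        "ctrl": rng.normal(10.0, 1.0, 16),
        "Proc": rng.normal(15.0, 1.0, 16),  # +5 SD
        "wash": rng.normal(10.0, 1.0, 16),
    }
    rep = condition_comparison(groups, "a")
    assert rep.p < 0.001
    for pair in rep.posthoc:
        if "Proc" in (pair["group1"], pair["group2"]):
            assert pair["significant"]


def test_condition_comparison_gates_are_auditable():
    rng = np.random.default_rng(2)
    normal_groups = {
        "ctrl": rng.normal(10, 1, 16), "Proc": rng.normal(11, 1, 16),
    }
    rep = condition_comparison(normal_groups)
    assert rep.test == "anova" and rep.posthoc_test == "tukey"
    assert rep.normality_pass and rep.equal_variance_pass
    assert rep.df == 1 and rep.df_resid == 30
    skewed = {
        "ctrl": np.exp(rng.normal(0, 1.5, 20)),
        "Proc": np.exp(rng.normal(0.2, 1.5, 20)),
    }
    rep2 = condition_comparison(skewed)
    assert rep2.test == "ranks" and rep2.posthoc_test == "dunn"
    assert not rep2.normality_pass


def test_rank_branch_reports_medians_and_is_transform_invariant():
    """A monotone transform changes nothing in the rank test: identical H
    and p before and after."""
    rng = np.random.default_rng(3)
    groups = {
        "ctrl": np.exp(rng.normal(0.0, 1.4, 18)),
        "Proc": np.exp(rng.normal(0.8, 1.4, 18)),
        "wash": np.exp(rng.normal(0.1, 1.4, 18)),
    }
    rep_raw = condition_comparison(groups)
    rep_log = condition_comparison({g: np.log(v) for g, v in groups.items()})
    assert rep_raw.test == "ranks"
    assert rep_raw.statistic == pytest.approx(rep_log.statistic, rel=1e-12)
    assert rep_raw.p == pytest.approx(rep_log.p, rel=1e-9)
    assert rep_raw.central["ctrl"] == pytest.approx(np.median(groups["ctrl"]))


def test_condition_comparison_excludes_sparse_groups():
    groups = {"ctrl": [1.0, 2.0, 3.0, 4.0], "Proc": [np.nan, np.nan, 1.0]}
    with pytest.raises(ValueError):
        condition_comparison(groups)


def test_dunn_test_symmetric_null():
    rng = np.random.default_rng(4)
    g = {c: rng.normal(0, 1, 15) for c in "abc"}
    for pair in dunn_test(g):
        assert 0.0 <= pair["p"] <= 1.0


def test_variability_report_structure():
    means = {"a": {"ctrl": 10.0, "Proc": 15.0}, "lat": {"ctrl": 0.3, "Proc": 0.1}}
    sds = {"a": {"ctrl": 2.0, "Proc": 2.0}, "lat": {"ctrl": 0.05, "Proc": 0.02}}
    table, _ = gen_condition_table(means, sds, n_rows=16, seed=5)
    rep = variability_report(
        table, scales={"a": "ratio", "lat": "interval"}
    )
    df = rep.table
    row = df[(df.parameter == "a") & (df.condition == "ctrl")].iloc[0]
    assert row.n == 16 and row.cv > 0
    lat_row = df[(df.parameter == "lat") & (df.condition == "ctrl")].iloc[0]
    assert np.isnan(lat_row.cv) and lat_row.sd > 0  # interval scale: SD only
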