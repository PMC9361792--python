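"""Interindividual variability metrics and condition comparisons.

Variability of a parameter across individuals (or models) is quantified
as the coefficient of variation, SD normalized to the absolute mean and
adjusted for sample size by the standard small-sample factor (1 + 1/4n),
for ratio-scale quantities; interval-scale quantities use the SD.
Bounded quantities are transformed toward normality (base-10 log, or
arctan of the value times π) before testing.

Condition comparisons follow a gated scheme: one-way ANOVA when every
group passes Shapiro–Wilk normality and the groups pass Levene's
equal-variance test, otherwise one-way ANOVA on ranks (Kruskal–Wallis);
post hoc pairs use Tukey's HSD in the equal-variance branch and Dunn's
rank test otherwise.  Central values are reported as means under ANOVA
and medians under the rank test.  α = 0.05; tests are unpaired.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONDITIONS",
    "adjusted_cv",
    "sample_sd",
    "bounded_transform",
    "dunn_test",
    "ComparisonReport",
    "condition_comparison",
    "VariabilityReport",
    "variability_report",
    "read_condition_table",
    "write_condition_table",
]

#: Canonical condition order of the experiments.
CONDITIONS = ("ctrl", "Proc", "ProcCCAP", "wash")

ALPHA = 0.05


def adjusted_cv(values: Sequence[float]) -> float:
    """Coefficient of variation with small-sample adjustment.

    CV = (sample SD / |mean|) · (1 + 1/(4n)).  Scale-invariant under
    positive multiplication; NaN when the mean is zero (undefined) or
    n < 2.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        return float("nan")
    mean = x.mean()
    if mean == 0:
        return float("nan")
    return float(x.std(ddof=1) / abs(mean) * (1.0 + 1.0 / (4.0 * n)))


def sample_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (ddof=1), NaN-tolerant."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    return float(x.std(ddof=1)) if x.size >= 2 else float("nan")


def bounded_transform(values: Sequence[float], kind: str) -> np.ndarray:
    """Monotone transform for bounded variables before normality-based tests.

    ``log``: base-10 logarithm (positive inputs only);
    ``arctan_pi``: arctan(value · π), for variables bounded in [0, 1].
    """
    x = np.asarray(values, dtype=float)
    if kind == "log":
        bad = np.nonzero(~(x > 0) & ~np.isnan(x))[0]
        if bad.size:
            raise ValueError(
                f"log transform requires positive values; offending rows: {bad.tolist()}"
            )
        return np.log10(x)
    if kind == "arctan_pi":
        return np.arctan(x * np.pi)
    raise ValueError(f"unknown transform {kind!r}")


def dunn_test(groups: Dict[str, np.ndarray]) -> List[dict]:
    """Dunn's post hoc rank comparison with Bonferroni adjustment.

    Pairwise z statistics from mean ranks of the pooled sample, with the
    tie correction in the variance term.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    out = []
    for g1, g2 in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * (1.0 - stats.norm.cdf(abs(z))) * m)
        out.append(
            dict(group1=g1, group2=g2, statistic=float(z), p=float(p),
                 significant=bool(p <= ALPHA))
        )
    return out


@dataclass
class ComparisonReport:
    """Outcome of one gated condition comparison (auditable)."""

    parameter: str
    test: str  # "anova" | "ranks"
    statistic: float  # F or H
    df: int  # between-groups degrees of freedom
    df_resid: Optional[int]  # residual df (ANOVA only)
    p: float
    central: Dict[str, float]  # mean (anova) or median (ranks) per group
    n: Dict[str, int]
    normality_pass: bool
    equal_variance_pass: Optional[bool]
    posthoc_test: str  # "tukey" | "dunn"
    posthoc: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter, "test": self.test,
            "statistic": self.statistic, "df": self.df,
            "df_resid": self.df_resid, "p": self.p, "central": self.central,
            "n": self.n, "normality_pass": self.normality_pass,
            "equal_variance_pass": self.equal_variance_pass,
            "posthoc_test": self.posthoc_test, "posthoc": self.posthoc,
        }


def condition_comparison(
    groups: Dict[str, Sequence[float]], parameter: str = ""
) -> ComparisonReport:
    """Gated one-way comparison across condition groups.

    Missing values are dropped per group; groups left with fewer than
    three values are excluded.  Needs at least two usable groups.
    """
    clean: Dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        x = x[~np.isnan(x)]
        if x.size >= 3:
            clean[name] = x
    if len(clean) < 2:
        raise ValueError("need at least two groups with >= 3 values")

    arrays = list(clean.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: no variance anywhere, null comparison
        return ComparisonReport(
            parameter=parameter, test="ranks", statistic=0.0,
            df=len(clean) - 1, df_resid=None, p=1.0,
            central={g: float(np.median(x)) for g, x in clean.items()},
            n={g: int(x.size) for g, x in clean.items()},
            normality_pass=False, equal_variance_pass=None,
            posthoc_test="dunn", posthoc=[],
        )
    normal = all(stats.shapiro(x).pvalue > ALPHA for x in arrays)
    equal_var: Optional[bool] = None
    if normal:
        equal_var = bool(stats.levene(*arrays, center="mean").pvalue > ALPHA)

    k = len(clean)
    n_total = sum(x.size for x in arrays)
    if normal and equal_var:
        res = stats.f_oneway(*arrays)
        tuk = stats.tukey_hsd(*arrays)
        names = list(clean)
        posthoc = [
            dict(group1=names[i], group2=names[j],
                 statistic=float(tuk.statistic[i, j]),
                 p=float(tuk.pvalue[i, j]),
                 significant=bool(tuk.pvalue[i, j] <= ALPHA))
            for i, j in itertools.combinations(range(k), 2)
        ]
        return ComparisonReport(
            parameter=parameter, test="anova", statistic=float(res.statistic),
            df=k - 1, df_resid=n_total - k, p=float(res.pvalue),
            central={g: float(x.mean()) for g, x in clean.items()},
            n={g: int(x.size) for g, x in clean.items()},
            normality_pass=True, equal_variance_pass=True,
            posthoc_test="tukey", posthoc=posthoc,
        )
    res = stats.kruskal(*arrays)
    return ComparisonReport(
        parameter=parameter, test="ranks", statistic=float(res.statistic),
        df=k - 1, df_resid=None, p=float(res.pvalue),
        central={g: float(np.median(x)) for g, x in clean.items()},
        n={g: int(x.size) for g, x in clean.items()},
        normality_pass=normal, equal_variance_pass=equal_var,
        posthoc_test="dunn", posthoc=dunn_test(clean),
    )


@dataclass
class VariabilityReport:
    """Per parameter × condition variability summary."""

    table: pd.DataFrame  # rows: (parameter, condition); columns below

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def variability_report(
    table: pd.DataFrame,
    scales: Optional[Dict[str, str]] = None,
    transforms: Optional[Dict[str, str]] = None,
) -> VariabilityReport:
    """Summarize a condition table (columns = (parameter, condition)).

    ``scales`` maps parameter -> "ratio" (report adjusted CV) or
    "interval" (report SD only); default ratio.  ``transforms`` maps
    parameter -> bounded_transform kind applied before the summary's
    central value is reported on the transformed scale (the CV/SD are
    computed on the raw scale, matching how variability is compared).
    """
    scales = scales or {}
    transforms = transforms or {}
    if not isinstance(table.columns, pd.MultiIndex):
        raise ValueError("condition table needs (parameter, condition) columns")
    rows = []
    for param in table.columns.get_level_values(0).unique():
        for cond in table[param].columns:
            vals = table[(param, cond)].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            scale = scales.get(param, "ratio")
            tkind = transforms.get(param)
            central_vals = bounded_transform(vals, tkind) if tkind else vals
            rows.append(
                dict(
                    parameter=param, condition=cond, n=int(vals.size),
                    mean=float(central_vals.mean()) if vals.size else float("nan"),
                    median=float(np.median(central_vals)) if vals.size else float("nan"),
                    sd=sample_sd(vals),
                    cv=adjusted_cv(vals) if scale == "ratio" else float("nan"),
                    scale=scale, transform=tkind or "none",
                )
            )
    return VariabilityReport(pd.DataFrame(rows))


def write_condition_table(table: pd.DataFrame, path) -> None:
    """Write a (parameter, condition) table to CSV or XLSX by extension."""
    flat = table.copy()
    flat.columns = [f"{p}|{c}" for p, c in table.columns]
    path = str(path)
    if path.endswith(".xlsx"):
        flat.to_excel(path, index=False)
    else:
        flat.to_csv(path, index=False)


def read_condition_table(path, mapping: Optional[Dict[str, tuple]] = None) -> pd.DataFrame:
    """Read a condition table written by :func:`write_condition_table` or an
    arbitrary sheet with an explicit column ``mapping``
    {source column -> (parameter, condition)}."""
    path = str(path)
    flat = pd.read_excel(path) if path.endswith((".xlsx", ".xls")) else pd.read_csv(path)
    if mapping:
        flat = flat[list(mapping)].rename(columns=mapping)
        flat.columns = pd.MultiIndex.from_tuples(flat.columns)
        return flat
    cols = []
    for c in flat.columns:
        if "|" not in str(c):
            raise ValueError(f"column {c!r} is not 'parameter|condition'; pass a mapping")
        p, cond = str(c).split("|", 1)
        cols.append((p, cond))
    flat.columns = pd.MultiIndex.from_tuples(cols)
    return flat
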