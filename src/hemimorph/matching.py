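"""Demographic matching statistics: two-proportion z tests and one-way ANOVA.

These are the tests used to show that patient groups (and patients vs
controls) are matched on gender, binned surgical outcome, and continuous
covariates such as age.  The z test pools the two samples for its variance
estimate — the convention that reproduces the study-style statistics from
raw counts — and reports ``df = n1 + n2 - 2`` for display parity with
ANOVA-style reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import validate_metadata


@dataclass(frozen=True)
class TestResult:
    label: str
    statistic: float
    df: int | tuple[int, int]
    p: float
    degenerate: bool = False


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pooled-variance two-proportion z test (two-sided).

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    A pooled proportion of exactly 0 or 1 has no sampling variance; the test
    degenerates to z = 0 with a flag.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n and n >= 1 in both groups")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    df = n1 + n2 - 2
    if pooled in (0.0, 1.0):
        return TestResult("two_proportion_z", 0.0, df, 1.0, degenerate=True)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult("two_proportion_z", float(z), df, float(p))


def oneway_anova(groups: list) -> TestResult:
    """One-way ANOVA: between/within mean-square ratio on (k-1, n-k) df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups, each non-empty")
    k = len(groups)
    n = sum(len(g) for g in groups)
    if n <= k:
        raise ValueError("need total n > number of groups")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ssw <= 1e-300:
        if ssb <= 1e-300:
            return TestResult("oneway_anova", 0.0, (df1, df2), 1.0, degenerate=True)
        return TestResult("oneway_anova", np.inf, (df1, df2), 0.0, degenerate=True)
    f = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(f, df1, df2)
    return TestResult("oneway_anova", float(f), (df1, df2), float(p))


def matching_report(meta: pd.DataFrame) -> pd.DataFrame:
    """Demographic matching table for a cohort's metadata.

    Compares the two patient groups (preserved LH vs preserved RH) and the
    pooled patients vs controls on age (ANOVA F) and gender / binned ILAE
    outcome (two-proportion z).
    """
    validate_metadata(meta)
    pat = meta[meta["group"] == "patient"]
    ctrl = meta[meta["group"] == "control"]
    lh = pat[pat["preserved_hemisphere"] == "LH"]
    rh = pat[pat["preserved_hemisphere"] == "RH"]
    rows = []

    def add(label: str, res: TestResult) -> None:
        df = res.df if isinstance(res.df, int) else f"{res.df[0]},{res.df[1]}"
        rows.append(dict(label=label, statistic=res.statistic, df=df, p=res.p,
                         degenerate=res.degenerate))

    if len(lh) and len(rh):
        add("age LHp vs RHp", oneway_anova([lh["age"], rh["age"]]))
        add(
            "gender LHp vs RHp",
            two_proportion_z((lh["gender"] == "F").sum(), len(lh),
                             (rh["gender"] == "F").sum(), len(rh)),
        )
        if (pat["ilae_binned"] != "none").all():
            add(
                "ilae LHp vs RHp",
                two_proportion_z((lh["ilae_binned"] == "high").sum(), len(lh),
                                 (rh["ilae_binned"] == "high").sum(), len(rh)),
            )
    if len(pat) and len(ctrl):
        add("age patients vs controls", oneway_anova([pat["age"], ctrl["age"]]))
        add(
            "gender patients vs controls",
            two_proportion_z((pat["gender"] == "F").sum(), len(pat),
                             (ctrl["gender"] == "F").sum(), len(ctrl)),
        )
    return pd.DataFrame(rows, columns=["label", "statistic", "df", "p", "degenerate"])
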