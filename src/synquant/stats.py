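"""Group-level statistics and reporting.

Implements the comparison battery used throughout the figures — one-way
ANOVA with Tukey's multiple-comparisons test for three or more groups,
paired/unpaired two-tailed t tests for two groups, one-sample t and
Wilcoxon signed-rank tests against a stated null — together with the
ΔΔCt relative-expression calculation for RT-qPCR, percent-change effect
sizes, and the box-and-whisker summary convention (box = 25th–75th
percentile, whiskers = min and max, line at the median).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GroupSample:
    """One experimental group: a label and its per-replicate values."""

    label: str
    values: np.ndarray
    unit: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.values) < 1:
            raise ValueError("a group needs at least one value")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class StatsResult:
    test: str
    groups: tuple
    statistic: float
    df: float | tuple | None
    p_value: float
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def percent_change(mean_control: float, mean_test: float) -> float:
    """Signed percent change of the test mean relative to control.

    ``100 * (mean_test - mean_control) / mean_control``; e.g. a density
    dropping from 100 to 74.78 is a change of −25.22%.
    """
    if mean_control == 0:
        raise ValueError("percent change undefined for zero control mean")
    return 100.0 * (mean_test - mean_control) / mean_control


def box_whisker(values: np.ndarray) -> dict:
    """Median, quartiles and range, with no outlier trimming.

    Quartiles use linear interpolation so the summary matches the plotting
    convention (box from Q1 to Q3, whiskers at min and max).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(v.size),
    }


def _two_group(a: GroupSample, b: GroupSample, paired: bool, equal_var: bool) -> StatsResult:
    if paired:
        if a.n != b.n:
            raise ValueError("paired design requires equal group sizes")
        res = sps.ttest_rel(a.values, b.values)
        return StatsResult("paired t", (a.label, b.label), float(res.statistic),
                           a.n - 1, float(res.pvalue))
    if a.n < 2 or b.n < 2:
        raise ValueError("unpaired t requires n >= 2 per group")
    res = sps.ttest_ind(a.values, b.values, equal_var=equal_var)
    df = a.n + b.n - 2 if equal_var else float(res.df)
    name = "unpaired t" if equal_var else "Welch t"
    return StatsResult(name, (a.label, b.label), float(res.statistic), df, float(res.pvalue))


def _anova_tukey(samples: list[GroupSample]) -> list[StatsResult]:
    for s in samples:
        if s.n < 2:
            raise ValueError("ANOVA requires n >= 2 per group")
    arrays = [s.values for s in samples]
    f, p = sps.f_oneway(*arrays)
    k = len(samples)
    ntot = sum(s.n for s in samples)
    out = [StatsResult("one-way ANOVA", tuple(s.label for s in samples),
                       float(f), (k - 1, ntot - k), float(p))]
    values = np.concatenate(arrays)
    labels = np.concatenate([[s.label] * s.n for s in samples])
    tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
    pairs = list(combinations(tk.groupsunique, 2))
    for (g1, g2), diff, padj in zip(pairs, tk.meandiffs, tk.pvalues):
        out.append(StatsResult("Tukey HSD", (str(g1), str(g2)),
                               float(diff), ntot - k, float(padj), adjusted=True))
    return out


def _one_sample(s: GroupSample, null_value: float) -> list[StatsResult]:
    if s.n < 2:
        raise ValueError("one-sample tests require n >= 2")
    t = sps.ttest_1samp(s.values, null_value)
    out = [StatsResult("one-sample t", (s.label,), float(t.statistic), s.n - 1, float(t.pvalue))]
    d = s.values - null_value
    method = "exact" if s.n <= 25 and not np.any(d == 0) else "approx"
    w = sps.wilcoxon(d, method=method, correction=(method == "approx"))
    out.append(StatsResult("Wilcoxon signed-rank", (s.label,),
                           float(w.statistic), None, float(w.pvalue)))
    return out


def compare_groups(
    samples: list[GroupSample],
    design: str = "unpaired",
    null_value: float = 0.0,
    equal_var: bool = True,
) -> list[StatsResult]:
    """Run the comparison appropriate to the experimental design.

    design
        ``"unpaired"`` / ``"paired"`` — two-tailed t test between exactly
        two groups; ``"anova"`` — one-way ANOVA over >= 3 groups followed
        by Tukey HSD on all pairs; ``"one-sample"`` — one-sample t and
        Wilcoxon signed-rank of each group against ``null_value``.
    equal_var
        For the unpaired t: classic pooled-variance test by default,
        Welch's correction when False.
    """
    if design == "one-sample":
        out: list[StatsResult] = []
        for s in samples:
            out.extend(_one_sample(s, null_value))
        return out
    if design in ("unpaired", "paired"):
        if len(samples) != 2:
            raise ValueError("t-test designs require exactly two groups")
        return [_two_group(samples[0], samples[1], design == "paired", equal_var)]
    if design == "anova":
        if len(samples) < 3:
            raise ValueError("ANOVA design requires >= 3 groups")
        return _anova_tukey(samples)
    raise ValueError(f"unknown design {design!r}")


def ddct(
    ct: pd.DataFrame,
    control_group: str,
    target_col: str = "target_ct",
    reference_col: str = "reference_ct",
    group_col: str = "group",
) -> pd.DataFrame:
    """Relative expression by the ΔΔCt method.

    Per sample, ΔCt = Ct(target) − Ct(reference); ΔΔCt is taken relative to
    the mean ΔCt of the control group, and relative expression is
    ``2 ** (−ΔΔCt)`` (control group averages to 1 by construction).
    """
    for col in (target_col, reference_col, group_col):
        if col not in ct.columns:
            raise ValueError(f"missing column {col!r}")
    if not np.all(np.isfinite(ct[target_col])) or not np.all(np.isfinite(ct[reference_col])):
        raise ValueError("Ct values must be finite")
    out = ct.copy()
    out["delta_ct"] = out[target_col] - out[reference_col]
    control = out.loc[out[group_col] == control_group, "delta_ct"]
    if control.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    out["delta_delta_ct"] = out["delta_ct"] - control.mean()
    out["rel_expression"] = 2.0 ** (-out["delta_delta_ct"])
    return out


def samples_from_tidy(
    table: pd.DataFrame, group_col: str = "group", value_col: str = "value"
) -> list[GroupSample]:
    """Build GroupSamples from a tidy (group, value) table, preserving
    first-appearance group order."""
    order = table[group_col].drop_duplicates().tolist()
    return [
        GroupSample(str(g), table.loc[table[group_col] == g, value_col].to_numpy())
        for g in order
    ]
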