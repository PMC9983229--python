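"""Group comparisons and the relative-expression calculation.

Two-group designs use the unpaired two-tailed t-test or the Mann-Whitney
U-test (exact when sample sizes permit and there are no ties).  Designs
with three or more groups use the Kruskal-Wallis test followed by Dunn's
pairwise rank z-tests with Holm adjustment — the standard nonparametric
post hoc — or one-way ANOVA with Tukey's HSD for the parametric variant.
Relative gene expression follows the Livak 2^(-ΔΔCt) convention with a
housekeeping reference gene and a control group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "dunn_posthoc",
    "delta_delta_ct",
    "ALPHA",
]

ALPHA = 0.05

_DESIGNS = (
    "two_group_nonparametric",
    "two_group_t",
    "multi_group_nonparametric",
    "multi_group_anova",
)


@dataclass
class ComparisonResult:
    metric: str
    groups: tuple[str, ...]
    test: str
    statistic: float
    pvalue: float
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha

    def posthoc_significant(self, a: str, b: str) -> bool:
        return self.posthoc_p(a, b) < self.alpha

    def posthoc_p(self, a: str, b: str) -> float:
        if (a, b) in self.posthoc:
            return self.posthoc[(a, b)]
        return self.posthoc[(b, a)]


def dunn_posthoc(
    values: np.ndarray,
    labels: np.ndarray,
    control: str | None = None,
    adjust: str = "holm",
) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z-tests on pooled mid-ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    with tie term T = sum(t^3 - t) / (12 (N - 1)).  When ``control`` is
    given only control-versus-other pairs are tested; p-values are
    multiplicity-adjusted (Holm by default).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    n_total = len(values)
    ranks = sps.rankdata(values)  # mid-ranks for ties
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    n = {g: int((labels == g).sum()) for g in groups}
    if control is not None:
        pairs = [(control, g) for g in groups if g != control]
    else:
        pairs = list(itertools.combinations(groups, 2))
    raw = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        raw.append(2.0 * sps.norm.sf(abs(z)))
    adjusted = multipletests(raw, method=adjust)[1] if raw else []
    return {pair: float(p) for pair, p in zip(pairs, adjusted)}


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    groups: list[str],
    design: str,
    control: str | None = None,
    value_col: str = "value",
    group_col: str = "group",
    metric_col: str = "metric",
) -> ComparisonResult:
    """Run the comparison appropriate for the design on a long-format
    metrics table (one row per observation).

    ``table`` needs at least ``group_col`` and ``value_col``; rows are
    filtered to ``metric`` via ``metric_col`` when that column exists.
    Every group must contribute at least 2 observations.
    """
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {_DESIGNS}")
    df = table
    if metric_col in df.columns:
        df = df[df[metric_col] == metric]
    samples = {g: df.loc[df[group_col] == g, value_col].to_numpy(float) for g in groups}
    for g, x in samples.items():
        if len(x) < 2:
            raise ValueError(f"group {g!r} has {len(x)} observations (< 2)")
    if design.startswith("two_group") and len(groups) != 2:
        raise ValueError(f"{design} needs exactly 2 groups, got {len(groups)}")
    if design.startswith("multi_group") and len(groups) < 3:
        raise ValueError(f"{design} needs >= 3 groups, got {len(groups)}")

    posthoc: dict[tuple[str, str], float] = {}
    if design == "two_group_nonparametric":
        a, b = (samples[g] for g in groups)
        # mid-ranks for ties; no continuity correction in the large-sample
        # normal approximation (keeps the test calibrated at alpha rather
        # than conservative), exact enumeration for small tie-free samples
        stat, p = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="auto", use_continuity=False
        )
        test = "Mann-Whitney U (two-sided, exact when tie-free and small)"
    elif design == "two_group_t":
        a, b = (samples[g] for g in groups)
        stat, p = sps.ttest_ind(a, b)
        test = "unpaired two-tailed t-test"
    elif design == "multi_group_nonparametric":
        stat, p = sps.kruskal(*(samples[g] for g in groups))
        test = "Kruskal-Wallis + Dunn (Holm-adjusted)"
        values = np.concatenate([samples[g] for g in groups])
        labels = np.concatenate([np.full(len(samples[g]), g) for g in groups])
        posthoc = dunn_posthoc(values, labels, control=control)
    else:  # multi_group_anova
        stat, p = sps.f_oneway(*(samples[g] for g in groups))
        test = "one-way ANOVA + Tukey HSD"
        values = np.concatenate([samples[g] for g in groups])
        labels = np.concatenate([np.full(len(samples[g]), g) for g in groups])
        tukey = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
        for (a, b), padj in zip(
            itertools.combinations(tukey.groupsunique, 2), tukey.pvalues
        ):
            posthoc[(str(a), str(b))] = float(padj)
    logger.info("compare_groups(%s, %s): %s p=%.4g", metric, design, test, p)
    return ComparisonResult(
        metric=metric,
        groups=tuple(groups),
        test=test,
        statistic=float(stat),
        pvalue=float(p),
        posthoc=posthoc,
        n_per_group={g: len(samples[g]) for g in groups},
    )


def delta_delta_ct(
    table: pd.DataFrame,
    control_group: str,
    sample_col: str = "sample",
    group_col: str = "group",
    target_col: str = "ct_target",
    reference_col: str = "ct_reference",
) -> pd.DataFrame:
    """Relative expression by the 2^(-ΔΔCt) method.

    Per sample, ΔCt = Ct_target - Ct_reference (housekeeping gene);
    ΔΔCt = ΔCt - mean ΔCt of the control group; relative expression is
    2^(-ΔΔCt), so the control group averages 1 by construction and a
     1-cycle higher ΔCt halves the reported expression.
    """
    df = table.copy()
    if df[reference_col].isna().any():
        bad = df.loc[df[reference_col].isna(), sample_col].tolist()
        raise ValueError(f"missing reference-gene Ct for samples {bad}")
    if not (df[group_col] == control_group).any():
        raise ValueError(f"control group {control_group!r} is empty")
    df["delta_ct"] = df[target_col] - df[reference_col]
    control_mean = df.loc[df[group_col] == control_group, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - control_mean
    df["relative_expression"] = 2.0 ** (-df["delta_delta_ct"])
    return df
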