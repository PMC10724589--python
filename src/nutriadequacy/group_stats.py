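"""Inferential statistics for grouped crop measurements.

Test selection is gated on normality: Shapiro-Wilk per group at alpha
routes to parametric tests (t-test, one-way ANOVA with Duncan's multiple
range test post hoc) when no group rejects, and to nonparametric
alternatives (Mann-Whitney U, Kruskal-Wallis) otherwise. Two-way ANOVA
decomposes variance into crop, zone and interaction shares (eta-squared,
Type II sums of squares for unbalanced designs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

import statsmodels.api as sm
from statsmodels.formula.api import ols


class GroupStatsError(ValueError):
    """Raised for invalid grouped-measurement inputs."""


@dataclass
class GroupedMeasurements:
    """A numeric response with one or two crossed grouping factors."""

    response: np.ndarray
    factor_a: np.ndarray
    factor_b: np.ndarray | None = None
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.factor_a = np.asarray(self.factor_a)
        if self.factor_b is not None:
            self.factor_b = np.asarray(self.factor_b)
            if len(self.factor_b) != len(self.response):
                raise GroupStatsError("factor_b length mismatch")
        if len(self.factor_a) != len(self.response):
            raise GroupStatsError("factor_a length mismatch")
        if np.isnan(self.response).any():
            raise GroupStatsError("response contains missing values")
        if len(np.unique(self.factor_a)) < 2:
            raise GroupStatsError("need >= 2 groups for any comparison")

    def groups(self) -> dict[str, np.ndarray]:
        return {str(level): self.response[self.factor_a == level]
                for level in np.unique(self.factor_a)}


@dataclass
class TestReport:
    test_name: str
    statistic: float
    p_value: float
    selected_by: str = "normality_gate"  # or "user"
    effect_sizes: dict[str, float] = field(default_factory=dict)
    term_p_values: dict[str, float] = field(default_factory=dict)
    posthoc: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise GroupStatsError(f"p-value {self.p_value} outside [0, 1]")
        if any(v < 0 for v in self.effect_sizes.values()):
            raise GroupStatsError("variance-explained percents must be >= 0")


def normality_gate(groups: Mapping[str, np.ndarray] | Sequence[np.ndarray],
                   alpha: float = 0.05) -> str:
    """Route to "parametric" iff no group rejects Shapiro-Wilk at alpha.

    Constant groups (undefined W) are treated as a normality violation
    and route to "nonparametric" with a warning.
    """
    values = groups.values() if isinstance(groups, Mapping) else groups
    for g in values:
        g = np.asarray(g, dtype=float)
        if len(g) < 3:
            raise GroupStatsError("Shapiro-Wilk needs >= 3 values per group")
        if np.ptp(g) == 0:
            warnings.warn("constant group has undefined Shapiro-Wilk W; "
                          "routing to nonparametric tests", stacklevel=2)
            return "nonparametric"
        if stats.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def _one_way_eta_squared(groups: Sequence[np.ndarray]) -> float:
    allv = np.concatenate(groups)
    ss_total = float(np.sum((allv - allv.mean()) ** 2))
    ss_between = float(sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups))
    return 100.0 * ss_between / ss_total if ss_total > 0 else 0.0


def compare_groups(data: GroupedMeasurements, alpha: float = 0.05,
                   force: str | None = None) -> TestReport:
    """Compare the response across factor_a groups.

    Two groups: Student's t-test or Mann-Whitney U; three or more:
    one-way ANOVA (with Duncan letters and eta-squared) or
    Kruskal-Wallis. The route follows :func:`normality_gate` unless
    ``force`` ("parametric"/"nonparametric") overrides it.
    """
    groups = data.groups()
    arrays = list(groups.values())
    if force is None:
        route = normality_gate(groups, alpha)
        selected_by = "normality_gate"
    else:
        if force not in ("parametric", "nonparametric"):
            raise GroupStatsError("force must be parametric/nonparametric")
        route, selected_by = force, "user"

    if len(arrays) == 2:
        if route == "parametric":
            res = stats.ttest_ind(arrays[0], arrays[1])
            return TestReport("t-test", float(res.statistic), float(res.pvalue),
                              selected_by)
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return TestReport("mann-whitney", float(res.statistic), float(res.pvalue),
                          selected_by)

    if route == "parametric":
        res = stats.f_oneway(*arrays)
        n_total = sum(len(g) for g in arrays)
        df_resid = n_total - len(arrays)
        mse = float(sum(np.sum((g - g.mean()) ** 2) for g in arrays)) / df_resid
        letters = duncan_posthoc({k: float(v.mean()) for k, v in groups.items()},
                                 mse, {k: len(v) for k, v in groups.items()},
                                 df_resid, alpha)
        return TestReport("one-way-anova", float(res.statistic), float(res.pvalue),
                          selected_by,
                          effect_sizes={"factor_a": _one_way_eta_squared(arrays)},
                          posthoc=letters)
    res = stats.kruskal(*arrays)
    return TestReport("kruskal-wallis", float(res.statistic), float(res.pvalue),
                      selected_by)


def two_way_anova_decomposition(data: GroupedMeasurements) -> TestReport:
    """Two-way ANOVA with interaction and eta-squared variance shares.

    Uses Type II sums of squares (suitable for the unbalanced crop x
    zone design); percent variance explained for each term is its SS
    over the total SS (terms + residual). Every observed factor_a x
    factor_b cell must contain data.
    """
    if data.factor_b is None:
        raise GroupStatsError("two-way ANOVA needs factor_b")
    df = pd.DataFrame({"response": data.response,
                       "a": data.factor_a.astype(str),
                       "b": data.factor_b.astype(str)})
    for level in df["a"].unique():
        for other in df["b"].unique():
            if not len(df[(df["a"] == level) & (df["b"] == other)]):
                raise GroupStatsError(f"empty design cell: factor_a={level!r}, "
                                      f"factor_b={other!r}")
    model = ols("response ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss = table["sum_sq"]
    total = float(ss.sum())
    key_map = {"C(a)": "factor_a", "C(b)": "factor_b",
               "C(a):C(b)": "interaction", "Residual": "residual"}
    effect_sizes = {key_map[k]: 100.0 * float(ss[k]) / total for k in ss.index}
    term_p = {key_map[k]: float(table.loc[k, "PR(>F)"])
              for k in table.index if k != "Residual"}
    f_inter = float(table.loc["C(a):C(b)", "F"])
    p_inter = term_p["interaction"]
    return TestReport("two-way-anova", f_inter, p_inter,
                      effect_sizes=effect_sizes, term_p_values=term_p)


def duncan_lsr(span: int, df_resid: int, mse: float, n_harmonic: float,
               alpha: float = 0.05) -> float:
    """Duncan's least significant range for means ``span`` ranks apart.

    The critical value is the studentized-range quantile at protection
    level (1 - alpha)^(span - 1), times the standard error
    sqrt(MSE / n_h).
    """
    if span < 2:
        raise GroupStatsError("span must be >= 2")
    q = _studentized_range_quantile((1.0 - alpha) ** (span - 1), span, df_resid)
    return q * float(np.sqrt(mse / n_harmonic))


@lru_cache(maxsize=4096)
def _studentized_range_quantile(protection: float, span: int, df: int) -> float:
    # the ppf is expensive to evaluate; identical (level, span, df)
    # triples recur constantly across post hoc calls
    return float(studentized_range.ppf(protection, span, df))


def duncan_posthoc(means: Mapping[str, float], mse: float,
                   sizes: Mapping[str, int], df_resid: int,
                   alpha: float = 0.05) -> dict[str, str]:
    """Duncan's multiple range test as a letter display.

    Means are ranked and each stretch of adjacent ranked means is tested
    against the least significant range for its span; unequal group
    sizes are handled through the harmonic mean n. Groups sharing a
    letter are not significantly different. Ranges nested inside a
    non-significant range are not declared significant (the usual
    protection rule).
    """
    if mse < 0 or df_resid < 1:
        raise GroupStatsError("need a valid ANOVA context (MSE, residual df)")
    names = sorted(means, key=lambda k: means[k], reverse=True)
    k = len(names)
    if k == 1:
        return {names[0]: "a"}
    n_h = len(sizes) / sum(1.0 / sizes[name] for name in sizes)
    lsr = {span: duncan_lsr(span, df_resid, mse, n_h, alpha) for span in range(2, k + 1)}

    def homogeneous(i: int, j: int) -> bool:
        # a ranked stretch is homogeneous when its endpoint difference is
        # within the least significant range for its span
        if i == j:
            return True
        return (means[names[i]] - means[names[j]]) <= lsr[j - i + 1]

    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and homogeneous(i, j + 1):
            j += 1
        intervals.append((i, j))
    # keep only maximal stretches
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                          for o in intervals)]
    maximal.sort()
    letters: dict[str, list[str]] = {name: [] for name in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (i, j) in enumerate(maximal):
        for pos in range(i, j + 1):
            letters[names[pos]].append(alphabet[idx % len(alphabet)])
    return {name: "".join(lets) for name, lets in letters.items()}


def contingency_test(table: np.ndarray | pd.DataFrame) -> TestReport:
    """Chi-square test of association for a contingency table.

    Warns when any expected cell count falls below 5 (the usual
    validity guideline for the chi-square approximation).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise GroupStatsError("contingency table must be at least 2 x 2")
    chi2, p, _, expected = stats.chi2_contingency(arr)
    if (expected < 5).any():
        warnings.warn("expected counts < 5; chi-square approximation may be poor",
                      stacklevel=2)
    return TestReport("chi-square", float(chi2), float(p))
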