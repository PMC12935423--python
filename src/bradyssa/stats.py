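"""Group comparison and correlation statistics for slowness cohorts.

The battery mirrors common practice for small movement-disorder cohorts:
Shapiro-Wilk normality gate; Kruskal-Wallis omnibus test on midranks with a
rank-based eta-squared effect size, eta2_H = (H - k + 1) / (n - k), binned by
the Cohen cut points 0.01 / 0.06 / 0.14 (small / moderate / large);
pairwise follow-ups with Bonferroni correction — Wilcoxon signed-rank for
matched pairs (ON vs OFF of the same participants), Wilcoxon rank-sum
(Mann-Whitney) for independent pairs (controls vs patients); Spearman
rank correlations classified as very weak / weak / moderate / strong /
very strong at |rho| cut points 0.2 / 0.4 / 0.6 / 0.8; and a plain one-way
ANOVA for the age-homogeneity check.

:class:`SlownessAnalysis` bundles the battery for one cohort table and
``fit()`` returns :class:`SlownessResults` with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import InsufficientDataError, PairingError, ParameterError
from .metrics import classify_on_off_change

ALPHA = 0.05

#: Cohen cut points for the rank eta-squared bins (half-open intervals).
ETA2_BINS = ((0.06, "small"), (0.14, "moderate"), (np.inf, "large"))
#: |rho| cut points for correlation-strength bins (half-open intervals).
RHO_BINS = ((0.2, "very_weak"), (0.4, "weak"), (0.6, "moderate"),
            (0.8, "strong"), (np.inf, "very_strong"))


def eta_squared_bin(eta2: float) -> str:
    """Cohen bin for a (rank) eta-squared; negative values floor to 0."""
    eta2 = max(0.0, float(eta2))
    for edge, label in ETA2_BINS:
        if eta2 < edge:
            return label
    return "large"


def rho_strength_bin(rho: float) -> str:
    """Strength class of a Spearman coefficient from |rho|."""
    r = abs(float(rho))
    for edge, label in RHO_BINS:
        if r < edge:
            return label
    return "very_strong"


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test, with optional effect size."""

    test_name: str
    statistic: float
    p_value: float
    group_sizes: Tuple[int, ...]
    df: Optional[float] = None
    effect_size: Optional[float] = None
    effect_bin: Optional[str] = None
    correction: str = "none"
    m_comparisons: int = 1
    comparison: Optional[str] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ParameterError(f"p-value {self.p_value} outside [0, 1]")

    def significant(self, alpha: float = ALPHA) -> bool:
        return self.p_value < alpha


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman coefficient with its strength class and sign."""

    rho: float
    n: int
    strength_bin: str
    sign: str
    variables: Optional[Tuple[str, str]] = None
    defined: bool = True


def shapiro_gate(groups: Dict[str, Sequence[float]],
                 alpha: float = ALPHA) -> Dict[str, object]:
    """Shapiro-Wilk normality verdict per group plus a branch recommendation.

    A constant group is degenerate and reported as non-testable (treated as
    non-normal for branching). The recommended branch is ``"nonparametric"``
    as soon as any group rejects normality at ``alpha``.
    """
    verdicts: Dict[str, Dict[str, object]] = {}
    any_reject = False
    for name, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size < 3:
            raise InsufficientDataError(
                f"group {name!r}: need >= 3 observations, got {x.size}")
        if np.ptp(x) == 0:
            verdicts[name] = {"normal": None, "p_value": None,
                              "testable": False}
            any_reject = True
            continue
        stat, p = scipy.stats.shapiro(x)
        reject = p < alpha
        verdicts[name] = {"normal": not reject, "p_value": float(p),
                          "statistic": float(stat), "testable": True}
        any_reject = any_reject or reject
    return {"groups": verdicts,
            "branch": "nonparametric" if any_reject else "parametric"}


def kruskal_wallis(groups: Dict[str, Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H on midranks with tie correction and rank eta-squared.

    eta2_H = (H - k + 1) / (n - k); it may be slightly negative under the
    null and is floored at 0 for binning only (the raw value is reported).
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ParameterError("need at least 2 groups")
    for name, a in zip(names, arrays):
        if a.size == 0:
            raise ParameterError(f"group {name!r} is empty")
    n = sum(a.size for a in arrays)
    k = len(arrays)
    if n < k + 1:
        raise InsufficientDataError("need total n >= k + 1")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        # all observations identical: H = 0 by convention
        h, p, degenerate = 0.0, 1.0, True
    else:
        h, p = scipy.stats.kruskal(*arrays)
        degenerate = False
    eta2 = (h - k + 1) / (n - k)
    return TestResult(
        test_name="kruskal_wallis", statistic=float(h), p_value=float(p),
        group_sizes=tuple(a.size for a in arrays), df=float(k - 1),
        effect_size=float(eta2), effect_bin=eta_squared_bin(eta2),
        degenerate=degenerate,
    )


def _signed_rank(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, bool]:
    diffs = x - y
    if np.all(diffs == 0):
        return 0.0, 1.0, True
    stat, p = scipy.stats.wilcoxon(x, y)
    return float(stat), float(p), False


def pairwise_wilcoxon(groups: Dict[str, Sequence[float]],
                      paired: Sequence[Tuple[str, str]] = (),
                      ids: Optional[Dict[str, Sequence[str]]] = None,
                      m: Optional[int] = None) -> List[TestResult]:
    """All pairwise comparisons with Bonferroni correction.

    Pairs listed in ``paired`` (same participants measured twice, e.g. ON
    vs OFF) use the Wilcoxon signed-rank test; all other pairs use the
    rank-sum (Mann-Whitney) test. Raw p-values are multiplied by ``m``
    (default: the number of comparisons) and capped at 1.

    When ``ids`` is given, matched pairs must agree element-wise on the
    participant ids; a mismatch raises :class:`PairingError`.
    """
    names = list(groups)
    pairs = [(names[i], names[j]) for i in range(len(names))
             for j in range(i + 1, len(names))]
    m = m if m is not None else len(pairs)
    paired_set = {frozenset(p) for p in paired}
    results: List[TestResult] = []
    for a_name, b_name in pairs:
        a = np.asarray(groups[a_name], dtype=float)
        b = np.asarray(groups[b_name], dtype=float)
        matched = frozenset((a_name, b_name)) in paired_set
        degenerate = False
        if matched:
            if a.size != b.size:
                raise PairingError(
                    f"matched pair {a_name}/{b_name} has unequal sizes")
            if ids is not None and list(ids[a_name]) != list(ids[b_name]):
                raise PairingError(
                    f"matched pair {a_name}/{b_name}: participant ids differ")
            stat, p, degenerate = _signed_rank(a, b)
            test_name = "wilcoxon_signed_rank"
        else:
            stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
            test_name = "wilcoxon_rank_sum"
        results.append(TestResult(
            test_name=test_name, statistic=float(stat),
            p_value=float(min(1.0, m * p)),
            group_sizes=(a.size, b.size),
            correction="bonferroni", m_comparisons=m,
            comparison=f"{a_name} vs {b_name}", degenerate=degenerate,
        ))
    return results


def spearman(x: Sequence[float], y: Sequence[float],
             variables: Optional[Tuple[str, str]] = None) -> CorrelationResult:
    """Spearman rank correlation with the printed strength classification."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ParameterError("x and y must have equal length")
    if xa.size < 3:
        raise InsufficientDataError("need n >= 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return CorrelationResult(rho=float("nan"), n=int(xa.size),
                                 strength_bin="undefined", sign="zero",
                                 variables=variables, defined=False)
    rho = float(scipy.stats.spearmanr(xa, ya).statistic)
    sign = "positive" if rho > 0 else ("negative" if rho < 0 else "zero")
    return CorrelationResult(rho=rho, n=int(xa.size),
                             strength_bin=rho_strength_bin(rho), sign=sign,
                             variables=variables)


def anova_oneway(groups: Dict[str, Sequence[float]]) -> TestResult:
    """One-way ANOVA F-test (used for the age-homogeneity check)."""
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ParameterError("need at least 2 groups")
    for name, a in zip(names, arrays):
        if a.size < 2:
            raise ParameterError(f"group {name!r}: need >= 2 observations")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        f, p, degenerate = 0.0, 1.0, True
    else:
        f, p = scipy.stats.f_oneway(*arrays)
        degenerate = False
        if np.isnan(f):  # identical groups with zero within-variance
            f, p, degenerate = 0.0, 1.0, True
    k = len(arrays)
    n = pooled.size
    return TestResult(
        test_name="anova_oneway", statistic=float(f), p_value=float(p),
        group_sizes=tuple(a.size for a in arrays), df=float(k - 1),
        degenerate=degenerate,
    )


class SlownessAnalysis:
    """The full statistical battery over one cohort table.

    Parameters
    ----------
    cohort : pandas.DataFrame
        Cohort table with columns ``participant_id, cohort, state, rt_s,
        av_dps, brad_score`` (the format of
        :func:`bradyssa.tables.fixture_table2`). Groups are CG (state NA),
        EG-ON, and EG-OFF.
    alpha : float
        Significance level, default 0.05.
    pool_states : bool
        Pool EG ON and OFF rows for the clinical-score correlations
        (default) or compute them per state.
    """

    def __init__(self, cohort: pd.DataFrame, alpha: float = ALPHA,
                 pool_states: bool = True):
        self.cohort = cohort.reset_index(drop=True)
        self.alpha = alpha
        self.pool_states = pool_states

    def _groups(self, metric: str) -> Dict[str, np.ndarray]:
        c = self.cohort
        out = {}
        for label, mask in (
            ("CG", (c["cohort"] == "CG")),
            ("EG-ON", (c["cohort"] == "EG") & (c["state"] == "ON")),
            ("EG-OFF", (c["cohort"] == "EG") & (c["state"] == "OFF")),
        ):
            vals = c.loc[mask, metric].dropna().to_numpy(dtype=float)
            if vals.size:
                out[label] = vals
        return out

    def _group_ids(self, metric: str) -> Dict[str, List[str]]:
        c = self.cohort
        out = {}
        for label, mask in (
            ("EG-ON", (c["cohort"] == "EG") & (c["state"] == "ON")),
            ("EG-OFF", (c["cohort"] == "EG") & (c["state"] == "OFF")),
        ):
            sub = c.loc[mask].dropna(subset=[metric])
            out[label] = sorted(sub["participant_id"].str.lstrip("EG"))
        return out

    def fit(self) -> "SlownessResults":
        omnibus: Dict[str, TestResult] = {}
        pairwise: Dict[str, List[TestResult]] = {}
        normality: Dict[str, Dict] = {}
        for metric in ("rt_s", "av_dps"):
            groups = self._groups(metric)
            if len(groups) < 2:
                continue
            normality[metric] = shapiro_gate(groups, alpha=self.alpha)
            omnibus[metric] = kruskal_wallis(groups)
            # matched ON/OFF samples must share participant order
            ordered: Dict[str, np.ndarray] = {}
            ids: Dict[str, List[str]] = {}
            for g in groups:
                if g.startswith("EG"):
                    state = g.split("-")[1]
                    sub = self.cohort[
                        (self.cohort["cohort"] == "EG")
                        & (self.cohort["state"] == state)
                    ].dropna(subset=[metric])
                    sub = sub.sort_values("participant_id")
                    ordered[g] = sub[metric].to_numpy(dtype=float)
                    ids[g] = list(sub["participant_id"])
                else:
                    ordered[g] = groups[g]
            pairwise[metric] = pairwise_wilcoxon(
                ordered, paired=[("EG-ON", "EG-OFF")], ids=ids or None)
        correlations: Dict[str, CorrelationResult] = {}
        eg = self.cohort[(self.cohort["cohort"] == "EG")
                         & self.cohort["brad_score"].notna()]
        state_sets = ([eg] if self.pool_states
                      else [eg[eg["state"] == s] for s in ("ON", "OFF")])
        for sub in state_sets:
            tag = "pooled" if self.pool_states else str(sub["state"].iloc[0])
            for metric in ("rt_s", "av_dps"):
                ok = sub.dropna(subset=[metric, "brad_score"])
                if len(ok) >= 3:
                    correlations[f"{metric}~brad_score[{tag}]"] = spearman(
                        ok[metric], ok["brad_score"],
                        variables=(metric, "brad_score"))
        try:
            change = classify_on_off_change(self.cohort)
        except PairingError:
            change = pd.Series(dtype=object, name="change")
        return SlownessResults(
            cohort=self.cohort, alpha=self.alpha, normality=normality,
            omnibus=omnibus, pairwise=pairwise, correlations=correlations,
            on_off_change=change,
        )


@dataclass(frozen=True)
class SlownessResults:
    """Fitted statistical battery for one cohort."""

    cohort: pd.DataFrame
    alpha: float
    normality: Dict[str, Dict]
    omnibus: Dict[str, TestResult]
    pairwise: Dict[str, List[TestResult]]
    correlations: Dict[str, CorrelationResult]
    on_off_change: pd.Series

    def both_improved(self) -> List[str]:
        """Participants whose RT fell and AV rose from OFF to ON."""
        return list(self.on_off_change[
            self.on_off_change == "both_improved"].index)

    def summary(self) -> str:
        lines = ["Slowness cohort analysis", "=" * 48]
        for metric, res in self.omnibus.items():
            branch = self.normality.get(metric, {}).get("branch", "?")
            lines.append(
                f"{metric}: Kruskal-Wallis H = {res.statistic:.3f}, "
                f"p = {res.p_value:.3g}, eta2 = {res.effect_size:.4f} "
                f"({res.effect_bin}); normality branch: {branch}")
            for pw in self.pairwise.get(metric, []):
                lines.append(
                    f"    {pw.comparison}: {pw.test_name} "
                    f"stat = {pw.statistic:.1f}, "
                    f"p_bonf = {pw.p_value:.3g}"
                    + (" [degenerate]" if pw.degenerate else ""))
        if self.correlations:
            lines.append("Spearman correlations vs bradykinesia score:")
            for key, corr in self.correlations.items():
                lines.append(
                    f"    {key}: rho = {corr.rho:.3f} "
                    f"({corr.strength_bin}, {corr.sign}, n = {corr.n})")
        if len(self.on_off_change):
            lines.append(
                "ON-vs-OFF change: both improved = "
                f"{self.both_improved()}")
        return "\n".join(lines)
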