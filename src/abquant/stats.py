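"""Cohort statistics: the nonparametric battery over per-case density tables.

Deposit densities in autopsy cohorts are heavily skewed with many zeros, so
the primary comparisons are nonparametric: a Kruskal–Wallis omnibus test per
outcome per grouping, followed — when the omnibus is significant — by Dunn's
pairwise post-hoc test with Bonferroni correction; a Wilcoxon rank-sum test
when only two groups are compared. Demographics use means/SD with one-way
ANOVA, and categorical tables use chi-square or Fisher's exact test (Fisher
whenever any expected cell is below 5). Analyses exclude cases with missing
data for the variables involved; no imputation is attempted, and no covariate
adjustment is applied anywhere.

The cohort table is a plain pandas DataFrame, one row per case, with a group
label column per staging scheme (e.g. ADNC, Thal, Braak, CERAD, APOE4, MRA)
and numeric outcome columns (per-class, per-region counts and densities).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "TestResult",
    "summarize_groups",
    "kruskal_wallis",
    "dunn_posthoc",
    "wilcoxon_rank_sum",
    "categorical_test",
    "one_way_anova",
    "AnalysisSpec",
    "AnalysisPlan",
    "BatteryReport",
    "run_analysis_battery",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    group_sizes: tuple[int, ...] | None = None
    adjusted_p: float | None = None
    comparison: str | None = None
    method_detail: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.adjusted_p is not None:
            self.adjusted_p = min(1.0, max(self.adjusted_p, self.p_value))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def summarize_groups(
    cohort: pd.DataFrame,
    variable: str,
    by_group: str,
    kind: str = "median_iqr",
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group summary of one numeric variable.

    ``median_iqr`` reports n, median, Q1, Q3, IQR with linearly interpolated
    (type-7) quartiles; ``mean_sd`` reports n, mean, SD (ddof=1) for
    demographics. Missing values are dropped per group; an empty group keeps
    its row with n=0 and missing statistics.
    """
    if kind not in ("median_iqr", "mean_sd"):
        raise ValueError("kind must be 'median_iqr' or 'mean_sd'")
    levels = group_order or sorted(cohort[by_group].dropna().unique().tolist())
    rows = []
    for level in levels:
        vals = pd.to_numeric(
            cohort.loc[cohort[by_group] == level, variable], errors="coerce"
        ).dropna().to_numpy()
        row: dict = {by_group: level, "variable": variable, "n": int(vals.size)}
        if kind == "median_iqr":
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                row.update(median=med, q1=q1, q3=q3, iqr=q3 - q1)
            else:
                row.update(median=np.nan, q1=np.nan, q3=np.nan, iqr=np.nan)
        else:
            if vals.size:
                row.update(mean=vals.mean(), sd=vals.std(ddof=1) if vals.size > 1 else np.nan)
            else:
                row.update(mean=np.nan, sd=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------


def _as_groups(groups) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float) for g in groups]


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H with tie correction; p from chi-square on k−1 df."""
    gs = _as_groups(groups)
    if len(gs) < 2 or any(g.size < 1 for g in gs):
        raise ValueError("kruskal_wallis needs >= 2 groups, each with n >= 1")
    pooled = np.concatenate(gs)
    k = len(gs)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, df=k - 1,
                          group_sizes=tuple(g.size for g in gs))
    h, p = sps.kruskal(*gs)
    return TestResult("kruskal_wallis", float(h), float(p), df=k - 1,
                      group_sizes=tuple(g.size for g in gs))


def _pooled_rank_stats(gs: list[np.ndarray]) -> tuple[list[float], float, int]:
    """Per-group mean pooled ranks, the tie-corrected variance factor, and N."""
    pooled = np.concatenate(gs)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in gs:
        mean_ranks.append(float(ranks[start : start + g.size].mean()) if g.size else np.nan)
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term
    return mean_ranks, var_factor, n_total


def dunn_posthoc(
    groups, labels: list[str] | None = None, adjustment: str = "bonferroni"
) -> list[TestResult]:
    """Dunn's pairwise z tests on pooled ranks, Bonferroni-adjusted.

    z_ij = (R̄_i − R̄_j) / sqrt([N(N+1)/12 − Σ(t³−t)/(12(N−1))]·(1/n_i + 1/n_j))
    with two-sided normal p-values; adjusted_p = min(1, p·k(k−1)/2) over the
    k nonempty groups. Pairs involving an empty group are skipped with a
    notice. A fully tied pool gives z = 0 and adjusted p = 1.
    """
    if adjustment != "bonferroni":
        raise ValueError("only Bonferroni adjustment is supported")
    gs = _as_groups(groups)
    if len(gs) < 3:
        raise ValueError("dunn_posthoc needs >= 3 groups (use wilcoxon_rank_sum for 2)")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(gs))]
    nonempty = [i for i, g in enumerate(gs) if g.size > 0]
    k = len(nonempty)
    n_comparisons = k * (k - 1) // 2
    mean_ranks, var_factor, _ = _pooled_rank_stats([gs[i] for i in nonempty])
    rank_of = dict(zip(nonempty, mean_ranks))
    results: list[TestResult] = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        comparison = f"{labels[i]} vs {labels[j]}"
        if gs[i].size == 0 or gs[j].size == 0:
            results.append(
                TestResult("dunn", np.nan, np.nan, comparison=comparison,
                           group_sizes=(gs[i].size, gs[j].size),
                           method_detail="skipped: empty group")
            )
            continue
        denom = var_factor * (1.0 / gs[i].size + 1.0 / gs[j].size)
        if denom <= 0:
            z, p = 0.0, 1.0
        else:
            z = (rank_of[i] - rank_of[j]) / np.sqrt(denom)
            p = 2.0 * sps.norm.sf(abs(z))
        results.append(
            TestResult(
                "dunn",
                float(z),
                float(min(p, 1.0)),
                adjusted_p=min(1.0, p * n_comparisons),
                comparison=comparison,
                group_sizes=(gs[i].size, gs[j].size),
                method_detail=f"bonferroni x{n_comparisons}",
            )
        )
    return results


def wilcoxon_rank_sum(a, b, two_sided: bool = True) -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test for two groups.

    Uses the exact null distribution when the pooled sample is small
    (n_a + n_b ≤ 12) and tie-free, otherwise the normal approximation with
    tie correction (no continuity correction); the path taken is recorded.
    The reported statistic is the rank sum of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size <= 12) and not has_ties
    alternative = "two-sided" if two_sided else "greater"
    res = sps.mannwhitneyu(
        a, b, alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    w_a = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return TestResult(
        "wilcoxon_rank_sum",
        w_a,
        float(res.pvalue),
        group_sizes=(a.size, b.size),
        method_detail="exact" if exact else "normal approximation, tie-corrected",
    )


# ---------------------------------------------------------------------------
# Categorical tests
# ---------------------------------------------------------------------------


def _table_log_prob(table: np.ndarray) -> float:
    """Log conditional (hypergeometric) probability of an r×c table given margins."""
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _fisher_monte_carlo(table: np.ndarray, n_sim: int, seed: int) -> float:
    """Seeded Monte-Carlo Fisher p for r×c tables: resample tables with the
    observed margins and compare conditional probabilities."""
    rng = np.random.default_rng(seed)
    r, c = table.shape
    row_vec = np.repeat(np.arange(r), table.sum(axis=1))
    col_vec = np.repeat(np.arange(c), table.sum(axis=0))
    logp_obs = _table_log_prob(table)
    hits = 0
    for _ in range(n_sim):
        perm = rng.permutation(col_vec)
        sim = np.bincount(row_vec * c + perm, minlength=r * c).reshape(r, c)
        if _table_log_prob(sim) <= logp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_sim + 1)


def categorical_test(
    table,
    method: str = "auto",
    yates: bool = False,
    n_sim: int = 20000,
    seed: int = 0,
) -> TestResult:
    """Chi-square or Fisher's exact test on an r×c contingency table.

    ``auto`` picks Fisher whenever any expected cell count is below 5, else
    the chi-square test (without Yates continuity correction unless
    ``yates``). Fisher on tables larger than 2×2 uses a seeded Monte-Carlo
    sampler of tables with the observed margins; the method taken is
    recorded. Rows and columns with zero margins are dropped with a notice.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a 2-D array of nonnegative counts")
    notices = []
    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        notices.append(
            f"dropped {int((~keep_rows).sum())} zero rows, "
            f"{int((~keep_cols).sum())} zero columns"
        )
        table = table[keep_rows][:, keep_cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table needs at least 2 nonempty rows and columns")
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if method == "auto":
        method = "fisher" if np.any(expected < 5) else "chisq"
    if method == "chisq":
        if np.all(table == expected):
            stat, p, dof = 0.0, 1.0, (table.shape[0] - 1) * (table.shape[1] - 1)
        else:
            stat, p, dof, _ = sps.chi2_contingency(table, correction=yates)
        notices.append("chi-square" + (" (Yates)" if yates else ""))
        return TestResult("chi_square", float(stat), float(p), df=float(dof),
                          method_detail="; ".join(notices))
    if method == "fisher":
        if table.shape == (2, 2):
            stat, p = sps.fisher_exact(table, alternative="two-sided")
            notices.append("exact 2x2")
        else:
            stat = np.nan
            p = _fisher_monte_carlo(table, n_sim=n_sim, seed=seed)
            notices.append(f"monte-carlo B={n_sim} seed={seed}")
        return TestResult("fisher_exact", float(stat), float(p),
                          method_detail="; ".join(notices))
    raise ValueError(f"unknown method {method!r}")


def one_way_anova(groups) -> TestResult:
    """One-way ANOVA: F = MS_between / MS_within with F(k−1, N−k) p-value.

    Zero within-group variance with unequal means reports F infinite, p = 0;
    fully identical data reports F = 0, p = 1.
    """
    gs = _as_groups(groups)
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("one_way_anova needs >= 2 groups, each with n >= 2")
    k = len(gs)
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n_total - k
    sizes = tuple(g.size for g in gs)
    if ssw == 0:
        if ssb == 0:
            return TestResult("anova", 0.0, 1.0, df=df1, group_sizes=sizes)
        return TestResult("anova", float("inf"), 0.0, df=df1, group_sizes=sizes)
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult("anova", float(f), p, df=df1, group_sizes=sizes)


# ---------------------------------------------------------------------------
# Analysis battery
# ---------------------------------------------------------------------------


@dataclass
class AnalysisSpec:
    """One analysis: a grouping variable, its outcomes, and the test choice.

    ``test`` is ``auto`` (Wilcoxon for exactly two groups, Kruskal–Wallis
    otherwise), ``kruskal_wallis``, or ``wilcoxon``. Cases whose group label
    matches an entry of ``exclude_levels`` (case-insensitive) are dropped —
    by default "deferred" diagnoses, which carry no usable clinical category.
    Dunn–Bonferroni post-hoc comparisons run when the omnibus p is below
    ``posthoc_alpha`` (set to None to disable, 1.0 to force).
    """

    grouping: str
    outcomes: list[str]
    test: str = "auto"
    posthoc_alpha: float | None = 0.05
    exclude_levels: tuple[str, ...] = ("deferred",)
    group_order: list[str] | None = None


@dataclass
class AnalysisPlan:
    analyses: list[AnalysisSpec] = field(default_factory=list)


@dataclass
class BatteryReport:
    """Tidy test results plus per-group summaries and a Markdown rendering."""

    results: pd.DataFrame
    summaries: pd.DataFrame

    def to_markdown(self) -> str:
        lines = ["# Cohort analysis report", ""]
        if not self.summaries.empty:
            lines += ["## Group summaries (median, IQR)", ""]
            lines.append(self.summaries.to_markdown(index=False))
            lines.append("")
        lines += ["## Tests", ""]
        if self.results.empty:
            lines.append("(no analyses run)")
        else:
            lines.append(self.results.to_markdown(index=False))
        lines.append("")
        return "\n".join(lines)


def _select_groups(
    cohort: pd.DataFrame, spec: AnalysisSpec, outcome: str
) -> tuple[list[str], list[np.ndarray], int]:
    sub = cohort[[spec.grouping, outcome]].copy()
    sub[outcome] = pd.to_numeric(sub[outcome], errors="coerce")
    sub = sub.dropna()
    excluded = 0
    if spec.exclude_levels:
        lowered = {e.lower() for e in spec.exclude_levels}
        mask = sub[spec.grouping].astype(str).str.lower().isin(lowered)
        excluded = int(mask.sum())
        sub = sub[~mask]
    levels = spec.group_order or sorted(sub[spec.grouping].astype(str).unique().tolist())
    groups = [
        sub.loc[sub[spec.grouping].astype(str) == level, outcome].to_numpy()
        for level in levels
    ]
    keep = [i for i, g in enumerate(groups) if g.size > 0]
    return [levels[i] for i in keep], [groups[i] for i in keep], excluded


def run_analysis_battery(cohort: pd.DataFrame, plan: AnalysisPlan) -> BatteryReport:
    """Run the omnibus + post-hoc battery over a cohort table.

    Per (grouping, outcome): cases with missing data are excluded for that
    analysis only; two groups get a Wilcoxon rank-sum test, three or more a
    Kruskal–Wallis omnibus with Dunn–Bonferroni pairwise comparisons when the
    omnibus is significant. Groupings with fewer than two nonempty groups are
    skipped with a notice row.
    """
    rows: list[dict] = []
    summaries: list[pd.DataFrame] = []

    def add(spec: AnalysisSpec, outcome: str, result: TestResult, note: str = "") -> None:
        rows.append(
            {
                "grouping": spec.grouping,
                "outcome": outcome,
                "comparison": result.comparison or "omnibus",
                "test": result.test_name,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "adjusted_p": result.adjusted_p,
                "n_per_group": ";".join(str(n) for n in (result.group_sizes or ())),
                "method": result.method_detail or "",
                "note": note,
            }
        )

    for spec in plan.analyses:
        if spec.grouping not in cohort.columns:
            raise ValueError(f"grouping column {spec.grouping!r} not in cohort table")
        for outcome in spec.outcomes:
            if outcome not in cohort.columns:
                raise ValueError(f"outcome column {outcome!r} not in cohort table")
            labels, groups, n_excluded = _select_groups(cohort, spec, outcome)
            note = f"excluded {n_excluded} cases by level filter" if n_excluded else ""
            if len(groups) < 2:
                rows.append(
                    {
                        "grouping": spec.grouping, "outcome": outcome,
                        "comparison": "omnibus", "test": "skipped",
                        "statistic": np.nan, "p_value": np.nan, "adjusted_p": None,
                        "n_per_group": ";".join(str(g.size) for g in groups),
                        "method": "", "note": "fewer than 2 nonempty groups",
                    }
                )
                continue
            summary = summarize_groups(
                cohort.assign(**{spec.grouping: cohort[spec.grouping].astype(str)})
                .loc[lambda d: d[spec.grouping].isin(labels)],
                outcome,
                spec.grouping,
                group_order=labels,
            )
            summary.insert(0, "grouping", spec.grouping)
            summary = summary.rename(columns={spec.grouping: "group"})
            summaries.append(summary)

            use_wilcoxon = spec.test == "wilcoxon" or (spec.test == "auto" and len(groups) == 2)
            if use_wilcoxon:
                if len(groups) != 2:
                    raise ValueError(
                        f"{spec.grouping}/{outcome}: wilcoxon requested for "
                        f"{len(groups)} groups"
                    )
                res = wilcoxon_rank_sum(groups[0], groups[1])
                res.comparison = f"{labels[0]} vs {labels[1]}"
                add(spec, outcome, res, note)
            else:
                omni = kruskal_wallis(groups)
                add(spec, outcome, omni, note)
                if (
                    len(groups) >= 3
                    and spec.posthoc_alpha is not None
                    and omni.p_value < spec.posthoc_alpha
                ):
                    for res in dunn_posthoc(groups, labels=labels):
                        add(spec, outcome, res)

    results = pd.DataFrame(
        rows,
        columns=[
            "grouping", "outcome", "comparison", "test", "statistic",
            "p_value", "adjusted_p", "n_per_group", "method", "note",
        ],
    )
    summary_df = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )
    return BatteryReport(results=results, summaries=summary_df)
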