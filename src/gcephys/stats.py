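"""Normality-gated two-group statistics and the mixed-design ANOVA.

The comparison protocol: each feature is tested for normality per group
with the Shapiro-Wilk test; when both groups are compatible with
normality (p > alpha_gate) the groups are compared with an unpaired
two-sided Student's t test (pooled variance) and summarized as
mean +/- SEM, otherwise with a two-sided Mann-Whitney U test (exact
when feasible) and summarized as median (Q1, Q3).  Voltage-current
relations are compared with a two-way mixed-design ANOVA (genotype as
the between-subject factor, current level as the repeated measure,
cells as subjects); the genotype effect is tested against the
subjects-within-groups error with df = (1, n1 + n2 - 2).  No sphericity
correction and no multiple-testing correction are applied; significance
is read at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "AnovaResult",
    "shapiro_wilk",
    "two_group_compare",
    "mann_whitney",
    "mixed_anova_vi",
    "summarize",
]

EXACT_MWU_LIMIT = 400  # exact enumeration when n1*n2 <= this and no ties


@dataclass
class ComparisonResult:
    feature: str
    test_used: str  # "student_t" | "mann_whitney"
    statistic: float
    dof: float | None  # t only
    u: float | None  # U only
    p_value: float
    summary_a: str
    summary_b: str
    n_a: int
    n_b: int
    exact: bool | None = None  # U only
    shapiro_p: tuple[float, float] | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "test": self.test_used,
            "statistic": self.statistic,
            "dof": self.dof,
            "U": self.u,
            "p": self.p_value,
            "group_a": self.summary_a,
            "group_b": self.summary_b,
            "n": [self.n_a, self.n_b],
            "exact": self.exact,
            "significant": self.significant,
        }


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: tuple[int, int]
    p_value: float
    factors: tuple[str, str] = ("genotype", "current_level")
    n_per_group: tuple[int, int] = (0, 0)
    levels: list[float] = field(default_factory=list)
    dropped_subjects: list[str] = field(default_factory=list)
    note: str = "no sphericity correction applied"

    def as_dict(self) -> dict:
        return {
            "F": self.f_statistic,
            "df": list(self.df_between),
            "p": self.p_value,
            "factors": list(self.factors),
            "n": list(self.n_per_group),
            "levels": [float(x) for x in self.levels],
            "dropped_subjects": self.dropped_subjects,
            "note": self.note,
        }


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a 1-d sample (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk p-value unreliable for n > 5000")
    if np.ptp(x) == 0:
        # all-equal sample: maximally non-normal for gating purposes
        return 1.0, 0.0
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _fmt(x: float, sig: int = 3) -> str:
    return f"{x:.{sig}g}"


def summarize(x, family: str, unit: str = "") -> str:
    """Format a sample the way electrophysiology papers print it.

    parametric -> "mean ± SEM"; nonparametric -> "median (Q1, Q3)" with
    quartiles by linear interpolation between order statistics.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty sample")
    suffix = f" {unit}" if unit else ""
    if family == "parametric":
        mean = x.mean()
        if x.size < 2:
            return f"{_fmt(mean)}{suffix}"
        sem = x.std(ddof=1) / np.sqrt(x.size)
        return f"{_fmt(mean)} ± {_fmt(sem)}{suffix}"
    if family == "nonparametric":
        med = np.median(x)
        q1, q3 = np.percentile(x, [25, 75])
        return f"{_fmt(med)} ({_fmt(q1)}, {_fmt(q3)}){suffix}"
    raise ValueError(f"unknown family {family!r}")


def two_group_compare(
    a,
    b,
    alpha_gate: float = 0.05,
    feature: str = "",
    unit: str = "",
) -> ComparisonResult:
    """Normality-gated unpaired two-group comparison.

    Both groups pass Shapiro-Wilk at ``alpha_gate`` -> two-sided
    Student's t with pooled variance; otherwise two-sided Mann-Whitney U
    (exact enumeration when n1*n2 <= 400 and the data carry no ties,
    tie-corrected normal approximation otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero-variance input: both groups constant")
    _, p_a = shapiro_wilk(a)
    _, p_b = shapiro_wilk(b)
    normal = p_a > alpha_gate and p_b > alpha_gate

    if normal:
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return ComparisonResult(
            feature=feature,
            test_used="student_t",
            statistic=float(t),
            dof=float(a.size + b.size - 2),
            u=None,
            p_value=float(p),
            summary_a=summarize(a, "parametric", unit),
            summary_b=summarize(b, "parametric", unit),
            n_a=a.size,
            n_b=b.size,
            shapiro_p=(p_a, p_b),
        )

    result = mann_whitney(a, b, feature=feature, unit=unit)
    result.shapiro_p = (p_a, p_b)
    return result


def mann_whitney(a, b, feature: str = "", unit: str = "") -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when n1*n2 <= 400 and the pooled data carry
    no ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = (a.size * b.size <= EXACT_MWU_LIMIT) and not ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact else "asymptotic")
    return ComparisonResult(
        feature=feature,
        test_used="mann_whitney",
        statistic=float(res.statistic),
        dof=None,
        u=float(res.statistic),
        p_value=float(res.pvalue),
        summary_a=summarize(a, "nonparametric", unit),
        summary_b=summarize(b, "nonparametric", unit),
        n_a=a.size,
        n_b=b.size,
        exact=exact,
    )


def mixed_anova_vi(
    curves_a: list[tuple[np.ndarray, np.ndarray]],
    curves_b: list[tuple[np.ndarray, np.ndarray]],
    levels: np.ndarray | None = None,
    group_labels: tuple[str, str] = ("A", "B"),
) -> AnovaResult:
    """Two-way mixed ANOVA over per-cell V-I values at shared levels.

    Each element of ``curves_a``/``curves_b`` is a (levels, voltages)
    pair for one cell.  ``levels`` selects the current levels entering
    the ANOVA; by default the levels present in every cell.  Cells
    missing any included level are dropped with a warning (complete-case
    restriction).  The between-subject (genotype) F is tested against
    subjects-within-groups with df (1, n1 + n2 - 2).
    """
    all_cells = [(group_labels[0], i, lv, np.asarray(v, float))
                 for i, (lv, v) in enumerate(curves_a)] + [
        (group_labels[1], i, lv, np.asarray(v, float)) for i, (lv, v) in enumerate(curves_b)
    ]
    if levels is None:
        sets = [set(np.round(np.asarray(lv, float), 9)) for _, _, lv, _ in all_cells]
        common = set.intersection(*sets) if sets else set()
        if not common:
            raise ValueError("no current level shared by every cell; pass levels=")
        levels = np.array(sorted(common))
    levels = np.round(np.asarray(levels, dtype=float), 9)

    records = []
    dropped = []
    for grp, idx, lv, v in all_cells:
        lv = np.round(np.asarray(lv, dtype=float), 9)
        lookup = dict(zip(lv, v))
        if any(l not in lookup for l in levels):
            dropped.append(f"{grp}_{idx}")
            continue
        for l in levels:
            records.append(
                {"subject": f"{grp}_{idx}", "group": grp, "level": l, "voltage": lookup[l]}
            )
    if dropped:
        warnings.warn(f"dropping incomplete cells: {dropped}")
    df = pd.DataFrame(records)
    n1 = df.loc[df.group == group_labels[0], "subject"].nunique()
    n2 = df.loc[df.group == group_labels[1], "subject"].nunique()
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 complete cells per group")

    # between-subject partition: genotype tested against subjects-within-groups
    k = len(levels)
    subj = df.groupby(["subject", "group"], as_index=False)["voltage"].mean()
    grand = subj["voltage"].mean()
    grp = subj.groupby("group")["voltage"].agg(["mean", "count"])
    ss_group = k * float((grp["count"] * (grp["mean"] - grand) ** 2).sum())
    merged = subj.merge(grp["mean"].rename("gmean"), left_on="group", right_index=True)
    ss_subj = k * float(((merged["voltage"] - merged["gmean"]) ** 2).sum())
    df1, df2 = 1, n1 + n2 - 2
    if ss_group == 0.0:
        f_stat, p = 0.0, 1.0
    elif ss_subj == 0.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_group / df1) / (ss_subj / df2)
        p = float(sps.f.sf(f_stat, df1, df2))
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=(df1, df2),
        p_value=p,
        factors=("genotype", "current_level"),
        n_per_group=(n1, n2),
        levels=list(levels),
        dropped_subjects=dropped,
    )
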