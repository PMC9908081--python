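"""Gated group-comparison procedure.

Every outcome is first gated: Shapiro-Wilk normality per group and
Brown-Forsythe (median-centered Levene) equality of variances, both at
``alpha``.  If all groups pass both gates the parametric branch runs
(one-way ANOVA omnibus + Tukey HSD post hoc); otherwise the
non-parametric branch runs (Kruskal-Wallis omnibus + Dunn's post hoc
with multiple-comparison adjustment).  Two-way designs always use
parametric two-way ANOVA (type-II table via OLS) with Tukey HSD over the
factor-combination cells.

Dunn's test is implemented here directly (rank-sum z statistics with tie
correction; Bonferroni adjustment by default, per Dunn 1964; ``holm``
and ``none`` available).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateData

__all__ = [
    "GroupData",
    "GroupReport",
    "select_branch",
    "compare",
    "dunn_test",
]


@dataclass
class GroupData:
    """Samples of one outcome across ≥ 2 groups.

    For ``two_way`` designs each group label must be a ``(levelA,
    levelB)`` tuple (or ``"A:B"`` string) identifying the factor cell.
    """

    outcome: str
    groups: list[tuple[str, np.ndarray]]
    design: str = "one_way"  # one_way | two_way
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = [
            (str(label), np.asarray(vals, dtype=float).ravel())
            for label, vals in self.groups
        ]
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for label, vals in self.groups:
            if vals.size < 2:
                raise ValueError(f"group {label!r} needs at least 2 values")
        if self.design not in ("one_way", "two_way"):
            raise ValueError("design must be 'one_way' or 'two_way'")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.groups]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"group": label, "value": v}
                for label, vals in self.groups
                for v in vals
            ]
        )


@dataclass
class GroupReport:
    outcome: str
    branch_taken: str  # parametric | nonparametric
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    posthoc_test: str
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_raw, p_adj
    normality_p: dict = field(default_factory=dict)
    variance_equality_p: float | None = None
    flags: list[str] = field(default_factory=list)
    group_summary: pd.DataFrame | None = None
    anova_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "branch_taken": self.branch_taken,
            "omnibus_test": self.omnibus_test,
            "omnibus_statistic": self.omnibus_statistic,
            "omnibus_p": self.omnibus_p,
            "posthoc_test": self.posthoc_test,
            "pairwise": self.pairwise.to_dict(orient="records"),
            "normality_p": self.normality_p,
            "variance_equality_p": self.variance_equality_p,
            "flags": list(self.flags),
        }


def _group_summary(data: GroupData) -> pd.DataFrame:
    rows = []
    for label, vals in data.groups:
        rows.append(
            {
                "group": label,
                "n": vals.size,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                "median": float(np.median(vals)),
            }
        )
    return pd.DataFrame(rows)


def select_branch(
    data: GroupData, alpha: float = 0.05
) -> tuple[str, dict, float | None, list[str]]:
    """Choose the statistical branch for an outcome.

    Returns ``(branch, normality_p_per_group, variance_p, flags)``;
    ``branch`` is ``"parametric"`` iff every group passes Shapiro-Wilk
    at ``alpha`` and the Brown-Forsythe test passes at ``alpha``.
    Groups too small for the normality test (< 3 values) force the
    non-parametric branch with a flag.
    """
    flags: list[str] = []
    samples = [vals for _, vals in data.groups]
    if all(np.ptp(v) == 0 for v in samples) and len({v[0] for v in samples}) == 1:
        raise DegenerateData("all groups constant and identical")

    normality_p: dict = {}
    untestable = False
    for label, vals in data.groups:
        if vals.size < 3:
            normality_p[label] = None
            untestable = True
            flags.append(f"normality_untestable:{label}")
            continue
        if np.ptp(vals) == 0:
            normality_p[label] = 0.0
            flags.append(f"constant_group:{label}")
            continue
        normality_p[label] = float(stats.shapiro(vals).pvalue)

    try:
        variance_p = float(stats.levene(*samples, center="median").pvalue)
    except Exception:
        variance_p = None
        flags.append("variance_test_failed")

    if untestable:
        return "nonparametric", normality_p, variance_p, flags
    normal = all(p is not None and p > alpha for p in normality_p.values())
    equal_var = variance_p is not None and variance_p > alpha
    branch = "parametric" if (normal and equal_var) else "nonparametric"
    return branch, normality_p, variance_p, flags


def dunn_test(
    groups: Sequence[tuple[str, np.ndarray]],
    p_adjust: str = "bonferroni",
) -> pd.DataFrame:
    """All-pairs Dunn post hoc test after Kruskal-Wallis.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the
    tie correction T = Σ(t³−t)/(12(N−1)); two-sided normal p-values,
    adjusted by ``p_adjust`` ∈ {bonferroni, holm, none}.
    """
    labels = [label for label, _ in groups]
    samples = [np.asarray(v, dtype=float) for _, v in groups]
    pooled = np.concatenate(samples)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for label, v in zip(labels, samples):
        mean_ranks[label] = ranks[start : start + v.size].mean()
        start += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))
    var_unit = N * (N + 1) / 12.0 - tie_term

    rows = []
    for (la, va), (lb, vb) in itertools.combinations(zip(labels, samples), 2):
        se = np.sqrt(var_unit * (1.0 / va.size + 1.0 / vb.size))
        z = (mean_ranks[la] - mean_ranks[lb]) / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"group_a": la, "group_b": lb, "statistic": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = _adjust_p(df["p_raw"].to_numpy(), p_adjust)
    return df


def _adjust_p(p: np.ndarray, method: str) -> np.ndarray:
    m = p.size
    if method == "none" or m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, p[idx] * (m - rank))
            adj[idx] = min(running, 1.0)
        return adj
    raise ValueError(f"unknown p_adjust {method!r}")


def _tukey_pairs(groups: Sequence[tuple[str, np.ndarray]]) -> pd.DataFrame:
    labels = [label for label, _ in groups]
    samples = [v for _, v in groups]
    res = stats.tukey_hsd(*samples)
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "statistic": float(res.statistic[i, j]),
                "p_raw": float(res.pvalue[i, j]),
                "p_adj": float(res.pvalue[i, j]),  # Tukey p is family-adjusted
            }
        )
    return pd.DataFrame(rows)


def _two_way_anova(data: GroupData) -> pd.DataFrame:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rows = []
    for label, vals in data.groups:
        if ":" not in label:
            raise ValueError(
                "two_way design needs 'levelA:levelB' group labels"
            )
        a, b = label.split(":", 1)
        rows.extend({"A": a, "B": b, "value": v} for v in vals)
    df = pd.DataFrame(rows)
    model = smf.ols("value ~ C(A) * C(B)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def compare(data: GroupData, alpha: float = 0.05, p_adjust: str = "bonferroni") -> GroupReport:
    """Run the full gated comparison for one outcome.

    One-way designs take the branch chosen by :func:`select_branch`;
    two-way designs always use parametric two-way ANOVA with Tukey HSD
    over the factor cells.
    """
    branch, normality_p, variance_p, flags = select_branch(data, alpha)
    summary = _group_summary(data)
    samples = [v for _, v in data.groups]

    if data.design == "two_way":
        table = _two_way_anova(data)
        interaction = [ix for ix in table.index if ":" in str(ix)]
        key = interaction[0] if interaction else table.index[0]
        return GroupReport(
            outcome=data.outcome,
            branch_taken="parametric",
            omnibus_test="two-way ANOVA",
            omnibus_statistic=float(table.loc[key, "F"]),
            omnibus_p=float(table.loc[key, "PR(>F)"]),
            posthoc_test="Tukey HSD",
            pairwise=_tukey_pairs(data.groups),
            normality_p=normality_p,
            variance_equality_p=variance_p,
            flags=flags,
            group_summary=summary,
            anova_table=table,
        )

    if branch == "parametric":
        stat, p = stats.f_oneway(*samples)
        pairwise = _tukey_pairs(data.groups)
        omnibus, posthoc = "one-way ANOVA", "Tukey HSD"
    else:
        stat, p = stats.kruskal(*samples)
        pairwise = dunn_test(data.groups, p_adjust=p_adjust)
        omnibus, posthoc = "Kruskal-Wallis", f"Dunn ({p_adjust})"

    return GroupReport(
        outcome=data.outcome,
        branch_taken=branch,
        omnibus_test=omnibus,
        omnibus_statistic=float(stat),
        omnibus_p=float(p),
        posthoc_test=posthoc,
        pairwise=pairwise,
        normality_p=normality_p,
        variance_equality_p=variance_p,
        flags=flags,
        group_summary=summary,
    )
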