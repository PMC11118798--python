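"""Group-level statistics on fitted connection weights.

Null-referenced one-sample t-tests with Bonferroni correction across the
inter-region connections, weight-vs-covariate regression, and
group x covariate ANCOVA.

Tail conventions
----------------
``t_critical`` returns the upper-tail Student-t quantile (with the study's
one-sample design, ``t_critical(0.05 / 32, 14)`` reproduces the reported
threshold of 3.563).  Significance testing defaults to ``tails="two_sided"``
(two-sided p compared to the corrected alpha), which keeps the familywise
false-positive rate at its nominal level; ``tails="upper"`` applies
``|t| >= t_critical(alpha, df)`` instead, matching the reported threshold
but doubling the effective per-connection level.  Both rules keep the
p-value and the threshold rule mutually consistent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import NullReference
from .network import NetworkModel, connection_count

__all__ = [
    "StatResult",
    "GroupStatsTable",
    "RegressionResult",
    "AncovaResult",
    "bonferroni",
    "t_critical",
    "connection_ttest",
    "regress_db",
    "ancova",
    "summarize_table",
]


@dataclass
class StatResult:
    connection: tuple[str, str]
    group_mean: float
    group_sem: float
    t_stat: float
    p_value: float
    significant: bool
    n: int
    group: str = ""
    condition: str = ""


@dataclass
class GroupStatsTable:
    rows: list[StatResult]
    alpha_family: float
    m_tests: int
    alpha_corrected: float
    t_threshold: float
    tails: str = "two_sided"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": r.group,
                    "condition": r.condition,
                    "connection": f"{r.connection[0]}->{r.connection[1]}",
                    "mean_db": r.group_mean,
                    "sem_db": r.group_sem,
                    "t": r.t_stat,
                    "p": r.p_value,
                    "significant": r.significant,
                    "n": r.n,
                }
                for r in self.rows
            ]
        )

    def to_markdown(self) -> str:
        frame = self.to_frame()
        lines = [
            f"Connectivity statistics (alpha_family={self.alpha_family}, "
            f"m={self.m_tests}, corrected alpha={self.alpha_corrected:.3g}, "
            f"|t| threshold={self.t_threshold:.3f}, tails={self.tails})",
            "",
        ]
        header = "| group | condition | connection | DB (mean ± SEM) | T | significant |"
        lines += [header, "|" + "---|" * 6]
        for _, r in frame.iterrows():
            star = "**" if r["significant"] else ""
            lines.append(
                f"| {r['group']} | {r['condition']} | {r['connection']} | "
                f"{star}{r['mean_db']:.3f} ± {r['sem_db']:.3f}{star} | "
                f"{star}{r['t']:.2f}{star} | {bool(r['significant'])} |"
            )
        return "\n".join(lines)


@dataclass
class RegressionResult:
    connection: tuple[str, str]
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


@dataclass
class AncovaResult:
    connection: tuple[str, str]
    effect: str  # "group" | "covariate" | "interaction"
    p_value: float
    f_stat: float
    group_means: dict[str, float] = field(default_factory=dict)


# -- thresholds ------------------------------------------------------------

def bonferroni(alpha_family: float, m: int) -> float:
    """Per-test alpha ``alpha_family / m``."""
    if not 0 < alpha_family <= 1:
        raise ValueError("alpha_family must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha_family / m


def t_critical(alpha: float, df: int) -> float:
    """Upper-tail Student-t quantile at probability ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(sps.t.isf(alpha, df))


def _threshold(alpha: float, df: int, tails: str) -> float:
    if tails == "two_sided":
        return t_critical(alpha / 2.0, df)
    if tails == "upper":
        return t_critical(alpha, df)
    raise ValueError(f"tails must be 'two_sided' or 'upper', got {tails!r}")


# -- tests -----------------------------------------------------------------

def connection_ttest(
    db_values: Sequence[float],
    null_mean: float = 0.0,
    *,
    connection: tuple[str, str] = ("", ""),
    alpha: float = 0.05 / 32,
    tails: str = "two_sided",
) -> StatResult:
    """One-sample t-test of per-participant weights against a null mean.

    ``t = (mean - null_mean) / (sd / sqrt(n))`` with ``df = n - 1``.  The
    p-value follows the chosen tail convention (see module docstring) so
    that ``significant == (p < alpha) == (|t| >= threshold)``.
    """
    values = np.asarray(db_values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 participants")
    sd = values.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(values).max())):
        raise ValueError("degenerate zero-variance sample")
    df = n - 1
    t = float((values.mean() - null_mean) / (sd / np.sqrt(n)))
    if tails == "two_sided":
        p = float(2.0 * sps.t.sf(abs(t), df))
    elif tails == "upper":
        p = float(sps.t.sf(abs(t), df))
    else:
        raise ValueError(f"tails must be 'two_sided' or 'upper', got {tails!r}")
    return StatResult(
        connection=connection,
        group_mean=float(values.mean()),
        group_sem=float(sd / np.sqrt(n)),
        t_stat=t,
        p_value=p,
        significant=bool(p < alpha),
        n=n,
    )


def regress_db(
    covariate: Sequence[float], db_values: Sequence[float], *, connection=("", "")
) -> RegressionResult:
    """OLS of weights on a covariate: slope, Pearson r, two-sided slope p."""
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(db_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matching covariate/db arrays with n >= 3")
    if x.std() == 0:
        raise ValueError("constant covariate")
    res = sps.linregress(x, y)
    return RegressionResult(
        connection=tuple(connection),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def ancova(
    group_labels: Sequence[str],
    covariate: Sequence[float],
    db_values: Sequence[float],
    *,
    connection: tuple[str, str] = ("", ""),
) -> list[AncovaResult]:
    """Linear model ``db ~ group + covariate + group:covariate``.

    Partial (type-III style) F-tests with sum-coded groups, so the
    interaction p-value does not depend on which group is the reference.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    labels = np.asarray(group_labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    for g in groups:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 members")
    frame = pd.DataFrame(
        {
            "db": np.asarray(db_values, dtype=float),
            "grp": labels,
            "cov": np.asarray(covariate, dtype=float),
        }
    )
    fit = smf.ols("db ~ C(grp, Sum) * cov", data=frame).fit()
    table = sm.stats.anova_lm(fit, typ=3)
    group_means = {
        str(g): float(frame.loc[frame["grp"] == g, "db"].mean()) for g in groups
    }
    effect_rows = {
        "group": "C(grp, Sum)",
        "covariate": "cov",
        "interaction": "C(grp, Sum):cov",
    }
    out = []
    for effect, row in effect_rows.items():
        out.append(
            AncovaResult(
                connection=tuple(connection),
                effect=effect,
                p_value=float(table.loc[row, "PR(>F)"]),
                f_stat=float(table.loc[row, "F"]),
                group_means=group_means,
            )
        )
    return out


def summarize_table(
    db_by_group_condition: Mapping[tuple[str, str], Sequence[Mapping[tuple[str, str], float]]],
    net: NetworkModel,
    null_ref: NullReference | None = None,
    *,
    alpha_family: float = 0.05,
    tails: str = "two_sided",
    connections: Sequence[tuple[str, str]] | None = None,
) -> GroupStatsTable:
    """Per-connection group statistics across groups/conditions.

    ``db_by_group_condition`` maps ``(group, condition)`` to a list of
    per-participant db mappings.  Bonferroni correction runs over the
    network's inter-region connections (latent links excluded).  Null
    reference means default to 0 when no reference is supplied.
    """
    m_tests = connection_count(net, include_latent=False)
    alpha_corr = bonferroni(alpha_family, m_tests)
    keys = list(connections) if connections is not None else [
        c.key for c in net.connections
    ]
    rows: list[StatResult] = []
    df_ref = None
    for (group, condition), fits in db_by_group_condition.items():
        for key in keys:
            values = [f[key] for f in fits]
            null_mean = null_ref.mean.get(key, 0.0) if null_ref is not None else 0.0
            res = connection_ttest(
                values, null_mean, connection=key, alpha=alpha_corr, tails=tails
            )
            res.group = group
            res.condition = condition
            rows.append(res)
            df_ref = res.n - 1
    threshold = _threshold(alpha_corr, df_ref if df_ref else 14, tails)
    return GroupStatsTable(
        rows=rows,
        alpha_family=alpha_family,
        m_tests=m_tests,
        alpha_corrected=alpha_corr,
        t_threshold=threshold,
        tails=tails,
    )
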