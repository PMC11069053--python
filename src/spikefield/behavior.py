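"""Open-field metrics and the group-comparison reporting stage.

Open-field sessions yield total distance traveled (a hyperlocomotion index)
and the percentage of time spent in the center region — a concentric
rectangle whose sides are half the arena's, hence exactly 25% of its area.

Group comparisons follow the conventional two-stage design: two-sample
t-tests for single-factor (vehicle vs MK-801) metrics, and 2x2
(group x treatment) ANOVA with Šídák-adjusted post-hoc contrasts for
drug-treatment experiments.  These are standard routines (scipy /
statsmodels), reported with mean ± SD per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .session import Session, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class OftMetrics:
    total_distance_cm: float
    pct_time_center: float
    duration_s: float


def center_bounds(traj: Trajectory) -> tuple[float, float, float, float]:
    """(x_lo, x_hi, y_lo, y_hi) of the concentric 25%-area center rectangle."""
    L, W = traj.arena_length_cm, traj.arena_width_cm
    return (L * 0.25, L * 0.75, W * 0.25, W * 0.75)


def oft_metrics(traj: Trajectory, duration_s: float = 1800.0) -> OftMetrics:
    """Total path length and % time in center over the analysis window."""
    n_want = int(round(duration_s * traj.fs))
    if traj.x.size < n_want:
        logger.warning(
            "trajectory covers %.1f s < requested %.1f s; using available span",
            traj.duration_s, duration_s,
        )
        n_want = traj.x.size
    x, y = traj.x[:n_want], traj.y[:n_want]
    dist = float(np.hypot(np.diff(x), np.diff(y)).sum())
    x_lo, x_hi, y_lo, y_hi = center_bounds(traj)
    inside = (x >= x_lo) & (x <= x_hi) & (y >= y_lo) & (y <= y_hi)
    return OftMetrics(
        total_distance_cm=dist,
        pct_time_center=float(inside.mean() * 100.0),
        duration_s=n_want / traj.fs,
    )


@dataclass
class GroupTable:
    """Per-session metric rows plus the comparison table."""

    rows: pd.DataFrame  # session_id, group, treatment, metric, value
    cell_summary: pd.DataFrame  # mean ± SD per (group, treatment, metric)
    comparisons: pd.DataFrame  # metric, contrast, test, statistic, df, p, p_adj


def _sidak_adjust(p: np.ndarray) -> np.ndarray:
    """Šídák family-wise adjustment: p_adj = 1 - (1 - p)^m."""
    m = p.size
    return 1.0 - (1.0 - p) ** m


def group_report(sessions: list[Session],
                 metrics: dict[str, "callable"]) -> GroupTable:
    """Compare metric extractors across groups (and treatments if present).

    ``metrics`` maps a metric name to a callable ``Session -> float``.
    With one treatment level the design is a two-sample Student t-test
    (vehicle vs mk801); with both saline and ARI cells it is a two-way
    ANOVA with Šídák-adjusted vehicle-vs-mk801 contrasts within each
    treatment.
    """
    records = []
    for s in sessions:
        for name, fn in metrics.items():
            try:
                val = float(fn(s))
            except Exception as e:  # a missing modality skips the row
                logger.warning("session %s metric %s failed: %s",
                               s.session_id, name, e)
                continue
            records.append(
                {"session_id": s.session_id, "group": s.group,
                 "treatment": s.treatment, "metric": name, "value": val}
            )
    rows = pd.DataFrame(records)
    if rows.empty:
        raise ValueError("no metric values could be computed")

    cell = (
        rows.groupby(["metric", "group", "treatment"])["value"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )

    comparisons = []
    for name, sub in rows.groupby("metric"):
        treatments = sorted(sub["treatment"].unique())
        groups = sorted(sub["group"].unique())
        if len(groups) < 2:
            logger.warning("metric %s: only one group; contrast skipped", name)
            continue
        if len(treatments) == 1:
            a = sub.loc[sub.group == "vehicle", "value"].to_numpy()
            b = sub.loc[sub.group == "mk801", "value"].to_numpy()
            if a.size < 2 or b.size < 2:
                logger.warning("metric %s: cell with <2 sessions; skipped", name)
                continue
            t, p = stats.ttest_ind(a, b, equal_var=True)
            comparisons.append(
                {"metric": name, "contrast": "vehicle vs mk801",
                 "test": "t-test", "statistic": float(t),
                 "df": float(a.size + b.size - 2), "p": float(p),
                 "p_adj": float(p)}
            )
        else:
            # 2x2 group x treatment ANOVA + Šídák post-hoc per treatment
            model = smf.ols("value ~ C(group) * C(treatment)", data=sub).fit()
            anova = sm.stats.anova_lm(model, typ=2)
            for effect in ("C(group)", "C(treatment)", "C(group):C(treatment)"):
                if effect in anova.index:
                    comparisons.append(
                        {"metric": name, "contrast": effect, "test": "anova-F",
                         "statistic": float(anova.loc[effect, "F"]),
                         "df": float(anova.loc[effect, "df"]),
                         "p": float(anova.loc[effect, "PR(>F)"]),
                         "p_adj": float("nan")}
                    )
            posthoc = []
            for tr in treatments:
                a = sub.loc[(sub.group == "vehicle") & (sub.treatment == tr),
                            "value"].to_numpy()
                b = sub.loc[(sub.group == "mk801") & (sub.treatment == tr),
                            "value"].to_numpy()
                if a.size < 2 or b.size < 2:
                    logger.warning(
                        "metric %s treatment %s: empty/small cell; skipped",
                        name, tr,
                    )
                    continue
                t, p = stats.ttest_ind(a, b, equal_var=True)
                posthoc.append(
                    {"metric": name, "contrast": f"vehicle vs mk801 | {tr}",
                     "test": "t-test (Sidak)", "statistic": float(t),
                     "df": float(a.size + b.size - 2), "p": float(p)}
                )
            if posthoc:
                padj = _sidak_adjust(np.array([r["p"] for r in posthoc]))
                for r, pa in zip(posthoc, padj):
                    r["p_adj"] = float(pa)
                comparisons.extend(posthoc)
    return GroupTable(rows=rows, cell_summary=cell,
                      comparisons=pd.DataFrame(comparisons))
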