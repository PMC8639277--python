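"""Group statistics and cohort reporting.

One-way ANOVA with Tukey's HSD for between-group comparisons, two-way
ANOVA (pressure bin x group) for baroreflex dose-response curves, and the
unpaired t-test; variability is reported as SEM. The two-way model treats
subject-level bin means as independent observations per (bin, group) cell,
a documented simplification of the repeated-measures structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .baroreflex import BaroreflexCurve
from .core import DataError, DegenerateSeriesError
from .model import RSNAResults

__all__ = [
    "GroupComparison",
    "one_way_anova_tukey",
    "two_way_curve_anova",
    "unpaired_t",
    "summarize_cohort",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus + pairwise comparison of one variable across groups."""

    variable: str
    groups: dict  # label -> {"mean", "sem", "n"}
    test: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None  # columns a, b, diff, p_raw, p_adj, significant
    alpha: float = ALPHA
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.pvalue < self.alpha)


def _describe(values: Sequence[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return {"mean": float(arr.mean()), "sem": sem, "n": int(arr.size)}


def one_way_anova_tukey(
    groups: Mapping[str, Sequence[float]],
    variable: str = "",
    alpha: float = ALPHA,
) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``pairwise`` also reports the unadjusted pooled-variance t-test p-value
    per pair for reference; Tukey-adjusted p is never smaller.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise DataError("need at least two groups")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in data.items():
        if v.size < 2:
            raise DataError(f"group {k!r} needs n >= 2")
    if all(np.ptp(v) == 0 for v in data.values()):
        raise DegenerateSeriesError("zero within-group variance in every group")
    f_stat, pval = sps.f_oneway(*data.values())
    if not np.isfinite(f_stat):  # identical groups: no between-group variance
        f_stat, pval = 0.0, 1.0

    values = np.concatenate(list(data.values()))
    codes = np.concatenate([[k] * data[k].size for k in labels])
    tuk = pairwise_tukeyhsd(values, codes, alpha=alpha)
    tuk_df = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])

    # pooled-MSE df and variance for raw pairwise t-tests
    n_total = values.size
    k = len(labels)
    df_w = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in data.values()) / df_w
    rows = []
    for _, r in tuk_df.iterrows():
        a, b = str(r["group1"]), str(r["group2"])
        na, nb = data[a].size, data[b].size
        diff = data[b].mean() - data[a].mean()
        if mse > 0:
            t = diff / np.sqrt(mse * (1.0 / na + 1.0 / nb))
            p_raw = float(2 * sps.t.sf(abs(t), df_w))
        else:
            p_raw = 1.0 if diff == 0 else 0.0
        rows.append(
            {
                "a": a,
                "b": b,
                "diff": float(diff),
                "p_raw": p_raw,
                "p_adj": float(r["p-adj"]),
                "significant": bool(r["reject"]),
            }
        )
    return GroupComparison(
        variable=variable,
        groups={k: _describe(v) for k, v in data.items()},
        test="one-way ANOVA + Tukey HSD",
        statistic=float(f_stat),
        pvalue=float(pval),
        pairwise=pd.DataFrame(rows),
        alpha=alpha,
    )


def two_way_curve_anova(
    group_curves: Mapping[str, Sequence[BaroreflexCurve]],
    alpha: float = ALPHA,
) -> GroupComparison:
    """Two-way ANOVA of RSNA% on pressure bin and group over shared bins.

    Observations are subject-level bin means; bins used are those present
    in every group. Main-effect and interaction p-values are computed from
    a type-II ANOVA of ``rsna ~ C(bin) + C(group) + C(bin):C(group)``.
    """
    if len(group_curves) < 2:
        raise DataError("need at least two groups of curves")
    per_group_bins = []
    rows = []
    for label, curves in group_curves.items():
        bins_here = set()
        for si, c in enumerate(curves):
            for left, mean in zip(c.bin_left, c.mean_pct):
                rows.append(
                    {"group": label, "subject": f"{label}-{si}", "bin": float(left), "rsna": float(mean)}
                )
                bins_here.add(round(float(left), 6))
        per_group_bins.append(bins_here)
    shared = set.intersection(*per_group_bins)
    if len(shared) < 2:
        raise DataError("groups share fewer than two pressure bins")
    df = pd.DataFrame(rows)
    df = df[df["bin"].round(6).isin(shared)]
    fit = ols("rsna ~ C(bin) + C(group) + C(bin):C(group)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    p_group = float(table.loc["C(group)", "PR(>F)"])
    f_group = float(table.loc["C(group)", "F"])
    p_bin = float(table.loc["C(bin)", "PR(>F)"])
    p_inter = float(table.loc["C(bin):C(group)", "PR(>F)"])
    groups_desc = {
        label: _describe(df[df["group"] == label]["rsna"].to_numpy())
        for label in group_curves
    }
    return GroupComparison(
        variable="baroreflex curve",
        groups=groups_desc,
        test="two-way ANOVA (pressure bin x group, subject bin means)",
        statistic=f_group,
        pvalue=p_group,
        pairwise=None,
        alpha=alpha,
        extras={
            "p_pressure": p_bin,
            "p_group": p_group,
            "p_interaction": p_inter,
            "shared_bins": sorted(shared),
            "note": "subject bin means treated as independent observations",
        },
    )


def unpaired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Unpaired (pooled-variance) Student's t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("both samples need n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

_RESPONSE_VARS = {
    "diltiazem": [("delta_mbp", "diltiazem dMBP (mmHg)"), ("delta_hr", "diltiazem dHR (bpm)")],
    "phenylephrine": [
        ("delta_mbp", "phenylephrine dMBP (mmHg)"),
        ("delta_hr", "phenylephrine dHR (bpm)"),
    ],
    "cpbg": [
        ("rsna_inhibition_pct", "CPBG RSNA inhibition (%)"),
        ("delta_mbp", "CPBG dMBP (mmHg)"),
        ("delta_hr", "CPBG dHR (bpm)"),
    ],
}


def _harvest(results: Sequence[RSNAResults]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "subject": r.subject_id,
            "group": r.group,
            "control MBP (mmHg)": r.control_mbp,
            "control HR (bpm)": r.control_hr,
        }
        if r.burst is not None:
            row["burst max/mean"] = r.burst.max_over_mean
            row["burst min/mean"] = r.burst.min_over_mean
        if r.slope is not None:
            row["baroreflex slope (%/mmHg)"] = r.slope.slope
        if r.plateau_mmhg is not None:
            row["plateau pressure (mmHg)"] = r.plateau_mmhg
        for resp in r.responses:
            for attr, name in _RESPONSE_VARS.get(resp.agent, []):
                val = getattr(resp, attr)
                if np.isfinite(val):
                    row[name] = val
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(
    results: Sequence[RSNAResults],
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, str]:
    """Cohort report: per-variable group means +- SEM with omnibus tests.

    Returns a machine-readable table (columns variable, group, mean, sem,
    n, test, stat, p, pairwise, flag) and a human-readable text block that
    also echoes the analysis settings of the first result.
    """
    if len(results) == 0:
        raise DataError("empty cohort")
    wide = _harvest(results)
    variables = [c for c in wide.columns if c not in ("subject", "group")]
    out_rows = []
    text = ["Cohort summary", "=" * 60]
    for var in variables:
        sub = wide[["group", var]].dropna()
        groups = {g: d[var].to_numpy() for g, d in sub.groupby("group", sort=False)}
        testable = {g: v for g, v in groups.items() if v.size >= 2}
        comp = None
        flag = ""
        if len(testable) >= 2:
            try:
                comp = one_way_anova_tukey(testable, variable=var, alpha=alpha)
            except DegenerateSeriesError:
                flag = "degenerate"
        else:
            flag = "insufficient groups for testing"
        text.append(f"\n{var}:")
        for g, vals in groups.items():
            d = _describe(vals)
            pair_text = ""
            if comp is not None and comp.pairwise is not None:
                sig = comp.pairwise[
                    (comp.pairwise["significant"])
                    & ((comp.pairwise["a"] == g) | (comp.pairwise["b"] == g))
                ]
                pairs = {
                    (r["b"] if r["a"] == g else r["a"]): r["p_adj"] for _, r in sig.iterrows()
                }
                if pairs:
                    pair_text = "; ".join(f"vs {o}: p_adj={p:.3g}" for o, p in pairs.items())
            out_rows.append(
                {
                    "variable": var,
                    "group": g,
                    "mean": d["mean"],
                    "sem": d["sem"],
                    "n": d["n"],
                    "test": comp.test if comp else "",
                    "stat": comp.statistic if comp else np.nan,
                    "p": comp.pvalue if comp else np.nan,
                    "pairwise": pair_text,
                    "flag": flag if vals.size >= 2 else (flag + " n<2").strip(),
                }
            )
            text.append(f"  {g:<6} {d['mean']:10.2f} +- {d['sem']:.2f} (n={d['n']}) {pair_text}")
        if comp is not None:
            text.append(f"  {comp.test}: F={comp.statistic:.3g}, p={comp.pvalue:.3g}")
        elif flag:
            text.append(f"  [{flag}]")
    settings = results[0].settings
    if settings:
        text.append("\nAnalysis settings:")
        for k, v in settings.items():
            text.append(f"  {k}: {v}")
    return pd.DataFrame(out_rows), "\n".join(text)
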