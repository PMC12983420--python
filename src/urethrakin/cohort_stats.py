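"""Cohort summaries and group statistics.

The cohort table is a tidy long-format DataFrame with columns
``subject, group, maneuver, roi, metric, value`` (one row per
subject x maneuver x roi x metric).  On top of it:

* :func:`summarize` — n, mean, sample SD, SEM, range and CV% per cell;
* :func:`rm_anova_2x3` — a two-way mixed-design (split-plot) ANOVA per ROI
  and metric, with group (control vs. SUI) as the between-subject factor and
  maneuver as the within-subject factor;
* :func:`pairwise_compare` — pooled-variance independent t-tests (group
  contrasts at each maneuver) and paired t-tests (maneuver contrasts within
  each group) with Bonferroni correction over the declared family.

Conventions: SD uses the n-1 denominator; CV is ``100 * SD / |mean|`` (the
absolute value makes CVs of negative-mean direction metrics positive —
circular statistics are deliberately not used, matching how such tables are
conventionally reported); no sphericity correction is applied (with only
three within-subject levels the mixed ANOVA here is reported uncorrected,
and this is recorded in the result metadata).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, MissingDataError

COHORT_COLUMNS = ["subject", "group", "maneuver", "roi", "metric", "value"]


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    sem: float
    range: float
    cv_percent: float


def summarize(values) -> SummaryStats:
    """Basic descriptive statistics of a sample (n >= 2 finite values)."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise ArgumentError("summarize needs >= 2 finite values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cv = 100.0 * sd / abs(mean) if mean != 0 else (0.0 if sd == 0 else np.inf)
    return SummaryStats(int(arr.size), mean, sd, sd / np.sqrt(arr.size),
                        float(arr.max() - arr.min()), cv)


def coefficient_of_variation(mean: float, sd: float) -> int:
    """CV as reported in summary tables: ``round(100 * sd / |mean|)``."""
    if mean == 0:
        raise ArgumentError("CV undefined for zero mean")
    if sd == 0:
        return 0
    return int(round(100.0 * sd / abs(mean)))


# ---------------------------------------------------------------------------
# mixed-design ANOVA
# ---------------------------------------------------------------------------

def _complete_wide(table: pd.DataFrame, roi: str, metric: str) -> pd.DataFrame:
    sub = table[(table["roi"] == roi) & (table["metric"] == metric)]
    if sub.empty:
        raise MissingDataError(f"no rows for roi='{roi}', metric='{metric}'")
    dup = sub.duplicated(["subject", "maneuver"])
    if dup.any():
        raise MissingDataError("duplicate subject x maneuver cells")
    wide = sub.pivot(index="subject", columns="maneuver", values="value")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise MissingDataError(
            f"incomplete within-subject cells for subject(s) {missing}; "
            "every subject needs all maneuvers (no imputation is performed)"
        )
    groups = sub.groupby("subject")["group"].agg(lambda s: s.iloc[0])
    wide.insert(0, "group", groups.reindex(wide.index))
    return wide


def rm_anova_2x3(table: pd.DataFrame, roi: str, metric: str) -> pd.DataFrame:
    """Two-way mixed ANOVA: between factor = group, within factor = maneuver.

    Classic split-plot sums-of-squares decomposition; p-values from the F
    distribution, no sphericity correction.  Returns one row per effect
    (``group``, ``maneuver``, ``interaction``) with SS, df, MS, F, p.
    Raises :class:`MissingDataError` for incomplete cells.
    """
    wide = _complete_wide(table, roi, metric)
    groups = wide["group"].to_numpy()
    data = wide.drop(columns="group").to_numpy(dtype=float)
    levels = list(wide.columns[1:])
    group_names = pd.unique(groups)
    if len(group_names) < 2:
        raise MissingDataError("need two groups for the mixed ANOVA")
    N, b = data.shape
    a = len(group_names)
    grand = data.mean()
    subj_means = data.mean(axis=1)
    group_means = np.array([subj_means[groups == g].mean() for g in group_names])
    n_per = np.array([(groups == g).sum() for g in group_names])
    level_means = data.mean(axis=0)
    cell_means = np.array([data[groups == g].mean(axis=0) for g in group_names])

    ss_total = float(((data - grand) ** 2).sum())
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    ss_group = float(b * (n_per * (group_means - grand) ** 2).sum())
    ss_err_between = ss_between_subj - ss_group
    ss_within = float(N * ((level_means - grand) ** 2).sum())
    ss_inter = float((n_per[:, None] * (cell_means - group_means[:, None]
                                        - level_means[None, :] + grand) ** 2).sum())
    ss_err_within = ss_total - ss_between_subj - ss_within - ss_inter

    df_group, df_eb = a - 1, N - a
    df_within, df_inter, df_ew = b - 1, (a - 1) * (b - 1), (N - a) * (b - 1)

    def _effect(name, ss, df, ss_err, df_err):
        ms = ss / df if df > 0 else np.nan
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        tiny = 1e-12 * max(ss_total, 1.0)
        if ss <= tiny:
            F, p = 0.0, 1.0
        elif ms_err <= tiny:
            F, p = np.inf, 0.0
        else:
            F = ms / ms_err
            p = float(stats.f.sf(F, df, df_err))
        return {"effect": name, "ss": ss, "df1": df, "df2": df_err,
                "ms": ms, "F": F, "p": p}

    rows = [
        _effect("group", ss_group, df_group, ss_err_between, df_eb),
        _effect("maneuver", ss_within, df_within, ss_err_within, df_ew),
        _effect("interaction", ss_inter, df_inter, ss_err_within, df_ew),
    ]
    out = pd.DataFrame(rows)
    out.attrs["roi"] = roi
    out.attrs["metric"] = metric
    out.attrs["within_levels"] = levels
    out.attrs["sphericity_correction"] = "none"
    return out


# ---------------------------------------------------------------------------
# pairwise contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contrast:
    """One declared pairwise comparison.

    ``kind='independent'``: control vs. SUI at one maneuver (pooled-variance
    t-test).  ``kind='paired'``: two maneuvers within one group (paired
    t-test matched by subject).
    """

    kind: str
    roi: str
    metric: str
    maneuver: str | None = None            # independent
    group: str | None = None               # paired
    maneuver_pair: tuple[str, str] | None = None  # paired

    @property
    def label(self) -> str:
        if self.kind == "independent":
            return f"{self.roi}/{self.metric}: control vs sui @ {self.maneuver}"
        return (f"{self.roi}/{self.metric}: {self.maneuver_pair[0]} vs "
                f"{self.maneuver_pair[1]} in {self.group}")


def default_contrast_family(roi: str, metric: str = "dmag_mm",
                            maneuvers: Sequence[str] = ("cough", "valsalva", "pmc"),
                            groups: Sequence[str] = ("control", "sui")) -> list[Contrast]:
    """The per-ROI family of five: group contrast at each maneuver, plus
    cough-vs-valsalva within each group."""
    fam = [Contrast("independent", roi, metric, maneuver=m) for m in maneuvers]
    fam += [Contrast("paired", roi, metric, group=g,
                     maneuver_pair=("cough", "valsalva")) for g in groups]
    return fam


def pairwise_compare(table: pd.DataFrame, contrasts: Sequence[Contrast]) -> pd.DataFrame:
    """Run the declared contrasts; Bonferroni multiplicity over the family.

    ``p_bonferroni = min(1, m * p_raw)`` with ``m = len(contrasts)``.
    """
    if len(contrasts) == 0:
        raise ArgumentError("empty contrast list")
    m = len(contrasts)
    rows = []
    for con in contrasts:
        sub = table[(table["roi"] == con.roi) & (table["metric"] == con.metric)]
        if con.kind == "independent":
            x = sub[(sub["maneuver"] == con.maneuver)
                    & (sub["group"] == "control")]["value"].to_numpy(float)
            y = sub[(sub["maneuver"] == con.maneuver)
                    & (sub["group"] == "sui")]["value"].to_numpy(float)
            if len(x) < 2 or len(y) < 2:
                raise ArgumentError(f"contrast '{con.label}': need n >= 2 per arm")
            res = stats.ttest_ind(x, y, equal_var=True)
            df = len(x) + len(y) - 2
        elif con.kind == "paired":
            g = sub[sub["group"] == con.group]
            m1, m2 = con.maneuver_pair
            wide = g.pivot(index="subject", columns="maneuver", values="value")
            if m1 not in wide.columns or m2 not in wide.columns:
                raise MissingDataError(f"contrast '{con.label}': missing maneuver data")
            pair = wide[[m1, m2]].dropna()
            if len(pair) < 2:
                raise ArgumentError(f"contrast '{con.label}': need >= 2 complete pairs")
            res = stats.ttest_rel(pair[m1], pair[m2])
            df = len(pair) - 1
        else:
            raise ArgumentError(f"unknown contrast kind '{con.kind}'")
        p_raw = float(res.pvalue)
        rows.append({"contrast": con.label, "kind": con.kind, "roi": con.roi,
                     "metric": con.metric, "t": float(res.statistic), "df": df,
                     "p_raw": p_raw, "p_bonferroni": min(1.0, m * p_raw)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table-style group summaries
# ---------------------------------------------------------------------------

def summarize_cohort(table: pd.DataFrame,
                     metrics: Sequence[str] = ("dmag_mm", "phi_deg")) -> pd.DataFrame:
    """Group-level summary per (maneuver, roi, group, metric): n, mean, SD,
    SEM, range and integer CV%, mirroring how reference cohort tables are
    reported."""
    rows = []
    for (maneuver, roi, group, metric), sub in table[
            table["metric"].isin(metrics)].groupby(
            ["maneuver", "roi", "group", "metric"], sort=False):
        s = summarize(sub["value"])
        rows.append({
            "maneuver": maneuver, "roi": roi, "group": group, "metric": metric,
            "n": s.n, "mean": s.mean, "sd": s.sd, "sem": s.sem,
            "range": s.range,
            "cv_percent": coefficient_of_variation(s.mean, s.sd)
            if s.mean != 0 else np.nan,
        })
    return pd.DataFrame(rows)
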