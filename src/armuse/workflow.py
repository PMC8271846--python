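"""End-to-end orchestration: synchronize, validate wear, compute outcomes,
and run the method-comparison statistics over a cohort."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .io import SubjectWeekRecording, synchronize_streams
from .outcomes import (
    DailyOutcomes,
    OUTCOMES,
    WeeklyOutcomes,
    aggregate_weekly,
    compute_daily_outcomes,
    daily_frame,
    weekly_frame,
)
from .wear import WearSummary, restrict_waking_hours, validate_days

logger = logging.getLogger("armuse")


@dataclass
class ProcessedRecording:
    """One subject-week after the full preprocessing chain."""

    recording: SubjectWeekRecording      # synchronized, windowed, non-wear cleaned
    daily: list                          # DailyOutcomes per day (all days, flagged)
    weekly: WeeklyOutcomes | None        # None when the week is invalid
    wear: WearSummary


def process_recording(recording: SubjectWeekRecording) -> ProcessedRecording:
    """Run one subject-week through synchronization, the waking-hours window,
    non-wear exclusion, validity rules, and the daily/weekly outcomes."""
    rec = synchronize_streams(recording)
    rec = restrict_waking_hours(rec)
    summary, clean = validate_days(rec)
    valid = dict(zip(summary.days["date"], summary.days["valid_day"]))
    daily = []
    dates = pd.unique(np.asarray(clean.thigh.start_times.date))
    for date in dates:
        daily.append(compute_daily_outcomes(clean, date, valid_day=bool(valid.get(date, False))))
    weekly = aggregate_weekly(daily)
    if weekly is None:
        logger.info(
            "%s week %s: fewer than 2 valid days; week excluded from weekly means",
            recording.subject_id, recording.week,
        )
    return ProcessedRecording(recording=clean, daily=daily, weekly=weekly, wear=summary)


@dataclass
class CohortOutcomes:
    daily: pd.DataFrame
    weekly: pd.DataFrame
    wear: pd.DataFrame
    processed: list = field(default_factory=list)


def process_cohort(recordings: list) -> CohortOutcomes:
    """Process every subject-week; collect tidy per-day/per-week/wear tables."""
    processed, all_daily, all_weekly, wear_rows = [], [], [], []
    for rec in recordings:
        p = process_recording(rec)
        processed.append(p)
        all_daily.extend(p.daily)
        if p.weekly is not None:
            all_weekly.append(p.weekly)
        for _, row in p.wear.days.iterrows():
            wear_rows.append(
                {"subject_id": rec.subject_id, "week": rec.week, **row.to_dict()}
            )
    daily = daily_frame(all_daily) if all_daily else pd.DataFrame()
    if not daily.empty:
        # wear-summary export carries the Fig-2-style daily durations
        wear = daily[
            ["subject_id", "week", "date", "wear_min", "sit_stand_min", "walk_min", "valid_day"]
        ].copy()
    else:
        wear = pd.DataFrame(wear_rows)
    return CohortOutcomes(
        daily=daily, weekly=weekly_frame(all_weekly), wear=wear, processed=processed
    )


@dataclass
class ComparisonReport:
    bland_altman: pd.DataFrame     # one row per outcome x week
    correlations: pd.DataFrame     # cross-sectional walking-vs-difference rows
    change_scores: pd.DataFrame    # week 3 -> 26 change-score correlation rows
    gee: dict                      # outcome -> GEEResult (or None if not estimable)


def compare_methods(weekly: pd.DataFrame, outcomes=OUTCOMES) -> ComparisonReport:
    """Quantify the whole-body-movement effect on the weekly outcome table.

    For every outcome and week: Bland–Altman agreement between the P&M and
    sit/stand methods and the Spearman correlation of the method difference
    with daily walking time; plus week 3 → 26 change-score correlations and
    a Gaussian GEE (time × method, exchangeable working correlation) per
    outcome.
    """
    if weekly.empty:
        raise ValueError("no valid subject-weeks to compare")
    for col in ("paretic_PM", "paretic_SS"):
        if col not in weekly.columns:
            raise ValueError("weekly table must contain both methods' outcome columns")
    weeks = sorted(weekly["week"].unique())

    ba_rows, corr_rows, change_rows = [], [], []
    for outcome in outcomes:
        for wk in weeks:
            sub = weekly[weekly["week"] == wk].dropna(
                subset=[f"{outcome}_PM", f"{outcome}_SS"]
            )
            if len(sub) < 2:
                logger.warning(
                    "week %s: fewer than 2 subjects with %s in both methods; "
                    "Bland-Altman skipped", wk, outcome,
                )
                continue
            mc = stats.bland_altman(
                sub[f"{outcome}_PM"], sub[f"{outcome}_SS"], outcome=outcome, week=wk
            )
            ba_rows.append(vars(mc))
            diff = (sub[f"{outcome}_PM"] - sub[f"{outcome}_SS"]).to_numpy()
            if len(sub) >= 3:
                cr = stats.correlate_walking_difference(sub["walk_min"].to_numpy(), diff)
                corr_rows.append(
                    {"outcome": outcome, "week": wk, "r": cr.r, "n": cr.n,
                     "label": cr.label, "p": cr.p}
                )
        try:
            cs = stats.change_score_correlation(weekly, outcome)
            change_rows.append(
                {"outcome": outcome, "week_from": 3, "week_to": 26,
                 "r": cs.r, "n": cs.n, "label": cs.label, "p": cs.p}
            )
        except ValueError as exc:
            logger.warning("change-score correlation skipped for %s: %s", outcome, exc)

    gee = {}
    for outcome in outcomes:
        long = weekly.melt(
            id_vars=["subject_id", "week"],
            value_vars=[f"{outcome}_PM", f"{outcome}_SS"],
            var_name="method",
            value_name="value",
        )
        long["method"] = long["method"].str.rsplit("_", n=1).str[-1]
        try:
            gee[outcome] = stats.fit_gee(long)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("GEE not estimable for %s: %s", outcome, exc)
            gee[outcome] = None

    return ComparisonReport(
        bland_altman=pd.DataFrame(ba_rows),
        correlations=pd.DataFrame(corr_rows),
        change_scores=pd.DataFrame(change_rows),
        gee=gee,
    )


def render_report(report: ComparisonReport) -> str:
    """Human-readable summary: D_pct per outcome and week, correlation labels,
    and GEE factor tests (post-hoc family size declared in the header)."""
    lines = ["Arm-use method comparison (P&M vs sit/stand)", "=" * 46]
    m = next((g.n_contrasts for g in report.gee.values() if g is not None), None)
    if m is not None:
        lines.append(f"Post-hoc family: {m} contrasts (Bonferroni-adjusted)")
    lines.append("")
    lines.append("Bland-Altman mean differences (D, % of P&M mean):")
    for _, r in report.bland_altman.iterrows():
        lines.append(
            f"  {r['outcome']:>10s} week {int(r['week']):>2d}: "
            f"D={r['D']:.1f}  SDdiff={r['sd_diff']:.1f}  "
            f"LOA=[{r['loa_low']:.1f}, {r['loa_high']:.1f}]  "
            f"D%={r['d_pct']:.1f}%  (n={int(r['n'])})"
        )
    lines.append("")
    lines.append("Spearman: daily walking time vs method difference:")
    for _, r in report.correlations.iterrows():
        lines.append(
            f"  {r['outcome']:>10s} week {int(r['week']):>2d}: "
            f"r={r['r']:.2f} ({r['label']}, n={int(r['n'])})"
        )
    if not report.change_scores.empty:
        lines.append("")
        lines.append("Change scores (week 3 -> 26): walking change vs difference change:")
        for _, r in report.change_scores.iterrows():
            lines.append(
                f"  {r['outcome']:>10s}: r={r['r']:.2f} ({r['label']}, n={int(r['n'])})"
            )
    lines.append("")
    lines.append("GEE (Gaussian, exchangeable) Wald tests:")
    for outcome, g in report.gee.items():
        if g is None:
            lines.append(f"  {outcome:>10s}: not estimable")
            continue
        parts = [
            f"{row['factor']} p={row['p']:.3g}" for _, row in g.wald.iterrows()
        ]
        lines.append(f"  {outcome:>10s}: " + ", ".join(parts))
    return "\n".join(lines) + "\n"
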