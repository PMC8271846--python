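"""Method-comparison statistics: Bland–Altman, Spearman, and GEE.

The effect of whole-body movements on wrist-worn arm-use measurement is
quantified by comparing, per outcome and week, the P&M method against the
sit/stand method across subjects:

* Bland–Altman agreement — mean difference ``D`` (P&M − sit/stand), the SD
  of the differences, and limits of agreement ``D ± 1.96·SDdiff``; ``D`` is
  also expressed as a percentage of the cohort-mean P&M outcome.
* Spearman rank correlations between daily walking time and the method
  difference (cross-sectional per week, and week-3 → week-26 change
  scores), with the conventional strength bands (0.25/0.50/0.70/0.90).
* A marginal Gaussian GEE with factors time (weeks 3/12/26), method, and
  their interaction, an exchangeable working correlation, robust standard
  errors, and Bonferroni-adjusted post-hoc contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

LOA_Z = 1.96

#: interpretation bands for |r|: upper bounds (exclusive except the last)
CORRELATION_BANDS = (
    (0.25, "very weak"),
    (0.50, "weak"),
    (0.70, "moderate"),
    (0.90, "strong"),
    (1.0 + 1e-12, "very strong"),
)


@dataclass
class MethodComparison:
    """Bland–Altman summary for one outcome at one week."""

    outcome: str
    week: int | None
    n: int
    D: float
    sd_diff: float
    loa_low: float
    loa_high: float
    d_pct: float  # D as % of the cohort mean P&M value; NaN if that mean is 0


@dataclass
class CorrelationResult:
    r: float
    n: int
    label: str
    p: float = float("nan")

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r)


@dataclass
class GEEResult:
    params: pd.DataFrame      # coef, robust_se, z, p per design column
    wald: pd.DataFrame        # factor, df, chi2, p (joint Wald tests)
    contrasts: pd.DataFrame   # estimate, se, z, p, p_bonf per post-hoc contrast
    n_contrasts: int
    scale: float
    working_corr: float       # estimated exchangeable correlation
    n_subjects: int
    n_obs: int


def interpret_correlation(r: float) -> str:
    if np.isnan(r):
        return "undefined"
    a = abs(r)
    for bound, label in CORRELATION_BANDS:
        if a < bound:
            return label
    return "very strong"


def bland_altman(pm, ss, outcome: str = "", week: int | None = None) -> MethodComparison:
    """Bland–Altman statistics for paired per-subject (P&M, sit/stand) values.

    D is the mean difference P&M − sit/stand, SDdiff its sample SD (n−1
    denominator), and the limits of agreement D ± 1.96·SDdiff.  ``d_pct``
    divides D by the mean of the P&M values (NaN-flagged when that mean is
    zero).
    """
    pm = np.asarray(pm, dtype=float)
    ss = np.asarray(ss, dtype=float)
    if pm.shape != ss.shape:
        raise ValueError("paired methods need one value per subject in each method")
    n = len(pm)
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs (SD of differences undefined)")
    diff = pm - ss
    d = float(diff.mean())
    sd = float(diff.std(ddof=1))
    pm_mean = float(pm.mean())
    d_pct = 100.0 * d / pm_mean if pm_mean != 0 else float("nan")
    return MethodComparison(
        outcome=outcome,
        week=week,
        n=n,
        D=d,
        sd_diff=sd,
        loa_low=d - LOA_Z * sd,
        loa_high=d + LOA_Z * sd,
        d_pct=d_pct,
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    A constant vector makes the correlation undefined; this is flagged with
    ``r = NaN`` and the label "undefined" rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors required")
    if len(x) < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(r=float("nan"), n=len(x), label="undefined")
    r, p = scipy.stats.spearmanr(x, y)
    return CorrelationResult(r=float(r), n=len(x), label=interpret_correlation(float(r)), p=float(p))


def correlate_walking_difference(walking_min, method_diff) -> CorrelationResult:
    """Spearman correlation between daily walking time and the P&M − sit/stand difference."""
    return spearman(walking_min, method_diff)


def change_score_correlation(
    weekly: pd.DataFrame,
    outcome: str,
    week_from: int = 3,
    week_to: int = 26,
    walk_col: str = "walk_min",
) -> CorrelationResult:
    """Correlate per-subject changes in walking time with changes in the method difference.

    ``weekly`` is the tidy per-week table with columns ``subject_id``,
    ``week``, ``walk_min`` and ``<outcome>_PM`` / ``<outcome>_SS``.  Only
    subjects present at both weeks contribute (complete-pair analysis).
    """
    a = weekly[weekly["week"] == week_from].set_index("subject_id")
    b = weekly[weekly["week"] == week_to].set_index("subject_id")
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(
            f"change-score correlation needs >= 3 subjects present at weeks "
            f"{week_from} and {week_to}, got {len(common)}"
        )
    diff_a = a.loc[common, f"{outcome}_PM"] - a.loc[common, f"{outcome}_SS"]
    diff_b = b.loc[common, f"{outcome}_PM"] - b.loc[common, f"{outcome}_SS"]
    d_walk = (b.loc[common, walk_col] - a.loc[common, walk_col]).to_numpy()
    d_diff = (diff_b - diff_a).to_numpy()
    return spearman(d_walk, d_diff)


# ---------------------------------------------------------------------------
# GEE
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, weeks, method_ref: str = "SS"):
    """Treatment-coded design: intercept, week dummies (ref = first week),
    method dummy (ref = sit/stand), and their interactions."""
    w_ref, w_rest = weeks[0], list(weeks[1:])
    m_other = "PM" if method_ref == "SS" else "SS"
    cols = {"Intercept": np.ones(len(df))}
    for w in w_rest:
        cols[f"week[{w}]"] = (df["week"] == w).astype(float).to_numpy()
    cols[f"method[{m_other}]"] = (df["method"] == m_other).astype(float).to_numpy()
    for w in w_rest:
        cols[f"week[{w}]:method[{m_other}]"] = cols[f"week[{w}]"] * cols[f"method[{m_other}]"]
    X = pd.DataFrame(cols, index=df.index)
    return X, w_ref, w_rest, m_other


def _cell_vector(columns, week, method, w_ref, m_other) -> np.ndarray:
    """Row of the design matrix for the marginal mean of cell (week, method)."""
    v = pd.Series(0.0, index=columns)
    v["Intercept"] = 1.0
    if week != w_ref:
        v[f"week[{week}]"] = 1.0
    if method == m_other:
        v[f"method[{m_other}]"] = 1.0
        if week != w_ref:
            v[f"week[{week}]:method[{m_other}]"] = 1.0
    return v.to_numpy()


def fit_gee(
    long: pd.DataFrame,
    value_col: str = "value",
    method_ref: str = "SS",
) -> GEEResult:
    """Fit the Gaussian GEE for method and time effects on one arm-use outcome.

    ``long`` must contain ``subject_id``, ``week``, ``method`` (PM/SS) and
    the outcome column.  Uses an exchangeable working correlation with
    robust (sandwich) covariance; joint Wald tests are reported for the
    week, method, and interaction factors, and post-hoc pairwise contrasts
    (between-week within each method, between-method within each week) are
    Bonferroni-adjusted over the whole contrast family.
    """
    df = long.dropna(subset=[value_col]).copy()
    subjects = df["subject_id"].unique()
    if len(subjects) < 2:
        raise ValueError("GEE needs at least 2 subjects (clusters) to be estimable")
    weeks = sorted(df["week"].unique())
    if len(weeks) < 2 or df["method"].nunique() < 2:
        raise ValueError("GEE needs at least two weeks and both methods present")

    X, w_ref, w_rest, m_other = _design(df, weeks, method_ref)
    model = sm.GEE(
        df[value_col].to_numpy(),
        X,
        groups=df["subject_id"].to_numpy(),
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    res = model.fit(maxiter=200, ctol=1e-8)

    params = pd.DataFrame(
        {
            "coef": res.params,
            "robust_se": res.bse,
            "z": res.tvalues,
            "p": res.pvalues,
        }
    )

    cov = np.asarray(res.cov_params())
    beta = res.params.to_numpy()
    names = list(X.columns)

    def joint_wald(cols):
        idx = [names.index(c) for c in cols]
        L = np.zeros((len(idx), len(names)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        est = L @ beta
        v = L @ cov @ L.T
        chi2 = float(est @ np.linalg.solve(v, est))
        dfree = len(idx)
        return chi2, dfree, float(scipy.stats.chi2.sf(chi2, dfree))

    wald_rows = []
    groups = {
        "week": [c for c in names if c.startswith("week[") and ":" not in c],
        "method": [c for c in names if c.startswith("method[")],
        "week:method": [c for c in names if ":" in c],
    }
    for factor, cols in groups.items():
        chi2, dfree, p = joint_wald(cols)
        wald_rows.append({"factor": factor, "df": dfree, "chi2": chi2, "p": p})
    wald = pd.DataFrame(wald_rows)

    # post-hoc family: between-week contrasts within each method plus the
    # method contrast within each week
    contrast_rows = []
    for method in ("PM", "SS"):
        for i in range(len(weeks)):
            for j in range(i + 1, len(weeks)):
                la = _cell_vector(names, weeks[j], method, w_ref, m_other)
                lb = _cell_vector(names, weeks[i], method, w_ref, m_other)
                contrast_rows.append((f"{method}: week {weeks[j]} - week {weeks[i]}", la - lb))
    for w in weeks:
        la = _cell_vector(names, w, "PM", w_ref, m_other)
        lb = _cell_vector(names, w, "SS", w_ref, m_other)
        contrast_rows.append((f"week {w}: PM - SS", la - lb))

    m = len(contrast_rows)
    crows = []
    for name, L in contrast_rows:
        est = float(L @ beta)
        var = float(L @ cov @ L)
        se = float(np.sqrt(var)) if var > 0 else float("nan")
        z = est / se if se > 0 else float("nan")
        p = 2 * scipy.stats.norm.sf(abs(z)) if se > 0 else float("nan")
        crows.append(
            {
                "contrast": name,
                "estimate": est,
                "se": se,
                "z": z,
                "p": p,
                "p_bonf": bonferroni(p, m),
            }
        )
    contrasts = pd.DataFrame(crows)

    return GEEResult(
        params=params,
        wald=wald,
        contrasts=contrasts,
        n_contrasts=m,
        scale=float(res.scale),
        working_corr=float(model.cov_struct.dep_params),
        n_subjects=len(subjects),
        n_obs=len(df),
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m·p)."""
    if np.isnan(p):
        return p
    return min(1.0, m * p)
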