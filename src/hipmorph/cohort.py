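"""Cohort-level statistics: sex comparisons per tilt angle, CEA-versus-
coverage correlations, measurement reliability (ICC) and range/argmax
summaries, plus the packaged reference-cohort summary table.

The reference table (``data/reference_cohort.csv``) transcribes the
per-angle mean +/- SD summary of a published 3D-CT study of 142 normal
adult hips (76 male, 66 female); it feeds the range/argmax summaries
that are exactly derivable from printed group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateVarianceError, ValidationError

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "ICCResult",
    "two_sample_ttest",
    "ttest_from_summary",
    "pearson_with_label",
    "strength_label",
    "icc_reliability",
    "to_long",
    "summarize_by_sex",
    "range_stats",
    "range_from_means",
    "correlation_by_angle",
    "load_reference_cohort",
    "reference_range_stats",
]

MEASURES = ("acea", "lcea", "coverage")

_WIDE_COLS = {"acea": "acea_deg", "lcea": "lcea_deg", "coverage": "coverage"}


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    strength_label: str


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model_label: str = "ICC(2,1): two-way random effects, absolute agreement, single measures"


def two_sample_ttest(group_a, group_b, equal_var: bool = True) -> TTestResult:
    """Independent two-sample t-test (Student's pooled-variance by
    default; Welch with ``equal_var=False``), two-sided."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            df = len(a) + len(b) - 2 if equal_var else float("nan")
            return TTestResult(t=0.0, df=df, p=1.0)
        raise DegenerateVarianceError(
            "both groups have zero variance but different means; t is undefined"
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def ttest_from_summary(n1, mean1, sd1, n2, mean2, sd2, equal_var: bool = True) -> TTestResult:
    """Same test computed from group summary statistics (n, mean, SD)."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if sd1 == 0 and sd2 == 0:
        if np.isclose(mean1, mean2):
            df = n1 + n2 - 2 if equal_var else float("nan")
            return TTestResult(t=0.0, df=df, p=1.0)
        raise DegenerateVarianceError(
            "both groups have zero variance but different means; t is undefined"
        )
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


#: conventional absolute-r ladder; thresholds are inclusive
_STRENGTH_LADDER = (
    (0.8, "very strong"),
    (0.6, "strong"),
    (0.4, "moderate"),
    (0.2, "weak"),
)


def strength_label(r: float) -> str:
    for threshold, label in _STRENGTH_LADDER:
        if abs(r) >= threshold:
            return label
    return "negligible"


def pearson_with_label(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value and a strength label."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("correlation needs matched samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateVarianceError("correlation undefined: zero variance in an input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x), strength_label=strength_label(r))


def icc_reliability(ratings) -> ICCResult:
    """ICC(2,1) — two-way random effects, absolute agreement, single
    measures — from the standard mean-squares decomposition.

    ``ratings`` is a complete subjects x raters matrix (no missing
    values; no imputation is attempted).
    """
    M = np.asarray(ratings, float)
    if M.ndim != 2:
        raise ValidationError("ratings must be a 2D subjects x raters matrix")
    n, k = M.shape
    if n < 5 or k < 2:
        raise ValidationError(f"need >= 5 subjects and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(M)):
        raise ValidationError("ratings matrix is incomplete (non-finite entries)")

    grand = M.mean()
    ms_rows = k * np.sum((M.mean(axis=1) - grand) ** 2) / (n - 1)        # subjects
    ms_cols = n * np.sum((M.mean(axis=0) - grand) ** 2) / (k - 1)        # raters
    sse = np.sum((M - M.mean(axis=1, keepdims=True) - M.mean(axis=0) + grand) ** 2)
    ms_err = sse / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom == 0:
        raise DegenerateVarianceError("ICC undefined: no variance in ratings")
    return ICCResult(icc=float((ms_rows - ms_err) / denom))


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide per-hip sweep table (lcea_deg/acea_deg/coverage columns)
    into the long (hip, angle, measure, value) cohort format."""
    missing = [c for c in ("hip_id", "sex", "app_tilt_deg", *_WIDE_COLS.values()) if c not in wide.columns]
    if missing:
        raise ValidationError(f"sweep table is missing columns: {missing}")
    id_vars = [c for c in ("hip_id", "subject_id", "side", "sex", "app_tilt_deg") if c in wide.columns]
    long = wide.melt(id_vars=id_vars, value_vars=list(_WIDE_COLS.values()), var_name="measure")
    long["measure"] = long["measure"].map({v: k for k, v in _WIDE_COLS.items()})
    return long


def _require_long(table: pd.DataFrame) -> pd.DataFrame:
    need = {"hip_id", "sex", "app_tilt_deg", "measure", "value"}
    if not need.issubset(table.columns):
        if set(_WIDE_COLS.values()).issubset(table.columns):
            return to_long(table)
        raise ValidationError(f"cohort table must have columns {sorted(need)}")
    return table


def summarize_by_sex(table: pd.DataFrame, equal_var: bool = True) -> pd.DataFrame:
    """Per (angle, measure): n/mean/SD for each sex plus the two-sample
    t-test — the shape of a published sex-comparison summary table."""
    table = _require_long(table)
    sexes = set(table["sex"].unique())
    if not {"male", "female"}.issubset(sexes):
        raise ValidationError(f"both sexes required; table has {sorted(sexes)}")
    rows = []
    for (angle, measure), grp in table.groupby(["app_tilt_deg", "measure"], sort=True):
        males = grp.loc[grp.sex == "male", "value"].to_numpy()
        females = grp.loc[grp.sex == "female", "value"].to_numpy()
        if len(males) < 2 or len(females) < 2:
            raise ValidationError(
                f"missing or too-small stratum at angle {angle}, measure {measure}"
            )
        test = two_sample_ttest(males, females, equal_var=equal_var)
        rows.append(
            {
                "app_tilt_deg": angle,
                "measure": measure,
                "n_male": len(males),
                "male_mean": males.mean(),
                "male_sd": males.std(ddof=1),
                "n_female": len(females),
                "female_mean": females.mean(),
                "female_sd": females.std(ddof=1),
                "t": test.t,
                "df": test.df,
                "p": test.p,
            }
        )
    return pd.DataFrame(rows)


def range_from_means(means: pd.Series) -> tuple[float, float]:
    """(max - min, argmax angle) of per-angle means; ties toward the
    smaller angle."""
    if means.empty:
        raise ValidationError("empty angle window")
    means = means.sort_index()
    rng = float(means.max() - means.min())
    argmax = float(means.index[np.argmax(means.to_numpy())])
    return rng, argmax


def range_stats(
    table: pd.DataFrame,
    angle_lo: float,
    angle_hi: float,
    group: str = "overall",
) -> pd.DataFrame:
    """Max-min of per-angle group means within a tilt window, per measure,
    with the angle attaining the maximum."""
    table = _require_long(table)
    if group in ("male", "female"):
        table = table[table.sex == group]
    elif group != "overall":
        raise ValidationError(f"group must be overall/male/female, got {group!r}")
    window = table[(table.app_tilt_deg >= angle_lo) & (table.app_tilt_deg <= angle_hi)]
    if window.empty:
        raise ValidationError(f"no angles in window [{angle_lo}, {angle_hi}]")
    rows = []
    for measure, grp in window.groupby("measure"):
        means = grp.groupby("app_tilt_deg")["value"].mean()
        rng, argmax = range_from_means(means)
        rows.append({"measure": measure, "group": group, "range": rng, "argmax_angle": argmax})
    return pd.DataFrame(rows)


def correlation_by_angle(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of each CEA against coverage, within sex at each angle."""
    table = _require_long(table)
    wide = table.pivot_table(
        index=["hip_id", "sex", "app_tilt_deg"], columns="measure", values="value"
    ).reset_index()
    rows = []
    for (sex, angle), grp in wide.groupby(["sex", "app_tilt_deg"], sort=True):
        for cea in ("acea", "lcea"):
            res = pearson_with_label(grp[cea], grp["coverage"])
            rows.append(
                {
                    "sex": sex,
                    "app_tilt_deg": angle,
                    "cea_measure": cea,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                    "strength_label": res.strength_label,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged reference summary table
# ---------------------------------------------------------------------------

def load_reference_cohort() -> pd.DataFrame:
    """Long-format reference summary: columns app_tilt_deg, measure,
    group (overall/male/female), mean, sd, n."""
    with resources.files("hipmorph.data").joinpath("reference_cohort.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def reference_range_stats(
    measure: str,
    angle_lo: float,
    angle_hi: float,
    group: str = "overall",
    table: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """(max - min, argmax angle) of the reference table's printed group
    means for one measure within a tilt window."""
    if measure not in MEASURES:
        raise ValidationError(f"measure must be one of {MEASURES}, got {measure!r}")
    ref = load_reference_cohort() if table is None else table
    sel = ref[
        (ref.measure == measure)
        & (ref.group == group)
        & (ref.app_tilt_deg >= angle_lo)
        & (ref.app_tilt_deg <= angle_hi)
    ]
    if sel.empty:
        raise ValidationError(f"no reference rows for {measure}/{group} in [{angle_lo}, {angle_hi}]")
    return range_from_means(sel.set_index("app_tilt_deg")["mean"])
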