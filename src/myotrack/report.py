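"""Detector evaluation and cohort statistics.

``match_events`` scores detections against injected ground truth with
one-to-one onset matching at a fixed tolerance.  ``two_way_anova_sidak``
runs the group comparison used for event counts in behavioral phenotyping
cohorts: a two-factor (genotype x age) ANOVA — Type II sums of squares for
mild imbalance — followed by Sidak-adjusted per-age genotype comparisons
(``p_adj = 1 - (1 - p)^m`` over the m planned comparisons) on the pooled
residual variance, the convention of mainstream prism-style analyses.  A
repeated-measures (mixed) variant is available when each subject is
measured at every age.  ``summarize_cohort`` ties the two together and
emits per-cell mean +/- SD tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import TrackingSeries
from .events import MyoclonicEvent, SessionSummary


@dataclass
class MatchResult:
    """Detection-vs-truth tally at a given onset tolerance."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    onset_errors_s: list[float]
    tolerance_s: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def match_events(
    detected_onsets_s,
    truth_onsets_s,
    tolerance_s: float = 2.0,
) -> MatchResult:
    """One-to-one matching of detected to true event onsets.

    Candidate pairs within ``tolerance_s`` are taken greedily in order of
    onset proximity, each onset used at most once; leftovers are false
    positives (detected) / false negatives (truth).  Inputs may be plain
    onset arrays, :class:`MyoclonicEvent` lists, or anything with
    ``time_s``/``onset_s`` attributes; input order is irrelevant.
    """
    if tolerance_s < 0:
        raise ValueError("tolerance_s must be >= 0")
    det = np.sort(np.asarray(_onsets(detected_onsets_s), dtype=float))
    tru = np.sort(np.asarray(_onsets(truth_onsets_s), dtype=float))
    pairs = [
        (abs(d - g), i, j)
        for i, d in enumerate(det)
        for j, g in enumerate(tru)
        if abs(d - g) <= tolerance_s
    ]
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    errors: list[float] = []
    for err, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        errors.append(float(det[i] - tru[j]))
    tp = len(errors)
    fp = len(det) - tp
    fn = len(tru) - tp
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return MatchResult(tp, fp, fn, precision, recall, f1, errors, tolerance_s)


def _onsets(items) -> list[float]:
    out = []
    for x in items:
        if isinstance(x, MyoclonicEvent):
            if x.accepted:
                out.append(x.onset_s)
        elif hasattr(x, "onset_s"):
            out.append(float(x.onset_s))
        elif hasattr(x, "time_s"):
            out.append(float(x.time_s))
        else:
            out.append(float(x))
    return out


@dataclass
class PairwiseComparison:
    level_b: str           # e.g. the age at which genotypes are compared
    level_a1: str
    level_a2: str
    mean_diff: float
    t: float
    df: float
    p_raw: float
    p_sidak: float


@dataclass
class AnovaResult:
    """Two-factor ANOVA table plus Sidak-adjusted planned comparisons."""

    factor_a: str
    factor_b: str
    f_a: float
    df_a: tuple[float, float]
    p_a: float
    f_b: float
    df_b: tuple[float, float]
    p_b: float
    f_ab: float
    df_ab: tuple[float, float]
    p_ab: float
    n_comparisons: int
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    cell_means: pd.DataFrame | None = None   # mean, sd, n per (A, B) cell
    repeated: bool = False

    def to_dict(self) -> dict:
        d = {
            "factor_a": self.factor_a, "factor_b": self.factor_b,
            "f_a": self.f_a, "df_a": list(self.df_a), "p_a": self.p_a,
            "f_b": self.f_b, "df_b": list(self.df_b), "p_b": self.p_b,
            "f_ab": self.f_ab, "df_ab": list(self.df_ab), "p_ab": self.p_ab,
            "n_comparisons": self.n_comparisons,
            "repeated": self.repeated,
            "pairwise": [dataclasses.asdict(c) for c in self.pairwise],
        }
        if self.cell_means is not None:
            d["cell_means"] = self.cell_means.reset_index().to_dict(orient="records")
        return d


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity adjustment ``1 - (1 - p)^m`` (identity for m=1)."""
    return float(1.0 - (1.0 - p) ** m)


def two_way_anova_sidak(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "age",
    subject: str = "subject",
    repeated: bool = False,
) -> AnovaResult:
    """Two-way ANOVA with Sidak-adjusted within-B comparisons of factor A.

    ``table`` holds one observation per row.  The between-subjects variant
    (default) uses a Type II sums-of-squares decomposition; the
    repeated-measures variant (``repeated=True``; every subject observed at
    every level of ``factor_b``) uses a mixed ANOVA with ``factor_a``
    between and ``factor_b`` within subjects.  Planned comparisons are all
    pairs of A levels at each B level, tested on the pooled residual
    variance and Sidak-adjusted over the family.
    """
    df = table[[c for c in {value, factor_a, factor_b, subject} if c in table.columns]].copy()
    df[factor_a] = df[factor_a].astype(str)
    df[factor_b] = df[factor_b].astype(str)
    a_levels = sorted(df[factor_a].unique())
    b_levels = sorted(df[factor_b].unique())
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError(
            f"need >= 2 levels per factor, got {len(a_levels)} x {len(b_levels)}")
    counts = df.groupby([factor_a, factor_b], observed=True)[value].count()
    for a in a_levels:
        for b in b_levels:
            if (a, b) not in counts.index or counts[(a, b)] == 0:
                raise ValueError(f"empty design cell ({factor_a}={a}, {factor_b}={b})")
    cells = df.groupby([factor_a, factor_b], observed=True)[value].agg(
        mean="mean", sd="std", n="count")

    if repeated:
        import pingouin as pg

        aov = pg.mixed_anova(data=df, dv=value, within=factor_b,
                             subject=subject, between=factor_a)
        aov = aov.set_index("Source")
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        row_a = aov.loc[factor_a]
        row_b = aov.loc[factor_b]
        row_ab = aov.loc["Interaction"]
        f_a, df_a, p_a = row_a["F"], (row_a["DF1"], row_a["DF2"]), row_a[pcol]
        f_b, df_b, p_b = row_b["F"], (row_b["DF1"], row_b["DF2"]), row_b[pcol]
        f_ab, df_ab, p_ab = row_ab["F"], (row_ab["DF1"], row_ab["DF2"]), row_ab[pcol]
        mse = None
        df_resid = None
    else:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        work = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
        if not (counts.min() >= 2):
            raise ValueError("between-subjects ANOVA needs >= 2 observations per cell")
        model = smf.ols("_y ~ C(_a) * C(_b)", data=work).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        df_resid = float(aov.loc["Residual", "df"])
        mse = float(aov.loc["Residual", "sum_sq"] / df_resid)
        f_a = float(aov.loc["C(_a)", "F"])
        p_a = float(aov.loc["C(_a)", "PR(>F)"])
        df_a = (float(aov.loc["C(_a)", "df"]), df_resid)
        f_b = float(aov.loc["C(_b)", "F"])
        p_b = float(aov.loc["C(_b)", "PR(>F)"])
        df_b = (float(aov.loc["C(_b)", "df"]), df_resid)
        f_ab = float(aov.loc["C(_a):C(_b)", "F"])
        p_ab = float(aov.loc["C(_a):C(_b)", "PR(>F)"])
        df_ab = (float(aov.loc["C(_a):C(_b)", "df"]), df_resid)

    if mse is None:
        # pooled within-cell variance for the mixed variant's comparisons
        ss = 0.0
        dof = 0
        for (_, _), grp in df.groupby([factor_a, factor_b], observed=True):
            v = grp[value].to_numpy(dtype=float)
            ss += float(((v - v.mean()) ** 2).sum())
            dof += len(v) - 1
        mse = ss / dof if dof else float("nan")
        df_resid = float(dof)

    pairwise: list[PairwiseComparison] = []
    m = len(b_levels) * (len(a_levels) * (len(a_levels) - 1) // 2)
    for b in b_levels:
        for i in range(len(a_levels)):
            for j in range(i + 1, len(a_levels)):
                a1, a2 = a_levels[i], a_levels[j]
                g1 = df[(df[factor_a] == a1) & (df[factor_b] == b)][value].to_numpy(float)
                g2 = df[(df[factor_a] == a2) & (df[factor_b] == b)][value].to_numpy(float)
                diff = float(g1.mean() - g2.mean())
                se = np.sqrt(mse * (1.0 / len(g1) + 1.0 / len(g2)))
                tval = diff / se if se > 0 else 0.0
                p_raw = float(2.0 * stats.t.sf(abs(tval), df_resid))
                pairwise.append(PairwiseComparison(
                    level_b=b, level_a1=a1, level_a2=a2, mean_diff=diff,
                    t=float(tval), df=df_resid, p_raw=p_raw,
                    p_sidak=sidak_adjust(p_raw, m)))

    return AnovaResult(
        factor_a=factor_a, factor_b=factor_b,
        f_a=float(f_a), df_a=(float(df_a[0]), float(df_a[1])), p_a=float(p_a),
        f_b=float(f_b), df_b=(float(df_b[0]), float(df_b[1])), p_b=float(p_b),
        f_ab=float(f_ab), df_ab=(float(df_ab[0]), float(df_ab[1])), p_ab=float(p_ab),
        n_comparisons=m, pairwise=pairwise, cell_means=cells, repeated=repeated,
    )


@dataclass
class CohortReport:
    table: pd.DataFrame                  # one row per session
    cell_means: pd.DataFrame             # mean +/- SD of counts per cell
    anova: AnovaResult | None
    notice: str = ""

    def to_dict(self) -> dict:
        return {
            "sessions": self.table.to_dict(orient="records"),
            "cell_means": self.cell_means.reset_index().to_dict(orient="records"),
            "anova": self.anova.to_dict() if self.anova else None,
            "notice": self.notice,
        }


def summarize_cohort(
    summaries: list[SessionSummary],
    design: pd.DataFrame,
    repeated: bool = False,
    log1p: bool = False,
) -> CohortReport:
    """Cohort table + group statistics from per-session event summaries.

    ``design`` maps ``session_id`` to ``subject``, ``genotype`` and ``age``
    labels.  Event counts are analyzed untransformed by default
    (``log1p=True`` applies log(1+x) first).  With a single genotype the
    ANOVA is skipped with a notice; summaries are still emitted.
    Unmatched sessions raise, listing the offenders.
    """
    required = {"session_id", "subject", "genotype", "age"}
    if not required.issubset(design.columns):
        raise ValueError(f"design must have columns {sorted(required)}")
    rows = pd.DataFrame([s.to_dict() for s in summaries])
    unmatched = sorted(set(rows["session_id"]) - set(design["session_id"]))
    if unmatched:
        raise ValueError(f"sessions missing from design: {unmatched}")
    table = rows.merge(design, on="session_id", how="left")
    table["age"] = table["age"].astype(str)
    table["genotype"] = table["genotype"].astype(str)
    cells = table.groupby(["genotype", "age"], observed=True)["count"].agg(
        mean="mean", sd="std", n="count")
    value_col = "count"
    if log1p:
        table = table.assign(count_log1p=np.log1p(table["count"]))
        value_col = "count_log1p"
    anova = None
    notice = ""
    if table["genotype"].nunique() < 2 or table["age"].nunique() < 2:
        notice = ("ANOVA skipped: need >= 2 genotypes and >= 2 ages "
                  f"(got {table['genotype'].nunique()} x {table['age'].nunique()})")
    else:
        anova = two_way_anova_sidak(
            table, value=value_col, factor_a="genotype", factor_b="age",
            subject="subject", repeated=repeated)
    return CohortReport(table=table, cell_means=cells, anova=anova, notice=notice)


def per_animal_trajectories(report: CohortReport) -> pd.DataFrame:
    """Wide per-animal table of counts across ages (one line per animal)."""
    return report.table.pivot_table(
        index=["subject", "genotype"], columns="age", values="count",
        aggfunc="first")


def plot_event_window(
    series: TrackingSeries,
    events: list[MyoclonicEvent],
    center_s: float,
    out_path: str,
    span_s: float = 30.0,
    vel_max_cms: float = 60.0,
) -> str:
    """Diagnostic 30-s velocity trace with detected events flagged.

    Mirrors the integrated-visualization view used for manual review: the
    raw center velocity on a ~0-60 cm/s scale with accepted (green) and
    rejected (red) event onsets marked.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .kinematics import compute_velocity

    v = compute_velocity(series, "center").values
    lo = center_s - span_s / 2.0
    hi = center_s + span_s / 2.0
    sel = (series.t >= lo) & (series.t <= hi)
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(series.t[sel], v[sel], lw=0.8, color="k")
    for ev in events:
        if lo <= ev.onset_s <= hi:
            color = "tab:green" if ev.accepted else "tab:red"
            ax.axvspan(ev.onset_s, ev.offset_s, color=color, alpha=0.3)
    ax.set_xlim(lo, hi)
    ax.set_ylim(0, vel_max_cms)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("velocity (cm/s)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
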