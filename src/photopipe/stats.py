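"""Within-subject statistics for peak-response and freezing tables.

Subjects are always the error stratum: trial-level values are averaged to
one score per subject and condition before testing.  The layer provides
paired/unpaired t-tests, one-way repeated-measures ANOVA, two-way mixed
ANOVA (one between-subjects factor, one within-subjects factor, classical
split-plot partition, uncorrected degrees of freedom), and explicitly
enumerated Bonferroni-corrected post hoc comparisons.  All tests are
two-sided.

The ANOVA sums of squares are computed directly on the subject x level
matrix; e.g. for the one-way repeated-measures design with k levels and n
subjects, F = MS_condition / MS_error with df (k-1, (k-1)(n-1)).  A
Greenhouse–Geisser sphericity correction is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaResult",
    "PosthocTable",
    "paired_t",
    "unpaired_t",
    "rm_anova",
    "mixed_anova",
    "bonferroni_posthocs",
    "dose_response_summary",
    "ZeroVarianceError",
]


class ZeroVarianceError(ValueError):
    """All paired differences identical: the t statistic is undefined."""


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    kind: str  # "paired" | "unpaired"
    n: int

    def summary(self) -> str:
        return f"{self.kind} t({self.df}) = {self.t:.3f}, p = {self.p:.4g} (n = {self.n})"


@dataclass
class AnovaResult:
    """One effect line of an ANOVA table."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    design: str  # "rm_oneway" | "mixed_twoway"
    ss_effect: float = np.nan
    ss_error: float = np.nan
    correction: str = "none"

    def summary(self) -> str:
        return (f"{self.design} {self.effect}: F({self.df_num},{self.df_den}) "
                f"= {self.F:.3f}, p = {self.p:.4g}"
                + ("" if self.correction == "none" else f" [{self.correction}]"))


# ---------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------

def paired_t(pre: Sequence[float], post: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test of post vs pre (paired by subject).

    The statistic is mean(d) / (sd(d)/sqrt(n)) on the differences
    d = post - pre; raises :class:`ZeroVarianceError` when every
    difference is identical rather than returning an infinite t.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D arrays")
    n = len(pre)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2 pairs")
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ZeroVarianceError(
            "all paired differences are identical; t is undefined"
        )
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, kind="paired", n=n)


def unpaired_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sided two-sample t-test with pooled variance (equal-variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("unpaired t-test needs n >= 2 per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        raise ZeroVarianceError("both groups are constant; t is undefined")
    t = float((a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, kind="unpaired", n=na + nb)


# ---------------------------------------------------------------------
# ANOVA cores (subject x level matrices)
# ---------------------------------------------------------------------

def _f_p(ss_eff: float, df1: int, ss_err: float, df2: int,
         eps: float = 1.0) -> tuple[float, float]:
    if ss_eff <= 0.0:
        return 0.0, 1.0
    if ss_err <= 0.0:
        return float("inf"), 0.0
    F = (ss_eff / df1) / (ss_err / df2)
    p = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return float(F), p


def _gg_epsilon(Y: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the within-subject covariance."""
    S = np.cov(Y, rowvar=False, ddof=1)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S * S) - 2 * k * np.sum(S.mean(axis=1) ** 2)
                     + k * k * mean_all**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova_matrix(Y: np.ndarray, correction: str = "none") -> AnovaResult:
    """One-way repeated-measures ANOVA on an (n subjects x k levels) matrix."""
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 within levels")
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    ss_cond = float(n * ((Y.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(k * ((Y.mean(axis=1) - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    eps = _gg_epsilon(Y) if correction == "gg" else 1.0
    F, p = _f_p(ss_cond, df1, ss_err, df2, eps=eps)
    return AnovaResult(effect="condition", F=F, df_num=df1, df_den=df2, p=p,
                       design="rm_oneway", ss_effect=ss_cond, ss_error=ss_err,
                       correction="none" if correction == "none" else "greenhouse-geisser")


def mixed_anova_matrix(Y: np.ndarray, groups: np.ndarray) -> list[AnovaResult]:
    """Two-way mixed (split-plot) ANOVA on an (N subjects x b levels) matrix.

    ``groups`` assigns each subject row to a between-subjects group.
    Returns [between, within, interaction] effects; the between effect is
    tested against subjects-within-groups, the within and interaction
    effects against the within-subjects residual with
    df = (b-1)(N-a) — the uncorrected split-plot algebra.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    N, b = Y.shape
    if len(groups) != N:
        raise ValueError("groups must give one label per subject row")
    labels, inv = np.unique(groups, return_inverse=True)
    a = len(labels)
    if a < 2 or b < 2 or N <= a:
        raise ValueError("need >= 2 groups, >= 2 within levels, > 1 subject/group")

    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())
    subj_means = Y.mean(axis=1)
    ss_subjall = float(b * ((subj_means - grand) ** 2).sum())
    n_g = np.bincount(inv)
    G = np.array([Y[inv == g].mean() for g in range(a)])
    ss_betw = float(b * (n_g * (G - grand) ** 2).sum())
    T = Y.mean(axis=0)
    ss_with = float(N * ((T - grand) ** 2).sum())
    ss_resall = float(sum(((Y[inv == g] - Y[inv == g].mean(axis=0)) ** 2).sum()
                          for g in range(a)))
    ss_inter = ss_total - ss_resall - ss_with - ss_betw
    ss_reswith = (ss_total - ss_subjall - ss_with) - ss_inter
    ss_resbetw = ss_subjall - ss_betw

    df_betw, df_resbetw = a - 1, N - a
    df_with, df_reswith = b - 1, (b - 1) * (N - a)
    df_inter = (a - 1) * (b - 1)

    F_b, p_b = _f_p(ss_betw, df_betw, ss_resbetw, df_resbetw)
    F_w, p_w = _f_p(ss_with, df_with, ss_reswith, df_reswith)
    F_i, p_i = _f_p(ss_inter, df_inter, ss_reswith, df_reswith)
    return [
        AnovaResult("between", F_b, df_betw, df_resbetw, p_b, "mixed_twoway",
                    ss_betw, ss_resbetw),
        AnovaResult("within", F_w, df_with, df_reswith, p_w, "mixed_twoway",
                    ss_with, ss_reswith),
        AnovaResult("interaction", F_i, df_inter, df_reswith, p_i, "mixed_twoway",
                    ss_inter, ss_reswith),
    ]


# ---------------------------------------------------------------------
# long-table front ends
# ---------------------------------------------------------------------

def _pivot_within(table: pd.DataFrame, dv: str, within: str,
                  subject: str) -> pd.DataFrame:
    """Subject x level matrix of subject-mean scores; errors on missing cells."""
    wide = table.pivot_table(index=subject, columns=within, values=dv,
                             aggfunc="mean", observed=True)
    if wide.isna().any().any():
        missing = [(s, l) for s in wide.index for l in wide.columns
                   if pd.isna(wide.at[s, l])]
        raise ValueError(f"missing subject x level cells: {missing}")
    return wide


def rm_anova(table: pd.DataFrame, dv: str, within: str, subject: str,
             correction: str = "none") -> AnovaResult:
    """One-way repeated-measures ANOVA on a long-format table.

    Multiple rows per (subject, level) — e.g. trials — are averaged to one
    subject-level score first.  The layout must be complete (every subject
    observed at every level).
    """
    wide = _pivot_within(table, dv, within, subject)
    return rm_anova_matrix(wide.to_numpy(), correction=correction)


def mixed_anova(table: pd.DataFrame, dv: str, within: str, between: str,
                subject: str) -> list[AnovaResult]:
    """Two-way mixed ANOVA (between group x within level) on a long table.

    The between factor must be constant within each subject; the within
    layout must be complete.  Returns [between, within, interaction].
    """
    grp = table.groupby(subject, observed=True)[between].nunique()
    bad = grp[grp > 1].index.tolist()
    if bad:
        raise ValueError(f"between factor varies within subjects: {bad}")
    wide = _pivot_within(table, dv, within, subject)
    gmap = table.groupby(subject, observed=True)[between].first()
    groups = gmap.loc[wide.index].to_numpy()
    return mixed_anova_matrix(wide.to_numpy(), groups)


# ---------------------------------------------------------------------
# post hocs and summaries
# ---------------------------------------------------------------------

@dataclass
class PosthocTable:
    """Bonferroni-corrected family of t-test comparisons."""

    table: pd.DataFrame  # comparison, kind, t, df, p_raw, p_adj, m

    def summary(self) -> str:
        lines = [f"Bonferroni post hocs (family m = {int(self.table['m'].iloc[0])})"]
        for _, r in self.table.iterrows():
            lines.append(
                f"  {r['comparison']}: t({int(r['df'])}) = {r['t']:.3f}, "
                f"p_raw = {r['p_raw']:.4g}, p_adj = {r['p_adj']:.4g}"
            )
        return "\n".join(lines)


def bonferroni_posthocs(table: pd.DataFrame, family: Sequence[Mapping],
                        dv: str = "peak_dff",
                        subject: str = "subject_id") -> PosthocTable:
    """Run an explicitly enumerated family of post hoc t-tests.

    Each comparison in ``family`` is a mapping with keys ``label``,
    ``kind`` ("paired" or "unpaired"), ``factor`` (column name), ``a`` and
    ``b`` (the two factor levels), and optionally ``where`` (column ->
    value filters applied first).  Paired comparisons are joined by
    subject; unpaired ones compare subject means between the two levels.
    p_adj = min(1, m * p_raw) with m the family size — the family is never
    inferred implicitly.
    """
    if len(family) == 0:
        raise ValueError("post hoc family is empty; enumerate the comparisons")
    m = len(family)
    rows = []
    for comp in family:
        sub = table
        for col, val in (comp.get("where") or {}).items():
            sub = sub[sub[col] == val]
        factor, la, lb = comp["factor"], comp["a"], comp["b"]
        a_means = (sub[sub[factor] == la].groupby(subject, observed=True)[dv].mean())
        b_means = (sub[sub[factor] == lb].groupby(subject, observed=True)[dv].mean())
        if comp["kind"] == "paired":
            joined = pd.concat([a_means, b_means], axis=1, join="inner")
            if len(joined) < 2:
                raise ValueError(f"comparison {comp['label']!r}: fewer than 2 pairs")
            res = paired_t(joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy())
        elif comp["kind"] == "unpaired":
            res = unpaired_t(a_means.to_numpy(), b_means.to_numpy())
        else:
            raise ValueError(f"unknown comparison kind {comp['kind']!r}")
        rows.append(dict(comparison=comp["label"], kind=comp["kind"], t=res.t,
                         df=res.df, p_raw=res.p, p_adj=min(1.0, m * res.p), m=m))
    return PosthocTable(pd.DataFrame(rows))


def dose_response_summary(responses: pd.DataFrame, dv: str = "peak_dff",
                          intensity: str = "intensity",
                          subject: str = "subject_id",
                          phase: Optional[str] = "post") -> pd.DataFrame:
    """Per-intensity mean +/- SEM of peak responses across subjects.

    Trials are first averaged to one score per subject and intensity; the
    reported mean and standard error are then taken across subjects.  With
    a single subject the SEM is emitted as missing.
    """
    sub = responses if phase is None else responses[responses["phase"] == phase]
    per_subject = (sub.groupby([intensity, subject], observed=True)[dv]
                   .mean().reset_index())
    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
    out = (per_subject.groupby(intensity, observed=True)[dv]
           .agg(mean="mean", sem=_sem, n_subjects="count").reset_index())
    return out
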