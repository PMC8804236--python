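"""Inferential battery for longitudinal tissue volume change.

The sequence mirrors the analysis plan: a sex-effect check on the control
cohort, sphericity (Mauchly's W) and normality (one-sample
Kolmogorov-Smirnov) checks on the collision-sport data, a one-way
repeated-measures ANOVA over the four follow-up sessions, Bonferroni
post-hoc t-test matrices (paired within CSA, unpaired CSA vs NCA),
a Pearson screen of tissue change against exposure over the PTA threshold
grid, and an OLS linear predictor with 95% confidence band for the
screen's significant cells.

Conventions
-----------
* All p-value corrections are Bonferroni: ``p_corr = min(1, m * p_raw)``
  with the family size ``m`` always reported alongside.
* Mean differences in the pairwise matrix are rendered in percent, signed
  "later minus earlier" within CSA and "CSA session minus NCA Retest"
  across groups.
* Unpaired t-tests default to the classical pooled-variance form; Welch's
  correction is available via a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exposure import ExposureMatrix

ALPHA = 0.05

#: CSA follow-up sessions entering the rANOVA and pairwise matrix.
RANOVA_SESSIONS = ("In1", "In2", "Post1", "Post2")


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, df, raw and Bonferroni p."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p_raw: float
    m: int = 1
    note: str = ""

    @property
    def p_corrected(self) -> float:
        return min(1.0, self.m * self.p_raw)

    @property
    def significant(self) -> bool:
        return bool(self.p_corrected < ALPHA)


def bonferroni(result: TestResult, m: int) -> TestResult:
    """Attach a Bonferroni family size to a test result."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return replace(result, m=m)


# --------------------------------------------------------------- primitives


def paired_t(x: np.ndarray, y: np.ndarray, name: str = "paired t") -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired t requires two equal-length 1-D samples")
    if len(x) < 2:
        raise ValueError("paired t requires at least 2 pairs")
    d = y - x
    if np.allclose(d, d[0]) and np.isclose(d.std(ddof=1), 0):
        if np.isclose(d[0], 0):
            return TestResult(name, 0.0, (len(d) - 1,), 1.0)
        raise ValueError("degenerate paired t: constant non-zero differences")
    t, p = sps.ttest_rel(y, x)
    return TestResult(name, float(t), (len(d) - 1,), float(p))


def unpaired_t(
    x: np.ndarray, y: np.ndarray, welch: bool = False, name: str = "unpaired t"
) -> TestResult:
    """Two-sample t-test, pooled variance by default (Welch optional).

    Statistic is for ``mean(x) - mean(y)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("unpaired t requires >= 2 observations per group")
    if np.isclose(x.std(ddof=1), 0) and np.isclose(y.std(ddof=1), 0):
        if np.isclose(x.mean(), y.mean()):
            return TestResult(name, 0.0, (len(x) + len(y) - 2,), 1.0)
        raise ValueError("degenerate unpaired t: zero variance in both groups")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    if welch:
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    else:
        df = len(x) + len(y) - 2
    return TestResult(name, float(t), (float(df),), float(p), note="welch" if welch else "pooled")


def pearson_r(x: np.ndarray, y: np.ndarray, name: str = "pearson r") -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson r requires two equal-length samples with n >= 3")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("pearson r undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return TestResult(name, float(r), (len(x) - 2,), float(p))


# ------------------------------------------------------------ battery stages


def sex_effect_check(
    nca_rtvc: pd.DataFrame,
    session: str = "Retest",
    welch: bool = False,
) -> dict[str, TestResult]:
    """Unpaired t-test of control rTVC at Retest between sexes, per tissue.

    Guards the pooling of male and female controls into one reference
    group.  Requires at least two athletes of each sex.
    """
    sub = nca_rtvc[nca_rtvc["session"] == session]
    results: dict[str, TestResult] = {}
    for tissue, block in sub.groupby("tissue"):
        groups = {s: g["rtvc"].to_numpy() for s, g in block.groupby("sex")}
        if len(groups) < 2:
            raise ValueError(f"sex-effect check for {tissue}: a sex group is empty")
        (sa, xa), (sb, xb) = sorted(groups.items())
        results[tissue] = unpaired_t(
            xa, xb, welch=welch, name=f"sex effect {tissue} ({sa} vs {sb})"
        )
    return results


def _wide(values: pd.DataFrame, sessions: Sequence[str], value_col: str) -> pd.DataFrame:
    """Pivot long athlete/session values to complete-case wide format."""
    wide = values.pivot_table(
        index="athlete_id", columns="session", values=value_col
    ).reindex(columns=list(sessions))
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        raise ValueError(
            f"athletes missing sessions {list(sessions)}: {incomplete}; "
            "filter to complete cases first"
        )
    return wide


def complete_cases(values: pd.DataFrame, sessions: Sequence[str]) -> pd.DataFrame:
    """Listwise-complete subset: athletes with every listed session."""
    counts = values[values["session"].isin(sessions)].groupby("athlete_id")["session"].nunique()
    keep = counts.index[counts == len(sessions)]
    return values[values["athlete_id"].isin(keep) & values["session"].isin(sessions)]


def mauchly_test(
    values: pd.DataFrame,
    sessions: Sequence[str] = RANOVA_SESSIONS,
    value_col: str = "rtvc",
) -> TestResult:
    """Mauchly's W sphericity test on orthonormal within-subject contrasts.

    W = det(S') / (tr(S')/(k-1))^(k-1) with S' the covariance of the
    (k-1) orthonormal (Helmert) contrast scores; the p-value uses the
    standard chi-square approximation.  With k = 2 sessions sphericity is
    vacuous (W = 1, p = 1).
    """
    wide = _wide(values, sessions, value_col)
    n, k = wide.shape
    if k < 2:
        raise ValueError("sphericity needs at least 2 sessions")
    d = k - 1
    if n <= d:
        raise ValueError(f"n = {n} subjects cannot estimate a {d}x{d} contrast covariance")
    if k == 2:
        return TestResult("mauchly W", 1.0, (0,), 1.0, note="k=2: sphericity vacuous")
    contrasts = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, :d]
    scores = wide.to_numpy() @ contrasts
    s = np.cov(scores, rowvar=False)
    eig = np.linalg.eigvalsh(s)
    if eig.min() <= 0:
        raise ValueError("singular contrast covariance; more subjects needed")
    w = float(np.prod(eig) / (eig.mean() ** d))
    # chi-square approximation with the standard second-order correction
    f = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * (n - 1.0))
    w2 = (
        (d + 2.0) * (d - 1.0) * (d - 2.0) * (2.0 * d**3 + 6.0 * d**2 + 3.0 * k + 2.0)
        / (288.0 * ((n - 1.0) * d * f) ** 2)
    )
    chi2 = -(n - 1.0) * f * np.log(w)
    df = d * (d + 1) / 2.0 - 1.0
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return TestResult("mauchly W", w, (df,), p)


def ks_normality(values: np.ndarray, name: str = "ks normality") -> TestResult:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample mean and SD (the p-value is the
    standard KS one and is anti-conservative under estimated parameters —
    the Lilliefors caveat, recorded in the result note).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("KS normality check needs n >= 5")
    s = x.std(ddof=1)
    if np.isclose(s, 0):
        raise ValueError("KS normality undefined for constant input")
    d, p = sps.kstest(x, "norm", args=(x.mean(), s))
    return TestResult(
        name, float(d), (len(x),), float(p), note="reference normal fitted (Lilliefors caveat)"
    )


@dataclass(frozen=True)
class RmAnovaResult(TestResult):
    """rANOVA F with its sums-of-squares partition attached."""

    ss_subject: float = np.nan
    ss_session: float = np.nan
    ss_error: float = np.nan
    gg_epsilon: float = np.nan


def rm_anova(
    values: pd.DataFrame,
    sessions: Sequence[str] = RANOVA_SESSIONS,
    value_col: str = "rtvc",
    greenhouse_geisser: bool = False,
) -> RmAnovaResult:
    """One-way repeated-measures ANOVA over follow-up sessions.

    Complete cases only (an athlete missing a session is an error; use
    :func:`complete_cases` to pre-filter).  F = MS_session / MS_error
    with df = (k-1, (k-1)(n-1)) from the partition
    SS_total = SS_subject + SS_session + SS_error.  When
    ``greenhouse_geisser`` is set, df are scaled by the epsilon estimated
    from the contrast covariance before computing p.
    """
    wide = _wide(values, sessions, value_col)
    x = wide.to_numpy()
    n, k = x.shape
    if n < 2:
        raise ValueError("rANOVA needs at least 2 subjects")
    grand = x.mean()
    ss_subject = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_session = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = ss_total - ss_subject - ss_session
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_error = ss_error / df2
    if ms_error <= 0:
        f_stat = 0.0 if np.isclose(ss_session, 0) else np.inf
        p = 1.0 if f_stat == 0.0 else 0.0
    else:
        f_stat = (ss_session / df1) / ms_error
        p = float(sps.f.sf(f_stat, df1, df2))

    eps = np.nan
    note = ""
    if greenhouse_geisser and k > 2 and ms_error > 0:
        contrasts = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
        s = np.cov(x @ contrasts, rowvar=False)
        eig = np.clip(np.linalg.eigvalsh(s), 0, None)
        eps = float(eig.sum() ** 2 / ((k - 1) * (eig**2).sum()))
        p = float(sps.f.sf(f_stat, df1 * eps, df2 * eps))
        note = f"greenhouse-geisser eps={eps:.4f}"
    return RmAnovaResult(
        name="rANOVA",
        statistic=float(f_stat),
        df=(df1, df2),
        p_raw=p,
        note=note,
        ss_subject=float(ss_subject),
        ss_session=float(ss_session),
        ss_error=float(ss_error),
        gg_epsilon=eps,
    )


# --------------------------------------------------------- pairwise matrix


@dataclass(frozen=True)
class PairwiseComparison:
    tissue: str
    kind: str  # "within" (paired, CSA) or "across" (unpaired, CSA vs NCA)
    label: str  # e.g. "Post1 vs In1" or "Post1 vs Retest"
    n: int
    mean_diff_pct: float
    result: TestResult | None
    note: str = ""


@dataclass
class PairwiseMatrix:
    tissue: str
    comparisons: list[PairwiseComparison] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append(
                {
                    "tissue": c.tissue,
                    "kind": c.kind,
                    "comparison": c.label,
                    "n": c.n,
                    "mean_diff_pct": c.mean_diff_pct,
                    "t": c.result.statistic if c.result else np.nan,
                    "df": c.result.df[0] if c.result else np.nan,
                    "p_raw": c.result.p_raw if c.result else np.nan,
                    "p_bonf": c.result.p_corrected if c.result else np.nan,
                    "m": c.result.m if c.result else np.nan,
                    "significant": c.result.significant if c.result else False,
                    "note": c.note or (c.result.note if c.result else ""),
                }
            )
        return pd.DataFrame(rows)


def posthoc_matrix(
    csa_rtvc: pd.DataFrame,
    nca_rtvc: pd.DataFrame,
    tissue: str,
    sessions: Sequence[str] = RANOVA_SESSIONS,
    nca_session: str = "Retest",
    m_within: int | None = None,
    m_across: int | None = None,
    welch: bool = False,
) -> PairwiseMatrix:
    """Post-hoc t-test matrix for one tissue.

    Within CSA: paired t-tests over all session pairs (later minus
    earlier), Bonferroni family of 6 by default.  Across groups: unpaired
    t-tests of each CSA session against NCA Retest (CSA minus NCA),
    family of 4.  Mean differences are in percent.  A pair with fewer
    than two complete athletes is reported as unavailable rather than
    dropped.
    """
    csa = csa_rtvc[csa_rtvc["tissue"] == tissue]
    nca = nca_rtvc[(nca_rtvc["tissue"] == tissue) & (nca_rtvc["session"] == nca_session)]
    pairs = list(itertools.combinations(sessions, 2))
    m_w = m_within if m_within is not None else len(pairs)
    m_a = m_across if m_across is not None else len(sessions)
    out = PairwiseMatrix(tissue=tissue)

    by_session = {
        s: g.set_index("athlete_id")["rtvc"] for s, g in csa.groupby("session")
    }
    for earlier, later in pairs:
        label = f"{later} vs {earlier}"
        a = by_session.get(earlier, pd.Series(dtype=float))
        b = by_session.get(later, pd.Series(dtype=float))
        common = a.index.intersection(b.index)
        if len(common) < 2:
            out.comparisons.append(
                PairwiseComparison(tissue, "within", label, len(common), np.nan, None,
                                   note="unavailable: fewer than 2 paired athletes")
            )
            continue
        x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
        res = bonferroni(paired_t(x, y, name=f"{tissue} {label} (paired)"), m_w)
        out.comparisons.append(
            PairwiseComparison(tissue, "within", label, len(common),
                               float((y - x).mean() * 100.0), res)
        )

    nca_vals = nca["rtvc"].to_numpy()
    for s in sessions:
        label = f"{s} vs {nca_session}"
        csa_vals = by_session.get(s, pd.Series(dtype=float)).to_numpy()
        if len(csa_vals) < 2 or len(nca_vals) < 2:
            out.comparisons.append(
                PairwiseComparison(tissue, "across", label,
                                   min(len(csa_vals), len(nca_vals)), np.nan, None,
                                   note="unavailable: fewer than 2 athletes in a group")
            )
            continue
        res = bonferroni(
            unpaired_t(csa_vals, nca_vals, welch=welch, name=f"{tissue} {label} (unpaired)"),
            m_a,
        )
        out.comparisons.append(
            PairwiseComparison(tissue, "across", label, len(csa_vals),
                               float((csa_vals.mean() - nca_vals.mean()) * 100.0), res)
        )
    return out


# ------------------------------------------------------- exposure screening


@dataclass(frozen=True)
class ScreenResult:
    """Pearson screen cell: one (tissue, session, PTA threshold)."""

    tissue: str
    session: str
    threshold_g: float
    n: int
    r: float
    p_raw: float
    m: int
    degenerate: bool = False
    note: str = ""

    @property
    def p_corrected(self) -> float:
        return min(1.0, self.m * self.p_raw) if np.isfinite(self.p_raw) else np.nan

    @property
    def significant(self) -> bool:
        return bool(not self.degenerate and self.p_corrected < ALPHA)


def screen_correlation(
    rtvc: pd.DataFrame,
    exposure: ExposureMatrix,
    tissues: Sequence[str] | None = None,
    sessions: Sequence[str] | None = None,
    family_size: int | None = None,
) -> list[ScreenResult]:
    """Pearson r of rTVC against nHAE over the full threshold grid.

    One cell per (tissue, session, threshold).  Cells where every athlete
    shares the same count (typically high thresholds nobody exceeded) are
    degenerate: r is undefined and the cell is excluded from the
    Bonferroni family.  The family is thresholds x sessions within each
    tissue (minus degenerate cells) unless ``family_size`` overrides it.
    """
    sessions = tuple(sessions or exposure.sessions)
    tissues = tuple(tissues or pd.unique(rtvc["tissue"]))
    results: list[ScreenResult] = []
    for tissue in tissues:
        sub = rtvc[rtvc["tissue"] == tissue]
        cells = []
        for session in sessions:
            vals = sub[sub["session"] == session].set_index("athlete_id")["rtvc"]
            for th in exposure.thresholds:
                counts = exposure.wide(session, th)
                common = vals.index.intersection(counts.index)
                x = counts.loc[common].to_numpy(dtype=float)
                y = vals.loc[common].to_numpy(dtype=float)
                if len(common) < 3 or np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
                    cells.append((tissue, session, th, len(common), np.nan, np.nan, True))
                    continue
                r, p = sps.pearsonr(x, y)
                cells.append((tissue, session, th, len(common), float(r), float(p), False))
        m = family_size if family_size is not None else sum(1 for c in cells if not c[6])
        m = max(m, 1)
        for tissue_, session, th, n, r, p, degen in cells:
            results.append(
                ScreenResult(
                    tissue=tissue_, session=session, threshold_g=float(th), n=n,
                    r=r, p_raw=p, m=m, degenerate=degen,
                    note="degenerate: zero-variance cell" if degen else "",
                )
            )
    return results


def screen_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tissue": s.tissue, "session": s.session, "threshold_g": s.threshold_g,
                "n": s.n, "r": s.r, "p_raw": s.p_raw, "p_bonf": s.p_corrected,
                "m": s.m, "degenerate": s.degenerate, "significant": s.significant,
            }
            for s in results
        ]
    )


# --------------------------------------------------------- linear predictor


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of rTVC on nHAE with pointwise 95% confidence band."""

    slope: float
    intercept: float
    n: int
    slope_se: float
    sigma: float  # residual standard error
    x_mean: float
    sxx: float
    conf_level: float = 0.95

    @property
    def df(self) -> int:
        return self.n - 2

    def slope_ci(self) -> tuple[float, float]:
        t = sps.t.ppf(0.5 + self.conf_level / 2.0, self.df)
        return (self.slope - t * self.slope_se, self.slope + t * self.slope_se)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise CI for the mean response at ``x``."""
        x = np.asarray(x, dtype=float)
        t = sps.t.ppf(0.5 + self.conf_level / 2.0, self.df)
        half = t * self.sigma * np.sqrt(1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx)
        yhat = self.predict(x)
        return yhat - half, yhat + half


def fit_linear_predictor(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares of y on x (rTVC on nHAE).

    Intended for cells the correlation screen flagged significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("linear predictor requires n >= 3 paired observations")
    sxx = float(((x - x.mean()) ** 2).sum())
    if np.isclose(sxx, 0):
        raise ValueError("linear predictor undefined: no variance in exposure")
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sigma = float(np.sqrt((resid**2).sum() / (len(x) - 2)))
    return LinearFit(
        slope=slope,
        intercept=intercept,
        n=len(x),
        slope_se=sigma / np.sqrt(sxx),
        sigma=sigma,
        x_mean=float(x.mean()),
        sxx=sxx,
    )
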