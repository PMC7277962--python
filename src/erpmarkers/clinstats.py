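"""Cohort outcome statistics for biomarker-based treatment prediction.

Given per-subject biomarker values (FAA, LDAEP, MMN, melancholia score)
and Hamilton depression (HAM-D) scores at weeks 0/2/4/8, this module
implements the analysis chain:

* median split of each biomarker into low/high groups;
* remission (week-8 HAM-D <= 7) and response (>= 50% HAM-D decrease)
  classification, with uncorrected Pearson chi-square on the 2x2 group x
  outcome table;
* repeated-measures ANCOVA of HAM-D over the four weeks with group as the
  between factor and age, sex, baseline HAM-D and medication as
  covariates, with Mauchly's sphericity test and Greenhouse-Geisser
  adjustment of the week x group interaction;
* per-week one-way ANCOVA with the same covariates;
* partial correlation between the melancholia score and each biomarker,
  controlling for the same covariates.

No multiple-testing correction is applied across the biomarkers; p-values
are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "ClinicalRecord", "SubjectFeatures", "OutcomeFlags", "SplitAssignment",
    "ChiSquareResult", "RmAnovaResult", "AncovaResult", "PartialCorrResult",
    "classify_outcomes", "median_split", "contingency", "pearson_chi2",
    "mauchly_and_epsilon", "rm_ancova", "ancova_at_week", "partial_corr",
    "HAMD_WEEKS", "COVARIATES",
]

HAMD_WEEKS = (0, 2, 4, 8)
#: default covariate set for ANCOVA / partial correlation
COVARIATES = ("age", "sex", "hamd_w0", "medication")

SEX_LEVELS = ("male", "female")
MEDICATION_LEVELS = ("vortioxetine", "escitalopram")


@dataclass
class ClinicalRecord:
    """Demographics, medication and clinical scores for one subject."""

    subject_id: str
    age: float
    sex: str
    medication: str
    hamd: dict  # week -> integer score, weeks 0/2/4/8
    hama_baseline: int = None
    hama_week8: int = None
    core: int = None  # melancholia (MEL) score

    def __post_init__(self):
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if self.medication not in MEDICATION_LEVELS:
            raise ValueError(
                f"medication must be one of {MEDICATION_LEVELS}, got {self.medication!r}")
        for w, v in self.hamd.items():
            if v is not None and v < 0:
                raise ValueError(f"negative HAM-D score at week {w}")
        if self.core is not None and self.core < 0:
            raise ValueError("negative CORE score")

    @property
    def complete(self) -> bool:
        """True when all four HAM-D measurements are present."""
        return all(self.hamd.get(w) is not None for w in HAMD_WEEKS)


@dataclass
class SubjectFeatures:
    """The per-subject biomarker vector entering the cohort analysis."""

    subject_id: str
    faa_f5f6: float = None
    faa_f7f8: float = None
    ldaep: float = None
    mmn: float = None
    mel: float = None


@dataclass(frozen=True)
class OutcomeFlags:
    remission: bool
    response: bool


@dataclass
class SplitAssignment:
    index_name: str
    median: float
    groups: dict  # subject_id -> "low" | "high"

    def subjects(self, level: str) -> list:
        return [s for s, g in self.groups.items() if g == level]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class SphericityResult:
    mauchly_w: float
    mauchly_p: float
    epsilon: float  # Greenhouse-Geisser


@dataclass(frozen=True)
class RmAnovaResult:
    """Week x group interaction test from the repeated-measures ANCOVA."""

    F: float
    df1: float  # GG-adjusted when sphericity violated (fractional)
    df2: float
    p: float
    epsilon: float
    mauchly_w: float
    mauchly_p: float
    sphericity_assumed: bool
    df1_unadjusted: int = None
    df2_unadjusted: int = None


@dataclass(frozen=True)
class AncovaResult:
    week: int
    F: float
    p: float
    df1: int
    df2: int
    group_means: dict = None  # level -> (raw mean, raw sd, n)


@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    df: int
    p: float
    n: int
    covariates: tuple = ()


def classify_outcomes(rec) -> OutcomeFlags:
    """Remission: week-8 HAM-D <= 7. Response: >= 50% decrease from baseline.

    Accepts a :class:`ClinicalRecord` or any object with ``hamd`` mapping
    weeks 0 and 8 to scores.
    """
    h0, h8 = rec.hamd.get(0), rec.hamd.get(8)
    if h0 is None or h8 is None:
        raise ValueError(f"subject {rec.subject_id}: HAM-D weeks 0 and 8 required")
    if h0 <= 0:
        raise ValueError(
            f"subject {rec.subject_id}: response undefined for baseline HAM-D {h0}")
    return OutcomeFlags(remission=h8 <= 7, response=(h0 - h8) / h0 >= 0.5)


def median_split(values, index_name: str = "index") -> SplitAssignment:
    """Dichotomize a biomarker at the cohort median.

    ``values`` maps subject_id -> value (dict or pandas Series). Subjects
    at or below the median go to "low", above to "high"; with even n and
    no exact ties at the median the groups are equal-sized.
    """
    s = pd.Series(values).dropna()
    if len(s) < 4:
        raise ValueError(f"median split needs >= 4 values, got {len(s)}")
    if s.nunique() == 1:
        raise ValueError(f"median split of {index_name!r} undefined: all values equal")
    med = float(s.median())
    groups = {subj: ("low" if v <= med else "high") for subj, v in s.items()}
    return SplitAssignment(index_name=index_name, median=med, groups=groups)


def contingency(split: SplitAssignment, flags: dict) -> np.ndarray:
    """2x2 counts: rows (low, high) x columns (positive, negative outcome)."""
    table = np.zeros((2, 2), dtype=int)
    for subj, grp in split.groups.items():
        if subj not in flags:
            raise ValueError(f"subject {subj} has a group but no outcome flag")
        r = 0 if grp == "low" else 1
        c = 0 if flags[subj] else 1
        table[r, c] += 1
    return table


def pearson_chi2(table) -> ChiSquareResult:
    """Uncorrected Pearson chi-square on a 2x2 table (df = 1)."""
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("expected a 2x2 table of nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    res = stats.chi2_contingency(t, correction=False)
    return ChiSquareResult(statistic=float(res.statistic), df=int(res.dof),
                           p=float(res.pvalue))


def _orthonormal_poly_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal polynomial contrast matrix over the levels."""
    x = np.arange(k, dtype=float)
    V = np.vander(x, k, increasing=True)  # columns 1, x, x^2, ...
    Q, _ = np.linalg.qr(V)
    M = Q[:, 1:]  # drop the constant column
    return M


def _design_matrix(n: int, group=None, covariates: pd.DataFrame = None):
    """Between-subject design: intercept [+ group 0/1] [+ covariates].

    Two-level string covariates are coded 0/1 by sorted level order;
    numeric covariates enter as-is. Constant covariate columns carry no
    information and are dropped.
    """
    cols = [np.ones(n)]
    if group is not None:
        g = pd.Series(group)
        levels = sorted(g.unique())
        if len(levels) != 2:
            raise ValueError(f"group must have exactly 2 levels, got {levels}")
        cols.append((g == levels[1]).to_numpy(dtype=float))
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.nunique() < 2:
                continue
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                levels = sorted(col.unique())
                if len(levels) > 2:
                    raise ValueError(f"covariate {name!r} has >2 levels")
                cols.append((col == levels[-1]).to_numpy(dtype=float))
            else:
                cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("between-subject design matrix is rank deficient")
    return X


def _error_sscp(Y: np.ndarray, X: np.ndarray, M: np.ndarray):
    """Contrast-space error SSCP E = M' Y' Q Y M and its df (n - p)."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    E = M.T @ resid.T @ resid @ M
    return E, n - p, beta


def mauchly_and_epsilon(data, design: np.ndarray = None) -> SphericityResult:
    """Mauchly's sphericity test and Greenhouse-Geisser epsilon.

    ``data`` is the wide n x k matrix of repeated measures (k >= 3).
    ``design`` is the between-subject design matrix whose fit defines the
    error covariance (defaults to an intercept-only column, i.e. the plain
    within-subject covariance). Both statistics are computed from the
    error covariance of the orthonormal-contrast-transformed measures, as
    in standard GLM repeated-measures output.
    """
    Y = np.asarray(data, dtype=float)
    n, k = Y.shape
    if k < 3:
        raise ValueError("sphericity requires >= 3 repeated measures")
    X = design if design is not None else np.ones((n, 1))
    if n <= X.shape[1] + k - 1:
        raise ValueError(f"too few subjects (n={n}) for k={k} levels")
    M = _orthonormal_poly_contrasts(k)
    E, df_e, _ = _error_sscp(Y, X, M)
    S = E / df_e
    d = k - 1
    eigvals = np.linalg.eigvalsh(S)
    if eigvals.min() <= 0:
        raise ValueError("singular repeated-measures covariance matrix")
    # Greenhouse-Geisser epsilon from the contrast-space error covariance
    eps = np.trace(S) ** 2 / (d * np.sum(S * S))
    eps = float(min(eps, 1.0))
    # Mauchly's W with Box's two-term chi-square approximation
    W = float(np.prod(eigvals) / (np.trace(S) / d) ** d)
    rho = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * df_e)
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d ** 3 + 6 * d ** 2 + 3 * d + 2)
          / (288.0 * (df_e * d * rho) ** 2))
    z = -df_e * rho * np.log(W)
    df_w = k * (k - 1) // 2 - 1
    p1 = stats.chi2.sf(z, df_w)
    p2 = stats.chi2.sf(z, df_w + 4)
    p = float(p1 + w2 * (p2 - p1))
    return SphericityResult(mauchly_w=W, mauchly_p=p, epsilon=eps)


def rm_ancova(data: pd.DataFrame, dv: str = "hamd", within: str = "week",
              subject: str = "subject_id", between: str = "group",
              covariates=COVARIATES, sphericity_alpha: float = 0.05,
              drop_baseline_covariate: bool = False) -> RmAnovaResult:
    """Week x group interaction from a repeated-measures ANCOVA.

    ``data`` is long-format with one row per subject x within-level,
    constant between/covariate columns per subject. The model follows the
    univariate GLM repeated-measures approach: the repeated measures are
    transformed by orthonormal polynomial contrasts, the between-subject
    design (intercept, group, covariates) is fit to the transformed
    variables, and the interaction F averages the hypothesis and error
    SSCP traces. Greenhouse-Geisser df adjustment is applied when
    Mauchly's test rejects sphericity at ``sphericity_alpha``; otherwise
    unadjusted dfs are reported. Complete cases only.

    ``drop_baseline_covariate`` removes the baseline score from the
    covariate set for sensitivity analysis (by default the baseline enters
    both as a repeated-measures level and as a covariate, mirroring the
    reference design).
    """
    covariates = tuple(covariates)
    if drop_baseline_covariate:
        covariates = tuple(c for c in covariates if c != "hamd_w0")
    wide = data.pivot(index=subject, columns=within, values=dv).sort_index()
    keep_cols = [between, *covariates]
    per_subj = (data.drop_duplicates(subject).set_index(subject)[keep_cols]
                .reindex(wide.index))
    complete = wide.notna().all(axis=1) & per_subj.notna().all(axis=1)
    wide, per_subj = wide[complete], per_subj[complete]
    n, k = wide.shape
    if k < 3:
        raise ValueError("need >= 3 within-subject levels")
    counts = per_subj[between].value_counts()
    if len(counts) != 2 or counts.min() < 2:
        raise ValueError("need 2 group levels with >= 2 subjects each")

    Y = wide.to_numpy(dtype=float)
    X = _design_matrix(n, group=per_subj[between],
                       covariates=per_subj[list(covariates)] if covariates else None)
    p = X.shape[1]
    M = _orthonormal_poly_contrasts(k)
    E, df_e, beta = _error_sscp(Y, X, M)

    # hypothesis SSCP for the group column (index 1 in the design)
    L = np.zeros((1, p))
    L[0, 1] = 1.0
    XtX_inv = np.linalg.inv(X.T @ X)
    LB = L @ beta @ M  # 1 x (k-1)
    H = LB.T @ np.linalg.inv(L @ XtX_inv @ L.T) @ LB
    df_h = 1

    d = k - 1
    F = (np.trace(H) / (d * df_h)) / (np.trace(E) / (d * df_e))
    sph = mauchly_and_epsilon(Y, design=X)
    df1_un, df2_un = d * df_h, d * df_e
    if sph.mauchly_p < sphericity_alpha:
        df1, df2 = sph.epsilon * df1_un, sph.epsilon * df2_un
        assumed = False
    else:
        df1, df2 = float(df1_un), float(df2_un)
        assumed = True
    pval = float(stats.f.sf(F, df1, df2))
    return RmAnovaResult(F=float(F), df1=float(df1), df2=float(df2), p=pval,
                         epsilon=sph.epsilon, mauchly_w=sph.mauchly_w,
                         mauchly_p=sph.mauchly_p, sphericity_assumed=assumed,
                         df1_unadjusted=df1_un, df2_unadjusted=df2_un)


def gg_adjusted_dfs(epsilon: float, k: int, n: int, n_groups: int = 2,
                    n_covariates: int = 4) -> tuple:
    """Greenhouse-Geisser df pair for the week x group interaction.

    df1 = eps * (k-1); df2 = eps * (k-1) * (n - n_groups - n_covariates),
    the within-subject error df after fitting intercept, group and the
    covariates (p = 1 + (n_groups - 1) + n_covariates between-subject
    parameters).
    """
    p = 1 + (n_groups - 1) + n_covariates
    return float(epsilon * (k - 1)), float(epsilon * (k - 1) * (n - p))


def ancova_at_week(data: pd.DataFrame, week: int, dv: str = "hamd",
                   subject: str = "subject_id", between: str = "group",
                   covariates=COVARIATES) -> AncovaResult:
    """One-way ANCOVA on the HAM-D score of one week.

    Group F adjusting for the covariates (OLS + ANOVA on the group term;
    with no interactions in the model this equals the type-III group
    test). Raw per-group mean +/- sd are reported alongside.
    """
    sub = data[data["week"] == week].drop_duplicates(subject).copy()
    cols = [dv, between, *covariates]
    sub = sub.dropna(subset=cols)
    counts = sub[between].value_counts()
    if len(counts) != 2 or counts.min() < 2:
        raise ValueError("need 2 group levels with >= 2 subjects each")
    rhs = [f"C({between})"]
    for c in covariates:
        if sub[c].nunique() < 2:
            continue
        rhs.append(f"C({c})" if sub[c].dtype == object else c)
    model = ols(f"{dv} ~ {' + '.join(rhs)}", data=sub).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    row = aov.loc[f"C({between})"]
    means = {lvl: (float(g[dv].mean()), float(g[dv].std(ddof=1)), len(g))
             for lvl, g in sub.groupby(between)}
    return AncovaResult(week=int(week), F=float(row["F"]), p=float(row["PR(>F)"]),
                        df1=int(row["df"]), df2=int(aov.loc["Residual", "df"]),
                        group_means=means)


def partial_corr(x, y, covariates=None) -> PartialCorrResult:
    """Partial correlation of x and y controlling for a covariate set.

    Both variables are residualized on [1, covariates] by least squares
    and the Pearson correlation of the residuals is returned, with
    df = n - 2 - m and a two-sided p from the t transform. With no
    covariates this reduces to the ordinary product-moment correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have the same length")
    if covariates is None:
        Z = np.ones((n, 1))
        m = 0
        names = ()
    else:
        if isinstance(covariates, pd.DataFrame):
            names = tuple(covariates.columns)
            C = _design_matrix(n, covariates=covariates)[:, 1:]
        else:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != n:
                C = C.T
            names = tuple(f"z{i}" for i in range(C.shape[1]))
        Z = np.column_stack([np.ones(n), C])
        m = C.shape[1]
    if n <= m + 2:
        raise ValueError(f"need n > {m + 2} observations, got {n}")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is constant after residualization")
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - 2 - m
    t = r * np.sqrt(df / max(1.0 - r * r, np.finfo(float).tiny))
    p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r=r, df=df, p=p, n=n, covariates=names)
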