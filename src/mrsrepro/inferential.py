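"""Inferential layer: repeated-measures ANOVA over sessions, ANCOVA with
nuisance covariates, and the CRLB-CV correlation.

* :func:`rm_anova_sessions` - one-way within-subject ANOVA testing for a mean
  concentration difference between the repeated sessions (closed-form sums of
  squares; sphericity assumed by default, Greenhouse-Geisser correction
  optional).
* :func:`ancova_covariates` - least-squares model with participant and region
  fixed effects plus three continuous covariates (GM/WM ratio, daytime of
  measurement, absolute voxel displacement d); the per-covariate partial F is
  the squared t statistic of its single-df coefficient.
* :func:`crlb_cv_correlation` - Pearson correlation between per-cell mean
  fitting error (CRLB%) and mean intra-subject CV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .study_data import StudyTable

__all__ = [
    "COVARIATES",
    "RmAnovaResult",
    "AncovaResult",
    "CorrelationResult",
    "rm_anova_sessions",
    "ancova_covariates",
    "crlb_cv_correlation",
]

COVARIATES = ["gm_wm_ratio", "daytime_hours", "displacement_d"]


@dataclass(frozen=True)
class RmAnovaResult:
    region: str
    metabolite: str
    F: float
    df_num: int
    df_den: int
    p: float
    gg_epsilon: float | None = None
    p_gg: float | None = None
    n_subjects: int = 0
    n_sessions: int = 0


@dataclass(frozen=True)
class AncovaResult:
    """Per-covariate partial F tests from one least-squares fit."""

    metabolite: str
    terms: dict  # covariate -> {"F", "df_num", "df_den", "p", "t", "coef"}
    fixed_effects: tuple = ("subject", "region")
    full_rank: bool = True
    n_obs: int = 0


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    labels: list = field(default_factory=list)


def _session_matrix(table: StudyTable, region: str, metabolite: str) -> np.ndarray:
    cell = table.cell(region, metabolite)
    if cell.empty:
        raise ValueError(f"no records for ({region}, {metabolite})")
    mat = cell.pivot(index="subject", columns="session", values="concentration")
    incomplete = mat.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping subject(s) with incomplete sessions: {list(mat.index[incomplete])}",
            stacklevel=3,
        )
        mat = mat[~incomplete]
    return mat.to_numpy()


def rm_anova_sessions(
    table: StudyTable, region: str, metabolite: str, gg_correction: bool = False
) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on the session factor for one cell.

    F = MS_sessions / MS_(session x subject); df = (S-1, (S-1)(n-1)).  When
    both sums of squares vanish (every subject constant over sessions) the
    statistic is taken as F = 0, p = 1.  ``gg_correction`` additionally
    reports the Greenhouse-Geisser epsilon and the epsilon-adjusted p-value.
    """
    y = _session_matrix(table, region, metabolite)
    n, S = y.shape
    if n < 2 or S < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 sessions, got n={n}, S={S}")
    grand = y.mean()
    col = y.mean(axis=0)
    row = y.mean(axis=1)
    ss_sessions = n * ((col - grand) ** 2).sum()
    resid = y - row[:, None] - col[None, :] + grand
    ss_err = (resid**2).sum()
    df_num, df_den = S - 1, (S - 1) * (n - 1)
    if ss_err == 0:
        F = 0.0 if ss_sessions == 0 else np.inf
    else:
        F = (ss_sessions / df_num) / (ss_err / df_den)
    p = 1.0 if F == 0 else float(stats.f.sf(F, df_num, df_den))
    eps = p_gg = None
    if gg_correction:
        V = np.cov(y, rowvar=False)
        C = np.eye(S) - np.full((S, S), 1.0 / S)
        Vc = C @ V @ C
        tr = np.trace(Vc)
        eps = float(tr**2 / ((S - 1) * np.trace(Vc @ Vc))) if tr > 0 else 1.0
        eps = min(max(eps, 1.0 / (S - 1)), 1.0)
        p_gg = 1.0 if F == 0 else float(stats.f.sf(F, df_num * eps, df_den * eps))
    return RmAnovaResult(
        region=region, metabolite=metabolite, F=float(F),
        df_num=df_num, df_den=df_den, p=p,
        gg_epsilon=eps, p_gg=p_gg, n_subjects=n, n_sessions=S,
    )


def _build_design(data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded subject and region effects + the three covariates."""
    parts = [np.ones((len(data), 1))]
    names = ["intercept"]
    for factor in ("subject", "region"):
        dummies = pd.get_dummies(data[factor].astype(str), prefix=factor, drop_first=True)
        parts.append(dummies.to_numpy(dtype=float))
        names += list(dummies.columns)
    parts.append(data[COVARIATES].to_numpy(dtype=float))
    names += COVARIATES
    return np.hstack(parts), names


def ancova_covariates(
    table: StudyTable,
    covariates: pd.DataFrame,
    metabolite: str | None = None,
    pooled: bool = False,
) -> list[AncovaResult]:
    """ANCOVA of concentration on participant and region fixed effects plus
    GM/WM ratio, daytime, and displacement covariates.

    ``covariates`` is keyed by (subject, session, region) and must cover every
    retained measurement.  One model is fitted per metabolite (default), or a
    single pooled model on concentrations standardized within metabolite
    (``pooled=True``).  Each covariate's partial F against the model without
    it equals the square of its t statistic (single-df identity).
    """
    import statsmodels.api as sm

    req = {"subject", "session", "region", *COVARIATES}
    missing = req - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table lacks column(s): {sorted(missing)}")
    cov = covariates.copy()
    cov["subject"] = cov["subject"].astype(str)
    cov["session"] = cov["session"].astype(int)
    left = table.frame.drop(columns=[c for c in COVARIATES if c in table.frame.columns])
    merged = left.merge(cov, on=["subject", "session", "region"], how="left", validate="m:1")
    if merged[COVARIATES].isna().any().any():
        bad = merged.loc[merged[COVARIATES].isna().any(axis=1),
                         ["subject", "session", "region"]].drop_duplicates()
        raise ValueError(f"covariates missing for measurement(s):\n{bad.to_string(index=False)}")

    if pooled:
        z = merged.groupby("metabolite")["concentration"].transform(
            lambda x: (x - x.mean()) / x.std(ddof=1)
        )
        merged = merged.assign(concentration=z)
        groups = [("pooled", merged)]
    elif metabolite is not None:
        groups = [(metabolite, merged[merged["metabolite"] == metabolite])]
    else:
        groups = list(merged.groupby("metabolite"))

    out = []
    for metab, data in groups:
        if data.empty:
            raise ValueError(f"no records for metabolite {metab!r}")
        X, names = _build_design(data)
        y = data["concentration"].to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(X)
        full_rank = rank == X.shape[1]
        if not full_rank:
            # name the aliased columns via pivoted QR
            from scipy.linalg import qr

            _, _, piv = qr(X, pivoting=True)
            aliased = [names[i] for i in piv[rank:]]
            raise np.linalg.LinAlgError(
                f"rank-deficient ANCOVA design for {metab}: aliased column(s) {aliased}"
            )
        fit = sm.OLS(y, X).fit()
        df_den = int(fit.df_resid)
        terms = {}
        for cname in COVARIATES:
            i = names.index(cname)
            t = float(fit.tvalues[i])
            terms[cname] = {
                "F": t * t, "df_num": 1, "df_den": df_den,
                "p": float(fit.pvalues[i]), "t": t, "coef": float(fit.params[i]),
            }
        out.append(
            AncovaResult(metabolite=str(metab), terms=terms,
                         full_rank=full_rank, n_obs=len(data))
        )
    return out


def crlb_cv_correlation(
    mean_crlb: pd.Series | dict, mean_intra_cv: pd.Series | dict
) -> CorrelationResult:
    """Pearson correlation between mean CRLB and mean intra-subject CV,
    paired by (region, metabolite).

    A positive correlation indicates that fitting uncertainty drives the
    within-subject measurement scatter.
    """
    a = pd.Series(mean_crlb, dtype=float)
    b = pd.Series(mean_intra_cv, dtype=float)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired (region, metabolite) points")
    x, y = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroDivisionError("correlation undefined: zero variance in a margin")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(common), labels=list(common))
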