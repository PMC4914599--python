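"""Intra- and inter-subject coefficient-of-variation machinery.

The reproducibility statistics for a repeated-measures MRS design
(n subjects x S sessions per (region, metabolite) cell):

* CV = SD / mean x 100 (sample SD, denominator n-1).
* Intra-subject CV: per-subject CV across sessions, averaged over subjects
  (default), or mean per-subject SD over the grand mean.
* Inter-subject CV: a resampling estimator - draw one session per subject,
  compute the cross-subject mean and SD, repeat (5000 draws by default),
  average the means and the SDs, and form 100 x avg(SD)/avg(mean).  When the
  number of distinct draw combinations S^n is small the estimator is replaced
  by exact enumeration over all combinations.
* Aggregates: region means over metabolites, metabolite means over regions,
  study-level means and the inter-minus-intra gap.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_data import StudyTable

__all__ = [
    "CVResult",
    "ResamplingConfig",
    "VariabilityReport",
    "cv",
    "intra_subject_cv",
    "inter_subject_cv_resampled",
    "compute_cv_results",
    "aggregate_report",
]

#: E[sample SD]/sigma for Gaussian data at sample size n (Gaussian c4 factor)
def c4_factor(n: int) -> float:
    from scipy.special import gammaln

    return float(np.sqrt(2.0 / (n - 1)) * np.exp(gammaln(n / 2) - gammaln((n - 1) / 2)))


def cv(values) -> float:
    """Coefficient of variation in percent: sample SD (n-1) / mean x 100."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("cv requires at least 2 values")
    m = x.mean()
    if m == 0:
        raise ZeroDivisionError("cv undefined for zero mean")
    return float(np.std(x, ddof=1) / m * 100.0)


@dataclass(frozen=True)
class ResamplingConfig:
    """Controls the inter-subject resampling estimator.

    ``mode="independent_per_subject"`` draws a session independently for each
    subject (S^n combinations); ``"shared_timepoint"`` draws one session index
    shared by all subjects (S combinations).  ``method="auto"`` switches to
    exact enumeration whenever the number of combinations is at most
    ``enumeration_cap``; ``"monte_carlo"`` and ``"exhaustive"`` force a path.
    """

    n_iter: int = 5000
    seed: int = 0
    mode: str = "independent_per_subject"
    method: str = "auto"
    enumeration_cap: int = 1_000_000

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.mode not in ("independent_per_subject", "shared_timepoint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.method not in ("auto", "monte_carlo", "exhaustive"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class CVResult:
    """Intra- and inter-subject variability of one (region, metabolite) cell."""

    region: str
    metabolite: str
    mean_concentration: float
    intra_sd: float
    intra_cv_percent: float
    inter_sd: float
    inter_cv_percent: float
    n_subjects: int
    n_sessions: int


def _cell_matrix(table: StudyTable, region: str, metabolite: str) -> pd.DataFrame:
    """Subject x session concentration matrix for one cell (NaN where missing)."""
    cell = table.cell(region, metabolite)
    if cell.empty:
        raise ValueError(f"no records for ({region}, {metabolite})")
    return cell.pivot(index="subject", columns="session", values="concentration")


def intra_subject_cv(
    table: StudyTable, region: str, metabolite: str,
    method: str = "mean_of_subject_cvs",
) -> tuple[float, float]:
    """Within-subject session-to-session variability of one cell.

    ``mean_of_subject_cvs`` (default): each subject's CV across its sessions,
    averaged over subjects; the reported SD is the mean of per-subject SDs.
    ``mean_sd_over_mean``: mean per-subject SD divided by the grand mean.
    Subjects with fewer than 2 sessions are dropped with a warning.

    Returns ``(intra_sd, intra_cv_percent)``.
    """
    if method not in ("mean_of_subject_cvs", "mean_sd_over_mean"):
        raise ValueError(f"unknown method {method!r}")
    mat = _cell_matrix(table, region, metabolite)
    counts = mat.notna().sum(axis=1)
    if (counts < 2).any():
        dropped = list(mat.index[counts < 2])
        warnings.warn(
            f"dropping subject(s) with <2 sessions for ({region}, {metabolite}): {dropped}",
            stacklevel=2,
        )
        mat = mat[counts >= 2]
    if mat.empty:
        raise ValueError(f"no subject has >= 2 sessions for ({region}, {metabolite})")
    sds = mat.std(axis=1, ddof=1)
    means = mat.mean(axis=1)
    intra_sd = float(sds.mean())
    if method == "mean_of_subject_cvs":
        intra_cv = float((sds / means * 100.0).mean())
    else:
        intra_cv = float(intra_sd / means.mean() * 100.0)
    return intra_sd, intra_cv


def _draw_stats(values: np.ndarray) -> tuple[float, float]:
    return float(values.mean()), float(np.std(values, ddof=1))


def inter_subject_cv_resampled(
    table: StudyTable, region: str, metabolite: str,
    config: ResamplingConfig | None = None,
) -> tuple[float, float]:
    """Between-subject variability of one cell via the resampling estimator.

    Each draw selects one session per subject, yielding a cross-subject mean
    and sample SD; the draws' means and SDs are averaged separately and the
    inter-subject CV is 100 x avg(SD) / avg(mean).  Exact enumeration over all
    session combinations replaces Monte Carlo when feasible (see
    :class:`ResamplingConfig`).

    Returns ``(inter_sd, inter_cv_percent)``.
    """
    config = config or ResamplingConfig()
    mat = _cell_matrix(table, region, metabolite)
    if mat.isna().all(axis=1).any():
        raise ValueError("every subject needs at least one session")
    # per-subject available sessions (ragged if sessions are missing)
    rows = [r[~np.isnan(r)] for r in mat.to_numpy()]
    n_sub = len(rows)
    counts = np.array([len(r) for r in rows])

    if config.mode == "shared_timepoint":
        if mat.isna().any().any():
            raise ValueError("shared_timepoint mode requires a complete subject x session grid")
        full = mat.to_numpy()
        n_comb = full.shape[1]
        exhaustive = config.method == "exhaustive" or (
            config.method == "auto" and n_comb <= config.enumeration_cap
        )
        if exhaustive:
            stats = [_draw_stats(full[:, j]) for j in range(n_comb)]
        else:
            rng = np.random.default_rng(config.seed)
            js = rng.integers(0, n_comb, size=config.n_iter)
            stats = [_draw_stats(full[:, j]) for j in js]
    else:
        n_comb = int(np.prod(counts, dtype=np.float64)) if np.prod(counts, dtype=np.float64) < 2**62 else 2**62
        exhaustive = config.method == "exhaustive" or (
            config.method == "auto" and n_comb <= config.enumeration_cap
        )
        if exhaustive:
            if counts.max() == counts.min():
                # complete grid: vectorized enumeration
                S = counts[0]
                idx = np.stack(np.meshgrid(*([np.arange(S)] * n_sub), indexing="ij"))
                idx = idx.reshape(n_sub, -1)
                vals = np.stack([rows[i][idx[i]] for i in range(n_sub)])
                means = vals.mean(axis=0)
                sds = vals.std(axis=0, ddof=1)
                stats = list(zip(means, sds))
            else:
                stats = [
                    _draw_stats(np.array(c))
                    for c in itertools.product(*rows)
                ]
        else:
            rng = np.random.default_rng(config.seed)
            picks = np.stack(
                [rows[i][rng.integers(0, counts[i], size=config.n_iter)] for i in range(n_sub)]
            )
            means = picks.mean(axis=0)
            sds = picks.std(axis=0, ddof=1)
            stats = list(zip(means, sds))

    means = np.array([s[0] for s in stats])
    sds = np.array([s[1] for s in stats])
    avg_mean, avg_sd = float(means.mean()), float(sds.mean())
    if avg_mean == 0:
        raise ZeroDivisionError("inter-subject CV undefined for zero mean")
    return avg_sd, 100.0 * avg_sd / avg_mean


def compute_cv_results(
    table: StudyTable,
    intra_method: str = "mean_of_subject_cvs",
    resampling: ResamplingConfig | None = None,
) -> list[CVResult]:
    """Intra- and inter-subject CVs for every (region, metabolite) cell of a study."""
    resampling = resampling or ResamplingConfig()
    out = []
    for region in table.regions:
        for metab in table.metabolites:
            cell = table.cell(region, metab)
            if cell.empty:
                continue
            intra_sd, intra_cv = intra_subject_cv(table, region, metab, method=intra_method)
            inter_sd, inter_cv = inter_subject_cv_resampled(table, region, metab, resampling)
            out.append(
                CVResult(
                    region=region, metabolite=metab,
                    mean_concentration=float(cell["concentration"].mean()),
                    intra_sd=intra_sd, intra_cv_percent=intra_cv,
                    inter_sd=inter_sd, inter_cv_percent=inter_cv,
                    n_subjects=cell["subject"].nunique(),
                    n_sessions=cell["session"].nunique(),
                )
            )
    return out


@dataclass
class VariabilityReport:
    """Per-cell CVs plus region-, metabolite- and study-level aggregates.

    Every aggregate is the arithmetic mean of its constituent cells; the
    study-level gap is mean(inter CV) - mean(intra CV).
    """

    results: list[CVResult]
    region_means: pd.DataFrame = field(init=False)
    metabolite_means: pd.DataFrame = field(init=False)
    study_intra_cv: float = field(init=False)
    study_inter_cv: float = field(init=False)
    intra_inter_gap: float = field(init=False)

    def __post_init__(self):
        if not self.results:
            raise ValueError("no CV results to aggregate")
        f = self.to_frame()
        self.region_means = f.groupby("region")[["intra_cv_percent", "inter_cv_percent"]].mean()
        self.metabolite_means = f.groupby("metabolite")[["intra_cv_percent", "inter_cv_percent"]].mean()
        self.study_intra_cv = float(self.region_means["intra_cv_percent"].mean())
        self.study_inter_cv = float(self.region_means["inter_cv_percent"].mean())
        self.intra_inter_gap = self.study_inter_cv - self.study_intra_cv

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format report: level, region, metabolite, statistic, value."""
        rows = []
        for r in self.results:
            for stat in ("mean_concentration", "intra_sd", "intra_cv_percent",
                         "inter_sd", "inter_cv_percent"):
                rows.append(("cell", r.region, r.metabolite, stat, getattr(r, stat)))
        for region, row in self.region_means.iterrows():
            rows.append(("region", region, "", "intra_cv_percent", row["intra_cv_percent"]))
            rows.append(("region", region, "", "inter_cv_percent", row["inter_cv_percent"]))
        for metab, row in self.metabolite_means.iterrows():
            rows.append(("metabolite", "", metab, "intra_cv_percent", row["intra_cv_percent"]))
            rows.append(("metabolite", "", metab, "inter_cv_percent", row["inter_cv_percent"]))
        rows.append(("study", "", "", "intra_cv_percent", self.study_intra_cv))
        rows.append(("study", "", "", "inter_cv_percent", self.study_inter_cv))
        rows.append(("study", "", "", "intra_inter_gap", self.intra_inter_gap))
        return pd.DataFrame(rows, columns=["level", "region", "metabolite", "statistic", "value"])


def aggregate_report(cv_results: list[CVResult]) -> VariabilityReport:
    """Aggregate per-cell CV results into the full variability report."""
    return VariabilityReport(results=list(cv_results))
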