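"""Data model, I/O and quality filtering for repeated-measures MRS concentration tables.

The central container is :class:`StudyTable`, a validated long table with one
row per (subject, session, region, metabolite) quantification.  Concentrations
are water-scaled LCModel outputs in arbitrary units (AU); the per-record
Cramér–Rao lower bound (CRLB, in % of the fitted concentration) is the fitting
uncertainty used for quality control.  Metabolites whose CRLB summary exceeds a
threshold (20% by convention) are excluded per region before any variability
statistic is computed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "DEFAULT_METABOLITE_ALIASES",
    "ConcentrationRecord",
    "StudyTable",
    "QualityPolicy",
    "FormatError",
    "IntegrityError",
    "read_concentration_table",
    "write_concentration_table",
    "filter_by_crlb",
    "normalize_metabolite_names",
    "load_paper_fixture",
]

REQUIRED_COLUMNS = ["subject", "session", "region", "metabolite", "concentration", "crlb_percent"]
OPTIONAL_COLUMNS = ["snr", "linewidth_ppm", "daytime_hours", "acquisition_order"]
KEY_COLUMNS = ["subject", "session", "region", "metabolite"]

#: composite measures conventionally reported when component spectra overlap
DEFAULT_METABOLITE_ALIASES = {
    "GPC+PCh": "tCho",
    "NAA+NAAG": "tNAA",
    "Glu+Gln": "Glx",
}


class FormatError(ValueError):
    """A required column is missing or a field cannot be parsed."""


class IntegrityError(ValueError):
    """A table invariant (unique key, value range) is violated."""


@dataclass(frozen=True)
class ConcentrationRecord:
    """One metabolite quantification from one acquisition."""

    subject_id: str
    session_index: int
    region: str
    metabolite: str
    concentration: float  # AU, water-scaled
    crlb_percent: float
    snr: float | None = None
    linewidth_ppm: float | None = None
    daytime_hours: float | None = None
    acquisition_order: int | None = None

    def __post_init__(self):
        if self.concentration < 0:
            raise IntegrityError(f"negative concentration {self.concentration}")
        if self.crlb_percent < 0:
            raise IntegrityError(f"negative CRLB {self.crlb_percent}")
        if self.session_index < 1:
            raise IntegrityError(f"session_index must be >= 1, got {self.session_index}")


@dataclass(frozen=True)
class QualityPolicy:
    """CRLB-based inclusion rule applied per (region, metabolite).

    ``mean_below`` (the default) retains a metabolite in a region when the
    mean CRLB over all its acquisitions is below the threshold; ``all_below``
    requires every acquisition to pass, ``any_below`` requires at least one,
    and ``median_below`` uses the median.
    """

    crlb_threshold_percent: float = 20.0
    rule: str = "mean_below"

    _RULES = ("mean_below", "median_below", "all_below", "any_below")

    def __post_init__(self):
        if self.crlb_threshold_percent <= 0:
            raise ValueError("crlb_threshold_percent must be > 0")
        if self.rule not in self._RULES:
            raise ValueError(f"rule must be one of {self._RULES}, got {self.rule!r}")

    def passes(self, crlbs: np.ndarray) -> bool:
        c = np.asarray(crlbs, dtype=float)
        t = self.crlb_threshold_percent
        if self.rule == "mean_below":
            return bool(c.mean() < t)
        if self.rule == "median_below":
            return bool(np.median(c) < t)
        if self.rule == "all_below":
            return bool((c < t).all())
        return bool((c < t).any())


class StudyTable:
    """Long table of concentration records with a unique design key.

    Wraps a :class:`pandas.DataFrame` whose rows are one quantification each
    and whose key (subject, session, region, metabolite) is unique.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        frame["subject"] = frame["subject"].astype(str)
        frame["session"] = frame["session"].astype(int)
        frame["concentration"] = frame["concentration"].astype(float)
        frame["crlb_percent"] = frame["crlb_percent"].astype(float)
        dup = frame.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            keys = frame.loc[dup, KEY_COLUMNS].apply(tuple, axis=1).tolist()
            raise IntegrityError(f"duplicate record key(s): {keys}")
        if (frame["concentration"] < 0).any():
            raise IntegrityError("negative concentration(s) present")
        if (frame["crlb_percent"] < 0).any():
            raise IntegrityError("negative CRLB(s) present")
        if (frame["session"] < 1).any():
            raise IntegrityError("session indices must be >= 1")
        if len(frame) == 0:
            raise IntegrityError("table is empty")
        order = REQUIRED_COLUMNS + [c for c in frame.columns if c not in REQUIRED_COLUMNS]
        self.frame = frame[order].reset_index(drop=True)

    # -- design -----------------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return sorted(self.frame["subject"].unique())

    @property
    def sessions(self) -> list[int]:
        return sorted(self.frame["session"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.frame["region"].unique())

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.frame["metabolite"].unique())

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyTable):
            return NotImplemented
        a = self.frame.sort_values(KEY_COLUMNS).reset_index(drop=True)
        b = other.frame.sort_values(KEY_COLUMNS).reset_index(drop=True)
        return a.equals(b)

    def cell(self, region: str, metabolite: str) -> pd.DataFrame:
        """All records for one (region, metabolite) cell."""
        f = self.frame
        return f[(f["region"] == region) & (f["metabolite"] == metabolite)]

    def records(self) -> Iterable[ConcentrationRecord]:
        for row in self.frame.itertuples(index=False):
            yield ConcentrationRecord(
                subject_id=row.subject,
                session_index=row.session,
                region=row.region,
                metabolite=row.metabolite,
                concentration=row.concentration,
                crlb_percent=row.crlb_percent,
                snr=getattr(row, "snr", None),
                linewidth_ppm=getattr(row, "linewidth_ppm", None),
                daytime_hours=getattr(row, "daytime_hours", None),
                acquisition_order=getattr(row, "acquisition_order", None),
            )


def read_concentration_table(path: str | Path, format: str = "csv") -> StudyTable:
    """Read a per-acquisition concentration table.

    Parameters
    ----------
    path
        CSV file with header columns
        ``subject,session,region,metabolite,concentration,crlb_percent`` and
        optional extras, or a minimal LCModel-style summary spreadsheet
        (``format="lcmodel_summary"``: columns metabolite, concentration,
        %SD, plus subject/session/region columns added by the exporter).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        frame = pd.read_csv(path)
    elif format == "lcmodel_summary":
        frame = _read_lcmodel_summary(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return StudyTable(frame)


def _read_lcmodel_summary(path: Path) -> pd.DataFrame:
    """Minimal LCModel summary dialect: tab- or comma-separated columns
    including ``Metabolite``, ``Conc.`` and ``%SD`` (the CRLB)."""
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    raw = pd.read_csv(path, sep=sep)
    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key in ("metabolite", "metab"):
            rename[col] = "metabolite"
        elif key in ("conc.", "conc", "concentration"):
            rename[col] = "concentration"
        elif key in ("%sd", "sd%", "crlb", "crlb_percent"):
            rename[col] = "crlb_percent"
        else:
            rename[col] = key
    frame = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"LCModel summary lacks column(s) {', '.join(missing)}; "
            "pre-convert to the plain CSV layout"
        )
    return frame


def write_concentration_table(table: StudyTable, path: str | Path) -> Path:
    """Write the table as UTF-8 CSV (round-trips with :func:`read_concentration_table`)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)
    return path


def normalize_metabolite_names(
    table: StudyTable, aliases: dict[str, str] | None = None
) -> StudyTable:
    """Map component-sum labels to their composite names (e.g. GPC+PCh → tCho).

    Only relabels; summing fitted components is the spectral-fitting
    software's job and is out of scope here.
    """
    aliases = DEFAULT_METABOLITE_ALIASES if aliases is None else aliases
    frame = table.frame.copy()
    frame["metabolite"] = frame["metabolite"].map(lambda m: aliases.get(m, m))
    return StudyTable(frame)


@dataclass
class ExclusionReport:
    """Which (region, metabolite) cells a quality policy removed, with CRLB summaries."""

    policy: QualityPolicy
    excluded: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        cols = ["region", "metabolite", "n_records", "crlb_mean", "crlb_min", "crlb_max"]
        return pd.DataFrame(self.excluded, columns=cols)


def filter_by_crlb(
    table: StudyTable, policy: QualityPolicy | None = None
) -> tuple[StudyTable | None, ExclusionReport]:
    """Remove (region, metabolite) cells failing the CRLB quality policy.

    A metabolite failing the rule in a region is removed from that region
    entirely (all subjects and sessions).  Returns the filtered table and a
    report of removed cells; an empty result is signalled by returning
    ``None`` for the table, not by raising.  Idempotent.
    """
    policy = policy or QualityPolicy()
    report = ExclusionReport(policy=policy)
    keep = np.ones(len(table.frame), dtype=bool)
    for (region, metab), cell in table.frame.groupby(["region", "metabolite"], sort=True):
        crlbs = cell["crlb_percent"].to_numpy()
        if not policy.passes(crlbs):
            keep &= ~((table.frame["region"] == region) & (table.frame["metabolite"] == metab)).to_numpy()
            report.excluded.append(
                {
                    "region": region,
                    "metabolite": metab,
                    "n_records": len(cell),
                    "crlb_mean": float(crlbs.mean()),
                    "crlb_min": float(crlbs.min()),
                    "crlb_max": float(crlbs.max()),
                }
            )
    if not keep.any():
        import warnings

        warnings.warn("CRLB policy excluded every record", stacklevel=2)
        return None, report
    return StudyTable(table.frame[keep]), report


_FIXTURES = {"table1", "table2", "table3"}


def load_paper_fixture(name: str) -> pd.DataFrame:
    """Load one of the transcribed printed summary tables shipped with the package.

    ``table1``: per-axis head-movement maxima (mean, SD, range; mm / deg).
    ``table2``: spectral quality and voxel tissue fractions per region.
    ``table3``: per (region, metabolite) mean concentration, CRLB summary and
    intra-/inter-subject SD and CV.  Every row carries a provenance column.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {sorted(_FIXTURES)}")
    ref = importlib.resources.files("mrsrepro") / "fixtures" / f"{name}.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)
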