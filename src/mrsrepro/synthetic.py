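"""Synthetic study generator with known ground truth.

No raw per-acquisition data were deposited by the study this package
analyses, so every pipeline stage is exercised on generated data whose
variance components are known:

* concentration tables follow an additive Gaussian hierarchy per
  (region, metabolite) cell,

      C_ismk = mu_km + b_ik + e_ismk,
      b ~ N(0, sigma_between^2),  e ~ N(0, sd_record^2),  truncated at 0,

  with defaults transcribed from the printed per-cell summary table:
  mu = printed mean concentration, sigma_within = printed intra-subject SD,
  sigma_between = sqrt(max(inter_SD^2 - intra_SD^2, 0)).  Per-record CRLBs
  are drawn around the printed cell means and modulate the noise SD
  multiplicatively (records with larger fitting error are noisier), so the
  synthetic CRLB-CV correlation mirrors the empirical one.
* segmentation phantoms are piecewise-constant probability maps whose tissue
  fractions inside each emitted voxel are known in closed form.
* movement traces draw each session's per-axis maximum from a Gamma law
  matched to the printed mean +/- SD of maxima and realize a random walk
  rescaled to that extreme, so recorded ground truth equals the session
  maximum exactly.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .movement import PARAMS, RealignmentSeries
from .study_data import StudyTable, load_paper_fixture
from .voxel_geometry import SegmentationMaps, VoxelSpec

__all__ = [
    "REGIONS",
    "METABOLITES",
    "DAYTIME_SLOTS",
    "SyntheticConfig",
    "GroundTruth",
    "generate_concentration_table",
    "generate_covariates",
    "generate_study",
    "generate_phantom",
    "generate_movement",
]

REGIONS = ["aMCC", "pgACC", "pIL", "pIR"]
METABOLITES = ["mI", "Cre", "Glu", "tCho", "tNAA", "Glx"]
#: four 90-minute afternoon/evening slots, decimal hours (start, end)
DAYTIME_SLOTS = [(16.0, 17.5), (17.5, 19.0), (19.0, 20.5), (20.5, 22.0)]


def _cell_defaults() -> pd.DataFrame:
    """Per-cell (mu, sigma_within, sigma_between, CRLB mean/min/max) defaults."""
    t3 = load_paper_fixture("table3")
    df = t3.set_index(["region", "metabolite"])
    out = pd.DataFrame(index=df.index)
    out["mu"] = df["mean_concentration"]
    out["sigma_within"] = df["intra_sd"]
    out["sigma_between"] = np.sqrt(
        np.maximum(df["inter_sd"] ** 2 - df["intra_sd"] ** 2, 0.0)
    )
    out["crlb_mean"] = df["mean_crlb_percent"]
    out["crlb_min"] = df["crlb_range_min"]
    out["crlb_max"] = df["crlb_range_max"]
    return out


def _region_tissue_means() -> pd.DataFrame:
    t2 = load_paper_fixture("table2")
    piv = t2.pivot(index="region", columns="quantity", values="mean")
    f = piv[["gm_fraction", "wm_fraction", "csf_fraction"]] / 100.0
    return f.div(f.sum(axis=1), axis=0)


def _movement_targets() -> pd.DataFrame:
    t1 = load_paper_fixture("table1")
    t1 = t1.copy()
    t1["param"] = ["tx", "ty", "tz", "pitch", "roll", "yaw"]
    return t1.set_index("param")[["mean", "sd"]]


@dataclass
class SyntheticConfig:
    """Study-design and variance-component parameters of the generator.

    Defaults emulate the empirical study: 9 subjects x 4 sessions x 4 regions
    x 6 metabolites, cell means and variance components taken from the
    printed summary table, tissue-fraction Dirichlet means from the printed
    region compositions, movement maxima at the printed per-axis scale, and
    four 90-minute daytime slots.
    """

    n_subjects: int = 9
    n_sessions: int = 4
    regions: list = field(default_factory=lambda: list(REGIONS))
    metabolites: list = field(default_factory=lambda: list(METABOLITES))
    cells: pd.DataFrame | None = None  # per-cell mu/sigmas/CRLB; default from fixture
    crlb_link_slope: float = 1.0  # relative noise-SD change per relative CRLB deviation
    tissue_concentration: float = 200.0  # Dirichlet concentration (sharpness)
    movement_scale: float = 1.0  # multiplier on the printed movement targets
    scans_per_session: int = 9  # realignment scans per session (1 reference + 8)
    daytime_slots: list = field(default_factory=lambda: list(DAYTIME_SLOTS))
    covariate_slopes: dict = field(
        default_factory=lambda: {"gm_wm_ratio": 0.0, "daytime_hours": 0.0, "displacement_d": 0.0}
    )
    seed: int = 0

    def __post_init__(self):
        if self.cells is None:
            self.cells = _cell_defaults().loc[
                [(r, m) for r in self.regions for m in self.metabolites]
            ]
        if (self.cells["mu"] <= 0).any():
            raise ValueError("all cell means mu must be > 0")
        if (self.cells[["sigma_within", "sigma_between"]] < 0).to_numpy().any():
            raise ValueError("all SDs must be >= 0")
        if self.tissue_concentration <= 0:
            raise ValueError("Dirichlet concentration must be > 0")
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("need at least 1 subject and 1 session")


@dataclass
class GroundTruth:
    """Realized latent quantities stored alongside every generated dataset."""

    config: SyntheticConfig
    subject_effects: pd.DataFrame | None = None  # subject x (region, metabolite)
    record_noise_sd: pd.Series | None = None  # per generated record
    covariate_slopes: dict | None = None
    tissue_fractions: pd.DataFrame | None = None  # true fractions per phantom voxel
    movement_maxima: pd.DataFrame | None = None  # session x parameter drawn extremes


def _gamma_draw(rng: np.random.Generator, mean: float, sd: float, size=None) -> np.ndarray:
    """Gamma with exact first two moments (degenerate cases handled)."""
    shape_ = () if size is None else size
    if mean <= 0:
        return np.zeros(shape_)
    if sd <= 0:
        return np.full(shape_, mean)
    k = (mean / sd) ** 2
    return rng.gamma(k, sd**2 / mean, size=size)


def generate_concentration_table(
    config: SyntheticConfig | None = None,
) -> tuple[StudyTable, GroundTruth]:
    """Draw a complete synthetic concentration table plus its ground truth.

    Per-record CRLBs come from a Gamma law matched to the cell's printed mean
    with SD = (range width)/4, clipped to the printed range; the record noise
    SD is sigma_within * (1 + slope * (CRLB - CRLB_mean)/CRLB_mean), floored
    at 10% of sigma_within, so E[noise SD] ~ sigma_within while noisier fits
    yield noisier concentrations.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    subjects = [f"s{i + 1:02d}" for i in range(config.n_subjects)]
    sessions = list(range(1, config.n_sessions + 1))

    # daytime per (subject, session): uniform within a randomly chosen slot
    slots = np.asarray(config.daytime_slots, dtype=float)
    slot_idx = rng.integers(0, len(slots), size=(config.n_subjects, config.n_sessions))
    daytime = slots[slot_idx, 0] + rng.uniform(size=slot_idx.shape) * (
        slots[slot_idx, 1] - slots[slot_idx, 0]
    )

    rows, noise_sds, b_rows = [], [], {}
    for (region, metab), cell in config.cells.iterrows():
        b = rng.normal(0.0, cell["sigma_between"], size=config.n_subjects)
        b_rows[(region, metab)] = b
        crlb_sd = (cell["crlb_max"] - cell["crlb_min"]) / 4.0
        for i, subj in enumerate(subjects):
            for s_i, sess in enumerate(sessions):
                crlb = float(
                    np.clip(
                        _gamma_draw(rng, cell["crlb_mean"], crlb_sd, None),
                        cell["crlb_min"], cell["crlb_max"],
                    )
                )
                rel = (crlb - cell["crlb_mean"]) / cell["crlb_mean"]
                sd = cell["sigma_within"] * max(1.0 + config.crlb_link_slope * rel, 0.1)
                conc = cell["mu"] + b[i] + rng.normal(0.0, sd)
                rows.append(
                    {
                        "subject": subj, "session": sess, "region": region,
                        "metabolite": metab,
                        "concentration": max(conc, 0.0),
                        "crlb_percent": crlb,
                        "daytime_hours": daytime[i, s_i],
                        "acquisition_order": s_i + 1,
                    }
                )
                noise_sds.append(sd)

    table = StudyTable(pd.DataFrame(rows))
    effects = pd.DataFrame(b_rows, index=subjects)
    truth = GroundTruth(
        config=config,
        subject_effects=effects,
        record_noise_sd=pd.Series(noise_sds),
        covariate_slopes=dict(config.covariate_slopes),
    )
    return table, truth


def generate_covariates(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Per-(subject, session, region) nuisance covariates for the ANCOVA.

    GM/WM ratios derive from Dirichlet tissue draws around the printed region
    compositions; daytime is a slot draw; the displacement covariate d is the
    magnitude of Gamma-drawn per-axis translation maxima.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    tissue = _region_tissue_means().loc[config.regions]
    targets = _movement_targets().loc[["tx", "ty", "tz"]] * config.movement_scale
    slots = np.asarray(config.daytime_slots, dtype=float)

    rows = []
    for subj in [f"s{i + 1:02d}" for i in range(config.n_subjects)]:
        for sess in range(1, config.n_sessions + 1):
            k = rng.integers(0, len(slots))
            day = float(slots[k, 0] + rng.uniform() * (slots[k, 1] - slots[k, 0]))
            trans = [
                _gamma_draw(rng, targets.loc[ax, "mean"], targets.loc[ax, "sd"], None)
                for ax in ("tx", "ty", "tz")
            ]
            d = float(np.sqrt(np.sum(np.square(trans))))
            for region in config.regions:
                alpha = tissue.loc[region].to_numpy() * config.tissue_concentration
                f = rng.dirichlet(alpha)
                rows.append(
                    {
                        "subject": subj, "session": sess, "region": region,
                        "gm_wm_ratio": f[0] / f[1], "daytime_hours": day,
                        "displacement_d": d,
                        "f_gm": f[0], "f_wm": f[1], "f_csf": f[2],
                    }
                )
    return pd.DataFrame(rows)


def generate_study(config: SyntheticConfig | None = None) -> dict:
    """Complete synthetic study: table, covariates, movement and ground truth.

    Nonzero ``covariate_slopes`` add slope * (covariate - mean(covariate)) to
    the matching concentrations, giving the ANCOVA a known signal to recover.
    """
    config = config or SyntheticConfig()
    table, truth = generate_concentration_table(config)
    covariates = generate_covariates(config)
    if any(v != 0 for v in config.covariate_slopes.values()):
        merged = table.frame.merge(
            covariates, on=["subject", "session", "region"], how="left", validate="m:1"
        )
        shift = np.zeros(len(merged))
        for name, slope in config.covariate_slopes.items():
            if slope:
                c = merged[name].to_numpy()
                shift += slope * (c - c.mean())
        frame = table.frame.copy()
        frame["concentration"] = np.maximum(frame["concentration"] + shift, 0.0)
        table = StudyTable(frame)
    sessions, mv_truth = generate_movement(config)
    truth.movement_maxima = mv_truth.movement_maxima
    return {"table": table, "covariates": covariates, "movement": sessions, "truth": truth}


# ---------------------------------------------------------------------------
# segmentation phantoms


def _centered_affine(shape, spacing: float = 1.0) -> np.ndarray:
    """Index->mm affine with the grid centroid at the scanner origin."""
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = spacing
    affine[:3, 3] = -spacing * (np.asarray(shape) - 1) / 2.0
    return affine


def generate_phantom(
    kind: str = "uniform",
    fractions: tuple = (1.0, 0.0, 0.0),
    shape: tuple = (40, 40, 40),
    spacing: float = 1.0,
    voxel_dims: tuple = (12.0, 12.0, 12.0),
) -> tuple[SegmentationMaps, list[VoxelSpec], GroundTruth]:
    """Piecewise-constant phantom with closed-form voxel tissue fractions.

    ``kind="uniform"`` paints constant (gm, wm, csf) probabilities
    everywhere; ``kind="half_gm_csf"`` splits the grid at its central plane
    (third axis) into pure GM below and pure CSF above, and centers the voxel
    on the interface so its true composition is (0.5, 0, 0.5).  The voxel
    must fit inside the phantom.
    """
    shape = tuple(int(s) for s in shape)
    affine = _centered_affine(shape, spacing)
    extent = np.asarray(shape) * spacing
    if (np.asarray(voxel_dims) > extent).any():
        raise ValueError("voxel does not fit inside the phantom grid")
    gm = np.zeros(shape)
    wm = np.zeros(shape)
    csf = np.zeros(shape)
    if kind == "uniform":
        f = np.asarray(fractions, dtype=float)
        if f.min() < 0 or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")
        gm[:], wm[:], csf[:] = f
        true = tuple(f)
    elif kind == "half_gm_csf":
        if shape[2] % 2:
            raise ValueError("half_gm_csf needs an even grid size on the third axis")
        if int(round(voxel_dims[2] / spacing)) % 2:
            raise ValueError("half_gm_csf needs an even voxel edge (in grid cells) on the third axis")
        half = shape[2] // 2
        gm[:, :, :half] = 1.0
        csf[:, :, half:] = 1.0
        true = (0.5, 0.0, 0.5)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    maps = SegmentationMaps(gm=gm, wm=wm, csf=csf, affine=affine)
    voxel = VoxelSpec(center=(0.0, 0.0, 0.0), dims=voxel_dims, region="phantom")
    truth = GroundTruth(
        config=SyntheticConfig(),
        tissue_fractions=pd.DataFrame(
            [{"region": "phantom", "f_gm": true[0], "f_wm": true[1], "f_csf": true[2]}]
        ),
    )
    return maps, [voxel], truth


# ---------------------------------------------------------------------------
# movement traces


def generate_movement(
    config: SyntheticConfig | None = None,
    n_sessions: int | None = None,
    seed: int | None = None,
) -> tuple[list[RealignmentSeries], GroundTruth]:
    """Realignment series whose per-session maxima are drawn, not emergent.

    For each session and parameter the maximum absolute excursion is drawn
    from a Gamma law matched to the target mean +/- SD (scaled by
    ``movement_scale``); the scan trace is a random walk rescaled so its
    extreme equals the drawn maximum.  Ground truth therefore agrees exactly
    with ``session_max_displacement``.
    """
    config = config or SyntheticConfig()
    if n_sessions is None:
        n_sessions = config.n_subjects * config.n_sessions
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    targets = _movement_targets() * config.movement_scale
    n_scans = config.scans_per_session

    sessions, maxima = [], []
    for s in range(n_sessions):
        arr = np.zeros((n_scans, 6))
        row = {}
        for j, param in enumerate(PARAMS):
            m = float(_gamma_draw(rng, targets.loc[param, "mean"], targets.loc[param, "sd"], None))
            walk = np.cumsum(rng.normal(size=n_scans - 1))
            peak = np.abs(walk).max()
            arr[1:, j] = walk * (m / peak) if peak > 0 and m > 0 else 0.0
            row[param] = m if m > 0 else 0.0
        sessions.append(RealignmentSeries(scans=arr, session=s + 1))
        maxima.append(row)
    truth = GroundTruth(config=config, movement_maxima=pd.DataFrame(maxima))
    return sessions, truth
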