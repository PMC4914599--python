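# mrsrepro

Test–retest reproducibility analysis for repeated-measures single-voxel
¹H-MRS metabolite quantification.

## The problem

Proton MR spectroscopy quantifies brain metabolites (myo-inositol, creatine,
glutamate, total choline, total NAA, Glx) from a single cuboid voxel of a few
millilitres. Before such measurements can be used in small, functionally
homogeneous cortical subregions — pregenual anterior cingulate (pgACC),
anterior midcingulate (aMCC), left/right posterior insula (pIL/pIR) — one has
to know how repeatable they are across scan days and across people, and
whether nuisance factors (voxel tissue composition, head movement, time of
day, spectral-fit uncertainty) drive the observed variability.

`mrsrepro` implements that analysis for a subjects × sessions × regions ×
metabolites design:

* **Quality control** — per-record Cramér–Rao lower bounds (CRLB, % of the
  fitted concentration) gate inclusion: a metabolite whose CRLB summary in a
  region fails the threshold (20% by convention) is excluded there.
* **CSF partial-volume correction** — metabolite signal arises from tissue,
  not cerebrospinal fluid, so concentrations are rescaled as
  `C = C₀ / (1 − F_CSF)`. The CSF fraction comes from rasterizing the
  oriented cuboid voxel into GM/WM/CSF probability maps (cell-center-in-
  cuboid test) and normalizing the summed probabilities.
* **Head movement** — six rigid-body realignment parameters per scan are
  summarized as per-session maximum excursions, averaged over sessions; the
  scalar covariate is `d = √(x² + y² + z²)` over the translations.
* **Variability** — the coefficient of variation CV = SD/mean × 100.
  Intra-subject: each subject's CV across sessions, averaged over subjects.
  Inter-subject: a resampling estimator — draw one session per subject,
  compute the cross-subject mean and SD, repeat 5000 times, average the
  means and SDs, and form 100 · avg(SD)/avg(mean); exact enumeration over
  all Sⁿ combinations replaces Monte Carlo when feasible.
* **Inference** — repeated-measures ANOVA over sessions, ANCOVA with
  participant and region fixed effects plus GM/WM-ratio, daytime and
  displacement covariates, and the Pearson correlation between mean CRLB
  and mean intra-subject CV.
* **Synthetic studies** — a generator with known variance components,
  segmentation phantoms with closed-form fractions, and movement traces
  with drawn extremes, so every stage is testable without any data download.

## Worked example

```python
from mrsrepro.study_data import load_paper_fixture
from mrsrepro.variability import CVResult, aggregate_report
from mrsrepro.inferential import crlb_cv_correlation

t3 = load_paper_fixture("table3")          # per-cell printed summary values
results = [CVResult(r.region, r.metabolite, r.mean_concentration,
                    r.intra_sd, r.intra_cv_percent,
                    r.inter_sd, r.inter_cv_percent, 9, 4)
           for r in t3.itertuples()]
rep = aggregate_report(results)
print(rep.region_means.round(2))
corr = crlb_cv_correlation(t3.set_index(["region", "metabolite"])["mean_crlb_percent"],
                           t3.set_index(["region", "metabolite"])["intra_cv_percent"])
print(f"r = {corr.r:.3f}, p = {corr.p:.2g}")
```

prints

```
        intra_cv_percent  inter_cv_percent
region
aMCC                5.37              9.05
pIL                 7.28             10.00
pIR                 8.22             10.55
pgACC               6.57              8.83
r = 0.801, p = 2.6e-06
```

i.e. session-to-session variability of 5–8% and between-person variability
of 9–11% per region (their small gap, 2.75% at study level, reflects the
homogeneous young-male sample), and a strong positive correlation between
fitting error and within-subject scatter: spectral-fit quality, not
movement or tissue composition, limits repeatability.

The numbered scripts under `analysis/` run the full sequence on a synthetic
study: `01_simulate.py` (generate), `02_tissue_fractions.py` (geometry and
CSF correction), `03_movement.py`, `04_variability.py`, `05_inference.py`.
A `mrsrepro` CLI exposes the same stages (`mrsrepro simulate|fractions|
correct|movement|variability|stats|report|run`).

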