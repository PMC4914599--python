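"""Generate the default synthetic study and write its raw inputs.

Emulates the empirical design - 9 subjects x 4 sessions x 4 cingulate/insular
regions x 6 metabolites - with between- and within-subject variance
components, CRLB-linked noise, Dirichlet tissue fractions and sub-2-mm
movement traces.  Outputs land in results/synthetic/ in the same formats the
readers consume (concentration CSV, covariate CSV, rp_*.txt realignment).
"""

from pathlib import Path

import numpy as np

from mrsrepro.study_data import write_concentration_table
from mrsrepro.synthetic import SyntheticConfig, generate_study

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20160621


def main() -> None:
    study = generate_study(SyntheticConfig(seed=SEED))
    OUT.mkdir(parents=True, exist_ok=True)
    write_concentration_table(study["table"], OUT / "concentrations.csv")
    study["covariates"].to_csv(OUT / "covariates.csv", index=False)
    for s in study["movement"]:
        arr = np.column_stack([s.scans[:, :3], np.deg2rad(s.scans[:, 3:])])
        np.savetxt(OUT / f"rp_session{s.session:03d}.txt", arr)
    t = study["table"]
    print(f"wrote {len(t)} records: {len(t.subjects)} subjects x "
          f"{len(t.sessions)} sessions x {len(t.regions)} regions x "
          f"{len(t.metabolites)} metabolites -> {OUT}")
    print(f"plus {len(study['covariates'])} covariate rows and "
          f"{len(study['movement'])} realignment series (seed {SEED})")


if __name__ == "__main__":
    main()
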