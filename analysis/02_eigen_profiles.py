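#!/usr/bin/env python
"""Eigenvalue profiles of the GRM across population sizes.

How many of the largest eigenvalues are needed to explain 10-98% of the
genomic variation, for 3000 / 6000 / 12000 genotyped animals?  The low
thresholds need strikingly few (a handful of eigenvalues reach 10%) and
barely move with population size; the high-threshold counts grow with
the number of animals.
"""

import sys
from pathlib import Path

from eigenblup import popsim
from eigenblup.experiment import eigen_profile_study

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 1) -> None:
    template = popsim.SimScenario.desk_profile()
    df = eigen_profile_study(
        template, n_genotyped=(3000, 6000, 12000), master_seed=seed
    )
    df.to_csv(OUT / "02_eigen_profiles.csv", index=False)
    wide = df.pivot_table(
        index="threshold", columns="n_genotyped_design", values="n_eigenvalues"
    )
    print("eigenvalues needed per explained-variance threshold:")
    print(wide.to_string())
    print(f"wrote {OUT}/02_eigen_profiles.csv")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
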