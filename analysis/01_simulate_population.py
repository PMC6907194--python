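#!/usr/bin/env python
"""Simulate the base study population and summarize its structure.

Runs the desk-scale scenario (6000 genotyped animals in generations
8-10, 10 sires x 1000 dams per recent generation, Ne ~ 40, 10 x 100 cM
genome) and writes per-generation counts, variance components and
marker-panel statistics to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from eigenblup import io as eio
from eigenblup import popsim

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main(seed: int = 1) -> None:
    scenario = popsim.SimScenario.desk_profile(n_genotyped=6000, seed=seed)
    eio.save_scenario(OUT / "01_scenario.yaml", scenario)
    print(f"simulating: Ne={scenario.effective_size:.1f}, "
          f"L={scenario.genome_length_morgan:.0f} Morgan, "
          f"{scenario.eff_snp} SNPs / {scenario.eff_qtl} QTL")
    sim = popsim.simulate(scenario)

    arch = sim.architecture
    per_gen = (
        pd.DataFrame(
            {
                "generation": sim.generation,
                "tbv": sim.tbv,
                "phenotyped": ~np.isnan(sim.phenotypes),
            }
        )
        .groupby("generation")
        .agg(n=("tbv", "size"), var_tbv=("tbv", "var"),
             n_phenotyped=("phenotyped", "sum"))
        .reset_index()
    )
    per_gen.to_csv(OUT / "01_per_generation.csv", index=False)

    p = sim.genotypes.allele_frequencies()
    maf = np.minimum(p, 1 - p)
    summary = pd.DataFrame(
        [
            ("n_genotyped", sim.genotypes.n_animals),
            ("n_markers_segregating", sim.genotypes.n_markers),
            ("mean_maf", round(float(maf.mean()), 4)),
            ("sigma_u2", round(arch.sigma_u2, 3)),
            ("sigma_e2", round(arch.sigma_e2, 3)),
            ("alpha", round(arch.alpha, 3)),
            ("heritability", arch.heritability),
            ("realized_var_phen_over_expected",
             round(float(np.nanvar(sim.phenotypes) * arch.heritability
                         / arch.sigma_u2), 4)),
            ("n_validation", len(sim.validation_idx)),
        ],
        columns=["quantity", "value"],
    )
    summary.to_csv(OUT / "01_population_summary.csv", index=False)
    print(per_gen.to_string(index=False))
    print(summary.to_string(index=False))
    print(f"wrote {OUT}/01_per_generation.csv and 01_population_summary.csv")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
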