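"""Study orchestration: replicated simulations x GRM options x thresholds.

One replicate is simulated once and then analysed under every GRM option
and heritability (a paired design): GBLUP with the standard blended GRM,
with the eigen-truncated GRM at the rank reaching each explained-variance
threshold, and with the APY inverse using that same rank as the number
of randomly chosen core animals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import accuracy as acc_mod
from . import gblup, grm, popsim

__all__ = [
    "StudyDesign",
    "replicate_seed",
    "scenario_for",
    "run_replicate",
    "run_study",
    "aggregate_study",
    "eigen_profile_study",
    "population_accuracy_from_pev",
]

DEFAULT_THRESHOLDS = (0.10, 0.30, 0.50, 0.70, 0.90, 0.95, 0.98)


@dataclass(frozen=True)
class StudyDesign:
    """Scenario grid, thresholds, GRM options and replication plan."""

    template: popsim.SimScenario
    heritabilities: tuple[float, ...] = (0.1, 0.3, 0.6, 0.9)
    n_genotyped: tuple[int, ...] = (6000,)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_replicates: int = 5
    grm_options: tuple[str, ...] = ("standard", "eig", "apy")
    master_seed: int = 20190516

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for t in self.thresholds:
            if not 0.0 < t <= 1.0:
                raise ValueError(f"threshold {t} outside (0, 1]")
        unknown = set(self.grm_options) - {"standard", "eig", "apy"}
        if unknown:
            raise ValueError(f"unknown grm options: {sorted(unknown)}")


def replicate_seed(master_seed: int, n_genotyped: int, replicate: int) -> int:
    """Deterministic per-cell seed below 2^31."""
    ss = np.random.SeedSequence([master_seed, n_genotyped, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def scenario_for(
    template: popsim.SimScenario, n_genotyped: int, seed: int
) -> popsim.SimScenario:
    """Template with a different population size.

    The dam count scales with the genotyped target (litter size stays 2
    and every animal of the last three generations is genotyped), which
    is how the study varies population size while 10 sires keep Ne ~ 40.
    The final historical size grows if needed so it can supply the first
    recent generation's breeders.
    """
    n_dams = max(template.n_sires_per_gen, n_genotyped // 6)
    return dataclasses.replace(
        template,
        n_genotyped=n_genotyped,
        n_dams_per_gen=n_dams,
        hist_size_end=max(template.hist_size_end, 3 * n_dams),
        seed=seed,
    )


def run_replicate(
    scenario: popsim.SimScenario,
    heritabilities: tuple[float, ...],
    thresholds: tuple[float, ...],
    grm_options: tuple[str, ...],
    analysis_seed: int | None = None,
) -> pd.DataFrame:
    """All GRM options and heritabilities on one simulated replicate.

    Returns a tidy frame with one row per (h2, option, threshold); the
    standard-GRM rows carry threshold NaN.
    """
    rng = np.random.default_rng(
        scenario.seed if analysis_seed is None else analysis_seed
    )
    sim = popsim.simulate(scenario)
    bundle = grm.build_grm(sim.genotypes)
    need_spectrum = bool({"eig", "apy"} & set(grm_options)) or bool(thresholds)
    counts = {}
    if need_spectrum:
        grm.eigendecompose(bundle)
        counts, _ = grm.variance_explained_profile(bundle.eigenvalues, thresholds)
    sims_h = {h2: sim.with_heritability(h2, rng) for h2 in heritabilities}

    def fit_rows(ginv: np.ndarray, option: str, threshold: float, rank: int):
        for h2, sim_h in sims_h.items():
            arch = sim_h.architecture
            tr = sim_h.training_idx
            fit = gblup.solve(
                gblup.GblupProblem(
                    y=sim_h.phenotypes[tr],
                    phen_idx=tr,
                    sigma_u2=arch.sigma_u2,
                    sigma_e2=arch.sigma_e2,
                    g_inverse=ginv,
                    grm_option=option,
                )
            )
            yield {
                "h2": h2,
                "n_genotyped": sim.genotypes.n_animals,
                "seed": scenario.seed,
                "grm_option": option,
                "threshold": threshold,
                "rank": rank,
                "accuracy": acc_mod.realized_accuracy(
                    fit.gebv, sim_h.tbv, sim_h.validation_idx
                ),
            }

    rows = []
    if "standard" in grm_options:
        ginv = gblup.grm_inverse_standard(bundle)
        rows.extend(fit_rows(ginv, "standard", np.nan, bundle.n_animals))
    # one inverse per threshold, shared across heritabilities
    for t in thresholds:
        r = counts[t]
        if "eig" in grm_options:
            rows.extend(
                fit_rows(gblup.grm_inverse_truncated(bundle, r), "eig", t, r)
            )
        if "apy" in grm_options:
            core = grm.select_core_random(bundle.animal_ids, r, rng)
            rows.extend(
                fit_rows(grm.apy_inverse(bundle, core).matrix(), "apy", t, r)
            )
    return pd.DataFrame(rows)


def run_study(design: StudyDesign) -> pd.DataFrame:
    """Replicated accuracy study over the whole design grid.

    Per-replicate failures are recorded and the study continues; more
    than one failed replicate aborts with a summary.
    """
    frames, failures = [], []
    for n_g in design.n_genotyped:
        for rep in range(design.n_replicates):
            seed = replicate_seed(design.master_seed, n_g, rep)
            scenario = scenario_for(design.template, n_g, seed)
            try:
                df = run_replicate(
                    scenario,
                    design.heritabilities,
                    design.thresholds,
                    design.grm_options,
                )
            except Exception as e:  # noqa: BLE001 - stage failures are data
                failures.append((n_g, rep, repr(e)))
                continue
            df["replicate"] = rep
            df["n_genotyped_design"] = n_g
            frames.append(df)
    if len(failures) > 1:
        raise RuntimeError(f"{len(failures)} replicates failed: {failures}")
    out = pd.concat(frames, ignore_index=True)
    out.attrs["failures"] = failures
    return out


def aggregate_study(df: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean and standard error per scenario x option x threshold."""
    keys = ["n_genotyped_design", "h2", "grm_option", "threshold"]
    g = df.groupby(keys, dropna=False)["accuracy"]
    agg = g.agg(["mean", "std", "count"]).reset_index()
    agg["se"] = agg["std"] / np.sqrt(agg["count"])
    return agg.rename(columns={"mean": "accuracy", "count": "n_replicates"})


def eigen_profile_study(
    template: popsim.SimScenario,
    n_genotyped: tuple[int, ...] = (3000, 6000, 12000),
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    n_replicates: int = 1,
    master_seed: int = 20190516,
) -> pd.DataFrame:
    """Eigenvalue counts per explained-variance threshold and population size."""
    rows = []
    for n_g in n_genotyped:
        for rep in range(n_replicates):
            seed = replicate_seed(master_seed, n_g, rep)
            scenario = scenario_for(template, n_g, seed)
            sim = popsim.simulate(scenario)
            bundle = grm.eigendecompose(
                grm.build_grm(sim.genotypes), vectors=False
            )
            counts, _ = grm.variance_explained_profile(
                bundle.eigenvalues, thresholds
            )
            n_eigen = bundle.n_animals
            for t, r in counts.items():
                rows.append(
                    {
                        "n_genotyped_design": n_g,
                        "n_animals": n_eigen,
                        "replicate": rep,
                        "threshold": t,
                        "n_eigenvalues": r,
                        "log10_n_eigenvalues": float(np.log10(r)),
                        "pct_of_all_eigenvalues": 100.0 * r / n_eigen,
                    }
                )
    return pd.DataFrame(rows)


def population_accuracy_from_pev(
    sim: popsim.SimOutput,
) -> dict[str, float]:
    """PEV-protocol validation: training-only equations, effective records.

    Rebuilds the GRM on the training (phenotyped) animals only, computes
    per-animal PEV by direct inversion of the left-hand side, converts to
    accuracies and effective genomic record counts, and returns the
    population-level approximation for unphenotyped validation animals.
    """
    tr = sim.training_idx
    geno_tr = grm.GenotypeMatrix(
        sim.genotypes.values[tr],
        sim.genotypes.animal_ids[tr],
        sim.genotypes.marker_ids,
    ).drop_monomorphic()
    bundle = grm.build_grm(geno_tr)
    arch = sim.architecture
    ginv = gblup.grm_inverse_standard(bundle)
    problem = gblup.GblupProblem(
        y=sim.phenotypes[tr],
        phen_idx=np.arange(len(tr)),
        sigma_u2=arch.sigma_u2,
        sigma_e2=arch.sigma_e2,
        g_inverse=ginv,
    )
    pev = gblup.pev_direct(problem)
    g_ii = bundle.blended().diagonal()
    acc_i = acc_mod.pev_accuracy(pev, arch.sigma_u2, g_ii)
    d_g = acc_mod.effective_genomic_records(acc_i, arch.alpha, d_p=1.0)
    mean_d_g = float(np.nanmean(d_g))
    return {
        "mean_training_accuracy": float(np.mean(acc_i)),
        "mean_effective_genomic_records": mean_d_g,
        "population_accuracy": acc_mod.population_accuracy(mean_d_g, arch.alpha),
    }
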