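"""Reading and writing the delimited tables the analyses exchange.

Genotypes travel as PLINK ``.raw``-style tables (six metadata columns,
then one 0/1/2 column per marker) or as plain ``id`` + marker tables;
pedigree, phenotype and map tables are whitespace/CSV frames.  Scenario
files are YAML mappings of :class:`~eigenblup.popsim.SimScenario` fields.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grm import GenotypeMatrix
from .popsim import GeneticMap, SimOutput, SimScenario

__all__ = [
    "write_genotypes_raw",
    "read_genotypes_raw",
    "read_genotypes_table",
    "write_pedigree",
    "read_pedigree",
    "write_phenotypes",
    "write_marker_map",
    "load_scenario",
    "save_scenario",
    "write_sim_output",
]

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_genotypes_raw(path: str | Path, genotypes: GenotypeMatrix) -> None:
    """PLINK ``.raw``-compatible layout: metadata columns then markers."""
    n = genotypes.n_animals
    meta = pd.DataFrame(
        {
            "FID": np.zeros(n, dtype=int),
            "IID": genotypes.animal_ids,
            "PAT": np.zeros(n, dtype=int),
            "MAT": np.zeros(n, dtype=int),
            "SEX": np.zeros(n, dtype=int),
            "PHENOTYPE": np.full(n, -9),
        }
    )
    markers = pd.DataFrame(
        genotypes.values, columns=[str(m) for m in genotypes.marker_ids]
    )
    pd.concat([meta, markers], axis=1).to_csv(path, sep=" ", index=False)


def read_genotypes_raw(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _RAW_META if c not in df.columns]
    if missing:
        raise ValueError(f"not a PLINK raw table; missing columns {missing}")
    marker_cols = [c for c in df.columns if c not in _RAW_META]
    return GenotypeMatrix(
        values=df[marker_cols].to_numpy(dtype=np.uint8),
        animal_ids=df["IID"].to_numpy(),
        marker_ids=np.array(marker_cols),
    )


def read_genotypes_table(path: str | Path, sep: str = ",") -> GenotypeMatrix:
    """Plain delimited table: first column animal id, remaining markers."""
    df = pd.read_csv(path, sep=sep)
    return GenotypeMatrix(
        values=df.iloc[:, 1:].to_numpy(dtype=np.uint8),
        animal_ids=df.iloc[:, 0].to_numpy(),
        marker_ids=np.array(df.columns[1:]),
    )


def write_pedigree(path: str | Path, pedigree: pd.DataFrame) -> None:
    pedigree[["id", "sire", "dam", "generation"]].to_csv(path, index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_phenotypes(path: str | Path, sim: SimOutput) -> None:
    pd.DataFrame(
        {
            "id": sim.genotypes.animal_ids,
            "generation": sim.generation,
            "tbv": sim.tbv,
            "phenotype": sim.phenotypes,
        }
    ).to_csv(path, index=False)


def write_marker_map(path: str | Path, genome: GeneticMap) -> None:
    snp = genome.snp_indices
    pd.DataFrame(
        {
            "chrom": genome.chrom[snp] + 1,
            "cM": genome.pos_morgan[snp] * 100.0,
            "id": snp,
        }
    ).to_csv(path, index=False)


def save_scenario(path: str | Path, scenario: SimScenario) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(scenario), fh, sort_keys=False)


def load_scenario(path: str | Path) -> SimScenario:
    with open(path) as fh:
        fields = yaml.safe_load(fh)
    return SimScenario(**fields)


def write_sim_output(outdir: str | Path, sim: SimOutput) -> None:
    """Genotypes, pedigree and phenotype/TBV tables under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes_raw(outdir / "genotypes.raw", sim.genotypes)
    write_pedigree(outdir / "pedigree.csv", sim.pedigree)
    write_phenotypes(outdir / "phenotypes.csv", sim)
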