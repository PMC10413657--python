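"""TSV readers/writers for the package's tabular interchange formats.

Column dictionaries (all files are tab-separated with a header row):

gene table
    gene_id, inheritance (AD/AR/XLD/XLR/none), mechanism
    (DN/GOF/LOF/unclassified), coassembly (True/False), oligomer_class,
    symmetry, abundance_ppm (may be empty), functional_class, chromosome
variant table
    protein_id, position (1-based), ref, alt, pathogenic (True/False),
    ddg (kcal/mol, may be empty), plddt (0-100, may be empty)
interface profile
    chain, residue_index (1-based), area_A2 (ΔSASA in Å²)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .interfaces import InterfaceProfile
from .stats import GeneRecord
from .variants import MutationSet

GENE_COLUMNS = [
    "gene_id",
    "inheritance",
    "mechanism",
    "coassembly",
    "oligomer_class",
    "symmetry",
    "abundance_ppm",
    "functional_class",
    "chromosome",
]

VARIANT_COLUMNS = ["protein_id", "position", "ref", "alt", "pathogenic", "ddg", "plddt"]


def write_gene_table(records: list[GeneRecord], path: str) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "inheritance": r.inheritance,
            "mechanism": r.mechanism,
            "coassembly": r.coassembly,
            "oligomer_class": r.oligomer_class,
            "symmetry": r.symmetry,
            "abundance_ppm": r.abundance_ppm,
            "functional_class": r.functional_class,
            "chromosome": r.chromosome,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_gene_table(path: str) -> list[GeneRecord]:
    # "NA" is a legitimate symmetry label, not a missing value
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chromosome": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"gene table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        ab = row.abundance_ppm
        records.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                inheritance=str(row.inheritance),
                mechanism=str(row.mechanism),
                coassembly=bool(row.coassembly),
                oligomer_class=str(row.oligomer_class),
                symmetry=str(row.symmetry),
                abundance_ppm=None if pd.isna(ab) else float(ab),
                functional_class=str(row.functional_class),
                chromosome=str(row.chromosome),
            )
        )
    return records


def write_variant_table(mutations: MutationSet, path: str) -> None:
    n = len(mutations.positions)
    df = pd.DataFrame(
        {
            "protein_id": [mutations.protein_id] * n,
            "position": mutations.positions,
            "ref": ["X"] * n,
            "alt": ["X"] * n,
            "pathogenic": mutations.pathogenic,
            "ddg": mutations.ddg if mutations.ddg is not None else [np.nan] * n,
            "plddt": mutations.plddt if mutations.plddt is not None else [np.nan] * n,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_variant_table(path: str) -> dict[str, MutationSet]:
    """Read a variant TSV into one MutationSet per protein_id."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"variant table missing columns: {missing}")
    out = {}
    for pid, grp in df.groupby("protein_id", sort=True):
        ddg = grp["ddg"].to_numpy(dtype=float)
        plddt = grp["plddt"].to_numpy(dtype=float)
        out[str(pid)] = MutationSet(
            protein_id=str(pid),
            positions=grp["position"].to_numpy(dtype=int),
            pathogenic=grp["pathogenic"].to_numpy(dtype=bool),
            ddg=None if np.isnan(ddg).all() else ddg,
            plddt=None if np.isnan(plddt).all() else plddt,
        )
    return out


def write_interface_profile(profile: InterfaceProfile, path: str) -> None:
    pd.DataFrame(
        {
            "chain": profile.chain_id,
            "residue_index": profile.residue_ids,
            "area_A2": profile.per_residue_area,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_interface_profile(path: str, length: int | None = None) -> InterfaceProfile:
    df = pd.read_csv(path, sep="\t")
    for col in ("chain", "residue_index", "area_A2"):
        if col not in df.columns:
            raise ValidationError(f"profile table missing column {col!r}")
    rid = df["residue_index"].to_numpy(dtype=int)
    return InterfaceProfile(
        chain_id=str(df["chain"].iloc[0]),
        length=int(length if length is not None else rid.max()),
        residue_ids=rid,
        per_residue_area=df["area_A2"].to_numpy(dtype=float),
    )
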