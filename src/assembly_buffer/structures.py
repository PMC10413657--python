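"""In-memory representation of multimeric protein structures.

A :class:`ComplexStructure` is a list of chains; each chain stores flat
per-atom arrays (coordinates in Å, van der Waals radii in Å, the 1-based
canonical residue index of each atom) plus an optional per-residue
confidence score (pLDDT, 0-100) for predicted models.

Reading PDB and mmCIF files goes through gemmi; the first model of the file
is used, so biological-assembly extraction must happen upstream.  Synthetic
Cα-only structures are written as minimal PDB ATOM records so they round-trip
through any standard reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

# Van der Waals radii (Å) keyed by element symbol; a conservative generic
# fallback is used for anything else (metals, selenium, ...).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.80

#: Radius used for Cα-only synthetic backbones (carbon).
CA_RADIUS = 1.70


@dataclass
class Chain:
    """One polypeptide chain as flat per-atom arrays.

    ``atom_residue`` maps every atom to its 1-based canonical residue index;
    ``residue_ids`` is the strictly increasing list of indices present.
    ``plddt`` (optional) is per-residue, aligned with ``residue_ids``.
    """

    chain_id: str
    coords: np.ndarray
    radii: np.ndarray
    atom_residue: np.ndarray
    plddt: np.ndarray | None = None
    residue_ids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.atom_residue = np.asarray(self.atom_residue, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(f"chain {self.chain_id}: coords must be (n, 3)")
        n = len(self.coords)
        if n == 0:
            raise ValidationError(f"chain {self.chain_id}: empty chain")
        if len(self.radii) != n or len(self.atom_residue) != n:
            raise ValidationError(f"chain {self.chain_id}: array length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"chain {self.chain_id}: non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValidationError(f"chain {self.chain_id}: radii must be positive")
        ids = np.unique(self.atom_residue)
        # np.unique sorts, so strict monotonicity is guaranteed; what we must
        # check is that the original per-atom order never steps backwards.
        if np.any(np.diff(self.atom_residue) < 0):
            raise ValidationError(
                f"chain {self.chain_id}: residue indices must be non-decreasing"
            )
        self.residue_ids = ids
        if self.plddt is not None:
            self.plddt = np.asarray(self.plddt, dtype=float)
            if len(self.plddt) != len(ids):
                raise ValidationError(
                    f"chain {self.chain_id}: plddt must align with residues"
                )

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def length(self) -> int:
        """Canonical sequence length (highest residue index present)."""
        return int(self.residue_ids[-1])

    def ca_coords(self) -> np.ndarray:
        """One representative coordinate per residue (centroid of its atoms).

        For Cα-only chains this is the Cα position itself.
        """
        out = np.empty((self.n_residues, 3))
        for k, rid in enumerate(self.residue_ids):
            out[k] = self.coords[self.atom_residue == rid].mean(axis=0)
        return out


@dataclass
class ComplexStructure:
    """A multimeric complex: one or more chains with unique chain IDs."""

    chains: list[Chain]

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValidationError("structure has no chains")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate chain ids: {ids}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ValidationError(f"no chain {chain_id!r}; have {self.chain_ids}")

    def subset(self, chain_ids: list[str]) -> "ComplexStructure":
        return ComplexStructure([self.chain(cid) for cid in chain_ids])


def _radius_for(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_RADIUS)


def read_structure(path: str, plddt_from_bfactor: bool = False) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    Uses the first model. Waters and other non-polymer residues are dropped.
    With ``plddt_from_bfactor=True`` the B-factor column is interpreted as a
    per-residue confidence score (AlphaFold convention) and averaged per
    residue.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_waters()
    st.setup_entities()
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        coords, radii, res_idx, bf = [], [], [], {}
        for i, res in enumerate(ch, start=1):
            seqid = res.seqid.num if res.seqid.num is not None else i
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(_radius_for(atom.element.name))
                res_idx.append(seqid)
                bf.setdefault(seqid, []).append(atom.b_iso)
        if not coords:
            continue
        plddt = None
        if plddt_from_bfactor:
            ids = sorted(bf)
            plddt = np.array([float(np.mean(bf[r])) for r in ids])
        chains.append(
            Chain(
                chain_id=ch.name,
                coords=np.array(coords),
                radii=np.array(radii),
                atom_residue=np.array(res_idx),
                plddt=plddt,
            )
        )
    return ComplexStructure(chains)


def write_pdb(structure: ComplexStructure, path: str) -> None:
    """Write minimal PDB ATOM records (one CA atom per stored atom).

    Intended for the synthetic Cα-only fixtures; atom and residue names are
    generic (CA / GLY), coordinates keep 3 decimals as per PDB format.
    """
    lines = []
    serial = 1
    for chain in structure.chains:
        for (x, y, z), rid in zip(chain.coords, chain.atom_residue):
            lines.append(
                f"ATOM  {serial:>5}  CA  GLY {chain.chain_id:>1}{rid:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
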