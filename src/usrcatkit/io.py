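"""Conformer input and descriptor-table round-tripping.

Conformers are read from multi-record SDF files (V2000) or from SMILES lists
that are embedded into 3D with the chemistry backend.  Consecutive SDF records
sharing a title are treated as conformers of one molecule, numbered in file
order starting at 0 (conformer 0 of an energy-sorted ensemble is the lowest
energy conformer).  Descriptor tables are plain CSV with the fixed header
``mol_id,conf_id,m1,...,m60`` and moments printed with repr-level precision so
that a write/read round trip is bit-faithful.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "ConformerRecord",
    "DescriptorRow",
    "read_conformers",
    "write_descriptor_table",
    "read_descriptor_table",
    "conformer_from_rdkit",
    "write_conformers_sdf",
]

SUBSET_SD_TAG = "pharmacophore_subsets"


@dataclass
class ConformerRecord:
    """One 3D conformer of a molecule.

    ``mol`` optionally carries the chemistry backend's molecular graph (with
    connectivity and aromaticity perceived) for SMARTS atom typing; synthetic
    point-cloud records leave it ``None``.
    """

    mol_id: str
    conf_id: int
    coords: np.ndarray  # (N, 3) float64, Å
    elements: list[str]
    is_hydrogen: np.ndarray  # (N,) bool
    mol: Optional[object] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.is_hydrogen = np.asarray(self.is_hydrogen, dtype=bool)
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError(f"conformer {self.mol_id}/{self.conf_id} has no atoms")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.elements) != n or self.is_hydrogen.shape[0] != n:
            raise ValueError(
                "coords, elements and is_hydrogen must have identical length"
            )
        if self.conf_id < 0:
            raise ValueError("conf_id must be nonnegative")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class DescriptorRow:
    """One descriptor-table row: a conformer identity plus its 60 moments."""

    mol_id: str
    conf_id: int
    moments: np.ndarray

    def __post_init__(self) -> None:
        self.moments = np.asarray(self.moments, dtype=np.float64)
        if self.moments.shape != (60,):
            raise ValueError("moments must hold exactly 60 values")
        if not np.all(np.isfinite(self.moments)):
            raise ValueError("moments must be finite")


def conformer_from_rdkit(mol, mol_id: str, conf_id: int) -> ConformerRecord:
    """Build a :class:`ConformerRecord` from an RDKit molecule with one
    conformer, keeping the graph for downstream SMARTS typing."""
    conf = mol.GetConformer()
    coords = np.array(
        [[p.x, p.y, p.z] for p in (conf.GetAtomPosition(i) for i in range(mol.GetNumAtoms()))],
        dtype=np.float64,
    )
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    is_h = np.array([a.GetAtomicNum() == 1 for a in mol.GetAtoms()], dtype=bool)
    return ConformerRecord(
        mol_id=mol_id, conf_id=conf_id, coords=coords, elements=elements,
        is_hydrogen=is_h, mol=mol,
    )


def _read_sdf(path: Path, group_by_title: bool) -> list[ConformerRecord]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    records: list[ConformerRecord] = []
    conf_counter: dict[str, int] = {}
    prev_title: str | None = None
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparsable SDF record at index {i} in {path}")
        if mol.GetNumConformers() == 0:
            raise ValueError(f"SDF record {i} in {path} has no 3D coordinates")
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        mol_id = title.strip() or f"record_{i}"
        if not group_by_title:
            mol_id = mol_id if not title.strip() else f"{mol_id}#{i}"
            conf_id = 0
        else:
            if mol_id != prev_title:
                conf_counter[mol_id] = conf_counter.get(mol_id, 0)
            conf_id = conf_counter.get(mol_id, 0)
            conf_counter[mol_id] = conf_id + 1
            prev_title = mol_id
        records.append(conformer_from_rdkit(mol, mol_id, conf_id))
    return records


def _read_smiles(path: Path, embed_seed: int) -> list[ConformerRecord]:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    records: list[ConformerRecord] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    idx = 0
    for lineno, line in enumerate(lines, start=1):
        if not line:
            continue
        parts = line.split(None, 1)
        smi = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"smiles_{idx}"
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES at line {lineno}: {smi!r}")
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = embed_seed
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise ValueError(
                f"no 3D coordinates: embedding failed for SMILES at line {lineno}"
            )
        records.append(conformer_from_rdkit(mol, mol_id, 0))
        idx += 1
    return records


def read_conformers(
    path,
    fmt: str = "sdf",
    group_by_title: bool = True,
    embed_seed: int = 20120417,
) -> list[ConformerRecord]:
    """Read conformers from an SDF or SMILES file.

    For ``fmt="sdf"`` each record must carry 3D coordinates; consecutive
    records with an identical title become conformers 0, 1, ... of one
    molecule unless ``group_by_title`` is disabled.  For ``fmt="smiles"`` one
    conformer per molecule is embedded deterministically (``embed_seed``).
    Hydrogens are read and flagged, never silently dropped.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.stat().st_size == 0:
        return []
    if fmt == "sdf":
        return _read_sdf(p, group_by_title)
    if fmt == "smiles":
        return _read_smiles(p, embed_seed)
    raise ValueError(f"unknown format: {fmt!r}")


_HEADER = ["mol_id", "conf_id"] + [f"m{i}" for i in range(1, 61)]


def write_descriptor_table(rows: Iterable[DescriptorRow], path) -> None:
    """Write a descriptor table as CSV (``mol_id,conf_id,m1..m60``).

    Moments are printed with ``repr``-level precision (17 significant digits)
    so that reading the file back reproduces them bit-for-bit.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("refusing to write an empty descriptor table")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for row in rows:
            writer.writerow(
                [row.mol_id, row.conf_id] + [repr(float(m)) for m in row.moments]
            )


def read_descriptor_table(path) -> list[DescriptorRow]:
    """Read a descriptor table written by :func:`write_descriptor_table`."""
    out: list[DescriptorRow] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _HEADER:
            raise ValueError(f"{path}: bad header, expected {','.join(_HEADER[:3])},...")
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != 62:
                raise ValueError(
                    f"{path}:{lineno}: expected 62 columns (mol_id, conf_id, 60 "
                    f"moments), got {len(rec)}"
                )
            out.append(
                DescriptorRow(
                    mol_id=rec[0],
                    conf_id=int(rec[1]),
                    moments=np.array([float(x) for x in rec[2:]], dtype=np.float64),
                )
            )
    return out


def write_conformers_sdf(records, path, subsets_map=None) -> None:
    """Write conformer records to an SDF file.

    Records without a molecular graph (synthetic point clouds) are written as
    bond-less molecules.  If ``subsets_map`` maps ``(mol_id, conf_id)`` to a
    pharmacophore subset object, the subsets are stored as a JSON SD tag so a
    later read can recover the labels without SMARTS typing.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for rec in records:
            if rec.mol is not None:
                mol = Chem.Mol(rec.mol)
            else:
                rw = Chem.RWMol()
                for sym in rec.elements:
                    rw.AddAtom(Chem.Atom(sym))
                conf = Chem.Conformer(rec.n_atoms)
                for i, (x, y, z) in enumerate(rec.coords):
                    conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
                rw.AddConformer(conf)
                mol = rw.GetMol()
                mol.UpdatePropertyCache(strict=False)
            mol.SetProp("_Name", rec.mol_id)
            if subsets_map is not None:
                ss = subsets_map.get((rec.mol_id, rec.conf_id))
                if ss is not None:
                    mol.SetProp(
                        SUBSET_SD_TAG,
                        json.dumps(
                            {
                                "hydrophobic": sorted(ss.hydrophobic),
                                "aromatic": sorted(ss.aromatic),
                                "donor": sorted(ss.donor),
                                "acceptor": sorted(ss.acceptor),
                            }
                        ),
                    )
            writer.write(mol)
    finally:
        writer.close()
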