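"""Seeded synthetic fixtures: labeled point clouds, shape twins and
active/decoy benchmark sets.

The generators bypass chemistry entirely: a "conformer" is a labeled 3D point
cloud (coordinates in Å plus per-atom pharmacophore labels), which is all the
moment machinery sees.  The central construction is the *shape twin* -- a
cloud with identical coordinates but permuted labels.  Twins are
indistinguishable to the all-atom (classic USR) moments by construction yet
differ in the pharmacophore blocks, which isolates exactly the discrimination
problem the subset moments exist to solve: screening libraries can contain
molecules with near-identical coordinate distributions but unrelated
pharmacophoric profiles.

``build_benchmark_set`` assembles a target set from one template cloud:
actives are label-preserving jittered copies, decoys a mixture of independent
clouds and label-permuted twins at matched jitter.  With ``twin_fraction=1``
and decoy jitter equal to active jitter, shape alone carries no signal and
only the labels separate actives from decoys.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import ConformerRecord
from .atom_typing import SUBSET_NAMES, PharmacophoreSubsets
from .benchmark import BenchMolecule, TargetSet

__all__ = [
    "FixtureSpec",
    "generate_cloud",
    "make_shape_twin",
    "build_benchmark_set",
    "write_benchmark_dir",
]

#: Per-class probability that an atom carries each pharmacophore label.
#: Roughly drug-like proportions: mostly apolar atoms, aromatic rings common,
#: acceptors somewhat more frequent than donors.
DEFAULT_LABEL_PROBS = {
    "hydrophobic": 0.40,
    "aromatic": 0.30,
    "donor": 0.15,
    "acceptor": 0.20,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic generators.

    ``n_atoms`` is an inclusive (low, high) range sampled per cloud.
    ``jitter_sigma`` (Å) is the coordinate noise of conformer 0; later
    conformers of a molecule get proportionally larger jitter, standing in
    for an energy-sorted ensemble (conformer 0 = least perturbed = LEC).
    ``twin_fraction`` is the fraction of decoys built as label-permuted shape
    twins of the actives' template; the rest are independent clouds.
    """

    seed: int
    n_atoms: tuple[int, int] = (10, 25)
    coordinate_model: str = "gaussian_blob"
    label_probs: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_PROBS))
    jitter_sigma: float = 0.15
    n_actives: int = 10
    n_decoys: int = 200
    twin_fraction: float = 1.0
    n_conformers: int = 3
    target_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_atoms[0] < 1 or self.n_atoms[1] < self.n_atoms[0]:
            raise ValueError("n_atoms must be a valid (low, high) range with low >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not (0.0 <= self.twin_fraction <= 1.0):
            raise ValueError("twin_fraction must lie in [0, 1]")
        for name, p in self.label_probs.items():
            if name not in SUBSET_NAMES:
                raise ValueError(f"unknown subset in label_probs: {name!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"label probability for {name} outside [0, 1]")
        if self.n_actives < 0 or self.n_decoys < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")


def _coordinates(model: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if model == "gaussian_blob":
        return rng.normal(0.0, 2.0, size=(n, 3))
    if model == "chain":
        # extended chain: ~1.5 Å spacing along x with small lateral wobble
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * 1.5
        coords[:, 1:] = rng.normal(0.0, 0.3, size=(n, 2))
        return coords
    if model == "ring_chain":
        n_ring = min(6, n)
        angles = 2.0 * math.pi * np.arange(n_ring) / 6.0
        ring = np.stack(
            [1.4 * np.cos(angles), 1.4 * np.sin(angles), np.zeros(n_ring)], axis=1
        )
        n_tail = n - n_ring
        tail = np.zeros((n_tail, 3))
        tail[:, 0] = 1.4 + (np.arange(n_tail) + 1) * 1.5
        tail[:, 1:] = rng.normal(0.0, 0.3, size=(n_tail, 2))
        return np.vstack([ring, tail])
    raise ValueError(f"unknown coordinate model: {model!r}")


def _draw_labels(
    n: int, label_probs: dict, rng: np.random.Generator
) -> PharmacophoreSubsets:
    members = {}
    for name in SUBSET_NAMES:
        p = label_probs.get(name, 0.0)
        members[name] = frozenset(np.flatnonzero(rng.random(n) < p).tolist())
    return PharmacophoreSubsets(**members)


def generate_cloud(
    spec: FixtureSpec,
    mol_id: str,
    conf_id: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ConformerRecord, PharmacophoreSubsets]:
    """One labeled point cloud, a pure function of (spec, mol_id, conf_id).

    The default random stream is derived from the spec seed together with the
    identifiers, so regenerating the same cloud twice is reproducible without
    sharing generator state.
    """
    if rng is None:
        rng = np.random.default_rng(
            [spec.seed, zlib.crc32(mol_id.encode()) & 0x7FFFFFFF, conf_id]
        )
    n = int(rng.integers(spec.n_atoms[0], spec.n_atoms[1] + 1))
    coords = _coordinates(spec.coordinate_model, n, rng)
    subsets = _draw_labels(n, spec.label_probs, rng)
    record = ConformerRecord(
        mol_id=mol_id,
        conf_id=conf_id,
        coords=coords,
        elements=["C"] * n,
        is_hydrogen=np.zeros(n, dtype=bool),
    )
    return record, subsets


def _label_tuples(subsets: PharmacophoreSubsets, n: int) -> list[tuple[bool, ...]]:
    return [
        tuple(i in getattr(subsets, name) for name in SUBSET_NAMES) for i in range(n)
    ]


def _subsets_from_tuples(tuples: list[tuple[bool, ...]]) -> PharmacophoreSubsets:
    return PharmacophoreSubsets(
        **{
            name: frozenset(i for i, t in enumerate(tuples) if t[k])
            for k, name in enumerate(SUBSET_NAMES)
        }
    )


def permute_labels(
    subsets: PharmacophoreSubsets, n: int, rng: np.random.Generator, max_tries: int = 200
) -> PharmacophoreSubsets:
    """Permute per-atom label assignments so that at least one subset changes.

    Raises if every atom carries the identical label tuple (no permutation
    can change any subset).
    """
    tuples = _label_tuples(subsets, n)
    if len(set(tuples)) < 2:
        raise ValueError(
            "cannot permute labels: all atoms carry identical label assignments"
        )
    for _ in range(max_tries):
        perm = rng.permutation(n)
        permuted = [tuples[i] for i in perm]
        candidate = _subsets_from_tuples(permuted)
        if candidate != subsets:
            return candidate
    raise RuntimeError("failed to find a label permutation that changes a subset")


def make_shape_twin(
    record: ConformerRecord,
    subsets: PharmacophoreSubsets,
    seed: int,
) -> tuple[ConformerRecord, PharmacophoreSubsets]:
    """A shape twin: identical coordinates, permuted pharmacophore labels.

    The twin's classic 12-moment vector equals the original's exactly (same
    coordinates); the full 60-moment vector differs because at least one
    subset changes.
    """
    if record.n_atoms < 2:
        raise ValueError("a shape twin needs at least 2 atoms")
    if all(not getattr(subsets, name) for name in SUBSET_NAMES):
        raise ValueError("a shape twin needs at least one nonempty subset")
    rng = np.random.default_rng(seed)
    twin_subsets = permute_labels(subsets, record.n_atoms, rng)
    twin = ConformerRecord(
        mol_id=f"{record.mol_id}_twin",
        conf_id=record.conf_id,
        coords=record.coords.copy(),
        elements=list(record.elements),
        is_hydrogen=record.is_hydrogen.copy(),
    )
    return twin, twin_subsets


def _jittered_conformers(
    base: np.ndarray,
    mol_id: str,
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> list[ConformerRecord]:
    n = base.shape[0]
    records = []
    for k in range(spec.n_conformers):
        sigma = spec.jitter_sigma * (1 + k)  # conformer 0 = least perturbed
        coords = base + rng.normal(0.0, sigma, size=base.shape)
        records.append(
            ConformerRecord(
                mol_id=mol_id,
                conf_id=k,
                coords=coords,
                elements=["C"] * n,
                is_hydrogen=np.zeros(n, dtype=bool),
            )
        )
    return records


def build_benchmark_set(spec: FixtureSpec) -> TargetSet:
    """Assemble a synthetic active/decoy target set from one template cloud.

    Actives are jittered copies of the template that keep its labels; decoys
    are ``twin_fraction`` label-permuted twins at the same jitter plus
    independent clouds for the remainder.  Requires at least two actives
    (one query plus one retrievable) and one decoy.
    """
    if spec.n_actives < 2:
        raise ValueError("need n_actives >= 2 (one query plus one retrievable active)")
    if spec.n_decoys < 1:
        raise ValueError("need n_decoys >= 1")
    rng = np.random.default_rng([spec.seed, 0xBE7C])

    # Template with a permutable label assignment when twins are requested.
    for attempt in range(64):
        template, template_subsets = generate_cloud(
            spec, f"{spec.target_id}_template", rng=rng
        )
        tuples = _label_tuples(template_subsets, template.n_atoms)
        if spec.twin_fraction == 0.0 or len(set(tuples)) >= 2:
            break
    else:
        raise RuntimeError("could not draw a template with permutable labels")

    actives = []
    for i in range(spec.n_actives):
        mol_id = f"{spec.target_id}_active_{i:03d}"
        confs = _jittered_conformers(template.coords, mol_id, spec, rng)
        actives.append(
            BenchMolecule(
                mol_id=mol_id,
                conformers=confs,
                subsets=[template_subsets] * len(confs),
            )
        )

    n_twins = int(round(spec.twin_fraction * spec.n_decoys))
    decoys = []
    for i in range(spec.n_decoys):
        mol_id = f"{spec.target_id}_decoy_{i:03d}"
        if i < n_twins:
            # shape twin at matched jitter: template geometry, permuted labels
            subsets = permute_labels(template_subsets, template.n_atoms, rng)
            confs = _jittered_conformers(template.coords, mol_id, spec, rng)
        else:
            base, subsets = generate_cloud(spec, mol_id, rng=rng)
            confs = _jittered_conformers(base.coords, mol_id, spec, rng)
        decoys.append(
            BenchMolecule(
                mol_id=mol_id, conformers=confs, subsets=[subsets] * len(confs)
            )
        )

    return TargetSet(target_id=spec.target_id, actives=actives, decoys=decoys)


def write_benchmark_dir(ts: TargetSet, directory) -> None:
    """Write a target set as the on-disk layout the benchmark CLI consumes:
    ``actives.sdf`` and ``decoys.sdf`` (multi-conformer, subsets stored as an
    SD tag)."""
    from pathlib import Path

    from .io import write_conformers_sdf

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, mols in (("actives.sdf", ts.actives), ("decoys.sdf", ts.decoys)):
        records = []
        subsets_map = {}
        for mol in mols:
            for k, conf in enumerate(mol.conformers):
                records.append(conf)
                if mol.subsets:
                    subsets_map[(conf.mol_id, conf.conf_id)] = mol.subsets[k]
        write_conformers_sdf(records, d / name, subsets_map=subsets_map)
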