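"""Retrospective virtual-screening benchmark machinery.

The benchmark follows the standard active/decoy protocol: for each target,
every active's lowest-energy conformer (conformer 0) is used in turn as the
query against all conformers of all actives and decoys of that target, with
every conformer of the query molecule excluded to avoid self-retrieval.  The
ranked, molecule-collapsed hit list is cut at the top x% and an enrichment
factor computed at each level:

    EF = (a / d) / (A / D)

with ``a``/``d`` the actives/decoys retrieved at the cut and ``A``/``D`` the
target's totals.  This printed form normalises the retrieved active:decoy
ratio by the dataset ratio; the more common convention (a/n)/(A/N) is
available as ``convention="standard"``.  Per-query EFs are averaged per
target, and target means averaged again for a method's overall figure (an
unweighted two-stage mean).

A scaffold-hopping analysis counts, per query, the actives retrieved by the
shape method but not by topological fingerprint similarity at the same level;
queries for which either method retrieved no actives are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .io import ConformerRecord, DescriptorRow
from .atom_typing import PharmacophoreSubsets
from .descriptors import usrcat_descriptor
from .similarity import ScreenConfig, ScreeningHit, Weights, prefilter_candidates, _similarity_bulk

__all__ = [
    "BenchMolecule",
    "TargetSet",
    "load_target_set",
    "EfRecord",
    "BenchmarkResult",
    "ScaffoldHopSummary",
    "UsrcatMethod",
    "FingerprintMethod",
    "enrichment_factor",
    "run_benchmark",
    "average_ef",
    "ef_records_to_frame",
    "tanimoto_topological",
    "scaffold_hop_counts",
    "probe_radius_sweep",
]


@dataclass
class BenchMolecule:
    """A benchmark molecule: ≥1 conformer, conformer 0 = lowest energy."""

    mol_id: str
    conformers: list[ConformerRecord]
    subsets: list[PharmacophoreSubsets] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError(f"molecule {self.mol_id} has no conformers")
        if self.subsets and len(self.subsets) != len(self.conformers):
            raise ValueError(
                f"molecule {self.mol_id}: one subset assignment per conformer required"
            )


@dataclass
class TargetSet:
    """Actives plus decoys for one benchmark target."""

    target_id: str
    actives: list[BenchMolecule]
    decoys: list[BenchMolecule]

    def __post_init__(self) -> None:
        if len(self.actives) < 1 or len(self.decoys) < 1:
            raise ValueError("a target set needs at least one active and one decoy")
        ids = [m.mol_id for m in self.actives] + [m.mol_id for m in self.decoys]
        if len(set(ids)) != len(ids):
            raise ValueError("active and decoy molecule ids must be disjoint and unique")

    @property
    def A(self) -> int:
        return len(self.actives)

    @property
    def D(self) -> int:
        return len(self.decoys)


@dataclass(frozen=True)
class EfRecord:
    target_id: str
    query_mol_id: str
    level: float  # percent
    a: int
    d: int
    ef: float
    degenerate_d_zero: bool = False
    all_tied: bool = False


@dataclass
class BenchmarkResult:
    """EF records plus per-query ranked hits (for scaffold-hopping analysis).

    ``query_hits`` maps query mol_id to the ranked hit list truncated at the
    largest requested level; ``retrieved_actives`` maps (query, level) to the
    set of active mol_ids inside that level's cut.
    """

    target_id: str
    levels: tuple[float, ...]
    ef_records: list[EfRecord]
    query_hits: dict[str, list[ScreeningHit]]
    retrieved_actives: dict[tuple[str, float], frozenset[str]]


@dataclass(frozen=True)
class ScaffoldHopSummary:
    target_id: str
    level: float
    n_queries: int  # queries eligible after the both-methods-retrieved rule
    min: Optional[int]
    max: Optional[int]
    avg: Optional[float]


def load_target_set(directory, target_id: Optional[str] = None, patterns=None) -> TargetSet:
    """Load a per-target benchmark directory (``actives.sdf`` + ``decoys.sdf``).

    Pharmacophore subsets are taken from the JSON SD tag written by the
    fixture generator when present, otherwise assigned by SMARTS typing with
    the given (or default) pattern set.
    """
    import json
    from pathlib import Path

    from .io import SUBSET_SD_TAG, read_conformers
    from .atom_typing import assign_subsets

    d = Path(directory)

    def _load(path) -> list[BenchMolecule]:
        records = read_conformers(path, fmt="sdf")
        by_mol: dict[str, BenchMolecule] = {}
        for rec in records:
            if rec.mol is not None and rec.mol.HasProp(SUBSET_SD_TAG):
                ss = PharmacophoreSubsets.from_dict(
                    json.loads(rec.mol.GetProp(SUBSET_SD_TAG))
                )
            else:
                ss = assign_subsets(rec, patterns)
            mol = by_mol.get(rec.mol_id)
            if mol is None:
                by_mol[rec.mol_id] = BenchMolecule(
                    mol_id=rec.mol_id, conformers=[rec], subsets=[ss]
                )
            else:
                mol.conformers.append(rec)
                mol.subsets.append(ss)
        return list(by_mol.values())

    return TargetSet(
        target_id=target_id or d.name,
        actives=_load(d / "actives.sdf"),
        decoys=_load(d / "decoys.sdf"),
    )


def enrichment_factor(
    a: int, d: int, A: int, D: int, convention: str = "printed"
) -> tuple[float, bool]:
    """Enrichment factor with a degeneracy flag.

    ``printed`` computes (a/d)/(A/D); when d = 0 and a > 0, d is replaced by 1
    and the flag set, keeping EF finite and monotone in a.  ``standard``
    computes (a/(a+d))/(A/(A+D)).  a = 0 gives EF = 0 either way.
    """
    if A < 1 or D < 1:
        raise ValueError("A and D must be >= 1")
    if not (0 <= a <= A and 0 <= d <= D):
        raise ValueError("need 0 <= a <= A and 0 <= d <= D")
    if a == 0:
        return 0.0, False
    if convention == "printed":
        if d == 0:
            return (a / 1.0) / (A / D), True
        return (a / d) / (A / D), False
    if convention == "standard":
        n = a + d
        return (a / n) / (A / (A + D)), False
    raise ValueError(f"unknown EF convention: {convention!r}")


class ScreeningMethod(Protocol):
    """Descriptor + similarity plug-in used by :func:`run_benchmark`."""

    supports_prefilter: bool

    def describe(self, mol: BenchMolecule, conf_index: int): ...

    def similarity(self, query_obj, target_obj) -> float: ...


class UsrcatMethod:
    """The shape method: USRCAT vectors compared with weighted similarity.

    With ``weights=Weights.usr_only()`` this is exactly classic USR, since the
    first 12 moments are identical and the other blocks get weight zero.
    """

    supports_prefilter = True

    def __init__(self, weights: Weights = Weights(), hydrogens: str = "exclude"):
        self.weights = weights
        self.hydrogens = hydrogens

    def describe(self, mol: BenchMolecule, conf_index: int) -> np.ndarray:
        subsets = (
            mol.subsets[conf_index] if mol.subsets else PharmacophoreSubsets()
        )
        return usrcat_descriptor(
            mol.conformers[conf_index], subsets, hydrogens=self.hydrogens
        )

    def similarity(self, query_obj, target_obj) -> float:
        from .similarity import usrcat_similarity

        return usrcat_similarity(query_obj, target_obj, self.weights)


class FingerprintMethod:
    """Topological comparator: 2048-bit fingerprints with Tanimoto similarity.

    Conformer-independent (it sees only the molecular graph), so all
    conformers of a molecule share one fingerprint.  Requires records that
    carry a molecular graph.
    """

    supports_prefilter = False

    def __init__(self, fp_kind: str = "circular", nbits: int = 2048):
        self.fp_kind = fp_kind
        self.nbits = nbits
        self._cache: dict[str, object] = {}

    def describe(self, mol: BenchMolecule, conf_index: int):
        fp = self._cache.get(mol.mol_id)
        if fp is None:
            rd = mol.conformers[0].mol
            if rd is None:
                raise ValueError(
                    f"molecule {mol.mol_id} has no molecular graph for fingerprinting"
                )
            fp = _fingerprint(rd, self.fp_kind, self.nbits)
            self._cache[mol.mol_id] = fp
        return fp

    def similarity(self, query_obj, target_obj) -> float:
        from rdkit import DataStructs

        return float(DataStructs.TanimotoSimilarity(query_obj, target_obj))


def _fingerprint(mol, fp_kind: str, nbits: int):
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

    if fp_kind == "circular":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
        return gen.GetFingerprint(mol)
    if fp_kind == "path":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=nbits, branchedPaths=False)
        return gen.GetFingerprint(mol)
    if fp_kind == "tree":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=nbits, branchedPaths=True)
        return gen.GetFingerprint(mol)
    if fp_kind == "maccs":
        return MACCSkeys.GenMACCSKeys(mol)
    raise ValueError(f"unsupported fingerprint kind: {fp_kind!r}")


def tanimoto_topological(molA, molB, fp_kind: str = "circular", nbits: int = 2048) -> float:
    """Tanimoto coefficient between the fingerprints of two molecular graphs."""
    from rdkit import DataStructs

    return float(
        DataStructs.TanimotoSimilarity(
            _fingerprint(molA, fp_kind, nbits), _fingerprint(molB, fp_kind, nbits)
        )
    )


def _rank_entries(entries: list[tuple[str, int, float]]) -> list[tuple[str, int, float]]:
    return sorted(entries, key=lambda e: (-e[2], e[0], e[1]))


def run_benchmark(
    ts: TargetSet,
    method: ScreeningMethod,
    cfg: ScreenConfig,
    levels: Sequence[float] = (1.0, 0.5, 0.25),
    ef_convention: str = "printed",
) -> BenchmarkResult:
    """Run the per-query retrospective screen for one target.

    Every active's conformer 0 is the query; the screened set is every
    conformer of every active and decoy except the query molecule's own.
    Molecules are collapsed to their best conformer, ranked, and EF computed
    at each percent level with a retrieved-set size of ceil(level/100 * M)
    where M is the number of molecules screened.
    """
    levels = tuple(sorted(levels, reverse=True))
    active_ids = {m.mol_id for m in ts.actives}
    all_mols = ts.actives + ts.decoys

    # descriptor rows for every conformer of every molecule, computed once
    described: dict[str, list[tuple[int, object]]] = {}
    for mol in all_mols:
        described[mol.mol_id] = [
            (conf.conf_id, method.describe(mol, k))
            for k, conf in enumerate(mol.conformers)
        ]

    use_vectors = getattr(method, "supports_prefilter", False)
    ef_records: list[EfRecord] = []
    query_hits: dict[str, list[ScreeningHit]] = {}
    retrieved: dict[tuple[str, float], frozenset[str]] = {}

    for active in ts.actives:
        if not active.conformers:
            raise ValueError(f"active {active.mol_id} has no conformers")
        query_obj = described[active.mol_id][0][1]  # LEC only

        target_rows = [
            (mol_id, conf_id, obj)
            for mol_id, confs in described.items()
            if mol_id != active.mol_id
            for conf_id, obj in confs
        ]
        n_screened = len(all_mols) - 1

        if use_vectors:
            rows = [DescriptorRow(m, c, v) for m, c, v in target_rows]
            if cfg.probe_radius is not None:
                rows = prefilter_candidates(query_obj, rows, cfg.probe_radius)
            if rows:
                matrix = np.stack([r.moments for r in rows])
                scores = _similarity_bulk(np.asarray(query_obj), matrix, cfg.weights)
                entries = [
                    (r.mol_id, r.conf_id, float(s)) for r, s in zip(rows, scores)
                ]
            else:
                entries = []
        else:
            entries = [
                (m, c, method.similarity(query_obj, obj)) for m, c, obj in target_rows
            ]

        # collapse to best conformer per molecule
        best: dict[str, tuple[str, int, float]] = {}
        for mol_id, conf_id, s in entries:
            cur = best.get(mol_id)
            if cur is None or s > cur[2] or (s == cur[2] and conf_id < cur[1]):
                best[mol_id] = (mol_id, conf_id, s)
        ranked = _rank_entries(list(best.values()))

        all_tied = len(ranked) > 1 and ranked[0][2] == ranked[-1][2]
        max_cut = math.ceil(levels[0] / 100.0 * n_screened)
        query_hits[active.mol_id] = [
            ScreeningHit(mol_id=m, conf_id=c, score=s, rank=i + 1)
            for i, (m, c, s) in enumerate(ranked[:max_cut])
        ]

        for level in levels:
            n_ret = min(math.ceil(level / 100.0 * n_screened), len(ranked))
            top = ranked[:n_ret]
            a = sum(1 for m, _, _ in top if m in active_ids)
            d = len(top) - a
            ef, flag = enrichment_factor(a, d, ts.A, ts.D, convention=ef_convention)
            ef_records.append(
                EfRecord(
                    target_id=ts.target_id,
                    query_mol_id=active.mol_id,
                    level=level,
                    a=a,
                    d=d,
                    ef=ef,
                    degenerate_d_zero=flag,
                    all_tied=all_tied,
                )
            )
            retrieved[(active.mol_id, level)] = frozenset(
                m for m, _, _ in top if m in active_ids
            )

    return BenchmarkResult(
        target_id=ts.target_id,
        levels=levels,
        ef_records=ef_records,
        query_hits=query_hits,
        retrieved_actives=retrieved,
    )


def ef_records_to_frame(records: Sequence[EfRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": r.target_id,
                "query_mol_id": r.query_mol_id,
                "level": r.level,
                "a": r.a,
                "d": r.d,
                "ef": r.ef,
                "degenerate_d_zero": r.degenerate_d_zero,
                "all_tied": r.all_tied,
            }
            for r in records
        ]
    )


def average_ef(records: Sequence[EfRecord]) -> pd.DataFrame:
    """Two-stage unweighted mean: per-target mean over queries, then mean over
    targets.  Returns one row per level with per-target and overall means."""
    if not records:
        raise ValueError("no EF records to average")
    df = ef_records_to_frame(records)
    per_target = (
        df.groupby(["level", "target_id"], as_index=False)["ef"].mean()
    )
    overall = per_target.groupby("level", as_index=False)["ef"].mean()
    overall["target_id"] = "__overall__"
    return pd.concat([per_target, overall], ignore_index=True)[
        ["level", "target_id", "ef"]
    ]


def scaffold_hop_counts(
    shape_result: BenchmarkResult,
    fp_result: BenchmarkResult,
    level: float,
) -> ScaffoldHopSummary:
    """Per-target summary of actives found by the shape method but missed by
    the fingerprint method at the same level.

    A query enters the analysis only if both methods retrieved at least one
    active for it.  With no eligible queries the summary carries
    ``n_queries=0`` and ``None`` statistics.
    """
    shape_q = {q for (q, lv) in shape_result.retrieved_actives if lv == level}
    fp_q = {q for (q, lv) in fp_result.retrieved_actives if lv == level}
    if shape_q != fp_q:
        raise ValueError("shape and fingerprint registries cover different query sets")

    counts: list[int] = []
    for q in sorted(shape_q):
        shape_hits = shape_result.retrieved_actives[(q, level)]
        fp_hits = fp_result.retrieved_actives[(q, level)]
        if not shape_hits or not fp_hits:
            continue  # both-methods-retrieved eligibility rule
        counts.append(len(shape_hits - fp_hits))
    if not counts:
        return ScaffoldHopSummary(
            target_id=shape_result.target_id, level=level, n_queries=0,
            min=None, max=None, avg=None,
        )
    return ScaffoldHopSummary(
        target_id=shape_result.target_id,
        level=level,
        n_queries=len(counts),
        min=min(counts),
        max=max(counts),
        avg=sum(counts) / len(counts),
    )


def probe_radius_sweep(
    ts: TargetSet,
    radii: Sequence[float],
    cfg: ScreenConfig,
    levels: Sequence[float] = (0.25,),
    method: Optional[UsrcatMethod] = None,
    ef_convention: str = "printed",
) -> pd.DataFrame:
    """Mean EF per probe radius, plus a no-prefilter reference run.

    Returns a tidy frame with columns (radius, level, mean_ef); the reference
    linear-scan row carries ``radius = inf``.
    """
    if any(r < 0 for r in radii):
        raise ValueError("radii must be nonnegative")
    if method is None:
        method = UsrcatMethod(weights=cfg.weights)
    rows = []
    for radius in list(radii) + [None]:
        res = run_benchmark(
            ts, method, cfg.with_radius(radius), levels=levels,
            ef_convention=ef_convention,
        )
        summary = average_ef(res.ef_records)
        overall = summary[summary.target_id == "__overall__"]
        for _, rec in overall.iterrows():
            rows.append(
                {
                    "radius": math.inf if radius is None else radius,
                    "level": rec["level"],
                    "mean_ef": rec["ef"],
                }
            )
    return pd.DataFrame(rows)
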