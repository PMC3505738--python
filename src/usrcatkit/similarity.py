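"""Weighted USRCAT similarity, probe-radius prefiltering and ranked screening.

Similarity between two 60-moment vectors is an inverse scaled Manhattan
distance computed block-wise:

    S = 1 / (1 + ow*d1 + hw*d2 + rw*d3 + aw*d4 + dw*d5),

where each ``d_b`` is one twelfth of the L1 distance between the b-th
12-moment blocks (all atoms, hydrophobic, aromatic, acceptor, donor) and the
five nonnegative weights rescale the pharmacophore contributions at query
time.  S lies in (0, 1] and equals 1 iff every weighted block distance is
zero; with weights (1, 0, 0, 0, 0) it reduces exactly to classic USR
similarity on the first 12 moments.

The probe-radius prefilter reproduces the bounding-box semantics of a
12-dimensional cube index in-process: a candidate passes iff every one of its
first 12 moments lies within ``radius`` of the query's (a Chebyshev box on the
all-atom block only).  Any acceleration structure must return exactly this
set, so screening with a sufficiently large radius is identical to a linear
scan.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .io import ConformerRecord, DescriptorRow

__all__ = [
    "Weights",
    "ScreenConfig",
    "ScreeningHit",
    "usr_similarity",
    "usrcat_similarity",
    "prefilter_candidates",
    "screen",
    "cross_join_screen",
]

_BLOCK_SLICES = [slice(12 * b, 12 * b + 12) for b in range(5)]


@dataclass(frozen=True)
class Weights:
    """Block weights: ow (all atoms), hw (hydrophobes), rw (aromatics),
    aw (acceptors), dw (donors).  Defaults all 1.0; USR is (1, 0, 0, 0, 0)."""

    ow: float = 1.0
    hw: float = 1.0
    rw: float = 1.0
    aw: float = 1.0
    dw: float = 1.0

    def __post_init__(self) -> None:
        for name, val in self.as_dict().items():
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"weight {name} must be finite and >= 0, got {val}")

    def as_dict(self) -> dict[str, float]:
        return {"ow": self.ow, "hw": self.hw, "rw": self.rw, "aw": self.aw, "dw": self.dw}

    def as_array(self) -> np.ndarray:
        return np.array([self.ow, self.hw, self.rw, self.aw, self.dw], dtype=np.float64)

    @classmethod
    def usr_only(cls) -> "Weights":
        return cls(1.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScreenConfig:
    """Screening parameters.

    Exactly one of ``top_k`` / ``top_fraction`` must be set.  ``top_fraction``
    is taken relative to the number of molecules in the full table, so a
    prefilter can only shrink -- never re-normalise -- the retrieved set.
    ``probe_radius=None`` means a plain linear scan.
    """

    weights: Weights = Weights()
    probe_radius: Optional[float] = None
    top_k: Optional[int] = None
    top_fraction: Optional[float] = None
    conformer_collapse: bool = True

    def __post_init__(self) -> None:
        if (self.top_k is None) == (self.top_fraction is None):
            raise ValueError("exactly one of top_k / top_fraction must be set")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be a positive integer")
        if self.top_fraction is not None and not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.probe_radius is not None and self.probe_radius < 0:
            raise ValueError("probe_radius must be nonnegative")

    def with_radius(self, radius: Optional[float]) -> "ScreenConfig":
        return replace(self, probe_radius=radius)


@dataclass(frozen=True)
class ScreeningHit:
    mol_id: str
    conf_id: int
    score: float
    rank: int


def _check_vector(v, length: int) -> np.ndarray:
    arr = np.asarray(v, dtype=np.float64)
    if arr.shape != (length,):
        raise ValueError(f"expected a length-{length} vector, got shape {arr.shape}")
    return arr


def usr_similarity(vi12, vj12) -> float:
    """Classic USR similarity: 1 / (1 + mean absolute moment difference)."""
    a = _check_vector(vi12, 12)
    b = _check_vector(vj12, 12)
    return float(1.0 / (1.0 + np.abs(a - b).sum() / 12.0))


def usrcat_similarity(vi, vj, weights: Weights = Weights()) -> float:
    """Weighted block similarity of two 60-moment vectors (see module docs)."""
    a = _check_vector(vi, 60)
    b = _check_vector(vj, 60)
    diff = np.abs(a - b)
    w = weights.as_array()
    dist = sum(w[k] * diff[_BLOCK_SLICES[k]].sum() / 12.0 for k in range(5))
    return float(1.0 / (1.0 + dist))


def _similarity_bulk(query: np.ndarray, matrix: np.ndarray, weights: Weights) -> np.ndarray:
    """Vectorised usrcat_similarity of one query against an (M, 60) matrix."""
    diff = np.abs(matrix - query)
    w = weights.as_array()
    block = diff.reshape(-1, 5, 12).sum(axis=2) / 12.0
    return 1.0 / (1.0 + block @ w)


def prefilter_candidates(
    query, table: Sequence[DescriptorRow], radius: float
) -> list[DescriptorRow]:
    """Rows whose first 12 moments all lie within ``radius`` of the query's.

    ``query`` may be a 60- or 12-element vector; only the all-atom block is
    used, matching the cube-index semantics.
    """
    if radius < 0:
        raise ValueError("probe radius must be nonnegative")
    q = np.asarray(query, dtype=np.float64)
    if q.shape == (60,):
        q = q[:12]
    elif q.shape != (12,):
        raise ValueError("query must have 12 or 60 elements")
    if not table:
        return []
    m = np.stack([row.moments[:12] for row in table])
    mask = (np.abs(m - q) <= radius).all(axis=1)
    return [row for row, keep in zip(table, mask) if keep]


def _resolve_query_vector(query, subsets=None, hydrogens: str = "exclude") -> np.ndarray:
    if isinstance(query, DescriptorRow):
        return query.moments
    if isinstance(query, ConformerRecord):
        from .descriptors import usrcat_descriptor
        from .atom_typing import assign_subsets

        if subsets is None:
            subsets = assign_subsets(query)
        return usrcat_descriptor(query, subsets, hydrogens=hydrogens)
    return _check_vector(query, 60)


def screen(
    query: Union[np.ndarray, DescriptorRow, ConformerRecord],
    table: Sequence[DescriptorRow],
    cfg: ScreenConfig,
    subsets=None,
) -> list[ScreeningHit]:
    """Rank a descriptor table against a query.

    With ``conformer_collapse`` each molecule is scored by its best conformer.
    Hits are sorted by descending score with ties broken by ascending
    (mol_id, conf_id), then truncated to ``top_k`` molecules or
    ``ceil(top_fraction * M)`` where M counts the molecules of the full
    table.  An empty candidate set after prefiltering yields an empty list.
    """
    if not table:
        raise ValueError("descriptor table is empty")
    qv = _resolve_query_vector(query, subsets=subsets)
    if np.all(cfg.weights.as_array() == 0.0):
        warnings.warn(
            "all similarity weights are zero: every pair scores 1.0 and the "
            "ranking is pure tie-ordering",
            stacklevel=2,
        )

    n_molecules = len({row.mol_id for row in table})
    candidates = list(table)
    if cfg.probe_radius is not None:
        candidates = prefilter_candidates(qv, candidates, cfg.probe_radius)
        if not candidates:
            return []

    matrix = np.stack([row.moments for row in candidates])
    scores = _similarity_bulk(qv, matrix, cfg.weights)

    entries = [
        (row.mol_id, row.conf_id, float(s)) for row, s in zip(candidates, scores)
    ]
    if cfg.conformer_collapse:
        best: dict[str, tuple[str, int, float]] = {}
        for mol_id, conf_id, s in entries:
            cur = best.get(mol_id)
            if cur is None or s > cur[2] or (s == cur[2] and conf_id < cur[1]):
                best[mol_id] = (mol_id, conf_id, s)
        entries = list(best.values())

    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    if cfg.top_k is not None:
        limit = cfg.top_k
    else:
        limit = math.ceil(cfg.top_fraction * n_molecules)
    entries = entries[:limit]
    return [
        ScreeningHit(mol_id=m, conf_id=c, score=s, rank=i + 1)
        for i, (m, c, s) in enumerate(entries)
    ]


def cross_join_screen(
    query_vectors: Sequence, table: Sequence[DescriptorRow], cfg: ScreenConfig
) -> list[ScreeningHit]:
    """Screen with several query conformers; each target row is scored by the
    best-scoring query conformer (an all-by-all comparison collapsed by max).
    """
    if not query_vectors:
        raise ValueError("at least one query conformer is required")
    if not table:
        raise ValueError("descriptor table is empty")
    vectors = [_resolve_query_vector(q) for q in query_vectors]

    n_molecules = len({row.mol_id for row in table})
    candidates = list(table)
    if cfg.probe_radius is not None:
        kept: dict[int, DescriptorRow] = {}
        for qv in vectors:
            for row in prefilter_candidates(qv, candidates, cfg.probe_radius):
                kept[id(row)] = row
        candidates = [row for row in candidates if id(row) in kept]
        if not candidates:
            return []

    matrix = np.stack([row.moments for row in candidates])
    scores = np.max(
        [_similarity_bulk(qv, matrix, cfg.weights) for qv in vectors], axis=0
    )
    entries = [
        (row.mol_id, row.conf_id, float(s)) for row, s in zip(candidates, scores)
    ]
    if cfg.conformer_collapse:
        best: dict[str, tuple[str, int, float]] = {}
        for mol_id, conf_id, s in entries:
            cur = best.get(mol_id)
            if cur is None or s > cur[2] or (s == cur[2] and conf_id < cur[1]):
                best[mol_id] = (mol_id, conf_id, s)
        entries = list(best.values())
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    limit = cfg.top_k if cfg.top_k is not None else math.ceil(cfg.top_fraction * n_molecules)
    entries = entries[:limit]
    return [
        ScreeningHit(mol_id=m, conf_id=c, score=s, rank=i + 1)
        for i, (m, c, s) in enumerate(entries)
    ]
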