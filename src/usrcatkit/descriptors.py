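"""Moment-based shape descriptors (USR and USRCAT).

Ultrafast Shape Recognition (USR) encodes the 3D shape of a conformer as the
first three statistical moments of four distance distributions: the distances
from every atom to each of four reference points derived from the coordinates
alone.  The four reference points are

* ``ctd`` -- the all-atom centroid,
* ``cst`` -- the atom closest to the centroid,
* ``fct`` -- the atom farthest from the centroid,
* ``ftf`` -- the atom farthest from ``fct``.

Each distance distribution is summarised by its mean, its population standard
deviation and the signed cube root of its third central moment, giving a
rotation- and translation-invariant vector of 12 reals.

USRCAT extends this with four additional 12-moment blocks computed over
pharmacophore atom subsets (hydrophobic, aromatic, acceptor, donor).  The
subset distributions are measured against the *same* four all-atom reference
points, so the extra blocks encode where the pharmacophoric features sit
relative to the overall shape.  The result is a 60-element vector whose first
12 entries are exactly the classic USR moments; a block whose subset is empty
is twelve exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import ConformerRecord
from .atom_typing import PharmacophoreSubsets

__all__ = [
    "ReferencePoints",
    "compute_reference_points",
    "moment_triple",
    "usr_moments",
    "usr_descriptor",
    "usrcat_descriptor",
    "SUBSET_BLOCK_ORDER",
]

#: Order of the pharmacophore blocks after the all-atom block: elements 13-24
#: are hydrophobic, 25-36 aromatic, 37-48 acceptor, 49-60 donor (1-based).
SUBSET_BLOCK_ORDER = ("hydrophobic", "aromatic", "acceptor", "donor")


@dataclass(frozen=True)
class ReferencePoints:
    """The four USR reference points, each a 3-vector in Å.

    ``cst``, ``fct`` and ``ftf`` coincide with coordinates of actual atoms of
    the considered set; ``ctd`` generally does not.  For a single-atom input
    all four coincide.
    """

    ctd: np.ndarray
    cst: np.ndarray
    fct: np.ndarray
    ftf: np.ndarray

    def as_tuple(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (self.ctd, self.cst, self.fct, self.ftf)


def _as_coords(coords: Iterable) -> np.ndarray:
    arr = np.asarray(coords, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) coordinate array, got shape {arr.shape}")
    if arr.shape[0] < 1:
        raise ValueError("coordinate set is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("coordinates contain non-finite values")
    return arr


def compute_reference_points(coords: Iterable) -> ReferencePoints:
    """Compute the four reference points of a coordinate set.

    Ties for closest/farthest atoms are broken by the lowest atom index so the
    result is deterministic under a fixed input ordering.
    """
    arr = _as_coords(coords)
    ctd = arr.mean(axis=0)
    d_ctd = np.linalg.norm(arr - ctd, axis=1)
    cst = arr[int(np.argmin(d_ctd))]
    fct = arr[int(np.argmax(d_ctd))]
    d_fct = np.linalg.norm(arr - fct, axis=1)
    ftf = arr[int(np.argmax(d_fct))]
    return ReferencePoints(ctd=ctd, cst=cst.copy(), fct=fct.copy(), ftf=ftf.copy())


def moment_triple(distances: Sequence[float]) -> tuple[float, float, float]:
    """Mean, population standard deviation and signed cube root of the third
    central moment of a distance distribution.

    The population (1/N) normalisation is used throughout: the atoms of a
    conformer are a complete population, and a single-value distribution must
    give ``sigma = 0`` rather than an undefined sample variance.  The cube
    root keeps the skewness term in Å and finite even when ``sigma = 0``.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("moment_triple requires a non-empty 1-D distance list")
    mu = float(d.mean())
    centred = d - mu
    sigma = float(np.sqrt(np.mean(centred * centred)))
    third = float(np.mean(centred * centred * centred))
    # A third moment smaller than the rounding error of its own summation is
    # numerically zero (e.g. any two-value distribution, whose residual is
    # exactly symmetric); flushing it keeps the ill-conditioned cube root
    # from amplifying cancellation noise into ~1e-6 jitter.  The error bound
    # scales with the raw distance magnitude through the mean subtraction.
    max_c = float(np.max(np.abs(centred)))
    eps = float(np.finfo(np.float64).eps)
    noise = 32.0 * d.size * eps * max_c**2 * max(abs(mu), max_c)
    if abs(third) < noise:
        third = 0.0
    kappa = float(np.cbrt(third))
    return mu, sigma, kappa


def usr_moments(coords: Iterable, ref: ReferencePoints | None = None) -> np.ndarray:
    """12 USR moments of a raw coordinate set.

    If ``ref`` is given, distances are measured against those reference points
    instead of points derived from ``coords`` (used for USRCAT subset blocks).
    Ordering: (ctd mu, sigma, kappa), (cst ...), (fct ...), (ftf ...).
    """
    arr = _as_coords(coords)
    if ref is None:
        ref = compute_reference_points(arr)
    out = np.empty(12, dtype=np.float64)
    for k, point in enumerate(ref.as_tuple()):
        dists = np.linalg.norm(arr - point, axis=1)
        out[3 * k : 3 * k + 3] = moment_triple(dists)
    return out


def _considered_indices(record: ConformerRecord, hydrogens: str) -> np.ndarray:
    if hydrogens not in ("exclude", "include"):
        raise ValueError(f"unknown hydrogen policy: {hydrogens!r}")
    n = record.n_atoms
    if hydrogens == "include":
        return np.arange(n)
    keep = np.flatnonzero(~np.asarray(record.is_hydrogen, dtype=bool))
    if keep.size == 0:
        raise ValueError(
            f"conformer {record.mol_id}/{record.conf_id} has no non-hydrogen atoms"
        )
    return keep


def usr_descriptor(record: ConformerRecord, hydrogens: str = "exclude") -> np.ndarray:
    """Classic 12-element USR vector of a conformer.

    Hydrogens are excluded from the considered atom set by default; pass
    ``hydrogens="include"`` to keep them.
    """
    idx = _considered_indices(record, hydrogens)
    return usr_moments(record.coords[idx])


def usrcat_descriptor(
    record: ConformerRecord,
    subsets: PharmacophoreSubsets,
    hydrogens: str = "exclude",
) -> np.ndarray:
    """60-element USRCAT vector of a conformer.

    Block 1 (elements 1-12) is the classic USR vector over the considered
    atoms.  Blocks 2-5 are the moment triples of the distances from only the
    subset atoms (hydrophobic, aromatic, acceptor, donor, in that order) to
    the *same* four all-atom reference points.  An empty subset contributes
    twelve exact zeros.
    """
    idx = _considered_indices(record, hydrogens)
    considered = record.coords[idx]
    ref = compute_reference_points(considered)

    out = np.zeros(60, dtype=np.float64)
    out[:12] = usr_moments(considered, ref=ref)

    n = record.n_atoms
    for b, name in enumerate(SUBSET_BLOCK_ORDER, start=1):
        members = sorted(getattr(subsets, name))
        if not members:
            continue
        if members[0] < 0 or members[-1] >= n:
            raise IndexError(
                f"subset {name!r} refers to atom index {members[-1]} outside the "
                f"{n}-atom conformer {record.mol_id}/{record.conf_id}"
            )
        out[12 * b : 12 * b + 12] = usr_moments(record.coords[members], ref=ref)
    return out
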