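"""Pharmacophore atom typing via configurable SMARTS patterns.

Each heavy atom of a conformer is assigned to zero or more of four feature
classes -- hydrophobic, aromatic, hydrogen-bond donor, hydrogen-bond acceptor
-- by SMARTS substructure matching.  The classes are independent: an atom may
belong to several (a hydroxyl oxygen is both donor and acceptor) or to none.
The pattern set is configuration, not code: a default file ships with the
package and can be replaced wholesale, since different projects legitimately
disagree on feature definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .io import ConformerRecord

__all__ = [
    "SUBSET_NAMES",
    "PatternSet",
    "PharmacophoreSubsets",
    "load_pattern_set",
    "default_pattern_set",
    "assign_subsets",
]

SUBSET_NAMES = ("hydrophobic", "aromatic", "donor", "acceptor")


@dataclass(frozen=True)
class PharmacophoreSubsets:
    """Atom-index sets (into the parent conformer) for the four classes."""

    hydrophobic: frozenset[int] = field(default_factory=frozenset)
    aromatic: frozenset[int] = field(default_factory=frozenset)
    donor: frozenset[int] = field(default_factory=frozenset)
    acceptor: frozenset[int] = field(default_factory=frozenset)

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreSubsets":
        return cls(**{name: frozenset(int(i) for i in d.get(name, ())) for name in SUBSET_NAMES})

    def as_dict(self) -> dict[str, list[int]]:
        return {name: sorted(getattr(self, name)) for name in SUBSET_NAMES}

    def validate_against(self, n_atoms: int) -> None:
        for name in SUBSET_NAMES:
            for i in getattr(self, name):
                if not (0 <= i < n_atoms):
                    raise IndexError(
                        f"subset {name!r} index {i} out of range for {n_atoms} atoms"
                    )


class PatternSet:
    """Compiled SMARTS patterns for the four pharmacophore classes."""

    def __init__(self, patterns: dict[str, list[str]]):
        from rdkit import Chem

        unknown = set(patterns) - set(SUBSET_NAMES)
        if unknown:
            raise ValueError(f"unknown subset name(s): {', '.join(sorted(unknown))}")
        missing = [n for n in SUBSET_NAMES if n not in patterns]
        if missing:
            raise ValueError(f"missing subset: {', '.join(missing)}")
        self.smarts: dict[str, list[str]] = {n: list(patterns[n]) for n in SUBSET_NAMES}
        self._compiled: dict[str, list] = {}
        for name in SUBSET_NAMES:
            compiled = []
            for s in self.smarts[name]:
                q = Chem.MolFromSmarts(s)
                if q is None:
                    raise ValueError(f"invalid SMARTS for subset {name!r}: {s!r}")
                compiled.append(q)
            self._compiled[name] = compiled

    def queries(self, name: str) -> list:
        return self._compiled[name]


def load_pattern_set(path) -> PatternSet:
    """Load a pattern file: a YAML mapping of subset name to SMARTS list."""
    p = Path(path)
    with open(p) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{p}: pattern file must map subset names to SMARTS lists")
    patterns = {}
    for key, val in data.items():
        if isinstance(val, str):
            val = [val]
        if not isinstance(val, list) or not all(isinstance(s, str) for s in val):
            raise ValueError(f"{p}: subset {key!r} must be a list of SMARTS strings")
        patterns[key] = val
    return PatternSet(patterns)


def default_pattern_set() -> PatternSet:
    """The pattern file shipped with the package."""
    ref = resources.files("usrcatkit").joinpath("data/pharmacophore_patterns.yaml")
    with resources.as_file(ref) as p:
        return load_pattern_set(p)


def assign_subsets(record: ConformerRecord, patterns: PatternSet | None = None) -> PharmacophoreSubsets:
    """Match a conformer's atoms against the four pattern lists.

    An atom index enters subset *s* iff it matches at least one SMARTS of
    *s*.  Hydrogens never enter subsets (feature patterns address heavy
    atoms), regardless of what a user-supplied pattern matches.
    """
    if record.mol is None:
        raise ValueError(
            f"conformer {record.mol_id}/{record.conf_id} carries no molecular "
            "graph; SMARTS typing needs connectivity and aromaticity"
        )
    if patterns is None:
        patterns = default_pattern_set()
    mol = record.mol
    heavy = {i for i, h in enumerate(record.is_hydrogen) if not h}
    out: dict[str, frozenset[int]] = {}
    for name in SUBSET_NAMES:
        hits: set[int] = set()
        for q in patterns.queries(name):
            for match in mol.GetSubstructMatches(q, uniquify=True):
                hits.update(match)
        out[name] = frozenset(hits & heavy)
    return PharmacophoreSubsets(**out)
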