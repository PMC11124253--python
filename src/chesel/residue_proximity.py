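"""Which receptor residues the docked poses cluster against.

For every mode-1 ligand atom of a chosen element class (polar H, O and N by
default, per-element distance cutoffs of 1.5 / 1.5 / 2.5 Å), the minimum
distance to each receptor residue is computed; a (ligand atom, residue) pair
within the element's cutoff is one contact event. Events aggregate into a
per-(residue, element) density profile whose top-k residues describe the
preferred interaction partners — in a cholinesterase gorge these are the
hydrogen-bonding serines/tyrosines and the charged glutamate/histidine of
the catalytic machinery.

Contacts are counted once per (ligand atom, residue) pair at the minimum
atom–atom distance; counting every receptor atom within the cutoff instead
(``per_receptor_atom=True``) over-weights large residues but is available
for sensitivity analysis. The cutoff is inclusive: d == cutoff counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .pdbqt_io import DockedLigand, Receptor

__all__ = [
    "ProximityCutoffs",
    "ContactEvent",
    "ProximityProfile",
    "SpatialCloud",
    "find_contacts",
    "accumulate_profile",
    "top_residues",
    "export_cloud",
    "profile_table",
    "contacts_table",
]

ResidueKey = tuple[str, int, str]  # (chain, residue number, 3-letter name)


@dataclass(frozen=True)
class ProximityCutoffs:
    """Per-element contact distance thresholds in Å."""

    cutoffs: dict[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cutoffs",
            dict(self.cutoffs) if self.cutoffs else {"H": 1.5, "O": 1.5, "N": 2.5},
        )
        for element, value in self.cutoffs.items():
            if value <= 0:
                raise ValueError(f"cutoff for {element} must be > 0")

    @property
    def elements(self) -> set[str]:
        return set(self.cutoffs)

    def __getitem__(self, element: str) -> float:
        return self.cutoffs[element]

    @property
    def max_cutoff(self) -> float:
        return max(self.cutoffs.values())


@dataclass(frozen=True)
class ContactEvent:
    ligand_id: str
    target_name: str
    atom_serial: int
    element: str
    charge: float
    chain: str
    residue_number: int
    residue_name: str
    min_distance: float

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain, self.residue_number, self.residue_name)


def find_contacts(
    ligand: DockedLigand,
    receptor: Receptor,
    cutoffs: ProximityCutoffs | None = None,
    per_receptor_atom: bool = False,
) -> list[ContactEvent]:
    """Contact events between one ligand's mode-1 atoms and receptor residues.

    Each qualifying (ligand atom, residue) pair yields at most one event at
    the minimum atom–atom distance; with ``per_receptor_atom`` every receptor
    atom within the cutoff yields its own event.
    """
    if not ligand.mode1_atoms:
        raise ValueError(f"{ligand.ligand_id}: mode-1 atoms not parsed")
    if not receptor.atoms:
        raise ValueError(f"{receptor.target_name}: empty receptor")
    cutoffs = cutoffs or ProximityCutoffs()

    lig_atoms = [a for a in ligand.mode1_atoms if a.element in cutoffs.elements]
    if not lig_atoms:
        return []
    lig_xyz = np.array([(a.x, a.y, a.z) for a in lig_atoms])
    rec_xyz = np.array([(a.x, a.y, a.z) for a in receptor.atoms])
    dists = cdist(lig_xyz, rec_xyz)

    rec_keys = [
        (a.chain, a.residue_number, a.residue_name) for a in receptor.atoms
    ]
    events: list[ContactEvent] = []
    for i, atom in enumerate(lig_atoms):
        cutoff = cutoffs[atom.element]
        row = dists[i]
        if per_receptor_atom:
            for j in np.flatnonzero(row <= cutoff):
                chain, resnum, resname = rec_keys[j]
                events.append(
                    ContactEvent(
                        ligand_id=ligand.ligand_id,
                        target_name=receptor.target_name,
                        atom_serial=atom.serial,
                        element=atom.element,
                        charge=atom.partial_charge,
                        chain=chain,
                        residue_number=resnum,
                        residue_name=resname,
                        min_distance=float(row[j]),
                    )
                )
            continue
        per_residue: dict[ResidueKey, float] = {}
        for j in np.flatnonzero(row <= cutoff):
            key = rec_keys[j]
            d = float(row[j])
            if key not in per_residue or d < per_residue[key]:
                per_residue[key] = d
        for (chain, resnum, resname), d in per_residue.items():
            events.append(
                ContactEvent(
                    ligand_id=ligand.ligand_id,
                    target_name=receptor.target_name,
                    atom_serial=atom.serial,
                    element=atom.element,
                    charge=atom.partial_charge,
                    chain=chain,
                    residue_number=resnum,
                    residue_name=resname,
                    min_distance=d,
                )
            )
    return events


@dataclass
class ProximityProfile:
    """Per-(residue, element) contact counts aggregated over a screen."""

    target_name: str
    counts: dict[tuple[ResidueKey, str], int] = field(default_factory=dict)
    n_ligands: int = 0
    cutoffs: ProximityCutoffs = field(default_factory=ProximityCutoffs)

    def count(self, residue: ResidueKey, element: str) -> int:
        return self.counts.get((residue, element), 0)

    @property
    def residues(self) -> set[ResidueKey]:
        return {key for key, _ in self.counts}


def accumulate_profile(
    contacts: Iterable[ContactEvent],
    cutoffs: ProximityCutoffs | None = None,
    n_ligands: int | None = None,
) -> ProximityProfile:
    """Aggregate contact events (from one receptor) into a density profile.

    Events against different targets cannot be mixed. The result is a pure
    count table, invariant to the order the ligands were processed in.
    """
    events = list(contacts)
    targets = {e.target_name for e in events}
    if len(targets) > 1:
        raise ValueError(f"contacts mix targets: {sorted(targets)}")
    target = targets.pop() if targets else ""
    counts: dict[tuple[ResidueKey, str], int] = {}
    ligand_ids = set()
    for e in events:
        key = (e.residue_key, e.element)
        counts[key] = counts.get(key, 0) + 1
        ligand_ids.add(e.ligand_id)
    return ProximityProfile(
        target_name=target,
        counts=counts,
        n_ligands=n_ligands if n_ligands is not None else len(ligand_ids),
        cutoffs=cutoffs or ProximityCutoffs(),
    )


def top_residues(
    profile: ProximityProfile,
    k: int = 10,
    elements: set[str] | None = None,
) -> list[tuple[ResidueKey, int]]:
    """The k residues with the highest contact density over chosen elements.

    Descending by summed count; ties broken by ascending residue number.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    totals: dict[ResidueKey, int] = {}
    for (residue, element), count in profile.counts.items():
        if elements is not None and element not in elements:
            continue
        totals[residue] = totals.get(residue, 0) + count
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0][1], kv[0][0]))
    return ranked[:k]


@dataclass
class SpatialCloud:
    """All atoms of one element across a screen's mode-1 poses, with charges.

    Points live in the shared receptor frame, ready for the 3-D scatter view
    of where an element accumulates in the binding site.
    """

    element: str
    points: np.ndarray  # (n, 4): x, y, z, partial charge

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        if self.n_points == 0:
            raise ValueError("empty cloud has no bounding box")
        xyz = self.points[:, :3]
        return xyz.min(axis=0), xyz.max(axis=0)


def export_cloud(
    ligands: Iterable[DockedLigand], element: str
) -> SpatialCloud:
    """Collect every mode-1 atom of one element class across a screen.

    Carbon is deliberately not part of the default analysis set (the heavy-
    atom maps exclude it), but any element class may be requested.
    """
    rows = []
    for ligand in ligands:
        for atom in ligand.mode1_atoms:
            if atom.element == element:
                rows.append((atom.x, atom.y, atom.z, atom.partial_charge))
    if not rows:
        warnings.warn(f"no atoms of element {element!r} in any ligand", stacklevel=2)
        return SpatialCloud(element=element, points=np.empty((0, 4)))
    return SpatialCloud(element=element, points=np.array(rows, dtype=float))


def contacts_table(contacts: Iterable[ContactEvent]) -> pd.DataFrame:
    cols = ["ligand_id", "atom_serial", "element", "charge",
            "chain", "residue_number", "residue_name", "min_distance"]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in contacts],
                        columns=cols)


def profile_table(profile: ProximityProfile) -> pd.DataFrame:
    rows = [
        {
            "chain": residue[0],
            "residue_number": residue[1],
            "residue_name": residue[2],
            "element": element,
            "count": count,
        }
        for (residue, element), count in sorted(profile.counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["chain", "residue_number", "residue_name", "element", "count"]
    )
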