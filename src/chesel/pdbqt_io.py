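"""Reading and writing the PDBQT dialects a Vina-style screen produces.

Two dialects matter here: multi-model ligand *output* files, in which each
``MODEL``/``ENDMDL`` block carries one docked pose headed by a
``REMARK VINA RESULT: <energy> <rmsd_lb> <rmsd_ub>`` line, and single-model
receptor files that are ordinary PDB ``ATOM``/``HETATM`` tables extended with
a partial charge (columns 67-76) and an AutoDock atom type (columns 78-79).

Ligand PDBQT files carry only polar hydrogens (AutoDock merges non-polar H
into the heavy atoms), so every "hydrogen" downstream of this module means a
polar hydrogen of AutoDock type ``HD``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "BindingMode",
    "LigandAtom",
    "DockedLigand",
    "ReceptorAtom",
    "Receptor",
    "PDBQTParseError",
    "map_autodock_element",
    "read_vina_output",
    "read_screen_dir",
    "write_vina_output",
    "read_receptor",
    "write_receptor",
]

WATER_RESNAMES = {"HOH", "WAT", "H2O", "TIP", "TIP3", "TIP4", "SOL"}

# AutoDock atom type -> coarse element class. The mapping is total: anything
# unrecognised becomes "other", never dropped.
_AD_ELEMENT = {
    "A": "C", "C": "C", "CG0": "C", "G0": "C",
    "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O",
    "H": "H", "HD": "H", "HS": "H",
    "S": "S", "SA": "S",
    "P": "P",
    "F": "halogen", "CL": "halogen", "BR": "halogen", "I": "halogen",
}


class PDBQTParseError(ValueError):
    """Raised when a PDBQT file cannot be interpreted."""


def map_autodock_element(ad_type: str) -> str:
    """Map an AutoDock atom type to one of C, N, O, H, S, P, halogen, other."""
    return _AD_ELEMENT.get(ad_type.strip().upper(), "other")


@dataclass(frozen=True)
class BindingMode:
    """One ranked docked pose: Vina energy and RMSD bounds relative to mode 1."""

    rank: int
    affinity: float  # kcal/mol; may be positive for clashing poses
    rmsd_lb: float  # Å
    rmsd_ub: float  # Å

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"mode rank must be >= 1, got {self.rank}")
        if self.rmsd_lb < 0 or self.rmsd_ub < 0:
            raise ValueError("RMSD bounds must be non-negative")


@dataclass(frozen=True)
class LigandAtom:
    serial: int
    name: str
    element: str  # coarse class from map_autodock_element
    x: float
    y: float
    z: float
    partial_charge: float  # e
    ad_type: str = ""


@dataclass
class DockedLigand:
    """One ligand's ranked binding modes plus the mode-1 atom table.

    ``modes`` are ordered exactly as the file orders its MODEL blocks; rank is
    the 1-based MODEL position and is never re-sorted, so energy ties keep
    file order. ``order_violation`` is set (with a warning at parse time) when
    affinities are not nondecreasing with rank, which only happens in
    hand-edited files.
    """

    ligand_id: str
    modes: list[BindingMode]
    mode1_atoms: list[LigandAtom] = field(default_factory=list)
    source_path: str = ""
    torsdof: int | None = None
    order_violation: bool = False

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def first_affinity(self) -> float:
        return self.modes[0].affinity

    def validate(self) -> None:
        if not self.modes:
            raise ValueError(f"{self.ligand_id}: no binding modes")
        for i, mode in enumerate(self.modes, start=1):
            if mode.rank != i:
                raise ValueError(f"{self.ligand_id}: rank {mode.rank} at position {i}")
        affs = [m.affinity for m in self.modes]
        if any(b < a - 1e-9 for a, b in zip(affs, affs[1:])):
            raise ValueError(f"{self.ligand_id}: affinities decrease with rank")


@dataclass(frozen=True)
class ReceptorAtom:
    serial: int
    atom_name: str
    residue_name: str
    residue_number: int
    chain: str
    x: float
    y: float
    z: float
    partial_charge: float
    element: str
    ad_type: str = ""

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.residue_number)


@dataclass
class Receptor:
    """A rigid receptor: an atom table with a (chain, residue number) index."""

    target_name: str
    atoms: list[ReceptorAtom]
    residue_index: dict[tuple[str, int], list[ReceptorAtom]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residue_index:
            index: dict[tuple[str, int], list[ReceptorAtom]] = {}
            for atom in self.atoms:
                index.setdefault(atom.residue_key, []).append(atom)
            self.residue_index = index

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    def residue_name(self, key: tuple[str, int]) -> str:
        return self.residue_index[key][0].residue_name


def _parse_atom_line(line: str, lineno: int) -> tuple[dict, str]:
    """Parse one ATOM/HETATM record of the PDBQT fixed-column layout."""
    try:
        fields = {
            "serial": int(line[6:11]),
            "name": line[12:16].strip(),
            "resname": line[17:20].strip(),
            "chain": (line[21] if len(line) > 21 else " ").strip() or "A",
            "resnum": int(line[22:26]) if line[22:26].strip() else 0,
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
        }
    except (ValueError, IndexError) as exc:
        raise PDBQTParseError(f"line {lineno}: malformed ATOM record: {line.rstrip()!r}") from exc
    charge_str = line[66:76].strip() if len(line) > 66 else ""
    try:
        fields["charge"] = float(charge_str) if charge_str else 0.0
    except ValueError:
        fields["charge"] = 0.0
    ad_type = line[77:79].strip() if len(line) > 77 else ""
    return fields, ad_type


def read_vina_output(path: str | Path, parse_atoms: bool = True) -> DockedLigand:
    """Read a multi-model Vina ligand output file.

    Parameters
    ----------
    path
        Ligand output PDBQT. Must contain at least one MODEL block with a
        ``REMARK VINA RESULT:`` line of three numeric fields.
    parse_atoms
        If True, the ATOM/HETATM records of the first MODEL are kept as
        ``mode1_atoms`` (the lowest-energy pose, the one all spatial analyses
        use).

    The ligand identifier is taken from a ``REMARK  Name = ...`` record when
    present, otherwise from the filename stem with a trailing ``_out``
    stripped (the Vina batch convention).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    modes: list[BindingMode] = []
    atoms: list[LigandAtom] = []
    torsdof: int | None = None
    remark_name: str | None = None
    in_model = 0
    current_result: tuple[float, float, float] | None = None

    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model += 1
                current_result = None
            elif line.startswith("REMARK VINA RESULT:"):
                parts = line.split(":", 1)[1].split()
                if len(parts) < 3:
                    raise PDBQTParseError(
                        f"line {lineno}: RESULT line needs 3 numeric fields: {line.rstrip()!r}"
                    )
                try:
                    current_result = (float(parts[0]), float(parts[1]), float(parts[2]))
                except ValueError as exc:
                    raise PDBQTParseError(
                        f"line {lineno}: non-numeric RESULT field: {line.rstrip()!r}"
                    ) from exc
                modes.append(
                    BindingMode(
                        rank=len(modes) + 1,
                        affinity=current_result[0],
                        rmsd_lb=current_result[1],
                        rmsd_ub=current_result[2],
                    )
                )
            elif line.startswith("REMARK") and "Name" in line and "=" in line:
                remark_name = line.split("=", 1)[1].strip() or remark_name
            elif rec == "TORSDO" or line.startswith("TORSDOF"):
                parts = line.split()
                if len(parts) >= 2:
                    try:
                        torsdof = int(parts[1])
                    except ValueError:
                        pass
            elif rec in ("ATOM", "HETATM") and parse_atoms and in_model <= 1:
                fields, ad_type = _parse_atom_line(line, lineno)
                atoms.append(
                    LigandAtom(
                        serial=fields["serial"],
                        name=fields["name"],
                        element=map_autodock_element(ad_type),
                        x=fields["x"],
                        y=fields["y"],
                        z=fields["z"],
                        partial_charge=fields["charge"],
                        ad_type=ad_type,
                    )
                )

    if not modes:
        raise PDBQTParseError(f"{path}: no MODEL block with a REMARK VINA RESULT line")

    stem = path.stem
    if stem.endswith("_out"):
        stem = stem[: -len("_out")]
    ligand_id = remark_name or stem

    affs = [m.affinity for m in modes]
    violated = any(b < a - 1e-9 for a, b in zip(affs, affs[1:]))
    if violated:
        warnings.warn(
            f"{path}: binding affinities are not nondecreasing with rank",
            stacklevel=2,
        )
    return DockedLigand(
        ligand_id=ligand_id,
        modes=modes,
        mode1_atoms=atoms,
        source_path=str(path),
        torsdof=torsdof,
        order_violation=violated,
    )


def read_screen_dir(
    directory: str | Path, parse_atoms: bool = True, pattern: str = "*.pdbqt"
) -> list[DockedLigand]:
    """Read every ligand output file in a screen directory, sorted by name."""
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} files in {directory}")
    return [read_vina_output(f, parse_atoms=parse_atoms) for f in files]


def _format_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    charge: float,
    ad_type: str,
) -> str:
    name4 = name if len(name) >= 4 else f" {name:<3}"
    return (
        f"ATOM  {serial:>5d} {name4:<4}{resname:>4} {chain:1}{resnum:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}{charge:10.3f} {ad_type:<2}"
    )


def write_vina_output(
    ligand: DockedLigand, path: str | Path, energy_decimals: int = 1
) -> Path:
    """Write a DockedLigand back to a Vina-style multi-model PDBQT.

    Vina itself prints RESULT energies to one decimal; fixtures that must
    round-trip statistics use ``energy_decimals=3``. Coordinates always go
    out at 3 decimals (the PDB column width).
    """
    ligand.validate()
    path = Path(path)
    lines: list[str] = [f"REMARK  Name = {ligand.ligand_id}"]
    for mode in ligand.modes:
        lines.append(f"MODEL {mode.rank}")
        lines.append(
            "REMARK VINA RESULT: "
            f"{mode.affinity:>8.{energy_decimals}f} "
            f"{mode.rmsd_lb:>10.3f} {mode.rmsd_ub:>10.3f}"
        )
        if mode.rank == 1:
            lines.append("ROOT")
            for atom in ligand.mode1_atoms:
                lines.append(
                    _format_atom_line(
                        atom.serial, atom.name, "LIG", "A", 1,
                        atom.x, atom.y, atom.z, atom.partial_charge,
                        atom.ad_type or _default_ad_type(atom.element),
                    )
                )
            lines.append("ENDROOT")
        if ligand.torsdof is not None:
            lines.append(f"TORSDOF {ligand.torsdof}")
        lines.append("ENDMDL")
    path.write_text("\n".join(lines) + "\n")
    return path


def _default_ad_type(element: str) -> str:
    return {"C": "C", "N": "N", "O": "OA", "H": "HD", "S": "SA", "P": "P",
            "halogen": "Cl"}.get(element, "Du")


def read_receptor(
    path: str | Path, target_name: str, skip_water: bool = True
) -> Receptor:
    """Read a prepared single-model receptor PDBQT (or PDB-like) file.

    Water residues (HOH and friends) are excluded when ``skip_water`` is on;
    prepared docking receptors have them stripped already, but raw PDB files
    do not. Charges are taken as the file states them and never recomputed.
    """
    path = Path(path)
    atoms: list[ReceptorAtom] = []
    seen_serials: set[int] = set()
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            fields, ad_type = _parse_atom_line(line, lineno)
            if skip_water and fields["resname"].upper() in WATER_RESNAMES:
                continue
            if fields["serial"] in seen_serials:
                warnings.warn(f"{path}: duplicate atom serial {fields['serial']}", stacklevel=2)
            seen_serials.add(fields["serial"])
            atoms.append(
                ReceptorAtom(
                    serial=fields["serial"],
                    atom_name=fields["name"],
                    residue_name=fields["resname"],
                    residue_number=fields["resnum"],
                    chain=fields["chain"],
                    x=fields["x"],
                    y=fields["y"],
                    z=fields["z"],
                    partial_charge=fields["charge"],
                    element=map_autodock_element(ad_type) if ad_type
                    else _element_from_atom_name(fields["name"]),
                    ad_type=ad_type,
                )
            )
    if not atoms:
        raise PDBQTParseError(f"{path}: no atoms found")
    return Receptor(target_name=target_name, atoms=atoms)


def _element_from_atom_name(name: str) -> str:
    lead = name.strip()[:1].upper()
    return {"C": "C", "N": "N", "O": "O", "H": "H", "S": "S", "P": "P"}.get(lead, "other")


def write_receptor(receptor: Receptor, path: str | Path) -> Path:
    """Write a receptor atom table as a single-model PDBQT (fixture support)."""
    path = Path(path)
    lines = []
    for atom in receptor.atoms:
        lines.append(
            _format_atom_line(
                atom.serial, atom.atom_name, atom.residue_name, atom.chain,
                atom.residue_number, atom.x, atom.y, atom.z,
                atom.partial_charge, atom.ad_type or _default_ad_type(atom.element),
            )
        )
    lines.append("TER")
    path.write_text("\n".join(lines) + "\n")
    return path
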