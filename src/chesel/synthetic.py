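"""Synthetic paired screens and geometric fixtures with planted ground truth.

The generator emulates what a paired Vina-style virtual screen of one ligand
library against two cholinesterases produces, without running any docking:

* per-ligand ranked mode-energy lists with nondecreasing affinities, 6-20
  modes per ligand as screening runs typically request;
* a controllable signed selectivity distribution: a near-zero nonselective
  component plus gamma-shaped selective magnitudes per class, with the
  A-selective (AChE-like) class kept small in magnitude and the B-selective
  (BChE-like) class broader, concentrated roughly over 0.1-10 kcal/mol;
* a separate uniform tail of extreme positive-energy cases (>100 kcal/mol
  magnitude) standing in for sterically excluded ligands whose affinity
  against the narrow-gorge target turns repulsive — a distinct mechanism,
  so a distinct mixture component rather than a stretched gamma;
* small receptor/ligand coordinate sets with contacts planted at exact
  distances for proximity testing.

Everything is deterministic under the seed, with an independent substream
per ligand index, so increasing ``n_ligands`` never reshuffles the ligands
already generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .pdbqt_io import (
    BindingMode,
    DockedLigand,
    LigandAtom,
    Receptor,
    ReceptorAtom,
    write_receptor,
    write_vina_output,
)
from .selectivity import A_SELECTIVE, B_SELECTIVE, NONSELECTIVE, DEFAULT_THRESHOLD

__all__ = [
    "SyntheticScreenConfig",
    "LigandTruth",
    "GroundTruth",
    "generate_paired_screen",
    "generate_proximity_fixture",
    "generate_mode_stat_fixture",
    "sample_delta_magnitude",
]

_ELEMENT_CYCLE = ("C", "N", "O", "H")
_AD_TYPE = {"C": "C", "N": "N", "O": "OA", "H": "HD"}


@dataclass(frozen=True)
class SyntheticScreenConfig:
    """Distributional knobs for a paired mock screen.

    Defaults mirror the screen-level conditions of a paired cholinesterase
    screen: class fractions (0.48, 0.46, 0.06), 6-20 modes per ligand, and
    base first-mode energies around -8.5 kcal/mol, the range summary tables
    of such screens print.
    """

    n_ligands: int = 1000
    seed: int = 0
    base_mean: float = -8.5  # kcal/mol, first-mode energy vs target A
    base_sd: float = 1.0
    frac_a: float = 0.48
    frac_b: float = 0.46
    frac_nonselective: float = 0.06
    threshold: float = DEFAULT_THRESHOLD
    #: selective |ΔE_A| = threshold + selective_margin + Gamma(shape, scale)
    gamma_shape_a: float = 2.0
    gamma_scale_a: float = 0.35
    gamma_shape_b: float = 2.0
    gamma_scale_b: float = 1.5
    selective_margin: float = 0.002  # keeps planted labels clear of the threshold
    tail_fraction: float = 0.01  # of B-selective draws go to the extreme tail
    tail_range: tuple[float, float] = (100.0, 120.0)
    n_modes_range: tuple[int, int] = (6, 20)
    gap_scale: float = 0.25  # exponential inter-mode energy gaps, kcal/mol
    n_atoms_range: tuple[int, int] = (8, 30)
    charge_sd: float = 0.2  # e; draws clipped to [-1, 1]
    energy_decimals: int = 3  # 1 = Vina-faithful quantisation
    torsdof_range: tuple[int, int] = (0, 24)

    def __post_init__(self) -> None:
        total = self.frac_a + self.frac_b + self.frac_nonselective
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")
        if self.gamma_shape_a <= 0 or self.gamma_scale_a <= 0 \
                or self.gamma_shape_b <= 0 or self.gamma_scale_b <= 0:
            raise ValueError("gamma shape/scale must be > 0")
        if self.gap_scale < 0:
            raise ValueError("inter-mode gaps cannot be negative")


@dataclass(frozen=True)
class LigandTruth:
    ligand_id: str
    label: str
    s_signed: float
    delta_ea: float
    energies_a: tuple[float, ...]
    energies_b: tuple[float, ...]


@dataclass
class GroundTruth:
    """Planted truth for a generated artifact; same seed, same bytes."""

    ligands: list[LigandTruth] = field(default_factory=list)
    contacts: list[tuple[tuple[str, int, str], str, int, float]] = field(default_factory=list)

    def label_of(self, ligand_id: str) -> str:
        return next(t.label for t in self.ligands if t.ligand_id == ligand_id)

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "ligands": [asdict(t) for t in self.ligands],
            "contacts": [
                {"chain": r[0], "residue_number": r[1], "residue_name": r[2],
                 "element": el, "multiplicity": m, "distance": d}
                for r, el, m, d in self.contacts
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def sample_delta_magnitude(
    label: str, rng: np.random.Generator, config: SyntheticScreenConfig
) -> float:
    """Draw one |ΔE_A| magnitude for a planted class."""
    if label == NONSELECTIVE:
        return float(rng.uniform(0.0, config.threshold))
    if label == A_SELECTIVE:
        body = rng.gamma(config.gamma_shape_a, config.gamma_scale_a)
    elif label == B_SELECTIVE:
        if rng.random() < config.tail_fraction:
            return float(rng.uniform(*config.tail_range))
        body = rng.gamma(config.gamma_shape_b, config.gamma_scale_b)
    else:
        raise ValueError(f"unknown class label {label!r}")
    return float(config.threshold + config.selective_margin + body)


def _round(x: float, decimals: int) -> float:
    return float(np.round(x, decimals))


def _mode_list(
    e1: float, n_modes: int, rng: np.random.Generator, config: SyntheticScreenConfig
) -> list[BindingMode]:
    gaps = rng.exponential(config.gap_scale, size=n_modes - 1)
    energies = e1 + np.concatenate([[0.0], np.cumsum(gaps)])
    energies = np.round(energies, config.energy_decimals)
    energies = np.maximum.accumulate(energies)  # rounding must not break ordering
    modes = [BindingMode(rank=1, affinity=float(energies[0]), rmsd_lb=0.0, rmsd_ub=0.0)]
    for k in range(1, n_modes):
        lb = _round(rng.uniform(1.0, 3.0), 3)
        ub = _round(lb + rng.uniform(0.5, 4.0), 3)
        modes.append(BindingMode(rank=k + 1, affinity=float(energies[k]),
                                 rmsd_lb=lb, rmsd_ub=ub))
    return modes


def _mode1_atoms(rng: np.random.Generator, config: SyntheticScreenConfig) -> list[LigandAtom]:
    n_atoms = int(rng.integers(config.n_atoms_range[0], config.n_atoms_range[1] + 1))
    atoms = []
    for i in range(n_atoms):
        element = _ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)]
        x, y, z = np.round(rng.uniform(-5.0, 5.0, size=3), 3)
        q = float(np.clip(rng.normal(0.0, config.charge_sd), -1.0, 1.0))
        atoms.append(
            LigandAtom(
                serial=i + 1,
                name=f"{element}{i + 1}",
                element=element,
                x=float(x), y=float(y), z=float(z),
                partial_charge=_round(q, 3),
                ad_type=_AD_TYPE[element],
            )
        )
    return atoms


def generate_paired_screen(
    config: SyntheticScreenConfig,
    out_dir_a: str | Path | None = None,
    out_dir_b: str | Path | None = None,
) -> tuple[list[DockedLigand], list[DockedLigand], GroundTruth]:
    """Generate one ligand library docked against two mock targets.

    For each ligand a class is drawn from the configured fractions, a signed
    selectivity from that class's magnitude distribution (negative sign for
    the A-selective class), first-mode energies set so that
    ``E_A(B) = E_A(A) − s``, and full rank-nondecreasing mode lists emitted
    for both targets. When output directories are given, each screen is
    written as one Vina-style PDBQT per ligand that parses and round-trips
    through ``pdbqt_io``.
    """
    ligands_a: list[DockedLigand] = []
    ligands_b: list[DockedLigand] = []
    truth = GroundTruth()
    labels = (A_SELECTIVE, B_SELECTIVE, NONSELECTIVE)
    probs = (config.frac_a, config.frac_b, config.frac_nonselective)

    for i in range(config.n_ligands):
        rng = np.random.default_rng([config.seed, i])
        ligand_id = f"ZINC{i:09d}"
        label = labels[int(rng.choice(3, p=probs))]
        magnitude = sample_delta_magnitude(label, rng, config)
        if label == A_SELECTIVE:
            s = -magnitude
        elif label == B_SELECTIVE:
            s = magnitude
        else:
            s = float(rng.choice([-1.0, 1.0])) * magnitude

        ea1 = _round(rng.normal(config.base_mean, config.base_sd), config.energy_decimals)
        s = _round(s, config.energy_decimals)
        eb1 = _round(ea1 - s, config.energy_decimals)

        n_modes = int(rng.integers(config.n_modes_range[0], config.n_modes_range[1] + 1))
        torsdof = int(rng.integers(config.torsdof_range[0], config.torsdof_range[1] + 1))
        modes_a = _mode_list(ea1, n_modes, rng, config)
        modes_b = _mode_list(eb1, n_modes, rng, config)
        atoms_a = _mode1_atoms(rng, config)
        atoms_b = _mode1_atoms(rng, config)

        lig_a = DockedLigand(ligand_id=ligand_id, modes=modes_a,
                             mode1_atoms=atoms_a, torsdof=torsdof)
        lig_b = DockedLigand(ligand_id=ligand_id, modes=modes_b,
                             mode1_atoms=atoms_b, torsdof=torsdof)
        ligands_a.append(lig_a)
        ligands_b.append(lig_b)
        truth.ligands.append(
            LigandTruth(
                ligand_id=ligand_id,
                label=label,
                s_signed=float(modes_a[0].affinity - modes_b[0].affinity),
                delta_ea=abs(float(modes_a[0].affinity - modes_b[0].affinity)),
                energies_a=tuple(m.affinity for m in modes_a),
                energies_b=tuple(m.affinity for m in modes_b),
            )
        )

    for out_dir, ligands in ((out_dir_a, ligands_a), (out_dir_b, ligands_b)):
        if out_dir is None:
            continue
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for lig in ligands:
            write_vina_output(lig, out_dir / f"{lig.ligand_id}_out.pdbqt",
                              energy_decimals=config.energy_decimals)
    return ligands_a, ligands_b, truth


# Residue scaffold geometry for proximity fixtures: residues sit on a line
# 12 Å apart, side atoms offset along ±x, and planted ligand atoms in the
# local yz-plane — so the designated central atom is always the nearest
# receptor atom and other residues stay far outside every cutoff.
_RESIDUE_SPACING = 12.0
_SIDE_OFFSET = 1.3
_RESNAMES = ("SER", "HIS", "GLU", "TYR", "TRP", "GLY", "ASP", "THR", "PHE", "ALA")


def generate_proximity_fixture(
    n_residues: int,
    planted: Sequence[tuple[int, str, float, int]],
    seed: int = 0,
    target_name: str = "mock",
    cutoff_guard: float = 0.01,
    allow_boundary: bool = False,
) -> tuple[Receptor, DockedLigand, GroundTruth]:
    """Build a receptor/ligand pair with contacts at exact planted distances.

    ``planted`` rows are ``(residue_index, element, distance, multiplicity)``.
    Each planted entry puts ``multiplicity`` ligand atoms of ``element`` at
    exactly ``distance`` Å from the designated residue's central atom; the
    construction is its own oracle, since every other ligand-receptor pair is
    kept beyond any plausible cutoff.
    """
    rng = np.random.default_rng(seed)
    if n_residues < 1:
        raise ValueError("need at least one residue")
    for idx, element, distance, mult in planted:
        if not 0 <= idx < n_residues:
            raise ValueError(f"planted residue index {idx} out of range")
        if distance <= 0:
            raise ValueError("planted distances must be positive")
        if distance > _RESIDUE_SPACING / 2 - 1.0:
            raise ValueError(
                f"planted distance {distance} Å too large for the residue spacing"
            )
        if mult < 1:
            raise ValueError("multiplicity must be >= 1")
        if not allow_boundary and any(
            abs(distance - c) < cutoff_guard for c in (1.5, 2.5)
        ):
            raise ValueError(
                f"planted distance {distance} within {cutoff_guard} Å of a default "
                "cutoff; pass allow_boundary=True for boundary tests"
            )

    rec_atoms: list[ReceptorAtom] = []
    serial = 0
    centers = []
    for r in range(n_residues):
        cx = r * _RESIDUE_SPACING
        resname = _RESNAMES[r % len(_RESNAMES)]
        centers.append((cx, resname))
        for name, dx in (("CA", 0.0), ("CB", _SIDE_OFFSET), ("N", -_SIDE_OFFSET)):
            serial += 1
            rec_atoms.append(
                ReceptorAtom(
                    serial=serial, atom_name=name, residue_name=resname,
                    residue_number=r + 1, chain="A",
                    x=cx + dx, y=0.0, z=0.0,
                    partial_charge=_round(float(np.clip(rng.normal(0, 0.2), -1, 1)), 3),
                    element="C" if name.startswith("C") else "N",
                    ad_type="C" if name.startswith("C") else "N",
                )
            )
    receptor = Receptor(target_name=target_name, atoms=rec_atoms)

    lig_atoms: list[LigandAtom] = []
    truth = GroundTruth()
    atom_serial = 0
    for idx, element, distance, mult in planted:
        cx, resname = centers[idx]
        for k in range(mult):
            theta = 2.0 * np.pi * k / max(mult, 1)
            atom_serial += 1
            lig_atoms.append(
                LigandAtom(
                    serial=atom_serial,
                    name=f"{element}{atom_serial}",
                    element=element,
                    x=cx,
                    y=float(distance * np.sin(theta)),
                    z=float(distance * np.cos(theta)),
                    partial_charge=_round(float(np.clip(rng.normal(0, 0.2), -1, 1)), 3),
                    ad_type=_AD_TYPE.get(element, "C"),
                )
            )
        truth.contacts.append((("A", idx + 1, resname), element, mult, distance))

    # decoy carbons well away from every residue
    for _ in range(3):
        atom_serial += 1
        lig_atoms.append(
            LigandAtom(
                serial=atom_serial, name=f"C{atom_serial}", element="C",
                x=-30.0 + float(rng.uniform(-2, 2)),
                y=float(rng.uniform(-2, 2)), z=float(rng.uniform(-2, 2)),
                partial_charge=0.0, ad_type="C",
            )
        )

    ligand = DockedLigand(
        ligand_id="fixture_ligand",
        modes=[BindingMode(rank=1, affinity=-7.0, rmsd_lb=0.0, rmsd_ub=0.0)],
        mode1_atoms=lig_atoms,
    )
    return receptor, ligand, truth


def generate_mode_stat_fixture(
    mean: float,
    sd: float,
    n_modes: int,
    seed: int = 0,
    ligand_id: str = "stat_fixture",
) -> DockedLigand:
    """A ligand whose mode energies hit requested sample statistics exactly.

    A random normal draw is affinely rescaled so the sample mean and sample
    (n-1) standard deviation equal the request to ~1e-12, then sorted so
    mode 1 carries the minimum, as docking output would order it.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd > 0 and n_modes < 2:
        raise ValueError("a nonzero sd needs at least 2 modes")
    if n_modes < 1:
        raise ValueError("need at least one mode")
    rng = np.random.default_rng(seed)
    if sd == 0:
        energies = np.full(n_modes, mean)
    else:
        x = rng.normal(size=n_modes)
        while np.std(x, ddof=1) == 0:  # pragma: no cover - essentially impossible
            x = rng.normal(size=n_modes)
        z = (x - x.mean()) / np.std(x, ddof=1)
        energies = np.sort(mean + sd * z)
    modes = [BindingMode(rank=1, affinity=float(energies[0]), rmsd_lb=0.0, rmsd_ub=0.0)]
    for k in range(1, n_modes):
        lb = _round(rng.uniform(1.0, 3.0), 3)
        modes.append(
            BindingMode(rank=k + 1, affinity=float(energies[k]),
                        rmsd_lb=lb, rmsd_ub=_round(lb + rng.uniform(0.5, 4.0), 3))
        )
    return DockedLigand(ligand_id=ligand_id, modes=modes,
                        mode1_atoms=_mode1_atoms(rng, SyntheticScreenConfig()))
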