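"""Published reference values for the paired cholinesterase screens.

These are the printed per-ligand summary rows and screen-level counts from
the paired AChE (PDB 1W6R) / BChE (PDB 4BDS) virtual screens of an
FDA-approved library (1,614 ligands) and a clean-metabolites-in-vivo
library. They serve as fixed inputs for consistency checks and worked
examples; the raw docking outputs behind them are not redistributed.

Row order of the table tuples: (ligand, ΔE_A, 1st E_A, <E_A>, σE_A,
<rmsd l.b.>, <rmsd u.b.>), energies in kcal/mol, RMSDs in Å. ΔE_A is the
magnitude of the difference between the two targets' first-mode energies.
"""

from __future__ import annotations

from .mode_stats import ModeStatistics

__all__ = [
    "TableRow",
    "FDA_ACHE_SELECTIVE",
    "FDA_BCHE_SELECTIVE",
    "MET_ACHE_SELECTIVE",
    "MET_BCHE_SELECTIVE",
    "FDA_SCREEN_COUNTS",
    "CAFFEINE_FORMULA",
    "CAFESTROL_ENERGIES",
    "BBOX_DIMENSIONS",
    "row_statistics",
]

TableRow = tuple[str, float, float, float, float, float, float]

# FDA-approved library, AChE-selective Lipinski-agreeable examples (10 modes).
FDA_ACHE_SELECTIVE: list[TableRow] = [
    ("Ambrisentan", 1.9, -10.8, -9.0, 0.97, 1.855, 3.895),
    ("Methadone", 1.9, -9.9, -8.9, 0.60, 1.696, 4.326),
    ("Triamterene", 1.8, -9.6, -8.4, 0.45, 2.176, 4.693),
    ("Prednisone", 1.7, -11.0, -8.7, 1.20, 1.639, 4.357),
    ("Metaxalone", 1.6, -8.8, -8.0, 0.59, 2.085, 3.697),
    ("Doxapram", 1.5, -10.9, -9.2, 1.07, 1.617, 3.620),
]

# FDA-approved library, BChE-selective examples (10 modes).
FDA_BCHE_SELECTIVE: list[TableRow] = [
    ("Ergotamine", 12.6, -12.0, -11.5, 0.31, 2.568, 8.325),
    ("Ciclesonide", 9.9, -11.8, -11.0, 0.49, 2.789, 5.359),
    ("Suvorexant", 7.0, -10.1, -9.1, 0.30, 4.740, 8.674),
    ("Nintedanib", 6.8, -10.6, -10.2, 0.24, 2.664, 6.214),
    ("Lurasidone", 6.0, -11.1, -11.1, 0.55, 2.985, 5.905),
    ("Amcinonide", 5.0, -10.9, -10.2, 0.40, 3.320, 6.541),
]

# Clean-metabolites-in-vivo library, AChE-selective examples (6 modes).
MET_ACHE_SELECTIVE: list[TableRow] = [
    ("Afzelchin", 2.1, -10.2, -8.3, 0.95, 1.937, 6.013),
    ("Aminoclonazepam", 1.9, -10.7, -9.3, 0.78, 2.708, 4.454),
    ("Dihydroisorhamnetin", 1.7, -10.2, -9.0, 0.68, 1.254, 5.850),
    ("Bisphenol A", 1.5, -9.3, -8.7, 0.42, 1.989, 5.145),
    ("N-cinnamoyloctopamin", 1.3, -10.4, -10.0, 0.24, 2.816, 4.520),
]

# Clean-metabolites-in-vivo library, BChE-selective examples (6 modes).
MET_BCHE_SELECTIVE: list[TableRow] = [
    ("Azukisapogenol", 15.0, -10.5, -10.1, 0.23, 1.926, 2.790),
    ("D-maslinic acid", 11.0, -10.6, -10.2, 0.25, 1.687, 4.801),
    ("Isoliensinine", 7.4, -11.3, -10.9, 0.26, 2.491, 6.986),
    ("Dukunolide D", 4.8, -11.0, -10.8, 0.13, 2.211, 5.002),
    ("Zanthobisquinolone", 3.2, -11.1, -10.7, 0.23, 1.770, 5.954),
]

#: FDA-approved screen: paired library size and selectivity call counts.
FDA_SCREEN_COUNTS = {"n_paired": 1614, "n_a_selective": 779, "n_b_selective": 739}

CAFFEINE_FORMULA = "C8H10N4O2"

#: Cafestrol first-mode energies (AChE, BChE) under two search-box sizes.
CAFESTROL_ENERGIES = {
    "large_box": (-8.9, -9.0),  # 30x30x30 Å
    "small_box": (-7.4, -9.0),  # 15x15x15 Å
}

#: Printed bounding-box extents (Å, descending) of three size exemplars.
BBOX_DIMENSIONS = {
    "ambrisentan": (10.48, 8.38, 7.60),
    "ergotamine": (18.931, 10.122, 6.750),
    "ZINC_253700110": (16.27, 10.90, 9.24),
}


def row_statistics(row: TableRow, n_modes: int) -> ModeStatistics:
    """View a published table row as a ModeStatistics record.

    The underlying per-mode energies are unpublished, so the standard error
    is reconstructed as σE_A/√n; RMSD means are taken as printed.
    """
    ligand, _delta, first_ea, mean_ea, sd_ea, rmsd_lb, rmsd_ub = row
    return ModeStatistics(
        ligand_id=ligand,
        n_modes=n_modes,
        first_ea=first_ea,
        mean_ea=mean_ea,
        sd_ea=sd_ea,
        se_ea=sd_ea / n_modes**0.5,
        mean_rmsd_lb=rmsd_lb,
        mean_rmsd_ub=rmsd_ub,
    )
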