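"""Per-ligand binding-mode statistics: the rows of a screen's summary table.

For each docked ligand, the first-mode (lowest) energy, the mean, standard
deviation and standard error of all mode energies, and the mean RMSD bounds
are computed over however many modes the docking produced (runs may use
anywhere from 6 to 20 modes, so ``n_modes`` is always reported alongside).
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .pdbqt_io import DockedLigand

__all__ = [
    "ModeStatistics",
    "compute_mode_statistics",
    "rank_and_filter",
    "statistics_table",
    "write_statistics_tsv",
]

_OPS: dict[str, Callable[[float, float], bool]] = {
    "<": operator.lt, "<=": operator.le, ">": operator.gt,
    ">=": operator.ge, "==": operator.eq, "!=": operator.ne,
}


@dataclass(frozen=True)
class ModeStatistics:
    """Summary statistics of one ligand's binding-mode energies.

    ``first_ea`` is the mode-1 (lowest) energy in kcal/mol; ``mean_ea``,
    ``sd_ea`` and ``se_ea`` are taken over all modes; the RMSD means are over
    all modes' lower/upper bounds (mode 1 contributes 0/0 by construction).
    """

    ligand_id: str
    n_modes: int
    first_ea: float
    mean_ea: float
    sd_ea: float
    se_ea: float
    mean_rmsd_lb: float
    mean_rmsd_ub: float


def compute_mode_statistics(
    ligand: DockedLigand, sample_sd: bool = True
) -> ModeStatistics:
    """Compute the per-ligand statistics over all binding modes.

    The standard deviation uses the sample (n-1) denominator by default; with
    as few as 6 modes the distinction from the population form is material,
    so ``sample_sd=False`` switches to the n denominator. A single mode gives
    sd = se = 0 by convention.
    """
    if not ligand.modes:
        raise ValueError(f"{ligand.ligand_id}: no binding modes")
    energies = np.array([m.affinity for m in ligand.modes], dtype=float)
    n = energies.size
    if n == 1:
        sd = 0.0
    else:
        sd = float(np.std(energies, ddof=1 if sample_sd else 0))
    return ModeStatistics(
        ligand_id=ligand.ligand_id,
        n_modes=n,
        first_ea=float(energies[0]),
        mean_ea=float(energies.mean()),
        sd_ea=sd,
        se_ea=sd / math.sqrt(n),
        mean_rmsd_lb=float(np.mean([m.rmsd_lb for m in ligand.modes])),
        mean_rmsd_ub=float(np.mean([m.rmsd_ub for m in ligand.modes])),
    )


_FIELD_NAMES = {f.name for f in dataclass_fields(ModeStatistics)}

Predicate = Callable[[ModeStatistics], bool] | tuple[str, str, float]


def rank_and_filter(
    stats: Sequence[ModeStatistics],
    key: str,
    limit: int | None = None,
    predicate: Predicate | None = None,
    descending: bool = False,
) -> list[ModeStatistics]:
    """Filter then stably sort ligand statistics by one field.

    ``predicate`` is either a callable on ModeStatistics or a threshold
    triple like ``("sd_ea", "<", 0.5)``. Sorting is ascending by default
    (most negative energy first) and always stable, so ties keep input order.
    """
    if key not in _FIELD_NAMES:
        raise KeyError(f"unknown ModeStatistics field {key!r}")
    if predicate is None:
        kept = list(stats)
    elif callable(predicate):
        kept = [s for s in stats if predicate(s)]
    else:
        field_name, op, value = predicate
        if field_name not in _FIELD_NAMES:
            raise KeyError(f"unknown ModeStatistics field {field_name!r}")
        if op not in _OPS:
            raise ValueError(f"unknown comparison operator {op!r}")
        fn = _OPS[op]
        kept = [s for s in stats if fn(getattr(s, field_name), value)]
    kept.sort(key=lambda s: getattr(s, key), reverse=descending)
    return kept if limit is None else kept[:limit]


# Summary-table column order: ligand first, then the energy statistics, then
# the RMSD means; the paired-screen ΔE_A column is joined by the selectivity
# stage and not known here.
_TSV_COLUMNS = [
    "ligand_id", "n_modes", "first_ea", "mean_ea", "sd_ea", "se_ea",
    "mean_rmsd_lb", "mean_rmsd_ub",
]


def statistics_table(stats: Iterable[ModeStatistics]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats], columns=_TSV_COLUMNS)


def write_statistics_tsv(stats: Iterable[ModeStatistics], path: str | Path) -> Path:
    path = Path(path)
    statistics_table(stats).to_csv(path, sep="\t", index=False, float_format="%.4f")
    return path
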