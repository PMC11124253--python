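"""Paired-screen selectivity: the ΔE_A statistic, classification and testing.

A ligand docked against two targets (A = AChE, B = BChE throughout the
defaults) gets a signed selectivity ``s = E_A(A) − E_A(B)`` from the two
first-mode energies. Under the more-negative-is-stronger convention,
``s < 0`` means the ligand binds target A more favourably (A-selective) and
``s > 0`` means target B; tables report the magnitude ``ΔE_A = |s|``. A
ligand is called selective only when the magnitude strictly exceeds a
threshold (0.1 kcal/mol, one Vina energy-resolution unit, by default).

Positive (repulsive) docking energies are retained: ligands too large for a
narrow active-site gorge produce strongly positive energies against that
target and drive the >100 kcal/mol tail of the ΔE_A distribution.

The Mann–Whitney U comparison of two screens' ΔE_A samples is implemented
here from rank sums with midranks, the tie-corrected normal approximation
for the p value, and exact enumeration for small samples.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .pdbqt_io import DockedLigand

__all__ = [
    "A_SELECTIVE",
    "B_SELECTIVE",
    "NONSELECTIVE",
    "DEFAULT_THRESHOLD",
    "SelectivityRecord",
    "PairingResult",
    "ScreenSummary",
    "MWUResult",
    "classify",
    "pair_screens",
    "summarize_screen",
    "mann_whitney",
    "records_table",
    "write_records_tsv",
]

logger = logging.getLogger(__name__)

A_SELECTIVE = "A_selective"
B_SELECTIVE = "B_selective"
NONSELECTIVE = "nonselective"

#: |s| must strictly exceed this (kcal/mol) for a selectivity call.
DEFAULT_THRESHOLD = 0.1


def classify(s_signed: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Label a signed selectivity; |s| == threshold is nonselective."""
    if s_signed < -threshold:
        return A_SELECTIVE
    if s_signed > threshold:
        return B_SELECTIVE
    return NONSELECTIVE


@dataclass(frozen=True)
class SelectivityRecord:
    ligand_id: str
    ea_target_a: float  # first-mode energy vs target A, kcal/mol
    ea_target_b: float  # first-mode energy vs target B, kcal/mol
    s_signed: float  # ea_target_a - ea_target_b
    delta_ea: float  # |s_signed|
    label: str


class PairingResult(NamedTuple):
    records: list[SelectivityRecord]
    unpaired_a: list[str]
    unpaired_b: list[str]


def _first_energies(screen: Iterable[DockedLigand] | Mapping[str, float]) -> dict[str, float]:
    if isinstance(screen, Mapping):
        return dict(screen)
    out: dict[str, float] = {}
    for lig in screen:
        out[lig.ligand_id] = lig.first_affinity
    return out


def pair_screens(
    screen_a: Iterable[DockedLigand] | Mapping[str, float],
    screen_b: Iterable[DockedLigand] | Mapping[str, float],
    threshold: float = DEFAULT_THRESHOLD,
) -> PairingResult:
    """Pair ligands by identifier across two screens and classify each.

    Accepts either parsed ligands or pre-extracted ``{ligand_id: first-mode
    energy}`` mappings. Ligands present in only one screen are returned in
    the ``unpaired_*`` lists and logged, never silently dropped.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ea = _first_energies(screen_a)
    eb = _first_energies(screen_b)
    shared = [lid for lid in ea if lid in eb]
    unpaired_a = sorted(set(ea) - set(eb))
    unpaired_b = sorted(set(eb) - set(ea))
    if not shared:
        raise ValueError("no ligand identifiers shared between the two screens")
    if unpaired_a or unpaired_b:
        logger.info(
            "pairing: %d shared, %d only in screen A, %d only in screen B",
            len(shared), len(unpaired_a), len(unpaired_b),
        )
    records = []
    for lid in shared:
        s = ea[lid] - eb[lid]
        records.append(
            SelectivityRecord(
                ligand_id=lid,
                ea_target_a=ea[lid],
                ea_target_b=eb[lid],
                s_signed=s,
                delta_ea=abs(s),
                label=classify(s, threshold),
            )
        )
    return PairingResult(records, unpaired_a, unpaired_b)


@dataclass
class ScreenSummary:
    """Dataset-level view of a paired screen's selectivity calls.

    Percentages are on ``n_paired`` and reported both rounded to the nearest
    integer (the way screen-level fractions are conventionally quoted) and at
    full precision. ``histogram`` bins the signed selectivity; the per-class
    histograms bin |ΔE_A| with everything beyond ``histogram_cutoff`` pooled
    into a final overflow bin.
    """

    n_paired: int
    n_a_selective: int
    n_b_selective: int
    n_nonselective: int
    pct_a: int
    pct_b: int
    pct_a_exact: float
    pct_b_exact: float
    max_delta_a: float | None
    max_delta_b: float | None
    histogram: list[tuple[float, int]]
    class_histograms: dict[str, list[tuple[float, int]]] = field(default_factory=dict)
    bin_width: float = 0.1
    histogram_cutoff: float | None = None

    def to_json_dict(self) -> dict:
        d = dict(self.__dict__)
        d["histogram"] = [[e, c] for e, c in self.histogram]
        d["class_histograms"] = {
            k: [[e, c] for e, c in v] for k, v in self.class_histograms.items()
        }
        return d


def _binned(values: np.ndarray, bin_width: float, lo: float,
            cutoff: float | None) -> list[tuple[float, int]]:
    """Histogram with fixed-width bins from ``lo``; values beyond ``cutoff``
    pooled into one overflow bin whose edge is the cutoff."""
    if values.size == 0:
        return []
    if cutoff is not None:
        over = int(np.sum(values > cutoff))
        values = values[values <= cutoff]
    else:
        over = 0
    if values.size:
        hi = float(values.max())
        n_bins = max(1, int(math.floor((hi - lo) / bin_width)) + 1)
        edges = lo + bin_width * np.arange(n_bins + 1)
        counts, _ = np.histogram(values, bins=edges)
        out = [(float(edges[i]), int(counts[i])) for i in range(n_bins)]
    else:
        out = []
    if over:
        out.append((float(cutoff), over))
    return out


def summarize_screen(
    records: Sequence[SelectivityRecord],
    bin_width: float = 0.1,
    histogram_cutoff: float | None = None,
) -> ScreenSummary:
    """Count and histogram the selectivity calls of one paired screen."""
    if not records:
        raise ValueError("no selectivity records to summarize")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n = len(records)
    by_label: dict[str, list[SelectivityRecord]] = {
        A_SELECTIVE: [], B_SELECTIVE: [], NONSELECTIVE: []
    }
    for r in records:
        by_label[r.label].append(r)
    n_a = len(by_label[A_SELECTIVE])
    n_b = len(by_label[B_SELECTIVE])

    signed = np.array([r.s_signed for r in records])
    lo = math.floor(signed.min() / bin_width) * bin_width
    signed_cut = histogram_cutoff if histogram_cutoff is None else abs(histogram_cutoff)
    hist = _binned(signed, bin_width, lo, signed_cut)

    class_hists = {}
    for label, recs in by_label.items():
        mags = np.array([r.delta_ea for r in recs])
        class_hists[label] = _binned(mags, bin_width, 0.0, histogram_cutoff)

    return ScreenSummary(
        n_paired=n,
        n_a_selective=n_a,
        n_b_selective=n_b,
        n_nonselective=len(by_label[NONSELECTIVE]),
        pct_a=round(100.0 * n_a / n),
        pct_b=round(100.0 * n_b / n),
        pct_a_exact=100.0 * n_a / n,
        pct_b_exact=100.0 * n_b / n,
        max_delta_a=max((r.delta_ea for r in by_label[A_SELECTIVE]), default=None),
        max_delta_b=max((r.delta_ea for r in by_label[B_SELECTIVE]), default=None),
        histogram=hist,
        class_histograms=class_hists,
        bin_width=bin_width,
        histogram_cutoff=histogram_cutoff,
    )


@dataclass(frozen=True)
class MWUResult:
    """Mann–Whitney U comparison of two ΔE_A samples.

    ``u_statistic`` is U for the first sample; ``U1 + U2 = n1*n2`` always.
    ``p_two_sided`` comes from the tie-corrected normal approximation (no
    continuity correction); for n1+n2 ≤ 12 an exact enumeration p is also
    reported in ``p_exact``. When every pooled value is identical the
    variance is zero and the result is flagged degenerate with p = 1.
    """

    u_statistic: float
    z_statistic: float
    p_two_sided: float
    n1: int
    n2: int
    tie_corrected: bool = True
    degenerate: bool = False
    p_exact: float | None = None


_EXACT_LIMIT = 12


def _exact_p(pooled: np.ndarray, n1: int, observed_u: float) -> float:
    """Two-sided permutation p by enumerating all first-sample subsets."""
    n = pooled.size
    ranks = rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    obs_dev = abs(observed_u - mu)
    hits = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= obs_dev - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(
    sample_1: Sequence[float], sample_2: Sequence[float]
) -> MWUResult:
    """Rank-sum U test with midranks for ties and tie-corrected variance."""
    x = np.asarray(sample_1, dtype=float)
    y = np.asarray(sample_2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks on ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    if n > 1:
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:
        var = 0.0

    p_exact = _exact_p(pooled, n1, u1) if n <= _EXACT_LIMIT else None

    if var <= 0:
        return MWUResult(
            u_statistic=float(u1), z_statistic=0.0, p_two_sided=1.0,
            n1=n1, n2=n2, degenerate=True, p_exact=p_exact,
        )
    z = (u1 - mu) / math.sqrt(var)
    p = float(min(1.0, 2.0 * _normal_sf(abs(z))))
    return MWUResult(
        u_statistic=float(u1), z_statistic=float(z), p_two_sided=p,
        n1=n1, n2=n2, p_exact=p_exact,
    )


def _normal_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


_RECORD_COLUMNS = ["ligand_id", "ea_target_a", "ea_target_b", "s_signed", "delta_ea", "label"]


def records_table(records: Iterable[SelectivityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=_RECORD_COLUMNS)


def write_records_tsv(records: Iterable[SelectivityRecord], path: str | Path) -> Path:
    path = Path(path)
    records_table(records).to_csv(path, sep="\t", index=False, float_format="%.3f")
    return path
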