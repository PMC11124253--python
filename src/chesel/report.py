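"""Pipeline orchestration: configuration, the full analysis run, reporting.

`run_pipeline` wires the stages together for a paired screen: read both
screen directories, per-ligand mode statistics, pairing + selectivity
classification, screen summary with histograms, a Mann–Whitney comparison of
the two selective classes' |ΔE_A| samples, and (when receptors are given)
residue-proximity profiles and element clouds. Outputs are TSV/JSON with
UTF-8 and Unix newlines; two runs on identical inputs produce identical
bytes (plots excluded). Input files are never mutated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import mode_stats, residue_proximity, selectivity
from .pdbqt_io import Receptor, read_receptor, read_screen_dir
from .residue_proximity import ProximityCutoffs, contacts_table, profile_table

__all__ = ["RunConfig", "VinaConfig", "run_pipeline", "emit_vina_config", "parse_vina_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; persisted alongside its outputs."""

    screen_a: str
    screen_b: str
    out_dir: str
    target_a: str = "AChE"
    target_b: str = "BChE"
    receptor_a: str | None = None
    receptor_b: str | None = None
    threshold: float = selectivity.DEFAULT_THRESHOLD
    cutoffs: dict[str, float] = field(default_factory=lambda: {"H": 1.5, "O": 1.5, "N": 2.5})
    bin_width: float = 0.1
    histogram_cutoff: float | None = None
    top_k: int = 10
    seed: int = 0
    make_plots: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("screen_a", "screen_b"):
            if not Path(getattr(self, name)).is_dir():
                raise FileNotFoundError(f"{name}: {getattr(self, name)} is not a directory")
        for name in ("receptor_a", "receptor_b"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.threshold < 0 or self.bin_width <= 0 or self.top_k < 1:
            raise ValueError("threshold >= 0, bin_width > 0 and top_k >= 1 required")
        ProximityCutoffs(self.cutoffs)  # validates positivity

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path


def _proximity_stage(
    ligands, receptor: Receptor, cutoffs: ProximityCutoffs, out: Path,
    top_k: int, make_plots: bool,
) -> None:
    all_events = []
    for lig in ligands:
        if lig.mode1_atoms:
            all_events.extend(
                residue_proximity.find_contacts(lig, receptor, cutoffs)
            )
    profile = residue_proximity.accumulate_profile(
        all_events, cutoffs=cutoffs, n_ligands=len(ligands)
    )
    tag = receptor.target_name
    contacts_table(all_events).to_csv(
        out / f"contacts_{tag}.tsv", sep="\t", index=False, float_format="%.3f"
    )
    profile_table(profile).to_csv(out / f"profile_{tag}.tsv", sep="\t", index=False)
    ranked = residue_proximity.top_residues(profile, k=top_k)
    with (out / f"top_residues_{tag}.tsv").open("w") as fh:
        fh.write("chain\tresidue_number\tresidue_name\tcount\n")
        for (chain, num, name), count in ranked:
            fh.write(f"{chain}\t{num}\t{name}\t{count}\n")
    for element in sorted(cutoffs.elements):
        cloud = residue_proximity.export_cloud(ligands, element)
        if cloud.n_points:
            import numpy as np

            np.savetxt(
                out / f"cloud_{tag}_{element}.tsv", cloud.points,
                delimiter="\t", header="x\ty\tz\tcharge", comments="", fmt="%.3f",
            )
    if make_plots:
        from . import plots

        plots.plot_top_residues(profile, out / f"top_residues_{tag}.png", k=top_k)
    logger.info("proximity[%s]: %d contact events over %d ligands",
                tag, len(all_events), len(ligands))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full paired-screen analysis; returns a manifest of outputs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")

    screens = {}
    for tag, directory in (("a", config.screen_a), ("b", config.screen_b)):
        ligands = read_screen_dir(directory)
        screens[tag] = ligands
        logger.info("screen %s: read %d ligands from %s", tag, len(ligands), directory)
        stats = [mode_stats.compute_mode_statistics(l) for l in ligands]
        mode_stats.write_statistics_tsv(stats, out / f"mode_stats_{tag}.tsv")

    pairing = selectivity.pair_screens(screens["a"], screens["b"], config.threshold)
    logger.info(
        "paired %d ligands (%d unpaired in A, %d in B)",
        len(pairing.records), len(pairing.unpaired_a), len(pairing.unpaired_b),
    )
    selectivity.write_records_tsv(pairing.records, out / "selectivity.tsv")

    summary = selectivity.summarize_screen(
        pairing.records, bin_width=config.bin_width,
        histogram_cutoff=config.histogram_cutoff,
    )
    summary_dict = summary.to_json_dict()
    summary_dict["unpaired_a"] = pairing.unpaired_a
    summary_dict["unpaired_b"] = pairing.unpaired_b
    (out / "summary.json").write_text(json.dumps(summary_dict, indent=1))
    with (out / "histogram_signed.tsv").open("w") as fh:
        fh.write("bin_edge\tcount\n")
        for edge, count in summary.histogram:
            fh.write(f"{edge:.3f}\t{count}\n")

    # Rank comparison of the two selective classes' |ΔE_A| samples.
    deltas_a = [r.delta_ea for r in pairing.records if r.label == selectivity.A_SELECTIVE]
    deltas_b = [r.delta_ea for r in pairing.records if r.label == selectivity.B_SELECTIVE]
    mwu_path = None
    if deltas_a and deltas_b:
        mwu = selectivity.mann_whitney(deltas_a, deltas_b)
        mwu_path = out / "mann_whitney.json"
        mwu_path.write_text(json.dumps(dataclasses.asdict(mwu), indent=1))
        logger.info("Mann-Whitney: U=%.1f Z=%.3f p=%.3g", mwu.u_statistic,
                    mwu.z_statistic, mwu.p_two_sided)

    cutoffs = ProximityCutoffs(config.cutoffs)
    for tag, receptor_path, target in (
        ("a", config.receptor_a, config.target_a),
        ("b", config.receptor_b, config.target_b),
    ):
        if receptor_path is None:
            continue
        receptor = read_receptor(receptor_path, target_name=target)
        _proximity_stage(screens[tag], receptor, cutoffs, out,
                         config.top_k, config.make_plots)

    if config.make_plots:
        from . import plots

        plots.plot_class_histograms(summary, out / "histograms_by_class.png")
        plots.plot_signed_histogram(summary, out / "histogram_signed.png")

    return {
        "out_dir": str(out),
        "n_screen_a": len(screens["a"]),
        "n_screen_b": len(screens["b"]),
        "n_paired": len(pairing.records),
        "n_unpaired_a": len(pairing.unpaired_a),
        "n_unpaired_b": len(pairing.unpaired_b),
        "summary": summary_dict,
        "mann_whitney": str(mwu_path) if mwu_path else None,
    }


@dataclass(frozen=True)
class VinaConfig:
    """A Vina-family docking configuration (search box and sampling)."""

    receptor: str
    center_x: float
    center_y: float
    center_z: float
    size_x: float
    size_y: float
    size_z: float
    exhaustiveness: int = 8
    num_modes: int = 9

    def __post_init__(self) -> None:
        if min(self.size_x, self.size_y, self.size_z) <= 0:
            raise ValueError("box sizes must be > 0")
        if not 1 <= self.num_modes <= 20:
            raise ValueError("num_modes must be in [1, 20]")
        if self.exhaustiveness < 1:
            raise ValueError("exhaustiveness must be >= 1")


_VINA_KEYS = ["receptor", "center_x", "center_y", "center_z",
              "size_x", "size_y", "size_z", "exhaustiveness", "num_modes"]


def emit_vina_config(spec: VinaConfig, path: str | Path) -> Path:
    """Write a ``key = value`` config file accepted by Vina-family tools."""
    path = Path(path)
    lines = []
    for key in _VINA_KEYS:
        value = getattr(spec, key)
        if isinstance(value, float) and value == int(value):
            value = int(value)
        lines.append(f"{key} = {value}")
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_vina_config(path: str | Path) -> VinaConfig:
    """Read a ``key = value`` Vina config back into a VinaConfig."""
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    kwargs: dict = {"receptor": values.get("receptor", "")}
    for key in _VINA_KEYS[1:7]:
        kwargs[key] = float(values[key])
    for key in ("exhaustiveness", "num_modes"):
        if key in values:
            kwargs[key] = int(values[key])
    return VinaConfig(**kwargs)
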