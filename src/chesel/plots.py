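"""Matplotlib views of screen summaries and proximity profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .residue_proximity import ProximityProfile, SpatialCloud, top_residues
from .selectivity import A_SELECTIVE, B_SELECTIVE, ScreenSummary

__all__ = [
    "plot_class_histograms",
    "plot_signed_histogram",
    "plot_top_residues",
    "plot_cloud",
]


def _bar(ax, hist, width, **kwargs):
    if not hist:
        return
    edges = [e for e, _ in hist]
    counts = [c for _, c in hist]
    ax.bar(edges, counts, width=width, align="edge", **kwargs)


def plot_class_histograms(summary: ScreenSummary, path: str | Path) -> Path:
    """Side-by-side |ΔE_A| occurrence histograms for the two selective classes."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=False)
    for ax, label, title in zip(
        axes, (A_SELECTIVE, B_SELECTIVE), ("target-A selective", "target-B selective")
    ):
        _bar(ax, summary.class_histograms.get(label, []), summary.bin_width,
             color="steelblue", edgecolor="none")
        ax.set_title(title)
        ax.set_xlabel(r"$\Delta E_A$ (kcal/mol)")
        ax.set_ylabel("occurrences")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_signed_histogram(summary: ScreenSummary, path: str | Path) -> Path:
    """One-graph signed selectivity histogram; left of 0 = A-selective."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    _bar(ax, summary.histogram, summary.bin_width, color="darkorange")
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel(r"$s = E_A(\mathrm{A}) - E_A(\mathrm{B})$ (kcal/mol)")
    ax.set_ylabel("occurrences")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_top_residues(
    profile: ProximityProfile, path: str | Path, k: int = 10
) -> Path:
    """Horizontal bars of the k highest-density residues."""
    ranked = top_residues(profile, k=k)
    labels = [f"{name}{num}" for (_, num, name), _ in ranked]
    counts = [c for _, c in ranked]
    fig, ax = plt.subplots(figsize=(5, 0.4 * max(len(ranked), 1) + 1.5))
    ax.barh(range(len(ranked)), counts, color="seagreen")
    ax.set_yticks(range(len(ranked)), labels)
    ax.invert_yaxis()
    ax.set_xlabel("contact events")
    ax.set_title(f"{profile.target_name}: top residues by contact density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_cloud(cloud: SpatialCloud, path: str | Path) -> Path:
    """3-D scatter of one element's positions, coloured by partial charge."""
    fig = plt.figure(figsize=(5, 4.5))
    ax = fig.add_subplot(projection="3d")
    if cloud.n_points:
        pts = cloud.points
        sc = ax.scatter(pts[:, 0], pts[:, 1], pts[:, 2], c=pts[:, 3],
                        cmap="coolwarm", s=8)
        fig.colorbar(sc, label="partial charge (e)", shrink=0.7)
    ax.set_title(f"{cloud.element} spatial distribution")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
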