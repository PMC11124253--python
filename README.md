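# chesel

Post-docking selectivity analysis for paired virtual screens against the two
cholinergic hydrolases, acetylcholinesterase (AChE) and
butyrylcholinesterase (BChE) — or any pair of related targets docked with a
Vina-family program.

Selective cholinesterase inhibitors matter because AChE levels fall and
BChE levels rise as Alzheimer's disease progresses, so late-stage therapy
looks for BChE-selective compounds. Virtual screening produces one
multi-model PDBQT file per ligand per target; `chesel` turns two such
directories into selectivity calls and the analyses around them:

* **PDBQT I/O** — multi-model Vina ligand output (`REMARK VINA RESULT`
  energy/RMSD lines, atom records with partial charges and AutoDock types,
  `TORSDOF`) and single-model receptor files.
* **Mode statistics** — per ligand: first-mode energy `1st E_A`, mean
  `⟨E_A⟩`, sample SD `σE_A`, SE, mean RMSD bounds; sorting/filtering on any
  of them.
* **Selectivity** — the signed statistic `s = E_A(AChE) − E_A(BChE)` and its
  magnitude `ΔE_A = |s|`; a ligand is AChE-selective when `s < −0.1`
  kcal/mol, BChE-selective when `s > +0.1`, else nonselective. Screen
  summaries with per-class counts, percentages, max ΔE_A and occurrence
  histograms; a tie-corrected Mann–Whitney U/Z test (exact enumeration for
  small samples) for comparing two screens' ΔE_A distributions.
* **Residue proximity** — per-element distance cutoffs (H 1.5 Å, O 1.5 Å,
  N 2.5 Å) against receptor residues, contact-density profiles, top-k
  residue rankings and spatial charge clouds.
* **Ligand properties** — molecular weight, the >18-rotatable-bond
  (TORSDOF) exclusion filter, axis-aligned bounding boxes and volumes,
  Lipinski rule checks.
* **Synthetic screens** — a seeded generator that emulates paired screens
  with planted class fractions, gamma-shaped ΔE_A magnitudes and an extreme
  steric-exclusion tail, so the entire pipeline is testable without running
  docking.

## Worked example

```python
from chesel import (SyntheticScreenConfig, generate_paired_screen,
                    pair_screens, summarize_screen, mann_whitney)

cfg = SyntheticScreenConfig(n_ligands=2000, seed=7)
screen_a, screen_b, truth = generate_paired_screen(cfg)

pairing = pair_screens(screen_a, screen_b, threshold=0.1)
summary = summarize_screen(pairing.records, bin_width=0.1)
print(summary.n_paired, summary.pct_a, summary.pct_b, round(summary.max_delta_a, 2))
```

prints

```
2000 47 47 3.63
```

2,000 ligands paired; 47% called AChE-selective and 47% BChE-selective
(the generator planted fractions 48/46/6, and these counts sit within
binomial sampling error of them). The largest AChE-selective ΔE_A is
3.63 kcal/mol — small, as expected when both targets share a catalytic
triad: A-selective differences stay modest while B-selective ones range
widely. Comparing the two selective classes' magnitudes:

```python
da = [r.delta_ea for r in pairing.records if r.label == "A_selective"]
db = [r.delta_ea for r in pairing.records if r.label == "B_selective"]
res = mann_whitney(da, db)
print(f"U={res.u_statistic:.0f} Z={res.z_statistic:.1f} p={res.p_two_sided:.2g}")
```

```
U=92213 Z=-29.9 p=2e-196
```

a strongly significant difference in ΔE_A distributions, driven by the
broad B-selective gamma tail.

The same stages are available as a CLI:

```bash
chesel simulate --n 500 --seed 1 --out demo
chesel selectivity --screen-a demo/screen_a --screen-b demo/screen_b --out demo/sel
chesel report --screen-a demo/screen_a --screen-b demo/screen_b --out demo/full --plots
chesel vina-config --receptor rec.pdbqt --size 30 30 30 --out conf.txt
```

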