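# Methods

## Problem and model

`chesel` analyses paired virtual screens: one ligand library docked with a
Vina-family program against two related targets — canonically
acetylcholinesterase (AChE) and butyrylcholinesterase (BChE), the two
cholinergic hydrolases whose relative levels shift as Alzheimer's disease
progresses. Docking itself is out of scope; the package starts from the
multi-model PDBQT output files docking produces and ends with selectivity
calls, distributions, a rank test, residue-contact densities and property
filters.

The selectivity statistic is the difference between the two first-mode
(lowest, i.e. most favourable) binding free-energy estimates:

    s = E_A(AChE) − E_A(BChE)        [kcal/mol]
    ΔE_A = |s|

Since more negative energy means stronger predicted binding, `s < 0` marks
an AChE-selective ligand and `s > 0` a BChE-selective one; summary tables
report the magnitude ΔE_A. A ligand is called selective only when
`|s| > threshold` strictly; `|s| = threshold` is nonselective. The default
threshold of 0.1 kcal/mol is one unit of the energy resolution Vina prints,
i.e. the smallest difference the output format can express.

Assumptions worth stating:

* **First-mode comparison.** Only mode-1 energies enter `s`. Per-ligand mode
  statistics (mean, sample SD, SE over all modes) are computed precisely to
  let users check that the mode-1 energy is representative; in practice the
  all-mode mean tracks the first mode closely.
* **Positive energies are data.** Ligands too large for a narrow active-site
  gorge can receive positive (repulsive) energies against that target. They
  are retained, and they generate the >100 kcal/mol tail of the ΔE_A
  distribution; dropping them would silently remove exactly the
  steric-exclusion signal the analysis is about.
* **Polar hydrogens only.** Ligand PDBQT files carry only polar hydrogens
  (AutoDock merges non-polar H into heavy atoms), so every hydrogen analysis
  means AutoDock type `HD`.

## Per-ligand mode statistics

For a ligand with mode energies `e_1 ≤ … ≤ e_n`: `first_ea = e_1`,
`mean_ea = ē`, `sd_ea` with the sample (n−1) denominator, `se = sd/√n`, and
means of the RMSD lower/upper bounds (mode 1 contributes 0/0 by Vina's
convention). The sample denominator is the default because screens run with
as few as 6 modes, where the n vs n−1 distinction is material;
`sample_sd=False` switches to the population form. A single mode yields
sd = se = 0 by convention. `n_modes` is always reported so consumers can
stratify screens that used varying mode counts (6–20).

## Classification and summaries

Pairing joins the two screens on ligand identifier; unpaired ligands are
counted and returned, never dropped. Classification partitions every paired
ligand into exactly one of {A_selective, B_selective, nonselective}.
Percentages are reported both exactly and rounded to the nearest integer
(the convention for quoting screen-level fractions). Histograms use a
default bin width of 0.1 kcal/mol — again the printed energy resolution —
and an optional cutoff beyond which values pool into one overflow bin whose
edge is the cutoff, so bin counts always sum to the number of records.

## Mann–Whitney U

Two ΔE_A samples are compared with the rank-sum U statistic using midranks
for ties, the tie-corrected variance

    Var(U) = n1·n2/12 · [ (N+1) − Σ(t³−t) / (N(N−1)) ],   N = n1+n2,

`Z = (U − n1·n2/2)/√Var`, and a two-sided p from the normal approximation
with no continuity correction. Tie correction is always on because energies
quantised at 0.1 kcal/mol tie constantly. When `n1+n2 ≤ 12` an exact
permutation p (enumeration of all C(N, n1) first-sample placements, counting
arrangements at least as far from n1·n2/2 as observed) is also reported.

The normal approximation is a large-sample device. Exhaustive enumeration of
the null distribution shows its worst-case deviation from the exact
two-sided p is large for tiny or unbalanced samples (≈0.23 at n1=n2=2,
≈0.22 at 1 vs 9, ≈0.12 at 4 vs 4) and first falls below 0.05 around
n1=n2=8 (worst case 0.046). The tests therefore check exact-enumeration
correctness on every split with N ≤ 10 and the ≤0.05 normal-vs-exact
agreement at 8 vs 8, where it holds for every possible sample. Callers with
small samples should use `p_exact`. When all pooled values are identical the
variance is zero; the result is flagged degenerate with p = 1.

## Residue proximity

For each mode-1 ligand atom with element in the cutoff set (defaults
H 1.5 Å, O 1.5 Å, N 2.5 Å), the minimum distance to every receptor residue
is computed from the full atom–atom distance matrix; a (ligand atom,
residue) pair with minimum distance ≤ cutoff (inclusive boundary) is one
contact event. Counting per pair at minimum distance, rather than per
receptor atom, avoids over-weighting large residues; a
`per_receptor_atom` flag enables the alternative for sensitivity analysis.
Events aggregate into per-(residue, element) counts whose top-k ranking
(ties broken by ascending residue number) identifies the preferred
interaction partners. Brute-force all-pairs search is the implementation as
well as the test oracle — screen sizes here never justify a spatial index,
and correctness at the cutoff boundary is easier to guarantee.

Spatial clouds collect all mode-1 atoms of one element with their partial
charges for 3-D scatter maps; carbon is excluded from the default analysis
set since the maps target hydrogen-bonding and electrostatic partners.

## Ligand properties

* Molecular weight: Σ count·weight with IUPAC 2021 conventional atomic
  weights, reported to 2 decimals (caffeine C8H10N4O2 → 194.19 g/mol).
  PDBQT files omit non-polar hydrogens, so MW requires a formula and is
  never inferred from the atom records.
* Rotatable bonds: the PDBQT `TORSDOF` value — the torsion count the docking
  search actually used, and the only rotor count those files carry. The
  filter drops ligands with strictly more than 18 rotors by default; a
  missing record keeps the ligand with a warning.
* Bounding box: axis-aligned extents (max−min per axis) sorted descending,
  volume = product. This is a shape proxy, not a van der Waals volume; the
  printed dimension products of the size exemplars (ambrisentan
  10.48×8.38×7.60 ≈ 667 Å³, ergotamine 18.931×10.122×6.750 ≈ 1293 Å³)
  reproduce under exactly this definition. Extents are frame-dependent; an
  optional principal-axes mode is rotation-invariant up to reflection.
* Lipinski: MW ≤ 500, HBD ≤ 5, HBA ≤ 10, logP ≤ 5, each individually
  togglable since screens often apply only a subset. HBD/HBA are
  operationalised structurally (polar H count; N+O count) because PDBQT has
  no bond table; logP must be supplied externally or the rule is skipped.

## Synthetic screens: what they emulate and what they do not

The generator plants, per ligand: a class label from fractions
(0.48, 0.46, 0.06) — the composition observed in an FDA-approved-library
screen of this kind; a signed selectivity whose magnitude is
`threshold + 0.002 + Gamma(shape, scale)` for selective classes (A: shape 2,
scale 0.35, keeping A-selective magnitudes concentrated below ~2.7 kcal/mol;
B: shape 2, scale 1.5, concentrated over 0.1–10) and uniform on
[0, threshold] for the nonselective class; a 1% uniform 100–120 kcal/mol
tail inside the B class for the steric-exclusion regime; first-mode energies
N(−8.5, 1.0) kcal/mol, matching the range screen tables print; 6–20 modes
with Exponential(0.25 kcal/mol) inter-mode gaps; and simple atom sets
(C/N/O/HD cycling, charges N(0, 0.2 e) clipped to [−1, 1]). The 0.002
margin keeps planted labels at least two write-precision units clear of the
threshold, so pipeline recovery is exact away from the boundary.

Fixture energies default to 3 decimals rather than Vina's 1 so statistical
tests are not quantisation-dominated; a 1-decimal mode restores the faithful
format. Each ligand draws from an independent seeded substream, making
output byte-identical under a seed and prefix-stable as `n_ligands` grows.

Not emulated: physically realistic poses, pose–energy correlation,
force-field structure in the energies, conformer diversity, or any
receptor-dependent geometry. Passing recovery tests therefore demonstrates
that the *bookkeeping and statistics* of the pipeline are correct under
known truth — not that docking energies themselves are accurate, which no
post-processing can show.

Proximity fixtures place single-purpose residues 12 Å apart with side atoms
offset along ±x and plant ligand atoms in the local yz-plane at exact
distances, so the designated atom is provably the nearest and the planted
table is its own oracle. Planted distances within 0.01 Å of a default
cutoff are rejected unless boundary testing is requested explicitly.

## Numerical choices and degenerate inputs

* Energies are stored at full float precision; files fix the precision
  (RESULT lines %.1f by default, %.3f for fixtures; coordinates %.3f).
* Ties in mode energies keep file order; the parser never re-sorts, and rank
  is the 1-based MODEL position.
* Affinity-order violations in input files warn and set a flag rather than
  erroring, since hand-edited third-party outputs occur in practice.
* Unknown AutoDock atom types map to "other", never dropped.
* Empty mode lists, empty receptors, zero paired ligands and empty record
  lists raise; empty element clouds warn and return an empty cloud.
* Problem sizes in the test-suite oracles (1,000-fixture contact sweeps,
  1,000-ligand statistics sweeps, a 5,000-ligand recovery screen) were
  chosen to make binomial 2σ bounds meaningful while keeping the whole
  suite around twenty seconds on one CPU.

## Known limitations

* Selectivity is a docking-score difference; it inherits every bias of the
  scoring function and says nothing about kinetics or mechanism.
* ΔE_A between screens with different search-box sizes is not comparable
  (the cafestrol example flips from nonselective to B-selective when the
  box shrinks); the package treats box provenance as the caller's problem
  and only emits docking config files.
* HBD/HBA counts from PDBQT atom records approximate the bond-aware
  definitions; for publication-grade Lipinski filtering use a
  cheminformatics toolkit on the original structures.
* The Mann–Whitney normal approximation is unreliable below ~8 observations
  per group; use the exact p there (reported automatically).
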