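# Methods

## The model

The package analyses trajectories of a protein adsorbing onto a single
rigid graphene sheet. Graphene carbons are treated as uncharged 12-6
Lennard-Jones particles (σ_cc = 3.4 Å, ε_cc = 0.3598 kJ/mol), so the only
protein–sheet interaction term is dispersion:

    V(r) = 4 ε_ij [ (σ_ij / r)^12 − (σ_ij / r)^6 ],

with Lorentz–Berthelot combining (σ_ij arithmetic mean, ε_ij geometric
mean) and plain truncation at the cutoff (default 12 Å; no switching or
shifting function, and no electrostatics — the carbons carry no charge).
Minimum-image distances are used whenever a frame carries an orthorhombic
box; frames without a box are treated as non-periodic.

All internal lengths are ångström (PDB native); configuration values given
in nm are converted on load (1 nm = 10 Å). Energies are computed in kJ/mol
and reported in kcal/mol by default (1 kcal = 4.184 kJ).

### Protein-side Lennard-Jones parameters — the main simplification

Per-residue energies need LJ parameters for every protein heavy atom. The
package ships a compact **element-level** table (`data/lj_params.txt`:
C, N, O, S, P, H with σ/ε of CHARMM-family heavy-atom magnitude) instead
of full force-field atom typing. This is a deliberate simplification and
the largest one in the package: element-level parameters preserve the
*relative* dispersion strengths that per-residue rankings, threshold
tagging and energy-drop comparisons rest on, but absolute per-residue
energies are approximate. The table is a plain-text file
(`element sigma_nm epsilon_kJmol`) and fully overridable per run
(`energy.lj_params` in the configuration). Hydrogens are excluded from
energy sums by default (the sheet has none; protein hydrogens contribute
negligibly to dispersion ranking) and can be switched on.

## Metric definitions and conventions

* **Contact**: heavy-atom pair of the two groups with distance strictly
  < 6.0 Å ("smaller than"); a tie at exactly 6.0 Å does not count.
* **Contact surface area**: ½(SASA_A + SASA_B − SASA_AB), Shrake–Rupley
  SASA with probe 1.4 Å, 960 sphere points, element radii
  (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å). The half-buried-SASA
  convention is a choice — "contact area" has no unique definition — and
  is stated here so numbers are comparable across runs.
* **Contact probability**: fraction of window frames (default: the whole
  trajectory; an equilibration discard is configurable) in which a residue
  has ≥ 1 heavy-atom contact with the sheet.
* **Native contacts**: residue pairs whose closest heavy atoms are < 6.0 Å
  in the reference frame, with sequence separation j − i > 3 applied
  *within* a chain only; inter-chain pairs are always eligible (the
  separation rule is a sequence notion and has no meaning across chains).
  Q of a frame is the fraction of native pairs whose minimum heavy-atom
  distance is still below that same cutoff; the reference frame scores
  exactly 1.
* **RMSD** is computed after optimal least-squares superposition (Kabsch,
  SVD) of the selected heavy atoms. Without superposition the rigid drift
  of an adsorbing protein would dominate, which would defeat RMSD's role
  as a structure-integrity measure. Per-chain RMSD superposes each chain
  independently by default (switchable to one whole-protein fit).
* **FSS count**: number of distinct water molecules whose counting site is
  within (≤) 5 Å of any side-chain heavy atom. The counting site is the
  water oxygen by default — the standard convention, insensitive to
  hydrogen placement — with an any-heavy-atom mode for sensitivity checks;
  the boundary is inclusive ("within 5 Å"), with an exclusive mode
  available. Side chain = all residue atoms except N, CA, C, O, terminal
  oxygens and backbone hydrogens; glycine (no side-chain heavy atom) is
  rejected with a pointer to use a backbone shell instead.
* **Key-residue rules**: (i) energy rule — window-averaged vdW energy
  ≤ −10 kcal/mol (inclusive) in at least 2 of 3 replicas; the averaging
  window defaults to the final 25 % of frames, i.e. the adsorbed plateau;
  (ii) probability rule — contact probability strictly > 0.6. The rules
  are reported separately and composed in union/intersection/single-rule
  modes, since they corroborate rather than define each other. Histidine
  is classed as basic by default (switchable to polar).
* **Energy drop** of a residue = (baseline-window mean) − (plateau-window
  mean); positive when binding strengthens. Cross-replica spread is the
  sample standard deviation (ddof = 1).

## Neighbour search

All pairwise metrics are defined by their brute-force double loop; the
implementation uses a k-d tree (periodic when boxed, `scipy.spatial.cKDTree`)
with a padded query radius and exact re-filtering at the boundary, so the
accelerated path returns *identical* results to the double loop. That
equivalence — contacts, per-residue energies, FSS counts, native sets —
is asserted over randomized fixtures in the test suite rather than assumed.
When a box edge is shorter than twice the cutoff (minimum-image ambiguity)
the code falls back to the exact dense path.

## Graphene builder

Rectangular honeycomb lattice, two-atom basis arranged as a four-atom
rectangular cell (x-period 3a, y-period √3·a), armchair edge along x by
convention — the edge type of a production sheet is not standardised, so
the convention is arbitrary and stated here. Equilibrium C–C bond length
1.42 Å, the accepted graphene value. The requested extents are rounded to
whole lattice periods. Edge atoms are left unsaturated, consistent with an
uncharged pure-carbon LJ model; atoms on the rectangular rim have 1–2
bonded neighbours (corner atoms 1), interior atoms the full 3. The sheet
is static: its bonded flexibility belongs to the MD engine, not to this
analysis package.

## The synthetic-data generator

The generator exists so that every stage has inputs with exactly known
answers. It emulates the qualitative features of protein-onto-graphene
adsorption trajectories:

* **Chains** are hairpins of two antiparallel strands (6 Å spacing both
  along and between strands), so cross-strand partner residues provide
  native contacts and Q is well defined. Residues are rigid, flat
  side-chain templates named and sized after real side chains (Arg 7 heavy
  atoms with 3 N, Tyr 8 with 1 O, Trp 8 with 1 N, plus compact background
  templates); metrics depend only on distances, so fixed templates keep
  the planted ground truth exact.
* **Successive-wave schedule**: each chain translates rigidly toward the
  sheet at 2 Å/frame, crossing the 6 Å contact cutoff *exactly* at its
  planted onset frame (gap 5 Å at onset, 7 Å the frame before) and
  settling at the adsorbed gap of 3.45 Å — the LJ contact-minimum distance
  for the carbon cross pair, where planted adsorber energies sit at
  −11.5 to −12.3 kcal/mol. Non-adsorbing residues ride 8.4 Å higher, which
  puts them outside the contact cutoff and at the very edge of the energy
  cutoff (≈ −0.05 kcal/mol): planted and background residues straddle both
  tagging thresholds with a wide margin. The default plan plants 14
  adsorbers — 9 basic, 5 aromatic — across three chains with onsets at
  frames 10/20/30 of 100 frames sampled every 20 ps, echoing the observed
  asynchronous, burst-like adsorption of a multi-chain protein and the
  preponderance of basic residues among its key binders.
* **Jitter** is an optional per-frame Gaussian *rigid displacement of each
  chain* (residue clusters and chains are rigid by construction, so
  per-atom noise would contradict the generator's own geometry). Because a
  symmetric height distribution is unphysical against a hard wall — rare
  2σ excursions into the 12-6 repulsion produce +20 kcal/mol spikes that
  no adsorbed molecule would sample — the chain's lowest atom is floored
  0.1 Å below the equilibrium gap, a one-sided excluded-volume constraint.
  With σ = 0.3 Å, planted onset frames are recovered within ±2 frames and
  planted energies stay below −10.7 kcal/mol.
* **Water** is a static oxygen grid (3 Å spacing) in a slab 2–14 Å above
  the sheet. Grid sites the descending solute would ever overlap (< 1.2 Å)
  are moved to a far reservoir from the start; at each chain's onset the
  interface waters under its adsorbing residues (xy within 4 Å of the
  final footprint, z ≤ 5.2 Å) are expelled to the reservoir — the scripted
  analogue of interfacial dehydration. Waters are otherwise immobile:
  solvent dynamics are irrelevant to counting-logic tests. Atom counts
  stay constant across frames (expelled waters relocate, never vanish).
* **Replicas** share the schedule and ground truth and differ only in
  their jitter stream; a fixed seed fixes the full output bit pattern.

What passing tests on this generator do **not** show: real force-field
energetics (absolute contact magnitudes of a ~600 k-atom system are out of
reach at this scale), solvent dynamics, protein flexibility or unfolding,
or rotameric side-chain behaviour. They do show that every metric computes
its definition exactly and that the tagging logic recovers a known answer
through the complete I/O → metrics → report chain.

## Numerical choices and degenerate inputs

* Cutoff boundaries: contacts strict `<`; FSS inclusive `≤`; energy-rule
  threshold inclusive `≤`; probability-rule threshold strict `>`. Each is
  tested at the boundary.
* Empty native-contact set: building one is a valid (warned) result;
  evaluating Q against one is an error, and the pipeline omits Q columns.
* RMSD superposition requires ≥ 3 atoms; the SVD reflection case is
  handled by the usual determinant sign correction.
* Table output is TSV with 6 significant digits.
* Problem sizes: the shipped tests and the acceptance script run systems
  of ~3 300 atoms × 100 frames × 3 replicas (one-chain variants are
  smaller), chosen so the complete suite runs in well under a minute of
  compute per stage while still exercising the accelerated search paths.

## Known limitations

* Element-level protein LJ table (see above) — per-residue rankings, not
  absolute binding energies.
* Orthorhombic boxes only; triclinic cells are not reduced.
* The contact-area convention (half buried SASA) is one of several in use;
  compare like with like.
* The builder emits finite rigid sheets only — no periodic (infinite)
  sheets, nanotubes, multilayers or oxidised decorations.
* No secondary-structure, RMSF, hydrogen-bond or residence-time analyses.
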