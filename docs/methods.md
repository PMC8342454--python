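# Methods

This note documents the models, conventions and design choices behind the
package, in the order a user meets them: the fibril data model, the
restraint machinery, the sampler, and the analysis pipeline. It also states
what the synthetic test bed does and does not demonstrate.

## Fibril specification and the ideal lattice

A `FibrilSpec` declares a target fibril: the peptide sequence (one per
chain; all protocols require identical chains), the chain count, the strand
arrangement (`parallel` or `antiparallel`, applying to adjacent strands
within a sheet), an ordered assignment of chains to sheets, and an integer
registry offset (0 = in-register).

`fixtures.build_ideal_fibril` turns a spec into coordinates. Each chain is
grown by internal-coordinate (NeRF) placement of three backbone beads per
residue (N, Cα, C; standard bond lengths 1.458/1.525/1.329 Å and angles
111.0/116.6/121.9°, ω = 180°) at the arrangement's dihedral centers, so
every chain is an exact discrete helix. Parallel neighbours are pure
translations at the strand spacing (default 4.8 Å), which makes every
in-register Cα–Cα pair distance exactly the spacing. Antiparallel
neighbours exploit an exact symmetry: the reversed Cα trace of a
uniform-dihedral chain is rigidly congruent to the forward trace (the dyad
of a discrete helix), so superposing the reversed trace and translating
yields exact 4.8 Å distances for the i ↔ L+1−i pairing. Sheets are offset
along the sheet normal (default 10 Å, inside the 8.8–14.6 Å range seen
across real fibrils). Fixtures carry no side chains; "heavy-atom" inputs
are accepted from users but never generated.

The pairing convention is shared between the builder and the restraint
generator: parallel strands pair residue i with i, antiparallel strands
pair i with L+1−i, shifted by the registry offset. This makes the ideal
lattice satisfy every protocol restraint exactly — the cross-module
consistency oracle the test suite leans on.

## Flat-bottom restraints and activation

Distance restraints are zero on [r2, r3], quadratic on [r1, r2] and
[r3, r4], and continue linearly (slope-matched) outside, keeping forces
bounded for arbitrarily wrong configurations. Protocol values:

* inter-strand: centre 4.8 Å, half-width 0.2 Å, shoulders 1.0 Å;
* inter-sheet: centre 10 Å, half-width **3.0 Å**. The wide bottom is
  deliberate: the protocol connects all 3×3 pairs of the three central
  residues of facing strands, and in any rigid ideal lattice those pairs
  span roughly 10–12.6 Å (pairs offset along the strand axis sit on the
  lattice diagonal). A ±0.2 Å bottom would make the protocol unsatisfiable
  by construction; the 3.0 Å half-width also encodes the genuine spread of
  sheet spacings in real fibrils.
* dihedrals: half-width 30°, quadratic outside with no linear tail (angles
  are bounded); centres (−119°, +113°) parallel, (−139°, +135°)
  antiparallel; applied to interior residues (2..L−1) only, since terminal
  residues lack one of φ/ψ.

The base distance force constant is 2.5 kJ/mol/Å² (the conventional
250 kJ/mol/nm², converted by 0.01 at the config boundary); the dihedral
constant is 0.02 kJ/mol/deg², a few kT at ~15° beyond tolerance.

Restraints form a two-level hierarchy: within a group only the `n_active`
lowest-energy members are enforced (ties broken by declaration order), and
within a collection only the `n_active_groups` lowest-energy groups. This
is re-selected at every evaluation, so inconsistent members of ambiguous
data are silently ignored wherever the structure contradicts them.
Protocol-generated restraints are all asserted true and default to full
activation; partial activation is exposed for user-supplied tables. The
posterior log-weight is −(E_phys + E_c)/(k_B T) with k_B fixed at
0.0083145 kJ/mol/K; the data normalisation cancels in every ratio and is
never computed.

A density report (restraints per residue, advisory flag below 0.5) flags
protocols sparse enough that prediction reliability is empirically poor.

## The coarse-grained surrogate potential

The sampler's physical engine is a backbone-bead Metropolis Monte-Carlo
model, chosen so the replica-exchange machinery — the actual subject of the
package — runs in minutes on one CPU. Terms and defaults:

* harmonic virtual bonds (200 kJ/mol/Å²) at the standard backbone lengths
  (Cα-only inputs use a 3.8 Å Cα–Cα bond instead);
* harmonic bond angles (100 kJ/mol/rad²) at the backbone rest angles and a
  planar-peptide ω torsion (0.02 kJ/mol/deg²) — without these, bead chains
  are far floppier than real peptides and no amount of restraining
  produces a rigid aggregate;
* soft-core excluded volume: ½·k(r_ev − r)² below r_ev = 3.0 Å with
  k = 2 kJ/mol/Å². The softness is a feature: at ladder-top temperatures
  chains can pass through each other and re-register instead of jamming;
* cohesion wells: Gaussian attractions between Cα pairs whose centres are
  read off the ideal lattice for the spec (a Gō-style, structure-based
  parameterisation). In-sheet wells connect corresponding residues of
  adjacent strands plus the two residue-diagonal neighbours (depth
  8 kJ/mol, σ 0.5 Å); sheet-interface wells connect same-rank and
  diagonal-rank strand pairs across facing sheets at every residue (depth
  6 kJ/mol, σ 0.6 Å). The diagonal members matter: distance wells alone
  are shear-soft (a perpendicular slide changes a distance only to second
  order), and without them sheets slide and strands slip register freely.
  These wells are the surrogate's stand-in for backbone hydrogen bonding
  and steric-zipper packing, which a molecular force field provides and a
  bead model otherwise lacks. The surrogate is therefore deliberately
  funnelled toward cross-β geometry; see "What the tests show" below.
* an optional flat-bottom spherical wall (radius 20 Å in the demonstration
  runs, 1 kJ/mol/Å²) emulating a finite simulation volume, so that the
  unrestrained top replica keeps revisiting assembled states instead of
  diffusing away irreversibly.

## Replica exchange

`build_ladder` produces a geometric temperature ladder
T_i = T_min (T_max/T_min)^{i/(n−1)} (defaults 300→450 K, 30 replicas; the
demonstration uses 8) and restraint scales
α_i = (e^{s(1−i/(n−1))} − 1)/(e^s − 1) with shape s = 3: exactly 1 at the
bottom, exactly 0 at the top, exponential in between. One sweep attempts a
Gaussian displacement per bead (σ 0.25 Å at 300 K) and a rigid
translation+rotation per chain (σ 0.6 Å / 0.15 rad), widths scaled by
√(T/300); each proposal is symmetric and accepted by the Metropolis rule
at the replica's Hamiltonian U_i = E_cg + α_i E_c, so balance holds
move-by-move. Because α scales all restraints equally, the lowest-energy
activation ranking is α-invariant and restraint energies are cached at
unit scale.

Every `swap_interval` sweeps (default 10) alternating even/odd neighbour
pairs attempt an exchange with
Δ = β_i[U_i(x_j) − U_i(x_i)] + β_j[U_j(x_i) − U_j(x_j)], acceptance
min(1, e^{−Δ}); configurations swap on acceptance and walker identities
are tracked. Each replica draws from its own counter-based seed stream
derived from the master seed, so runs are bit-reproducible and independent
of execution order. Kernel calls recompute all cached energies from
scratch on entry, bounding any incremental drift to a single interval.

## Ensemble processing and classification

Frames from the `n_lowest` = 5 lowest-temperature replicas are pooled
after discarding the first `discard_fraction` = 0.25 of each replica's
frames (the surrogate has no physical clock, so equilibration is a
fraction, not a time). Pairwise whole-aggregate Cα RMSD after optimal
superposition (batched Kabsch via vectorised 3×3 SVD) feeds average-linkage
agglomerative clustering; merging stops when the smallest average linkage
exceeds ε = 2 Å. Clusters are ordered by population (ties: lowest member
frame first) and represented by their medoid. Classification: top
population > 0.40 → confident success (additionally requiring the centroid
within 5.0 Å Cα RMSD when a reference is supplied; a high population with
a distant centroid is reported as ambiguous, not success), < 0.20 → likely
failure, otherwise ambiguous.

## Structure metrics

* Kabsch superposition with optional weights and reflection correction.
* Whole-aggregate RMSD over one global fit; `best_permutation` searches
  chain assignments among identical-sequence chains (exhaustive ≤ 8
  chains, pair-swap hill climbing beyond).
* GDT_TS: mean over {1, 2, 4, 8} Å of the percentage of Cα pairs within
  the cutoff after a single global fit — a documented simplification of
  the full LGA multi-superposition search.
* TM-score: (1/L) Σ 1/(1+(d_i/d0)²) with d0 = 1.24(L−15)^{1/3} − 1.8
  computed from the total aggregate length and clamped to ≥ 0.5 Å (short
  peptide aggregates give a negative d0 otherwise). The score-maximising
  superposition is approximated by iterative subset refinement seeded from
  the global fit and contiguous fragments, followed by a direct
  Nelder–Mead polish of the score over the rigid motion; on 5-residue toys
  this matches (or exceeds) an exhaustive rotation-grid search within 1e−3.
* Native contacts: reference Cα pairs within 8 Å, excluding intra-chain
  pairs separated by fewer than 3 residues; the score is the percentage
  preserved in the model. The criterion is a documented package choice.

## Problem sizes and numerical conventions

The demonstration system is a 6-residue × 4-chain fibril (two sheets of
two parallel strands). Folding runs use 8 replicas and 10⁵ sweeps from
extended chains separated by ≥ 15 Å: the toy converges well within half
that (top-cluster population is stable from ~5×10⁴ sweeps), so 10⁵ gives a
comfortable margin while keeping a five-seed demonstration inside a
coffee-break on one CPU. Coordinates are Å throughout; energies kJ/mol;
temperatures K. PDB output is fixed-column with 10³ coordinate precision;
only the first model is read by default, alternate locations other than
blank/'A' are dropped, HETATM and insertion codes are rejected or ignored
as documented in `structures`.

## What the synthetic test bed shows — and what it does not

The fixtures emulate the geometry of cross-β fibrils (spacings, registry,
dihedrals, polymorph moves) but not their chemistry: no side chains, no
solvent, no sequence-dependent energetics. The surrogate potential is
structure-based, so the folding demonstration shows that the restraint
machinery, ladder, exchange rule and analysis pipeline are correct and
work together — it does not show that this package predicts novel fibril
structures from sequence with a physical force field, and per-system
accuracies obtained with molecular dynamics engines are out of its scope.
Restraint-level degeneracies the protocol genuinely cannot resolve (e.g.
a sheet flipped about the strand axis preserves every protocol restraint)
are likewise resolved here only by the surrogate's structure-based wells.

Known limitations: homomeric protocols only (the types allow heteromeric
specs, but no protocol is generated for them); no mmCIF; no biological-
assembly expansion; the clustering operates jointly on the pooled frames
rather than per replica; GDT_TS is single-superposition; staged assembly
requires single-sheet specs with a divisible chain count.
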