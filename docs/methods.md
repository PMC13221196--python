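# Methods

This note documents the models, numerical choices, and limitations behind
`hotforge`, in the order the pipeline runs.

## Structure model

PDB files are parsed (via gemmi) into a flat atom/residue model. Alternate
locations other than blank/'A' are dropped — a deterministic single-conformer
choice appropriate for energetic analysis. Waters (HOH/WAT) are retained and
flagged; they are excluded from all hotspot aggregation. Non-water HETATM
residues (ions, nucleotide analogs, small-molecule ligands) stay in the model
and participate in atom-level energetics, but residue-level hotspot tables
cover protein residues only unless `include_hetero` is set. Residue numbering
is taken verbatim from the file, so published residue labels survive into
every table; the canonical identifier used in all exports is
`chain:resname:resseq[icode]` (e.g. `A:GLU:957`). Coordinates are Å
throughout. PDB is the contract format; mmCIF is out of the minimal build.

## Nonbonded parameters and the hydrogen-folding scheme

The package ships an embedded parameter table
(`src/hotforge/data/ff14sb_subset.csv`) with partial charges (e) and LJ
σ (Å) / ε (kcal/mol) per (residue, atom) in the Amber fixed-charge
convention, covering the 20 canonical amino acids plus the HID/HIP histidine
variants. "HIS" maps to the neutral Nε tautomer (HIE) and cysteine defaults
to the neutral thiol — the most common states at pH 7. Every template sums
to its integer formal charge within 1e-3 e (tested exhaustively).

Crystal structures usually lack hydrogens, and this package deliberately
avoids hydrogen reconstruction and pKa prediction. Instead,
`fold_hydrogen_charges` adds the template charge of each absent hydrogen to
its canonically bonded heavy atom (the bond topology is a column of the
parameter table), leaving a heavy-atom-only model whose per-residue monopole
is exact. Hydrogen LJ terms are dropped with the hydrogens. Consequences:

* absolute pair energies differ from a fully protonated calculation
  (hydrogen-bond geometries are represented only through their heavy atoms);
* relative per-residue rankings — the quantity the pipeline actually
  consumes — are robust to the approximation, because favorable
  electrostatics between charged/polar groups are preserved at the monopole
  level;
* results near histidines depend on the assumed tautomer, as they do in any
  fixed-protonation workflow.

Terminal residues: when terminal-variant atoms are present, OXT receives the
carbonyl-oxygen parameters and the backbone carbon absorbs the remainder so
the residue nets −1 (symmetrically +1 for H1–H3 amine termini). This is a
charge-balanced package convention, not a published terminal charge set.
Termini without variant atoms use the internal template, with a warning.

## Pair energetics

For receptor–ligand atom pairs within the distance threshold (default 4.5 Å,
inclusive):

* `E_LJ = 4 ε_ij [(σ_ij/r)^12 − (σ_ij/r)^6]`, Lorentz–Berthelot combination
  (σ arithmetic mean, ε geometric mean — the Amber convention);
* vacuum electrostatics `E_coul = K q_i q_j / r`, K = 332.0636
  kcal Å mol⁻¹ e⁻²;
* screened electrostatics `E_coul = K q_i q_j / (s r²)`, i.e. a
  distance-dependent dielectric ε(r) = s·r with s = 1 by default. The
  screening factor is a knob so ε(r) = 4r conventions can be matched.
  Screened mode is the default for residue-level aggregation.

No switching/shifting function, periodicity, or Ewald summation is applied:
energies are the bare formulas over the enumerated pairs, and the cutoff may
be set to infinity for exhaustive sums. Since all evaluated pairs are
inter-chain, every pair is a true nonbonded pair and no 1-4 scaling arises.
Neighbor search uses a k-d tree; ordering of the contact list is
deterministic (receptor atom index, then ligand atom index).

## Hotspot aggregation

Two favorability definitions are first-class:

* **atom_pair** (default): an atom pair contributes iff E_total < 0 and
  r ≤ 4.5 Å. This is the physics-engine path.
* **residue_pair**: a residue pair contributes iff its summed E_total ≤
  −1.0 kcal/mol and its minimum interatomic distance ≤ 3.5 Å. Summation over
  atom pairs happens *before* thresholding. This is the convention used when
  aggregating external residue-pair contact tables.

Each qualifying contribution adds |E| to exactly one residue on each side,
so receptor and ligand totals agree exactly (a standing invariant). Ranks
are 1-based by descending strength with a total-order tie-break (ascending
chain id, then residue number, then insertion code) so Top-N selections are
reproducible across platforms. Strengths are reported in kcal/mol.
Thresholds are inclusive (≤) everywhere.

## Contact maps

Maps are built over Cα atoms of an ordered chain list: distance (Å),
reciprocal distance 100/d (dimensionless), and binary d ≤ cutoff (default
8 Å, inclusive). The reciprocal map's diagonal and any pair closer than
1e-6 Å are masked as NaN rather than reported infinite, keeping exports
finite and plottable. Residues without a Cα (HETATM ligands) are dropped
with a warning, never interpolated. Chain boundaries are recorded so
interface blocks can be sliced; `interchain_block(A, B)` equals the
transpose of `interchain_block(B, A)`.

## Benchmarking

External residue-pair exports are canonicalized under a configurable dialect
(column mapping + residue-label regex; the shipped default parses labels
like `GLU 957 (A)`), waters are dropped, and the table is aggregated with
the same residue-pair criteria as native tables. Concordance between two
hotspot tables uses:

* Spearman rank correlation over residues present in **both** tables
  (average ranks on ties); residues unique to one method are reported as a
  diagnostic list, not silently mixed in;
* Pearson correlation of strength magnitudes over the same shared set;
* Top-N overlap at configurable N (default 5, 10, 20, 30, 50): intersection
  size, Jaccard index, and recall. `recall_a = |TopN_a ∩ TopN_b| / N` (B's
  recovery of A's Top-N at the same N), symmetrically for `recall_b`; for
  tables shorter than N the denominator falls back to the actual set size.

With fewer than 3 shared residues (or zero variance in either strength
vector) correlations are flagged undefined rather than fabricated; overlap
statistics are still computed.

## Ensemble triage and diagnostics

* **Confidence filter**: keep designs with mean pLDDT ≥ 80 and iPAE ≤ 15,
  both inclusive; rank by ascending iPAE, then descending pLDDT, then design
  id (a deterministic total order, since confidence alone is not one); keep
  the top 100 by default. iPAE is treated as an engine-reported scalar and
  thresholds are applied verbatim with no unit conversion — prediction
  engines are not consistent about its units, and the filter is defined on
  the reported numbers. `helicity`, `mpnn_score`, and
  `n_interface_residues` are upstream pass-through columns, never
  recomputed.
* **Backbone RMSD**: one optimal rigid-body least-squares superposition
  (Kabsch, SVD with a determinant correction guaranteeing a proper
  rotation) over all mapped backbone atoms (N, Cα, C, O), then per-residue
  RMSD over each residue's four atoms and a global RMSD over all of them.
  Residue correspondence defaults to a global sequence alignment of the two
  chains, so renumbered designs map through their sequence; an explicit
  mapping can be supplied. Residues missing backbone atoms are skipped with
  a warning; fewer than 3 usable residues is an error. Note that a single
  displaced residue in an otherwise identical structure reports slightly
  under its true displacement, because it participates in (and drags) the
  global fit — the effect shrinks as 1/N.
* **Energy–distance regression**: ordinary least squares of residue-pair
  energy against mean contact distance; the Pearson r diagnoses packing
  quality (well-packed interfaces show the inverse relationship).
  Zero-variance inputs are flagged undefined.
* **Global alignment**: Needleman–Wunsch with affine gaps (Gotoh recursion),
  BLOSUM62, gap open 11 / extend 1 in the BLAST existence/extension
  convention (a gap of length L costs 11 + L). Traceback ties prefer
  diagonal over up over left, making reported alignments deterministic. The
  test suite checks scores against exhaustive enumeration of all alignments
  for short pairs and against an independent aligner implementation for
  longer ones.
* **Diversity**: normalized Hamming = mismatches / length for equal-length
  ensembles; in alignment mode, pairwise global alignments are used and gap
  columns count as mismatches (normalized by alignment length). Identity is
  1 − Hamming for the same pair. Shannon entropy H = −Σ p log₂ p in bits is
  computed per column, ignoring gaps; entropy profiles for unequal-length
  ensembles are projected onto the columns of the first sequence. A
  per-column residue frequency matrix is exportable as the substrate for
  logo rendering; logo drawing itself is out of scope.

## Synthetic fixtures — what they emulate, and what they do not

`make_helix_dimer` builds two parallel ideal α-helices: backbones are grown
by internal coordinates (φ = −57°, ψ = −47°, ω = 180°, standard bond
lengths/angles), which reproduces the canonical ~1.5 Å rise and ~100°/turn.
Side chains are idealized extended heavy-atom templates pointing radially
outward. `separation` is defined as the closest approach between the two Cα
traces (axes sit at separation + 2 r_Cα apart, and each chain is rotated so
one residue faces its partner), so the minimum inter-chain Cα–Cα distance
lands near the requested value. Engineered salt-bridge residues (Glu/Asp vs
Lys/Arg) are built as directed side chains whose tilt out of the interface
plane is solved numerically so the terminal charged groups meet at a target
contact distance (default 2.9 Å) without interpenetration. Gaussian
coordinate jitter (default σ = 0.02 Å) with a mandatory seed makes fixtures
realistic-looking yet bit-reproducible; there is no global RNG state.

These fixtures emulate interface *energetics* well enough to test ranking,
conservation, and geometry contracts. They do not emulate: rotamer-accurate
side chains (rings are planar approximations), crystallographic artifacts
(altlocs, anisotropy, chain breaks), waters, or realistic sequence
composition. Passing tests therefore demonstrate the correctness of the
machinery, not force-field accuracy on real complexes.

`make_mock_contact_table` splits each planned per-residue strength across
one or more rows with energies at or below the −1.0 kcal/mol favorability
threshold and distances within 3.5 Å, so residue-pair aggregation recovers
the plan exactly at zero noise. `make_sequence_ensemble` mutates
non-conserved positions independently at the given per-site rate to a
uniformly random *different* residue; the expected pairwise normalized
Hamming distance is 2r(1−r) + r²·18/19, which the tests verify by
simulation. `make_mock_metrics` constructs exactly round(n·fraction) rows
passing the confidence thresholds.

## Problem sizes and numerics

The test suite and the acceptance script run entirely on synthetic fixtures:
dimers of 8–60 residues per chain (≤ a few hundred atoms), 20-dimer oracle
sweeps, 100 random rigid transforms, 60-residue benchmark tables, 200-row
metrics tables, and exhaustive alignment enumeration on a reduced two-letter
alphabet — sizes chosen so every oracle can be brute-forced while still
exercising each code path. Energetics agree with the naive double loop to
~1e-13 kcal/mol (double precision round-off); closed-form checks use 1e-12
(LJ) and 1e-6 (Coulomb) tolerances; Kabsch invariance holds to 1e-6 Å.
Floating-point ties in alignment traceback are compared with a 1e-9
tolerance, exact for the integer-valued default scoring.

## Known limitations

* No bonded terms, solvation model, minimization, or dynamics; energies are
  single-point nonbonded interactions on fixed coordinates.
* The screened dielectric is a convention, not a fitted solvent model;
  absolute magnitudes should not be compared across dielectric modes.
* Hydrogen folding discards hydrogen-bond directionality; rankings near
  His/Ser/Thr-mediated contacts are less reliable than those dominated by
  charged groups.
* Biological-assembly generation is not performed; the deposited chains
  named in the interface spec are analyzed as-is.
* The multiple-sequence entropy profile in alignment mode is
  reference-projected, not a true MSA; for equal-length design ensembles
  (the common case) this distinction vanishes.
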