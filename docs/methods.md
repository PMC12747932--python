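# Methods

## Coordinate model

Structures are held in a small Structure → Model → Chain → Residue → Atom
hierarchy; gemmi does the PDB/mmCIF parsing and serialisation behind it.
Author residue numbering is the canonical addressing scheme throughout,
because the structural literature on this system refers to WDR5 24–334 and
Kif2A 114–122 in author numbers. Waters are ordinary residues and are never
dropped on read: the water-network analysis depends on them. Hydrogens are
kept when present, but every geometric criterion is defined on heavy atoms —
the relevant crystal structures are ~1.6–1.9 Å and hydrogen-free. Alternate
locations are collapsed by highest occupancy, ties broken by altloc letter.
Coordinates are Å everywhere; no unit conversion happens internally. PDB
round-trips preserve coordinates to the format's 3 decimals; mmCIF keeps
full precision. Past the PDB serial limit gemmi's hybrid-36 numbering takes
over.

## Superposition

Rigid-body superposition is the SVD (Kabsch) solution with a determinant
correction to exclude reflections; inputs with fewer than three points or
collinear geometry are rejected. Residue matching is by shared author
numbers by default, or by global sequence alignment (identity scoring,
affine gaps, Biopython's PairwiseAligner) when numbering schemes differ;
only aligned identical positions are paired. The default comparison frame is
the Cα set of matched receptor residues in author range 31–334 — the
modelled propeller — since every ring-rotation comparison is made in that
frame. Superposition is unweighted; no B-factor scheme is used. When a
crystal form carries two receptor copies per asymmetric unit, every
copy-pair is superposed and reported, and the headline number is the pair
with minimal RMSD.

## The ring-rotation switch metric

How far the Tyr191 (or Phe191) ring has swung between two structures is
measured as the angle between the unit normals of the least-squares planes
through the six ring carbons, after mapping the second structure into the
first one's propeller frame, folded into [0°, 90°]. This definition was
chosen over alternatives (χ-angle differences, atom displacement) because it
is invariant to the crystallographic CD1/CD2–CE1/CE2 label ambiguity and to
the normal's sign, it needs only the six carbons shared by Tyr and Phe (so
Tyr↔Phe variant comparisons are well defined), and it spans the full
printed range of reported rotations (≈9° to ≈88°). Δχ1 (wrapped to
(−180°, 180°]) and Δχ2 (folded to [0°, 90°] under the ring's 2-fold
symmetry) are reported as secondary descriptors. Against constructed ring
rotations about the CB–CG axis — an axis that lies in the ring plane, so the
normal rotates by exactly the applied angle — the metric recovers the ground
truth to numerical precision; the package's own tolerance target for
synthetic recovery is 0.5°. Comparisons against printed rotation values for
deposited entry pairs should be read with a ±5° allowance, since the
original measurement protocol behind those numbers is not specified.

## Interface fingerprints

All contact typing is heavy-atom geometric, with thresholds collected in
`InteractionCriteria` (defaults in parentheses, all exposed):

- **Hydrogen bond**: donor–acceptor heavy-atom distance ≤ 3.5 Å, plus an
  angle rule — antecedent–donor–acceptor ≥ 90° — that prunes geometrically
  impossible bonds without placing hydrogens. The rule is skipped for donors
  with no antecedent (water O). Donor/acceptor roles come from a chemistry
  table covering the twenty standard residues (backbone N donor except
  proline, carbonyl O and OXT acceptors, the usual side-chain polar atoms)
  and water (both).
- **Salt bridge**: cationic N (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2) to
  carboxylate O (Asp/Glu, terminal OXT) ≤ 4.0 Å.
- **Cation-π**: cationic-group centre (Arg CZ for the guanidinium, Lys NZ)
  within 6.0 Å of an aromatic ring centroid and elevated ≥ 45° above the
  ring plane (elevation = arcsin of the normal component).
- **van der Waals**: C/S atom pairs at 3.0–4.0 Å, deduplicated to the
  closest pair per residue pair.
- **Water bridge / water census**: an ordered water belongs to the site
  network when its O lies within `site_radius` (8.0 Å) of the site centre
  and makes ≥ 2 polar contacts ≤ 3.5 Å to non-water atoms, at least one of
  them inside the two analysis selections. Site membership, not strict
  A-to-B bridging, drives the census, because the reported network includes
  waters linking peptide atoms to each other and waters sitting on aromatic
  faces; water–aromatic proximity (O within 3.6 Å of a ring centroid) is
  recorded as a geometry note. `site_radius` is the one calibration knob and
  is echoed with every census result.

Every finder is symmetric in its two selections, monotone in its distance
cutoffs (tightening can only shrink the record set), and is verified against
a brute-force all-pairs oracle on randomized fixtures. Neighbour search uses
a k-d tree; the oracle ignores it.

## WIN / S7 site geometry and openness

Site centres are derived from anchor residues: S7 is the centroid of
{Phe133 ring centroid, Phe149 ring centroid, Pro173 CA, Tyr191 CB} with a
6.0 Å scan radius; WIN is the centroid of the backbone carbonyl O of Ser91,
Phe133 and Cys261 — the atoms that coordinate the WIN-motif arginine — with
a 4.0 Å radius (the channel is narrow). The water census uses the midpoint
of the two centres.

Openness is quantified as probe-accessible buried cavity volume, a
deterministic stand-in for the rendered-surface depictions in the structural
literature (no numeric volumes are published for this pocket, so open/closed
classification, not absolute volume, is the meaningful output). A cubic grid
(spacing 0.5 Å) anchored at the site centre is scanned inside the site
sphere; a grid point is cavity when no retained heavy atom is closer than
its van der Waals radius (C 1.70, N 1.55, O 1.52, S 1.80 Å) plus the probe
radius (1.4 Å, water), and when axis-aligned rays find it blocked by protein
in at least 4 of 6 directions (the burial test keeps mouth-adjacent solvent
out of the count while tolerating an open pocket mouth). Ligands, compounds
and waters are excluded before scanning so the measurement reflects the
protein pocket, not its occupant. Volume is the buried-point count times the
grid-cell volume. The scanner reproduces the analytic interior volume of a
synthetic hollow shell within discretisation error (the package asserts
20%), halving the grid spacing changes calibration-structure volumes by
well under 15%, and the volume is invariant to rigid motion of the whole
structure because the grid travels with the site.

Classification is a threshold at the midpoint of an open-reference and a
closed-reference volume. The calibration shipped with the package is
computed from the package's own synthetic tyrosine-gate microsite (a cup of
pseudo-residues with the gate ring plugging the cavity at 0° and swung out
at 80°) — a synthetic stand-in; `wins7.pocket.calibrate()` recomputes the
constants from any user-supplied open/closed pair, such as local copies of
the deposited Kif2A-bound (open) and arginine-bound (closed) entries.

## ITC model and fitting

The forward model is the 1:1 Wiseman isotherm. Total cell concentrations
after cumulative injected volume ΔV use the standard perfusion displacement
factors, M_t = M0·(1 − ΔV/2V0)/(1 + ΔV/2V0) and
L_t = L0·(ΔV/V0)/(1 + ΔV/2V0); the bound concentration is the physical root
of the binding quadratic; the cumulative heat is Q = ΔH·V0·[ML]; and the
per-injection heat is q_i = Q_i − Q_{i−1} + (v_i/V0)(Q_i + Q_{i−1})/2.
Default conditions mirror the experimental protocol for this system: 200 µL
cell, 0.05 mM macromolecule, 1 mM injectant, one 1 µL priming injection
followed by 19 × 2 µL, 20 °C (293.15 K). The cell volume and injection count
are documented assumptions — instrument defaults — since they are not part
of the published protocol text.

Fitting minimises Σ(q_obs − q_model)² over (N, log10 K_A, ΔH) with lmfit's
Levenberg–Marquardt; the log-association parameterisation conditions the
problem across the c = N·M0/K_D range. Initialisation ("midpoint" policy):
ΔH from the earliest retained normalized heat, N from the molar ratio at
which the cumulative heat reaches half its total, K_D from assuming c ≈ 20.
The first injection is discarded by default (the small priming shot).
Standard errors come from the least-squares covariance, with the delta
method mapping log10 K_A uncertainty onto K_D; duplicate-experiment
statistics are out of scope (single-curve fits only). Flat or non-finite
thermograms, and fits landing at c < 1, are flagged unreliable rather than
silently returned. Derived quantities use ΔG = RT ln K_D at 1 M standard
state with R = 1.9872×10⁻³ kcal/(mol·K), and −TΔS = ΔG − ΔH, so the
thermodynamic identity holds to machine precision by construction.

At the wild-type conditions (c ≈ 58) with Gaussian heat noise of 2% of the
peak injection heat, the fit covariance puts the relative standard error of
K_D near 10%; the package's recovery study (50 replicates, seeds 1–50, fixed
as part of the study design) measures the median absolute K_D error, which
sits around 8–9%. Noise-free round trips recover the generating parameters
to optimizer tolerance across c ∈ [1, 1000].

Computed K_D ratios between variants are reported as-is. Note that the
published fold-change prose for this system (1.8-, 3.8-, 7.6-fold) does not
match the ratios of the published K_D values (2.77, 4.77, 8.60); the package
reports the computed ratios.

## Synthetic generators

The generators produce every input class the pipeline consumes, with ground
truth known by construction: tyrosine pairs sharing a rigid 10-residue
scaffold with the ring rotated a stated angle about the in-plane CB–CG axis;
minimal contact geometries (donor/acceptor pair, bidentate
guanidinium–carboxylate, cation over a ring face at a stated elevation, a
doubly-coordinated bridging water) exact to construction; rigid copies under
a stated transform with optional isotropic Gaussian coordinate noise (RMSD
expectation σ√3); a closed carbon shell whose interior cavity volume is
analytic; the tyrosine-gated cavity microsite; and single-site thermograms
at the experimental conditions. Residue geometry is idealized
(internal-coordinate chaining with standard bond lengths/angles); seeds are
explicit arguments and fixed seeds give byte-identical output.

What the generators do not emulate — and hence what passing tests do not
show about real data: crystallographic disorder and B-factor effects,
alternate conformations, chemically incomplete side chains, non-ideal ring
planarity, correlated instrument drift or baseline-integration error in
thermograms, and the conformational coupling between ligand binding and
pocket opening (gate angle is imposed, not induced). Entry-level numbers
(copy-pair RMSD 0.132 Å over 291 Cα, the printed rotation angles, the
nine-water census, the deposited open/closed states) therefore require local
copies of the deposited coordinate files, which the `report` command
consumes when present and skips with notice otherwise.

## Problem sizes

Synthetic structures are a few hundred atoms; grids are ≤ 25³ points;
the ITC recovery study runs 50 fits of 20-injection curves. The full test
suite and the acceptance script each complete in well under a minute on one
CPU.
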