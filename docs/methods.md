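# Methods

## Model

The binding free energy of a peptide in an MHC groove is approximated as a
linear combination of five physicochemical descriptors computed from the
three-dimensional complex,

ΔG_bind ≈ ΔG₀ + α·HB + β·LIPO + γ·BP + δ·ROT + ε·DESOLV,

with the coefficients calibrated per dataset against experimental
affinities. The approach assumes (i) rigid MHC frame and peptide backbone —
a new peptide is threaded onto the backbone of a solved structure and only
side chains are rebuilt; (ii) additivity of interface contributions; and
(iii) that IC50 from a competitive assay approximates the dissociation
constant at low peptide concentration, so ΔG = R·T·ln IC50 (IC50 molar,
T in kelvin, R = 8.314462 J mol⁻¹ K⁻¹, result reported in kJ/mol).

### Descriptors

Every pairwise contribution uses the block (ramp) kernel
`block(x; x1, x2)` = 1 for x ≤ x1, linear to 0 at x2, 0 beyond. Defaults
are the ChemScore-family values; all are exposed in `TermParams`:

* **HB** — over intermolecular donor–H⋯acceptor triples:
  `block(|d_HA − 1.85 Å|; 0.25, 0.65) × block(|θ_DHA − 180°|; 30°, 80°)`.
  An optional heavy-atom mode (`heavy_atom_hb`) scores D⋯A distances
  against an ideal 2.85 Å when hydrogen positions are unavailable.
* **LIPO** — over intermolecular lipophilic heavy-atom pairs:
  `block(d; R1, R1 + 3.0 Å)`, R1 = r_i + r_j + 0.5 Å.
* **BP** — same kernel over mixed pairs (lipophilic on one side, polar —
  donor/acceptor/donor–acceptor — on the other, both directions).
* **ROT** — per-residue count of side-chain rotatable bonds frozen on
  binding (A/G/P 0; S/C/T/V 1; D/N/I/L/F/W/H/Y 2; E/Q/M 3; K/R 4),
  a pure function of sequence. No lipophilic-fraction weighting is applied;
  the simpler count is stated and configurable.
* **DESOLV** — ΔG_solv(complex) − ΔG_solv(MHC) − ΔG_solv(peptide). The
  default backend multiplies per-class atomic solvation parameters
  (kJ mol⁻¹ Å⁻²: lipophilic +0.067, polar-neutral +0.033, polar −0.025)
  by Shrake–Rupley solvent-accessible areas (probe 1.4 Å, 1000 sphere
  points, heavy atoms only). A file-ingestion backend accepts per-complex
  energies from an external Poisson–Boltzmann solver for users who need
  electrostatic desolvation; since the regression coefficient ε absorbs any
  linear rescaling, the SASA surrogate preserves the calibration's form.

Pair sums use a KD-tree neighbour query with an 8 Å cutoff, beyond the
support of every kernel, so the cutoff changes no value.

### Atom typing and protonation

Typing is a fixed, total function of (residue, atom name) over the 20
standard residues, derived from the Chemical Component Dictionary topology:
C/S bound only to C/S/H are lipophilic; N/O carrying a hydrogen in the
protonation model are donors; bare O and bare N are acceptors; hydroxyl
oxygens and both histidine ring nitrogens are donor–acceptors; everything
else is polar-neutral. Unknown residues or atoms fall back to an inert
`other` class with a warning. Histidine is fixed to the NE2-protonated
tautomer. Proline's ring nitrogen carries no hydrogen and is typed as an
acceptor by the bare-N rule. Radii are PARSE-like per element (C 1.70,
N 1.50, O 1.40, S 1.85, H 1.00 Å) and overridable.

Polar hydrogens are placed geometrically at canonical lengths (N–H 1.01 Å,
O–H 0.96 Å): the backbone amide H in-plane, anti to the preceding carbonyl
oxygen; sp² groups (guanidinium, amide, ring NH) in their group plane; sp³
groups (lysine ammonium, hydroxyls, terminal amine) staggered. Heavy atoms
never move and existing hydrogens are kept (idempotence).

### Threading

The reference backbone (N, CA, C, O) is copied exactly; positions whose
residue is unchanged keep their native side chain. Mutated positions get
the CCD ideal-geometry side chain superposed on the local N/CA/C frame
(this also covers CB placement when mutating from glycine), then a
deterministic search over canonical rotamers ({−60°, 60°, 180°} per chi,
up to 81 candidates) placed greedily from N- to C-terminus. The objective
is the count of non-bonded heavy-atom pairs closer than 0.8 × (r_i + r_j),
excluding 1-2/1-3 neighbours; ties break by lower signed chi sum, then
enumeration order. Proline side chains are placed rigidly from the
template. No minimisation follows threading. Pre-threaded models built with
an external side-chain engine can be supplied as ordinary PDB input
instead. Only peptides matching the reference peptide's length are
threadable; the data-curation layer enforces the same filter.

### Regression and validation

Descriptor columns are mean-centred and, by default, scaled to unit
variance (configurable) before PLS1 (NIPALS, via scikit-learn). The default
component count is min(5, n − 2), clamped to the column rank; minimal-PRESS
selection per dataset is available (`select_components`). With the maximal
component count the fit coincides with ordinary least squares. Columns
whose sample variation is below float-noise level (std ≤ 1e−9 relative to
the column's magnitude) are excluded from the latent fit and assigned zero
coefficient: autoscaling such columns would amplify rounding noise into
unbounded extrapolations. Validation is leave-one-out by explicit
refitting — no shortcut formulas — reporting q² = 1 − PRESS/SS_tot and
S_press = √(PRESS/n), matching the cross-validated RMSEP convention. Folds
are in input order; the module contains no randomness.

### Data curation

Binding tables declare their IC50 unit explicitly — published tables mix
headers and magnitudes too inconsistently to guess, and a uniform unit
error only shifts every ΔG by a constant that the intercept absorbs (q² and
S_press are unit-invariant). Temperatures are per record (°C, converted by
+273.15). Replicated peptides are reduced to one record by policy:
`exclude` drops peptides whose replicate IC50 values span more than 10-fold
(the operationalisation of manual-curation rejection of irreconcilable
measurements; threshold configurable) and merges consistent replicates by
geometric mean; `geometric_mean` always merges; `keep_first` keeps file
order.

### Reference-set experiments

A reference set combines structures with one member per distinct native
peptide; enumeration is the Cartesian product over peptides represented
more than once, joined with all singletons, in deterministic lexicographic
order. Default experiment mode is *native*: each training point is a
peptide scored in its own crystal structure. A pooled *threaded* mode
(every binding peptide threaded on every length-compatible member frame) is
provided as an exploratory alternative, since the original description of
the combination experiment is ambiguous on this point. Set similarity is
the unweighted mean pairwise RMSD after Kabsch superposition over heavy
atoms matched by chain role, residue position and atom name (whole
structure, MHC frame only, peptide only), plus the mean crystallographic
resolution where the header provides one (members without resolution are
dropped from that average with a warning). Quality-versus-similarity
association uses Spearman rank correlation with average ranks for ties.

## Synthetic data

`make_toy_complex` lays each requested interaction in its own cell of a
40 Å lattice with all remaining atoms parked on rows 60 Å away, so exactly
the requested pairs fall inside any kernel's support: expected HB/LIPO/BP
follow in closed form from the requested geometries and ROT from the
residue alphabet (fixtures use G/A/S plus optional parked G/A/L/S/K
residues, covering every typing rule with the smallest alphabet). Expected
DESOLV is not analytic — any contact changes accessible surface in a
geometry-dependent way — so the generator reports it as unspecified and the
SASA backend is validated separately against the closed-form two-sphere
spherical-cap area. Fixtures are kernel probes, not physical structures:
parked backbones are deliberately unphysical, and threading tests that
assert side-chain geometry use ideally built backbones instead.

`simulate_binding` draws term matrices uniformly from per-term ranges
(defaults: HB 0–10, LIPO 0–60, BP 0–30, ROT 5–30, DESOLV −30–10, spanning
magnitudes a class I/II interface produces) and builds free energies from a
known linear model (defaults: intercept −10 kJ/mol, coefficients −2.5,
−0.15, 0.3, 1.2, 0.05 — favourable hydrogen bonding and lipophilic contact,
unfavourable mismatch and rotor freezing) plus Gaussian noise (default sd
0.5 kJ/mol, the scale of replicate IC50 scatter). All generators use
seeded, portable NumPy RNGs; fixture files record the seed in a header.

The frame-perturbation study builds six fixtures sharing one atom layout
but different interface geometries, assigns free energies from the known
linear model on the *true* terms, then jitters the MHC frame with growing
Gaussian noise (sd 0–0.6 Å, several replicates per level, median q²) before
recomputing descriptors. Larger jitter raises the set's mean pairwise RMSD
and corrupts the descriptors, reproducing the negative rank correlation
between structural spread and cross-validated predictive power that
motivates using structurally homogeneous reference sets.

What passing synthetic tests shows — and what it does not: they verify the
kernels, the threading contract, the regression/validation machinery and
the direction of the similarity effect, but not the accuracy of the scoring
function on real MHC chemistry (real grooves have dense, correlated
interfaces; fixtures have isolated probes). The published-value benchmarks
on real crystal structures run through `groovescore.benchmarks` when the
PDB entries are present locally; they are not redistributed with the
package.

## Numerical choices

* Block kernels are exact piecewise-linear functions; pairwise terms agree
  with exhaustive-loop evaluation to better than 1e−9 and are exactly
  invariant under rigid motions.
* SASA uses deterministic Fibonacci quadrature; it is rotation-invariant
  only to quadrature accuracy (~1% at 1000 points), which bounds the
  reproducibility of DESOLV under re-orientation; raise `sasa_points` when
  tighter invariance matters.
* Superposition RMSD is recomputed from the transformed coordinates rather
  than from the SVD residual to avoid cancellation (identity pairs report
  < 1e−12 Å).
* Altloc resolution keeps the highest occupancy, ties preferring altloc A.
  Degenerate regression targets (zero variance) yield a flat model in
  fitting and an explicit error in cross-validation, where q² is undefined.
  Reference sets whose descriptors cannot support cross-validation are
  reported with q² = NaN and flagged, not dropped silently.

## Known limitations

* The side-chain engine is a canonical-rotamer clash minimiser, not a
  rotamer-library optimiser; crystallographic side-chain accuracy is out of
  scope, and an external engine's output can be substituted via PDB input.
* Default DESOLV is surface-area based; electrostatic desolvation requires
  the external-table backend.
* Backbone flexibility, loop modelling, peptides of different length than
  the reference, explicit water bridges, metal coordination and
  charged-interaction terms are out of scope.
* Classification-style scoring (binder/non-binder) is not implemented; the
  calibration consumes quantitative IC50 values only.
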