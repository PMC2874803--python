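# Methods

## Problem and model

Given the structure of a protein–protein complex partitioned into two sides,
the package classifies each interface residue as *hot spot* or *non-hot
spot*.  Labels for training come from alanine-scanning data: a residue is
hot when ΔΔG ≥ 2.0 kcal/mol, non-hot when ΔΔG < 0.4 kcal/mol, and excluded
from training in between (0.4 itself falls in the excluded band, since the
non-hot rule is a strict inequality).  Categorical-strength data are mapped
`strong → hot`, everything else (`intermediate`, `weak`, `insignificant`)
→ non-hot, case-insensitively after trimming.

The predictor is a majority-vote committee of single-feature RBF-SVMs built
on the features that best separate the two classes.  The premise is the
O-ring picture of interfaces: hot spots are occluded from bulk solvent by
surrounding residues, so solvent accessibility lost upon complexation and
the local convexity of the residue (protrusion) carry most of the signal,
while conservation, pair potentials and the temperature factor add little.

## Structural features

**Structure handling.** PDB files are parsed with Bio.PDB; only the first
model is kept, HETATM records, waters and hydrogens are dropped, and for
alternate locations the highest-occupancy conformer wins (ties go to the
first listed).  Residue identity is (chain, seq_num, insertion code);
insertion codes are preserved.  Missing side-chain atoms are tolerated —
all features are computed over the atoms present, and residues with fewer
than four atoms are flagged (`sparse` column) rather than repaired.
The unbound form of a chain set is simply the bound coordinates viewed in
isolation; no relaxation is attempted.

**Atom classes.** N, CA, C, O and the terminal OXT are backbone, all other
heavy atoms side chain.  Polarity follows the element: O/N polar, C
non-polar; sulfur (and any other element) counts in neither polar nor
non-polar sums, so `total ≥ polar + non_polar` while
`total = backbone + side_chain` holds exactly.

**ASA.** Shrake–Rupley with a deterministic Fibonacci dot lattice,
`sphere_points = 960` per atom, probe 1.4 Å, van der Waals radii
C 1.70 / N 1.55 / O 1.52 / S 1.80 / P 1.80 / Se 1.90 Å (1.80 Å fallback;
all constants configurable).  The lattice is laid out in a canonical
molecular frame — principal axes with a deterministic, rigid-motion-
invariant sign convention (atom-order-weighted projections, falling back to
the third moment) — so all geometric features are exactly invariant under
rotation and translation of the input rather than invariant only up to
sampling noise.  The sampling resolution is one dot ≈ 4πr²/960; tests
against an independent 10×-denser point-sampling oracle therefore use a
3 % relative tolerance with an absolute floor of ten dots' worth of area.

**RASA.** Each ASA attribute is divided by a residue-type reference value
for the same attribute class.  The shipped reference table
(`src/apis/data/rasa_reference.tsv`) is computed by the package's own ASA
engine on ideal isolated residue conformations taken from the chemical
component dictionary bundled with biotite (OXT removed), rather than on
extended Gly-X-Gly tripeptides: that keeps the reference self-consistent
with the engine and per-attribute-class without inventing tripeptide
geometry.  Values are therefore somewhat larger than tripeptide maxima and
RASA correspondingly smaller; since every downstream use z-scores the
features, only the residue-type normalization matters.  Glycine's
side-chain reference is the Cα area (pseudo-side-chain) so the denominator
is never zero; glycine's side-chain ASA itself is 0.  The table regenerates
with `scripts/generate_reference_data.py`.

**Depth index.** The depth of an atom is its minimum Euclidean distance to
the retained accessible dots of the Shrake–Rupley run on the same model
(an isolated atom has depth r + probe — its own surface).  Using surface
dots rather than a triangulated molecular surface keeps the quantity
oracle-testable and is documented as an approximation of mesh-based depth.
A model with no accessible dot at all raises `BuriedModelError`.

**Protrusion index.** For each atom, heavy atoms within a 10 Å sphere are
counted (self included); occupied volume is count × 20.1 ų, the external
volume is the sphere remainder clamped at 0, and PI = V_ext / V_int.  An
isolated atom scores ≈ 207.4 with the default constants.

**Aggregation.** ASA/RASA attributes are sums over the atom classes; DI/PI
attributes are total mean, side-chain mean (glycine falls back to Cα), max
and min.  The relative change upon complexation is
`(x_unbound − x_bound)/x_unbound` with 0/0 → 0; the sign convention makes
ASA burial positive, and the denominator is flippable to the bound value
via `GeometryParams.rc_denominator` for sensitivity analyses.  The 15 ASA +
10 RASA + 12 DI + 12 PI features are exactly the 49 structural columns.

**Temperature factor.** Per chain, Cα B-factors are z-scored with the
population SD; a zero-variance chain maps to zeros and a residue without a
Cα is flagged missing (NaN).

## Sequence-derived features

The ten physicochemical values are type-level constants shipped as a
delimited table assembled from standard published scales (Kyte–Doolittle
hydrophobicity, Hopp–Woods hydrophilicity, Veljkovic electron–ion
interaction potential, residue masses and isoelectric points, heavy-atom
counts, side-chain hydrogen-bond capacity, a conformational-propensity
scale, and an approximate 14 Å contact-number scale).  Any cell can be
overridden by a user table, which is the recommended route when a specific
published variant of a scale is required.

Conservation (`Rc`) is read from Rate4Site/ConSurf-style files and passed
through unscaled (lower = more conserved).  The pair potential (`Pp`) of a
residue sums a user-supplied symmetric 20×20 matrix over partner-side
residues whose minimum heavy-atom distance is within 6.5 Å (configurable);
only partner-side contacts are counted, matching the interface-pairing
reading of the statistic.  The default matrix is all zeros, so `Pp` is
inert until a real matrix is supplied.  Both features are optional: absent
inputs drop the columns instead of zero-filling them.  Missing values are
excluded pairwise from F-score computation and imputed with the training
mean at SVM input.

## Feature selection and classifiers

The F-score default is `|Δmean|/(σ_h + σ_n)` with sample (n−1) SDs; the
squared form `(Δmean)²/(σ_h² + σ_n²)` is behind a flag.  The ratio form is
the default because the calibration anchor — equal SDs, mean gap equal to
the average SD, F = 0.5 — holds for it unconditionally; notably both forms
pass that anchor, so the anchor cannot distinguish them.  Population SDs
are available by option since the convention behind historical reported
F-scores is not recoverable.  Zero total spread with unequal means returns
+inf; selection keeps features strictly above the threshold (default 0.60),
ties broken alphabetically.

SVMs use scikit-learn's `SVC` with RBF kernel, C = 1 and γ = 1/#features —
the LIBSVM-style defaults pinned explicitly because "default parameters"
drifts across tool versions.  Features are z-scored with training
mean/population-SD, stored on the model.  Cross-validation is stratified
10-fold with a fixed seed (fold sizes and class ratios within ±1).
Class-weighting is off by default despite the 62:92 imbalance of the
reference training composition; `SVMParams(class_weight="balanced")`
enables it.

Ensemble members are chosen by cross-validated F1 *on the training data* —
deliberately not by test-set F1, which would leak the evaluation set into
model selection; a test-set-based grouping can still be reproduced manually
by passing the desired member list to `cross_validate_ensemble`.  The
default committee is the top 3 single-feature classifiers; an
`f1_threshold` rule is also provided.  An even qualifying set is reduced by
dropping the weakest member so a strict majority always exists; the
residual exact tie of an even committee resolves to *hot*, favouring
recall.

## Synthetic data

The generator provides the study conditions for testing without any
download:

* `single_atom`, `cage` (a centre atom occluded by an 80-atom shell at
  2.8 Å) and `random_cloud` (uniform carbons at ~0.045 atoms/ų, protein
  packing density) give closed-form or brute-force-checkable geometry;
* `helix_pair_complex` is an idealized pair of contacting 6-residue chains
  (Cβ atoms facing across a 3.8 Å gap) whose aligned residues necessarily
  lose surface on binding;
* `gaussian_two_class` draws labeled feature tables with exact class sizes
  and controlled per-feature mean gaps; the default pipeline-recovery
  checks use the 62/92 class composition of the reference training set,
  three informative features with a 2σ gap among nine pure-noise features,
  and 20 seeded repetitions.

What the toys do *not* emulate: real side-chain geometry and packing,
correlated features (real ASA/PI features correlate at |r| > 0.6–0.9),
conformational change between bound and unbound forms, and label noise from
heterogeneous experiments.  Passing tests therefore demonstrate
correctness of the computations and the expected qualitative behaviour of
selection and voting, not benchmark-level accuracy on real complexes; the
full benchmark requires external PDB/ASEdb/BID-derived inputs and is
scripted in `scripts/reproduce_study.py` instead of asserted.  The packaged
training mutation table is a synthetic stand-in (generated ΔΔG values over
the published 15-complex roster) whose only asserted property is the
62 hot / 92 non-hot composition under the labeling rules.

## Numerical choices and edge cases

* Rounding for comparisons against reported 2-decimal tables is decimal
  half-up.
* Undefined metric denominators report 0 with an explicit flag instead of
  raising, so batch evaluation never aborts.
* Two F1 cells in the reported benchmark tables are inconsistent with
  their own confusion matrices by exactly one rounding unit; the regression
  fixture records both the reported and the recomputed value and pins the
  difference (see `tests/reference_metrics.py`).
* `relative_change` rejects negative inputs and defines 0/0 = 0; it is
  scale-invariant and zero on equal inputs by construction.
* Duplicate residues in mutation tables are a hard error with row numbers;
  unknown strength categories list the accepted vocabulary.
* Unknown elements get the 1.80 Å fallback radius unless
  `strict_elements=True`.
* Problem sizes in the test suite (clouds of ≤ 100 atoms, tables of
  ≤ 1000 rows, 20 CV repetitions) were chosen so the complete suite runs in
  well under a minute while keeping every statistical assertion at ≥ 3
  standard errors of headroom.

## Known limitations

* ASA/DI/PI values are algorithmically standard but not numerically
  identical to any particular legacy tool (different radii sets, lattice,
  and the dot-based depth definition); comparisons across tools should be
  made on z-scored features.
* The unbound form is the rigid bound conformation; induced fit is outside
  scope.
* mmCIF input, biological-assembly generation and structure repair are not
  supported; nucleic-acid ASA is out of scope.
* The shipped physicochemical defaults are assembled, documented scales,
  not a reproduction of any specific historical table — override them for
  exact comparisons.
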