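# Methods

## Scope and assumptions

The package models a *pre-aligned* congeneric series: superposition is an
input precondition, not something the code performs. All molecules of a
set are assumed to share one coordinate frame; the synthetic generator
satisfies this exactly, and `perturb_alignment` exists precisely to show
what happens when the assumption is violated (q² degrades). Partial
charges are likewise inputs (carried in the SDF `PARTIAL_CHARGES` field);
a Gasteiger fallback (`charge_policy="compute"`) is provided for sets that
arrive without charges, and the charge source should be recorded by the
caller because electrostatic fields inherit its systematic error.

## Field generation

Grid: axis-aligned lattice over the union bounding box of all atoms,
expanded by a margin (default 4 Å) with 2 Å spacing.

CoMFA functional forms are not uniquely defined across historical
implementations; the package adopts the common Tripos-style conventions
and keeps every constant in `FieldConfig` so alternates are testable:

- steric: Lennard-Jones 6-12 with r\*ᵢₚ = Rᵥdw,ᵢ + R_probe (arithmetic
  combination) and εᵢₚ = √(εᵢ ε_probe) (geometric); atom well depths
  default to a uniform 0.1 kcal/mol, editable per element. The repulsive
  branch is truncated at the 30 kcal/mol cutoff; the attractive branch is
  left untouched (it cannot diverge).
- electrostatic: Coulomb with distance-dependent dielectric D(r) = r and
  the conversion factor 332.0636 kcal·Å/(mol·e²), clamped to ±cutoff. At
  lattice points where a compound's steric energy is capped ("inside" the
  molecule) the electrostatic value is replaced by the column mean over
  uncapped compounds — the conventional treatment that stops meaningless
  inside-molecule Coulomb values from dominating the PLS. The policy is
  switchable (`electrostatic_inside_policy="clamp"`).
- CoMSIA: Gaussian attenuation exp(−α r²) with α = 0.3 Å⁻², no cutoff.
  Atom weights: steric Rᵥdw³, electrostatic the partial charge,
  hydrophobic/donor/acceptor from an editable element-typing table
  (defaults: carbon and halogens hydrophobic +1/+0.5, N/O hydrophilic −1
  with donor/acceptor +1). The negative-similarity sign convention is
  fixed by the r = 0, unit-weight ⇒ −1 anchor case.

Column filtering drops columns whose *sample* standard deviation across
training compounds is below 2.0 (in each block's native units) from
modeling only; masked columns remain addressable for contour export. The
filter is interpreted as a minimum-variation threshold; an
energy-difference reading of "column filter" is not recoverable from
available descriptions, and the minimum-sigma reading is the one
implemented. Block scaling divides each field block by the pooled standard
deviation of its centered values (CoMFA-STD style) so no block dominates
the covariance; the factors are recorded and coefficients are
back-transformed to raw field units for reporting.

## PLS and model selection

PLS components are extracted by the NIPALS algorithm as implemented in
scikit-learn (`PLSRegression`, `scale=False`; centering internal), on the
block-scaled retained columns. Two independent anchors pin the
implementation in the test suite: score vectors must be orthogonal, and at
full rank the predictions must equal ordinary least squares.

Leave-one-out cross-validation is run explicitly — each compound removed,
the model refit, the compound predicted — rather than through a
sample-distance shortcut; the series sizes involved (tens of compounds)
make the O(n) refits cheap. q² uses the full-training-set mean in the
denominator. The component count is chosen to maximise q², ties broken
toward the smaller model, with the whole q²-versus-N profile reported; the
component cap defaults to 6.

SEE = √(RSS/(n − N − 1)). Field fractions are shares of Σ|coef·sd| per
block. Contours threshold the per-column coef·sd product at the 80th/20th
percentiles (configurable); "favored" means activity increases with the
field value. Degenerate (constant) product fields yield empty contours
with a warning.

## Validation battery

`external_metrics` computes r²test (ordinary squared correlation),
through-origin slopes k = Σyŷ/Σŷ² and k′ = Σyŷ/Σy², and the through-origin
determination coefficients in both directions. The battery flags are
q² > 0.5; r²test > 0.6; (r²test − r²₀)/r²test < 0.1 or the primed
analogue; 0.85 ≤ k ≤ 1.15 or 0.85 ≤ k′ ≤ 1.15; and |r²₀ − r′²₀| < 0.3.
The r²m = r²test(1 − √|r²test − r²₀|) > 0.5 check is reported as its own
flag, not folded into the verdict, since its status as a battery member
versus a separate metric is ambiguous in common usage; the absolute value
covers the r²₀ > r²test corner (the typeset form of the metric is
frequently garbled, and this is the standard Roy reading).

Y-randomization permutes y without replacement (seeded), refits with the
original component count, and passes only if *every* iteration has
q² < 0.5 and r²ncv < 0.6. The iteration count defaults to 50. Note the
all-iterations pass criterion is demanding at small n: with a dozen
compounds and hundreds of columns, a scrambled PLS fit occasionally
reaches r²ncv ≈ 0.6 by chance, which is the statistic working as intended;
the pass criterion is meaningful at the default 58-compound scale.

Outliers are compounds with |observed − predicted| strictly greater than
1.0 pIC50 unit (a residual of exactly 1.0 is not flagged).

## Applicability domain

Standardized deviates Sᵢₖ = |xᵢₖ − meanᵢ|/sdᵢ against the training set;
sample (n−1) standard deviation throughout (the population/sample choice
is not standardised in the method's descriptions; `ddof` is switchable).
Verdicts: inside if max ≤ 3; outside if min > 3; otherwise
S_new = mean + 1.28·sd ≤ 3 decides (1.28 ≈ z₀.₉₀, so S_new estimates the
90th percentile of a compound's deviates). The ≤ 3 comparison for S_new is
taken from the source standardization method. By default the domain is
assessed in PLS latent-score space rather than on raw grid columns:
standardizing thousands of collinear, near-duplicate columns is degenerate
(a single unusual substituent would trip hundreds of correlated deviates),
whereas the score space is the geometry the model actually predicts from.
Raw-descriptor assessment remains available through `ad_report` directly.

## Druglikeness rules

Lipinski (MW ≤ 500, HBD ≤ 5, HBA ≤ 10, cLogP ≤ 5; classic pass allows one
violation), Veber (TPSA ≤ 140 Å², NRB ≤ 10), and a six-axis
bioavailability radar with the customary ranges (LIPO −0.7..5, SIZE
150..500, POLAR 20..130 Å², FLEX ≤ 9, INSOLU logS −6..0, INSATU
Fsp³ ≥ 0.25); axes whose descriptor is absent are skipped. All boundaries
are inclusive on the compliant side. Descriptors are caller-supplied;
cLogP method differences are the caller's responsibility.

## Synthetic generator

What it emulates: a congeneric series after alignment — a rigid shared
scaffold (a planar purine-like 9-atom template) with four substituent
positions whose single-atom occupants vary in element (H…I, hence vdW
radius and similarity weights) and partial charge (N(0, 0.3 e), clipped).
Activity is linear in the *true CoMFA steric field values* at the lattice
points within 2.9 Å (≈ the first 2 Å-lattice shell) of one "beneficial"
site (+1 per column) and one "detrimental" site (−1), affinely mapped so
the noiseless activities span pIC50 4.0–7.8 — a realistic potency range
for a kinase-inhibitor series — then perturbed with Gaussian noise
(default sd 0.3 pIC50 units, about twofold IC50 error). The remaining two
sites vary but carry zero coefficient; these decoys make contour recovery
non-trivial (the favored contour must single out the beneficial
neighbourhood among several varying regions). Defaults: 58 compounds, 20%
activity-stratified test split.

What it does not emulate: real chemistry (no bonds or valence rules),
conformational flexibility, alignment error (available only through
`perturb_alignment`), correlated substituent effects, or activity cliffs.
Passing recovery tests therefore demonstrates that the descriptor → PLS →
validation → contour machinery is correct and well-calibrated, not that
any particular real series will yield a predictive model.

Because activity is planted in descriptor space, field-PLS is the
correctly specified estimator: with zero noise the pipeline must recover
the relation almost exactly (q² ≥ 0.95, RMSE < 0.05), and contour
recovery is scored as the Jaccard overlap between the favored steric
contour and the planted positive-coefficient lattice points, restricted
to points that survive the column filter (points the model cannot see are
excluded from both sets). Recovery statistics quoted for the default
conditions are medians over ten seeds, with the external verdict required
in the majority of seeds.

## Numerical choices and degenerate inputs

- Distances are floored at 10⁻³ Å before energy evaluation; the steric
  cap absorbs the resulting large values, so no non-finite field values
  can arise.
- Percentile thresholds use linear interpolation (NumPy default); on n
  distinct values the 80/20 defaults select ⌈0.2 n⌉ points per side.
- Ties in component selection go to the smaller N; model-search ranking
  sorts by q² descending.
- Empty SDF → empty set with a warning; a record without charges under
  `charge_policy="from-file"`, a 2D record, a molecule outside the
  lattice, constant y, or an empty AD vector each raise a named error.
- Censored GI50 inputs (">25") propagate as lower-bound flags through the
  selectivity index; SI display rounds to integers at ≥ 10, one decimal
  below. Printed IC50/pIC50 pairs that disagree at the third decimal
  trigger a warning but are kept as given.
- Problem sizes used in the shipped tests and the acceptance study — 58
  compounds, ~550 lattice points, ten seeds, 50 randomization iterations —
  were chosen as the smallest sizes at which every statistic is stable;
  the whole study runs in well under a minute on one core.

## Known limitations

- CoMFA energies follow the package's stated conventions; numbers from
  other field implementations (different ε tables, dielectric models or
  inside-molecule treatments) will differ systematically, so cross-tool
  comparisons should be made on q²/validation level, not raw fields.
- The applicability domain in latent space inherits the model: refitting
  with a different component count changes the domain.
- No region focusing, bootstrapped coefficient errors, or progressive
  scrambling; SAMPLS-style accelerated LOO is unnecessary at these sizes.
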