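# Methods

## The property and the models

The modelled property is the intrinsic aqueous solubility of drug
substances, logS0, in log10 molar units: the solubility of the uncharged
species, independent of pH. The package ships three fixed multilinear
regression models (M1–M3, two or three descriptors each, coefficients as
published with their QsarDB archives) plus their consensus, and implements
the methodology used to derive and assess such models. The descriptors map
onto the physical steps of dissolution: polarity/polarizability terms
(SM04_EA(bo), TPSA, SpMax1_Bhp, SHBd) reflect escape from the crystal and
cavity formation, and hydrophobicity terms (ALOGP2, MolLogP) reflect
hydration.

Consensus predictions are the unweighted arithmetic mean of the member
predictions computed at full floating precision; rounding (2 dp,
round-half-to-even) happens only at reporting. When a member's descriptors
are unavailable (e.g. no XlogS input for M3), the consensus is taken over
the available members and the exclusion is reported — the published
methodology does not address partial availability, so the package treats
availability-weighted averaging with an explicit warning as the least
surprising behavior.

## Descriptor dialects

Descriptor programs disagree in undocumented details, and the published
coefficients were fit to specific implementations that cannot be
byte-matched. The package therefore pins one dialect per descriptor,
documented here, and exposes the pieces (bond-order convention, logP
provider, donor definition) for substitution:

* **SM04_EA(bo)** — edge adjacency matrix B over bonds with conventional
  bond orders (aromatic = 1.5) on the diagonal and 1 for bond pairs sharing
  an atom; the descriptor is ln(trace(B⁴)). The natural-log scale is
  required for dimensional consistency with the published coefficient
  (−1.645) and intercept (8.33): raw fourth-moment traces reach 10²–10⁴ for
  drug-sized molecules.
* **SpMax1_Bhp** — Burden-type matrix over heavy atoms: diagonal = atomic
  polarizability relative to carbon (CRC static polarizabilities, carbon
  entry exactly 1), bonded off-diagonal = 0.1 × bond order, non-bonded
  = 0.001; the descriptor is the largest absolute eigenvalue. This is the
  classic Burden/BCUT construction; the exact weights of the original
  "Bh" implementation are not published.
* **SHBd** — Kier–Hall E-states with intrinsic state
  I = ((2/N)²·δv + 1)/δ, δv = valence electrons − attached hydrogens,
  perturbed by (I_i − I_j)/(d_ij + 1)² over all heavy-atom pairs (topological
  distance d); summed over N/O atoms bearing ≥ 1 hydrogen (S–H excluded by
  default, flag to include). The implementation is independent and is
  cross-checked against RDKit's E-state module in the tests.
* **TPSA, MolLogP** — delegated to RDKit (Ertl group contributions;
  Wildman–Crippen atom contributions). These are standard steps, not the
  package's contribution; tests pin the Ertl hydroxyl fragment value
  (20.23 Å²) and atom-contribution additivity independently.
* **ALOGP2** — square of a pluggable atom-contribution logP provider.
  Default provider: Wildman–Crippen. The descriptor's original definition
  uses the Ghose–Crippen 90-type table; since the two schemes differ only
  in their published increment tables, the provider abstraction makes the
  substitution explicit and reversible
  (`atom_contribution_provider` accepts any per-element table).
* **XlogS** — a group-contribution solubility estimate treated strictly as
  an input column (id → value); M3 predictions for compounds without a
  value are refused with a clear message.

Structure standardization uses RDKit sanitization: one aromaticity model,
nitro groups normalized to the charge-separated dialect, canonical SMILES
as the dataset structure key. Multi-fragment inputs (salts/mixtures) are
rejected by default — the provenance of salt handling in the source data
is unknowable — with an opt-in to keep the largest organic fragment.

## Statistics

R² is the squared Pearson correlation of observed vs calculated logS0
(affine-invariant; used for training/CV/validation). R²det = 1 − Σ(y_obs −
y_calc)²/Σ(y_obs − ȳ_obs)² fixes slope 1 and intercept 0 and is used for
external test sets; it can be negative. MPP is the percentage of predictions
within 0.5 log units, **boundary inclusive**; a strong outlier has
|experimental − predicted| **strictly** greater than 2 log units. These
boundary conventions follow the verbatim definitions and are observable in
the bundled worked example: the Folic-acid consensus residual of −2.08
stays flagged while Itraconazole's −1.71 does not. R²cv applies the Pearson
formula to leave-one-out predictions (not the PRESS-based Q²), matching the
statistic's definition across set types. LOO predictions are computed by
explicit per-fold refits; the algebraically equivalent hat-matrix shortcut
is available on `MLRResults` and the two routes are cross-checked in tests.

## Applicability domain

Leverage is computed against the training design with intercept,
h = x′(X′X)⁻¹x. The warning leverage is h* = 3(p+1)/n, the standard
Williams-plot threshold (the AD literature the models cite uses it; the
formula is not printed alongside the models). Williams tables carry raw
residuals (experimental − predicted), per the stated residual definition,
with ±2 log-unit outlier lines. Range checks use closed intervals
[training min, training max] per descriptor.

## Selection workflows

* **BMLR-style forward selection.** The original implementation's internal
  thresholds are proprietary; defaults here are |t| ≥ 2.0 for the
  univariate significance screen, pairwise |R| ≤ 0.6 among selected
  descriptors, and a greedy stopping increment of 0.01 R² units, all
  configurable. Ties break lexicographically by descriptor name for
  determinism.
* **OMP.** Classic orthogonal matching pursuit on internally standardized
  columns with OLS refits on the active set; the model size is the smallest
  k at which R²(k+1) − R²(k) < ε, default ε = 0.02 R² units (the source
  rule is qualitative — "only a minor improvement").
* **RF preselection + exhaustive search.** Default 100 forest runs of 500
  trees with distinct derived seeds; per run, the ten most important
  descriptors by permutation importance are set aside; descriptors
  appearing in strictly more than five per-run top lists survive; OLS
  models are fit on every survivor subset of size ≤ 3 and ranked by R² (or
  LOO R²cv). Permutation importance is computed with scikit-learn's
  permutation routine (one repeat, seeded) on the training data rather than
  per-tree out-of-bag permutation; the multistep protocol — not the
  importance estimator's internals — is what the workflow reproduces, and
  the frequency filter makes the survivor set insensitive to the estimator
  variant at the tested signal strengths. Frequency counting is one count
  per run (per-run top lists contain unique names).

All workflows record a per-step trace (candidate scores, picks, survivor
frequencies) sufficient to replay the selection, and are deterministic
given (X, y, config, seed).

## Synthetic data

The generator plants a sparse linear model in standard-normal descriptor
columns: defaults are two signal columns with coefficients (2, −1),
intercept 3, twenty noise columns, n = 200 and residual SD 0.1 — the
conditions used for the selection-recovery studies. Residual-noise presets
of 0.17 and 0.62 log units emulate the interlaboratory SD of high-consensus
("tight") and low-consensus ("loose") solubility measurements. An optional
equicorrelation parameter injects correlated noise columns. What the
generator does **not** emulate: real descriptor distributions (heavy tails,
discreteness, inter-descriptor correlation structure of chemical space),
curation artifacts, or structure-dependent errors — so passing recovery
tests demonstrate the correctness and statistical behavior of the
workflows, not their chemical performance on real descriptor universes.

Replicate-measurement fixtures emit k noisy copies of a base logS0 per
compound, cycling through log-molar, mg/mL and molar units (default
molecular weight 250 g/mol, a typical drug substance), to exercise unit
conversion and median aggregation end to end. Medians of even-sized groups
are the midpoint of the two central values.

## Problem sizes and numerical choices

The stochastic test studies use 100 seeded replicates each: selection
recovery at n = 200–250 with 20 noise columns and noise SD 0.1, and the
tight/loose contrast at n = 200 per regime. The RF workflow runs in the
replicate studies with 12 forest runs of 50 trees — a scaled-down protocol
chosen so the full study completes in minutes on one CPU; library defaults
remain 100 × 500. OLS uses `numpy.linalg.lstsq` with an explicit rank check
that names the linearly dependent columns; leverage uses a direct inverse
of X′X after the same rank check (p ≤ 3 in practice). Zero-variance columns
are detected by exact equality (bit-identical constants), correlation
filtering by |Pearson R| > 0.9 with stable column order (the later column
of an offending pair is dropped). Eigenvalues of symmetric matrices use
`eigvalsh`; tests cross-check against the general eigensolver.

## Known limitations

* The six descriptors are implemented in pinned dialects; byte-exact
  agreement with the proprietary descriptor programs the coefficients were
  fit to is not attainable and not claimed. Predictions from
  package-computed descriptors are therefore best treated as a faithful
  re-implementation of the published equations over clearly documented
  descriptor definitions.
* XlogS is an input, not a computation; M3 is only usable where XlogS
  values are supplied.
* The original training sets are not bundled (their structures are not
  public in tabular form); model refitting utilities operate on
  user-supplied or synthetic data.
* No uncertainty estimates accompany predictions; the registry models carry
  their published training/validation statistics as metadata only.
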