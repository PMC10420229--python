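# Methods

## Retention model

MEKC separates neutral analytes by their partitioning between an aqueous
buffer and a micellar pseudo-stationary phase. The observable is the
analyte migration time *t*_R, bracketed by the electro-osmotic-flow marker
*t*₀ (an unretained tracer) and the micellar marker *t*ₘ (a fully
micelle-bound tracer). The retention factor

&nbsp;&nbsp;&nbsp;&nbsp;k = (t_R − t₀) / (t₀ (1 − t_R/t_m))

is zero at *t*_R = *t*₀ and diverges as *t*_R → *t*ₘ; times at or beyond
*t*ₘ are treated as domain errors ("analyte co-elutes with or after the
micellar marker") rather than mapped to infinite logP. The link to the
partition coefficient is the phase-ratio relation

&nbsp;&nbsp;&nbsp;&nbsp;k = P φ / (1 − φ),&nbsp;&nbsp;&nbsp;φ = ῡ (C_T − CMC),

where only the surfactant above its critical micellar concentration
contributes micellar volume. The registry ships the constants of the three
measured systems:

| system | C_T (mol/L) | CMC (mol/L) | ῡ (L/mol) | φ |
|--------|------------|-------------|-----------|---|
| SC     | 0.080 | 0.0124  | 0.317 | 0.02143 |
| LPFOS  | 0.040 | 0.00327 | 0.285 | 0.01047 |
| HTAB   | 0.020 | 0.00034 | 0.324 | 0.00637 |

Every system must satisfy 0 < φ < 1 (validated at construction).
Concentrations are stored in mol/L; mM inputs are converted at the
registry boundary. Replicate retention records for a (compound, system)
pair are averaged on the logP scale — the reported quantity — with the
replicate standard deviation carried alongside; boundary records (k = 0 or
t_R ≥ t_m) become missing entries with a warning so batch conversion is
total.

## Solvation conversion

The solvent/water partition coefficient follows from the transfer free
energy ΔΔG° = ΔG°_solv − ΔG°_wat as logP = −ΔΔG°/(RT ln 10). The default
temperature is 298.15 K (RT ln 10 = 1.36425 kcal/mol); energies are
kcal/mol internally with a kJ/mol conversion flag (4.184). Missing
energies propagate to missing logP values. Electronic-structure
computation of the energies themselves is out of scope; the package
consumes tabulated values.

## Surrogate-solvent identification

Correlation matrices between experimental (micellar) and computed
(solvent/water) logP columns use pairwise-complete observations — the
experimental table has missing entries, and discarding a compound from
every pair because one system failed to resolve it would waste data. Cells
with fewer than `min_pairs` joint observations, and all pairs involving a
zero-variance column, are reported missing. Calibration fits use listwise
deletion within each (micelle, solvent) pair. These complementary policies
are recorded in the output metadata.

Calibrations are ordinary least squares; R² is the squared Pearson r of
the fitted pairs (identical to the coefficient of determination for simple
regression with intercept); MAE/MSE/RMSE are computed on the fitted
residuals. Slope and intercept standard errors support t-based confidence
intervals. Surrogate ranking sorts non-experimental columns by descending
r with alphabetical tie-breaking.

The exclusion filter implements the rule that compounds with nitrogen in
an aromatic ring or a urea (carbamide) group partition anomalously in the
cationic HTAB system: SMARTS `[n]` (ring-membership aromatic nitrogen
under RDKit's default aromaticity perception) and `[NX3][CX3](=O)[NX3]`
(urea, including N-substituted herbicides). The urea pattern requires a
nitrogen on *both* sides of the carbonyl, so plain amides and anilides
(benzamide, N-phenylacetamide) are retained, as are anilines whose
nitrogen is attached to, not inside, the ring. On the bundled 63-compound
set the filter excludes exactly 14 compounds: six aromatic-N heterocycles
(pyrimidine, pyrrole, quinoline, caffeine, atrazine, propazine) and eight
urea herbicides.

## Descriptor-space analysis

Descriptor matrices are z-transformed column-wise with the sample (n−1)
standard deviation, consistent with the correlation-matrix PCA convention
(total variance = number of descriptors). Zero-variance columns are
dropped with a warning.

k-means minimises within-cluster squared Euclidean distance with
k-means++ seeding, 25 restarts by default, and an explicit seed; the
returned labels are renumbered by decreasing cluster size so the 1..k
indexing is stable. k is a user hypothesis (default 3, matching the
empirically observed three-group structure of the measured collection:
one large mixed group, a pesticide group, a small hormone group).

PCA is the eigendecomposition of the correlation matrix; explained
variance ratios are reported for all computable components (they sum
to 1), with loadings and scores truncated to the requested count.

SVM regression uses an RBF kernel. The complete rows are ordered by
compound name (making results invariant to input row order), split 85/15
by a seeded shuffle, and hyperparameters are selected by 10-fold
cross-validated grid search on the training split only, with features
standardized by training-set statistics. The default grid is
C ∈ {0.1, 1, 10, 100}, ε ∈ {0.01, 0.1, 0.5}, γ ∈ scale·{0.1, 1, 10} with
scale = 1/(p·var(X_train)); all values are overridable. Test metrics (R²,
RMSE, MAE) are computed only on compounds never seen in training or model
selection. The split is not stratified.

The bundled descriptor generator produces an open RDKit set
(constitutional counts, element percentages, topological/connectivity
indices, and the SlogP/SMR/PEOE VSA families that sum van-der-Waals
surface-area contributions binned by an atomic property). It is *not* the
commercial descriptor set used to produce the published per-micelle
models; those descriptor name lists ship as presets
(`data/svm_descriptor_presets.yaml`) for users who have that software, and
exact reproduction of the published SVM metrics or cluster memberships is
not a goal of this package.

## Synthetic data

The generators are pure functions of (spec, seed) via
`numpy.random.default_rng`.

**Retention.** Noise is applied on migration times — the measurement
domain — not on logP, so simulations exercise the nonlinearity of the
retention model. Defaults: t₀ = 2 min, tₘ = 10 min, sd 0.05 min,
triplicate injections, truth logP uniform over [0.19, 3.71] (the observed
span of the measured table). Simulated times are clipped into the open
marker interval with a warning rather than rejection-sampled, keeping
generation O(n) and deterministic. A consequence worth knowing: analytes
whose retention margin t_R − t₀ is comparable to the time noise (logP
below ≈ 1 in the low-phase-ratio systems) recover logP with heavy-tailed
error — exactly the regime where real MEKC determinations lose precision —
so unbiasedness holds for well-retained analytes and robust summaries
(medians) are appropriate across the full range.

**Solvation panels.** For a planted calibration y = a·x + b with residual
sd σ, the solvent logP x is drawn conditionally on the true micellar
logP y along the *inverse-regression* line

&nbsp;&nbsp;&nbsp;&nbsp;x = c (y − ȳ) + (ȳ − b)/a + ε,&nbsp;&nbsp;
c = (1 − σ²/var(y))/a,&nbsp;&nbsp; var(ε) = c·var(y)(1 − a c)/a,

so that the forward regression of y on x has slope a, intercept b and
residual sd σ. The naive alternative — inverting the line and adding noise
to x — would attenuate the refitted slope by var(x_true)/(var(x_true)+var(noise))
(classical errors-in-variables), breaking parameter recovery; the
inverse-regression construction keeps OLS refitting unbiased and reduces
to the exact inversion x = (y − b)/a at σ = 0. It requires σ² < var(y)
(otherwise the planted line would explain no variance) and is validated by
Monte-Carlo: over 500 replicates at the study size (n = 63, a = 0.47,
b = 0.55, σ = 0.5), the 95% slope CI covers the planted value in ≈ 98% of
replicates. Because y is uniform rather than Gaussian, E[y|x] is not
exactly linear, which makes the CI slightly conservative, never
anti-conservative in these conditions.

**Descriptors.** Gaussian blobs (unit within-blob sd) whose centres sit at
the stated separation from the origin along random orthogonal-ish
directions; default sizes 45/13/5 in 85 dimensions at 10σ, mirroring the
observed group structure. Hidden truth labels are returned for recovery
tests. At 10σ separation k-means recovers the planted sizes exactly; at
zero separation recovery is at chance, confirming the structure, not the
algorithm's bias, drives the result.

What the synthetic data does *not* emulate: electropherogram peak shapes,
drifting markers, correlated replicate errors, real descriptor
correlation structure, or the physics behind solvation energies. Passing
the synthetic-recovery tests therefore demonstrates the correctness of the
computational chain, not the accuracy of any upstream measurement or
quantum-chemistry model.

## Pipeline and reproducibility

The orchestrated run chains: load → computed-logP → correlations (all
compounds and filtered) → calibrations → descriptors → clustering →
PCA → SVM, writing CSVs plus a JSON manifest (config echo, version,
seeds, row counts). Any stage failure aborts with a stage-tagged error and
the manifest marked incomplete. Reruns with the same config are
byte-identical. Problem sizes used by the test-suite and acceptance
simulations (500 calibration replicates, 100 SVM null replicates at
n = 40, single 63 × 85 cluster recovery) were chosen to give stable
Monte-Carlo margins at interactive runtimes.

## Known limitations

- The retention model assumes neutral analytes; charged-species mobility
  is out of scope (measurements were at pH 7 on neutral compounds).
- "-" entries in the bundled table are treated uniformly as missing
  (whether unmeasured or unresolved is not recorded in the source) and
  never imputed.
- The published micelle-vs-alcohol calibration coefficients ship as
  reference data and are not recomputable here: the underlying solvation
  energies are not public.
- Conformational averaging of solvation energies is not implemented;
  energies are taken as given.
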