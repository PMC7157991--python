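# Methods

## Problem setting

High-throughput screening programmes produce sparse compound × endpoint
hitcall matrices: thousands of small molecules, hundreds of assay
endpoints, each cell active (1), inactive (0) or never tested.  A model
supporting regulatory risk assessment must not only predict per-endpoint
toxicity for a novel compound but also state how much that prediction can
be trusted.  `toxcp` addresses this with conformal prediction, and
complements the statistical prediction with two knowledge-driven prongs:
SMARTS structural-alert screening and Tanimoto similarity read-across.

## Structure standardisation (`toxcp.chemprep`)

Every raw structure passes a deterministic chain: parse → reject
carbon-free inputs (`non_organic`) → split multi-component inputs and
strip components on a shipped ~30-entry counter-ion/solvent list (if the
list would strip everything, the largest carbon-containing component is
retained instead) → reject residual multi-component structures
(`mixture`) → neutralise formal charges (RDKit Uncharger) → reject
structures with elements outside {H, B, C, N, O, F, Si, P, S, Cl, Se, Br,
I} → canonical tautomer (RDKit TautomerEnumerator) → reject fragments
with fewer than three heavy atoms (`too_small`) → canonical SMILES.

The chain is idempotent: re-standardising its output is a no-op.  The
canonical SMILES serves as the structure identity key for duplicate
resolution, which runs both before and after standardisation because
standardisation can merge previously distinct structures (e.g. a free
base and its salt).  Replicate (structure, endpoint) measurements
collapse to one record when all labels agree and are discarded entirely
when they conflict.  Every input record lands in exactly one of matrix or
rejection log.

Single-component inputs are never treated as strippable solvents, so
ethanol is a valid compound while an ethanol solvate of another molecule
loses the ethanol.

## Descriptors (`toxcp.features`)

Two modes:

* **fingerprint_only** — the 167 MACCS keys concatenated with a 1024-bit
  Morgan fingerprint (radius 3): a fixed 1191-bit binary vector,
  corpus-independent.  Used for similarity search and the `original`
  conformal variant.
* **fingerprint_plus_physchem** — the same bits filtered at variance
  ≥ 0.01 over the fit corpus, concatenated with all RDKit 2-D
  physicochemical descriptors (~210 in the pinned RDKit), z-scored per
  descriptor and then filtered at post-normalisation variance ≥ 0.001.
  Because z-scoring maps every non-constant descriptor to unit variance,
  the second threshold effectively removes constant (zero-scale)
  descriptors; it is kept as a parameter so alternative normalisations
  remain pluggable.  Non-finite descriptor values (e.g. overflow on
  information-content indices) are imputed with the fit-corpus mean and
  logged.

The final feature length is corpus-dependent in physchem mode; only the
1191-bit constant of the fingerprint mode is asserted.  All fitted state
(masks, means, scales) is frozen after `fit` and serialises to a
versioned JSON file.

## Conformal machinery (`toxcp.conformal`)

Nonconformity of a (compound, label) pair is the inverse probability
nc = 1 − p̂, with p̂ the random forest's predicted probability of that
label.  The conformal p-value of a query score against a calibration list
is

    p = (#{α_cal ≥ nc_new} + 1) / (n_cal + 1),

ties counting as at least as nonconforming; the +1 correction is required
for the finite-sample validity guarantee.  Calibration is *mondrian*
(class-conditional): separate lists per true label, giving per-class
validity under class imbalance.  A label enters the prediction set at
significance ε iff its p-value exceeds ε; sets are nested in ε.
Credibility is the largest p-value, confidence is 1 − second-largest.

Variants:

* `original` — nc scores used as-is.
* `normalised` — nc scores divided by a norm value: the mean nc score of
  the compound's k = 5 nearest proper-training neighbours (Euclidean
  distance on the model's feature vector, implemented as a
  KNeighborsRegressor fitted on the proper-training features against
  their own resubstitution nc scores), plus a smoothing constant
  β = 0.01 that keeps the divisor strictly positive.  Out-of-bag
  probabilities for the normaliser targets are available behind a flag.
* `normalised_balanced` — additionally, each ACP loop draws 5 random
  class-balanced subsamples (majority class downsampled to the minority
  count) of both the proper-training and the calibration partition, one
  constituent per subsample.

An aggregated conformal predictor (ACP) runs 25 stratified random 70/30
proper-training/calibration splits (so 25 constituents, or 125 for the
balanced variant) and aggregates constituent p-values by their median —
a single median over all loops × subsamples in the balanced case.  The
cross-validated ensemble holds out a stratified 20% test split, runs
5-fold CV over the remaining 80%, trains one ACP per fold on the fold's
CV-training portion, and averages fold-level p-values by their mean, both
for the internal test report and for deployment; no refit on 100% of the
data.  Random forests use 500 trees and library defaults otherwise.

All randomness descends from one root seed through a NumPy SeedSequence;
equal seeds give bit-identical models and predictions.

## Evaluation (`toxcp.evaluate`)

Validity = fraction of prediction sets containing the true label (empty
sets are errors); efficiency = fraction of single-class predictions
(SCPs); SCP accuracy = correct singletons / all singletons, reported as
missing (NaN) when no singletons exist.  Calibration curves tabulate
error rate and efficiency over an ε grid (default 0.01…0.99 step 0.01);
the explicit "valid" verdict is error_rate ≤ ε + 3·√(ε(1−ε)/n) at every
grid point.  Chemical-space diagnostics: 2-component PCA with loadings
frozen on a caller-specified reference set, and mean Tanimoto similarity
of each query to its 10 most similar reference compounds.

## Alerts and read-across

Alert libraries are TSV/JSON tables of (alert_id, SMARTS, effect,
source); rows with unparseable SMARTS are skipped with a warning,
duplicate ids are an error.  Screening enumerates symmetry-distinct
substructure matches (highlighting, not counting, is the use case).  The
shipped 12-alert library is a curated example of textbook toxicophores,
not a reproduction of any published alert collection.

Similarity search ranks reference compounds by Tanimoto similarity on the
raw 1191-bit fingerprint (no variance mask), ties broken by compound id;
the default of 4 hits per query is configurable.  The Tanimoto of two
all-zero fingerprints is defined as 1.0 and logged.  MCS uses RDKit
rdFMCS with connected-MCS semantics, ring-bond matching and exact
bond-order comparison (an aromatic ring never merges with an aliphatic
one), and a 10 s timeout returning the best-so-far result flagged
approximate.  Read-across extracts each hit's tested endpoint → hitcall
map; untested endpoints are absent, not zero.

## Pipeline

An endpoint is eligible for a registry model when at least 300 active and
300 inactive measurements exist (thresholds configurable); the default
registry variant is `normalised_balanced`.  Per-endpoint training
failures are logged and skipped.  Profiling runs standardisation
(rejections surface in the report, never crash it), per-endpoint
conformal prediction, alert screening and similarity read-across, and
emits one JSON report with provenance (package version, config hash,
ε).  Reports are byte-identical across reruns with equal inputs and seed.

## Synthetic data (`toxcp.fixtures`)

The molecule generator enumerates ~1500 substituted scaffolds (benzenes,
pyridines, furans, naphthalenes, cyclohexanes, alkanes, epoxides with
halogen / nitro / thioether / carbonyl / nitrile decorations) and stores
them in standardised canonical form, so every emitted structure survives
`chemprep` unchanged; randomness affects only selection, labels and
masks.  Labels follow a planted SMARTS rule XOR Bernoulli label noise
(noise < 0.5 keeps the rule learnable); a target active fraction can be
requested for imbalance studies.  The abstract feature generator draws
i.i.d. rows from a two-component Gaussian mixture (labels Bernoulli(½),
unit noise, class means a stated Euclidean distance apart) — exactly the
exchangeability premise of conformal validity.  The activity-matrix
generator plants one rule per endpoint and masks cells at a stated
missingness rate.

What the synthetic data does *not* emulate: real assay noise structure,
correlated endpoints, activity cliffs, and the chemical diversity of
screening libraries.  Passing validity tests on it demonstrates the
conformal guarantee under its stated premise (exchangeability), not
real-world predictive performance.

## Problem sizes and numerical choices

The validity suite uses n = 2000 mixture samples (dim 20, class
separation 2.0), a reduced ensemble of 10 ACP loops and 100-tree forests;
the conformal guarantee is distribution-free and does not depend on these
sizes.  The balancing study uses 600 molecules at a 1:6 active:inactive
ratio with 10% label noise, 5 ACP loops, 100-tree forests, predictions
pooled over 5 seeds before computing per-class SCP accuracies.  Model
selection inside the package is deliberately absent: random forests use
library defaults apart from tree count, and k-NN normalisation uses k = 5
uniform-weight neighbours.

Degenerate inputs: a single-molecule corpus cannot support variance
estimation (error); single-class splits cannot be calibrated (error); a
class too small to balance raises with the required minimum; empty
surviving corpora yield an explicit empty matrix with a warning.

## Known limitations

* The conformal guarantee is marginal and assumes exchangeability;
  covariate shift between training and query chemistry voids it (the
  similarity and PCA diagnostics exist to flag this, not fix it).
* Binary mondrian calibration only; no multi-class endpoints, no
  cross-conformal predictors, no deep-learning base models.
* The standardiser is a compact explicit rule chain, not a full
  pharmaceutical registration system; stereochemistry policy follows
  RDKit defaults.
* Median aggregation of constituent p-values trades exact validity for
  stability; empirical error stays within binomial tolerance in the
  shipped tests but the aggregate is not a provably exact p-value.
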