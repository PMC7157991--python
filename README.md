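# toxcp

Confidence-calibrated toxicity profiling for small molecules: mondrian
aggregated conformal prediction over molecular fingerprints, SMARTS
structural-alert screening, and Tanimoto similarity read-across — the three
complementary lines of evidence a risk assessor wants about a novel
compound, built as scikit-learn-compatible estimators.

## Who this is for

Computational toxicologists and cheminformaticians working with sparse
high-throughput screening matrices (compounds × assay endpoints, cells in
{0, 1, missing}) who need per-endpoint activity predictions with *error
control*: instead of a bare label, a conformal model returns a prediction
set — {0}, {1}, {0, 1} or {} — that contains the true label with
probability at least 1 − ε, under exchangeability.

## The statistics in brief

A random forest is fitted on a proper-training split; the nonconformity of
a (compound, label) pair is the inverse probability

    nc = 1 − p̂(label)

scored on a held-out calibration split, with separate (mondrian)
calibration lists per class.  The p-value of a query score is its rank
among the calibration scores, (#{α ≥ nc} + 1)/(n + 1), and a label enters
the prediction set at significance ε iff p > ε.  Optionally each nc score
is normalised by the mean nc of the compound's k = 5 nearest
proper-training neighbours (plus smoothing β = 0.01), making the regions
locally adaptive, and each loop's splits can be class-balanced by
subsampling to counter imbalance.  Aggregation: median over the 25
constituents of an ACP, mean over the folds of a 5-fold cross-validated
ensemble.  Credibility = largest p-value; confidence = 1 − second-largest.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from toxcp import MondrianConformalClassifier, credibility_confidence, prediction_set
from toxcp.fixtures import generate_feature_dataset
from toxcp.evaluate import validity, efficiency

# interpreting one p-value pair (p0, p1) for a query compound
p = (0.19, 0.56)
print(prediction_set(p, 0.2))        # {1}       -> predicted active at eps=0.2
print(credibility_confidence(p))     # (0.56, 0.81)

# training on exchangeable synthetic data
X, y = generate_feature_dataset(1000, dim=20, class_separation=2.0, seed=0)
Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.2, stratify=y, random_state=0)
model = MondrianConformalClassifier(variant="normalised_balanced",
                                    n_acp_loops=10, rf_n_trees=100,
                                    random_state=0).fit(Xtr, ytr)
pv = model.predict_p(Xte)
print(np.round(pv[0], 3), yte[0])    # [0.58  0.214] 0
print(round(validity(pv, yte, 0.2), 3))    # 0.91
print(round(efficiency(pv, 0.2), 3))       # 0.805
```

The first query's p-value pair (0.19, 0.56) yields the singleton set {1}
at ε = 0.2: only the active label's p-value clears the 0.2 bar.  Its
credibility 0.56 is the highest ε at which any label would still be
assigned; its confidence 0.81 says the alternative (inactive) label is
implausible.  On the held-out split the empirical validity 0.91 exceeds
the 0.8 guaranteed at ε = 0.2, and 80.5% of predictions are decisive
single-class sets.

## Command line

`toxcp` exposes subcommands `standardize`, `featurize`, `train`,
`predict`, `evaluate`, `alerts`, `similar`, `profile` and `fixtures`;
`toxcp --help` lists options.  A full profile run combines per-endpoint
conformal p-values, structural-alert hits with matched atom indices, and
the most similar reference compounds with their experimental activities
into one JSON report.

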