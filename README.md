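# rsvmcluster

Random SVM cluster classification of brain functional-connectivity
networks, with frequency-based feature selection and brain-region
weight mapping.

## The problem

Two-group neuroimaging studies (for example autism spectrum disorder
patients versus typical controls) often try to classify subjects from
resting-state fMRI and, just as importantly, to say *which* brain
regions drive the separation.  A single support vector machine on
thousands of connectivity-derived features is unstable: its accuracy
swings with the kernel settings and it offers no principled feature
ranking.  This package implements the *random SVM cluster* approach —
a random-subspace ensemble of SVMs — for both tasks.

## The method

Starting from each subject's regional mean time series (T volumes x N
regions; N = 90 for the AAL cerebral atlas):

1. **Connectivity.**  The functional connectivity between regions *i*
   and *j* is the absolute Pearson correlation |r<sub>ij</sub>| of
   their signals.
2. **Brain graph.**  Thresholding at |r| > τ (default τ = 0.25) gives a
   binary adjacency matrix.
3. **Graph features.**  Four node-wise metric families are assembled
   into one vector per subject, in a fixed canonical order: the N
   degrees k<sub>i</sub>, the N(N−1)/2 pairwise shortest-path lengths
   d<sub>ij</sub> (hop counts; disconnected pairs take the finite
   sentinel N), the N Latora–Marchiori local efficiencies
   E<sub>loc,i</sub>, and the N clustering coefficients C<sub>i</sub>.
   For N = 90 that is 90 + 4,005 + 90 + 90 = 4,275 features.
4. **Random SVM cluster.**  Subjects are split 7:3 into train and test.
   B = 500 base classifiers are trained, each a hard-margin RBF SVM
   (width σ = 3 per standardized feature, penalty 10<sup>10</sup>) on a
   random subset of s = 50 training subjects and f = 62 features, both
   drawn without replacement.  The ensemble predicts by majority vote;
   the label of a patient is −1 and a control +1.
5. **Feature selection.**  Base classifiers are ranked by individual
   test accuracy; the feature subsets of the top K = 100 form a
   100 × 62 index matrix whose entry frequencies define the M = 400
   "important features".  Rebuilding clusters whose subsets are drawn
   from the first *q* important features only (q = 70, 72, …, 400)
   locates the optimal feature set, which is finally mapped to
   per-region weights (pairwise features credit both endpoint regions).

A planted-effect simulator (`rsvmcluster.synth`) generates two-group
multivariate-normal cohorts over a modular background correlation
structure, with the patient group's correlations raised by δ on a known
edge set, so the whole pipeline is testable end to end without any data
download.

## Worked example

```bash
python examples/02_simulate_and_classify.py
```

```
cohort: 40 subjects, 525 graph features each
split: 28 train / 12 test
mean single-SVM accuracy: 85.29%
majority-vote ensemble accuracy: 91.67%
```

A 30-region cohort (20 patients + 20 controls, T = 110 volumes) with
the patient group's connectivity raised by 0.4 on 10 planted region
pairs.  Each base SVM, trained on a random sample/feature subset, is
individually mediocre (85.3% on average); the 200-classifier majority
vote reaches 91.7% on held-out subjects.  `examples/03_feature_selection.py`
continues to feature selection and region weights, and
`examples/01_graph_metrics.py` / `examples/04_demographics.py` show the
graph-metric and demographics building blocks.

The same pipeline is available from the shell:

```bash
rsvmcluster simulate --outdir data/            # synthetic cohort
rsvmcluster run --outdir results/run1 --seed 1 # full pipeline
rsvmcluster demographics                       # group comparison tests
```

Note on evaluation modes: the default `mode="paper"` protocol ranks
base classifiers and selects *q* on the same test subjects whose
accuracy it reports, reproducing the published procedure (which leaks
test information into selection).  `mode="honest"` carves a validation
subset out of training for selection and keeps the test set untouched.

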