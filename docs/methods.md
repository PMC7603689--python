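# Methods

## Scope and model

`negspace` treats binary interaction prediction as a negative-construction
problem. Positives are the curated interacting cytokine–receptor pairs; the
candidate-negative pool is everything else in the closed world
(cytokines × receptors minus positives, enumerated in deterministic
lexicographic order so seeded sampling reproduces across platforms). All
sampling and selection operates on pair feature vectors after column-wise
min–max normalization fitted on the table being sampled; constant columns map
to 0. Whether downstream classifiers see normalized or raw features is a
caller choice — the harness's `build_balanced_dataset` passes vectors through
unchanged, and the sampling routines normalize internally, which matters for
the distance-based methods only.

## Feature blocks

Residue order is alphabetical by one-letter code everywhere
(ACDEFGHIKLMNPQRSTVWY), recorded in every block's feature names. Non-canonical
letters are resolved by a configurable policy (default `drop`; alternatively
B→N, Z→Q, U→C, J→L, O→K with X dropped, or a hard error).

* **AAC / DPC** are plain composition vectors normalized by L and L−1.
* **ATC** sums per-residue C/H/N/O/S atom counts using peptide-bonded residue
  formulas (free amino acid minus one water) and normalizes by the total atom
  count. Ignoring the terminal water is a deliberate simplification whose
  effect vanishes with chain length.
* **PGC / P2G** share an 11-group residue classification (hydrophobic,
  hydrophilic, aromatic, aliphatic, positively charged, negatively charged,
  polar uncharged, small, tiny, sulfur-containing, amide). The memberships
  follow standard residue-classification conventions (Taylor-style tiny/small
  sets, physiological-pH charge groups) and are overridable via
  `ResiduePropertyTable`; P2G hard-requires 11 groups because the combined
  56-dim block depends on that width, PGC does not. P2G counts adjacent
  residue pairs falling jointly inside a group, over L−1.
* **PCP** is the per-scale mean over the sequence; seven standard scales ship
  (Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, Grantham polarity,
  Charton–Charton polarizability, net side-chain charge, average residue
  mass, isoelectric point), all overridable.
* **AAC_PSSM / D-FPSSM** consume PSI-BLAST ASCII PSSMs. Only the log-odds
  block is read (standard descriptor practice); columns are reordered to the
  alphabetical convention at parse time so no downstream code ever sees
  PSI-BLAST column order. D-FPSSM clamps negative scores to zero, sums each
  column, and normalizes; the normalization is a flag (`length` default,
  `max`, `none`) because more than one convention exists in the descriptor
  literature.

The combined per-protein block is ATC ‖ P2G ‖ AAC_PSSM ‖ D-FPSSM = 56 dims;
pair vectors are cytokine block first, then receptor block (112 dims). The
order is arbitrary but fixed and self-described by the feature names.

## Sampling

* **Random** — `numpy` Generator choice without replacement, seeded.
* **K-means** — a Lloyd iteration seeded with k-means++ (best of `n_init=3`
  restarts by SSE, iteration cap 100, relative tolerance 1e-6), written
  in-house so that the per-iteration SSE trajectory is recorded (it must be
  non-increasing; the test suite checks this) and the empty-cluster policy is
  explicit: an empty centroid is re-seeded at the currently worst-fit point
  during iteration; if a converged run still has empty clusters it is retried
  with derived seeds up to 3 times, after which the largest clusters donate
  extra distinct members. One member per cluster is then drawn uniformly at
  random (seeded). `sklearn.cluster.KMeans` is used as an independent
  cross-check in tests, not as the implementation.
* **Kennard–Stone** — first pick is the row nearest the column mean;
  subsequent picks maximize the minimum Euclidean distance to the selected
  set. Ties break to the lowest row index, making the procedure fully
  deterministic; it takes no seed. A brute-force O(n²·|pool|) oracle written
  with plain Python loops verifies it exhaustively on pools of ≤ 12 points.

## Autoencoder stratification

The autoencoder is a multilayer-perceptron regressor fit to reproduce its own
input (`MLPRegressor`, Adam, seeded). Two presets ship:

| preset | hidden layers | activation | epochs | l2 |
|--------|--------------|------------|--------|------|
| paper  | 1000-500-100 | tanh       | 1000   | 1e-4 |
| small  | 32-16-8      | tanh       | 400    | 1e-4 |

The `paper` preset is the architecture the original study selected; `small`
is the desk-scale default used throughout the test suite. Optimizer, learning
rate (1e-3) and batch size (`auto`) are not dictated by the method and are
plain configuration.

Training uses positive pairs only; every pair is then scored by
Δ = mean squared per-feature residual. Negatives are banded at Δ ≤ 0.001
(hard), ≤ 0.003 (intermediate) and > 0.003 (easy); both bounds are upper
inclusive. These default cutoffs were data-derived on the original study's
feature scale, so `quantile_cutoffs` offers positive-error-quantile cutoffs
(defaults: 50th and 95th percentiles) for data whose error scale differs —
the synthetic data, for instance, produces Δ an order of magnitude larger.
Pairs are scored on the same assembled pair vector used for classification.

## Evaluation harness

Metrics are computed from pooled held-out predictions per run; averages are
arithmetic over runs. Undefined values (zero denominators, single-class
truth for AUC) are NaN and excluded from averages with a warning. MCC returns
0 when any radicand factor vanishes. AUC is the rank-based (Mann–Whitney)
statistic with ties counted half. The 70/30 split protocol stratifies by
class, so positives and negatives are each split 70/30. Degenerate folds
(a class missing from training) are skipped and flagged on the report.

The classifier registry approximates the commonly used Weka-default learners
with scikit-learn defaults: GaussianNB, SVC with RBF / polynomial /
Pearson-VII-universal (PUK, ω = σ = 1) kernels, 1-nearest-neighbour,
bagged decision trees, and random forest. These are approximations — Weka's
SMO and sklearn's SVC differ in defaults — and an averaged one-dependence
estimator (A1DE) has no scikit-learn counterpart, so it is not shipped.
Hyperparameter search is deliberately out of scope.

`benchmark` draws `reps` negative sets per sampling method, builds balanced
datasets against the fixed positives, and evaluates every classifier under
the chosen protocol, averaging across negative sets. Kennard–Stone is
deterministic, so its `reps` draws coincide; variation then comes only from
the protocol's splits.

## Synthetic data generator

The generator emulates the structure, not the biology: random canonical
sequences (uniform residues, lengths uniform in the configured range), mock
PSSMs (integer log-odds in [−8, 12] with the own-residue column biased to
[5, 12]), and a latent-factor model for pair vectors,

    v = μ + 0.1·(W z) + σ·ε,   z = standardized random projection of the
                               concatenated per-protein features,

with isotropic ε and stratum-dependent σ: positives σ₀ = 0.02, hard
negatives (1+s)·σ₀, intermediate (1+5s)·σ₀, easy (1+19s)·σ₀, where s is
`signal_strength` (default 1). The manifold spread (0.1 per coordinate)
deliberately sits between the positive noise and the easy offset so that
distance to the positive manifold orders the strata — which is exactly the
structure the autoencoder grouping is meant to detect. Stratum fractions
default to 10% hard / 20% mid / 70% easy, making hard negatives the rare
"small disjuncts" that random sampling under-represents. Stratum labels are
test-only ground truth, serialized in a JSON sidecar, never in feature
columns.

Defaults mirror the study scale (123 cytokines, 102 receptors, 203
positives → 12,343-pool); the `tiny` preset (24 × 18, 40 positives, 392-pool,
sequences of 30–60 residues) keeps the end-to-end tests at desk scale. What
passing tests show is that the pipeline recovers planted geometric structure;
they do not show that random sequences resemble cytokines, that mock PSSMs
carry evolutionary signal, or that absolute performance numbers transfer to
real data.

## Numerical choices and limitations

* Min–max normalization maps constant columns to 0; parameters applied to a
  different table can legitimately leave [0, 1].
* ARFF values are written with 12 significant digits; round-trips preserve
  row order and class counts.
* The acceptance script and the directional tests run at the sizes stated
  above (study-scale pool for the K-means count; tiny preset, 10 and 5 seeds,
  for the sampling-contrast and stratification checks) — chosen as the
  smallest sizes at which the planted structure is unambiguous.
* Absolute performances on the original curated dataset are not reproducible
  here: they require the original sequences and database-dependent PSSMs.
  The toolkit consumes PSSMs; it never runs PSI-BLAST.
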