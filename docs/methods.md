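# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `phenobar`, in the order the pipeline runs.

## Screen design and the synthetic generator

A screening block for one chemical is a 48-well plate: one solvent-control
row plus five concentration rows of eight wells, run as technical
triplicates with the row-to-concentration assignment cyclically rotated
between the three replicate plates (guarding against edge effects), giving
n = 24 animals per concentration. Chemicals tested at more than five
concentrations occupy additional plate blocks, each with its own control
row. Compounds are taken from the packaged study table: 19 experimentally
screened drugs (7 antidepressants, 7 antipsychotics, 5 anxiolytics), their
counterion controls, and computational-only stereoisomer entries. For 2D
(stereochemistry-blind) chemical analyses the escitalopram/citalopram pair
collapses to one structure (18 drugs); for 3D analyses the three racemic
drugs expand into enantiomer pairs (21 structures). The study table lists 4
experimental counterions; descriptor exports that count 5 trigger a
validation warning rather than silent reconciliation, since the fifth
identity is not determinable from the table.

The generator's dose-response model is a Hill curve,
`effect(c) = m·c^h / (ec50^h + c^h)`, applied multiplicatively for
percent-ratio endpoints, additively (as a fraction of time) for
percent-difference endpoints, and additively in raw units for burst counts.
A Hill form was chosen because it is the standard monotone pharmacological
dose-response with only two shape parameters; the real screen measured
animals, so any generative model here is a modeling choice, not a
reproduction. Binary outcomes are Bernoulli with probability interpolating
from the background rate to the class maximum along the same curve.
Crawl-out is sampled first; a crawled-out animal is excluded from every
other endpoint. Lethality is not simulated (the compound classes modeled do
not kill at screen concentrations). Specific body shapes (contraction,
C-shape, corkscrew, pharynx extrusion, hyperkinesis) are sampled per
category and capped at three per animal, as in manual scoring; "any abnormal
shape" is their union.

Default control noise is normal on the raw scale, clipped to each
endpoint's physical range, with scales set once so that the 5th/95th
percentile of the normalized controls lands near the registry BMRs (e.g.
anxiety: mean 0.60, SD 0.11, giving a 5th-percentile magnitude near 30%).
Default class signatures give each drug class a distinct endpoint subset
with maxima around 2–3× the BMR at `ec50 = 5 µM`, hill slope 1.5:
antidepressants are dominated by hyperkinetic shapes, scrunching loss and
slowed blue-light speed; antipsychotics by phototaxis failure, reduced
anxiety (wall preference) and dark-speed, contraction/C-shapes;
anxiolytics by locomotor bursts, blue-cycle resting, blunted noxious-heat
response. Counterions carry no signature. These defaults define the study
conditions for all tests; they emulate class-consistent, monotone,
independent per-endpoint effects and do **not** emulate non-monotone
(toxicity-confounded) high-dose responses, pH artifacts, solubility limits,
between-animal correlation, or plate drift — so passing tests demonstrate
the pipeline's correctness and statistical behavior, not performance on
real screens.

## Normalization

Continuous endpoints are normalized per animal against the *median* of the
same plate's vehicle controls: percent ratio `(R/R_veh)·100 − 100` for
speeds, anxiety and noxious-stimulus displacement; difference ×100 for
fraction-of-time endpoints (resting); raw difference for locomotor bursts.
A zero vehicle median under the ratio rule is an error naming plate and
endpoint. Binary endpoints are pooled across the three replicate plates
(counts summed to n ≈ 24) and corrected by the pooled control incidence;
the control count is scaled by `total/control_total` before subtraction so
the rule stays defined when exclusions unbalance denominators, and negative
corrected counts clip to 0. Crawl-out reports the raw incidence (it has no
meaningful in-plate control correction). Whether correction should happen
before or after pooling is ambiguous when exclusions occur; pooled-then-
subtract is the default and a per-plate-then-pool variant is available via
`binary_pooling="per_plate"`. Missing values propagate as explicit markers,
never as zeros, until barcode assembly.

## Benchmark responses and concentrations

Each endpoint carries a benchmark response (BMR): the noise threshold a
normalized response must exceed to count as an effect (25–35% for binary
incidences; 20–80 for continuous endpoints depending on control variance).
When a registry value is not used, the fallback BMR is the 95th (increasing
direction) or |5th| (decreasing) percentile of the pooled normalized
vehicle controls; a variance-minimization BMR search is out of scope and
registry values are accepted as fixed inputs.

The BMC is estimated by bootstrap (default n = 1000). Continuous endpoints
resample replicates with replacement within each level and summarize by the
median; binary endpoints resample the pooled corrected incidence
binomially. Each bootstrap curve's directional effect is scanned for its
first crossing of the BMR; the crossing is interpolated linearly in log10
concentration between the bracketing levels. Crossings already above the
BMR at the lowest tested level clamp to that level with a flag —
extrapolation below the tested range is never performed. A
chemical-endpoint pair is *active* when at least half the bootstrap curves
cross (this threshold keeps the reported median well-defined); the median
and 5th/95th percentiles of the active crossings are reported in µM. This
level-wise summary + first-crossing scheme is a deliberate, oracle-checkable
simplification of monotonized curve-fitting approaches used with real
screen data; on noiseless step curves it reproduces the closed-form
interpolation exactly, and on simulated Hill data with n = 24/level it
recovers the analytic BMR crossing to well within 0.25 log10 units.
Endpoints that can move in both directions are tested in each direction
separately; only crossings are reported.

## Barcodes

A concentration barcode is a fixed-order 13-vector (CRO, STK, SHP, SCR,
PTX, ANX, RSD, RSB, SPD, SB1, SB2, LBT, NSS): corrected incidence (%) for
binary endpoints, median per-animal normalized response for continuous
ones. A chemical's master barcode concatenates its concentration barcodes
in *relative* order (rank within the chemical's tested series, not absolute
µM), right-aligned at the top tested concentration, truncated to the
highest five blocks (65 entries). Chemicals tested at fewer than five
levels get zero-filled lower blocks; zero denotes "no effect", and a
companion boolean mask records which entries were measured so the
information loss is auditable. Column labels use a study-wide relative
scale: when the deepest series runs to 12 levels, the retained blocks are
labeled 8–12 for every chemical. An optional flag appends the five specific
shape-class incidences per level (18 × 5 = 90 entries) for analyses that
need shape detail. Chemicals with no active endpoint anywhere can be
dropped from the matrix (logged), mirroring the exclusion of fully inactive
compounds from classification. Potency-anchored (e.g. BMC-aligned)
concatenation is a known limitation and deliberately not implemented.

## Feature preparation

Basic culling removes non-numeric, all-zero, all-missing, singleton and
constant columns. Model culling additionally removes columns identical to
an earlier one, columns with coefficient of variation ≤ 1% (CV = SD/|mean|,
sample SD; zero-mean columns are exempt since their CV is undefined and
deleting centered informative columns would be wrong), columns non-zero for
at most three rows, and — for each pair with |Pearson r| ≥ 0.98 — the later
column in input order (deterministic tie-break; absolute correlation is
used). Standardization brings every surviving column to mean 0, SD 1
(sample SD), ignoring and preserving missing entries; it is idempotent to
1e-10.

## Ordination classifiers

Gower distance: the mean over jointly observed columns of range-normalized
absolute differences, in [0, 1]; zero-range columns are skipped and a row
pair sharing no observed column is an error. PCoA double-centers the
squared distances (−½·J·D²·J), eigendecomposes, and retains positive-
eigenvalue axes scaled by √λ; negative eigenvalues are reported as
diagnostics and excluded from percent-of-total denominators (no
Cailliez/Lingoes correction — the simplest defensible treatment). LDA uses
equal class priors and predicts by nearest class centroid in canonical
space; 95% confidence ellipses use the chi-square 0.95 quantile on 2
degrees of freedom with the class covariance in the plotted plane. The
eigendecomposition behind LDA is delegated to scikit-learn's svd solver.

Reported accuracy is an exhaustive leave-one-out jackknife. The default
*fast* mode reduces once on all samples and refits only the LDA per fold —
the behavior observed in common desktop ordination software; a *strict*
mode recomputes Gower ranges, distances and PCoA on each n−1 training set
and places the held-out sample by the add-a-point double-centering
projection. Strict mode is defined only for PCoA (UMAP has no exact
out-of-sample projection for a precomputed metric). The axis count is
chosen by exhaustive search over 2..min(n−2, 10), ties toward fewer axes.
Within jackknife folds a class may be left with a single member; the fold
fit tolerates that (the svd solver handles the rank-deficient scatter),
while the user-facing `lda_fit` enforces two samples per class.

UMAP runs on the same Gower distances (precomputed metric, 100
optimization epochs, fixed random state for determinism). Because "maximum
separation of clusters" is a visual criterion in interactive software, the
parameter search operationalizes it as the label-aware mean silhouette of
the embedding over a small grid of `n_neighbors`/`min_dist`, ties to the
first grid point.

## Machine-learning classifiers

Test sets are drawn by randomized stratified sampling by class:
largest-remainder rounding of proportional quotas (remainder ties to the
larger class, then class order), members uniform within class,
deterministic per seed.

Descriptor subsets are selected by a genetic algorithm over binary masks:
fitness is the verification-set k-class Youden of a model built on the
masked columns minus 0.5 percentage points per descriptor (the size penalty
is a package default; smaller values select larger subsets), tournament
selection, uniform crossover, bit-flip mutation, one elite survivor, a cap
on subset size, and memoized fitness. The verification split (2:1) is fixed
once per search so chromosome comparisons are consistent.

Each ANNE submodel is a single-hidden-layer net (logistic hidden units,
2–5 of them, softmax output) trained by full-batch Adam (lr 0.05) on the
cross-entropy, with its own random initialization and internal 2:1
training/verification split (resampled up to 10 times to keep every class
in the training part). Training halts when the verification Youden fails to
improve for 20 consecutive checks (one check every 5 epochs, 300 epochs
cap); the best-scoring weights are restored. Submodels are scored
`J_ver − |J_ver − J_train|`, penalizing the train/verification gap; the
ensemble of 10 submodels predicts by majority vote with a mean-probability
tie-break. The net is implemented directly in numpy because the stopping
criterion (verification Youden with patience) and the scoring rule are not
expressible through standard library early stopping. The ensemble size (10)
and the patience are package defaults, configurable.

SVMs use scikit-learn's SVC (one-vs-one multiclass), linear kernel and
C = 1 by default; rbf is available. SVMs have no overfitting guard
analogous to the ANNE stopping rule, which is why the ranking's parsimony
terms matter.

Every model is evaluated with nine indicators: Youden J (macro-averaged
one-vs-rest sensitivity+specificity−1), Matthews R_k (computed from the
confusion matrix as the correlation of true/predicted indicator matrices),
and accuracy — each on the training set, test set and all chemicals,
expressed as percentages. Degenerate denominators score 0 with a flag. The
macro-average definition of the k-class Youden is one of several in use;
it is the package's chosen convention and is flagged here deliberately.

A battery runs 10 independent split/select/train/evaluate pipelines from
seeds derived from one master seed and summarizes mean ± SE per indicator.
Ranking uses `S = Σ(train J, MCC, Acc) + Σ(test J, MCC, Acc) +
100·N_min/N (ensembles only) + 100·D_min/D` with battery minima N_min,
D_min and average-rank ties; "train + test" intentionally excludes the
"all" metrics. If the top-ranked model's test set misses a class, the
ranking notes the next-ranked model covering all classes. Models without
test metrics are excluded from ranking with a log entry.

## Problem sizes and determinism

Default analysis sizes: 1000 bootstrap curves per BMC, 10 models per
battery, 10 submodels per ensemble, GA population 16 × 8 generations, 100
UMAP epochs, 5 barcode blocks. The test suite and the acceptance script use
these defaults except where a statistical property is averaged over seeds
(10–20 screens/batteries/permutations, chosen as the smallest sweeps that
make the pass/fail bands stable). Every stochastic stage takes an explicit
seed; batteries and the full-study runner derive per-stage seeds from one
master seed via numpy's SeedSequence, so reruns are bit-identical (the
manifest records artifact hashes to make this checkable).

## Known limitations

- The generator's per-endpoint independence and monotone Hill effects make
  classification easier than on real behavioral data; reported accuracies
  on synthetic screens are upper bounds of plumbing correctness, not
  biological performance claims.
- The BMC estimator does not fit parametric curves and cannot report Hill
  parameters; heavily non-monotone responses yield conservative
  "first-crossing" estimates.
- Binary BMC bootstraps the corrected pooled incidence, which ignores
  plate-level overdispersion.
- UMAP results depend on the library's implementation details; only
  seed-determinism and the epoch budget are guaranteed.
- Chemical descriptors are external inputs; no structure handling beyond
  the stereoisomer bookkeeping is performed.
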