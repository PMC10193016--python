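# Methods

`fragscreen` implements a ligand-based screening workflow for targets with
very little labeled bioactivity data: conservative fragment-growing data
augmentation around a small seed set, fingerprint/property featurization,
classifier training with generalization-gap diagnostics, similarity-network
hit triage of an unlabeled library, and four-parameter logistic (4PL)
concentration-response analysis of follow-up assays. This note documents
the models, the defaults and why they were chosen, the synthetic-data
generator and its limits, and the numerical decisions.

## Featurization

Molecules are canonicalized with RDKit (largest organic fragment kept, so
salt forms collapse to the parent); the toolkit's default aromaticity and
canonical SMILES dialect are used throughout and recorded implicitly by the
RDKit version in run manifests. A feature vector concatenates:

* a folded Morgan (extended-connectivity) fingerprint, radius 2, 2048 bits;
* the 166 standard MACCS structural keys;
* seven physicochemical properties — LogP (Crippen estimator), H-bond
  donors, H-bond acceptors, molecular weight (g/mol), TPSA (Å²), rotatable
  bonds, ring count.

Fingerprint blocks stay binary; the property block is Z-scored with a
scaler fitted on the training set only. A zero-variance property column is
flagged and transformed to exactly 0, including for unseen values — a
constant training column carries no information and must not leak spurious
variation at predict time (this is why a 15-line scaler is used instead of
`StandardScaler`, whose unit-scale fallback maps unseen values away from 0).
The 2048-bit folding and bit (rather than count) encoding are conventional
choices; both are configurable in `FeaturizerConfig`.

## Fragment-growing augmentation

The augmentation engine expands each labeled seed into up to `k` analogs
(default 20) that inherit the seed's label. A fragment library is built
from a reference compound collection by cutting every single acyclic bond
between heavy atoms; each removed fragment is stored under a key — the
canonical subgraph within `radius` bonds (default 3) of the attachment
point on the retained side. Two edit types are enumerated on a seed:

* **grow** — replace a hydrogen on a carbon with a library fragment whose
  key matches the site's radius-r environment;
* **mutate** — cut an acyclic bond and swap the removed fragment for a
  different library fragment under the same environment key.

All admissible (site, fragment) edits are enumerated in a stable order,
shuffled with a seed derived from the run seed and the molecule id, and
materialized lazily until `k` unique, valence-valid, canonical analogs are
collected (globally deduplicated across the dataset; collisions are
replaced from the remaining candidates). Fewer than `k` possible analogs
produces a warning by default and an error in strict mode.

Two size caps keep edits conservative. `max_heavy_atom_delta` (default 8)
bounds the net size change. `max_fragment_size` (default 8 heavy atoms)
bounds the removed and inserted fragments themselves: without it, an
"edit" may retain only a methyl group and swap in an entirely different
molecule body, which satisfies the delta cap while destroying the seed's
identity. With the cap, every analog provably contains a large connected
core of its parent, which is the structural meaning of label inheritance.

Linking (joining two seeds through a fragment) is not implemented; growing
and mutation cover the augmentation contract exercised here.

## Classifier and generalization gap

Splitting is stratified by class at seed level (default 75/25). With
`group_by_parent` (default), a seed and all of its analogs land on the
same side, so near-duplicates can never straddle the split — otherwise
test metrics are inflated by leakage. A `paper_mode` flag instead adds
analogs to the training side only, leaving a seeds-only test set.

Four model families are supported (random forest, SVM, logistic
regression, k-nearest neighbors). Hyperparameters are grid-searched with
stratified k-fold cross-validation (5 folds for seed-only sets, 10 for
augmented sets) scored by recall by default — for a screening tool, a
missed active is costlier than a false alarm. The grid is enumerated
simplest-first (fewest trees, shallowest depth, strongest regularization,
most neighbors) and score ties keep the earlier point, so tie-breaking
favors the simpler model. The CV table retains one row per (grid point,
fold).

Evaluation computes the 2×2 confusion matrix at probability threshold 0.5,
and accuracy, Matthews correlation and F1 directly from its entries
(MCC is defined as 0 when a marginal is empty — the constant-classifier
convention); ROC-AUC uses the full probability ranking. The
generalization-gap report Δ(Training − Test) is an element-wise
subtraction per metric: near-zero deltas indicate a model that
generalizes, large deltas a model that memorized its training set. The
headline diagnostic of the package is that fragment-grown augmentation
shrinks Δaccuracy relative to seeds-only training on the synthetic
benchmark (30 active / 20 inactive seeds, k=20) in at least 8 of 10
replicate seeds; the benchmark uses a fixed single-point random-forest
configuration (200 trees, balanced class weights) because the comparison
is between training sets, not grid-search outcomes, and a full grid adds
runtime without changing the contrast.

## Screening and hit triage

Library molecules are scored by the trained classifier. A similarity
network connects molecules whose ECFP4 Tanimoto similarity is at least
`edge_threshold` (default 0.4); the neighbor count is the node degree.
A t-SNE map of the feature matrix is produced for reporting only — it is
never used as a filter. A molecule is a hit when all criteria hold, with
inclusive bounds:

* probability in [0.6, 0.9] — the upper bound triages out trivial
  rediscoveries of the training chemistry; set `prob_max` to 1.0 for a
  pure "greater than 0.6" rule;
* neighbor count ≥ 3 — hits should sit in structurally coherent
  neighborhoods, not be isolated predictions;
* H-bond acceptors in [0, 10], donors in [0, 5], cLogP in [0, 5]
  (same Crippen estimator as featurization, for internal consistency),
  molecular weight in [300, 1000] g/mol.

An audit table records every molecule's per-criterion outcome; molecules
with a missing probability are flagged, never silently dropped.

## Concentration-response analysis

Raw enzymatic rates are normalized per batch to the mean of the
negative-control wells (untreated = 100%). The 4PL model is

    Y = Min + (Max − Min) / (1 + (X / IC50)^Hill)

with Y in % of control and X in μM: activity falls from Max at zero dose
to Min at saturation, and Y(IC50) = (Min + Max)/2. This is the standard
inhibitor-versus-normalized-response curve; the frequently printed
`(IC50/X)^HillSlope` form is the identical family with the slope sign
folded into the ratio, and the positive-slope convention is used so the
bounds below are one-sided. Maximal inhibition is 100 − Min.

Numerical choices: least squares (`scipy.optimize.curve_fit`) on all
replicate points, bounds Min ∈ [−20, 120]%, Max ∈ [50, 150]%,
IC50 ∈ [10⁻³, 10⁴] μM, Hill ∈ [0.2, 5]; five starting points with IC50
log-spaced across the measured concentration range guard against local
minima; the best SSE wins. R² is computed on replicate means, matching how
mean ± SD curves are plotted (raw-replicate fitting is available via
`on_means=False`/`True`). Zero-concentration rows anchor normalization only
and are excluded from the fit. A fit is unreliable — and its IC50 withheld
— when the optimizer fails, the IC50 lands on a bound, or the IC50
standard error exceeds the estimate. The activity call is "inhibitor" iff
the fit is reliable, R² ≥ `r2_min` (default 0.18, inclusive at the
boundary), and maximal inhibition exceeds twice the standard error of the
lower asymptote; otherwise "inactive". Flat curves therefore classify as
inactive through both the R² and the reliability route.

## Synthetic-data generator

All tests and the demo run offline on generated inputs.

**Seed sets.** Molecules are built by decorating one of 12 fixed ring-
system scaffolds (fused aromatics, a statin-like δ-valerolactone, a
1,4-dihydropyridine, benzene) with 2–3 substituents drawn from 31 common
medicinal-chemistry groups. Activity is a smooth latent in (0, 1):
a logistic link over a fixed linear combination of the seven properties
(gain 0.25, standardization constants describing this grammar's typical
chemistry) plus a per-scaffold offset in ±0.7–2.2. Labels threshold the
latent at 0.5, with 2% label-flip noise. Two design features enforce the
continuous-SAR premise the augmentation relies on: the property gain is
gentle, so one substituent edit moves the latent only slightly, and every
scaffold is a single or fused ring system with no acyclic internal bond,
so no fragment edit can create or destroy a scaffold match — the offset is
invariant under augmentation. Measured on 200 random single-edit pairs,
the 95th-percentile |Δ latent| is ≈ 0.17 and the label-flip (cliff) rate
≈ 2–3%.

**Fragment reference.** A fixed, deterministically generated collection of
800 molecules from the same grammar (1–4 substituents) stands in for a
public fragment database; it is dense enough that every generator seed
reaches k=20 unique analogs at radius 3 with no shortfall.

**Screening library.** n drug-like molecules (2–4 substituents, so a large
fraction clears the 300 g/mol filter), with ~10% planted single-edit
analogs of the active seeds recorded as retrieval ground truth.

**Assay curves.** Plate-style raw-rate tables generated from a 4PL truth
at the 10-point ladder 0.1, 0.25, 0.5, 1, 2.5, 5, 10, 25, 50, 100 μM,
3 replicates per concentration, Gaussian noise of 5 percentage points on
the %-of-control scale, plus noisy negative-control wells.

**What the generator does not emulate.** Real chemistry has activity
cliffs, assay-to-assay batch effects, scaffold families absent from
training data, and property distributions far broader than a 12-scaffold
grammar. Passing tests therefore demonstrate that the machinery behaves as
specified under the continuous-SAR regime the method assumes — not that
augmentation rescues any particular real dataset, where the cliff rate is
an empirical question.

## Reproducibility

One global `rng_seed` in `RunConfig` reproduces an entire run: per-stage
seeds are spawned from `numpy.random.SeedSequence(rng_seed)` in a fixed
stage order (sar, library, augment, split, train, screen, assay) and
recorded in the manifest. Artifacts are written with fixed float
formatting; two runs from the same config are byte-identical.

## Problem sizes used in the shipped experiments

The benchmark and demo run at desk scale by design: 30/20 or 68/37 seeds,
k=20 analogs, a 300-molecule demo library, 100 replicate assay
simulations. These sizes make every experiment reproducible in minutes on
one CPU while preserving the qualitative regime (tens of seeds, thousands
of augmented molecules) the workflow targets.

## Known limitations

* The augmentation engine edits one site per analog; multi-site edits and
  fragment linking are out of scope.
* Probabilities are raw random-forest votes, not calibrated; the [0.6, 0.9]
  band is a ranking heuristic, not a posterior statement.
* The cLogP estimator (Crippen) differs from other packages' estimators;
  filter outcomes near the 0/5 boundaries can differ across toolkits.
* t-SNE coordinates are seed-reproducible but not comparable across
  libraries or perplexities; they are a reporting aid only.
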