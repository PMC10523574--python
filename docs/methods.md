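# Methods

## Scope

The package implements a one-round federated-distillation workflow for
binary activity classification: partner-local teachers → predictions on
a shared unlabeled pool → consolidation → reliability filtering and
decidability ranking → federated-set construction → global students →
evaluation with applicability-domain (AD) restriction. Federation is
simulated in process over partner datasets; there is no network
transport, encryption or multi-site deployment, and only a single
distillation round is modeled.

## Feature space

All models share one representation: a block of 2D physicochemical
descriptors min-max scaled to [0, 1], concatenated with a 2048-bit
Morgan fingerprint of radius 3. The descriptor list is a frozen, named
configuration (`data/descriptors-rdkit2d.txt`, 209 descriptors = the
toolkit's full 2D pool minus `Ipc`, whose unbounded magnitude overflows
on mid-size molecules). The count is asserted at load rather than
hard-coded, because the full descriptor pool varies across toolkit
versions. SMILES standardization strips salts by keeping the largest
fragment (heavy-atom count; ties broken by lexicographically smallest
canonical SMILES) and canonicalizes; charge neutralization and tautomer
handling are deliberately out of scope.

Scaling has two modes. The classic mode fits the min-max scaler on all
datasets jointly, replicating the original protocol; this is mild
information leakage from test to train, so a strict mode fits on the
labeled training sources only and clips everything else to [0, 1]. The
mode used is recorded in the run config. Constant features map to 0.

## Confidence scores

The platform that inspired this workflow computes Reliability and
Decidability with proprietary formulas; this package publishes its own
definitions, chosen for monotonicity, [0, 1] range and faithfulness to
the verbal concepts, and both are pluggable through a registry:

* decidability(p) = |2p − 1|: 0 at an equivocal prediction, 1 at a
  decisive one, symmetric about p = 0.5;
* reliability(query) = mean Tanimoto similarity between the query
  fingerprint and its k nearest training fingerprints (default k = 5,
  truncated to the reference size). Computed on the fingerprint block
  only — Tanimoto is defined on bit sets and matches the notion of
  structural feature space. Adding training molecules can never lower
  any query's reliability, which makes AD coverage monotone in the
  training-space reference.

AD membership is the conjunction reliability ≥ r_min AND decidability ≥
d_min. Both in federation and in evaluation the package thresholds
reliability only by default (d_min = 0, configurable): the platform's
published filter step names reliability alone, and with a small
decidability threshold the coverage comparisons between model variants
were decided by one or two borderline-probability molecules — model-fit
noise rather than the chemical-space growth the analysis is about.

On the scale of k-NN Tanimoto reliability, the platform's published
filter value 0.005 excludes essentially nothing; it remains the
platform-scale default of `build_federated_set`. The workflow default is
r_min = 0.08, placed between the consolidated reliability of pool
chemistry *below every* member's training space (~0.03–0.05) and
chemistry at least one member has trained on (≳ 0.15): the filter's job
is to drop molecules nobody can assess, while keeping single-member
chemistry is precisely how distillation transfers one partner's
knowledge to the rest. Evaluation-side AD uses r_min = 0.2 by default
(within-training-space chemistry scores ≳ 0.3).

## Federation

Consolidation of member predictions is a decidability-weighted majority
vote (sum of decidability over label-1 voters vs label-0 voters), with
exact ties resolved to inactive — conservative for safety screening.
Unweighted majority and mean-probability rules are available in the
registry. Consensus decidability and reliability are member means, and
the reliability filter applies to the consolidated mean, matching the
single post-consolidation filter step of the original workflow.

The federated set takes, per class, the top-N consolidated predictions
by decidability (ties broken by higher reliability, then molecule id,
for full determinism); a shortfall in one class is filled by continuing
down the other class's ranking, and if both classes are exhausted the
set is returned short with a warning. Ranking is per class, the only
reading consistent with "first N entries of each label". The selection
is verified in the tests against an independent brute-force selector
and an exchange-optimality argument.

## Synthetic world

Molecules live in a latent coordinate x ∈ R^d (d = 16): cluster-
structured Gaussian modes stand in for chemical series. Each partner
samples a cluster mixture; `partner_cluster_overlap` controls how many
clusters are shared by all partners versus dealt privately (1.0 =
identical mixtures, 0.0 = disjoint). The public set and the pool draw
from all clusters. Partner test sets are temporally newer and draw a
fraction `test_novelty` (default 0.3) from the full cluster set —
temporal validation is only meaningful if newer molecules explore new
chemistry.

The measured percent response is logistic in a latent score: response =
100·σ(g·(w·x + c_k + ε)), with a global random unit direction w,
per-cluster offsets c_k, steepness g = 1.5, and Gaussian assay noise
ε ~ N(0, assay_noise²) (default 0.4 score units). A molecule is active
when the response reaches `activity_threshold` (default 50%, the ≥50%
inhibition/binding at 10 μM convention; the boundary value counts as
active). Observed labels are additionally flipped with probability
`label_noise` (default 0.05), modeling gross errors.

Two calibrations make the generator controllable:

* the per-cluster offsets are set analytically so that P(active) is the
  same in every cluster — any cluster mixture then realizes the
  requested inactive/active ratio, using the total sd
  √(cluster_spread² + assay_noise²);
* the target fraction is corrected for the symmetric flips, so the
  requested ratio describes the *observed* dataset composition, as in
  published composition tables.

The assay-noise channel matters beyond realism: with deterministic
thresholding of a noise-free response, an ideal model's probabilities
saturate and decidability degenerates to ties at 1.0, which silently
voids the decidability-ranking mechanism the federation stage is built
on. With assay noise, P(active | x) is smooth and decidability has a
continuous, informative distribution.

Fingerprints in the abstract emission mode are cluster-structured
random bits: each cluster owns a 64-bit pool; a molecule switches each
pool bit on with probability 0.5 plus 8 background bits. Same-cluster
Tanimoto ≈ 0.2–0.5, cross-cluster ≈ 0.02–0.05 — enough contrast for
reliability to be genuinely informative. The SMILES emission mode
assembles molecules from 11 scaffold templates × 24 substituents
(every combination pre-validated), biases substituent choice by the
true label so real fingerprints also carry signal, and feeds the full
chemistry pipeline; it exists for end-to-end integration, not for
medicinal-chemistry realism.

Default scale (3 partners × 2,000 train / 600 test, public 2,000, pool
20,000, federated 500+500) is a desk-scale reduction of the original
study's magnitudes chosen so a full run completes in about a minute on
one CPU; tests and the analysis drivers use it throughout.

### What the generator does not emulate

Real SAR landscapes (activity cliffs, scaffold hopping), inter-target
correlations, realistic descriptor marginals in abstract mode, and
assay-protocol heterogeneity beyond a per-partner threshold-jitter
knob (default off). Passing tests demonstrate that the workflow's
machinery is correct and that its qualitative claims hold under
controlled conditions — not that the same effect sizes would appear on
proprietary assay data.

### Learnability limits

The per-cluster offset reaches a model only through the sampled cluster
bits, which carry irreducible per-molecule noise (~0.25 score units),
and randomly drawn cluster means can overlap; consequently even a
latent-score oracle tops out near 0.96 accuracy on multi-cluster worlds
and practical learners near 0.89. Ground-truth recovery to the
label-noise ceiling is therefore tested on a single-series world
(n_clusters = 1), where a regularized logistic learner is correctly
specified and reaches ~0.96 against a 0.93 bar. On multi-cluster desk
worlds the linear classifier (`sgd`) is the best default: the latent
boundary is logistic in a rotated direction, which tree ensembles
approximate poorly at these sample sizes — the reason the workflow's
default teacher and composition-student architecture is `sgd` rather
than a random forest (both remain configurable; the full 11-member zoo
is available and uniformly probability-emitting).

## Teachers and students

Hyperparameter optimization is a budgeted search over per-architecture
spaces (default budget 25), scored on mean stratified-5-fold balanced
accuracy; among configurations within 1e−6 of the best, the highest
mean sensitivity wins. Literal re-optimization on sensitivity alone
would collapse to always-positive classifiers, so sensitivity acts only
as this tie-break. A Bayesian engine is used when the optional backend
is importable, otherwise a seeded random search runs within the same
budget; the engine, budget and seed are recorded. CV fold assignment
depends only on (seed, n, labels, scheme), so architectures are
compared on identical folds. Minority oversampling replicates whole
rows by the largest integer factor that does not exceed the target
ratio; the majority class is untouched.

Students come in two paths. The composition path trains a configurable
base classifier on a stated union of sources — T (internal), HI
(internal + public), HF (internal + public + federated) — with
duplicates resolved internal > public > federated (experimental labels
outrank distilled ones). The pretrain/fine-tune path is a multilayer
perceptron: PI (public), F (federated), and RI/RF which continue
training on internal data with the step size reduced ×0.1; refining on
a set identical to the pretraining set is skipped as a no-op and noted
in provenance. A refined model's training-space reference is the union
of pretraining and refinement fingerprints — both shaped the final
weights, and reliability must reflect everything the model has seen.
The seven-way internal comparison variants are data compositions with
channel tags (`@ft`, `@comp`) naming which student family produced the
pool labels; single-channel runs point both at the same federated set.

## Evaluation

Sensitivity, specificity, precision, balanced accuracy (arithmetic mean
of sensitivity and specificity) and MCC, with active as the positive
class. Zero-denominator ratios are reported as NaN and propagate into
balanced accuracy; MCC returns 0 when any denominator factor vanishes
(standard convention, keeps reports total). AD-restricted evaluation
computes the confusion table on the in-domain subset only and reports
the retained fraction as `ad_coverage`. Human-readable tables round to
2 decimals; machine-readable outputs keep full precision. Chemical-
space analysis is a joint t-SNE over the shared feature space
(delegated to the standard implementation — the contribution is the
joint-embedding protocol, not the algorithm), summarized by a
nearest-neighbour overlap statistic: the fraction of set-B points whose
nearest embedded neighbour lies in set A.

## Orchestration and reproducibility

`run_experiment` executes generate → featurize → teachers → federate →
students → evaluate, persisting every artifact under the run directory.
Every tabular output begins with a `# config_hash=` comment line; a
manifest records the sha256 of each CSV/JSON/YAML artifact, and
wall-clock stage logs live in a separate file so they never perturb the
comparable outputs. All randomness derives from the single run seed
(per-partner and per-stage seeds are fixed offsets of it), so re-running
with the same config and seed reproduces every CSV byte for byte; this
is asserted in the tests. A failed stage aborts with the stage name and
persists the partial manifest. The CLI subcommands are thin wrappers
that re-run the deterministic pipeline up to the requested stage.

## Known limitations

* One distillation round; no iterative federation.
* The decidability/reliability definitions are this package's own; no
  claim is made that the platform-internal 0.005 filter operates on the
  same scale (treated as a free parameter with documented defaults).
* How label space enters the AD (beyond descriptor and structural
  space) is unspecified in the source material and not implemented.
* At desk scale the federated set (500+500) is smaller than a partner's
  internal set, the reverse of the original proportions; students
  trained on the federated set alone trail their teachers by roughly
  0.1 balanced accuracy for sample-size reasons, while students trained
  on the full distilled pool match or beat them.
* Statistical significance testing between variants is out of scope, as
  is AUC-based model selection.
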