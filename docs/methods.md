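# Methods

## The question the pipeline answers

Given a library of compounds profiled in a panel of cancer cell lines, is a
compound-induced gene-expression signature (GES) — the 978-landmark z-score
vector of an L1000-style level-5 profile at one condition (10 µM, 24 h) — a
useful descriptor for predicting activity against a molecular target, and
how does it compare with the standard chemical descriptor, a hashed binary
Morgan (ECFP-family) fingerprint?  The pipeline makes the comparison fair by
construction: for every (target, cell line) prediction task, the GES model
and the Morgan FP *counterpart* model are trained on the identical compound
set with the identical train/test partitions, so any performance difference
is attributable to the descriptor alone.

## Dataset construction

Signatures are filtered to one nominal condition — dose 10 µM, exposure
24 h, a fixed cell-line panel, compounds with known structure (operationally:
a non-empty SMILES) — and replicates of the exact same condition are
averaged elementwise, giving one signature per (compound, cell line).
Doses are compared after rounding to two significant figures in µM because
real metadata records nominally identical doses with formatting jitter;
exact float equality would split replicates.  Filtering and averaging are
both idempotent and commute, which the tests assert rather than assume.

Activity labels form a sparse ternary matrix (1 active, 0 inactive, absent
unknown).  Targets enter the benchmark with ≥ 50 known actives overall; a
(target, cell line) task is kept when its dataset — compounds with both a
signature in that cell line and a label for that target — has ≥ 20 actives.

## The benchmark protocol

Per task and per pipeline repeat (10 repeats, fresh stratified 67/33 splits
shared by the two descriptor kinds):

1. **Feature screening.** Five forests are fit on the training split, their
   impurity importances averaged per column, and the top 20 columns kept
   (ties broken by ascending column index).  Screening applies identically
   to both descriptor kinds by default (a switch disables it for
   fingerprints).
2. **Depth tuning.** Stratified 4-fold CV over the depth grid
   {5, 10, unlimited}, maximizing mean balanced accuracy; exact ties go to
   the smallest depth.  A fold whose training part is single-class triggers
   one fold re-draw, then an error.
3. **Final model.** A 200-tree random forest with
   `class_weight='balanced_subsample'` at the tuned depth, scored on the
   held-out third.

Scoring uses sensitivity TP/(TP+FN), specificity TN/(TN+FP), balanced
accuracy (their mean — exactly 0.5 for any single-class predictor), and the
Matthews correlation coefficient with the 0-on-zero-denominator convention.
Splits are stratified by class because with as few as 20 actives an
unstratified 33% test set can lack actives entirely, leaving BA undefined.

**Forest sizes.**  The 200 trees of the protocol apply to the final models.
The screening and CV forests use 25 trees each (configurable,
`n_screen_trees`): importance *ranks* and depth *ranks* stabilize with far
fewer trees than calibrated predictions need, the importance average still
pools 5 × 25 = 125 trees, and the protocol fits ~30 forests per task ×
repeat — at single-CPU tree-building cost, full-size screening forests
would dominate the entire analysis for no measurable change in which
features or depths are chosen.  The depth grid is deliberately coarse
(shallow / medium / unrestricted) for the same reason; per-task tuned depths
are recorded in the provenance output.

All randomness derives from one master seed via fixed stage labels
(CRC-based child seeds < 2³¹), so the whole pipeline is reproducible from a
single integer and regenerating one stage never perturbs another.

## Distance kernels and quadrant diagnostics

Chemical similarity is Dice distance 1 − 2|A∩B|/(|A|+|B|) on fingerprints
(range [0, 1]); biological similarity is cosine distance 1 − x·y/(‖x‖‖y‖)
on signatures (range [0, 2] for signed z-vectors).  Dice distance is not a
metric (no triangle inequality) and nothing here assumes it is.  Two
all-zero fingerprints get distance 0, empty-versus-nonempty gets 1 (both
logged); a zero-norm signature is an error.

For one (target, cell line), every unordered pair of actives (optionally,
of all annotated compounds — pairs mixing an active with an inactive are
included, controlled by the population flag) is placed at (Dice, cosine)
and assigned to a quadrant split at 0.5/0.5: I different/different, II
similar structures only, III similar/similar, IV similar signatures only.
A distance of exactly 0.5 counts as "different" on its axis; the boundary
has probability zero under continuous descriptors, but a fixed convention
keeps the assignment total and deterministic.  Quadrant III+IV mass
(signature-similar pairs) should anticipate GES-model performance, II+III
mass fingerprint-model performance; `performance_association` reports the
top-k means and the Spearman correlation of III+IV mass with GES mean BA.

## The synthetic world

The generator reproduces the statistical structure the analysis consumes,
not the underlying chemistry or biology:

* **Fingerprints** come from a scaffold/bit-flip model: each scaffold is a
  base pattern (8 core bits shared by all scaffolds + scaffold-specific bits
  to 5% density of the 1024-bit vector), and a compound flips each bit
  independently with probability 0.02.  This yields tight within-scaffold
  Dice distances (closed-form expectation asserted in tests) against a
  diffuse background with mean pairwise Dice ≈ 0.82, the level reported for
  large screening libraries.  SMILES fields are placeholders; no molecular
  structures are simulated.
* **Signatures**: per cell line, 5 cluster prototypes (large screens show
  4–5 main GES clusters per cell line) with unit-variance isotropic noise;
  pairwise cosine distances are ≈ 0.5 within and ≈ 1.0 across clusters,
  giving background active-pair means of ≈ 0.9 — the level observed for
  targets without a conserved response.
* **Responsive actives** follow a two-component responder mixture: a
  fraction w of a target's actives draw tightly (calibrated pair distance
  0.35) around a (target, cell line) prototype, the rest stay
  background-like.  w is solved from the pair-mixture quadratic so that the
  realized mean pairwise cosine distance among actives hits the configured
  `active_cosine_target` (tolerance ±0.05; component noise scales are
  root-found against Monte-Carlo estimates over fixed noise draws, which
  makes the objective deterministic and smooth).  A single-component model
  was rejected: it concentrates pair distances so tightly that no pairs
  would fall below the 0.5 quadrant threshold at any mean distance above
  0.5, contradicting the 26–40% quadrant III+IV mass reported for
  conserved-response targets.  The mixture reproduces the mean-distance
  bands and the quadrant mass simultaneously.
* **Activity**: per target, a fixed active count (active fraction within
  the reported 1–63% range); chemically coherent targets place most actives
  (default 95%) in a few host scaffolds.  All active labels are observed;
  inactive labels are observed with probability `observed_fraction`
  (default 0.05, the reported sparsity of public activity annotations).

Named scenarios (2000 compounds unless noted, cell lines being the three
case-study lines A549/MCF7/PC3):

| scenario | chemistry | response | emulated bands |
|---|---|---|---|
| `nr3c1_like` | coherent (2 host scaffolds) | responsive in A549, PC3; not MCF7 | active cosine ≈ 0.76 responsive, ≈ 0.9 elsewhere |
| `tubb_like` | diffuse | responsive everywhere | active cosine calibrated to 0.68 (band 0.61–0.75) |
| `drd1_like` | diffuse but learnable (70% of actives over 12 of 40 scaffolds) | responsive nowhere | active Dice ≈ 0.81, cosine ≈ 0.89 |
| `mixed` | 12 responsive-diffuse targets with cosine targets swept 0.55–0.85 + 8 silent-coherent targets | — | 500 compounds, 1 cell line |

`drd1_like` keeps moderate scaffold concentration deliberately: real
aminergic-receptor ligand sets support above-chance fingerprint models even
at mean pairwise Dice ≈ 0.8, and a purely structureless library would make
the fingerprint arm exactly random — a regime the comparison never faces in
practice.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real chemistry (fingerprint bits are exchangeable
here; real bit semantics, molecular weight gradients and activity cliffs
are absent), dose–response and time structure (a single nominal condition,
with optional off-condition decoy rows only for exercising the filter),
replicate-level noise before averaging, correlated multi-target pharmacology
(actives are drawn per target; a compound active on several responsive
targets responds to the first), and inter-cell-line correlation of
responses (target prototypes are drawn independently per cell line).
Absolute balanced accuracies on synthetic worlds therefore do not transfer
to real data; the recovered *contrasts* between regimes are the tested
claim.

## Study problem sizes

The packaged studies run at: three-regime recovery — 2000 compounds, 10
pipeline repeats, 3 generator seeds per scenario; permuted-label null
control — 10 seeds × 10 repeats on a 400-compound dense-label world with
reduced dimensionality (120 genes, 128 bits; label permutation destroys
feature/label coupling at any dimensionality); mixed association — 20
targets × 500 compounds, 10 repeats.  These sizes put ≈ 30–60 compounds of
each class in every test split, which bounds the per-repeat BA standard
error near 0.04 — small against the ≥ 0.1 regime contrasts being measured.

## Known limitations

* Fingerprint parameters (radius 2, 2048 bits in real mode) are the common
  ECFP4-equivalent defaults; the published analysis never states its
  parameterization, so real-data results cannot be pinned to one.
* The depth grid, CV selection metric and split stratification are likewise
  unstated in the published protocol; our choices (coarse grid, balanced
  accuracy, stratified splits) are recorded in provenance output.
* t-SNE coordinates are stochastic-neighbor layouts over precomputed
  distances (perplexity 30 by default); only within-run relational
  properties (cluster preservation) are asserted, never absolute positions.
* The quadrant diagnostic is descriptive; no statistical test is attached
  to quadrant counts.
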