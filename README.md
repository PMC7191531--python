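# gesbench

Can a compound's induced **gene-expression signature** (GES) — the
978-landmark z-score profile it produces in a treated cancer cell line —
serve as a descriptor for predicting its activity against molecular
targets, and when does it beat the standard chemical descriptor, a binary
**Morgan fingerprint**?  `gesbench` implements the full comparison pipeline
for computational chemists and chemical biologists working with
L1000-style perturbation profiles and sparse public bioactivity labels.

## What it computes

* **Dataset construction** — level-5-style landmark signatures filtered to
  one condition (10 µM / 24 h, fixed cell-line panel, known-structure
  compounds), replicates averaged to one signature per (compound, cell
  line); sparse ternary activity labels (1/0/unknown).
* **Descriptors and kernels** — hashed binary Morgan fingerprints (RDKit;
  radius 2, 2048 bits by default) with Dice distance
  d(A,B) = 1 − 2|A∩B|/(|A|+|B|), and cosine distance
  1 − x·y/(‖x‖‖y‖) on signatures.
* **Paired benchmark** — per (target, cell line) task (targets with ≥ 50
  actives, datasets with ≥ 20), a GES random-forest model and its Morgan FP
  *counterpart* trained on the identical compounds and splits: 10 repeats of
  stratified 67/33 split → repeated-importance top-20 feature selection →
  4-fold CV depth tuning → 200-tree class-weight-balanced forest, scored by
  sensitivity, specificity, balanced accuracy BA = (Se + Sp)/2 and MCC.
* **Quadrant diagnostics** — every active pair plotted at (Dice, cosine)
  and assigned to quadrants split at 0.5/0.5; quadrant III+IV mass (pairs
  with similar signatures) is the leading indicator of GES-model success,
  II+III of fingerprint-model success.
* **Space maps** — t-SNE embeddings of chemical space (Dice) and of each
  cell line's biological space (cosine), with activity annotation.
* **Synthetic worlds** — a calibrated generator (scaffold/bit-flip
  chemistry, cluster-structured signature spaces, responder mixtures with
  tunable within-target similarity) so the entire analysis runs and is
  tested at desk scale without the multi-GB public downloads; real data in
  the same TSV layouts drops in unchanged.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Generate the "conserved response" scenario — a chemically diverse target
whose actives share signatures in every cell line — and benchmark it:

```python
from gesbench import experiments, synthgen

world = synthgen.make_scenario("tubb_like", seed=11)
pairs, results = experiments.benchmark_world(world, model_seed=123)
for r in sorted(results, key=lambda r: (r.cell_line, r.descriptor_kind)):
    print(r.cell_line, r.descriptor_kind, round(r.mean_ba, 3))
```

```
A549 GES 0.821
A549 MorganFP 0.488
MCF7 GES 0.829
MCF7 MorganFP 0.471
```

The signature models sit above 0.8 balanced accuracy in both cell lines
while the fingerprint counterparts are at chance — exactly the regime where
transcriptomic descriptors escape the applicability-domain limits of QSAR:
the actives share no learnable chemistry, but their induced response is
conserved.  The mirror regime (`nr3c1_like`: coherent chemistry, response
conserved only in some cell lines) flips the picture, and `drd1_like`
(diffuse in both spaces) gives neither descriptor an edge.

The numbered drivers under `analysis/` run the full studies and write their
tables under `results/`:

```bash
python analysis/01_simulate_worlds.py      # worlds + calibration readout
python analysis/02_benchmark_regimes.py    # three-regime benchmark (longest step)
python analysis/03_quadrant_diagnostics.py # quadrant percentages per cell line
python analysis/04_mixed_association.py    # quadrant mass vs performance, 20 targets
python analysis/05_space_embeddings.py     # t-SNE coordinate tables
```

A `gesbench` CLI wraps the same stages for on-disk data
(`gesbench simulate|prepare|benchmark|quadrants|embed|run-all --help`).

## Real data

Place level-5 landmark signatures and metadata (`signatures.tsv`,
`sigmeta.tsv`), compounds (`compounds.tsv`), and an activity matrix
(`activity.tsv`) under `data/real/` in the documented TSV layouts (see
`gesbench.sigio`), then use `gesbench prepare` / `run-all`.  An
accession-conditional test in `tests/test_acceptance.py` validates the
dataset-construction counts when such data is present; it is skipped
otherwise, since the public source is a multi-GB download that cannot be
redistributed here.
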