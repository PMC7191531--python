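"""Pre-packaged study runs at the conditions of the headline analyses.

Each function here regenerates its inputs from the synthetic-world
generator, executes the relevant pipeline stages, and returns the measured
quantities.  The same entry points back the analysis scripts, the test
suite and ``scripts/acceptance.py``, so every reported number is recomputed
from scratch wherever it is asked for.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd

from ._util import child_seed, rng_for
from . import quadrant, synthgen, taskbench
from .sigio import ActivityMatrix
from .synthgen import ScenarioConfig, SyntheticWorld, TargetSpec
from .taskbench import GES, MORGAN_FP, ModelConfig

__all__ = [
    "brute_force_metrics",
    "metrics_formula_check",
    "benchmark_world",
    "null_control",
    "regime_recovery",
    "mixed_association",
    "candidate_model_grid",
]


# ---------------------------------------------------------------------------
# metric formulas against an enumeration oracle


def brute_force_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Independent re-derivation of the four statistics by explicit
    enumeration over prediction/truth pairs, in exact rational arithmetic."""
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    sens = Fraction(tp, tp + fn) if tp + fn else Fraction(0)
    spec = Fraction(tn, tn + fp) if tn + fp else Fraction(0)
    # the two rates are exact rationals; their mean is taken in double
    # precision (the representable value of each rate, averaged), which is
    # the number any implementation of the printed formula produces
    ba = (float(sens) + float(spec)) / 2.0
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom2) if denom2 else 0.0
    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "sensitivity": float(sens),
        "specificity": float(spec),
        "balanced_accuracy": ba,
        "mcc": float(mcc),
    }


def metrics_formula_check(n_matrices: int = 100, seed: int = 0) -> dict:
    """Compare :func:`gesbench.taskbench.evaluate` with the enumeration
    oracle on randomized confusion settings; returns the match count and the
    largest absolute discrepancy over all statistics."""
    rng = rng_for(seed, "metrics-check")
    n_exact = 0
    max_diff = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(2, 200))
        y_true = rng.integers(0, 2, size=n)
        y_pred = rng.integers(0, 2, size=n)
        got = taskbench.evaluate(y_true, y_pred)
        want = brute_force_metrics(y_true, y_pred)
        diffs = [
            abs(got.sensitivity - want["sensitivity"]),
            abs(got.specificity - want["specificity"]),
            abs(got.balanced_accuracy - want["balanced_accuracy"]),
            abs(got.mcc - want["mcc"]),
        ]
        counts_match = (got.tp, got.tn, got.fp, got.fn) == (
            want["tp"],
            want["tn"],
            want["fp"],
            want["fn"],
        )
        if counts_match and max(diffs) == 0.0:
            n_exact += 1
        max_diff = max(max_diff, max(diffs))
    return {"n": n_matrices, "n_exact": n_exact, "max_abs_diff": max_diff}


# ---------------------------------------------------------------------------
# benchmark runners


def benchmark_world(
    world: SyntheticWorld, model_seed: int, **config_overrides
) -> tuple[list[taskbench.TaskPair], list[taskbench.BenchmarkResult]]:
    """Task construction plus the repeated benchmark for one world."""
    admitted = taskbench.admit_targets(world.activity)
    pairs = taskbench.build_tasks(
        world.signatures, world.compounds, world.activity, admitted
    )
    cfg = ModelConfig(seed=model_seed, **config_overrides)
    return pairs, taskbench.run_benchmark(pairs, cfg)


def _null_world(seed: int) -> SyntheticWorld:
    """A small dense-label world used for the permuted-label control.

    Dimensions are reduced (120 genes, 128 bits) — label permutation
    destroys any feature/label coupling regardless of dimensionality, and
    the control needs many independent seeds."""
    cfg = ScenarioConfig(
        n_compounds=400,
        n_genes=120,
        bit_length=128,
        cell_lines=("A549",),
        n_scaffolds=10,
        observed_fraction=1.0,
        targets=(
            TargetSpec(
                target_id="NULL",
                active_fraction=0.30,
                responsive_cell_lines=("A549",),
                active_cosine_target=0.6,
            ),
        ),
        seed=seed,
    )
    return synthgen.make_world(cfg)


def null_control(n_seeds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean BA of the full pipeline on permuted-label tasks.

    For each seed, the world's single task has its labels randomly permuted
    (the identical permutation for both descriptor kinds) before the
    10-repeat protocol runs.  Returns one row per (seed, descriptor kind).
    """
    rows = []
    for s in range(n_seeds):
        world = _null_world(child_seed(seed, "null-world", s))
        admitted = taskbench.admit_targets(world.activity)
        pairs = taskbench.build_tasks(
            world.signatures, world.compounds, world.activity, admitted
        )
        perm = rng_for(seed, "null-perm", s).permutation(len(pairs[0].ges.y))
        for task in (pairs[0].ges, pairs[0].fp):
            task.y = task.y[perm]
        results = taskbench.run_benchmark(
            pairs, ModelConfig(seed=child_seed(seed, "null-model", s))
        )
        for res in results:
            rows.append(
                {
                    "seed_index": s,
                    "descriptor_kind": res.descriptor_kind,
                    "mean_ba": res.mean_ba,
                }
            )
    return pd.DataFrame(rows)


def regime_recovery(
    seed: int = 0, n_seeds: int = 3, n_compounds: int = 2000
) -> dict:
    """The three-regime recovery study on the named scenarios.

    Runs each preset at ``n_seeds`` generator seeds, pools the per-cell-line
    mean balanced accuracies over seeds, and derives the regime statistics:

    * ``nr3c1_fp_min_ba`` — worst-cell-line FP performance on the
      chemically coherent target (should be high everywhere);
    * ``nr3c1_ges_gap`` — GES performance in responsive minus
      non-responsive cell lines (cell-context effect);
    * ``tubb_ges_min_ba`` — worst-cell-line GES performance on the
      everywhere-responsive target;
    * ``drd1_ges_minus_fp`` — GES minus FP on the doubly diffuse target
      (neither descriptor should have an edge).
    """
    tables = {}
    for preset in ("nr3c1_like", "tubb_like", "drd1_like"):
        rows = []
        for s in range(n_seeds):
            world = synthgen.make_scenario(
                preset, child_seed(seed, preset, "world", s), n_compounds=n_compounds
            )
            _, results = benchmark_world(world, child_seed(seed, preset, "model", s))
            responsive = set(
                world.config.targets[0].responsive_cell_lines
            )
            for res in results:
                rows.append(
                    {
                        "preset": preset,
                        "seed_index": s,
                        "cell_line": res.cell_line,
                        "descriptor_kind": res.descriptor_kind,
                        "mean_ba": res.mean_ba,
                        "responsive": res.cell_line in responsive,
                    }
                )
        tables[preset] = pd.DataFrame(rows)

    def pooled(df: pd.DataFrame, kind: str) -> pd.Series:
        sub = df[df["descriptor_kind"] == kind]
        return sub.groupby("cell_line")["mean_ba"].mean()

    nr = tables["nr3c1_like"]
    nr_ges = nr[nr["descriptor_kind"] == GES]
    gap = (
        nr_ges[nr_ges["responsive"]]["mean_ba"].mean()
        - nr_ges[~nr_ges["responsive"]]["mean_ba"].mean()
    )
    dr = tables["drd1_like"]
    stats = {
        "nr3c1_fp_min_ba": float(pooled(nr, MORGAN_FP).min()),
        "nr3c1_ges_responsive_ba": float(nr_ges[nr_ges["responsive"]]["mean_ba"].mean()),
        "nr3c1_ges_nonresponsive_ba": float(nr_ges[~nr_ges["responsive"]]["mean_ba"].mean()),
        "nr3c1_ges_gap": float(gap),
        "tubb_ges_min_ba": float(pooled(tables["tubb_like"], GES).min()),
        "tubb_fp_mean_ba": float(pooled(tables["tubb_like"], MORGAN_FP).mean()),
        "drd1_ges_mean_ba": float(dr[dr["descriptor_kind"] == GES]["mean_ba"].mean()),
        "drd1_fp_mean_ba": float(dr[dr["descriptor_kind"] == MORGAN_FP]["mean_ba"].mean()),
    }
    stats["drd1_ges_minus_fp"] = stats["drd1_ges_mean_ba"] - stats["drd1_fp_mean_ba"]
    return {"stats": stats, "tables": tables}


def mixed_association(seed: int = 0) -> dict:
    """Quadrant-mass versus model-performance association on the mixed world.

    Benchmarks all 20 targets, builds actives-only quadrant summaries per
    task, and reports the Spearman correlation between quadrant III+IV
    percentage and GES mean BA, the top-model quadrant means, and the
    descriptor comparison (fraction of tasks where GES wins, versus the
    fraction of tasks generated as responsive).
    """
    world = synthgen.make_scenario("mixed", child_seed(seed, "mixed", "world"))
    pairs, results = benchmark_world(world, child_seed(seed, "mixed", "model"))
    summaries = [
        quadrant.summarize(
            quadrant.pair_table(
                t, c, "actives_only", world.signatures, world.compounds, world.activity
            ),
            "actives_only",
        )
        for (t, c) in (p.key for p in pairs)
    ]
    association = quadrant.performance_association(summaries, results, top_k=5)
    comparison = taskbench.compare_descriptors(results)
    responsive_fraction = float(
        np.mean(
            [
                len(world.truth["targets"][p.key[0]]["responsive_cell_lines"]) > 0
                for p in pairs
            ]
        )
    )
    return {
        "world": world,
        "pairs": pairs,
        "results": results,
        "summaries": summaries,
        "association": association,
        "comparison": comparison,
        "responsive_fraction": responsive_fraction,
        "spearman": association["spearman_q3q4_vs_ba_ges"],
    }


# ---------------------------------------------------------------------------
# task-admission arithmetic


def candidate_model_grid(
    n_targets: int = 69, n_cell_lines: int = 8, min_actives_total: int = 50
) -> dict:
    """Candidate model count before the per-dataset activity filter.

    Builds an activity matrix with ``n_targets`` targets at exactly the
    admission threshold (plus one below-threshold decoy target), runs the
    admission rule, and multiplies out the candidate grid: admitted targets
    × cell lines × two descriptor kinds.
    """
    compounds = [f"c{i:03d}" for i in range(min_actives_total + 10)]
    triplets = []
    for t in range(n_targets):
        for cid in compounds[:min_actives_total]:
            triplets.append((cid, f"T{t:03d}", 1))
        triplets.append((compounds[-1], f"T{t:03d}", 0))
    for cid in compounds[: min_actives_total - 1]:  # one target just below threshold
        triplets.append((cid, "T_below", 1))
    activity = ActivityMatrix(triplets)
    admitted = taskbench.admit_targets(activity, min_actives_total)
    n_combinations = len(admitted) * n_cell_lines
    return {
        "n_admitted_targets": len(admitted),
        "n_candidate_combinations": n_combinations,
        "n_candidate_models": 2 * n_combinations,
    }
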