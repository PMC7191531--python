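"""Per-(target, cell line) datasets and the paired random-forest benchmark.

For every admitted target (≥50 known actives overall) and cell line, the
rows are the compounds that both have an averaged signature in that cell
line and a known label for the target.  Two *counterpart* models are built
over the identical rows — one on the 978 z-scores (GES model), one on the
fingerprint bits (Morgan FP model) — so any performance difference is
attributable to the descriptor, not the compound set.

Protocol per task and repeat (the whole pipeline is repeated
``n_pipeline_repeats`` times with fresh stratified 67/33 splits shared by
the two descriptor kinds):

1. feature screening — ``n_importance_repeats`` forests on the training
   split; impurity importances averaged per column; top
   ``n_selected_features`` kept (ties broken by ascending column index);
2. depth tuning — stratified 4-fold CV over ``depth_grid`` on the selected
   columns, maximizing mean balanced accuracy, ties to the smallest depth;
3. final model — a 200-tree forest with ``class_weight='balanced_subsample'``
   at the tuned depth, scored on the held-out third.

Screening and CV forests use a reduced tree count (``n_screen_trees``):
importance ranks and depth ranks stabilize with far fewer trees than the
final model needs, and the protocol fits hundreds of forests per task.

Evaluation uses the confusion-matrix statistics sensitivity TP/(TP+FN),
specificity TN/(TN+FP), balanced accuracy (their mean) and the Matthews
correlation coefficient, with MCC defined as 0 when its denominator
vanishes (the uninformative-predictor convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._util import child_seed
from .sigio import ActivityMatrix, CompoundRecord, SignatureRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TaskDataset",
    "TaskPair",
    "ModelConfig",
    "Metrics",
    "BenchmarkResult",
    "ComparisonReport",
    "admit_targets",
    "build_tasks",
    "split_train_test",
    "select_features",
    "tune_depth",
    "evaluate",
    "run_benchmark",
    "compare_descriptors",
    "results_table",
]

GES = "GES"
MORGAN_FP = "MorganFP"


@dataclass
class TaskDataset:
    """Descriptor matrix and labels for one (target, cell line, kind) task."""

    target_id: str
    cell_line: str
    descriptor_kind: str  # GES or MorganFP
    X: np.ndarray
    y: np.ndarray
    compound_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.size or self.X.shape[0] != len(self.compound_ids):
            raise ValueError("X, y and compound_ids must have matching row counts")

    @property
    def key(self) -> tuple[str, str]:
        return (self.target_id, self.cell_line)


@dataclass
class TaskPair:
    """Counterpart GES / Morgan FP datasets over the identical compound set."""

    ges: TaskDataset
    fp: TaskDataset

    def __post_init__(self) -> None:
        if self.ges.compound_ids != self.fp.compound_ids:
            raise ValueError("counterpart datasets must share the identical compound set")

    @property
    def key(self) -> tuple[str, str]:
        return self.ges.key


@dataclass(frozen=True)
class ModelConfig:
    """Benchmark protocol parameters (defaults follow the study protocol)."""

    n_trees: int = 200
    n_cv_folds: int = 4
    depth_grid: tuple[int | None, ...] = (5, 10, None)
    n_importance_repeats: int = 5
    n_selected_features: int = 20
    n_pipeline_repeats: int = 10
    train_fraction: float = 0.67
    n_screen_trees: int = 25  # forests used for screening/tuning only
    select_features_for_fp: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_trees",
            "n_cv_folds",
            "n_importance_repeats",
            "n_selected_features",
            "n_pipeline_repeats",
            "n_screen_trees",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not self.depth_grid:
            raise ValueError("depth_grid must not be empty")


@dataclass(frozen=True)
class Metrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    mcc: float


@dataclass
class BenchmarkResult:
    target_id: str
    cell_line: str
    descriptor_kind: str
    per_repeat: list[Metrics]
    depths: list[int | None]
    selected_features: list[list[int]]

    @property
    def mean_ba(self) -> float:
        return float(np.mean([m.balanced_accuracy for m in self.per_repeat]))

    @property
    def std_ba(self) -> float:
        return float(np.std([m.balanced_accuracy for m in self.per_repeat]))

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([m.mcc for m in self.per_repeat]))

    @property
    def key(self) -> tuple[str, str]:
        return (self.target_id, self.cell_line)


# ---------------------------------------------------------------------------
# dataset construction


def admit_targets(activity: ActivityMatrix, min_actives_total: int = 50) -> list[str]:
    """Targets with at least ``min_actives_total`` known actives overall."""
    return [t for t in activity.targets() if activity.n_actives(t) >= min_actives_total]


def build_tasks(
    signatures: Sequence[SignatureRecord],
    compounds: Sequence[CompoundRecord],
    activity: ActivityMatrix,
    admitted_targets: Iterable[str],
    min_actives_per_dataset: int = 20,
) -> list[TaskPair]:
    """Assemble counterpart task pairs for every (target, cell line).

    Expects one (averaged) signature per compound × cell line.  A pair is
    kept when it has at least ``min_actives_per_dataset`` actives and at
    least one inactive.  The number of candidate versus admitted
    combinations is logged.
    """
    fp_of = {c.compound_id: c.fingerprint for c in compounds if c.fingerprint is not None}
    by_cell: dict[str, dict[str, np.ndarray]] = {}
    for rec in signatures:
        cell_map = by_cell.setdefault(rec.cell_line, {})
        if rec.compound_id in cell_map:
            raise ValueError(
                f"multiple signatures for compound {rec.compound_id} in cell line "
                f"{rec.cell_line}; average replicates first"
            )
        cell_map[rec.compound_id] = rec.z

    admitted = list(admitted_targets)
    cells = sorted(by_cell)
    n_candidates = len(admitted) * len(cells)
    pairs: list[TaskPair] = []
    for target in admitted:
        labels = activity.labels_for(target)
        for cell in cells:
            cell_map = by_cell[cell]
            ids = [cid for cid in labels.index if cid in cell_map and cid in fp_of]
            if not ids:
                continue
            y = labels.loc[ids].to_numpy(dtype=int)
            if y.sum() < min_actives_per_dataset or (y == 0).sum() < 1:
                continue
            Xg = np.vstack([cell_map[cid] for cid in ids])
            Xf = np.vstack([fp_of[cid] for cid in ids]).astype(np.float64)
            pairs.append(
                TaskPair(
                    ges=TaskDataset(target, cell, GES, Xg, y, ids),
                    fp=TaskDataset(target, cell, MORGAN_FP, Xf, y, ids),
                )
            )
    logger.info(
        "build_tasks: %d of %d candidate (target, cell line) combinations admitted "
        "(%d candidate models before the %d-active filter)",
        len(pairs),
        n_candidates,
        2 * n_candidates,
        min_actives_per_dataset,
    )
    return pairs


# ---------------------------------------------------------------------------
# modeling steps


def split_train_test(
    n_rows: int, y: np.ndarray, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified-by-class random row split, returned as index arrays.

    Index-based so the identical partition can be applied to both members
    of a counterpart pair.
    """
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("class too small to split")
    idx = np.arange(n_rows)
    train, test = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed
    )
    return np.sort(train), np.sort(test)


def _forest(cfg: ModelConfig, seed: int, depth: int | None = None, n_trees: int | None = None):
    return RandomForestClassifier(
        n_estimators=n_trees if n_trees is not None else cfg.n_trees,
        max_depth=depth,
        class_weight="balanced_subsample",
        n_jobs=1,
        random_state=seed,
    )


def select_features(
    X: np.ndarray, y: np.ndarray, cfg: ModelConfig, seed: int
) -> np.ndarray:
    """Top-k columns by impurity importance averaged over repeated forests.

    Ties at the cut are broken by ascending column index (stable sort), so
    the selection is deterministic.  If the matrix has no more columns than
    the requested k, all columns pass through.
    """
    n_cols = X.shape[1]
    if n_cols <= cfg.n_selected_features:
        logger.info("select_features: only %d columns, keeping all", n_cols)
        return np.arange(n_cols)
    importances = np.zeros(n_cols)
    for r in range(cfg.n_importance_repeats):
        forest = _forest(cfg, child_seed(seed, "importance", r), n_trees=cfg.n_screen_trees)
        forest.fit(X, y)
        importances += forest.feature_importances_
    importances /= cfg.n_importance_repeats
    order = np.argsort(-importances, kind="stable")
    return np.sort(order[: cfg.n_selected_features])


def tune_depth(X: np.ndarray, y: np.ndarray, cfg: ModelConfig, seed: int) -> int | None:
    """Maximum tree depth chosen by stratified k-fold CV on balanced accuracy.

    The grid is scanned in its given order; exact ties go to the earliest
    (smallest) entry.  A fold whose training part is single-class triggers
    one re-draw of the folds, then an error.
    """
    if len(cfg.depth_grid) == 1:
        return cfg.depth_grid[0]

    def make_folds(fold_seed: int):
        skf = StratifiedKFold(n_splits=cfg.n_cv_folds, shuffle=True, random_state=fold_seed)
        folds = list(skf.split(X, y))
        ok = all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2 for tr, te in folds
        )
        return folds, ok

    folds, ok = make_folds(child_seed(seed, "folds"))
    if not ok:
        folds, ok = make_folds(child_seed(seed, "folds-redraw"))
        if not ok:
            raise ValueError("CV fold with a single class after re-draw")

    mean_bas = []
    for d_i, depth in enumerate(cfg.depth_grid):
        bas = []
        for f_i, (tr, te) in enumerate(folds):
            forest = _forest(
                cfg,
                child_seed(seed, "cv", d_i, f_i),
                depth=depth,
                n_trees=cfg.n_screen_trees,
            )
            forest.fit(X[tr], y[tr])
            bas.append(evaluate(y[te], forest.predict(X[te])).balanced_accuracy)
        mean_bas.append(float(np.mean(bas)))
    return cfg.depth_grid[int(np.argmax(mean_bas))]


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Confusion counts and the four derived statistics for binary labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty test set")
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/truth length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ba = (sens + spec) / 2.0
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return Metrics(tp, tn, fp, fn, sens, spec, ba, mcc)


# ---------------------------------------------------------------------------
# the benchmark loop


def _run_single(
    task: TaskDataset, train: np.ndarray, test: np.ndarray, cfg: ModelConfig, seed: int
) -> tuple[Metrics, int | None, list[int]]:
    Xtr, ytr = task.X[train], task.y[train]
    if task.descriptor_kind == MORGAN_FP and not cfg.select_features_for_fp:
        cols = np.arange(task.X.shape[1])
    else:
        cols = select_features(Xtr, ytr, cfg, child_seed(seed, "select"))
    Xtr_sel = Xtr[:, cols]
    depth = tune_depth(Xtr_sel, ytr, cfg, child_seed(seed, "tune"))
    final = _forest(cfg, child_seed(seed, "final"), depth=depth)
    final.fit(Xtr_sel, ytr)
    pred = final.predict(task.X[test][:, cols])
    return evaluate(task.y[test], pred), depth, cols.tolist()


def run_benchmark(
    task_pairs: Sequence[TaskPair], cfg: ModelConfig | None = None
) -> list[BenchmarkResult]:
    """Run the full repeated protocol on every counterpart pair.

    Within one repeat the GES and FP models share the identical train/test
    row partition.  Per-task failures are logged and skipped; the batch
    never aborts.
    """
    cfg = cfg or ModelConfig()
    cfg.validate()
    results: dict[tuple[str, str, str], BenchmarkResult] = {}
    for pair in task_pairs:
        target, cell = pair.key
        try:
            per_kind = {
                k: BenchmarkResult(target, cell, k, [], [], [])
                for k in (GES, MORGAN_FP)
            }
            for rep in range(cfg.n_pipeline_repeats):
                rep_seed = child_seed(cfg.seed, target, cell, rep)
                train, test = split_train_test(
                    len(pair.ges.compound_ids),
                    pair.ges.y,
                    cfg.train_fraction,
                    rep_seed,
                )
                for task in (pair.ges, pair.fp):
                    m, depth, cols = _run_single(
                        task, train, test, cfg, child_seed(rep_seed, task.descriptor_kind)
                    )
                    res = per_kind[task.descriptor_kind]
                    res.per_repeat.append(m)
                    res.depths.append(depth)
                    res.selected_features.append(cols)
            for res in per_kind.values():
                results[(target, cell, res.descriptor_kind)] = res
        except ValueError as exc:
            logger.warning("task (%s, %s) skipped: %s", target, cell, exc)
    return list(results.values())


# ---------------------------------------------------------------------------
# reporting


def results_table(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Per-repeat metrics as a flat table (one row per task × kind × repeat)."""
    rows = []
    for res in results:
        for rep, m in enumerate(res.per_repeat):
            rows.append(
                {
                    "target_id": res.target_id,
                    "cell_line": res.cell_line,
                    "descriptor_kind": res.descriptor_kind,
                    "repeat": rep,
                    "tp": m.tp,
                    "tn": m.tn,
                    "fp": m.fp,
                    "fn": m.fn,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "balanced_accuracy": m.balanced_accuracy,
                    "mcc": m.mcc,
                    "depth": res.depths[rep],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Paired GES-versus-fingerprint summary across tasks."""

    table: pd.DataFrame  # one row per (target, cell line)
    fraction_ges_wins: float  # ΔBA = BA_GES − BA_FP ≥ 0
    n_models_ba_gt_07: int  # models (both kinds) with mean BA > 0.7
    n_models_ba_gt_08: int


def compare_descriptors(results: Sequence[BenchmarkResult]) -> ComparisonReport:
    """ΔBA per (target, cell line) plus the global headline counts."""
    by_key: dict[tuple[str, str], dict[str, BenchmarkResult]] = {}
    for res in results:
        by_key.setdefault(res.key, {})[res.descriptor_kind] = res
    rows = []
    for (target, cell), kinds in sorted(by_key.items()):
        if GES not in kinds or MORGAN_FP not in kinds:
            logger.warning("unpaired task (%s, %s) excluded from comparison", target, cell)
            continue
        ba_g, ba_f = kinds[GES].mean_ba, kinds[MORGAN_FP].mean_ba
        rows.append(
            {
                "target_id": target,
                "cell_line": cell,
                "ba_ges": ba_g,
                "ba_fp": ba_f,
                "delta_ba": ba_g - ba_f,
                "mcc_ges": kinds[GES].mean_mcc,
                "mcc_fp": kinds[MORGAN_FP].mean_mcc,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        frac = float((table["delta_ba"] >= 0).mean())
        all_bas = table[["ba_ges", "ba_fp"]].to_numpy().ravel()
        n07 = int((all_bas > 0.7).sum())
        n08 = int((all_bas > 0.8).sum())
    else:
        frac, n07, n08 = float("nan"), 0, 0
    return ComparisonReport(table, frac, n07, n08)
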