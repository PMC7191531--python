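"""Distance-plot quadrant diagnostics.

For one (target, cell line), every unordered pair of active compounds (or
of all annotated compounds) is placed in the plane spanned by the Dice
distance between their fingerprints (x) and the cosine distance between
their signatures in that cell line (y).  Both axes are split at 0.5:

* quadrant I  — different structures, different signatures (x ≥ 0.5, y ≥ 0.5);
* quadrant II — similar structures only (x < 0.5, y ≥ 0.5);
* quadrant III — similar structures and similar signatures (x < 0.5, y < 0.5);
* quadrant IV — similar signatures only (x ≥ 0.5, y < 0.5).

A distance of exactly 0.5 counts as "different" (the quadrant-I side of its
axis); the 0.5 boundary has probability zero under continuous descriptors
but the convention keeps the assignment total and deterministic.

High quadrant III+IV mass (pairs with similar signatures) anticipates good
signature-based models; high II+III mass anticipates good fingerprint
models.  :func:`performance_association` quantifies both readings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .chemdesc import pairwise_distances
from .sigio import ActivityMatrix, CompoundRecord, SignatureRecord
from .taskbench import GES, MORGAN_FP, BenchmarkResult

logger = logging.getLogger(__name__)

__all__ = [
    "QuadrantSummary",
    "assign_quadrant",
    "pair_table",
    "summarize",
    "performance_association",
    "summaries_table",
]

QUADRANTS = ("I", "II", "III", "IV")


@dataclass
class QuadrantSummary:
    target_id: str
    cell_line: str
    population: str  # "actives_only" or "all_annotated"
    n_pairs: int
    counts: dict[str, int]
    percentages: dict[str, float]  # of n_pairs; nan when n_pairs == 0
    mean_dice: float
    mean_cosine: float


def assign_quadrant(dice: float, cosine: float) -> str:
    """Quadrant label for one pair; boundary 0.5 counts as 'different'."""
    if not 0.0 <= dice <= 1.0:
        raise ValueError(f"Dice distance out of [0,1]: {dice}")
    if not 0.0 <= cosine <= 2.0:
        raise ValueError(f"cosine distance out of [0,2]: {cosine}")
    if dice >= 0.5:
        return "I" if cosine >= 0.5 else "IV"
    return "II" if cosine >= 0.5 else "III"


def pair_table(
    target_id: str,
    cell_line: str,
    population: str,
    signatures: Sequence[SignatureRecord],
    compounds: Sequence[CompoundRecord],
    activity: ActivityMatrix,
) -> pd.DataFrame:
    """Dice and cosine distances for every eligible unordered compound pair.

    Eligible compounds have a fingerprint, a signature in ``cell_line`` and
    the required label for ``target_id`` (1 for ``"actives_only"``, 0 or 1
    for ``"all_annotated"``).  Fewer than two eligible compounds yield an
    empty table (logged).  Columns: target_id, cell_line, id_a, id_b, dice,
    cosine, quadrant; pairs in condensed order over the sorted id list.
    """
    if population not in ("actives_only", "all_annotated"):
        raise ValueError(f"unknown population {population!r}")
    labels = activity.labels_for(target_id)
    wanted = set(labels[labels == 1].index) if population == "actives_only" else set(labels.index)
    sig = {
        r.compound_id: r.z
        for r in signatures
        if r.cell_line == cell_line and r.compound_id in wanted
    }
    fp = {
        c.compound_id: c.fingerprint
        for c in compounds
        if c.fingerprint is not None and c.compound_id in wanted
    }
    ids = sorted(set(sig) & set(fp))
    cols = ["target_id", "cell_line", "id_a", "id_b", "dice", "cosine", "quadrant"]
    if len(ids) < 2:
        logger.warning(
            "pair_table(%s, %s, %s): fewer than 2 eligible compounds",
            target_id,
            cell_line,
            population,
        )
        return pd.DataFrame(columns=cols)

    dice = pairwise_distances(np.vstack([fp[i] for i in ids]), "dice")
    cosine = pairwise_distances(np.vstack([sig[i] for i in ids]), "cosine")
    n = len(ids)
    ia, ib = np.triu_indices(n, k=1)
    df = pd.DataFrame(
        {
            "target_id": target_id,
            "cell_line": cell_line,
            "id_a": np.array(ids)[ia],
            "id_b": np.array(ids)[ib],
            "dice": dice,
            "cosine": np.clip(cosine, 0.0, 2.0),  # guard FP round-off at range ends
        }
    )
    df["quadrant"] = [assign_quadrant(d, c) for d, c in zip(df["dice"], df["cosine"])]
    return df[cols]


def summarize(pairs: pd.DataFrame, population: str = "actives_only") -> QuadrantSummary:
    """Quadrant counts, percentages and mean distances for one pair table."""
    n = len(pairs)
    target = pairs["target_id"].iloc[0] if n else ""
    cell = pairs["cell_line"].iloc[0] if n else ""
    counts = {q: int((pairs["quadrant"] == q).sum()) if n else 0 for q in QUADRANTS}
    percentages = {
        q: (100.0 * counts[q] / n) if n else float("nan") for q in QUADRANTS
    }
    return QuadrantSummary(
        target_id=target,
        cell_line=cell,
        population=population,
        n_pairs=n,
        counts=counts,
        percentages=percentages,
        mean_dice=float(pairs["dice"].mean()) if n else float("nan"),
        mean_cosine=float(pairs["cosine"].mean()) if n else float("nan"),
    )


def summaries_table(summaries: Sequence[QuadrantSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "target_id": s.target_id,
            "cell_line": s.cell_line,
            "population": s.population,
            "n_pairs": s.n_pairs,
            "mean_dice": s.mean_dice,
            "mean_cosine": s.mean_cosine,
        }
        for q in QUADRANTS:
            row[f"count_{q}"] = s.counts[q]
            row[f"pct_{q}"] = s.percentages[q]
        rows.append(row)
    return pd.DataFrame(rows)


def performance_association(
    summaries: Sequence[QuadrantSummary],
    benchmark_results: Sequence[BenchmarkResult],
    top_k: int = 50,
) -> dict:
    """Relate quadrant mass of active pairs to counterpart model performance.

    Joins actives-only summaries with benchmark results on (target, cell
    line) and reports: the mean quadrant III+IV percentage among the
    ``top_k`` GES models by mean balanced accuracy, the mean II+III
    percentage among the ``top_k`` Morgan FP models, and the Spearman rank
    correlation between III+IV percentage and GES mean BA over all joined
    tasks (nan with a note when degenerate).
    """
    q_rows = {
        (s.target_id, s.cell_line): s
        for s in summaries
        if s.population == "actives_only" and s.n_pairs > 0
    }
    by_kind: dict[str, dict[tuple[str, str], BenchmarkResult]] = {GES: {}, MORGAN_FP: {}}
    for res in benchmark_results:
        by_kind.setdefault(res.descriptor_kind, {})[res.key] = res

    keys = sorted(set(q_rows) & set(by_kind[GES]) & set(by_kind[MORGAN_FP]))
    rows = []
    for key in keys:
        s = q_rows[key]
        rows.append(
            {
                "target_id": key[0],
                "cell_line": key[1],
                "pct_q3q4": s.percentages["III"] + s.percentages["IV"],
                "pct_q2q3": s.percentages["II"] + s.percentages["III"],
                "ba_ges": by_kind[GES][key].mean_ba,
                "ba_fp": by_kind[MORGAN_FP][key].mean_ba,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < top_k:
        logger.info(
            "performance_association: only %d tasks for top_k=%d, using all",
            len(table),
            top_k,
        )
    k = min(top_k, len(table))

    out: dict = {"table": table, "top_k": k}
    if k:
        best_ges = table.nlargest(k, "ba_ges")
        best_fp = table.nlargest(k, "ba_fp")
        out["top_ges_mean_pct_q3q4"] = float(best_ges["pct_q3q4"].mean())
        out["top_ges_mean_pct_q2q3"] = float(best_ges["pct_q2q3"].mean())
        out["top_fp_mean_pct_q2q3"] = float(best_fp["pct_q2q3"].mean())
        out["top_fp_mean_pct_q3q4"] = float(best_fp["pct_q3q4"].mean())
    if len(table) >= 3 and table["pct_q3q4"].nunique() > 1 and table["ba_ges"].nunique() > 1:
        rho = spearmanr(table["pct_q3q4"], table["ba_ges"]).statistic
        out["spearman_q3q4_vs_ba_ges"] = float(rho)
    else:
        out["spearman_q3q4_vs_ba_ges"] = float("nan")
        out["note"] = "correlation undefined: fewer than 3 tasks or constant values"
    return out
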