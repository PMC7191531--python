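"""2-D chemical- and biological-space embeddings, plus pipeline orchestration.

Chemical space embeds the compound library from the condensed Dice distances
between fingerprints; each biological space embeds one cell line's
signatures from their cosine distances (optionally all cell lines pooled).
The embedding itself is delegated to scikit-learn's t-SNE in precomputed-
distance mode; this module owns only the distance inputs, the seeding, and
the output schema.  Coordinates are in arbitrary units, meaningful only
within one run; downstream use is purely illustrative (which points land
near which), never inferential.

:func:`run_all` chains the whole pipeline — condition filtering, replicate
averaging, task construction, the paired benchmark, quadrant diagnostics
and the embeddings — over one prepared data directory and writes the
machine-readable report bundle with a provenance manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from . import chemdesc, quadrant, sigio, taskbench
from ._util import child_seed

logger = logging.getLogger(__name__)

__all__ = ["EmbeddingResult", "embed", "annotate", "run_all"]


@dataclass
class EmbeddingResult:
    item_ids: list[str]
    coords: np.ndarray  # (n, 2)
    space: str  # "chemical", "biological:<cell_line>" or "biological:all"
    metric: str  # "dice" or "cosine"
    seed: int
    perplexity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "space": self.space,
                "seed": self.seed,
                "perplexity": self.perplexity,
            }
        )


def embed(
    condensed_distances: np.ndarray,
    item_ids: Sequence[str],
    space: str,
    metric: str,
    seed: int,
    perplexity: float = 30.0,
    max_items: int = 10_000,
    force: bool = False,
) -> EmbeddingResult:
    """t-SNE on a condensed distance vector (from :mod:`gesbench.chemdesc`).

    Requires at least ``3 * perplexity + 1`` items (the usual t-SNE
    feasibility bound) and refuses degenerate all-equal distances.  Beyond
    ``max_items`` items the quadratic memory of the square matrix becomes a
    hazard and an explicit ``force=True`` is required.
    """
    from sklearn.manifold import TSNE

    n = len(item_ids)
    if n * (n - 1) // 2 != condensed_distances.size:
        raise ValueError("condensed distance length does not match item count")
    if n < 3 * perplexity + 1:
        raise ValueError(
            f"too few items ({n}) for perplexity {perplexity}; need ≥ {int(3 * perplexity) + 1}"
        )
    if n > max_items and not force:
        raise ValueError(f"{n} items exceeds the {max_items} cap; pass force=True")
    if np.ptp(condensed_distances) == 0.0:
        raise ValueError("degenerate input: all pairwise distances equal")

    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perplexity,
    )
    coords = tsne.fit_transform(squareform(condensed_distances))
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return EmbeddingResult(list(item_ids), coords, space, metric, seed, perplexity)


def annotate(
    embedding: EmbeddingResult, activity: sigio.ActivityMatrix, target_id: str
) -> pd.DataFrame:
    """Join per-item activity status for one target onto the coordinates.

    Status is "active", "inactive" or "unknown"; labels are read from the
    activity matrix and never altered.  Unknown targets raise.
    """
    if target_id not in activity.targets():
        raise ValueError(f"unknown target {target_id!r}")
    labels = activity.labels_for(target_id)
    status = [
        ("active" if labels[i] == 1 else "inactive") if i in labels.index else "unknown"
        for i in embedding.item_ids
    ]
    df = embedding.to_frame()
    df["target_id"] = target_id
    df["status"] = status
    return df


# ---------------------------------------------------------------------------
# orchestration


DEFAULT_RUN_CONFIG = {
    "dose": 10.0,
    "time": 24.0,
    "cell_lines": None,  # None: all cell lines present
    "min_actives_total": 50,
    "min_actives_per_dataset": 20,
    "quadrant_populations": ["actives_only"],
    "embedding": {"enabled": False, "perplexity": 30.0, "max_compounds": 400},
    "model": {},  # overrides for taskbench.ModelConfig
    "seed": 0,
}


def _merged_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_RUN_CONFIG))
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_all(data_dir: str | Path, out_dir: str | Path, config: dict | None = None) -> dict:
    """Execute the full pipeline over a prepared data directory.

    ``data_dir`` must contain ``signatures.tsv``, ``sigmeta.tsv``,
    ``compounds.tsv``, ``fingerprints.tsv`` and ``activity.tsv`` (the layout
    written by :meth:`gesbench.synthgen.SyntheticWorld.write`).  Writes the
    report bundle (benchmark tables, comparison, quadrant summaries,
    association report, optional embeddings) plus ``provenance.json`` into
    ``out_dir`` and returns the in-memory results.  Stage failures are
    raised with the stage name; outputs written before the failure remain.
    """
    cfg = _merged_config(config)
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        for fname in ("signatures.tsv", "sigmeta.tsv", "compounds.tsv", "activity.tsv"):
            if not (data / fname).exists():
                raise FileNotFoundError(f"missing input file: {data / fname}")
        signatures = sigio.read_signatures(data / "signatures.tsv", data / "sigmeta.tsv")
        compounds = sigio.read_compounds(data / "compounds.tsv")
        if (data / "fingerprints.tsv").exists():
            sigio.read_fingerprints(data / "fingerprints.tsv", compounds)
        else:
            for c in compounds:
                c.fingerprint = chemdesc.fingerprint(c.smiles, compound_id=c.compound_id)
        activity = sigio.read_activity(data / "activity.tsv")

        stage = "prepare"
        known = [c.compound_id for c in compounds if c.has_structure]
        filtered = sigio.filter_conditions(
            signatures, cfg["dose"], cfg["time"], cfg["cell_lines"], known
        )
        averaged = sigio.average_replicates(filtered)

        stage = "build_tasks"
        admitted = taskbench.admit_targets(activity, cfg["min_actives_total"])
        pairs = taskbench.build_tasks(
            averaged, compounds, activity, admitted, cfg["min_actives_per_dataset"]
        )

        stage = "benchmark"
        model_cfg = taskbench.ModelConfig(seed=cfg["seed"], **cfg["model"])
        results = taskbench.run_benchmark(pairs, model_cfg)
        taskbench.results_table(results).to_csv(
            out / "benchmark_per_repeat.tsv", sep="\t", index=False
        )
        comparison = taskbench.compare_descriptors(results)
        comparison.table.to_csv(out / "benchmark_comparison.tsv", sep="\t", index=False)
        _write_mean_matrix(comparison.table, "ba", out / "mean_ba_matrix.tsv")
        _write_mean_matrix(comparison.table, "mcc", out / "mean_mcc_matrix.tsv")

        stage = "quadrants"
        summaries = []
        pair_frames = []
        for pair in pairs:
            for population in cfg["quadrant_populations"]:
                table = quadrant.pair_table(
                    pair.key[0], pair.key[1], population, averaged, compounds, activity
                )
                pair_frames.append(table.assign(population=population))
                summaries.append(quadrant.summarize(table, population))
        if pair_frames:
            pd.concat(pair_frames, ignore_index=True).to_csv(
                out / "quadrant_pairs.tsv", sep="\t", index=False
            )
        quadrant.summaries_table(summaries).to_csv(
            out / "quadrant_summaries.tsv", sep="\t", index=False
        )
        association = quadrant.performance_association(summaries, results)
        association["table"].to_csv(out / "quadrant_vs_ba.tsv", sep="\t", index=False)

        embeddings = []
        if cfg["embedding"]["enabled"]:
            stage = "embed"
            emb_cfg = cfg["embedding"]
            with_fp = [c for c in compounds if c.fingerprint is not None]
            lib = with_fp[: emb_cfg["max_compounds"]]
            dice = chemdesc.pairwise_distances(
                np.vstack([c.fingerprint for c in lib]), "dice"
            )
            embeddings.append(
                embed(
                    dice,
                    [c.compound_id for c in lib],
                    "chemical",
                    "dice",
                    child_seed(cfg["seed"], "embed", "chemical"),
                    emb_cfg["perplexity"],
                )
            )
            for cell in sorted({r.cell_line for r in averaged}):
                recs = [r for r in averaged if r.cell_line == cell][: emb_cfg["max_compounds"]]
                cos = chemdesc.pairwise_distances(np.vstack([r.z for r in recs]), "cosine")
                embeddings.append(
                    embed(
                        cos,
                        [r.compound_id for r in recs],
                        f"biological:{cell}",
                        "cosine",
                        child_seed(cfg["seed"], "embed", cell),
                        emb_cfg["perplexity"],
                    )
                )
            pd.concat([e.to_frame() for e in embeddings], ignore_index=True).to_csv(
                out / "embeddings.tsv", sep="\t", index=False
            )

        stage = "provenance"
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {
                    "config": cfg,
                    "n_signatures_in": len(signatures),
                    "n_signatures_used": len(averaged),
                    "n_compounds": len(compounds),
                    "admitted_targets": admitted,
                    "n_task_pairs": len(pairs),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "task_pairs": pairs,
        "results": results,
        "comparison": comparison,
        "quadrant_summaries": summaries,
        "association": association,
        "embeddings": embeddings,
    }


def _write_mean_matrix(table: pd.DataFrame, metric: str, path: Path) -> None:
    """Target × cell-line matrix of mean scores, GES and FP side by side."""
    if not len(table):
        pd.DataFrame().to_csv(path, sep="\t")
        return
    wide = table.pivot(index="target_id", columns="cell_line", values=[f"{metric}_ges", f"{metric}_fp"])
    wide.columns = [f"{cell}:{kind.split('_')[1]}" for kind, cell in wide.columns]
    wide.sort_index(axis=1).to_csv(path, sep="\t", float_format="%.4f")
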