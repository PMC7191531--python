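"""Data model and I/O for signatures, compounds and activity labels.

The working unit is the level-5-style *gene expression signature* (GES): a
vector of plate-normalized z-scores over the 978 L1000 landmark genes,
attached to one experimental condition (compound, cell line, dose in µM,
exposure time in hours).  This module reads and writes the plain-text
formats used throughout the pipeline, applies the condition filter (a single
dose/time point, a fixed cell-line panel, compounds with known structure)
and collapses replicates of the same condition by elementwise averaging.

On-disk formats (all TSV, readable with any table tool):

* signature matrix  — genes in rows, signature ids in columns, first column
  ``gene_id`` (a GCT-flavoured dense layout);
* signature metadata — columns ``sig_id, pert_id, cell_id, pert_dose,
  pert_time`` (dose in µM, time in hours);
* compounds — columns ``compound_id, smiles``;
* fingerprints — columns ``compound_id, fp_hex, radius, nbits`` (bit vector
  packed big-endian per byte, hex encoded);
* activity — columns ``compound_id, target_id, label`` with label in {0,1};
  pairs absent from the file are unknown.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_LANDMARK_GENES = 978

__all__ = [
    "SignatureRecord",
    "CompoundRecord",
    "ActivityMatrix",
    "read_signatures",
    "write_signatures",
    "read_compounds",
    "write_compounds",
    "read_fingerprints",
    "write_fingerprints",
    "read_activity",
    "write_activity",
    "filter_conditions",
    "average_replicates",
    "condition_key",
]


# ---------------------------------------------------------------------------
# records


@dataclass
class SignatureRecord:
    """One GES: a z-score vector plus the condition that produced it."""

    signature_id: str
    compound_id: str
    cell_line: str
    dose: float  # µM
    time: float  # hours
    z: np.ndarray  # shape (n_genes,), float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 1:
            raise ValueError(f"signature {self.signature_id}: z must be 1-D")
        if not np.all(np.isfinite(self.z)):
            raise ValueError(f"signature {self.signature_id}: non-finite z-scores")


@dataclass
class CompoundRecord:
    """A compound identifier, its SMILES and (optionally) its fingerprint."""

    compound_id: str
    smiles: str = ""
    fingerprint: np.ndarray | None = None  # 0/1 uint8 vector

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint, dtype=np.uint8)
            if fp.ndim != 1 or not np.isin(fp, (0, 1)).all():
                raise ValueError(
                    f"compound {self.compound_id}: fingerprint must be a 1-D 0/1 vector"
                )
            self.fingerprint = fp

    @property
    def has_structure(self) -> bool:
        """Whether the compound counts as having a known structure."""
        return bool(self.smiles.strip())


class ActivityMatrix:
    """Sparse ternary compound × target labels (1 active, 0 inactive, unknown).

    Stored as triplets; duplicate (compound, target) pairs with identical
    labels are deduplicated, conflicting duplicates are an error.
    """

    def __init__(self, triplets: Iterable[tuple[str, str, int]]):
        df = pd.DataFrame(triplets, columns=["compound_id", "target_id", "label"])
        if len(df):
            if not df["label"].isin([0, 1]).all():
                bad = df.loc[~df["label"].isin([0, 1])].iloc[0]
                raise ValueError(
                    f"activity label outside {{0,1}}: "
                    f"({bad.compound_id}, {bad.target_id}) -> {bad.label}"
                )
            df = df.drop_duplicates()
            dup = df.duplicated(subset=["compound_id", "target_id"], keep=False)
            if dup.any():
                bad = df.loc[dup].iloc[0]
                raise ValueError(
                    "conflicting duplicate activity labels for "
                    f"({bad.compound_id}, {bad.target_id})"
                )
        df["label"] = df["label"].astype(int) if len(df) else df["label"]
        self._df = df.reset_index(drop=True)

    # -- accessors ----------------------------------------------------------

    @property
    def triplets(self) -> pd.DataFrame:
        """Copy of the triplet table (compound_id, target_id, label)."""
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def targets(self) -> list[str]:
        return sorted(self._df["target_id"].unique())

    def labels_for(self, target_id: str) -> pd.Series:
        """Known labels for one target, indexed by compound id."""
        sub = self._df[self._df["target_id"] == target_id]
        return sub.set_index("compound_id")["label"]

    def n_actives(self, target_id: str) -> int:
        return int(self.labels_for(target_id).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActivityMatrix):
            return NotImplemented
        a = self._df.sort_values(["compound_id", "target_id"]).reset_index(drop=True)
        b = other._df.sort_values(["compound_id", "target_id"]).reset_index(drop=True)
        return a.equals(b)


# ---------------------------------------------------------------------------
# condition handling


def _round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def condition_key(rec: SignatureRecord) -> tuple[str, str, float, float]:
    """Identity of an experimental condition.

    Doses are compared after rounding to two significant figures in µM:
    real L1000 metadata records nominally identical doses with small
    formatting jitter, and exact float equality would split replicates.
    """
    return (rec.compound_id, rec.cell_line, _round_sig(rec.dose), rec.time)


def filter_conditions(
    records: Sequence[SignatureRecord],
    dose: float = 10.0,
    time: float = 24.0,
    cell_lines: Iterable[str] | None = None,
    known_structure_ids: Iterable[str] | None = None,
) -> list[SignatureRecord]:
    """Keep signatures at one dose/time, from an allowed cell-line panel,
    produced by compounds of known structure.

    ``cell_lines=None`` keeps every cell line; ``known_structure_ids=None``
    skips the structure check.  Record order is preserved.
    """
    if cell_lines is not None:
        allowed_cells = set(cell_lines)
        if not allowed_cells:
            raise ValueError("allowed cell-line set is empty")
    else:
        allowed_cells = None
    known = set(known_structure_ids) if known_structure_ids is not None else None
    dose = _round_sig(dose)

    kept = [
        r
        for r in records
        if _round_sig(r.dose) == dose
        and r.time == time
        and (allowed_cells is None or r.cell_line in allowed_cells)
        and (known is None or r.compound_id in known)
    ]
    if records and not kept:
        logger.warning(
            "condition filter (dose=%g µM, time=%g h) kept 0 of %d signatures",
            dose,
            time,
            len(records),
        )
    return kept


def average_replicates(records: Sequence[SignatureRecord]) -> list[SignatureRecord]:
    """Collapse replicates: one signature per condition, z averaged elementwise.

    The replacement signature id is derived from the condition key, so the
    operation is idempotent and deterministic.  Output is ordered by first
    appearance of each condition.
    """
    if not records:
        return []
    n_genes = {len(r.z) for r in records}
    if len(n_genes) != 1:
        raise ValueError(f"signatures have mixed gene counts: {sorted(n_genes)}")

    order: list[tuple] = []
    groups: dict[tuple, list[SignatureRecord]] = {}
    for rec in records:
        key = condition_key(rec)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    out = []
    for key in order:
        members = groups[key]
        compound, cell, dose, time = key
        z = np.mean([m.z for m in members], axis=0)
        out.append(
            SignatureRecord(
                signature_id=f"{compound}:{cell}:{dose:g}uM:{time:g}h",
                compound_id=compound,
                cell_line=cell,
                dose=dose,
                time=time,
                z=z,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O


def write_signatures(
    records: Sequence[SignatureRecord],
    matrix_path: str | Path,
    metadata_path: str | Path,
    gene_ids: Sequence[str] | None = None,
) -> None:
    """Write a dense genes × signatures matrix TSV plus a metadata TSV."""
    if not records:
        raise ValueError("no signatures to write")
    n_genes = len(records[0].z)
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    mat = pd.DataFrame(
        np.column_stack([r.z for r in records]),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[r.signature_id for r in records],
    )
    mat.to_csv(matrix_path, sep="\t", float_format="%.6g")
    meta = pd.DataFrame(
        {
            "sig_id": [r.signature_id for r in records],
            "pert_id": [r.compound_id for r in records],
            "cell_id": [r.cell_line for r in records],
            "pert_dose": [r.dose for r in records],
            "pert_time": [r.time for r in records],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_signatures(
    matrix_path: str | Path, metadata_path: str | Path
) -> list[SignatureRecord]:
    """Read signatures from the matrix + metadata TSV pair.

    Column order of the matrix defines record order; gene order is preserved
    as given.  Every matrix column must have exactly one metadata row.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.columns.duplicated().any():
        dups = mat.columns[mat.columns.duplicated()].tolist()
        raise ValueError(f"duplicate signature ids in matrix: {dups}")
    try:
        values = mat.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric z entries in {matrix_path}: {exc}") from exc

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sig_id": str})
    if meta["sig_id"].duplicated().any():
        dups = meta.loc[meta["sig_id"].duplicated(), "sig_id"].tolist()
        raise ValueError(f"duplicate signature ids in metadata: {dups}")
    meta = meta.set_index("sig_id")
    missing = [c for c in mat.columns if c not in meta.index]
    if missing:
        raise ValueError(f"metadata missing signature ids: {missing}")

    records = []
    for j, sig_id in enumerate(mat.columns):
        row = meta.loc[sig_id]
        records.append(
            SignatureRecord(
                signature_id=str(sig_id),
                compound_id=str(row["pert_id"]),
                cell_line=str(row["cell_id"]),
                dose=float(row["pert_dose"]),
                time=float(row["pert_time"]),
                z=values[:, j],
            )
        )
    return records


def write_compounds(compounds: Sequence[CompoundRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "compound_id": [c.compound_id for c in compounds],
            "smiles": [c.smiles for c in compounds],
        }
    ).to_csv(path, sep="\t", index=False)


def read_compounds(path: str | Path) -> list[CompoundRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if df["compound_id"].duplicated().any():
        dups = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
        raise ValueError(f"duplicate compound ids: {dups}")
    return [
        CompoundRecord(compound_id=row.compound_id, smiles=row.smiles)
        for row in df.itertuples()
    ]


def _pack_hex(bits: np.ndarray) -> str:
    return np.packbits(bits.astype(np.uint8)).tobytes().hex()


def _unpack_hex(fp_hex: str, nbits: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(fp_hex), dtype=np.uint8)
    return np.unpackbits(raw)[:nbits]


def write_fingerprints(
    compounds: Sequence[CompoundRecord], path: str | Path, radius: int = 2
) -> None:
    rows = []
    for c in compounds:
        if c.fingerprint is None:
            raise ValueError(f"compound {c.compound_id} has no fingerprint")
        rows.append(
            {
                "compound_id": c.compound_id,
                "fp_hex": _pack_hex(c.fingerprint),
                "radius": radius,
                "nbits": len(c.fingerprint),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fingerprints(
    path: str | Path, compounds: Sequence[CompoundRecord] | None = None
) -> dict[str, np.ndarray]:
    """Read fingerprints; if ``compounds`` is given, attach them in place."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "fp_hex": str})
    fps = {
        row.compound_id: _unpack_hex(row.fp_hex, int(row.nbits))
        for row in df.itertuples()
    }
    if compounds is not None:
        for c in compounds:
            if c.compound_id in fps:
                c.fingerprint = fps[c.compound_id]
    return fps


def write_activity(activity: ActivityMatrix, path: str | Path) -> None:
    activity.triplets.to_csv(path, sep="\t", index=False)


def read_activity(path: str | Path) -> ActivityMatrix:
    df = pd.read_csv(
        path, sep="\t", dtype={"compound_id": str, "target_id": str, "label": int}
    )
    return ActivityMatrix(df.itertuples(index=False, name=None))
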