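"""Molecular fingerprints and the two distance kernels of the pipeline.

Chemical space is described by hashed binary circular (Morgan/ECFP-family)
fingerprints compared with the Dice distance; biological space by GES
z-score vectors compared with the cosine distance.  The downstream analysis
only ever consumes these two kernels.

Conventions
-----------
* Dice distance ``1 - 2|A∩B| / (|A| + |B|)`` lies in [0, 1].  Two all-zero
  fingerprints are *identical* objects and get distance 0; an all-zero
  versus a non-empty fingerprint gets distance 1.  Both cases are logged,
  since an empty fingerprint usually means a degenerate molecule.
  Dice distance violates the triangle inequality in general; nothing here
  assumes metricity.
* Cosine distance ``1 - x·y/(‖x‖‖y‖)`` lies in [0, 2] on signed z-vectors.
  A zero-norm vector has no direction and raises.
* Condensed pairwise output follows the scipy convention: pair (i, j) with
  i < j sits at index ``i*n - i*(i+1)//2 + (j - i - 1)``.
"""

from __future__ import annotations

import logging
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "fingerprint",
    "dice_distance",
    "cosine_distance",
    "pairwise_distances",
    "condensed_index",
    "condensed_pair",
]

DEFAULT_RADIUS = 2
DEFAULT_NBITS = 2048


def fingerprint(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
    compound_id: str | None = None,
) -> np.ndarray:
    """Binary Morgan fingerprint of a SMILES, folded to ``n_bits``.

    Deterministic for identical input molecules: SMILES are canonicalized
    by the toolkit before hashing, so alternative valid spellings of the
    same structure give identical bit vectors.  Raises ``ValueError``
    (naming ``compound_id`` when given) for unparseable SMILES.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = compound_id or smiles
        raise ValueError(f"unparseable SMILES for compound {who!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def dice_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dice distance between two equal-length binary vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        logger.warning("Dice distance of two empty fingerprints: 0 by convention")
        return 0.0
    if na == 0 or nb == 0:
        logger.warning("Dice distance empty vs non-empty fingerprint: 1 by convention")
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return 1.0 - 2.0 * inter / (na + nb)


def cosine_distance(x: np.ndarray, y: np.ndarray, signature_id: str | None = None) -> float:
    """Cosine distance between two z-score vectors, in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError(
            f"zero-norm signature{f' {signature_id!r}' if signature_id else ''}: "
            "cosine distance undefined"
        )
    return float(1.0 - np.dot(x, y) / (nx * ny))


# ---------------------------------------------------------------------------
# condensed pairwise evaluation


def condensed_index(i: int, j: int, n: int) -> int:
    """Condensed index of unordered pair {i, j} among n items."""
    if i == j:
        raise ValueError("self-pairs have no condensed index")
    i, j = (i, j) if i < j else (j, i)
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def condensed_pair(k: int, n: int) -> tuple[int, int]:
    """Inverse of :func:`condensed_index`."""
    i = 0
    rows_before = 0
    while rows_before + (n - i - 1) <= k:
        rows_before += n - i - 1
        i += 1
    j = i + 1 + (k - rows_before)
    return i, j


def _chunks(n: int, size: int) -> Iterator[tuple[int, int]]:
    for start in range(0, n, size):
        yield start, min(start + size, n)


def pairwise_distances(
    items: Sequence[np.ndarray] | np.ndarray,
    kernel: str,
    chunk_size: int = 512,
) -> np.ndarray:
    """All n(n-1)/2 pairwise distances in condensed (scipy) order.

    ``kernel`` is ``"dice"`` (binary fingerprints) or ``"cosine"``
    (z-vectors).  Rows are processed in chunks of ``chunk_size`` so the full
    n × n matrix is never materialized; memory is O(chunk_size · n).
    """
    X = np.asarray(items)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items for pairwise distances")
    if kernel not in ("dice", "cosine"):
        raise ValueError(f"unknown kernel {kernel!r}")

    if kernel == "dice":
        # integer-arithmetic route evaluating exactly the scalar formula
        # 1 − 2|A∩B|/(|A|+|B|), so bulk and scalar results agree bitwise
        Xi = (X != 0).astype(np.int32)
        set_bits = Xi.sum(axis=1)
        if (set_bits == 0).any():
            logger.warning(
                "%d empty fingerprints in pairwise Dice", int((set_bits == 0).sum())
            )
    else:
        X = X.astype(float)
        norms = np.linalg.norm(X, axis=1)
        if (norms == 0).any():
            bad = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(f"zero-norm signature at row {bad}: cosine undefined")

    out = np.empty(n * (n - 1) // 2, dtype=float)
    for lo, hi in _chunks(n - 1, chunk_size):
        if kernel == "dice":
            inter = Xi[lo:hi] @ Xi[lo:].T
            denom = set_bits[lo:hi, None] + set_bits[None, lo:]
            with np.errstate(invalid="ignore"):
                block = 1.0 - 2.0 * inter / denom
            block[denom == 0] = 0.0  # both-empty convention
        else:
            block = cdist(X[lo:hi], X[lo:], metric=kernel)
        for local_i, i in enumerate(range(lo, hi)):
            row = block[local_i, local_i + 1 :]
            start = condensed_index(i, i + 1, n)
            out[start : start + row.size] = row
    return out
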