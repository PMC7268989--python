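"""Phenotype × gene score matrices: loading, validation, transforms, permutation.

The universal input is a dense real matrix with one row per phenotype and one
column per gene, holding gene-level association statistics on one of two
scales:

* ``pvalue`` — raw gene-level association P-values in (0, 1], as produced by
  gene-level tests such as PEGASUS, PASCAL or VEGAS;
* ``neglog10`` — the −log10-transformed scores used for clustering, in
  [0, ∞).

Matrices travel as :class:`GeneScoreMatrix`, which validates its invariants on
construction so downstream code can assume a clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PVALUE = "pvalue"
NEGLOG10 = "neglog10"
_SCALES = (PVALUE, NEGLOG10)

#: P-values of exactly 0 are clamped here before the −log10 transform so that
#: downstream Euclidean distances stay finite (gene-level tests can report
#: values at machine precision).
DEFAULT_CLAMP_FLOOR = 1e-300


class MatrixValidationError(ValueError):
    """Raised when a score matrix violates a structural or range invariant."""


@dataclass
class GeneScoreMatrix:
    """A validated phenotype × gene matrix of gene-level association scores.

    Parameters
    ----------
    phenotype_ids
        Unique row labels (the phenotypes being jointly analysed); at least 2.
    gene_ids
        Unique column labels (genes or other genomic regions).
    values
        Dense ``(n_phenotypes, n_genes)`` float array with no missing entries.
    scale
        ``"pvalue"`` (values in (0, 1]) or ``"neglog10"`` (finite, ≥ 0).
    """

    phenotype_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.phenotype_ids = [str(p) for p in self.phenotype_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        _validate(self)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.phenotype_ids, columns=self.gene_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneScoreMatrix):
            return NotImplemented
        return (
            self.phenotype_ids == other.phenotype_ids
            and self.gene_ids == other.gene_ids
            and self.scale == other.scale
            and np.array_equal(self.values, other.values)
        )


def _first_duplicate(ids: list[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _validate(m: GeneScoreMatrix) -> None:
    if m.scale not in _SCALES:
        raise MatrixValidationError(f"unknown scale {m.scale!r}; expected one of {_SCALES}")
    if m.values.ndim != 2:
        raise MatrixValidationError(f"values must be 2-D, got shape {m.values.shape}")
    n, g = m.values.shape
    if n != len(m.phenotype_ids) or g != len(m.gene_ids):
        raise MatrixValidationError(
            f"shape {m.values.shape} does not match {len(m.phenotype_ids)} phenotypes"
            f" × {len(m.gene_ids)} genes"
        )
    if n < 2:
        raise MatrixValidationError("at least 2 phenotype rows are required")
    dup = _first_duplicate(m.phenotype_ids)
    if dup is not None:
        raise MatrixValidationError(f"duplicate phenotype id {dup!r}")
    dup = _first_duplicate(m.gene_ids)
    if dup is not None:
        raise MatrixValidationError(f"duplicate gene id {dup!r}")
    bad = ~np.isfinite(m.values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MatrixValidationError(
            f"non-finite value at phenotype {m.phenotype_ids[i]!r},"
            f" gene {m.gene_ids[j]!r}"
        )
    if m.scale == PVALUE:
        bad = (m.values <= 0) | (m.values > 1)
    else:
        bad = m.values < 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MatrixValidationError(
            f"value {m.values[i, j]!r} at phenotype {m.phenotype_ids[i]!r},"
            f" gene {m.gene_ids[j]!r} is out of range for scale {m.scale!r}"
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_matrix(path: str | Path, scale: str) -> GeneScoreMatrix:
    """Load a score matrix from a delimited text file.

    The file must have a header row of gene IDs and a first column of
    phenotype IDs.  Tab and comma delimiters are auto-detected (tab
    preferred).  Row and column order are preserved.

    Raises
    ------
    MatrixValidationError
        On missing values, duplicate IDs, values out of range for ``scale``,
        or fewer than two phenotype rows; the message names the offending
        row/column.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup = _first_duplicate(header)
    if dup is not None:
        raise MatrixValidationError(f"duplicate gene id {dup!r} in {path}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    phen = [str(x) for x in df.index]
    genes = header
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise MatrixValidationError(
            f"missing value at phenotype {phen[i]!r}, gene {genes[j]!r} in {path}"
        )
    return GeneScoreMatrix(phen, genes, values, scale)


def write_matrix(m: GeneScoreMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix in the delimited format that :func:`load_matrix` reads.

    Floats are written with shortest round-trip precision, so
    ``load_matrix(write_matrix(m)) == m`` exactly.
    """
    df = m.to_frame()
    df.index.name = "phenotype"
    df.to_csv(path, sep=sep)


def neglog10_transform(
    m: GeneScoreMatrix, clamp_floor: float = DEFAULT_CLAMP_FLOOR
) -> GeneScoreMatrix:
    """Map a P-value matrix to gene scores: value → −log10(max(p, clamp_floor)).

    The transform is strictly monotone decreasing for p ≥ ``clamp_floor``, so
    it reverses the ordering of P-values: smaller P means larger score.  It
    stretches the small significant region of (0, 1] onto a wide range of
    scores, which is what lets shared significant genes dominate Euclidean
    distances between phenotypes.
    """
    if m.scale != PVALUE:
        raise MatrixValidationError("matrix is already on the neglog10 scale")
    if not 0 < clamp_floor <= 1:
        raise MatrixValidationError(f"clamp_floor {clamp_floor!r} not in (0, 1]")
    scores = -np.log10(np.maximum(m.values, clamp_floor))
    return GeneScoreMatrix(list(m.phenotype_ids), list(m.gene_ids), scores, NEGLOG10)


def shuffle_rows(m: GeneScoreMatrix, seed: int | np.random.Generator) -> GeneScoreMatrix:
    """Independently permute each phenotype's scores across gene columns.

    This is the permutation null: each row keeps its multiset of values but
    loses any column (gene) alignment with other rows, destroying shared
    architecture while preserving per-phenotype score distributions.
    Deterministic for a given integer seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shuffled = np.empty_like(m.values)
    for i in range(m.values.shape[0]):
        shuffled[i] = m.values[i, rng.permutation(m.values.shape[1])]
    return GeneScoreMatrix(list(m.phenotype_ids), list(m.gene_ids), shuffled, m.scale)
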