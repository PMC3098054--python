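"""Symmetric gene-by-gene similarity matrices with a defined-entry mask.

Both clustering constraints — expression correlation and GO semantic
similarity — are represented by the same container: a symmetric I x I
matrix of similarity values together with a boolean mask marking which
entries are defined.  Undefined entries (constant expression profiles,
genes sharing no annotated GO aspect) are carried explicitly rather than
being replaced by an arbitrary number, so that downstream neighborhood
construction can skip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimilarityMatrix", "write_similarity_tsv", "read_similarity_tsv"]

#: Value range of defined entries per similarity kind.
KIND_RANGES = {"expression": (-1.0, 1.0), "go": (0.0, 1.0)}

_RANGE_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """Symmetric similarity with a defined-entry mask.

    Parameters
    ----------
    gene_ids
        Ordered unique gene identifiers (length I).
    values
        I x I float array; entries where ``mask`` is False are meaningless.
    mask
        I x I boolean array, True where the similarity is defined.
    kind
        ``"expression"`` (defined entries in [-1, 1]) or ``"go"``
        (defined entries in [0, 1]).  Defined diagonal entries equal the
        kind's maximum of 1.
    """

    gene_ids: list[str]
    values: np.ndarray
    mask: np.ndarray
    kind: str = field(default="expression")

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        if self.kind not in KIND_RANGES:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        ids = self.gene_ids
        if len(ids) != len(set(ids)) or any(not g for g in ids):
            raise ValueError("gene_ids must be unique and non-empty")
        n = len(ids)
        if self.values.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("values and mask must be square I x I arrays")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        v = np.where(self.mask, self.values, 0.0)
        if not np.array_equal(v, v.T):
            raise ValueError("defined values must be symmetric")
        lo, hi = KIND_RANGES[self.kind]
        defined = self.values[self.mask]
        if defined.size and (
            defined.min() < lo - _RANGE_TOL or defined.max() > hi + _RANGE_TOL
        ):
            raise ValueError(f"defined {self.kind} similarities must lie in [{lo}, {hi}]")
        diag_defined = np.diag(self.mask)
        if diag_defined.any() and not np.allclose(
            np.diag(self.values)[diag_defined], hi, atol=_RANGE_TOL
        ):
            raise ValueError("defined diagonal entries must equal the maximum similarity")


def write_similarity_tsv(sim: SimilarityMatrix, path) -> None:
    """Write a square TSV with gene IDs as first row/column; masked entries as NA."""
    df = pd.DataFrame(
        np.where(sim.mask, sim.values, np.nan), index=sim.gene_ids, columns=sim.gene_ids
    )
    df.to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def read_similarity_tsv(path, kind: str = "expression") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    values = df.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    values = np.where(mask, values, 0.0)
    return SimilarityMatrix(list(df.index), values, mask, kind=kind)
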