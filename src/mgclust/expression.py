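"""Expression profiles and the Pearson-correlation constraint.

The first clustering constraint is built from log-ratio transformed
time-course expression profiles: the similarity between two genes is the
Pearson correlation coefficient of their profiles, ranging over [-1, 1]
with higher values meaning more similar.  Anti-correlated genes are kept
at their negative values — they are treated as most dissimilar, on the
grounds that co-expressed genes tend to share reaction steps while
opposite-phase genes do not.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "ExpressionMatrix",
    "read_expression_table",
    "write_expression_table",
    "log_ratio_transform",
    "impute_missing",
    "expression_similarity",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples log-ratio expression values with a missing mask.

    ``values`` holds NaN at missing positions; ``missing_mask`` is True
    exactly there.  Profile length must be at least 2 and every
    non-missing entry must be finite.
    """

    gene_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(self.gene_ids) != len(set(self.gene_ids)) or any(
            not g for g in self.gene_ids
        ):
            raise ValueError("gene_ids must be unique and non-empty")
        if self.values.ndim != 2 or self.values.shape[0] != len(self.gene_ids):
            raise ValueError("values must be an I x L matrix matching gene_ids")
        if self.values.shape[1] < 2:
            raise ValueError("profiles must have length L >= 2")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask must match the shape of values")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValueError("non-missing entries must be finite")
        if self.sample_ids is None:
            self.sample_ids = [f"s{j + 1}" for j in range(self.values.shape[1])]
        else:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != self.values.shape[1]:
                raise ValueError("sample_ids must match the number of columns")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def read_expression_table(path) -> ExpressionMatrix:
    """Read a TSV expression table (header of sample names, first column gene IDs).

    Empty cells or "NA" denote missing values.  Duplicate gene IDs,
    ragged rows and non-numeric cells are hard errors.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty expression table") from None
        sample_ids = header[1:]
        n_cols = len(header)
        gene_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        mask_rows: list[list[bool]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_cols:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} fields, expected {n_cols})"
                )
            gene = row[0]
            if gene in seen:
                raise ValueError(f"{path}: duplicate gene ID {gene!r}")
            seen.add(gene)
            gene_ids.append(gene)
            vals, miss = [], []
            for j, cell in enumerate(row[1:]):
                cell = cell.strip()
                if cell == "" or cell == "NA":
                    vals.append(math.nan)
                    miss.append(True)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise ValueError(
                            f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                            f"column {header[j + 1]!r}"
                        ) from None
                    miss.append(False)
            rows.append(vals)
            mask_rows.append(miss)
    return ExpressionMatrix(gene_ids, np.array(rows), np.array(mask_rows), sample_ids)


def write_expression_table(x: ExpressionMatrix, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gene", *x.sample_ids])
        for i, gene in enumerate(x.gene_ids):
            row = [
                "NA" if x.missing_mask[i, j] else repr(float(x.values[i, j]))
                for j in range(x.n_samples)
            ]
            writer.writerow([gene, *row])


def log_ratio_transform(raw: ExpressionMatrix, control) -> ExpressionMatrix:
    """log2 of the ratio between each sample point and a per-gene control.

    ``control`` is a scalar, a per-gene array, or a mapping gene -> value;
    raw values and controls must be strictly positive where observed.
    """
    if np.isscalar(control):
        ctrl = np.full(raw.n_genes, float(control))
    elif isinstance(control, dict):
        try:
            ctrl = np.array([float(control[g]) for g in raw.gene_ids])
        except KeyError as exc:
            raise ValueError(f"no control measurement for gene {exc.args[0]!r}") from None
    else:
        ctrl = np.asarray(control, dtype=float)
        if ctrl.shape != (raw.n_genes,):
            raise ValueError("control must provide one value per gene")
    bad = np.where(ctrl <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive control for gene {raw.gene_ids[bad[0]]!r}")
    observed = ~raw.missing_mask
    nonpos = observed & ~(raw.values > 0)
    if nonpos.any():
        i, j = np.argwhere(nonpos)[0]
        raise ValueError(
            f"non-positive expression value for gene {raw.gene_ids[i]!r}, "
            f"column {raw.sample_ids[j]!r}"
        )
    values = np.where(observed, np.log2(raw.values / ctrl[:, None]), np.nan)
    return ExpressionMatrix(raw.gene_ids, values, raw.missing_mask.copy(), raw.sample_ids)


def impute_missing(
    x: ExpressionMatrix, max_missing_fraction: float = 0.5
) -> ExpressionMatrix:
    """Row-mean imputation with a drop threshold.

    Genes whose missing fraction exceeds ``max_missing_fraction`` are
    dropped (warned); remaining missing entries are replaced by the mean
    of the gene's observed entries.  The output has no missing entries.
    """
    frac = x.missing_mask.mean(axis=1)
    keep = frac <= max_missing_fraction
    dropped = [g for g, k in zip(x.gene_ids, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d gene(s) with missing fraction > %.2f: %s",
            len(dropped),
            max_missing_fraction,
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    gene_ids = [g for g, k in zip(x.gene_ids, keep) if k]
    values = x.values[keep].copy()
    mask = x.missing_mask[keep]
    n_obs = (~mask).sum(axis=1)
    if np.any(n_obs == 0):
        i = int(np.where(n_obs == 0)[0][0])
        raise ValueError(f"gene {gene_ids[i]!r} retained with zero observed entries")
    with np.errstate(invalid="ignore"):
        row_mean = np.nansum(np.where(mask, np.nan, values), axis=1) / n_obs
    values[mask] = np.broadcast_to(row_mean[:, None], values.shape)[mask]
    return ExpressionMatrix(
        gene_ids, values, np.zeros_like(values, dtype=bool), x.sample_ids
    )


def expression_similarity(x: ExpressionMatrix) -> SimilarityMatrix:
    """Pearson-correlation similarity between log-ratio profiles.

    Uses population moments (the 1/L vs 1/(L-1) choice cancels in the
    correlation).  Pairs involving a constant profile (zero standard
    deviation) are masked undefined; the diagonal is 1 for every
    non-constant profile.  Anti-correlated pairs keep their negative
    value — no absolute value or shift is applied.
    """
    if x.n_genes < 2:
        raise ValueError("expression_similarity requires at least 2 genes")
    if x.missing_mask.any():
        raise ValueError("expression matrix contains missing values; impute first")
    centered = x.values - x.values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        logger.warning("%d constant profile(s) masked undefined", int(constant.sum()))
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr = (corr + corr.T) / 2.0  # exact bitwise symmetry
    corr = np.clip(corr, -1.0, 1.0)
    mask = ~constant[:, None] & ~constant[None, :]
    np.fill_diagonal(corr, 1.0)
    corr[~mask] = 0.0
    return SimilarityMatrix(x.gene_ids, corr, mask, kind="expression")
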