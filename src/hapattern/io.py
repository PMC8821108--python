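"""Readers, writers and expression preprocessing.

In-memory conventions
---------------------
* An expression matrix is a :class:`pandas.DataFrame` with gene identifiers
  as the index and sample identifiers as the columns.  By pipeline convention
  the values are on log2(TPM+1) scale; :func:`fpkm_to_tpm` and
  :func:`log2_transform` move linear-scale data onto it.
* A clinical table is a DataFrame indexed by ``sample_id`` with reserved
  columns ``os_time`` (positive survival time, unitless but cohort-consistent),
  ``os_event`` (1 = death observed, 0 = censored) and optionally ``batch``;
  any further columns are covariates.
* Gene sets are :class:`GeneSet` records (name + unique gene identifiers).

Gene identifier matching throughout the package is exact, case-sensitive
string equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "read_expression",
    "write_matrix",
    "read_clinical",
    "read_gmt",
    "write_gmt",
    "fpkm_to_tpm",
    "log2_transform",
    "batch_adjust",
    "validate_expression",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers.

    Duplicate genes are removed on construction (first occurrence kept);
    an empty gene list is rejected.
    """

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        deduped = tuple(dict.fromkeys(self.genes))
        if not deduped:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "genes", deduped)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def validate_expression(mat: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants (unique ids, finite values)."""
    dup_genes = mat.index[mat.index.duplicated()].unique()
    if len(dup_genes):
        raise ValueError(f"duplicate gene identifier(s): {list(dup_genes)}")
    dup_samples = mat.columns[mat.columns.duplicated()].unique()
    if len(dup_samples):
        raise ValueError(f"duplicate sample identifier(s): {list(dup_samples)}")
    if not np.isfinite(mat.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return mat


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV expression matrix.

    First column holds gene identifiers, the header row holds sample
    identifiers.  Rows containing any empty or non-numeric cell are dropped
    with a warning (downstream SVD and enrichment require complete rows).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty expression matrix: {path}")
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna().any(axis=1)
    if bad.any():
        dropped = list(values.index[bad])
        warnings.warn(
            f"dropped {len(dropped)} gene row(s) with missing/non-numeric "
            f"cells: {dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
        values = values.loc[~bad]
    if values.shape[0] == 0:
        raise ValueError(f"no complete gene rows in {path}")
    return validate_expression(values.astype(float))


def write_matrix(mat: pd.DataFrame, path, index_label: str = "gene_id",
                 comment: str | None = None) -> None:
    """Write a DataFrame as TSV, optionally with a ``#`` provenance line."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        mat.to_csv(fh, sep="\t", index_label=index_label, float_format="%.12g")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV keyed by ``sample_id`` and validate invariants."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in tab.columns:
        raise ValueError("clinical table must have a 'sample_id' column")
    tab["sample_id"] = tab["sample_id"].astype(str)
    if tab["sample_id"].duplicated().any():
        dups = list(tab.loc[tab["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample_id(s): {dups}")
    tab = tab.set_index("sample_id")
    for col in ("os_time", "os_event"):
        if col not in tab.columns:
            raise ValueError(f"clinical table must have an '{col}' column")
    if (tab["os_time"] <= 0).any():
        raise ValueError("os_time must be positive for every sample")
    if not tab["os_event"].isin([0, 1]).all():
        raise ValueError("os_event must be 0 (censored) or 1 (death)")
    return tab


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    The description field is ignored; within-set duplicate genes are removed.
    """
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in names:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            names.add(name)
            sets.append(GeneSet(name, tuple(genes)))
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


def fpkm_to_tpm(mat: pd.DataFrame) -> pd.DataFrame:
    """Convert a linear-scale FPKM matrix to TPM.

    TPM_ij = FPKM_ij / sum_i FPKM_ij * 1e6, so every sample column sums to
    one million.  The transform is scale-invariant per sample and idempotent.
    """
    values = mat.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    colsum = values.sum(axis=0)
    zero = colsum <= 0
    if zero.any():
        raise ValueError(
            f"sample(s) with all-zero expression: {list(mat.columns[zero])}"
        )
    return pd.DataFrame(values / colsum * 1e6, index=mat.index,
                        columns=mat.columns)


def log2_transform(mat: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) onto the pipeline's working scale."""
    return pd.DataFrame(np.log2(mat.to_numpy(dtype=float) + 1.0),
                        index=mat.index, columns=mat.columns)


def batch_adjust(mat: pd.DataFrame, batch) -> pd.DataFrame:
    """Per-gene location-scale batch adjustment.

    Within each batch a gene's values are standardized by the batch mean and
    (ddof=1) standard deviation, then re-expressed on that gene's pooled mean
    and standard deviation, so post-adjustment per-gene batch means and sds
    agree across batches.  This is a location-scale harmonisation without
    empirical-Bayes shrinkage of the batch parameters.

    A gene with zero variance inside some batch is only mean-centered for
    that batch (its scale is left alone), with a warning.
    """
    batch = pd.Series(batch)
    if batch.index.inferred_type in ("integer", "range"):
        batch.index = mat.columns  # positional labels
    missing = [s for s in mat.columns if s not in batch.index]
    if missing:
        raise ValueError(f"samples without batch label: {missing}")
    batch = batch.loc[mat.columns].astype(str)
    counts = batch.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"batch(es) with a single sample: {list(small.index)}"
        )
    values = mat.to_numpy(dtype=float)
    pooled_mean = values.mean(axis=1)
    pooled_sd = values.std(axis=1, ddof=1)
    out = np.empty_like(values)
    warned = False
    for lab in counts.index:
        cols = (batch == lab).to_numpy()
        block = values[:, cols]
        bmean = block.mean(axis=1)
        bsd = block.std(axis=1, ddof=1)
        degenerate = bsd == 0
        if degenerate.any() and not warned:
            warnings.warn(
                f"{int(degenerate.sum())} gene(s) with zero variance within "
                f"a batch were centered only"
            )
            warned = True
        scale = np.where(degenerate, 1.0, pooled_sd / np.where(bsd == 0, 1.0, bsd))
        out[:, cols] = (block - bmean[:, None]) * scale[:, None] \
            + pooled_mean[:, None]
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)
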