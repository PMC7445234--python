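"""Assembly of the decorrelated background expression distribution.

A phenotype's specificity is only meaningful relative to a broad atlas of
other cell types. This module turns a raw count compendium into that
background: low-depth and single-cell samples are removed, polyA and total
RNA libraries are kept separate (their gene-body coverage differs too much
to mix), near-duplicate samples are greedily pruned until all pairwise
Pearson correlations fall below a threshold, and the surviving counts are
converted to TPM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

LIBRARY_TYPES = ("polyA", "total")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus gene lengths.

    ``values`` is indexed by gene_id with one column per sample;
    ``gene_lengths`` (bp) is aligned to the same index. ``unit`` is
    either ``counts`` or ``TPM``.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not self.values.index.equals(self.gene_lengths.index):
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
            if self.gene_lengths.isna().any():
                raise ValueError("gene_lengths not aligned to gene ids")
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")
        if self.unit not in ("counts", "TPM"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[list(sample_ids)].copy(),
            gene_lengths=self.gene_lengths,
            unit=self.unit,
        )


@dataclass
class BackgroundSet:
    """A decorrelated background atlas in TPM, with the provenance needed
    to reproduce the greedy selection (seed and retained order)."""

    matrix: ExpressionMatrix  # unit TPM
    library_type: str
    selection_seed: int
    retained_order: List[str] = field(default_factory=list)


def filter_samples(
    matrix: ExpressionMatrix, metadata: pd.DataFrame, min_counts: int = 15000
) -> ExpressionMatrix:
    """Drop single-cell samples and samples with fewer than ``min_counts``
    total counts (strictly-below removal: a sum of exactly ``min_counts``
    is retained). The gene set is unchanged."""
    if matrix.unit != "counts":
        raise ValueError("filter_samples operates on raw counts")
    missing = [s for s in matrix.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing for samples {missing[:5]}")
    keep = []
    sums = matrix.values.sum(axis=0)
    for s in matrix.sample_ids:
        if int(metadata.loc[s, "is_single_cell"]):
            continue
        if sums[s] < min_counts:
            continue
        keep.append(s)
    if not keep:
        raise ValueError("empty background: all samples removed by filtering")
    return matrix.subset_samples(keep)


def split_by_library_type(
    matrix: ExpressionMatrix, metadata: pd.DataFrame
) -> Dict[str, ExpressionMatrix]:
    """Partition samples into polyA and total RNA-seq sets."""
    groups: Dict[str, List[str]] = {lt: [] for lt in LIBRARY_TYPES}
    for s in matrix.sample_ids:
        if s not in metadata.index:
            raise ValueError(f"metadata missing for sample {s}")
        lt = metadata.loc[s, "library_type"]
        if lt not in groups:
            raise ValueError(f"unknown library_type {lt!r} for sample {s}")
        groups[lt].append(s)
    return {lt: matrix.subset_samples(cols) for lt, cols in groups.items()}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; defined as 0 when either vector has zero variance, so a
    degenerate sample never blocks the greedy pass."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def decorrelate(
    matrix: ExpressionMatrix,
    r_max: float = 0.7,
    seed: int = 1,
    library_type: str = "unknown",
) -> BackgroundSet:
    """Greedy decorrelation of a count compendium.

    A seeded RNG fixes a random visit order; the first sample is always
    retained, and each subsequent sample is added iff its Pearson r (over
    all genes, on the input scale) with every already-retained sample is
    strictly below ``r_max``. The retained submatrix is converted to TPM.
    Deterministic given (matrix, seed).
    """
    if matrix.n_samples == 0:
        raise ValueError("cannot decorrelate an empty matrix")
    rng = np.random.default_rng(seed)
    order = [matrix.sample_ids[i] for i in rng.permutation(matrix.n_samples)]
    vals = matrix.values
    retained: List[str] = [order[0]]
    retained_vecs = [vals[order[0]].to_numpy(dtype=float)]
    for s in order[1:]:
        v = vals[s].to_numpy(dtype=float)
        if all(_pearson(v, w) < r_max for w in retained_vecs):
            retained.append(s)
            retained_vecs.append(v)
    sub = matrix.subset_samples(retained)
    tpm = counts_to_tpm(sub) if sub.unit == "counts" else sub
    return BackgroundSet(
        matrix=tpm,
        library_type=library_type,
        selection_seed=seed,
        retained_order=retained,
    )


def counts_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts-per-million: counts are divided by gene length in kb,
    then each sample is scaled to sum to 1e6. An all-zero sample stays
    all-zero (the one documented exception to the column-sum invariant)."""
    if (matrix.gene_lengths <= 0).any():
        bad = matrix.gene_lengths[matrix.gene_lengths <= 0].index.tolist()
        raise ValueError(f"non-positive gene length for {bad[:5]}")
    length_kb = matrix.gene_lengths.to_numpy(dtype=float) / 1000.0
    rates = matrix.values.to_numpy(dtype=float) / length_kb[:, None]
    col_sums = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(col_sums > 0, rates / col_sums * 1e6, 0.0)
    return ExpressionMatrix(
        values=pd.DataFrame(tpm, index=matrix.values.index, columns=matrix.values.columns),
        gene_lengths=matrix.gene_lengths,
        unit="TPM",
    )


def write_background(bg: BackgroundSet, out_prefix) -> None:
    """Write the background as <prefix>.tsv plus a <prefix>.json sidecar
    recording seed, retained order and library type."""
    out_prefix = Path(out_prefix)
    out = bg.matrix.values.copy()
    out.insert(0, "gene_length", bg.matrix.gene_lengths)
    out.to_csv(
        out_prefix.with_suffix(".tsv"), sep="\t", index_label="gene_id",
        float_format="%.6f",
    )
    sidecar = {
        "library_type": bg.library_type,
        "seed": bg.selection_seed,
        "retained_order": bg.retained_order,
        "unit": bg.matrix.unit,
    }
    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_background(out_prefix) -> BackgroundSet:
    out_prefix = Path(out_prefix)
    df = pd.read_csv(out_prefix.with_suffix(".tsv"), sep="\t", index_col="gene_id")
    with open(out_prefix.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    matrix = ExpressionMatrix(
        values=df.drop(columns=["gene_length"]),
        gene_lengths=df["gene_length"].astype(int),
        unit=sidecar.get("unit", "TPM"),
    )
    return BackgroundSet(
        matrix=matrix,
        library_type=sidecar["library_type"],
        selection_seed=int(sidecar["seed"]),
        retained_order=list(sidecar["retained_order"]),
    )
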