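"""Readers and writers for every tabular/genomic format the pipeline touches.

All files are plain TSV or BED-family text. Readers validate invariants on
the way in (coordinates, score ranges, required columns) and raise
informative errors naming the offending line or column; writers produce
deterministic, diff-stable output (stable sort orders, fixed float
formatting) so that identical runs are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .background import ExpressionMatrix
from .intervals import GenomicInterval, Peak
from .network import ComplexCall, CoreGRN, Edge
from .regions import EnhancerAssociation, PromoterAnnotation

_BED_FIELDS = {"bed3": 3, "bed6": 4, "narrowPeak": 10}


class SchemaError(ValueError):
    """A required column is missing or carries an out-of-vocabulary value."""


@dataclass(frozen=True)
class PpiRecord:
    """An undirected protein–protein interaction with a 0–1000 confidence
    score (STRING convention); (A, B) and (B, A) denote the same record."""

    protein_a: str
    protein_b: str
    score: int

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction {self.protein_a} is not allowed")
        if not 0 <= self.score <= 1000:
            raise ValueError(
                f"PPI score {self.score} for ({self.protein_a}, {self.protein_b}) "
                "outside [0, 1000]"
            )

    @property
    def pair(self) -> frozenset:
        return frozenset((self.protein_a, self.protein_b))


@dataclass(frozen=True)
class HicInteraction:
    """A chromatin interaction between two anchors (promoter-capture Hi-C)."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    kind: str  # promoter-promoter | promoter-other


def read_bed(path, format: str = "auto") -> List[Peak]:
    """Read a BED3/BED6/ENCODE-narrowPeak file into an ordered peak list.

    Coordinates are taken verbatim as 0-based half-open. With
    ``format="auto"`` the layout is inferred from the field count of the
    first data line (10 fields -> narrowPeak, >=4 -> bed6, 3 -> bed3).
    narrowPeak signalValue (7th field) is mapped to ``Peak.signal``.
    """
    if format not in _BED_FIELDS and format != "auto":
        raise ValueError(f"unknown BED format {format!r}")
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            fmt = format
            if fmt == "auto":
                fmt = (
                    "narrowPeak"
                    if len(fields) >= 10
                    else ("bed6" if len(fields) >= 4 else "bed3")
                )
            if len(fields) < _BED_FIELDS[fmt]:
                raise ValueError(
                    f"{path}: line {lineno}: expected >={_BED_FIELDS[fmt]} "
                    f"tab-separated fields for {fmt}, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            try:
                interval = GenomicInterval(fields[0], start, end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else ""
            signal = None
            if fmt == "narrowPeak":
                signal = float(fields[6])
            peaks.append(Peak(interval, name=name, signal=signal))
    return peaks


def write_bed(peaks: Sequence[Peak], path) -> None:
    """Write peaks as BED (4 columns when any name is set, else BED3)."""
    named = any(p.name for p in peaks)
    with open(path, "w") as fh:
        for p in peaks:
            row = [p.chrom, str(p.start), str(p.end)]
            if named:
                row.append(p.name or ".")
            fh.write("\t".join(row) + "\n")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_expression_table(path) -> ExpressionMatrix:
    """Read a gene-level expression TSV: gene_id, gene_length, then one
    column per sample. Values are interpreted as raw counts."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "gene_length"], path)
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise SchemaError(f"{path}: duplicate gene ids {dupes[:5]}")
    sample_cols = [c for c in df.columns if c not in ("gene_id", "gene_length")]
    values = df.set_index("gene_id")[sample_cols].astype(float)
    lengths = df.set_index("gene_id")["gene_length"].astype(int)
    return ExpressionMatrix(values=values, gene_lengths=lengths, unit="counts")


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene_length", matrix.gene_lengths)
    out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata: sample_id, library_type (polyA|total),
    is_single_cell (0|1)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, ["sample_id", "library_type", "is_single_cell"], path)
    bad = set(df["library_type"]) - {"polyA", "total"}
    if bad:
        raise SchemaError(
            f"{path}: library_type must be 'polyA' or 'total', found {sorted(bad)}"
        )
    df["is_single_cell"] = df["is_single_cell"].astype(int)
    return df.set_index("sample_id")


def read_ppi_table(path) -> List[PpiRecord]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["protein_a", "protein_b", "score"], path)
    return [
        PpiRecord(str(r.protein_a), str(r.protein_b), int(r.score))
        for r in df.itertuples(index=False)
    ]


def build_ppi_index(records: Iterable[PpiRecord]) -> Dict[frozenset, int]:
    """Unordered-pair -> best confidence score lookup."""
    index: Dict[frozenset, int] = {}
    for rec in records:
        index[rec.pair] = max(index.get(rec.pair, 0), rec.score)
    return index


def read_promoter_annotation(path) -> List[PromoterAnnotation]:
    """Read promoters (gene_id, chrom, tss, strand). The file carries
    1-based TSS positions; they are converted to 0-based on read."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "chrom", "tss", "strand"], path)
    out = []
    for r in df.itertuples(index=False):
        tss0 = int(r.tss) - 1
        if tss0 < 0:
            raise ValueError(f"{path}: 1-based TSS must be >= 1 ({r.gene_id})")
        if r.strand not in ("+", "-"):
            raise SchemaError(f"{path}: promoter strand must be + or - ({r.gene_id})")
        out.append(PromoterAnnotation(str(r.gene_id), str(r.chrom), tss0, str(r.strand)))
    return out


def write_promoter_annotation(promoters: Sequence[PromoterAnnotation], path) -> None:
    rows = [
        {"gene_id": p.gene_id, "chrom": p.chrom, "tss": p.tss + 1, "strand": p.strand}
        for p in promoters
    ]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def read_enhancer_associations(path) -> List[EnhancerAssociation]:
    """Read GeneHancer-style enhancer -> gene links
    (enhancer_id, chrom, start, end, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["enhancer_id", "chrom", "start", "end", "gene_id"], path)
    return [
        EnhancerAssociation(
            str(r.enhancer_id),
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            str(r.gene_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_enhancer_associations(assocs: Sequence[EnhancerAssociation], path) -> None:
    rows = [
        {
            "enhancer_id": a.enhancer_id,
            "chrom": a.interval.chrom,
            "start": a.interval.start,
            "end": a.interval.end,
            "gene_id": a.gene_id,
        }
        for a in assocs
    ]
    pd.DataFrame(
        rows, columns=["enhancer_id", "chrom", "start", "end", "gene_id"]
    ).to_csv(path, sep="\t", index=False)


def read_hic_interactions(path) -> List[HicInteraction]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df, ["chromA", "startA", "endA", "chromB", "startB", "endB", "kind"], path
    )
    return [
        HicInteraction(
            GenomicInterval(str(r.chromA), int(r.startA), int(r.endA)),
            GenomicInterval(str(r.chromB), int(r.startB), int(r.endB)),
            str(r.kind),
        )
        for r in df.itertuples(index=False)
    ]


def write_hic_interactions(interactions: Sequence[HicInteraction], path) -> None:
    rows = [
        {
            "chromA": h.anchor_a.chrom,
            "startA": h.anchor_a.start,
            "endA": h.anchor_a.end,
            "chromB": h.anchor_b.chrom,
            "startB": h.anchor_b.start,
            "endB": h.anchor_b.end,
            "kind": h.kind,
        }
        for h in interactions
    ]
    pd.DataFrame(
        rows, columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "kind"]
    ).to_csv(path, sep="\t", index=False)


def read_tf_list(path) -> List[str]:
    """One TF symbol per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        tfs = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not tfs:
        raise ValueError(f"{path}: empty TF list")
    return tfs


def load_chip_atlas(path) -> Dict[str, List[Peak]]:
    """Load a TF ChIP-seq peak atlas.

    Accepts either a directory of per-TF BED files (file stem = TF symbol)
    or a single >=4-column BED whose name field carries the TF symbol.
    """
    path = Path(path)
    atlas: Dict[str, List[Peak]] = {}
    if path.is_dir():
        for bed in sorted(path.iterdir()):
            if bed.suffix not in (".bed", ".narrowPeak"):
                continue
            atlas[bed.stem] = read_bed(bed)
    else:
        for peak in read_bed(path):
            if not peak.name:
                raise SchemaError(
                    f"{path}: single-file ChIP atlas requires a name column "
                    "carrying the TF symbol"
                )
            atlas.setdefault(peak.name, []).append(peak)
    return atlas


# ---------------------------------------------------------------------------
# Network tables


def write_network(grn: CoreGRN, out_dir) -> None:
    """Write edges.tsv / nodes.tsv / complexes.tsv under ``out_dir``.

    edges.tsv has one row per (edge, support peak); reading groups rows
    back into edges, so the round trip is lossless. All tables are sorted
    for reproducible diffs.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    edge_rows = []
    for e in grn.edges:
        for p in e.support_peaks:
            edge_rows.append(
                {
                    "source_tf": e.source_tf,
                    "target_tf": e.target_tf,
                    "region_type": e.region_type,
                    "region_id": e.region_id,
                    "peak_chrom": p.chrom,
                    "peak_start": p.start,
                    "peak_end": p.end,
                }
            )
    edges_df = pd.DataFrame(
        edge_rows,
        columns=[
            "source_tf",
            "target_tf",
            "region_type",
            "region_id",
            "peak_chrom",
            "peak_start",
            "peak_end",
        ],
    )
    if len(edges_df):
        edges_df = edges_df.sort_values(
            ["source_tf", "target_tf", "region_id", "peak_start"]
        )
    edges_df.to_csv(out_dir / "edges.tsv", sep="\t", index=False)

    node_rows = [
        {
            "tf": tf,
            "role": role,
            "jsd": grn.node_jsd.get(tf, float("nan")),
            "zscore": grn.node_zscore.get(tf, float("nan")),
        }
        for tf, role in grn.nodes.items()
    ]
    nodes_df = pd.DataFrame(node_rows, columns=["tf", "role", "jsd", "zscore"])
    if len(nodes_df):
        nodes_df = nodes_df.sort_values(["role", "tf"])
    nodes_df.to_csv(out_dir / "nodes.tsv", sep="\t", index=False, float_format="%.10g")

    cplx_rows = [
        {
            "region_id": c.region_id,
            "complex_id": c.complex_id,
            "members": ",".join(sorted(c.members)),
            "mode": c.mode,
        }
        for c in grn.complexes
    ]
    cplx_df = pd.DataFrame(
        cplx_rows, columns=["region_id", "complex_id", "members", "mode"]
    )
    if len(cplx_df):
        cplx_df = cplx_df.sort_values(["region_id", "complex_id"])
    cplx_df.to_csv(out_dir / "complexes.tsv", sep="\t", index=False)


def read_network(out_dir) -> CoreGRN:
    """Read a network written by :func:`write_network`."""
    out_dir = Path(out_dir)
    edges_df = pd.read_csv(out_dir / "edges.tsv", sep="\t")
    nodes_df = pd.read_csv(out_dir / "nodes.tsv", sep="\t")
    cplx_df = pd.read_csv(out_dir / "complexes.tsv", sep="\t")

    grouped: Dict[tuple, List[Peak]] = {}
    for r in edges_df.itertuples(index=False):
        key = (str(r.source_tf), str(r.target_tf), str(r.region_type), str(r.region_id))
        grouped.setdefault(key, []).append(
            Peak(GenomicInterval(str(r.peak_chrom), int(r.peak_start), int(r.peak_end)),
                 name=str(r.source_tf))
        )
    edges = [
        Edge(src, tgt, rtype, rid, tuple(peaks))
        for (src, tgt, rtype, rid), peaks in grouped.items()
    ]
    nodes = {str(r.tf): str(r.role) for r in nodes_df.itertuples(index=False)}
    node_jsd = {str(r.tf): float(r.jsd) for r in nodes_df.itertuples(index=False)}
    node_z = {str(r.tf): float(r.zscore) for r in nodes_df.itertuples(index=False)}
    complexes = [
        ComplexCall(
            str(r.region_id),
            str(r.complex_id),
            tuple(sorted(str(r.members).split(","))),
            str(r.mode),
        )
        for r in cplx_df.itertuples(index=False)
    ]
    return CoreGRN(
        nodes=nodes,
        edges=edges,
        complexes=complexes,
        node_jsd=node_jsd,
        node_zscore=node_z,
    )
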