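"""Active regulatory regions: promoters, enhancers, accessible sites.

A candidate TF's regulatory landscape is assembled in three layers, each
gated on phenotype-specific epigenomic evidence:

1. a promoter window around each annotated TSS (1500 bp upstream, 500 bp
   downstream, strand-aware) is *active* iff it overlaps at least one
   H3K4me3 peak;
2. enhancers linked to a TF with an active promoter are *active* iff they
   overlap at least one H3K27ac peak, and are truncated to the
   intersections with those peaks (inactive enhancers are dropped);
3. DNase (accessibility) peaks intersected with the active regions define
   the accessible sites — only these can support regulatory edges.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .intervals import GenomicInterval, Peak, overlap_length


@dataclass(frozen=True)
class PromoterAnnotation:
    """A transcription start site (0-based position of the TSS base)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"promoter strand must be + or - ({self.gene_id})")


@dataclass(frozen=True)
class EnhancerAssociation:
    """A GeneHancer-style enhancer interval linked to a target gene."""

    enhancer_id: str
    interval: GenomicInterval
    gene_id: str


@dataclass(frozen=True)
class RegulatoryRegion:
    """An active promoter or truncated enhancer owned by a TF.

    ``intervals`` holds one window for a promoter or >=1 peak-truncated
    pieces for an enhancer; ``accessible_sites`` are the DNase
    intersections within those intervals.
    """

    owner_tf: str
    region_type: str  # promoter | enhancer
    region_id: str
    intervals: Tuple[GenomicInterval, ...]
    active: bool = False
    accessible_sites: Tuple[GenomicInterval, ...] = field(default_factory=tuple)


def build_promoter_window(
    p: PromoterAnnotation, up: int = 1500, down: int = 500
) -> GenomicInterval:
    """Strand-aware promoter window of width up+down around the TSS.

    + strand: [tss − up, tss + down); − strand: [tss − down + 1,
    tss + up + 1), so the TSS base sits among the downstream bases on both
    strands. The start is clipped at 0 (width reduced accordingly).
    """
    if up <= 0 or down <= 0:
        raise ValueError("promoter window extents must be positive")
    if p.strand == "+":
        start, end = p.tss - up, p.tss + down
    else:
        start, end = p.tss - down + 1, p.tss + up + 1
    return GenomicInterval(p.chrom, max(0, start), end, strand=p.strand)


def _peaks_by_chrom(peaks: Iterable[Peak]) -> Dict[str, List[Peak]]:
    by_chrom: Dict[str, List[Peak]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append(p)
    return by_chrom


def _overlapping_peaks(iv: GenomicInterval, by_chrom: Dict[str, List[Peak]]) -> List[Peak]:
    return [
        p for p in by_chrom.get(iv.chrom, ())
        if overlap_length(iv, p.interval) >= 1
    ]


def promoter_regions(
    promoters: Sequence[PromoterAnnotation],
    tfs: Iterable[str],
    up: int = 1500,
    down: int = 500,
) -> List[RegulatoryRegion]:
    """One (inactive) promoter region per annotated TSS of each TF. Genes
    with multiple annotated promoters get one region per TSS, numbered in
    annotation order."""
    wanted = set(tfs)
    counter: Dict[str, int] = defaultdict(int)
    regions = []
    for p in promoters:
        if p.gene_id not in wanted:
            continue
        counter[p.gene_id] += 1
        regions.append(
            RegulatoryRegion(
                owner_tf=p.gene_id,
                region_type="promoter",
                region_id=f"{p.gene_id}:P{counter[p.gene_id]}",
                intervals=(build_promoter_window(p, up=up, down=down),),
            )
        )
    return regions


def call_active_promoters(
    promoter_windows: Sequence[RegulatoryRegion], h3k4me3: Sequence[Peak]
) -> List[RegulatoryRegion]:
    """Flag each promoter region active iff it overlaps (>=1 bp) at least
    one H3K4me3 peak."""
    by_chrom = _peaks_by_chrom(h3k4me3)
    out = []
    for r in promoter_windows:
        active = any(
            _overlapping_peaks(iv, by_chrom) for iv in r.intervals
        )
        out.append(replace(r, active=active))
    return out


def active_tfs(regions: Sequence[RegulatoryRegion]) -> Set[str]:
    """TFs with at least one active promoter window (a TF with several
    annotated TSSs is active if ANY window is active)."""
    return {r.owner_tf for r in regions if r.region_type == "promoter" and r.active}


def call_active_enhancers(
    associations: Sequence[EnhancerAssociation],
    active_tf_set: Iterable[str],
    h3k27ac: Sequence[Peak],
) -> List[RegulatoryRegion]:
    """Active, peak-truncated enhancers of TFs with active promoters.

    Only associations of active-promoter TFs are evaluated. An enhancer is
    active iff it overlaps >=1 H3K27ac peak; its intervals become the
    intersections of the annotated interval with each overlapping peak
    (truncation never extends beyond the annotation). Inactive enhancers
    are not emitted.
    """
    wanted = set(active_tf_set)
    by_chrom = _peaks_by_chrom(h3k27ac)
    out = []
    for a in associations:
        if a.gene_id not in wanted:
            continue
        pieces = []
        for p in _overlapping_peaks(a.interval, by_chrom):
            piece = a.interval.intersect(p.interval)
            if piece is not None:
                pieces.append(piece)
        if not pieces:
            continue
        out.append(
            RegulatoryRegion(
                owner_tf=a.gene_id,
                region_type="enhancer",
                region_id=a.enhancer_id,
                intervals=tuple(sorted(pieces)),
                active=True,
            )
        )
    return out


def compute_accessible_sites(
    regions: Sequence[RegulatoryRegion], dnase: Sequence[Peak]
) -> List[RegulatoryRegion]:
    """Intersect DNase peaks with each active region's intervals to define
    its accessible regulatory sites. Regions with no accessible site are
    retained but can support no edges downstream."""
    by_chrom = _peaks_by_chrom(dnase)
    out = []
    for r in regions:
        if not r.active:
            out.append(r)
            continue
        sites = []
        for iv in r.intervals:
            for p in _overlapping_peaks(iv, by_chrom):
                piece = iv.intersect(p.interval)
                if piece is not None:
                    sites.append(piece)
        out.append(replace(r, accessible_sites=tuple(sorted(sites))))
    return out


def build_regions(
    promoters: Sequence[PromoterAnnotation],
    associations: Sequence[EnhancerAssociation],
    candidate_tfs: Iterable[str],
    h3k4me3: Sequence[Peak],
    h3k27ac: Sequence[Peak],
    dnase: Sequence[Peak],
    up: int = 1500,
    down: int = 500,
    dnase_required: bool = True,
) -> List[RegulatoryRegion]:
    """Full region layer for a candidate TF set: active promoters, active
    truncated enhancers, accessible sites.

    With ``dnase_required=False`` (for datasets lacking accessibility
    data) every active region is treated as fully accessible: its own
    intervals become the accessible sites.
    """
    candidates = set(candidate_tfs)
    proms = call_active_promoters(
        promoter_regions(promoters, candidates, up=up, down=down), h3k4me3
    )
    act = active_tfs(proms)
    enhs = call_active_enhancers(associations, act, h3k27ac)
    active_regions = [r for r in proms if r.active] + enhs
    if dnase_required:
        return compute_accessible_sites(active_regions, dnase)
    return [replace(r, accessible_sites=r.intervals) for r in active_regions]
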