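"""Core GRN assembly from TF ChIP-seq evidence.

The scaffold is the set of directed edges source → target implied by a
source-TF ChIP-seq peak overlapping an accessible site in an active
regulatory region of the target. The scaffold is then pruned so that
every retained co-factor both regulates and is regulated by at least one
identity TF (iterated to a fixpoint — a single pass can strand co-factors
whose only qualifying partners were themselves removed).

Within one regulatory region, co-bound TFs are partitioned into
cooperative complexes (pairs whose peaks reciprocally overlap by at least
``ro_min`` AND that have a protein–protein interaction with confidence
> ``ppi_min`` are joined; connected components of size >= 2 form a
complex), competitive TFs (peaks overlap another bound TF's peaks by
>= 1 bp but no complex membership), and independent TFs (no peak overlap
with any other bound TF).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .intervals import GenomicInterval, Peak, overlap_length, reciprocal_overlap
from .regions import RegulatoryRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Edge:
    """A directed regulatory interaction supported by >=1 ChIP peak in one
    region of the target TF."""

    source_tf: str
    target_tf: str
    region_type: str
    region_id: str
    support_peaks: Tuple[Peak, ...]

    @property
    def key(self) -> Tuple[str, str, str, str]:
        return (self.source_tf, self.target_tf, self.region_type, self.region_id)


@dataclass(frozen=True)
class ComplexCall:
    region_id: str
    complex_id: str
    members: Tuple[str, ...]
    mode: str  # cooperative | competitive


@dataclass
class CoreGRN:
    nodes: Dict[str, str]  # tf -> role (identity | cofactor)
    edges: List[Edge]
    complexes: List[ComplexCall] = field(default_factory=list)
    node_jsd: Dict[str, float] = field(default_factory=dict)
    node_zscore: Dict[str, float] = field(default_factory=dict)

    def edge_pairs(self) -> Set[Tuple[str, str]]:
        """Deduplicated directed (source, target) pairs."""
        return {(e.source_tf, e.target_tf) for e in self.edges}


@dataclass
class OverlapThresholdCalibration:
    positive_overlaps: List[float]
    negative_overlaps: List[float]
    threshold: float


def build_scaffold(
    regions: Sequence[RegulatoryRegion],
    chip_atlas: Mapping[str, Sequence[Peak]],
    candidates: Iterable[str],
) -> List[Edge]:
    """Emit edge source → target whenever a candidate source TF's ChIP
    peak overlaps (>=1 bp) an accessible site of an active region of a
    candidate target TF. Evidence for the same (source, target, region)
    collapses to one edge retaining all support peaks; self-edges
    (autoregulation) are permitted.
    """
    candidate_set = sorted(set(candidates))
    for tf in candidate_set:
        if tf not in chip_atlas:
            logger.warning("candidate TF %s has no ChIP-seq peaks in the atlas", tf)

    support: Dict[Tuple[str, str, str, str], List[Peak]] = defaultdict(list)
    for region in regions:
        if region.owner_tf not in candidate_set or not region.active:
            continue
        if not region.accessible_sites:
            continue
        for source in candidate_set:
            for peak in chip_atlas.get(source, ()):
                if any(
                    overlap_length(peak.interval, site) >= 1
                    for site in region.accessible_sites
                ):
                    key = (source, region.owner_tf, region.region_type, region.region_id)
                    support[key].append(peak)
    return [
        Edge(src, tgt, rtype, rid, tuple(sorted(peaks)))
        for (src, tgt, rtype, rid), peaks in sorted(support.items())
    ]


def filter_cofactor_connectivity(
    edges: Sequence[Edge],
    identity_tfs: Iterable[str],
    cofactors: Iterable[str],
) -> CoreGRN:
    """Prune co-factors (to a fixpoint) that do not both regulate and get
    regulated by at least one identity TF; identity TFs are never removed.
    The result is independent of edge input order."""
    identity = set(identity_tfs)
    remaining = set(cofactors) - identity
    kept_edges = list(edges)
    while True:
        out_to_id: Dict[str, bool] = defaultdict(bool)
        in_from_id: Dict[str, bool] = defaultdict(bool)
        for e in kept_edges:
            if e.target_tf in identity:
                out_to_id[e.source_tf] = True
            if e.source_tf in identity:
                in_from_id[e.target_tf] = True
        drop = {
            cf for cf in remaining if not (out_to_id[cf] and in_from_id[cf])
        }
        if not drop:
            break
        remaining -= drop
        kept_edges = [
            e for e in kept_edges
            if e.source_tf not in drop and e.target_tf not in drop
        ]
    nodes = {tf: "identity" for tf in sorted(identity)}
    nodes.update({tf: "cofactor" for tf in sorted(remaining)})
    kept_edges = [
        e for e in kept_edges if e.source_tf in nodes and e.target_tf in nodes
    ]
    return CoreGRN(nodes=nodes, edges=sorted(kept_edges, key=lambda e: e.key))


@dataclass
class RegionBindingClasses:
    """Disjoint cover of the TFs bound in one region."""

    cooperative: List[Tuple[str, ...]]  # components of size >= 2
    competitive: List[str]
    independent: List[str]


def classify_binding(
    region: RegulatoryRegion,
    bound: Mapping[str, Sequence[Peak]],
    ppi: Mapping[FrozenSet[str], int],
    ppi_min: int = 800,
    ro_min: float = 0.62,
) -> RegionBindingClasses:
    """Partition the TFs bound in ``region`` into cooperative complexes,
    competitive TFs, and independent TFs.

    A pair is joined iff some peak of each reciprocally overlaps by
    >= ``ro_min`` AND a PPI with score strictly > ``ppi_min`` exists;
    connected components of size >= 2 are cooperative. TFs whose peaks
    merely overlap (>= 1 bp) another bound TF's peaks without joining a
    component are competitive; the rest are independent.
    """
    tfs = sorted(bound)
    g = nx.Graph()
    g.add_nodes_from(tfs)
    touches: Dict[str, bool] = {tf: False for tf in tfs}
    for i, u in enumerate(tfs):
        for v in tfs[i + 1:]:
            best_ro = 0.0
            any_overlap = False
            for pu in bound[u]:
                for pv in bound[v]:
                    if overlap_length(pu.interval, pv.interval) >= 1:
                        any_overlap = True
                        best_ro = max(best_ro, reciprocal_overlap(pu.interval, pv.interval))
            if any_overlap:
                touches[u] = touches[v] = True
            if best_ro >= ro_min and ppi.get(frozenset((u, v)), 0) > ppi_min:
                g.add_edge(u, v)
    cooperative = sorted(
        tuple(sorted(comp)) for comp in nx.connected_components(g) if len(comp) >= 2
    )
    in_complex = {tf for comp in cooperative for tf in comp}
    competitive = [tf for tf in tfs if tf not in in_complex and touches[tf]]
    independent = [tf for tf in tfs if tf not in in_complex and not touches[tf]]
    return RegionBindingClasses(cooperative, competitive, independent)


def assign_complexes(
    grn: CoreGRN,
    regions: Sequence[RegulatoryRegion],
    ppi: Mapping[FrozenSet[str], int],
    ppi_min: int = 800,
    ro_min: float = 0.62,
) -> CoreGRN:
    """Run cooperative/competitive classification in every region that
    supports at least one retained edge, and attach the calls to the GRN.

    A TF pair may be cooperative in one region and competitive in another;
    classification is strictly per-region. Cooperative components are
    recorded as complexes; competitive TFs as singleton calls.
    """
    region_index = {r.region_id: r for r in regions}
    bound_by_region: Dict[str, Dict[str, List[Peak]]] = defaultdict(dict)
    for e in grn.edges:
        bucket = bound_by_region[e.region_id].setdefault(e.source_tf, [])
        bucket.extend(e.support_peaks)
    complexes: List[ComplexCall] = []
    for region_id in sorted(bound_by_region):
        region = region_index.get(region_id)
        if region is None:
            continue
        classes = classify_binding(
            region, bound_by_region[region_id], ppi, ppi_min=ppi_min, ro_min=ro_min
        )
        for i, comp in enumerate(classes.cooperative, start=1):
            complexes.append(
                ComplexCall(region_id, f"{region_id}:c{i}", comp, "cooperative")
            )
        for tf in classes.competitive:
            complexes.append(
                ComplexCall(region_id, f"{region_id}:x:{tf}", (tf,), "competitive")
            )
    grn.complexes = complexes
    return grn


# ---------------------------------------------------------------------------
# Reciprocal-overlap threshold calibration


def pair_overlap_values(
    pairs: Sequence[Tuple[str, str]],
    chip_atlas_multi: Mapping[str, Mapping[str, Sequence[Peak]]],
) -> List[float]:
    """For each labelled TF pair and each cell type where both TFs have
    peaks, the maximum reciprocal overlap over all their peak pairs.
    Values are pooled across cell types."""
    values: List[float] = []
    for u, v in pairs:
        for cell_type in sorted(chip_atlas_multi):
            atlas = chip_atlas_multi[cell_type]
            if u not in atlas or v not in atlas:
                continue
            best = 0.0
            for pu in atlas[u]:
                for pv in atlas[v]:
                    best = max(best, reciprocal_overlap(pu.interval, pv.interval))
            values.append(best)
    return values


def calibrate_overlap_threshold(
    positive_overlaps: Sequence[float],
    negative_overlaps: Sequence[float],
) -> OverlapThresholdCalibration:
    """Find the smallest observed positive overlap value above which
    interacting pairs dominate non-interacting ones.

    The threshold is the smallest value t among the positive overlaps such
    that for every observed overlap t' >= t (from either class), the
    fraction of positives >= t' strictly exceeds the fraction of
    negatives >= t'. Raises when no such t exists (classes not separable).
    """
    pos = np.asarray(sorted(positive_overlaps), dtype=float)
    neg = np.asarray(sorted(negative_overlaps), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both labelled overlap samples must be nonempty")
    observed = np.unique(np.concatenate([pos, neg]))

    def frac_ge(arr: np.ndarray, t: float) -> float:
        return float((arr >= t).sum()) / arr.size

    for t in np.unique(pos):
        if all(
            frac_ge(pos, tp) > frac_ge(neg, tp) for tp in observed[observed >= t]
        ):
            return OverlapThresholdCalibration(
                positive_overlaps=list(pos),
                negative_overlaps=list(neg),
                threshold=float(t),
            )
    raise ValueError(
        "classes not separable above any threshold: positive and negative "
        "overlap distributions do not diverge"
    )


def calibrate_from_atlas(
    positive_pairs: Sequence[Tuple[str, str]],
    negative_pairs: Sequence[Tuple[str, str]],
    chip_atlas_multi: Mapping[str, Mapping[str, Sequence[Peak]]],
) -> OverlapThresholdCalibration:
    """Calibrate the reciprocal-overlap threshold from labelled TF pairs
    and a multi-cell-type ChIP atlas."""
    return calibrate_overlap_threshold(
        pair_overlap_values(positive_pairs, chip_atlas_multi),
        pair_overlap_values(negative_pairs, chip_atlas_multi),
    )
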