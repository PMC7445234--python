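"""Validation of reconstructed networks.

Two checks mirror how core-GRN reconstructions are benchmarked:

* ``edge_f1`` — precision/recall/F1 of a predicted edge set against a
  gold-standard edge set (e.g. cell-type-specific TF ChIP-seq edges
  mapped to promoters). Methods that output undirected pairs are scored
  with both orientations allowed.
* ``validate_enhancer_assignments`` — the percentage of a network's
  enhancer → TF assignments supported by promoter-capture Hi-C: an
  assignment counts as validated when one Hi-C anchor overlaps the
  enhancer and the other overlaps that same TF's promoter window.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, Set, Tuple

from .intervals import GenomicInterval, overlap_length


def edge_f1(
    predicted: Iterable[Tuple[str, str]],
    gold: Iterable[Tuple[str, str]],
    directed_prediction: bool = True,
) -> Tuple[float, float, float]:
    """Precision, recall and F1 of a predicted directed edge set against a
    gold standard.

    With ``directed_prediction=False`` a predicted pair matches a gold
    edge in either orientation (for methods that do not resolve edge
    direction). F1 = 2PR/(P+R), defined as 0 when P + R = 0.
    """
    gold_set: Set[Tuple[str, str]] = set(gold)
    if directed_prediction:
        pred_set: Set[Tuple[str, str]] = set(predicted)
        tp = len(pred_set & gold_set)
        fn = len(gold_set - pred_set)
        n_pred = len(pred_set)
    else:
        # canonicalize predicted pairs as unordered; both orientations match
        pred_pairs = {tuple(sorted((a, b))) for a, b in predicted}
        tp = 0
        covered: Set[Tuple[str, str]] = set()
        for a, b in pred_pairs:
            hits = {e for e in ((a, b), (b, a)) if e in gold_set}
            if hits:
                tp += 1
                covered |= hits
        fn = len(gold_set - covered)
        n_pred = len(pred_pairs)
    precision = tp / n_pred if n_pred else 0.0
    recall = (len(gold_set) - fn) / len(gold_set) if gold_set else 0.0
    denom = precision + recall
    f1 = 2 * precision * recall / denom if denom else 0.0
    return precision, recall, f1


def validate_enhancer_assignments(
    network_regions: Mapping[str, Sequence[GenomicInterval]],
    promoters: Mapping[str, Sequence[GenomicInterval]],
    hic: Sequence,
) -> float:
    """Percentage of enhancer → TF assignments supported by Hi-C.

    ``network_regions`` maps each network TF to the raw (untruncated)
    intervals of its active enhancers — Hi-C anchors are restriction-
    fragment-scale, so matching against peak-truncated pieces would
    produce spurious misses. An assignment (enhancer E of TF Y) is
    validated iff some interaction has one anchor overlapping E (>=1 bp)
    and the other anchor overlapping one of Y's promoter windows.
    """
    total = sum(len(enhs) for enhs in network_regions.values())
    if total == 0:
        raise ValueError("nothing to validate: no enhancer assignments")
    validated = 0
    for tf in sorted(network_regions):
        proms = promoters.get(tf, ())
        for enh in network_regions[tf]:
            hit = False
            for inter in hic:
                for e_anchor, p_anchor in (
                    (inter.anchor_a, inter.anchor_b),
                    (inter.anchor_b, inter.anchor_a),
                ):
                    if overlap_length(enh, e_anchor) >= 1 and any(
                        overlap_length(pw, p_anchor) >= 1 for pw in proms
                    ):
                        hit = True
                        break
                if hit:
                    break
            validated += hit
    return 100.0 * validated / total
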