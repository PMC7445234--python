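import random

import numpy as np
import pytest

from moni.intervals import GenomicInterval, Peak
from moni.network import (
    Edge,
    build_scaffold,
    calibrate_from_atlas,
    calibrate_overlap_threshold,
    classify_binding,
    filter_cofactor_connectivity,
    pair_overlap_values,
)
from moni.regions import RegulatoryRegion


def peak(start, end, name="", chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), name=name)


def region(owner, rid, lo, hi, sites=None, rtype="promoter"):
    iv = GenomicInterval("chr1", lo, hi)
    return RegulatoryRegion(
        owner_tf=owner,
        region_type=rtype,
        region_id=rid,
        intervals=(iv,),
        active=True,
        accessible_sites=tuple(sites) if sites else (),
    )


def edge(s, t, rid="r"):
    return Edge(s, t, "promoter", rid, (peak(0, 100, name=s),))


class TestBuildScaffold:
    def test_peak_over_site_makes_edge(self):
        site = GenomicInterval("chr1", 10000, 10500)
        regs = [region("Y", "Y:P1", 8500, 10500, sites=[site])]
        atlas = {"X": [peak(10050, 10250, "X")], "Y": []}
        edges = build_scaffold(regs, atlas, ["X", "Y"])
        assert [(e.source_tf, e.target_tf, e.region_id) for e in edges] == [
            ("X", "Y", "Y:P1")
        ]

    def test_no_accessible_site_no_edge(self):
        regs = [region("Y", "Y:P1", 8500, 10500, sites=None)]
        atlas = {"X": [peak(9000, 9200, "X")]}
        assert build_scaffold(regs, atlas, ["X", "Y"]) == []

    def test_peak_outside_truncated_enhancer_no_edge(self):
        # peak overlaps the raw enhancer span but not its truncated site
        site = GenomicInterval("chr1", 1500, 2000)
        regs = [region("Y", "E1", 1500, 2000, sites=[site], rtype="enhancer")]
        atlas = {"X": [peak(1000, 1400, "X")]}
        assert build_scaffold(regs, atlas, ["X", "Y"]) == []

    def test_duplicate_evidence_collapses(self):
        site = GenomicInterval("chr1", 100, 600)
        regs = [region("Y", "Y:P1", 0, 600, sites=[site])]
        atlas = {"X": [peak(100, 300, "X"), peak(350, 500, "X")]}
        (e,) = build_scaffold(regs, atlas, ["X", "Y"])
        assert len(e.support_peaks) == 2

    def test_self_edge_permitted(self):
        site = GenomicInterval("chr1", 100, 600)
        regs = [region("X", "X:P1", 0, 600, sites=[site])]
        atlas = {"X": [peak(200, 400, "X")]}
        (e,) = build_scaffold(regs, atlas, ["X"])
        assert (e.source_tf, e.target_tf) == ("X", "X")

    def test_missing_atlas_tf_logged(self, caplog):
        regs = [region("Y", "Y:P1", 0, 600,
                       sites=[GenomicInterval("chr1", 100, 600)])]
        with caplog.at_level("WARNING", logger="moni.network"):
            build_scaffold(regs, {}, ["X", "Y"])
        assert "X" in caplog.text


def connectivity_oracle(edges, identity, cofactors):
    """Exhaustive delete-until-stable: remove one failing co-factor at a
    time (in arbitrary order) until none fails. The fixpoint is unique."""
    identity = set(identity)
    kept = set(cofactors) | identity
    es = {(e.source_tf, e.target_tf) for e in edges}
    changed = True
    while changed:
        changed = False
        for cf in sorted(kept - identity):
            out_ok = any(s == cf and t in identity for s, t in es)
            in_ok = any(t == cf and s in identity for s, t in es)
            if not (out_ok and in_ok):
                kept.discard(cf)
                es = {(s, t) for s, t in es if s != cf and t != cf}
                changed = True
                break
    return kept, es


class TestCofactorConnectivity:
    def test_cofactor_regulating_only_cofactors_removed(self):
        edges = [edge("B", "A"), edge("A", "B"), edge("C", "B")]
        grn = filter_cofactor_connectivity(edges, ["A"], ["B", "C"])
        assert set(grn.nodes) == {"A", "B"}
        assert {(e.source_tf, e.target_tf) for e in grn.edges} == {
            ("B", "A"),
            ("A", "B"),
        }

    def test_unregulated_cofactor_removed(self):
        grn = filter_cofactor_connectivity([edge("C", "A")], ["A"], ["C"])
        assert set(grn.nodes) == {"A"}
        assert grn.edges == []

    def test_no_cofactors_identity_unchanged(self):
        edges = [edge("A", "B"), edge("B", "A")]
        grn = filter_cofactor_connectivity(edges, ["A", "B"], [])
        assert len(grn.edges) == 2

    def test_partial_failure_removes_only_failing_cofactor(self):
        # C lacks an incoming identity edge -> removed; D has both
        edges = [edge("C", "A"), edge("A", "D"), edge("D", "A")]
        grn = filter_cofactor_connectivity(edges, ["A"], ["C", "D"])
        assert set(grn.nodes) == {"A", "D"}

    def _random_case(self, rng):
        n = rng.integers(4, 30)
        tfs = [f"T{i}" for i in range(n)]
        identity = tfs[: max(1, n // 4)]
        cofactors = tfs[len(identity):]
        edges = []
        for i in range(rng.integers(3, 60)):
            s, t = rng.choice(tfs, 2)
            edges.append(edge(str(s), str(t), rid=f"r{i}"))
        return edges, identity, cofactors

    def test_agrees_with_oracle_idempotent_order_invariant(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            edges, identity, cofactors = self._random_case(rng)
            grn = filter_cofactor_connectivity(edges, identity, cofactors)
            kept, es = connectivity_oracle(edges, identity, cofactors)
            assert set(grn.nodes) == kept
            assert {(e.source_tf, e.target_tf) for e in grn.edges} == es
            # idempotence
            again = filter_cofactor_connectivity(
                grn.edges, identity, set(grn.nodes) - set(identity)
            )
            assert {e.key for e in again.edges} == {e.key for e in grn.edges}
            # input-order invariance
            shuffled = list(edges)
            random.Random(0).shuffle(shuffled)
            grn2 = filter_cofactor_connectivity(shuffled, identity, cofactors)
            assert {e.key for e in grn2.edges} == {e.key for e in grn.edges}
            assert grn2.nodes == grn.nodes


def union_find_oracle(tfs, qualifying_pairs):
    parent = {t: t for t in tfs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in qualifying_pairs:
        parent[find(u)] = find(v)
    comps = {}
    for t in tfs:
        comps.setdefault(find(t), set()).add(t)
    return {frozenset(c) for c in comps.values() if len(c) >= 2}


class TestClassifyBinding:
    def _region(self):
        return region("Y", "Y:P1", 0, 1000,
                      sites=[GenomicInterval("chr1", 0, 1000)])

    def test_cooperative_pair(self):
        bound = {"U": [peak(100, 300, "U")], "V": [peak(100, 300, "V")]}
        ppi = {frozenset(("U", "V")): 850}
        out = classify_binding(self._region(), bound, ppi)
        assert out.cooperative == [("U", "V")]
        assert out.competitive == [] and out.independent == []

    def test_low_reciprocal_overlap_is_competitive(self):
        # 50% reciprocal overlap fails the 62% rule despite strong PPI
        bound = {"U": [peak(100, 300, "U")], "V": [peak(200, 400, "V")]}
        ppi = {frozenset(("U", "V")): 999}
        out = classify_binding(self._region(), bound, ppi)
        assert out.cooperative == []
        assert set(out.competitive) == {"U", "V"}

    def test_ppi_cut_is_strict(self):
        bound = {"U": [peak(100, 300, "U")], "V": [peak(100, 300, "V")]}
        out = classify_binding(self._region(), bound,
                               {frozenset(("U", "V")): 800})
        assert out.cooperative == []  # exactly 800 fails "> 800"

    def test_transitive_component(self):
        # U-V and V-W qualify; U-W overlap only 50% -> one complex {U,V,W}
        bound = {
            "U": [peak(100, 200, "U")],
            "V": [peak(110, 210, "V")],  # ro(U,V) = 0.9
            "W": [peak(140, 240, "W")],  # ro(V,W) = 0.7, ro(U,W) = 0.6
        }
        ppi = {
            frozenset(("U", "V")): 850,
            frozenset(("V", "W")): 900,
            frozenset(("U", "W")): 900,
        }
        out = classify_binding(self._region(), bound, ppi, ro_min=0.62)
        assert out.cooperative == [("U", "V", "W")]

    def test_disjoint_peaks_are_independent(self):
        bound = {"U": [peak(0, 100, "U")], "V": [peak(500, 600, "V")]}
        out = classify_binding(self._region(), bound, {})
        assert out.independent == ["U", "V"]

    def test_partition_is_disjoint_cover(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            tfs = [f"T{i}" for i in range(int(rng.integers(2, 7)))]
            bound = {
                t: [peak(int(s), int(s) + int(rng.integers(50, 300)), t)
                    for s in rng.integers(0, 700, rng.integers(1, 3))]
                for t in tfs
            }
            ppi = {
                frozenset((u, v)): int(rng.integers(0, 1001))
                for i, u in enumerate(tfs)
                for v in tfs[i + 1:]
                if rng.random() < 0.6
            }
            out = classify_binding(self._region(), bound, ppi)
            labelled = (
                [t for c in out.cooperative for t in c]
                + out.competitive
                + out.independent
            )
            assert sorted(labelled) == sorted(tfs)

    def test_agrees_with_union_find(self):
        """Component detection matches an exhaustive union-find over all
        qualifying pairs on random regions with <= 6 bound TFs."""
        from moni.intervals import reciprocal_overlap

        rng = np.random.default_rng(8)
        for _ in range(100):
            tfs = [f"T{i}" for i in range(int(rng.integers(2, 7)))]
            bound = {
                t: [peak(int(s), int(s) + int(rng.integers(50, 400)), t)
                    for s in rng.integers(0, 600, rng.integers(1, 4))]
                for t in tfs
            }
            ppi = {
                frozenset((u, v)): int(rng.integers(0, 1001))
                for i, u in enumerate(tfs)
                for v in tfs[i + 1:]
            }
            qualifying = []
            for i, u in enumerate(tfs):
                for v in tfs[i + 1:]:
                    ro = max(
                        reciprocal_overlap(pu.interval, pv.interval)
                        for pu in bound[u]
                        for pv in bound[v]
                    )
                    if ro >= 0.62 and ppi[frozenset((u, v))] > 800:
                        qualifying.append((u, v))
            expected = union_find_oracle(tfs, qualifying)
            out = classify_binding(self._region(), bound, ppi)
            assert {frozenset(c) for c in out.cooperative} == expected


class TestCalibration:
    def test_separated_classes(self):
        cal = calibrate_overlap_threshold([0.7, 0.8, 0.9], [0.1, 0.2, 0.3])
        assert cal.threshold == pytest.approx(0.7)

    def test_perfect_separation(self):
        cal = calibrate_overlap_threshold([1.0, 1.0], [0.0, 0.0])
        assert cal.threshold == pytest.approx(1.0)

    def test_identical_distributions_raise(self):
        with pytest.raises(ValueError, match="not separable"):
            calibrate_overlap_threshold([0.2, 0.5], [0.2, 0.5])

    def test_threshold_within_observed_range(self):
        rng = np.random.default_rng(2)
        pos = (rng.beta(6, 2, 50)).tolist()
        neg = (rng.beta(2, 6, 50)).tolist()
        cal = calibrate_overlap_threshold(pos, neg)
        assert min(pos + neg) <= cal.threshold <= max(pos + neg)

    def test_pair_overlaps_pool_max_per_cell_type(self):
        atlas = {
            "cellA": {"U": [peak(0, 100, "U")], "V": [peak(0, 100, "V")]},
            "cellB": {"U": [peak(0, 100, "U")], "V": [peak(50, 150, "V")]},
            "cellC": {"U": [peak(0, 100, "U")]},  # V missing: skipped
        }
        vals = pair_overlap_values([("U", "V")], atlas)
        assert vals == pytest.approx([1.0, 0.5])

    def test_calibrate_from_atlas(self):
        atlas = {
            "cell": {
                "U": [peak(0, 100, "U")],
                "V": [peak(0, 100, "V")],
                "X": [peak(500, 600, "X")],
                "Y": [peak(900, 1000, "Y")],
            }
        }
        cal = calibrate_from_atlas([("U", "V")], [("X", "Y")], atlas)
        assert cal.threshold == pytest.approx(1.0)
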