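"""Synthetic multi-omics bundle with a planted ground-truth core GRN.

The generator emulates, at desk scale, every input the pipeline consumes:
an expression compendium (background atlas + query), promoter annotation,
GeneHancer-style enhancer links, H3K4me3 / H3K27ac / DNase peak sets, a
TF ChIP-seq atlas, a PPI table, promoter-capture Hi-C interactions, and a
gold-standard edge list — all generated consistently around a planted
network so that, with zero noise, the full pipeline recovers the planted
edges, identity TFs and cooperative complexes exactly.

Layout: one chromosome, one gene per fixed-width slot so that regulatory
regions of different genes never overlap. Identity TFs are expressed only
in the query; co-factors in the query (strongly) and a small minority of
background samples (weakly), which puts their query JSD at rank 1 of the
background null; all other genes are expressed i.i.d. across samples, so
background samples are mutually uncorrelated and survive decorrelation.

Noise dials (all default 0 so the recovery tests are exact):
``peak_dropout_rate`` independently deletes H3K27ac peaks (enhancer
evidence), ``decoy_edge_rate`` adds spurious ChIP peaks for non-planted
TF pairs, ``expression_noise_sd`` applies multiplicative log-normal noise
to nonzero counts, and ``hic_drop_rate`` thins the Hi-C interactions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .intervals import GenomicInterval, Peak
from .regions import EnhancerAssociation, PromoterAnnotation, build_promoter_window

CHROM = "chr1"


@dataclass
class NoiseConfig:
    peak_dropout_rate: float = 0.0  # applied to H3K27ac peaks
    decoy_edge_rate: float = 0.0
    expression_noise_sd: float = 0.0
    hic_drop_rate: float = 0.0


@dataclass
class FixtureConfig:
    n_tfs: int = 200
    n_other_genes: int = 100
    n_background: int = 50
    n_identity: int = 10
    n_cofactors: int = 5
    n_complex_regions: int = 3
    n_competitive_regions: int = 2
    gene_spacing: int = 100_000
    edge_prob: float = 0.15
    noise: NoiseConfig = field(default_factory=NoiseConfig)


@dataclass
class PlantedTruth:
    seed: int
    genome: Dict[str, int]
    tf_universe: List[str]
    identity_tfs: List[str]
    cofactors: List[str]
    edges: List[Tuple[str, str, str]]  # (source, target, region_id)
    enhancer_map: Dict[str, List[str]]  # tf -> enhancer ids (planted)
    active_enhancers: List[str]  # enhancer ids surviving H3K27ac dropout
    complex_map: Dict[str, List[str]]  # region_id -> cooperative members
    competitive_map: Dict[str, List[str]]  # region_id -> competitive pair

    def edge_pairs(self) -> set:
        return {(s, t) for s, t, _ in self.edges}


def _check_config(cfg: FixtureConfig) -> None:
    if cfg.n_identity + cfg.n_cofactors > cfg.n_tfs:
        raise ValueError("more planted roles than TFs")
    if cfg.n_cofactors > 0 and cfg.n_identity == 0:
        raise ValueError(
            "cannot satisfy co-factor connectivity without identity TFs"
        )
    if cfg.n_complex_regions + cfg.n_competitive_regions > cfg.n_identity:
        raise ValueError("not enough identity targets for planted complexes")
    if cfg.n_background < 10:
        raise ValueError("need >=10 background samples for a meaningful null")


def generate_bundle(out_dir, config: FixtureConfig | None = None, seed: int = 1) -> PlantedTruth:
    """Generate the bundle under ``out_dir`` and return the planted truth.

    Deterministic given (config, seed): the same call produces a
    byte-identical bundle. Also writes ``truth.json`` and a ready-to-run
    pipeline ``config.yaml``.
    """
    cfg = config or FixtureConfig()
    _check_config(cfg)
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tf_ids = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    other_ids = [f"G{i + 1:03d}" for i in range(cfg.n_other_genes)]
    gene_ids = tf_ids + other_ids
    n_genes = len(gene_ids)
    genome = {CHROM: (n_genes + 1) * cfg.gene_spacing}

    perm = rng.permutation(cfg.n_tfs)
    identity = sorted(tf_ids[i] for i in perm[: cfg.n_identity])
    cofactors = sorted(
        tf_ids[i] for i in perm[cfg.n_identity: cfg.n_identity + cfg.n_cofactors]
    )
    candidates = sorted(identity + cofactors)

    # --- gene geometry -----------------------------------------------------
    tss = {g: 50_000 + i * cfg.gene_spacing for i, g in enumerate(gene_ids)}
    strand = {g: "+" if i % 2 == 0 else "-" for i, g in enumerate(gene_ids)}
    lengths = {g: int(rng.integers(1_000, 5_001)) for g in gene_ids}
    promoters = [
        PromoterAnnotation(g, CHROM, tss[g], strand[g]) for g in gene_ids
    ]
    prom_window = {g: build_promoter_window(p) for g, p in zip(gene_ids, promoters)}

    # --- expression --------------------------------------------------------
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_background)]
    counts = pd.DataFrame(
        rng.integers(50, 501, size=(n_genes, cfg.n_background + 1)).astype(float),
        index=gene_ids,
        columns=["query"] + sample_ids,
    )
    n_expr = max(2, round(0.1 * cfg.n_background))
    for tf in identity:
        counts.loc[tf, sample_ids] = 0.0
        counts.loc[tf, "query"] = 3000.0
    for tf in cofactors:
        counts.loc[tf, sample_ids] = 0.0
        expressers = rng.choice(sample_ids, size=n_expr, replace=False)
        counts.loc[tf, expressers] = 500.0
        counts.loc[tf, "query"] = 3000.0
    if cfg.noise.expression_noise_sd > 0:
        factor = rng.lognormal(
            0.0, cfg.noise.expression_noise_sd, size=counts.shape
        )
        counts = counts.where(counts == 0, counts * factor)

    # --- planted regulatory regions ----------------------------------------
    h3k4me3: List[Peak] = []
    dnase: List[Peak] = []
    h3k27ac: List[Peak] = []
    associations: List[EnhancerAssociation] = []
    # per-region accessible site used for ChIP peak placement
    region_site: Dict[str, GenomicInterval] = {}
    region_of_target: Dict[str, List[str]] = {}
    enhancer_map: Dict[str, List[str]] = {}
    enhancer_interval: Dict[str, GenomicInterval] = {}
    active_enhancers: List[str] = []

    enh_counts = rng.choice([1, 2, 3], size=len(candidates), p=[0.55, 0.30, 0.15])
    for tf, k in zip(candidates, enh_counts):
        t0 = tss[tf]
        h3k4me3.append(Peak(GenomicInterval(CHROM, t0 - 200, t0 + 200), name="H3K4me3"))
        prom_site = GenomicInterval(CHROM, t0 - 400, t0 + 450)
        dnase.append(Peak(prom_site, name="DNase"))
        prom_id = f"{tf}:P1"
        region_site[prom_id] = prom_site
        region_of_target[tf] = [prom_id]
        enhancer_map[tf] = []
        for j in range(int(k)):
            side = 1 if j % 2 == 0 else -1
            offset = 6_000 + 4_000 * j + int(rng.integers(0, 500))
            start = t0 + side * offset if side > 0 else t0 - offset - 1_500
            enh = GenomicInterval(CHROM, start, start + 1_500)
            eid = f"GH_{tf}_{j + 1}"
            associations.append(EnhancerAssociation(eid, enh, tf))
            enhancer_map[tf].append(eid)
            enhancer_interval[eid] = enh
            if rng.random() >= cfg.noise.peak_dropout_rate:
                h3k27ac.append(
                    Peak(GenomicInterval(CHROM, enh.start + 100, enh.end - 100),
                         name="H3K27ac")
                )
                active_enhancers.append(eid)
                site = GenomicInterval(CHROM, enh.start + 300, enh.end - 300)
                dnase.append(Peak(site, name="DNase"))
                region_site[eid] = site
                region_of_target[tf].append(eid)

    # decoy enhancer links for inactive (non-candidate) genes: dropped by
    # the active-promoter gate downstream
    decoy_genes = [g for g in tf_ids if g not in candidates][:10]
    for g in decoy_genes:
        start = tss[g] + 8_000
        associations.append(
            EnhancerAssociation(f"GH_{g}_1", GenomicInterval(CHROM, start, start + 1_500), g)
        )

    # a little intergenic decor so peak files exercise non-regulatory hits
    for i in range(5):
        pos = genome[CHROM] - (i + 1) * 7_000
        h3k4me3.append(Peak(GenomicInterval(CHROM, pos, pos + 400), name="H3K4me3"))
        dnase.append(Peak(GenomicInterval(CHROM, pos + 50, pos + 350), name="DNase"))

    # --- planted edge set ---------------------------------------------------
    pairs = set()
    for s in candidates:
        for t in candidates:
            if rng.random() < cfg.edge_prob:
                pairs.add((s, t))
    for c in cofactors:
        if not any(t in identity for s, t in pairs if s == c):
            pairs.add((c, identity[int(rng.integers(len(identity)))]))
        if not any(s in identity for s, t in pairs if t == c):
            pairs.add((identity[int(rng.integers(len(identity)))], c))

    # forced co-binding at designated identity promoters for the planted
    # cooperative complexes and competitive pairs
    special_targets = [
        str(t)
        for t in rng.choice(
            identity, size=cfg.n_complex_regions + cfg.n_competitive_regions,
            replace=False,
        )
    ]
    complex_targets = special_targets[: cfg.n_complex_regions]
    competitive_targets = special_targets[cfg.n_complex_regions:]
    forced_to_promoter: Dict[str, set] = {}
    for t in special_targets:
        srcs = [s for s in candidates if s != t]
        chosen = {str(s) for s in rng.choice(srcs, size=2, replace=False)}
        forced_to_promoter[t] = chosen
        pairs.update((s, t) for s in chosen)

    # assign each planted pair's edge to one region of the target; forced
    # co-binding pairs go to the promoter so complexes land in one region
    edges: List[Tuple[str, str, str]] = []
    region_sources: Dict[str, set] = {rid: set() for rid in region_site}
    for s, t in sorted(pairs):
        if t in forced_to_promoter and s in forced_to_promoter[t]:
            rid = f"{t}:P1"
        else:
            choices = region_of_target[t]
            rid = choices[int(rng.integers(len(choices)))]
        edges.append((s, t, rid))
        region_sources[rid].add(s)

    # decoy ChIP evidence for non-planted pairs
    if cfg.noise.decoy_edge_rate > 0:
        for s in candidates:
            for t in candidates:
                if (s, t) in pairs:
                    continue
                if rng.random() < cfg.noise.decoy_edge_rate:
                    region_sources[f"{t}:P1"].add(s)

    # --- per-region ChIP peak layout ---------------------------------------
    chip_peaks: Dict[str, List[Peak]] = {tf: [] for tf in candidates}
    complex_map: Dict[str, List[str]] = {}
    competitive_map: Dict[str, List[str]] = {}
    for rid in sorted(region_sources):
        sources = sorted(region_sources[rid])
        if not sources:
            continue
        site = region_site[rid]
        target = rid.split(":")[0] if rid.endswith(":P1") else None
        rest = sources
        cursor = site.start
        if target in complex_targets and len(sources) >= 2:
            members = sources[:3]
            complex_map[rid] = members
            shared = GenomicInterval(CHROM, site.start, site.start + 200)
            for m in members:
                chip_peaks[m].append(Peak(shared, name=m))
            rest = sources[len(members):]
            cursor = site.start + 220
        elif target in competitive_targets and len(sources) >= 2:
            pair = sources[:2]
            competitive_map[rid] = pair
            chip_peaks[pair[0]].append(
                Peak(GenomicInterval(CHROM, site.start, site.start + 200), name=pair[0])
            )
            chip_peaks[pair[1]].append(
                Peak(GenomicInterval(CHROM, site.start + 100, site.start + 300),
                     name=pair[1])
            )
            rest = sources[2:]
            cursor = site.start + 320
        if rest:
            # disjoint slots: these TFs bind independently in the region;
            # slots shrink with crowding but always stay inside the site
            avail = site.end - cursor
            slot = avail // len(rest)
            if slot < 10:
                raise ValueError(
                    f"region {rid} cannot host {len(rest)} disjoint peaks"
                )
            width = min(200, slot - 5)
            for i, s in enumerate(rest):
                start = cursor + i * slot
                chip_peaks[s].append(
                    Peak(GenomicInterval(CHROM, start, start + width), name=s)
                )

    # --- PPI table ----------------------------------------------------------
    ppi_scores: Dict[frozenset, int] = {}
    for members in complex_map.values():
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                ppi_scores[frozenset((u, v))] = 900
    for pair in competitive_map.values():
        key = frozenset(pair)
        ppi_scores.setdefault(key, 300)
    for _ in range(30):  # decoy pairs at sub-threshold confidence
        u, v = (str(x) for x in rng.choice(tf_ids, size=2, replace=False))
        ppi_scores.setdefault(frozenset((u, v)), int(rng.integers(100, 801)))

    # --- Hi-C ---------------------------------------------------------------
    hic: List[mio.HicInteraction] = []
    for tf in candidates:
        for eid in enhancer_map[tf]:
            if eid not in active_enhancers:
                continue
            if rng.random() < cfg.noise.hic_drop_rate:
                continue
            hic.append(
                mio.HicInteraction(enhancer_interval[eid], prom_window[tf],
                                   "promoter-other")
            )
    for i in range(3):  # decoy promoter-promoter contacts among inactive genes
        a, b = decoy_genes[2 * i], decoy_genes[2 * i + 1]
        hic.append(mio.HicInteraction(prom_window[a], prom_window[b],
                                      "promoter-promoter"))

    # --- write bundle -------------------------------------------------------
    expr = counts.copy()
    expr.insert(0, "gene_length", pd.Series(lengths))
    expr.to_csv(out_dir / "expression.tsv", sep="\t", index_label="gene_id",
                float_format="%.6g")
    meta = pd.DataFrame(
        {
            "sample_id": ["query"] + sample_ids,
            "library_type": "polyA",
            "is_single_cell": 0,
        }
    )
    meta.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    (out_dir / "tf_list.txt").write_text("".join(f"{tf}\n" for tf in tf_ids))
    mio.write_promoter_annotation(promoters, out_dir / "promoters.tsv")
    mio.write_enhancer_associations(associations, out_dir / "enhancers.tsv")
    mio.write_bed(h3k4me3, out_dir / "h3k4me3.bed")
    mio.write_bed(h3k27ac, out_dir / "h3k27ac.bed")
    mio.write_bed(dnase, out_dir / "dnase.bed")
    atlas_rows = [p for tf in sorted(chip_peaks) for p in sorted(chip_peaks[tf])]
    mio.write_bed(atlas_rows, out_dir / "chip_atlas.bed")
    ppi_rows = sorted(
        (tuple(sorted(k)), v) for k, v in ppi_scores.items()
    )
    pd.DataFrame(
        [{"protein_a": a, "protein_b": b, "score": v} for (a, b), v in ppi_rows]
    ).to_csv(out_dir / "ppi.tsv", sep="\t", index=False)
    mio.write_hic_interactions(hic, out_dir / "hic.tsv")
    gold = pd.DataFrame(sorted({(s, t) for s, t, _ in edges}),
                        columns=["source_tf", "target_tf"])
    gold.to_csv(out_dir / "gold_edges.tsv", sep="\t", index=False)

    truth = PlantedTruth(
        seed=seed,
        genome=genome,
        tf_universe=tf_ids,
        identity_tfs=identity,
        cofactors=cofactors,
        edges=sorted(edges),
        enhancer_map=enhancer_map,
        active_enhancers=sorted(active_enhancers),
        complex_map=complex_map,
        competitive_map=competitive_map,
    )
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=2, sort_keys=True)
        fh.write("\n")

    run_config = {
        "expression": "expression.tsv",
        "sample_metadata": "samples.tsv",
        "query_sample": "query",
        "tf_list": "tf_list.txt",
        "promoters": "promoters.tsv",
        "enhancers": "enhancers.tsv",
        "h3k4me3": "h3k4me3.bed",
        "h3k27ac": "h3k27ac.bed",
        "dnase": "dnase.bed",
        "chip_atlas": "chip_atlas.bed",
        "ppi": "ppi.tsv",
        "gold_edges": "gold_edges.tsv",
        "hic": "hic.tsv",
        "out_dir": "results",
        "seed": seed,
    }
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    return truth


def load_truth(bundle_dir) -> PlantedTruth:
    with open(Path(bundle_dir) / "truth.json") as fh:
        d = json.load(fh)
    d["edges"] = [tuple(e) for e in d["edges"]]
    return PlantedTruth(**d)
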