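"""Orchestration of the full reconstruction workflow.

Stages: background assembly -> specificity scoring -> active regulatory
regions -> network scaffold + co-factor filter + complex calls ->
optional evaluation against gold-standard edges and promoter-capture
Hi-C. Every stage writes its TSV artifact and logs summary counts; with a
fixed seed and identical inputs the run is byte-reproducible (all output
tables are sorted).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import io as mio
from .background import (
    counts_to_tpm,
    decorrelate,
    filter_samples,
    split_by_library_type,
    write_background,
)
from .evaluation import edge_f1, validate_enhancer_assignments
from .network import (
    CoreGRN,
    assign_complexes,
    build_scaffold,
    filter_cofactor_connectivity,
)
from .regions import build_promoter_window, build_regions
from .specificity import score_tfs

logger = logging.getLogger("moni")

_PATH_FIELDS = (
    "expression", "sample_metadata", "tf_list", "promoters", "enhancers",
    "h3k4me3", "h3k27ac", "dnase", "chip_atlas", "ppi", "gold_edges", "hic",
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Paths and parameters for one reconstruction run. Defaults are the
    method's standard values: top-10 identity TFs, z < -1.5 co-factors,
    15,000-count sample floor, r < 0.7 decorrelation, 1500/500 bp promoter
    window, PPI > 800, reciprocal overlap >= 0.62."""

    expression: str
    sample_metadata: str
    query_sample: str
    tf_list: str
    promoters: str
    enhancers: str
    h3k4me3: str
    h3k27ac: str
    chip_atlas: str
    ppi: str
    out_dir: str
    dnase: Optional[str] = None
    gold_edges: Optional[str] = None
    hic: Optional[str] = None
    n_top: int = 10
    z_cut: float = -1.5
    min_counts: int = 15000
    r_max: float = 0.7
    up: int = 1500
    down: int = 500
    ppi_min: int = 800
    ro_min: float = 0.62
    seed: int = 1
    dnase_required: bool = True

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # resolve relative paths against the config file's directory
        base = path.parent
        for name in _PATH_FIELDS + ("out_dir",):
            value = getattr(cfg, name)
            if value is not None and not Path(value).is_absolute():
                setattr(cfg, name, str(base / value))
        return cfg

    def validate(self) -> None:
        for name in _PATH_FIELDS:
            value = getattr(self, name)
            if name == "dnase" and value is None:
                if self.dnase_required:
                    raise ConfigError(
                        "dnase peak file is required (pass dnase_required: "
                        "false / --no-dnase to relax accessibility gating)"
                    )
                continue
            if name in ("gold_edges", "hic") and value is None:
                continue
            if not Path(value).exists():
                raise ConfigError(f"{name}: path does not exist: {value}")
        if self.n_top < 1 or self.min_counts < 0 or not 0 < self.r_max <= 1:
            raise ConfigError("parameter out of range")
        if not 0 <= self.ro_min <= 1 or not 0 <= self.ppi_min <= 1000:
            raise ConfigError("parameter out of range")
        if self.up <= 0 or self.down <= 0:
            raise ConfigError("promoter window extents must be positive")


def _preflight_chroms(promoter_chroms, peaks, label: str) -> None:
    peak_chroms = {p.chrom for p in peaks}
    if peaks and not (peak_chroms & promoter_chroms):
        logger.warning(
            "%s peaks share no chromosome names with the promoter "
            "annotation; all overlaps will be empty", label
        )


def run_pipeline(config: RunConfig) -> CoreGRN:
    """Execute the full workflow; artifacts land under ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: background atlas -----------------------------------------
    try:
        expr = mio.read_expression_table(config.expression)
        meta = mio.read_sample_metadata(config.sample_metadata)
        if config.query_sample not in expr.sample_ids:
            raise ConfigError(
                f"query sample {config.query_sample!r} not in expression table"
            )
        if config.query_sample not in meta.index:
            raise ConfigError(
                f"query sample {config.query_sample!r} not in sample metadata"
            )
        query_lib = str(meta.loc[config.query_sample, "library_type"])
        bg_counts = expr.subset_samples(
            [s for s in expr.sample_ids if s != config.query_sample]
        )
        bg_counts = filter_samples(bg_counts, meta, min_counts=config.min_counts)
        by_lib = split_by_library_type(bg_counts, meta)
        selected = by_lib[query_lib]
        if selected.n_samples == 0:
            raise ValueError(
                f"no background samples with library_type {query_lib!r}"
            )
        background = decorrelate(
            selected, r_max=config.r_max, seed=config.seed, library_type=query_lib
        )
        write_background(background, out_dir / "background")
        logger.info(
            "background: %d %s samples retained of %d after filtering",
            len(background.retained_order), query_lib, selected.n_samples,
        )
    except Exception as exc:
        raise type(exc)(f"background: {exc}") from exc

    # --- stage 2: specificity ----------------------------------------------
    try:
        query_tpm = counts_to_tpm(expr.subset_samples([config.query_sample]))
        tf_symbols = mio.read_tf_list(config.tf_list)
        scores = score_tfs(
            query_tpm.values[config.query_sample],
            background.matrix.values,
            tf_symbols,
            n_top=config.n_top,
            z_cut=config.z_cut,
        )
        scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False,
                      float_format="%.10g")
        identity = list(scores.loc[scores["call"] == "identity", "tf"])
        cofactors = list(scores.loc[scores["call"] == "cofactor", "tf"])
        logger.info(
            "specificity: %d TFs scored, %d identity, %d co-factors",
            len(scores), len(identity), len(cofactors),
        )
    except Exception as exc:
        raise type(exc)(f"specificity: {exc}") from exc

    # --- stage 3: regulatory regions ---------------------------------------
    try:
        promoters = mio.read_promoter_annotation(config.promoters)
        associations = mio.read_enhancer_associations(config.enhancers)
        h3k4me3 = mio.read_bed(config.h3k4me3)
        h3k27ac = mio.read_bed(config.h3k27ac)
        dnase = mio.read_bed(config.dnase) if config.dnase else []
        prom_chroms = {p.chrom for p in promoters}
        _preflight_chroms(prom_chroms, h3k4me3, "H3K4me3")
        _preflight_chroms(prom_chroms, h3k27ac, "H3K27ac")
        _preflight_chroms(prom_chroms, dnase, "DNase")
        if not config.dnase_required:
            logger.warning(
                "accessibility gating disabled: active regions are treated "
                "as fully accessible"
            )
        candidates = sorted(set(identity) | set(cofactors))
        regions = build_regions(
            promoters, associations, candidates, h3k4me3, h3k27ac, dnase,
            up=config.up, down=config.down,
            dnase_required=config.dnase_required,
        )
        _write_regions(regions, out_dir / "regions.tsv")
        n_prom = sum(1 for r in regions if r.region_type == "promoter")
        n_enh = sum(1 for r in regions if r.region_type == "enhancer")
        logger.info("regions: %d active promoters, %d active enhancers",
                    n_prom, n_enh)
    except Exception as exc:
        raise type(exc)(f"regions: {exc}") from exc

    # --- stage 4: network ---------------------------------------------------
    try:
        atlas = mio.load_chip_atlas(config.chip_atlas)
        ppi = mio.build_ppi_index(mio.read_ppi_table(config.ppi))
        scaffold = build_scaffold(regions, atlas, candidates)
        grn = filter_cofactor_connectivity(scaffold, identity, cofactors)
        grn = assign_complexes(grn, regions, ppi,
                               ppi_min=config.ppi_min, ro_min=config.ro_min)
        jsd_map = dict(zip(scores["tf"], scores["jsd"]))
        z_map = dict(zip(scores["tf"], scores["zscore"]))
        grn.node_jsd = {tf: jsd_map[tf] for tf in grn.nodes}
        grn.node_zscore = {tf: z_map[tf] for tf in grn.nodes}
        mio.write_network(grn, out_dir)
        logger.info(
            "network: %d scaffold edges, %d after co-factor filter, "
            "%d nodes, %d complex calls",
            len(scaffold), len(grn.edges), len(grn.nodes), len(grn.complexes),
        )
    except Exception as exc:
        raise type(exc)(f"network: {exc}") from exc

    # --- stage 5: evaluation (optional) ------------------------------------
    metrics: Dict[str, object] = {
        "tfs_scored": int(len(scores)),
        "n_identity": len(identity),
        "n_cofactors_called": len(cofactors),
        "n_cofactors_retained": sum(
            1 for role in grn.nodes.values() if role == "cofactor"
        ),
        "active_promoters": n_prom,
        "active_enhancers": n_enh,
        "edges_scaffold": len(scaffold),
        "edges_final": len(grn.edges),
        "cooperative_complexes": sum(
            1 for c in grn.complexes if c.mode == "cooperative"
        ),
        "competitive_calls": sum(
            1 for c in grn.complexes if c.mode == "competitive"
        ),
    }
    try:
        if config.gold_edges:
            gold_df = pd.read_csv(config.gold_edges, sep="\t")
            network_tfs = set(grn.nodes)
            gold_pairs = {
                (str(r.source_tf), str(r.target_tf))
                for r in gold_df.itertuples(index=False)
                if r.source_tf in network_tfs and r.target_tf in network_tfs
            }
            p, r, f1 = edge_f1(grn.edge_pairs(), gold_pairs,
                               directed_prediction=True)
            metrics.update({"precision": p, "recall": r, "f1": f1})
            logger.info("evaluation: P=%.3f R=%.3f F1=%.3f", p, r, f1)
        if config.hic:
            hic = mio.read_hic_interactions(config.hic)
            enh_by_id = {a.enhancer_id: a.interval for a in associations}
            network_regions = {}
            for reg in regions:
                if reg.region_type != "enhancer" or reg.owner_tf not in grn.nodes:
                    continue
                # Hi-C matching uses the raw annotated enhancer interval:
                # anchors are fragment-scale, truncated pieces would
                # produce spurious misses
                network_regions.setdefault(reg.owner_tf, []).append(
                    enh_by_id[reg.region_id]
                )
            prom_windows: Dict[str, list] = {}
            for p_ann in promoters:
                if p_ann.gene_id in grn.nodes:
                    prom_windows.setdefault(p_ann.gene_id, []).append(
                        build_promoter_window(p_ann, up=config.up, down=config.down)
                    )
            if network_regions:
                pct = validate_enhancer_assignments(
                    network_regions, prom_windows, hic
                )
                metrics["hic_validated_pct"] = pct
                logger.info("evaluation: %.1f%% enhancer assignments "
                            "validated by Hi-C", pct)
            else:
                metrics["hic_validated_pct"] = None
    except Exception as exc:
        raise type(exc)(f"evaluation: {exc}") from exc

    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return grn


def _write_regions(regions, path) -> None:
    rows = [
        {
            "owner_tf": r.owner_tf,
            "region_type": r.region_type,
            "region_id": r.region_id,
            "intervals": ";".join(
                f"{iv.chrom}:{iv.start}-{iv.end}" for iv in r.intervals
            ),
            "active": int(r.active),
            "n_accessible_sites": len(r.accessible_sites),
        }
        for r in regions
    ]
    df = pd.DataFrame(
        rows,
        columns=["owner_tf", "region_type", "region_id", "intervals",
                 "active", "n_accessible_sites"],
    )
    if len(df):
        df = df.sort_values(["owner_tf", "region_type", "region_id"])
    df.to_csv(path, sep="\t", index=False)
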