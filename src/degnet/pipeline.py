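"""End-to-end orchestration: DEG table -> networks -> validation -> enrichment.

The up- and down-regulated networks are processed independently and never
merged. Every stage writes a headered TSV under the output directory and
is re-runnable from those intermediates; a JSON manifest records each
artifact with its SHA-256 checksum plus the fully-resolved configuration,
so a rerun with the same config and seed yields identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io
from .bipartite import (
    betweenness_centrality,
    build_bipartite,
    centrality_frame,
    closeness_centrality,
    degree_centrality,
    top_fraction_union,
)
from .enrichment import edge_overlap_significance, gene_set_enrichment, tf_enrichment
from .errors import DegnetError
from .nullmodel import validate_against_null
from .projection import (
    component_condition_profile,
    connected_components,
    project,
    threshold_edges,
)
from .simulate import SimulationParams, simulate_deg_table, simulate_references

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full run; defaults follow the standard workflow
    (top 5% centrality union, 10 null replicates at alpha 0.05, gene-side
    projection thresholded at Jaccard 0.9)."""

    outdir: str = "degnet_out"
    deg_path: Optional[str] = None
    simulate: Optional[SimulationParams] = None
    directions: tuple[str, ...] = ("up", "down")
    p_cutoff: float = 0.05
    lfc_cutoff: float = 1.0
    centrality_fraction: float = 0.05
    null_replicates: int = 10
    alpha: float = 0.05
    projection_side: str = "G"
    projection_cutoff: float = 0.9
    gmt_path: Optional[str] = None
    grn_path: Optional[str] = None
    ppi_path: Optional[str] = None
    tf_top_fraction: float = 0.25
    tf_adj_p_max: float = 0.05
    tf_min_targets: int = 10
    seed: int = 0
    max_profiled_components: int = 50

    def to_dict(self) -> dict:
        d = asdict(self)
        d["directions"] = list(self.directions)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "module_size_range" in sim:
                sim["module_size_range"] = tuple(sim["module_size_range"])
            raw["simulate"] = SimulationParams(**sim)
        if "directions" in raw:
            raw["directions"] = tuple(raw["directions"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for each direction and return the output manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    counts: dict[str, int] = {}

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts.append(path)
        return path

    references = None
    if config.simulate is not None:
        table, truth = simulate_deg_table(config.simulate)
        references = simulate_references(truth, config.simulate)
        emit("simulated_deg_table.tsv", lambda p: io.write_deg_table(table, p))
        truth_df = pd.DataFrame(
            sorted(
                (g, m, truth.breadth[g]) for g, m in truth.module_assignments.items()
            ),
            columns=["gene", "module", "breadth"],
        )
        emit("ground_truth.tsv", lambda p: io.write_table(truth_df, p))
    elif config.deg_path is not None:
        table = io.read_deg_table(config.deg_path, config.p_cutoff, config.lfc_cutoff)
    else:
        raise DegnetError("config needs either deg_path or a simulate block")

    gene_sets = io.read_gene_sets(config.gmt_path) if config.gmt_path else None
    grn = io.read_edge_list(config.grn_path, directed=True) if config.grn_path else None
    ppi = io.read_edge_list(config.ppi_path) if config.ppi_path else None
    if references is not None:
        sim_ppi, sim_grn, sim_sets = references
        ppi = ppi or sim_ppi
        grn = grn or sim_grn
        gene_sets = gene_sets or sim_sets
        emit(
            "simulated_ppi.tsv", lambda p: io.write_network(sim_ppi, p)
        )
        grn_df = pd.DataFrame(
            [(tf, g) for tf in sorted(sim_grn.targets_of)
             for g in sorted(sim_grn.targets_of[tf])],
            columns=["tf", "target"],
        )
        emit("simulated_grn.tsv", lambda p: io.write_table(grn_df, p))

    for direction in config.directions:
        tag = direction
        net = build_bipartite(table, direction)
        counts[f"{tag}_conditions"] = net.C_n
        counts[f"{tag}_genes"] = net.G_n
        counts[f"{tag}_edges"] = net.n_edges
        edge_df = pd.DataFrame(sorted(net.edges), columns=["condition", "gene"])
        emit(f"{tag}_bipartite_edges.tsv", lambda p, d=edge_df: io.write_table(d, p))

        tables = [
            degree_centrality(net),
            closeness_centrality(net),
            betweenness_centrality(net),
        ]
        frame = centrality_frame(tables, net)
        union, selected_by = top_fraction_union(
            tables, config.centrality_fraction, side="G"
        )
        frame["selected_by"] = [
            ",".join(sorted(selected_by.get(n, []))) if s == "G" else ""
            for n, s in zip(frame["node"], frame["side"])
        ]
        emit(f"{tag}_centrality.tsv", lambda p, d=frame: io.write_table(d, p))
        counts[f"{tag}_top_union"] = len(union)

        report = validate_against_null(
            net, replicates=config.null_replicates,
            seed=config.seed, alpha=config.alpha,
        )
        rep_df = pd.DataFrame(
            [(i, r.D, r.p_value, r.D_critical)
             for i, r in enumerate(report.replicate_results)],
            columns=["replicate", "D", "p_value", "D_critical"],
        )
        rep_df.loc[len(rep_df)] = ["average_D", report.average_D, "", report.D_critical]
        rep_df.loc[len(rep_df)] = ["verdict", report.verdict, "", ""]
        emit(f"{tag}_ks_validation.tsv", lambda p, d=rep_df: io.write_table(d, p))

        pn = project(net, side=config.projection_side)
        emit(f"{tag}_projected.tsv", lambda p, n=pn: io.write_network(n, p))
        thr = threshold_edges(pn, config.projection_cutoff)
        emit(f"{tag}_projected_thresholded.tsv", lambda p, n=thr: io.write_network(n, p))
        counts[f"{tag}_projected_edges"] = pn.n_edges
        counts[f"{tag}_thresholded_edges"] = thr.n_edges

        comps = connected_components(thr)
        comp_df = pd.DataFrame(
            [(i, len(c), ",".join(sorted(c))) for i, c in enumerate(comps)],
            columns=["component_id", "size", "members"],
        )
        emit(f"{tag}_components.tsv", lambda p, d=comp_df: io.write_table(d, p))
        counts[f"{tag}_components"] = len(comps)

        prof_rows = []
        for i, comp in enumerate(comps[: config.max_profiled_components]):
            profile = component_condition_profile(comp, table, direction)
            sub = profile.table.copy()
            sub.insert(0, "component_id", i)
            prof_rows.append(sub)
        if prof_rows:
            emit(
                f"{tag}_component_profiles.tsv",
                lambda p, d=pd.concat(prof_rows): io.write_table(d, p),
            )

        if gene_sets is not None and union:
            universe = set(net.genes)
            gse = gene_set_enrichment(union & universe, gene_sets, universe)
            emit(f"{tag}_gene_set_enrichment.tsv", lambda p, d=gse: io.write_table(d, p))
        if grn is not None and union:
            tfe = tf_enrichment(
                union, grn, config.tf_top_fraction,
                config.tf_adj_p_max, config.tf_min_targets,
            )
            emit(f"{tag}_tf_enrichment.tsv", lambda p, d=tfe: io.write_table(d, p))
        if ppi is not None and thr.n_edges:
            try:
                ov = edge_overlap_significance(thr, ppi)
            except DegnetError:
                ov = None
            if ov is not None:
                ov_df = pd.DataFrame([{
                    "shared_edges": ov.shared_edges,
                    "query_edges": ov.query_edges,
                    "reference_edges": ov.reference_edges,
                    "pair_universe": ov.pair_universe,
                    "p": ov.p,
                }])
                emit(f"{tag}_ppi_overlap.tsv", lambda p, d=ov_df: io.write_table(d, p))

    manifest = {
        "config": config.to_dict(),
        "counts": counts,
        "artifacts": [
            {"name": p.name, "sha256": _sha256(p)} for p in artifacts
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline wrote %d artifacts to %s", len(artifacts), out)
    return manifest
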