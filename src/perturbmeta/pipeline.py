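"""Umbrella pipeline: simulate/load -> DEGs -> meta-analysis -> network ->
enrichment -> summary tables.

Every output table carries a provenance header (tool version, config hash,
master seed) and the whole run is a pure function of the configuration, so
re-running a config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dex import differential_expression
from .enrichstats import GeneSetLibrary, enrich
from .io import write_edge_list, write_expression, write_table
from .metaperturb import (
    MetaConfig,
    ca_meta,
    compile_union,
    inverse_cumulative_distribution,
    rem_meta,
    top_perturbed,
    vc_meta,
)
from .nethub import centralities, load_network, prune_min_degree, select_hubs
from .report import summarize_counts
from .synthdata import (
    ExpressionStudy,
    SimulationConfig,
    generate_collection,
    generate_gene_set_library,
    generate_interactome,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration (serialisable to/from YAML)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    meta: MetaConfig = field(default_factory=MetaConfig)
    min_degree: int = 2
    interactome_extra_nodes: int = 60
    interactome_edges_per_node: int = 3
    library_terms: int = 50
    library_size_range: tuple[int, int] = (10, 200)
    background_size: int = 20000
    run_dex: bool = True
    run_meta: bool = True
    run_network: bool = True
    run_enrichment: bool = True
    run_summary: bool = True

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["tissue_labels"] = (
            list(self.simulation.tissue_labels)
            if self.simulation.tissue_labels is not None
            else None
        )
        d["library_size_range"] = list(self.library_size_range)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        if sim.get("tissue_labels") is not None:
            sim["tissue_labels"] = tuple(sim["tissue_labels"])
        meta = raw.pop("meta", {})
        if "library_size_range" in raw:
            raw["library_size_range"] = tuple(raw["library_size_range"])
        return cls(
            simulation=SimulationConfig(**sim), meta=MetaConfig(**meta), **raw
        )


def _header(config: PipelineConfig) -> list[str]:
    return [
        f"perturbmeta {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    studies: list[ExpressionStudy] | None = None,
) -> dict:
    """Execute the configured stages and return the result bundle.

    ``studies`` overrides the synthetic collection with externally loaded
    data.  Studies whose DEG table is empty are excluded from the
    meta-analysis, mirroring standard practice for evidence synthesis.
    Raises with the failing stage named on any stage error.
    """
    bundle: dict = {"config": config}
    header = _header(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if not config.run_dex:
        return bundle

    try:
        if studies is None:
            studies = generate_collection(config.simulation)
        bundle["studies"] = studies
        deg_tables = {}
        for study in studies:
            deg_tables[study.study_id] = differential_expression(
                study.expr, study.group, study.batch
            )
        bundle["deg_tables"] = deg_tables
        study_to_tissue = {s.study_id: s.tissue for s in studies}
        bundle["study_to_tissue"] = study_to_tissue
        if out is not None:
            for sid, table in deg_tables.items():
                write_table(table, out / f"deg_{sid}.tsv", header)
    except Exception as exc:
        raise RuntimeError(f"dex stage failed: {exc}") from exc

    if not config.run_meta:
        return bundle

    try:
        nonzero = {
            sid: t for sid, t in deg_tables.items() if (t["status"] != "ns").any()
        }
        bundle["studies_in_meta"] = sorted(nonzero)
        rem = rem_meta(nonzero, config.meta)
        vc = vc_meta(nonzero, config.meta)
        ca = ca_meta(nonzero, config.meta)
        sets = [
            top_perturbed(rem, "REM", config.meta),
            top_perturbed(vc, "VC", config.meta),
            top_perturbed(ca, "CA", config.meta),
        ]
        compiled = compile_union(sets)
        bundle.update(
            rem=rem, vc=vc, ca=ca, model_sets=sets, compiled=compiled,
            inverse_cdf=inverse_cumulative_distribution(vc),
        )
        if out is not None:
            write_table(rem, out / "meta_rem.tsv", header)
            write_table(vc, out / "meta_vc.tsv", header)
            write_table(ca, out / "meta_ca.tsv", header)
            write_table(bundle["inverse_cdf"], out / "meta_vc_inverse_cdf.tsv", header)
            for s in sets + [compiled]:
                df = pd.DataFrame(
                    {"gene": s.genes, "regulation": [s.regulation[g] for g in s.genes]}
                )
                write_table(df, out / f"set_{s.source.lower()}.tsv", header)
    except Exception as exc:
        raise RuntimeError(f"meta stage failed: {exc}") from exc

    if not config.run_network:
        bundle["centrality"] = None
    else:
        try:
            # synthetic stand-in for the interaction service: a scale-free
            # network over the compiled genes plus predicted neighbours
            import numpy as np

            rng = np.random.default_rng(config.seed + 10007)
            predicted = [
                f"PRED{i + 1:04d}" for i in range(config.interactome_extra_nodes)
            ]
            labels = compiled.genes + predicted
            rng.shuffle(labels)
            edges = generate_interactome(
                len(labels),
                config.interactome_edges_per_node,
                seed=config.seed + 10009,
                labels=labels,
            )
            graph = load_network(edges, predicted=set(predicted))
            pruned = prune_min_degree(graph, k=config.min_degree)
            records = select_hubs(centralities(pruned))
            bundle["network_edges"] = edges
            bundle["centrality"] = records
            if out is not None:
                write_edge_list(edges, out / "network_edges.tsv", header)
                means = records.attrs["means"]
                write_table(
                    records,
                    out / "centrality.tsv",
                    header + [
                        f"mean_betweenness {means['betweenness']:.6f}",
                        f"mean_closeness {means['closeness']:.9f}",
                        f"mean_degree {means['degree']:.6f}",
                    ],
                )
        except Exception as exc:
            raise RuntimeError(f"network stage failed: {exc}") from exc

    if config.run_enrichment:
        try:
            universe = list(config.simulation.gene_ids)
            lib = GeneSetLibrary(
                "synthetic_library",
                generate_gene_set_library(
                    universe,
                    config.library_terms,
                    config.library_size_range,
                    seed=config.seed + 20011,
                ),
                background_size=config.background_size,
            )
            enr_compiled = enrich(compiled.genes, lib, compiled.regulation)
            bundle["enrichment_compiled"] = enr_compiled
            if bundle.get("centrality") is not None:
                hubs = bundle["centrality"].loc[
                    bundle["centrality"]["is_hub"], "node"
                ].tolist()
                bundle["enrichment_hubs"] = (
                    enrich(hubs, lib, compiled.regulation) if hubs else None
                )
            if out is not None:
                write_table(enr_compiled, out / "enrichment_compiled.tsv", header)
                if bundle.get("enrichment_hubs") is not None:
                    write_table(
                        bundle["enrichment_hubs"], out / "enrichment_hubs.tsv", header
                    )
        except Exception as exc:
            raise RuntimeError(f"enrichment stage failed: {exc}") from exc

    if config.run_summary:
        try:
            summary = summarize_counts(
                deg_tables,
                study_to_tissue=study_to_tissue,
                compiled_regulation=compiled.regulation,
                hub_table=bundle.get("centrality"),
            )
            bundle["summary"] = summary
            if out is not None:
                write_table(summary["per_study"], out / "summary_per_study.tsv", header)
                if "per_tissue" in summary:
                    write_table(
                        summary["per_tissue"], out / "summary_per_tissue.tsv", header
                    )
                write_table(
                    summary["comparisons"], out / "summary_comparisons.tsv", header
                )
        except Exception as exc:
            raise RuntimeError(f"summary stage failed: {exc}") from exc

    return bundle
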