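"""End-to-end orchestration: expression + annotation + gene sets -> results.

Stages run in protocol order — moderated differential expression, two-way
hierarchical clustering of the significant genes, cis pair classification,
per-group coexpression networks with diffK ranking, and GO/pathway
over-representation — and every table is written as TSV/JSON/SIF/GraphML
under one output directory.  A run-log JSON records every threshold used and
the seed, so a run is fully determined by its inputs plus the log.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from . import de as de_mod
from . import enrichment as enr_mod
from . import network as net_mod
from . import pairing as pair_mod
from .config import PipelineConfig
from .io import (BIOTYPE_LNC, BIOTYPE_MRNA, CONTROL, DISEASE,
                 ExpressionMatrix, TranscriptAnnotation, write_json)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineResult:
    config: PipelineConfig
    de_results: pd.DataFrame
    up: List[str]
    down: List[str]
    pairs: List[pair_mod.PairRecord]
    pair_summary: pair_mod.PairSummary
    net_disease: nx.Graph
    net_control: nx.Graph
    node_stats: pd.DataFrame
    enrichment_go: pd.DataFrame
    enrichment_pathway: pd.DataFrame
    output_files: Dict[str, Path] = field(default_factory=dict)


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def _directions(results: pd.DataFrame, ids: Sequence[str]) -> Dict[str, str]:
    return {g: results.at[g, "direction"] for g in ids}


def run_pipeline(config: PipelineConfig,
                 expression: ExpressionMatrix,
                 annotation: TranscriptAnnotation,
                 term_map: Mapping[str, Sequence[str]],
                 outdir: str | Path) -> PipelineResult:
    """Run every stage and write all outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: Dict[str, Path] = {}
    biotype = annotation.df.set_index("id")["biotype"]

    with _stage("differential_expression"):
        results = de_mod.run_de(expression, config)
        up, down = de_mod.select_de(results, config)
        files["de_results"] = outdir / "de_results.tsv"
        results.to_csv(files["de_results"], sep="\t", float_format=_FLOAT_FMT,
                       lineterminator="\n")
        for name, ids in (("de_up", up), ("de_down", down)):
            files[name] = outdir / f"{name}.txt"
            files[name].write_text("".join(f"{g}\n" for g in ids))

    with _stage("hierarchical_clustering"):
        de_ids = up + down
        if len(de_ids) >= 2:
            sub = expression.subset_genes(de_ids)
            gene_order, sample_order, _, _ = de_mod.hierarchical_cluster(sub)
        else:
            gene_order, sample_order = de_ids, expression.sample_ids
        files["cluster_gene_order"] = outdir / "cluster_gene_order.txt"
        files["cluster_gene_order"].write_text(
            "".join(f"{g}\n" for g in gene_order))
        files["cluster_sample_order"] = outdir / "cluster_sample_order.txt"
        files["cluster_sample_order"].write_text(
            "".join(f"{s}\n" for s in sample_order))

    with _stage("pairing"):
        annotated = set(biotype.index)
        de_lnc = _directions(results, [g for g in de_ids
                                       if g in annotated
                                       and biotype[g] == BIOTYPE_LNC])
        de_mrna = _directions(results, [g for g in de_ids
                                        if g in annotated
                                        and biotype[g] == BIOTYPE_MRNA])
        pairs = pair_mod.find_pairs(annotation, de_lnc, de_mrna,
                                    config.pair_max_distance,
                                    config.pair_anchor)
        summary = pair_mod.summarize_pairs(pairs)
        files["pairs"] = outdir / "pairs.tsv"
        pair_mod.pairs_to_frame(pairs).to_csv(files["pairs"], sep="\t",
                                              index=False, lineterminator="\n")
        files["pairs_bedpe"] = outdir / "pairs.bedpe"
        pair_mod.write_pairs_bedpe(pairs, annotation, files["pairs_bedpe"])
        files["pair_summary"] = outdir / "pair_summary.json"
        frac = summary.concordance_fraction
        write_json({
            "counts": summary.counts, "total": summary.total,
            "n_concordant": summary.n_concordant,
            "n_discordant": summary.n_discordant,
            "concordance_fraction": round(frac, 4) if frac is not None else None,
            "concordance_percent": summary.concordance_percent,
        }, files["pair_summary"])

    with _stage("network"):
        net_d = net_mod.build_cnc_network(expression, DISEASE,
                                          sorted(de_lnc), sorted(de_mrna), config)
        net_c = net_mod.build_cnc_network(expression, CONTROL,
                                          sorted(de_lnc), sorted(de_mrna), config)
        stats = net_mod.diffk(net_d, net_c, config)
        files["node_stats"] = outdir / "node_stats.tsv"
        stats.to_csv(files["node_stats"], sep="\t", float_format=_FLOAT_FMT,
                     lineterminator="\n")
        for label, net in (("disease", net_d), ("control", net_c)):
            files[f"network_{label}_sif"] = outdir / f"network_{label}.sif"
            files[f"network_{label}_graphml"] = outdir / f"network_{label}.graphml"
            net_mod.export_network(net, stats if len(stats) else None,
                                   files[f"network_{label}_sif"],
                                   files[f"network_{label}_graphml"])

    with _stage("enrichment"):
        universe = [g for g in expression.gene_ids
                    if g in annotated and biotype[g] == BIOTYPE_MRNA]
        go_tables, pw_tables = [], []
        up_mrna = sorted(g for g, d in de_mrna.items() if d == de_mod.UP)
        down_mrna = sorted(g for g, d in de_mrna.items() if d == de_mod.DOWN)
        for direction, ids in (("up", up_mrna), ("down", down_mrna)):
            go_tables.append(enr_mod.enrich(ids, universe, term_map,
                                            enr_mod.GO_MODE, direction, config))
            pw_tables.append(enr_mod.enrich(ids, universe, term_map,
                                            enr_mod.PATHWAY_MODE, direction,
                                            config))
        enrichment_go = pd.concat(go_tables) if go_tables else pd.DataFrame()
        enrichment_pw = pd.concat(pw_tables) if pw_tables else pd.DataFrame()
        files["enrichment_go"] = outdir / "enrichment_go.tsv"
        enrichment_go.to_csv(files["enrichment_go"], sep="\t",
                             float_format=_FLOAT_FMT, lineterminator="\n")
        files["enrichment_pathway"] = outdir / "enrichment_pathway.tsv"
        enrichment_pw.to_csv(files["enrichment_pathway"], sep="\t",
                             float_format=_FLOAT_FMT, lineterminator="\n")

    with _stage("run_log"):
        files["run_log"] = outdir / "run_log.json"
        write_json({
            "config": config.to_dict(),
            "n_genes": len(expression.gene_ids),
            "n_samples": len(expression.sample_ids),
            "n_up": len(up), "n_down": len(down),
            "n_pairs": summary.total,
            "n_nodes_disease": net_d.number_of_nodes(),
            "n_edges_disease": net_d.number_of_edges(),
            "n_nodes_control": net_c.number_of_nodes(),
            "n_edges_control": net_c.number_of_edges(),
            "n_terms_go": int(len(enrichment_go)),
            "n_terms_pathway": int(len(enrichment_pw)),
            "note": "pathway mode is plain over-representation "
                    "(no topology-based impact factor)",
        }, files["run_log"])

    return PipelineResult(
        config=config, de_results=results, up=up, down=down, pairs=pairs,
        pair_summary=summary, net_disease=net_d, net_control=net_c,
        node_stats=stats, enrichment_go=enrichment_go,
        enrichment_pathway=enrichment_pw, output_files=files)
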