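"""End-to-end orchestration: expression -> coexpression -> motifs -> network.

``run_pipeline`` consumes a fixture directory (counts/TPM/sample sheet,
genome FASTA, TSS BED, JASPAR PWMs, TF list) and writes every stage's output
plus a run log and a summary JSON recording thresholds and stage-wise
gene/edge counts. When the fixture carries a planted-truth edge list the
summary also reports directed-edge precision/recall/F1.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .coexpression import coexpress
from .expression import ExpressionDataset, differential_expression, select_de_genes
from .motifs import build_binding_map, cre_enrichment, extract_promoters, read_jaspar, scan_promoters
from .network import assemble_grn, evaluate_recovery, export_network, summarize_network
from .simulate import read_fixture

__all__ = ["run_pipeline"]

log = logging.getLogger("waxgrn")


def run_pipeline(
    fixture_dir: str | Path,
    out_dir: str | Path,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Run the full GRN analysis on a fixture directory; returns the summary."""
    config = config or PipelineConfig()
    fixture = Path(fixture_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "config": config.__dict__.copy()}

    try:
        dataset, truth = read_fixture(fixture)
        log.info("loaded %d genes x %d samples", len(dataset.genes), dataset.counts.shape[1])

        # --- expression ---------------------------------------------------
        de_table = differential_expression(
            dataset,
            epidermis=config.epidermis_label,
            threshold_tpm=config.tpm_min,
            pseudocount=config.pseudocount,
            min_fold=config.fold_min,
            max_fdr=config.de_fdr_max,
        )
        direction = "up" if config.sign == "positive" else "down"
        de_genes = select_de_genes(
            de_table, config.fold_min, config.de_fdr_max, direction=direction
        )
        de_table.rename_axis("gene").to_csv(out / "de_table.tsv", sep="\t", float_format="%.6g")
        summary["n_genes"] = int(len(dataset.genes))
        summary["n_expressed"] = int(de_table["pass_expression_filter"].sum())
        summary["n_de_genes"] = int(len(de_genes))
        log.info("expression: %(n_expressed)d expressed, %(n_de_genes)d DE", summary)

        # --- coexpression -------------------------------------------------
        coex = coexpress(
            dataset.tpm.loc[de_genes], dataset.samples, sample_mode=config.sample_mode
        )
        coex.pair_table().to_csv(out / "coexpression.tsv", sep="\t", index=False,
                                 float_format="%.6g")
        log.info("coexpression over %d genes, %d samples", len(coex.genes), coex.n_samples)

        # --- motifs -------------------------------------------------------
        promoters, _ = extract_promoters(
            fixture / "genome.fa", fixture / "tss.bed", config.promoter_length
        )
        pwms = read_jaspar(fixture / "motifs.jaspar")
        hits = scan_promoters(pwms, promoters, config.motif_score_fraction)
        hits.to_csv(out / "hits.tsv", sep="\t", index=False, float_format="%.6g")
        enrichment = cre_enrichment(
            hits, de_genes, promoters.keys(), config.enrichment_q_max
        )
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        tf_motifs = pd.read_csv(fixture / "tf_motifs.tsv", sep="\t")
        binding = build_binding_map(hits, enrichment, tf_motifs, de_genes)
        binding.to_csv(out / "binding_map.tsv", sep="\t", index=False, float_format="%.6g")
        summary["n_hits"] = int(len(hits))
        summary["n_enriched_motifs"] = int(enrichment["enriched"].sum()) if len(enrichment) else 0
        summary["n_binding_pairs"] = int(len(binding))
        log.info("motifs: %(n_hits)d hits, %(n_enriched_motifs)d enriched, "
                 "%(n_binding_pairs)d binding pairs", summary)

        # --- network ------------------------------------------------------
        tf_list = (fixture / "tf_list.txt").read_text().split()
        pathway_path = fixture / "pathway_genes.txt"
        pathway = pathway_path.read_text().split() if pathway_path.exists() else []
        network = assemble_grn(
            de_genes,
            coex,
            binding,
            tf_list,
            pcc_min=config.pcc_min,
            q_max=config.edge_q_max,
            sign=config.sign,
            mr_max=config.mr_max,
            de_table=de_table,
            pathway_genes=pathway,
            all_genes=dataset.genes,
        )
        export_network(network, out)
        net_summary = summarize_network(network, pathway)
        summary["network"] = net_summary.to_dict()
        log.info("network: %d nodes, %d edges", network.n_nodes, network.n_edges)

        if truth.true_edges:
            summary["recovery"] = evaluate_recovery(network, truth.true_edges)
            log.info("recovery: %s", summary["recovery"])

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        return summary
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
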