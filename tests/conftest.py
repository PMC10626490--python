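import numpy as np
import pandas as pd
import pytest

from waxgrn.config import PipelineConfig, SimulationConfig
from waxgrn.coexpression import coexpress
from waxgrn.expression import ExpressionDataset, differential_expression, select_de_genes
from waxgrn.motifs import (
    build_binding_map,
    cre_enrichment,
    extract_promoters,
    read_jaspar,
    scan_promoters,
)
from waxgrn.network import assemble_grn
from waxgrn.simulate import generate_celltype_counts, generate_promoters, write_fixture

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    return generate_celltype_counts(sim_config)


@pytest.fixture(scope="session")
def promoter_fixture(sim_config, sim_data):
    _, truth = sim_data
    return generate_promoters(truth, sim_config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config, sim_data, promoter_fixture):
    dataset, truth = sim_data
    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(dataset, truth, promoter_fixture, out)


@pytest.fixture(scope="session")
def stages(fixture_dir, sim_data):
    """The pipeline's stages run once, in memory, on the default fixture."""
    dataset, truth = sim_data
    cfg = PipelineConfig()
    de_table = differential_expression(
        dataset, cfg.epidermis_label, cfg.tpm_min, cfg.pseudocount,
        cfg.fold_min, cfg.de_fdr_max,
    )
    de_genes = select_de_genes(de_table, cfg.fold_min, cfg.de_fdr_max)
    coex = coexpress(dataset.tpm.loc[de_genes], dataset.samples, cfg.sample_mode)
    promoters, _ = extract_promoters(
        fixture_dir / "genome.fa", fixture_dir / "tss.bed", cfg.promoter_length
    )
    pwms = read_jaspar(fixture_dir / "motifs.jaspar")
    hits = scan_promoters(pwms, promoters, cfg.motif_score_fraction)
    enrichment = cre_enrichment(hits, de_genes, promoters.keys(), cfg.enrichment_q_max)
    tf_motifs = pd.read_csv(fixture_dir / "tf_motifs.tsv", sep="\t")
    binding = build_binding_map(hits, enrichment, tf_motifs, de_genes)
    network = assemble_grn(
        de_genes, coex, binding, sorted(truth.tf_ids),
        pcc_min=cfg.pcc_min, q_max=cfg.edge_q_max, sign=cfg.sign,
        de_table=de_table, pathway_genes=sorted({t for _, t in truth.true_edges}),
    )
    return {
        "config": cfg,
        "dataset": dataset,
        "truth": truth,
        "de_table": de_table,
        "de_genes": de_genes,
        "coex": coex,
        "promoters": promoters,
        "pwms": pwms,
        "hits": hits,
        "enrichment": enrichment,
        "binding": binding,
        "network": network,
    }


def make_dataset(tpm_rows: dict, cell_types=("A", "B"), replicates=3,
                 counts_rows: dict | None = None) -> ExpressionDataset:
    """Small dataset helper: a filler gene absorbs the TPM remainder so each
    column sums to 1e6."""
    samples = [f"{c}_r{r+1}" for c in cell_types for r in range(replicates)]
    tpm = pd.DataFrame(tpm_rows, index=samples).T
    tpm.columns = samples
    filler = 1e6 - tpm.sum(axis=0)
    if (filler < 0).any():
        raise ValueError("TPM rows exceed 1e6")
    tpm.loc["filler"] = filler
    if counts_rows is None:
        counts = tpm.round().astype(int)
    else:
        counts = pd.DataFrame(counts_rows, index=samples).T
        counts.columns = samples
        counts.loc["filler"] = 1000
    meta = pd.DataFrame(
        {
            "cell_type": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionDataset(counts.loc[tpm.index], tpm, meta)
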