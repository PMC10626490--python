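"""Synthetic cell-type transcriptomes with a planted regulatory network.

The generator emulates a laser-capture cell-type RNA-seq study: six stem cell
types x 3 replicates, negative-binomial gene counts, an epidermis-upregulated
gene module, transcription factors whose targets track their log-expression
profile, and 1 kb promoters carrying the TFs' binding motifs. All of the
planted structure (module membership, TF->target edges, motif placements) is
returned as ground truth so every downstream stage can be verified exactly.

Setting ``nb_dispersion=0`` gives the deterministic noise-free limit: counts
equal the rounded expected means, so planted couplings are exact up to integer
rounding. The unrounded expected-mean matrix is exposed on ``PlantedTruth``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import ConfigurationError, SimulationConfig
from .expression import ExpressionDataset, tpm_from_counts

__all__ = [
    "PlantedTruth",
    "PromoterFixture",
    "generate_celltype_counts",
    "generate_promoters",
    "write_fixture",
    "read_fixture",
    "generate_fixture",
]

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    epidermis_module: set[str]
    tf_ids: set[str]
    true_edges: set[tuple[str, str]]
    motif_placements: list[tuple[str, str, int, str]] = field(default_factory=list)
    fold_change: Optional[pd.Series] = None
    tf_of_target: dict[str, str] = field(default_factory=dict)
    motif_of_tf: dict[str, str] = field(default_factory=dict)
    expected_mean: Optional[pd.DataFrame] = None
    depth: Optional[pd.Series] = None  # per-sample sequencing-depth factor

    def validate(self, promoter_length: Optional[int] = None, motif_length: Optional[int] = None) -> None:
        for tf, tgt in self.true_edges:
            if tf not in self.tf_ids:
                raise ValueError(f"edge source {tf} is not a TF")
        if not self.tf_ids <= self.epidermis_module:
            raise ValueError("tf_ids must be a subset of the epidermis module")
        targets = {t for _, t in self.true_edges}
        if not targets <= self.epidermis_module:
            raise ValueError("targets must be a subset of the epidermis module")
        if self.motif_placements:
            placed = {(g, m) for g, m, _, _ in self.motif_placements}
            for tf, tgt in self.true_edges:
                motif = self.motif_of_tf.get(tf)
                if motif is not None and (tgt, motif) not in placed:
                    raise ValueError(f"edge ({tf}, {tgt}) lacks a planted motif placement")
            if promoter_length is not None and motif_length is not None:
                for g, m, off, strand in self.motif_placements:
                    if not 0 <= off <= promoter_length - motif_length:
                        raise ConfigurationError(
                            f"placement of {m} in {g} at offset {off} overruns the promoter"
                        )


@dataclass
class PromoterFixture:
    """Promoter sequences, genome layout, PWMs and annotation for the fixture."""

    promoters: dict[str, str]          # gene -> 1 kb promoter (5'->3', gene sense)
    contigs: dict[str, str]            # contig name -> genomic sequence
    tss: pd.DataFrame                  # BED6: chrom, start, end, name, score, strand
    pwms: dict[str, np.ndarray]        # motif id -> 4 x L count matrix (A,C,G,T rows)
    consensus: dict[str, str]          # motif id -> consensus sequence
    tf_motifs: pd.DataFrame            # columns: tf, motif


def _sample_names(config: SimulationConfig) -> list[str]:
    return [f"{c}_r{r+1}" for c in config.cell_types for r in range(config.replicates)]


def generate_celltype_counts(config: SimulationConfig) -> tuple[ExpressionDataset, PlantedTruth]:
    """Simulate the count/TPM matrices and the planted regulatory truth.

    Expected means are built on the log scale: a per-gene baseline, an
    ``epidermis_fold`` uplift for module genes in epidermis samples, a
    per-cell-type signature for each TF, and each target's profile equal to
    its TF's profile plus N(0, correlation_noise_sd) sample noise. Counts are
    negative-binomial around the means (deterministic rounding when
    ``nb_dispersion=0``); TPM follows from counts and simulated gene lengths.
    """
    config.validate()
    c = config
    rng = np.random.default_rng(np.random.SeedSequence([c.seed, 0]))

    width = max(4, len(str(c.n_genes)))
    gene_names = [f"g{i+1:0{width}d}" for i in range(c.n_genes)]
    genes = np.array(gene_names)
    gene_index = pd.Index(gene_names, name="gene")
    sample_names = _sample_names(c)
    n_samples = len(sample_names)
    celltype_of = np.repeat(np.arange(len(c.cell_types)), c.replicates)
    epi_type = list(c.cell_types).index(c.epidermis_label)
    epi_cols = celltype_of == epi_type

    perm = rng.permutation(c.n_genes)
    module_idx = perm[: c.module_size]
    tf_idx = module_idx[: c.n_tfs]
    target_idx = module_idx[c.n_tfs : c.n_tfs + c.n_tfs * c.targets_per_tf]
    target_of_tf = {
        int(tf_idx[k]): [int(t) for t in target_idx[k * c.targets_per_tf : (k + 1) * c.targets_per_tf]]
        for k in range(c.n_tfs)
    }

    base = rng.normal(c.base_log_mean, c.base_log_sd, c.n_genes)
    logmu = np.repeat(base[:, None], n_samples, axis=1)

    # epidermis uplift for the whole planted module
    logmu[np.ix_(module_idx, np.where(epi_cols)[0])] += np.log(c.epidermis_fold)

    # mild per-cell-type variation for genes outside the module
    bg_idx = np.setdiff1d(np.arange(c.n_genes), module_idx)
    bg_ct = rng.normal(0.0, c.background_celltype_sd, (bg_idx.size, len(c.cell_types)))
    logmu[bg_idx] += bg_ct[:, celltype_of]

    # per-cell-type signature for TFs, inherited by their targets; centred so
    # the arithmetic-mean fold of epidermis over the other cell types stays
    # exactly epidermis_fold (epidermis itself carries no signature)
    tf_sig = rng.normal(0.0, c.tf_signature_sd, (c.n_tfs, len(c.cell_types)))
    tf_sig[:, epi_type] = 0.0
    non_epi = np.arange(len(c.cell_types)) != epi_type
    tf_sig[:, non_epi] -= np.log(np.exp(tf_sig[:, non_epi]).mean(axis=1, keepdims=True))
    logmu[tf_idx] += tf_sig[:, celltype_of]
    for k, tf in enumerate(tf_idx):
        profile = logmu[tf] - base[tf]
        for tgt in target_of_tf[int(tf)]:
            eps = rng.normal(0.0, c.correlation_noise_sd, n_samples)
            logmu[tgt] = base[tgt] + profile + eps

    depth = rng.uniform(c.depth_low, c.depth_high, n_samples)
    mu = np.exp(logmu) * depth

    if c.nb_dispersion < 1e-12:
        counts = np.rint(mu).astype(np.int64)
    else:
        r = 1.0 / c.nb_dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p).astype(np.int64)

    lengths = rng.integers(500, 5001, c.n_genes)
    counts_df = pd.DataFrame(counts, index=gene_index, columns=sample_names)
    lengths_s = pd.Series(lengths, index=gene_index, name="length_bp")
    tpm_df = tpm_from_counts(counts_df, lengths_s)
    samples_df = pd.DataFrame(
        {
            "cell_type": [c.cell_types[t] for t in celltype_of],
            "replicate": [r + 1 for _ in c.cell_types for r in range(c.replicates)],
        },
        index=pd.Index(sample_names, name="sample"),
    )
    dataset = ExpressionDataset(counts_df, tpm_df, samples_df, lengths_s)

    fold = pd.Series(1.0, index=gene_index, name="true_fold_change")
    fold.iloc[module_idx] = c.epidermis_fold
    truth = PlantedTruth(
        epidermis_module=set(genes[module_idx]),
        tf_ids=set(genes[tf_idx]),
        true_edges={(genes[tf], genes[t]) for tf, ts in target_of_tf.items() for t in ts},
        fold_change=fold,
        tf_of_target={genes[t]: genes[tf] for tf, ts in target_of_tf.items() for t in ts},
        expected_mean=pd.DataFrame(mu, index=gene_index, columns=sample_names),
        depth=pd.Series(depth, index=sample_names, name="depth"),
    )
    truth.validate()
    return dataset, truth


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n)


def _scrub_near_matches(
    seq: np.ndarray,
    patterns: np.ndarray,
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    max_mismatch: int = 1,
    max_rounds: int = 50,
) -> np.ndarray:
    """Re-randomize windows within ``max_mismatch`` of any planted consensus.

    Background promoters are motif-free by construction: any window (either
    strand, via the pattern set containing reverse complements) at Hamming
    distance <= max_mismatch from a consensus, other than the planted
    placements themselves, is perturbed until none remain.
    """
    if patterns.size == 0:
        return seq
    L = patterns.shape[1]
    prot_mask = np.zeros(seq.size, dtype=bool)
    for a, b in protected:
        prot_mask[a:b] = True
    for _ in range(max_rounds):
        if seq.size < L:
            break
        windows = np.lib.stride_tricks.sliding_window_view(seq, L)
        mism = (windows[None, :, :] != patterns[:, None, :]).sum(axis=2).min(axis=0)
        starts = np.nonzero(mism <= max_mismatch)[0]
        starts = [s for s in starts if (s, s + L) not in protected]
        if not starts:
            return seq
        for s in starts:
            for k in range(s, s + L):
                if not prot_mask[k]:
                    seq[k] = rng.integers(0, 4)
    raise RuntimeError("failed to scrub near-matches from a promoter")


def _to_str(arr: np.ndarray) -> str:
    return "".join(BASES[arr])


def generate_promoters(
    truth: PlantedTruth, config: SimulationConfig
) -> PromoterFixture:
    """Build promoters, a per-gene genome layout, PWMs and the TSS annotation.

    Each gene gets its own contig with a uniform-random promoter; the motif
    consensus of each TF is written into its targets' promoters at random
    offsets/strands; promoters without a planted placement are scrubbed so no
    TF consensus (either strand) occurs in them by chance. One informative
    PWM per TF (dominant base 88/100 per column).
    """
    c = config
    rng = np.random.default_rng(np.random.SeedSequence([c.seed, 1]))
    if truth.fold_change is None:
        raise ValueError("truth must come from generate_celltype_counts")
    genes = list(truth.fold_change.index)
    L = c.motif_length
    tf_list = sorted(truth.tf_ids)

    # one informative PWM per TF
    pwms: dict[str, np.ndarray] = {}
    consensus: dict[str, str] = {}
    motif_of_tf: dict[str, str] = {}
    for i, tf in enumerate(tf_list):
        motif_id = f"M{i+1:03d}"
        cons = _random_seq(rng, L)
        pfm = np.full((4, L), 4, dtype=int)
        pfm[cons, np.arange(L)] = 88
        pwms[motif_id] = pfm
        consensus[motif_id] = _to_str(cons)
        motif_of_tf[tf] = motif_id
    truth.motif_of_tf = dict(motif_of_tf)

    # placements: one per planted edge
    placements: list[tuple[str, str, int, str]] = []
    for tf, tgt in sorted(truth.true_edges):
        off = int(rng.integers(0, c.promoter_length - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append((tgt, motif_of_tf[tf], off, strand))
    truth.motif_placements = placements
    truth.validate(c.promoter_length, c.motif_length)
    placed_by_gene: dict[str, list[tuple[str, int, str]]] = {}
    for g, m, off, strand in placements:
        placed_by_gene.setdefault(g, []).append((m, off, strand))

    patterns = {m: consensus[m] for m in consensus}
    all_patterns = sorted(set(patterns.values()) | {_revcomp(p) for p in patterns.values()})
    pattern_arr = np.array(
        [["ACGT".index(b) for b in p] for p in all_patterns], dtype=np.int8
    ) if all_patterns else np.empty((0, L), dtype=np.int8)

    promoters: dict[str, str] = {}
    for g in genes:
        seq = _random_seq(rng, c.promoter_length).astype(np.int8)
        protected: list[tuple[int, int]] = []
        for m, off, strand in placed_by_gene.get(g, []):
            if off + L > c.promoter_length:
                raise ConfigurationError(
                    f"placement of {m} in {g} at offset {off} overruns the promoter"
                )
            word = patterns[m] if strand == "+" else _revcomp(patterns[m])
            seq[off : off + L] = np.array(["ACGT".index(b) for b in word], dtype=np.int8)
            protected.append((off, off + L))
        seq = _scrub_near_matches(seq, pattern_arr, protected, rng)
        promoters[g] = _to_str(seq)

    # genome layout: one contig per gene, strand alternating deterministically
    contigs: dict[str, str] = {}
    rows = []
    for i, g in enumerate(genes):
        contig = f"ctg_{g}"
        pad = _to_str(_random_seq(rng, 20))
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            contigs[contig] = promoters[g] + pad
            tss = c.promoter_length
        else:
            lead = _to_str(_random_seq(rng, 1))
            contigs[contig] = lead + _revcomp(promoters[g]) + pad
            tss = 0
        rows.append((contig, tss, tss + 1, g, 0, strand))
    tss_df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    tf_motifs = pd.DataFrame(
        sorted(motif_of_tf.items()), columns=["tf", "motif"]
    )
    return PromoterFixture(promoters, contigs, tss_df, pwms, consensus, tf_motifs)


def _write_jaspar(pwms: dict[str, np.ndarray], path: Path) -> None:
    records = []
    for motif_id, pfm in sorted(pwms.items()):
        counts = {b: [float(v) for v in pfm[i]] for i, b in enumerate("ACGT")}
        m = bio_motifs.Motif(alphabet="ACGT", counts=counts)
        m.matrix_id = motif_id
        m.name = motif_id
        records.append(m)
    path.write_text(bio_motifs.write(records, "jaspar"))


def write_fixture(
    dataset: ExpressionDataset,
    truth: PlantedTruth,
    promoters: PromoterFixture,
    outdir: str | Path,
) -> Path:
    """Write a self-contained fixture directory consumable by the CLI."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    dataset.counts.rename_axis("gene").to_csv(out / "counts.tsv", sep="\t")
    dataset.tpm.rename_axis("gene").to_csv(out / "tpm.tsv", sep="\t", float_format="%.6f")
    dataset.samples.rename_axis("sample").to_csv(out / "samples.tsv", sep="\t")
    if dataset.gene_lengths is not None:
        dataset.gene_lengths.rename_axis("gene").to_csv(out / "gene_lengths.tsv", sep="\t")

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(promoters.contigs.items())
    ]
    SeqIO.write(records, out / "genome.fa", "fasta")
    promoters.tss.to_csv(out / "tss.bed", sep="\t", header=False, index=False)
    _write_jaspar(promoters.pwms, out / "motifs.jaspar")
    promoters.tf_motifs.to_csv(out / "tf_motifs.tsv", sep="\t", index=False)

    (out / "tf_list.txt").write_text("\n".join(sorted(truth.tf_ids)) + "\n")
    edges = pd.DataFrame(sorted(truth.true_edges), columns=["tf", "target"])
    edges.to_csv(out / "truth_edges.tsv", sep="\t", index=False)
    (out / "module_genes.txt").write_text("\n".join(sorted(truth.epidermis_module)) + "\n")
    pathway = sorted({t for _, t in truth.true_edges})
    (out / "pathway_genes.txt").write_text("\n".join(pathway) + "\n")
    pd.DataFrame(
        truth.motif_placements, columns=["gene", "motif", "offset", "strand"]
    ).to_csv(out / "placements.tsv", sep="\t", index=False)
    return out


def read_fixture(fixture_dir: str | Path) -> tuple[ExpressionDataset, PlantedTruth]:
    """Load a fixture directory back into in-memory objects."""
    d = Path(fixture_dir)
    counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col=0)
    tpm = pd.read_csv(d / "tpm.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(d / "samples.tsv", sep="\t", index_col=0)
    lengths = None
    if (d / "gene_lengths.tsv").exists():
        lengths = pd.read_csv(d / "gene_lengths.tsv", sep="\t", index_col=0).iloc[:, 0]
    dataset = ExpressionDataset(counts, tpm, samples, lengths)

    tfs = set((d / "tf_list.txt").read_text().split())
    edges_df = pd.read_csv(d / "truth_edges.tsv", sep="\t")
    module = set((d / "module_genes.txt").read_text().split())
    placements: list[tuple[str, str, int, str]] = []
    if (d / "placements.tsv").exists():
        pl = pd.read_csv(d / "placements.tsv", sep="\t")
        placements = [tuple(r) for r in pl.itertuples(index=False)]
    motif_of_tf = {}
    if (d / "tf_motifs.tsv").exists():
        tm = pd.read_csv(d / "tf_motifs.tsv", sep="\t")
        motif_of_tf = dict(zip(tm["tf"], tm["motif"]))
    truth = PlantedTruth(
        epidermis_module=module,
        tf_ids=tfs,
        true_edges={(r.tf, r.target) for r in edges_df.itertuples(index=False)},
        motif_placements=placements,
        motif_of_tf=motif_of_tf,
    )
    return dataset, truth


def generate_fixture(config: SimulationConfig, outdir: str | Path) -> Path:
    """Convenience: simulate counts + promoters and write the fixture."""
    dataset, truth = generate_celltype_counts(config)
    promoters = generate_promoters(truth, config)
    return write_fixture(dataset, truth, promoters, outdir)
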