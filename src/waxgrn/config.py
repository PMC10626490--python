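"""Configuration objects for the simulation and the analysis pipeline.

All thresholds default to the values used throughout the package: genes must
reach 5 TPM in at least one cell type (mean of replicates), differential
expression requires a fold change of at least 5 at FDR < 0.05, network edges
require PCC >= 0.9 at correlation FDR <= 0.05 plus promoter-binding support,
and promoters span 1 kb upstream of the transcription start site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates one of its invariants."""


DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "epidermis",
    "pith_parenchyma",
    "phloem",
    "bundle_sheath",
    "xylem",
    "vascular_parenchyma",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cell-type transcriptome generator.

    The defaults emulate a laser-capture stem cell-type study: six cell
    types x 3 biological replicates, an epidermis-upregulated module of 200
    genes (8-fold above the other cell types, comfortably above the 5-fold
    selection threshold), 10 transcription factors each driving 5 targets
    whose log-expression tracks the TF's profile, negative-binomial counts,
    and 1 kb promoters carrying the TFs' binding motifs.
    """

    n_genes: int = 2000
    n_tfs: int = 10
    targets_per_tf: int = 5
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    replicates: int = 3
    epidermis_fold: float = 8.0
    nb_dispersion: float = 0.02
    correlation_noise_sd: float = 0.05
    module_size: int = 200
    promoter_length: int = 1000
    motif_length: int = 10
    seed: int = 0
    # secondary generator knobs (see docs/methods.md for rationale)
    tf_signature_sd: float = 0.8
    background_celltype_sd: float = 0.2
    base_log_mean: float = math.log(150.0)
    base_log_sd: float = 0.7
    depth_low: float = 0.7
    depth_high: float = 1.3
    epidermis_label: str = "epidermis"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self
        if c.n_genes < 1 or c.n_tfs < 0 or c.targets_per_tf < 0:
            raise ConfigurationError("n_genes, n_tfs and targets_per_tf must be positive counts")
        if c.n_tfs * c.targets_per_tf > c.n_genes - c.n_tfs:
            raise ConfigurationError(
                "invariant violated: targets_per_tf * n_tfs <= n_genes - n_tfs"
            )
        if c.epidermis_fold <= 1:
            raise ConfigurationError("invariant violated: epidermis_fold > 1")
        if c.promoter_length < c.motif_length:
            raise ConfigurationError("invariant violated: promoter_length >= motif_length")
        if c.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be nonnegative")
        if c.correlation_noise_sd < 0:
            raise ConfigurationError("correlation_noise_sd must be nonnegative")
        if c.replicates < 2:
            raise ConfigurationError("replicates must be >= 2 (group dispersion inestimable)")
        if c.epidermis_label not in c.cell_types:
            raise ConfigurationError("epidermis_label must be one of cell_types")
        if len(set(c.cell_types)) != len(c.cell_types):
            raise ConfigurationError("cell_types must be distinct")
        if c.module_size < c.n_tfs * (c.targets_per_tf + 1):
            raise ConfigurationError(
                "module_size must cover all TFs and their targets: "
                "module_size >= n_tfs * (targets_per_tf + 1)"
            )
        if c.module_size > c.n_genes:
            raise ConfigurationError("module_size must not exceed n_genes")
        if not 0 < c.depth_low <= c.depth_high:
            raise ConfigurationError("depth range must satisfy 0 < depth_low <= depth_high")

    @property
    def n_samples(self) -> int:
        return len(self.cell_types) * self.replicates


@dataclass
class PipelineConfig:
    """Thresholds and modes of the end-to-end GRN analysis.

    The defaults reproduce the published selection rules verbatim:
    ``tpm_min=5`` (expression filter on cell-type means), ``fold_min=5`` with
    ``de_fdr_max=0.05`` (DE selection; fold inclusive, FDR strict),
    ``pcc_min=0.9`` with ``edge_q_max=0.05`` (edge rule; both inclusive),
    1 kb promoters, and 0.05 motif-enrichment FDR.
    """

    tpm_min: float = 5.0
    fold_min: float = 5.0
    de_fdr_max: float = 0.05
    pcc_min: float = 0.9
    edge_q_max: float = 0.05
    promoter_length: int = 1000
    motif_score_fraction: float = 0.85
    enrichment_q_max: float = 0.05
    sign: str = "positive"
    mr_max: Optional[float] = None
    sample_mode: str = "replicates"
    pseudocount: float = 0.5
    epidermis_label: str = "epidermis"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sign not in ("positive", "negative"):
            raise ConfigurationError("sign must be 'positive' or 'negative'")
        if self.sample_mode not in ("replicates", "celltype_means"):
            raise ConfigurationError("sample_mode must be 'replicates' or 'celltype_means'")
        for name in ("tpm_min", "fold_min", "de_fdr_max", "pcc_min", "edge_q_max",
                     "motif_score_fraction", "enrichment_q_max", "pseudocount"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.promoter_length < 1:
            raise ConfigurationError("promoter_length must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
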