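"""Promoter extraction, log-odds PWM scanning, CRE enrichment and the
TF -> target binding map.

Promoters span 1 kb upstream of the transcription start site (strand-aware,
0-based half-open coordinates). Position frequency matrices are scored as
log-odds against a background composition; a window is a hit when its score
reaches a configurable fraction of the attainable score range (default 0.85).
Motif over-representation in a foreground promoter set is tested with a
one-sided Fisher's exact test on promoter presence/absence, BH-corrected
across motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta
from scipy import stats

from .expression import bh_fdr

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "read_jaspar",
    "extract_promoters",
    "pwm_log_odds",
    "scan_promoter",
    "scan_promoters",
    "cre_enrichment",
    "build_binding_map",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
UNIFORM_BG = np.full(4, 0.25)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionWeightMatrix:
    """A motif's 4 x L position frequency matrix (rows A, C, G, T)."""

    motif_id: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if (self.counts < 0).any():
            raise ValueError("frequencies must be nonnegative")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    gene_id: str
    start: int  # 0-based offset within the promoter
    strand: str
    score: float


def read_jaspar(path: str | Path) -> list[PositionWeightMatrix]:
    """Read a JASPAR-format PFM library."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(PositionWeightMatrix(m.matrix_id or m.name, counts))
    return out


def extract_promoters(
    genome_fasta: str | Path,
    tss: pd.DataFrame | str | Path,
    length: int = 1000,
) -> tuple[dict[str, str], dict[str, bool]]:
    """Strand-aware promoters of ``length`` bases upstream of each TSS.

    For a + strand gene with TSS at t the promoter is the half-open interval
    [t - length, t); for a - strand gene it is the reverse complement of
    [t + 1, t + 1 + length). Promoters running off a contig edge are
    truncated and flagged. Returns ``(promoters, truncated_flags)``.
    """
    if not isinstance(tss, pd.DataFrame):
        tss = pd.read_csv(
            tss, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
    fasta = Fasta(str(genome_fasta), as_raw=True, rebuild=False)
    promoters: dict[str, str] = {}
    truncated: dict[str, bool] = {}
    for row in tss.itertuples(index=False):
        if row.chrom not in fasta:
            raise KeyError(f"contig {row.chrom} absent from FASTA")
        contig = fasta[row.chrom]
        clen = len(contig)
        t = int(row.start)
        if not 0 <= t < clen:
            warnings.warn(f"TSS of {row.name} outside contig bounds; skipped")
            continue
        if row.strand == "+":
            lo = max(0, t - length)
            seq = str(contig[lo:t]).upper()
            truncated[row.name] = lo > t - length
        else:
            hi = min(clen, t + 1 + length)
            seq = _revcomp(str(contig[t + 1 : hi]).upper())
            truncated[row.name] = hi < t + 1 + length
        promoters[row.name] = seq
    return promoters, truncated


def pwm_log_odds(
    pfm: PositionWeightMatrix | np.ndarray,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.25,
) -> np.ndarray:
    """Log2-odds scoring matrix from a position frequency matrix.

    ``score[b, k] = log2(((freq[b, k] + pc * bg[b]) / (col_total + pc)) / bg[b])``.
    """
    if isinstance(pfm, PositionWeightMatrix):
        counts = pfm.counts
        if background is None:
            background = pfm.background
        pseudocount = pfm.pseudocount if pseudocount == 0.25 else pseudocount
    else:
        counts = np.asarray(pfm, dtype=float)
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if (bg <= 0).any():
        raise ValueError("background probabilities must be positive")
    totals = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    return np.log2(probs / bg[:, None])


def _encode(seq: str) -> np.ndarray:
    lut = np.full(128, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(enc: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Score every window of length L; windows containing N give NaN."""
    L = scores.shape[1]
    n_win = enc.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    padded = np.vstack([scores, np.full((1, L), np.nan)])  # row 4 = N
    total = np.zeros(n_win)
    for k in range(L):
        total += padded[enc[k : k + n_win], k]
    return total


def _revcomp_matrix(scores: np.ndarray) -> np.ndarray:
    return scores[::-1, ::-1]


def scan_promoter(
    scores: np.ndarray,
    sequence: str,
    min_score_fraction: float = 0.85,
    motif_id: str = "motif",
    gene_id: str = "gene",
) -> list[MotifHit]:
    """Slide a log-odds matrix over both strands of one promoter.

    A window is a hit when its score reaches ``min_score_fraction`` of the
    attainable score range above the minimum. Windows containing N are
    skipped; both-strand hits at the same position keep the higher score
    (forward wins ties). A motif longer than the sequence yields no hits.
    """
    L = scores.shape[1]
    if L > len(sequence):
        return []
    smax = scores.max(axis=0).sum()
    smin = scores.min(axis=0).sum()
    threshold = smin + min_score_fraction * (smax - smin)

    enc = _encode(sequence)
    fwd = _window_scores(enc, scores)
    rev = _window_scores(enc, _revcomp_matrix(scores))

    hits: list[MotifHit] = []
    with np.errstate(invalid="ignore"):
        fwd_ok = np.nan_to_num(fwd, nan=-np.inf) >= threshold - 1e-12
        rev_ok = np.nan_to_num(rev, nan=-np.inf) >= threshold - 1e-12
    for pos in np.nonzero(fwd_ok | rev_ok)[0]:
        f = fwd[pos] if fwd_ok[pos] else -np.inf
        r = rev[pos] if rev_ok[pos] else -np.inf
        if f >= r:
            hits.append(MotifHit(motif_id, gene_id, int(pos), "+", float(f)))
        else:
            hits.append(MotifHit(motif_id, gene_id, int(pos), "-", float(r)))
    return hits


def scan_promoters(
    pwms: Sequence[PositionWeightMatrix],
    promoters: Mapping[str, str],
    min_score_fraction: float = 0.85,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.25,
) -> pd.DataFrame:
    """Scan every promoter with every PWM; long-format hit table.

    Concatenates promoters (N-separated) so each motif is scanned in a single
    vectorized pass; equivalent to calling :func:`scan_promoter` per gene.
    """
    genes = list(promoters)
    seqs = [promoters[g] for g in genes]
    joined = ("N" * 64).join(seqs)
    enc = _encode(joined)
    offsets = np.cumsum([0] + [len(s) + 64 for s in seqs[:-1]])
    bounds = [(off, off + len(s)) for off, s in zip(offsets, seqs)]

    rows = []
    for pwm in pwms:
        scores = pwm_log_odds(pwm, background, pseudocount)
        L = scores.shape[1]
        smax = scores.max(axis=0).sum()
        smin = scores.min(axis=0).sum()
        threshold = smin + min_score_fraction * (smax - smin)
        fwd = _window_scores(enc, scores)
        rev = _window_scores(enc, _revcomp_matrix(scores))
        fwd_ok = np.nan_to_num(fwd, nan=-np.inf) >= threshold - 1e-12
        rev_ok = np.nan_to_num(rev, nan=-np.inf) >= threshold - 1e-12
        hit_pos = np.nonzero(fwd_ok | rev_ok)[0]
        if hit_pos.size == 0:
            continue
        gene_idx = np.searchsorted(offsets, hit_pos, side="right") - 1
        for pos, gi in zip(hit_pos, gene_idx):
            lo, hi = bounds[gi]
            if not (lo <= pos and pos + L <= hi):
                continue  # separator-spanning windows carry N and never hit
            f = fwd[pos] if fwd_ok[pos] else -np.inf
            r = rev[pos] if rev_ok[pos] else -np.inf
            strand, score = ("+", f) if f >= r else ("-", r)
            rows.append((pwm.motif_id, genes[gi], int(pos - lo), strand, float(score)))
    return pd.DataFrame(rows, columns=["motif", "gene", "start", "strand", "score"])


def cre_enrichment(
    hits: pd.DataFrame,
    foreground: Iterable[str],
    background: Iterable[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-motif over-representation of promoter hits in the foreground set.

    2x2 table of promoters with/without >= 1 hit, foreground vs
    background-minus-foreground; one-sided Fisher's exact p, BH q across
    motifs, enriched flag at ``q < q_threshold``.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValueError("empty foreground gene set")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    rest = bg - fg

    motif_genes = hits.groupby("motif")["gene"].agg(set) if len(hits) else pd.Series(dtype=object)
    rows = []
    for motif in sorted(motif_genes.index):
        with_hit = motif_genes[motif]
        a = len(with_hit & fg)
        b = len(fg) - a
        c = len(with_hit & rest)
        d = len(rest) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((motif, a, len(fg), c, len(rest), float(p)))
    table = pd.DataFrame(
        rows, columns=["motif", "fg_with_hit", "fg_total", "bg_with_hit", "bg_total", "p"]
    )
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    table["enriched"] = table["q"] < q_threshold
    return table


def build_binding_map(
    hits: pd.DataFrame,
    enrichment: pd.DataFrame,
    tf_motifs: pd.DataFrame,
    de_genes: Iterable[str],
    include_self: bool = False,
) -> pd.DataFrame:
    """TF -> target binding evidence from enriched motifs.

    One row per (tf, target, motif) where the target is in the DE gene set
    and its promoter carries >= 1 hit of an enriched motif mapped to the TF;
    self pairs are excluded by default. Motifs without a TF mapping are
    dropped with a warning.
    """
    de = set(de_genes)
    motif_to_tf = dict(zip(tf_motifs["motif"], tf_motifs["tf"]))
    unmapped = sorted(set(hits["motif"]) - set(motif_to_tf)) if len(hits) else []
    if unmapped:
        warnings.warn(f"dropping hits of unmapped motif(s): {unmapped}")
    enriched_q = dict(zip(enrichment["motif"], enrichment["q"]))
    enriched_set = set(enrichment.loc[enrichment["enriched"], "motif"])

    rows = []
    if len(hits):
        best = hits.groupby(["motif", "gene"])["score"].max().reset_index()
        for r in best.itertuples(index=False):
            tf = motif_to_tf.get(r.motif)
            if tf is None or r.motif not in enriched_set:
                continue
            if r.gene not in de:
                continue
            if not include_self and r.gene == tf:
                continue
            rows.append((tf, r.gene, r.motif, float(r.score), float(enriched_q[r.motif])))
    out = pd.DataFrame(rows, columns=["tf", "target", "motif", "best_score", "enrichment_q"])
    out["enriched"] = True
    return out.sort_values(["tf", "target"]).reset_index(drop=True)
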