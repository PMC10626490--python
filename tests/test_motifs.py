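"""Promoter extraction, PWM scoring/scanning, enrichment, binding map."""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
import pytest

from waxgrn.motifs import (
    PositionWeightMatrix,
    build_binding_map,
    cre_enrichment,
    extract_promoters,
    pwm_log_odds,
    read_jaspar,
    scan_promoter,
    scan_promoters,
)

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

def _write_fasta(tmp_path, records):
    path = tmp_path / "genome.fa"
    path.write_text("".join(f">{name}\n{seq}\n" for name, seq in records.items()))
    return path


def test_extract_promoter_plus_strand_convention(tmp_path):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 1200))
    fasta = _write_fasta(tmp_path, {"chr1": seq})
    tss = pd.DataFrame([("chr1", 1000, 1001, "gene1", 0, "+")],
                       columns=["chrom", "start", "end", "name", "score", "strand"])
    promoters, truncated = extract_promoters(fasta, tss, length=1000)
    assert promoters["gene1"] == seq[0:1000]
    assert not truncated["gene1"]


def test_extract_promoter_minus_strand_convention(tmp_path):
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), 1200))
    fasta = _write_fasta(tmp_path, {"chr1": seq})
    t = 100
    tss = pd.DataFrame([("chr1", t, t + 1, "gene1", 0, "-")],
                       columns=["chrom", "start", "end", "name", "score", "strand"])
    promoters, truncated = extract_promoters(fasta, tss, length=1000)
    assert promoters["gene1"] == revcomp(seq[t + 1 : t + 1 + 1000])
    assert not truncated["gene1"]


def test_extract_promoter_truncated_at_contig_edge(tmp_path):
    fasta = _write_fasta(tmp_path, {"chr1": "ACGT" * 50})
    tss = pd.DataFrame([("chr1", 100, 101, "gene1", 0, "+")],
                       columns=["chrom", "start", "end", "name", "score", "strand"])
    promoters, truncated = extract_promoters(fasta, tss, length=1000)
    assert len(promoters["gene1"]) == 100
    assert truncated["gene1"]


def test_extract_promoter_missing_contig_errors(tmp_path):
    fasta = _write_fasta(tmp_path, {"chr1": "ACGT" * 300})
    tss = pd.DataFrame([("chrX", 100, 101, "gene1", 0, "+")],
                       columns=["chrom", "start", "end", "name", "score", "strand"])
    with pytest.raises(KeyError, match="chrX"):
        extract_promoters(fasta, tss, length=50)


def test_extraction_reproduces_generator_promoters(fixture_dir, promoter_fixture):
    promoters, _ = extract_promoters(fixture_dir / "genome.fa", fixture_dir / "tss.bed",
                                     length=1000)
    assert promoters == promoter_fixture.promoters


# ---------------------------------------------------------------------------
# PWM log-odds
# ---------------------------------------------------------------------------

def test_log_odds_uniform_matrix_scores_zero():
    pfm = np.full((4, 6), 25.0)
    scores = pwm_log_odds(pfm)
    assert np.allclose(scores, 0.0, atol=1e-12)


def test_log_odds_pure_column_approaches_two_bits():
    pfm = np.zeros((4, 1))
    pfm[0, 0] = 100.0
    score = pwm_log_odds(pfm, pseudocount=1e-9)
    assert score[0, 0] == pytest.approx(2.0, abs=1e-6)


def test_log_odds_rejects_zero_background():
    with pytest.raises(ValueError):
        pwm_log_odds(np.ones((4, 3)), background=np.array([0.5, 0.5, 0.0, 0.0]))


@pytest.mark.parametrize("L", [3, 5, 8])
def test_max_kmer_score_is_sum_of_column_maxima(L):
    rng = np.random.default_rng(L)
    pfm = rng.integers(0, 50, size=(4, L)).astype(float)
    scores = pwm_log_odds(pfm)
    best = max(
        sum(scores["ACGT".index(b), k] for k, b in enumerate(kmer))
        for kmer in ("".join(t) for t in product("ACGT", repeat=L))
    )
    assert best == pytest.approx(scores.max(axis=0).sum(), abs=1e-12)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _informative_pwm(consensus):
    pfm = np.full((4, len(consensus)), 4.0)
    for k, b in enumerate(consensus):
        pfm["ACGT".index(b), k] = 88.0
    return PositionWeightMatrix("M1", pfm)


def test_scan_finds_planted_consensus_at_max_score():
    rng = np.random.default_rng(2)
    cons = "ACGTACGTTG"
    seq = list(rng.choice(list("ACGT"), 300))
    seq[100:110] = list(cons)
    seq = "".join(seq)
    scores = pwm_log_odds(_informative_pwm(cons))
    hits = scan_promoter(scores, seq, motif_id="M1", gene_id="g")
    exact = [h for h in hits if h.start == 100]
    assert exact and exact[0].strand == "+"
    assert exact[0].score == pytest.approx(scores.max(axis=0).sum())


def test_scan_reports_reverse_complement_hits():
    rng = np.random.default_rng(3)
    cons = "AACCGGTTAC"
    seq = list(rng.choice(list("ACGT"), 300))
    seq[50:60] = list(revcomp(cons))
    seq = "".join(seq)
    scores = pwm_log_odds(_informative_pwm(cons))
    hits = scan_promoter(scores, seq)
    exact = [h for h in hits if h.start == 50]
    assert exact and exact[0].strand == "-"


def test_scan_mirror_property_on_reverse_complement():
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), 500))
    pfm = PositionWeightMatrix("M1", rng.integers(1, 60, size=(4, 8)).astype(float))
    scores = pwm_log_odds(pfm)
    fwd_hits = scan_promoter(scores, seq, min_score_fraction=0.7)
    rev_hits = scan_promoter(scores, revcomp(seq), min_score_fraction=0.7)
    L = 8
    n = len(seq)
    mirrored = {(n - L - h.start, {"+": "-", "-": "+"}[h.strand], round(h.score, 9))
                for h in fwd_hits}
    got = {(h.start, h.strand, round(h.score, 9)) for h in rev_hits}
    assert got == mirrored


def test_scan_skips_windows_containing_n():
    cons = "ACGTAC"
    scores = pwm_log_odds(_informative_pwm(cons))
    seq = "ACGTAC" + "N" + "ACGTAC"
    hits = scan_promoter(scores, seq, min_score_fraction=0.99)
    assert {h.start for h in hits} == {0, 7}


def test_scan_motif_longer_than_sequence_yields_empty():
    scores = pwm_log_odds(_informative_pwm("ACGTACGTAC"))
    assert scan_promoter(scores, "ACGT") == []


def _bruteforce_scan(scores, seq, frac):
    L = scores.shape[1]
    smax = scores.max(axis=0).sum()
    smin = scores.min(axis=0).sum()
    thr = smin + frac * (smax - smin)
    found = {}
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if "N" in window:
            continue
        for strand, w in (("+", window), ("-", revcomp(window))):
            s = sum(scores["ACGT".index(b), k] for k, b in enumerate(w))
            if s >= thr - 1e-12:
                if start not in found or s > found[start][1]:
                    found[start] = (strand, s)
    return {(pos, strand, round(s, 9)) for pos, (strand, s) in found.items()}


@pytest.mark.parametrize("seed", range(3))
def test_scan_matches_bruteforce_enumeration(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    pfm = PositionWeightMatrix("M1", rng.integers(0, 40, size=(4, 8)).astype(float))
    scores = pwm_log_odds(pfm)
    hits = scan_promoter(scores, seq, min_score_fraction=0.75)
    got = {(h.start, h.strand, round(h.score, 9)) for h in hits}
    assert got == _bruteforce_scan(scores, seq, 0.75)


def test_batch_scanner_equals_per_promoter_scan(stages):
    pwms = stages["pwms"]
    promoters = dict(list(stages["promoters"].items())[:50])
    batch = scan_promoters(pwms, promoters, 0.85)
    singles = []
    for pwm in pwms:
        scores = pwm_log_odds(pwm)
        for gene, seq in promoters.items():
            for h in scan_promoter(scores, seq, 0.85, pwm.motif_id, gene):
                singles.append((h.motif_id, h.gene_id, h.start, h.strand, round(h.score, 9)))
    got = {(r.motif, r.gene, r.start, r.strand, round(r.score, 9))
           for r in batch.itertuples(index=False)}
    assert got == set(singles)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) for X ~ Hypergeometric(N, K, n) by exact summation."""
    n_fg, total_hits, N = a + b, a + c, a + b + c + d
    p = Fraction(0)
    for k in range(a, min(n_fg, total_hits) + 1):
        p += Fraction(math.comb(total_hits, k) * math.comb(N - total_hits, n_fg - k),
                      math.comb(N, n_fg))
    return float(p)


def _hits_df(pairs):
    return pd.DataFrame(pairs, columns=["motif", "gene", "start", "strand", "score"])


def test_enrichment_matches_hypergeometric_oracle():
    fg = [f"f{i}" for i in range(10)]
    bg_only = [f"b{i}" for i in range(90)]
    hits = _hits_df([("M1", g, 0, "+", 1.0) for g in fg[:8] + bg_only[:10]])
    table = cre_enrichment(hits, fg, fg + bg_only)
    assert table.loc[0, "p"] == pytest.approx(_hypergeom_tail_oracle(8, 2, 10, 80), abs=1e-12)


@pytest.mark.parametrize("seed", range(100))
def test_fisher_p_equals_bruteforce_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    a, b, c, d = rng.integers(0, 25, 4)
    from scipy.stats import fisher_exact
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    assert p == pytest.approx(_hypergeom_tail_oracle(int(a), int(b), int(c), int(d)),
                              abs=1e-10)


def test_enrichment_degenerate_cases():
    fg = ["f1", "f2"]
    bg = fg + ["b1", "b2"]
    everywhere = _hits_df([("M1", g, 0, "+", 1.0) for g in bg])
    assert cre_enrichment(everywhere, fg, bg).loc[0, "p"] == pytest.approx(1.0)
    # foreground == background: no contrast
    assert cre_enrichment(everywhere, bg, bg).loc[0, "p"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="foreground"):
        cre_enrichment(everywhere, [], bg)
    with pytest.raises(ValueError, match="subset"):
        cre_enrichment(everywhere, ["zz"], bg)


def test_enrichment_invariant_to_motif_order():
    rng = np.random.default_rng(0)
    rows = [(f"M{i%3}", f"g{rng.integers(0, 40)}", 0, "+", 1.0) for i in range(60)]
    fg = [f"g{i}" for i in range(10)]
    bg = [f"g{i}" for i in range(40)]
    t1 = cre_enrichment(_hits_df(rows), fg, bg)
    t2 = cre_enrichment(_hits_df(rows[::-1]), fg, bg)
    pd.testing.assert_frame_equal(t1, t2)


# ---------------------------------------------------------------------------
# binding map
# ---------------------------------------------------------------------------

def _enrichment_df(motifs, enriched=True):
    return pd.DataFrame(
        {"motif": motifs, "fg_with_hit": 1, "fg_total": 1, "bg_with_hit": 0,
         "bg_total": 1, "p": 0.01, "q": 0.01 if enriched else 0.9,
         "enriched": enriched}
    )


def test_binding_map_contains_planted_pairs(stages):
    binding = stages["binding"]
    truth = stages["truth"]
    de = set(stages["de_genes"])
    got = {(r.tf, r.target) for r in binding.itertuples(index=False)}
    planted_in_de = {(tf, t) for tf, t in truth.true_edges if t in de and tf != t}
    assert planted_in_de <= got


def test_binding_map_gates_on_enrichment_and_self_pairs():
    hits = _hits_df([("M1", "g1", 5, "+", 9.0), ("M2", "g2", 7, "-", 8.0),
                     ("M1", "tf1", 3, "+", 9.0)])
    tf_motifs = pd.DataFrame({"tf": ["tf1", "tf2"], "motif": ["M1", "M2"]})
    enr = pd.concat([_enrichment_df(["M1"], True), _enrichment_df(["M2"], False)],
                    ignore_index=True)
    bm = build_binding_map(hits, enr, tf_motifs, ["g1", "g2", "tf1"])
    pairs = {(r.tf, r.target) for r in bm.itertuples(index=False)}
    assert pairs == {("tf1", "g1")}  # M2 not enriched; tf1 self-hit excluded


def test_binding_map_warns_on_unmapped_motif():
    hits = _hits_df([("MX", "g1", 0, "+", 1.0)])
    tf_motifs = pd.DataFrame({"tf": ["tf1"], "motif": ["M1"]})
    with pytest.warns(UserWarning, match="unmapped"):
        bm = build_binding_map(hits, _enrichment_df(["MX"]), tf_motifs, ["g1"])
    assert bm.empty


def test_jaspar_roundtrip(fixture_dir, promoter_fixture):
    pwms = read_jaspar(fixture_dir / "motifs.jaspar")
    assert {p.motif_id for p in pwms} == set(promoter_fixture.pwms)
    for p in pwms:
        assert np.allclose(p.counts, promoter_fixture.pwms[p.motif_id])
        assert p.consensus == promoter_fixture.consensus[p.motif_id]
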