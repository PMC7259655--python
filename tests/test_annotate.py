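"""Segment discovery and classification against planted truth."""

import numpy as np
import pytest

from igannot.annotate import (AnnotationParams, GeneSegmentCandidate,
                              UnscannedCandidateError, annotate_d_segments,
                              annotate_j_segments, annotate_locus,
                              annotate_v_segments, classify_functionality,
                              find_leader, scan_for_v_candidates)
from igannot.db import FUNCTIONAL, ORF_NO_LEADER, PSEUDOGENE
from igannot.rss import HEPTAMER, NONAMER, detect_rss, revcomp
from igannot.simulate import LocusSimConfig, simulate_locus

from oracles import brute_force_rss


def _recip_overlap(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return inter / max(a[1] - a[0], b[1] - b[0])


# --------------------------------------------------------------------------
# detect_rss


def test_detect_rss_exact_consensus():
    rng = np.random.default_rng(0)
    spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, 23))
    seq = "TTTT" + HEPTAMER + spacer + NONAMER + "TTTT"
    hit = detect_rss(seq, 4, 23, search_window=10)
    assert hit.heptamer_score == 7
    assert hit.nonamer_score == 9
    assert hit.spacer_len == 23
    assert hit.heptamer_start == 4


def test_detect_rss_all_a_is_none():
    assert detect_rss("A" * 200, 0, 23, search_window=100) is None


@pytest.mark.parametrize("orientation", ["downstream", "upstream"])
def test_detect_rss_equals_brute_force(orientation):
    """Exhaustive scoring oracle over random windows with planted,
    partially degraded motifs."""
    rng = np.random.default_rng(42)
    for trial in range(40):
        seq = list("ACGT"[i] for i in rng.integers(0, 4, 300))
        # plant a heptamer with one mismatch and an exact nonamer
        pos = int(rng.integers(20, 220))
        hept = list(HEPTAMER)
        hept[int(rng.integers(3, 7))] = "T"
        if orientation == "downstream":
            seq[pos:pos + 7] = hept
            seq[pos + 30:pos + 39] = list(NONAMER)
            anchor, window = 0, 290
        else:
            seq[pos:pos + 7] = list(revcomp("".join(hept)))
            seq[pos - 32:pos - 23] = list(revcomp(NONAMER))
            anchor, window = 299, 290
        s = "".join(seq)
        hit = detect_rss(s, anchor, 23, window, orientation=orientation)
        oracle = brute_force_rss(s, anchor, 23, window, orientation)
        if oracle is None:
            assert hit is None
        else:
            assert (hit.heptamer_start, hit.spacer_len, hit.heptamer_score,
                    hit.nonamer_score) == oracle


def test_detect_rss_window_truncated_at_end():
    seq = "GGGG" + HEPTAMER + "A" * 23 + NONAMER
    hit = detect_rss(seq, 4, 23, search_window=500)
    assert hit is not None and hit.heptamer_start == 4


# --------------------------------------------------------------------------
# V scan


def test_random_contig_has_no_v_candidates():
    rng = np.random.default_rng(1)
    contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
    seeds = {"seed1": "".join("ACGT"[i] for i in rng.integers(0, 4, 294))}
    assert scan_for_v_candidates({"c": contig}, seeds, 0.6) == []


def test_empty_contigs_warn_not_fail():
    assert scan_for_v_candidates({}, {"s": "ACGT" * 50}, 0.6) == []


def test_planted_v_recovery_with_planted_seeds():
    sim = simulate_locus(LocusSimConfig(n_v=8, n_d=0, n_j=0, seed=2))
    seeds = {s.name: s.sequence for s in sim.database.v}
    cands = scan_for_v_candidates(sim.contigs, seeds, 0.6)
    truth = sim.truth
    assert len(cands) >= len(truth)
    for _, row in truth.iterrows():
        assert any(_recip_overlap((c.start, c.end), (row.start, row.end)) >= 0.9
                   for c in cands)


def test_minus_strand_v_reported_on_forward_frame():
    sim = simulate_locus(LocusSimConfig(
        n_v=1, n_d=0, n_j=0, minus_strand_fraction=1.0,
        pseudogene_fraction=0.0, leaderless_fraction=0.0, seed=6))
    seeds = {s.name: s.sequence for s in sim.database.v}
    cands = scan_for_v_candidates(sim.contigs, seeds, 0.6)
    row = sim.truth.iloc[0]
    assert row.strand == "-"
    assert len(cands) == 1
    c = cands[0]
    assert (c.start, c.end, c.strand) == (row.start, row.end, "-")
    contig = next(iter(sim.contigs.values()))
    assert c.sequence == revcomp(contig[c.start:c.end])


# --------------------------------------------------------------------------
# leader


def _v_candidates(sim):
    seeds = {s.name: s.sequence for s in sim.database.v}
    return scan_for_v_candidates(sim.contigs, seeds, 0.6)


def test_find_leader_equals_planted_truth(heavy_locus):
    contig = next(iter(heavy_locus.contigs.values()))
    cands = _v_candidates(heavy_locus)
    truth = heavy_locus.truth.set_index(["start", "end"])
    checked = 0
    for c in cands:
        row = truth.loc[(c.start, c.end)]
        found = find_leader(c, contig)
        if row.leader_exon_start >= 0:
            assert found is not None
            exon, intron = found
            assert exon == (row.leader_exon_start, row.leader_exon_end)
            assert intron == (row.intron_start, row.intron_end)
            checked += 1
        else:
            assert found is None
    assert checked > 0


def test_leader_requires_start_codon():
    sim = simulate_locus(LocusSimConfig(
        n_v=1, n_d=0, n_j=0, pseudogene_fraction=0.0,
        leaderless_fraction=0.0, seed=8))
    contig = next(iter(sim.contigs.values()))
    row = sim.truth.iloc[0]
    atg = row.leader_exon_start
    broken = contig[:atg] + "ATA" + contig[atg + 3:]
    cands = scan_for_v_candidates({row.contig: broken},
                                  {"v": sim.database.v[0].sequence}, 0.6)
    assert find_leader(cands[0], broken) is None


# --------------------------------------------------------------------------
# classification


def _scanned(cand):
    cand.rss_scanned = True
    cand.leader_scanned = True
    return cand


def test_classify_requires_scanning():
    cand = GeneSegmentCandidate("V", "c", 0, 6, "+", "ATGAAA")
    with pytest.raises(UnscannedCandidateError):
        classify_functionality(cand)


def test_internal_stop_is_pseudogene(heavy_locus):
    functional = next(c for c in _annotated(heavy_locus)
                      if c.functionality == FUNCTIONAL)
    broken = GeneSegmentCandidate(
        "V", functional.contig, functional.start, functional.end, "+",
        functional.sequence[:30] + "TAA" + functional.sequence[33:],
        rss=functional.rss, leader=functional.leader)
    assert classify_functionality(_scanned(broken)) == PSEUDOGENE


def test_missing_rss_is_pseudogene(heavy_locus):
    functional = next(c for c in _annotated(heavy_locus)
                      if c.functionality == FUNCTIONAL)
    broken = GeneSegmentCandidate(
        "V", functional.contig, functional.start, functional.end, "+",
        functional.sequence, rss=[], leader=functional.leader)
    assert classify_functionality(_scanned(broken)) == PSEUDOGENE


_cache = {}


def _annotated(sim):
    key = id(sim)
    if key not in _cache:
        seeds = {s.name: s.sequence for s in sim.database.v}
        _cache[key] = annotate_v_segments(sim.contigs, seeds, "heavy")
    return _cache[key]


def test_functionality_labels_match_truth_at_zero_rate(heavy_locus):
    """Label faithfulness: simulated classes reproduced exactly."""
    cands = _annotated(heavy_locus)
    truth = heavy_locus.truth[heavy_locus.truth.segment_type == "V"]
    assert len(cands) == len(truth)
    by_iv = {(c.start, c.end): c for c in cands}
    for _, row in truth.iterrows():
        assert by_iv[(row.start, row.end)].functionality == row.functionality


# --------------------------------------------------------------------------
# D and J


def test_planted_d_recovery():
    sim = simulate_locus(LocusSimConfig(n_v=0, n_d=4, n_j=0, seed=12))
    cands = annotate_d_segments(sim.contigs)
    truth = sim.truth
    assert len(cands) == 4
    for _, row in truth.iterrows():
        assert any((c.start, c.end) == (row.start, row.end) for c in cands)


def test_unpaired_rss_yields_no_d():
    rng = np.random.default_rng(3)
    pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    pad = pad.replace("CACAGTG", "CGCAGTG").replace("CACTGTG", "CGCTGTG")
    contig = pad[:200] + HEPTAMER + "GCATGCATGCAT" + NONAMER + pad[200:]
    assert annotate_d_segments({"c": contig}) == []


def test_opposite_strand_d_recovered_up_to_rc():
    """D cassettes are RC-symmetric, so strand is reported '+' by
    convention; the interval and sequence (up to RC) must be exact."""
    sim = simulate_locus(LocusSimConfig(
        n_v=0, n_d=2, n_j=0, minus_strand_fraction=0.5, seed=14))
    cands = annotate_d_segments(sim.contigs)
    truth = sim.truth
    assert {(r.start, r.end) for _, r in truth.iterrows()} == \
        {(c.start, c.end) for c in cands}
    strands = set(truth.strand)
    assert strands == {"+", "-"}
    db_seqs = {s.sequence for s in sim.database.d}
    for c in cands:
        assert c.sequence in db_seqs or revcomp(c.sequence) in db_seqs


def test_j_segment_criteria():
    rng = np.random.default_rng(4)
    pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    pad = pad.replace("CACAGTG", "CGCAGTG").replace("CACTGTG", "CGCTGTG")
    pad = pad.replace("GTAAGT", "GACAGT").replace("GTGAGT", "GACAGT")
    coding = "GCTACTGAC" + "TGGGGCCAAGGG" + "ACTGTAGCA"  # ...WGQG...
    rss = revcomp(HEPTAMER + "G" * 23 + NONAMER)
    good = pad + rss + coding + "GTAAGT" + pad
    found = annotate_j_segments({"c": good}, "heavy")
    assert len(found) == 1
    start = len(pad) + len(rss)
    assert (found[0].start, found[0].end) == (start, start + len(coding))

    bad_donor = pad + rss + coding + "GTCCGT" + pad
    assert annotate_j_segments({"c": bad_donor}, "heavy") == []


def test_planted_j_recovery():
    sim = simulate_locus(LocusSimConfig(n_v=0, n_d=0, n_j=5, seed=15))
    cands = annotate_j_segments(sim.contigs, "heavy")
    assert len(cands) == 5
    for _, row in sim.truth.iterrows():
        assert any((c.start, c.end, c.strand) == (row.start, row.end, row.strand)
                   for c in cands)


# --------------------------------------------------------------------------
# whole-locus properties


def test_strand_symmetry():
    """Annotating the reverse complement mirrors coordinates and strands."""
    sim = simulate_locus(LocusSimConfig(n_v=4, n_d=2, n_j=2, seed=16))
    seeds = {s.name: s.sequence for s in sim.database.v}
    fwd = annotate_locus(sim.contigs, seeds, "heavy")
    contig = next(iter(sim.contigs.values()))
    L = len(contig)
    rev = annotate_locus({"c": revcomp(contig)}, seeds, "heavy")
    for st in "VJ":
        mirrored = {(L - c.end, L - c.start,
                     "+" if c.strand == "-" else "-", c.functionality)
                    for c in rev[st]}
        original = {(c.start, c.end, c.strand, c.functionality)
                    for c in fwd[st]}
        assert mirrored == original
    assert {(L - c.end, L - c.start) for c in rev["D"]} == \
        {(c.start, c.end) for c in fwd["D"]}


def test_sensitivity_and_fdr_on_large_mutated_locus():
    """200 planted segments at 2% RSS mutation: sensitivity >= 0.95 and
    false discovery <= 0.05."""
    sim = simulate_locus(LocusSimConfig(
        n_v=150, n_d=25, n_j=25, rss_mutation_rate=0.02, seed=100))
    seeds = {s.name: s.sequence for s in sim.database.v}
    res = annotate_locus(sim.contigs, seeds, "heavy")
    truth = sim.truth
    tp = sum(
        any(_recip_overlap((c.start, c.end), (row.start, row.end)) >= 0.9
            for c in res[row.segment_type])
        for _, row in truth.iterrows())
    n_found = sum(len(res[s]) for s in "VDJ")
    assert tp / len(truth) >= 0.95
    assert (n_found - tp) / max(n_found, 1) <= 0.05
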