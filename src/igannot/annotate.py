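"""Discovery and classification of V, D and J gene segments in contigs.

The discovery strategy mirrors iterative homology search: seed germline
sequences (typically from a related species) are aligned against both
strands of each contig, recovered segments join the seed set, and the scan
repeats until no new loci appear.  Candidates are then structurally
validated — downstream/flanking/upstream RSSs of the chain-appropriate
spacer class, leader exons with canonical GT..AG splice boundaries, open
reading frames and critical residues — and classified as functional,
ORF-without-leader, or pseudogene.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib

from .db import (FUNCTIONAL, ORF_NO_LEADER, PSEUDOGENE, GermlineDatabase,
                 GermlineSegment)
from .rss import (DEFAULT_V_RSS_WINDOW, SPACER_CLASS, RSSHit, detect_rss,
                  downstream_rss_starts, revcomp, upstream_rss_starts)
from .simulate import translate

log = logging.getLogger(__name__)

_DONOR_RE = re.compile(r"GT[AG]AGT")
_MOTIF_RE = re.compile(r"[FW]G.G")


@dataclass
class AnnotationParams:
    """Tunable thresholds for segment discovery and classification."""

    min_identity: float = 0.6
    v_rss_window: int = DEFAULT_V_RSS_WINDOW
    leader_window: int = 400
    leader_exon_range: tuple[int, int] = (45, 75)
    min_intron: int = 50
    d_len_range: tuple[int, int] = (8, 40)
    j_len_range: tuple[int, int] = (24, 90)
    cys_tail_codons: int = 8       # FR3-end Cys must lie in the last k codons
    trp_codon_range: tuple[int, int] = (25, 46)  # FR2 Trp search range
    max_iterations: int = 10
    max_hits_per_seed: int = 100


class UnscannedCandidateError(RuntimeError):
    """classify_functionality was called before RSS/leader scanning."""


@dataclass
class GeneSegmentCandidate:
    segment_type: str                  # "V" | "D" | "J"
    contig: str
    start: int                         # forward strand, 0-based half-open
    end: int
    strand: str                        # "+" | "-"
    sequence: str                      # coding-strand (oriented) sequence
    seed_identity: float = 0.0
    net_indel: int = 0                 # vs best seed; frameshift evidence
    rss: list[RSSHit] = field(default_factory=list)
    leader: tuple[tuple[int, int], tuple[int, int]] | None = None  # exon, intron
    donor_offset: int | None = None    # J only: forward offset of GTRAGT
    functionality: str | None = None
    clan: str | None = None
    name: str | None = None
    rss_scanned: bool = False
    leader_scanned: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _oriented(contig_seq: str, strand: str) -> str:
    return contig_seq if strand == "+" else revcomp(contig_seq)


def _to_forward(iv: tuple[int, int], strand: str, length: int) -> tuple[int, int]:
    if strand == "+":
        return iv
    return (length - iv[1], length - iv[0])


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / min(a[1] - a[0], b[1] - b[0])


# --------------------------------------------------------------------------
# V discovery


def _seed_hits(seed: str, target: str, min_identity: float, cap: int):
    """All non-overlapping alignments of ``seed`` in ``target`` with
    identity >= min_identity, via repeated best-hit masking."""
    max_ed = int((1.0 - min_identity) * len(seed))
    masked = target
    hits = []
    while len(hits) < cap:
        r = edlib.align(seed, masked, mode="HW", task="path", k=max_ed)
        if r["editDistance"] < 0:
            break
        s, e = r["locations"][0]
        e += 1
        identity = 1.0 - r["editDistance"] / len(seed)
        hits.append((s, e, identity, len(seed) - (e - s)))
        masked = masked[:s] + "#" * (e - s) + masked[e:]
    return hits


def scan_for_v_candidates(
    contigs: dict[str, str],
    seeds: dict[str, str],
    min_identity: float = 0.6,
    params: AnnotationParams | None = None,
) -> list[GeneSegmentCandidate]:
    """Iterative homology scan for V coding exons on both strands.

    Hits from each round join the seed set for the next; iteration stops
    when a round adds no interval that is <50% overlapping with existing
    candidates, or after ``params.max_iterations`` rounds.
    """
    params = params or AnnotationParams()
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if not seeds:
        raise ValueError("seed set must be non-empty")
    if not contigs:
        log.warning("empty contig set: returning no V candidates")
        return []

    candidates: list[GeneSegmentCandidate] = []
    seed_pool = dict(seeds)
    for _ in range(params.max_iterations):
        new_this_round: list[GeneSegmentCandidate] = []
        for cname, cseq in contigs.items():
            for strand in "+-":
                oseq = _oriented(cseq, strand)
                for sname, sseq in seed_pool.items():
                    for s, e, ident, indel in _seed_hits(
                            sseq, oseq, min_identity, params.max_hits_per_seed):
                        f_iv = _to_forward((s, e), strand, len(cseq))
                        cand = GeneSegmentCandidate(
                            segment_type="V", contig=cname,
                            start=f_iv[0], end=f_iv[1], strand=strand,
                            sequence=oseq[s:e], seed_identity=ident,
                            net_indel=indel)
                        new_this_round.append(cand)
        added = False
        for cand in sorted(new_this_round,
                           key=lambda c: (-c.seed_identity,
                                          -(c.end - c.start), c.start)):
            if any(c.contig == cand.contig and
                   _overlap_frac(c.interval, cand.interval) >= 0.5
                   for c in candidates):
                continue
            candidates.append(cand)
            seed_pool[f"hit_{cand.contig}_{cand.start}_{cand.strand}"] = cand.sequence
            added = True
        if not added:
            break
    candidates.sort(key=lambda c: (c.contig, c.start))
    return candidates


def find_leader(
    candidate: GeneSegmentCandidate,
    contig_seq: str,
    upstream_window: int | None = None,
    params: AnnotationParams | None = None,
):
    """Locate a leader exon/intron arrangement upstream of a V candidate.

    Requires, in the candidate's reading orientation: an exon starting with
    ATG, 45-75 nt long and frame-preserving (length % 3 == 0), ending at a
    GT splice donor; an intron of >= ``min_intron`` nt ending in AG
    immediately before the V coding exon.  Returns ``(exon, intron)``
    forward-strand intervals or None.
    """
    params = params or AnnotationParams()
    window = upstream_window or params.leader_window
    L = len(contig_seq)
    oseq = _oriented(contig_seq, candidate.strand)
    v_start = candidate.start if candidate.strand == "+" else L - candidate.end

    lo, hi = params.leader_exon_range
    if v_start < 2 or oseq[v_start - 2:v_start] != "AG":
        return None
    g_min = max(v_start - window + lo, 0)
    for g in range(v_start - params.min_intron, g_min - 1, -1):
        if oseq[g:g + 2] != "GT":
            continue
        for exon_len in range(lo, hi + 1):
            if exon_len % 3:
                continue
            a = g - exon_len
            if a < v_start - window or a < 0:
                continue
            if oseq[a:a + 3] == "ATG":
                exon = _to_forward((a, g), candidate.strand, L)
                intron = _to_forward((g, v_start), candidate.strand, L)
                return (exon, intron)
    return None


def classify_functionality(
    candidate: GeneSegmentCandidate,
    params: AnnotationParams | None = None,
) -> str:
    """Apply the functionality rules to an RSS- and leader-scanned V.

    Pseudogene: in-frame stop, frameshift vs seed, missing/sub-threshold
    RSS, or missing critical residues (FR3-end Cys, FR2 Trp).  Functional:
    all criteria plus an identifiable leader.  ORF-without-leader: all but
    the leader.
    """
    params = params or AnnotationParams()
    if not (candidate.rss_scanned and candidate.leader_scanned):
        raise UnscannedCandidateError(
            "candidate must be RSS- and leader-scanned before classification")
    aa = translate(candidate.sequence)
    if "*" in aa:
        return PSEUDOGENE
    if candidate.net_indel % 3 != 0:
        return PSEUDOGENE
    if not candidate.rss:
        return PSEUDOGENE
    tail = aa[-params.cys_tail_codons:]
    if "C" not in tail:
        return PSEUDOGENE
    t0, t1 = params.trp_codon_range
    if "W" not in aa[t0:t1]:
        return PSEUDOGENE
    return FUNCTIONAL if candidate.leader else ORF_NO_LEADER


def annotate_v_segments(
    contigs: dict[str, str],
    seeds: dict[str, str],
    chain: str,
    params: AnnotationParams | None = None,
) -> list[GeneSegmentCandidate]:
    """Full V pipeline: scan, RSS, leader, classify, name in contig order."""
    params = params or AnnotationParams()
    spacer = SPACER_CLASS[(chain, "V")]
    cands = scan_for_v_candidates(contigs, seeds, params.min_identity, params)
    for cand in cands:
        cseq = contigs[cand.contig]
        oseq = _oriented(cseq, cand.strand)
        anchor = cand.end if cand.strand == "+" else len(cseq) - cand.start
        hit = detect_rss(oseq, anchor, spacer, params.v_rss_window)
        cand.rss = [hit] if hit else []
        cand.rss_scanned = True
        cand.leader = find_leader(cand, cseq, params.leader_window, params)
        cand.leader_scanned = True
        cand.functionality = classify_functionality(cand, params)
    prefix = {"heavy": "IGH", "kappa": "IGK", "lambda": "IGL"}[chain]
    for k, cand in enumerate(sorted(cands, key=lambda c: (c.contig, c.start))):
        cand.name = f"{prefix}V{k + 1}"
    return cands


# --------------------------------------------------------------------------
# D and J discovery


def annotate_d_segments(
    contigs: dict[str, str],
    params: AnnotationParams | None = None,
    chain: str = "heavy",
) -> list[GeneSegmentCandidate]:
    """Short segments flanked by inward-facing 12-spacer RSSs on both sides."""
    if chain != "heavy":
        raise ValueError("D segments are annotated in heavy-chain mode only")
    params = params or AnnotationParams()
    spacer = SPACER_CLASS[(chain, "D")]
    d_min, d_max = params.d_len_range
    found: list[GeneSegmentCandidate] = []
    for cname, cseq in contigs.items():
        for strand in "+-":
            oseq = _oriented(cseq, strand)
            starts = upstream_rss_starts(oseq, spacer)
            ends = downstream_rss_starts(oseq, spacer)
            for i, left in starts.items():
                for j, right in ends.items():
                    if d_min <= j - i <= d_max:
                        f_iv = _to_forward((i, j), strand, len(cseq))
                        found.append(GeneSegmentCandidate(
                            segment_type="D", contig=cname,
                            start=f_iv[0], end=f_iv[1], strand=strand,
                            sequence=oseq[i:j], rss=[left, right],
                            rss_scanned=True, leader_scanned=True,
                            functionality=FUNCTIONAL))
    found = _dedup_by_score(found)
    prefix = {"heavy": "IGH", "kappa": "IGK", "lambda": "IGL"}[chain]
    found.sort(key=lambda c: (c.contig, c.start))
    for k, cand in enumerate(found):
        cand.name = f"{prefix}D{k + 1}"
    return found


def annotate_j_segments(
    contigs: dict[str, str],
    chain: str,
    params: AnnotationParams | None = None,
) -> list[GeneSegmentCandidate]:
    """Segments with an upstream RSS, an F/W-G-X-G motif in some frame, and
    a GTRAGT splice donor at the segment's 3' end."""
    params = params or AnnotationParams()
    spacer = SPACER_CLASS[(chain, "J")]
    j_min, j_max = params.j_len_range
    found: list[GeneSegmentCandidate] = []
    for cname, cseq in contigs.items():
        for strand in "+-":
            oseq = _oriented(cseq, strand)
            starts = upstream_rss_starts(oseq, spacer)
            for i, up in starts.items():
                for e in range(i + j_min, min(i + j_max, len(oseq) - 6) + 1):
                    if not _DONOR_RE.match(oseq, e):
                        continue
                    coding = oseq[i:e]
                    if not any(_MOTIF_RE.search(translate(coding[f:]))
                               for f in range(3)):
                        continue
                    f_iv = _to_forward((i, e), strand, len(cseq))
                    found.append(GeneSegmentCandidate(
                        segment_type="J", contig=cname,
                        start=f_iv[0], end=f_iv[1], strand=strand,
                        sequence=coding, rss=[up], donor_offset=e,
                        rss_scanned=True, leader_scanned=True,
                        functionality=FUNCTIONAL))
                    break
    found = _dedup_by_score(found)
    prefix = {"heavy": "IGH", "kappa": "IGK", "lambda": "IGL"}[chain]
    found.sort(key=lambda c: (c.contig, c.start))
    for k, cand in enumerate(found):
        cand.name = f"{prefix}J{k + 1}"
    return found


def _dedup_by_score(cands: list[GeneSegmentCandidate]) -> list[GeneSegmentCandidate]:
    kept: list[GeneSegmentCandidate] = []
    # RSS arrangements are reverse-complement symmetric, so a D segment is
    # typically found with equal scores on both strands; prefer '+' on ties.
    for cand in sorted(cands, key=lambda c: (-sum(h.total_score for h in c.rss),
                                             c.start, c.strand != "+")):
        if any(k.contig == cand.contig and
               _overlap_frac(k.interval, cand.interval) >= 0.5
               for k in kept):
            continue
        kept.append(cand)
    return kept


# --------------------------------------------------------------------------
# orchestration


def annotate_locus(
    contigs: dict[str, str],
    seeds: dict[str, str],
    chain: str,
    params: AnnotationParams | None = None,
) -> dict[str, list[GeneSegmentCandidate]]:
    """Annotate V (and D for heavy) and J segments in one pass."""
    params = params or AnnotationParams()
    out = {"V": annotate_v_segments(contigs, seeds, chain, params),
           "D": annotate_d_segments(contigs, params, chain) if chain == "heavy" else [],
           "J": annotate_j_segments(contigs, chain, params)}
    return out


def database_from_candidates(
    candidates: dict[str, list[GeneSegmentCandidate]], chain: str,
) -> GermlineDatabase:
    """Package annotated candidates as a germline database.

    The FR3-end cysteine anchor for each functional V is located as the
    last Cys codon in the coding exon; the J motif codon is located by
    scanning frames for F/W-G-X-G.
    """
    db = GermlineDatabase(chain=chain)
    for cand in candidates["V"]:
        aa = translate(cand.sequence)
        cys = aa.rfind("C")
        db.v.append(GermlineSegment(
            name=cand.name, segment_type="V", sequence=cand.sequence,
            functionality=cand.functionality,
            cys_codon=cys if cys >= 0 else None, clan=cand.clan))
    for cand in candidates["D"]:
        db.d.append(GermlineSegment(name=cand.name, segment_type="D",
                                    sequence=cand.sequence))
    for cand in candidates["J"]:
        motif_codon = None
        for f in range(3):
            m = _MOTIF_RE.search(translate(cand.sequence[f:]))
            if m:
                motif_codon = m.start()
                break
        db.j.append(GermlineSegment(name=cand.name, segment_type="J",
                                    sequence=cand.sequence,
                                    motif_codon=motif_codon))
    return db
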