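"""Analysis of recombined B-cell-receptor sequences.

Each recovered (or simulated) sequence is assigned its closest germline V,
D and J segments by semi-global alignment, its CDR3 is extracted between
the conserved FR3-end cysteine and the J-segment F/W of the F/W-G-X-G
motif (both anchors included, matching the counting rule "from the
conserved cysteine to the conserved tryptophan/phenylalanine"; an
anchor-exclusive length is also reported for interoperability), its
isotype is read off the constant-region tail, near-germline sequences are
flagged, unexplained recurrent V sequences are promoted to novel-germline
candidates, and clonal families are clustered by shared V/J and CDR3
similarity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .db import GermlineDatabase
from .simulate import translate

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_MOTIF_RE = re.compile(r"[FW]G.G")


@dataclass
class RepertoireParams:
    v_floor_identity: float = 0.5
    d_min_match: int = 5            # minimum exact junction match for a D call
    germline_match_threshold: float = 0.99   # "less than 1% variable"
    clone_cdr3_identity: float = 0.8
    isotype_floor_identity: float = 0.7


@dataclass
class Rearrangement:
    sequence_id: str
    nt_sequence: str
    chain: str
    v_call: str | None = None
    d_call: str | None = None
    j_call: str | None = None
    v_identity: float = 0.0
    j_identity: float = 0.0
    v_end: int | None = None        # read coords, half-open
    j_start: int | None = None
    j_end: int | None = None
    cys_pos: int | None = None      # read offset of the CDR3 cysteine codon
    motif_pos: int | None = None    # read offset of the germline J motif F/W
    cdr3_aa: str = ""
    cdr3_length: int | None = None       # anchor-inclusive (C..F/W)
    cdr3_length_imgt: int | None = None  # anchor-exclusive
    isotype: str = "unknown"
    productive: bool = False
    clone_id: str | None = None
    novel_germline_id: str | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class NovelGermlineCandidate:
    novel_germline_id: str
    consensus_nt: str
    supporting_ids: list[str]
    distinct_junctions: int
    nearest_known: str | None
    nearest_identity: float


# --------------------------------------------------------------------------
# alignment helpers


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _align(germ: str, read: str):
    """Semi-global (infix) alignment of a germline segment within a read."""
    r = edlib.align(germ, read, mode="HW", task="path")
    s, e = r["locations"][0]
    return {"ed": r["editDistance"], "start": s, "end": e + 1,
            "ops": _parse_cigar(r["cigar"])}


def _walk(ops, read_pos, germ_pos):
    """Yield (op, read_pos, germ_pos) per cigar run, updating positions."""
    for n, op in ops:
        yield n, op, read_pos, germ_pos
        if op in "=XM":
            read_pos += n
            germ_pos += n
        elif op == "I":     # consumes germline only
            germ_pos += n
        elif op == "D":     # consumes read only
            read_pos += n
    yield 0, "$", read_pos, germ_pos


def _trimmed_stats(aln, *, strip: str):
    """Alignment stats with terminal non-match runs stripped.

    ``strip='tail'`` drops everything after the last match run (a trimmed
    germline 3' end aligned into the junction); ``strip='head'`` drops
    everything before the first match run.  Returns (matches, germ_cols,
    read_lo, read_hi, germ_lo, germ_hi).
    """
    ops = aln["ops"]
    runs = list(_walk(ops, aln["start"], 0))[:-1]
    match_idx = [k for k, (n, op, *_rest) in enumerate(runs) if op == "="]
    if not match_idx:
        return None
    lo = match_idx[0] if strip == "head" else 0
    hi = match_idx[-1] if strip == "tail" else len(runs) - 1
    matches = germ_cols = 0
    read_lo, germ_lo = runs[lo][2], runs[lo][3]
    read_hi, germ_hi = read_lo, germ_lo
    for n, op, rp, gp in runs[lo:hi + 1]:
        if op == "=":
            matches += n
        if op in "=XI":
            germ_cols += n
        read_hi = rp + (n if op in "=XD" else 0)
        germ_hi = gp + (n if op in "=XI" else 0)
    return matches, germ_cols, read_lo, read_hi, germ_lo, germ_hi


def _map_germ_to_read(aln, germ_target: int) -> int | None:
    """Read offset of germline position ``germ_target`` (match/mismatch only)."""
    for n, op, rp, gp in _walk(aln["ops"], aln["start"], 0):
        if op in "=XM" and gp <= germ_target < gp + n:
            return rp + (germ_target - gp)
    return None


def _identity(matches: int, cols: int) -> float:
    return matches / cols if cols else 0.0


# --------------------------------------------------------------------------
# V/D/J assignment


def _best_segment(read: str, segments, *, strip: str):
    """Best-identity germline for a read; deterministic name-order ties."""
    scored = []
    for seg in segments:
        aln = _align(seg.sequence, read)
        st = _trimmed_stats(aln, strip=strip)
        if st is None:
            continue
        matches, cols, read_lo, read_hi, germ_lo, germ_hi = st
        ident = _identity(matches, cols)
        scored.append((-ident, aln["ed"], seg.name, seg, aln, st))
    if not scored:
        return None
    scored.sort(key=lambda t: t[:3])
    ambiguous = (len(scored) > 1 and
                 abs(scored[0][0] - scored[1][0]) < 1e-12 and
                 scored[0][1] == scored[1][1])
    return scored[0][3], scored[0][4], scored[0][5], -scored[0][0], ambiguous


def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    for k in range(min(len(a), len(b)), 0, -1):
        kmers = {a[i:i + k] for i in range(len(a) - k + 1)}
        if any(b[i:i + k] in kmers for i in range(len(b) - k + 1)):
            return k
    return 0


def assign_vdj(
    rearr: Rearrangement,
    db: GermlineDatabase,
    params: RepertoireParams | None = None,
) -> Rearrangement:
    """Assign V, (D,) J calls and identities to a rearranged sequence.

    The V alignment is stripped of its trailing non-match run (the
    exonuclease-trimmed germline 3' end has no counterpart in the read) and
    the J alignment of its leading one; identity is matches over aligned
    germline columns.  D is assigned only within the junction window
    between V end and J start, requiring a >= ``d_min_match`` exact match.
    """
    params = params or RepertoireParams()
    read = rearr.nt_sequence
    vs = db.functional_v()
    if not vs:
        raise ValueError("no functional V segments in database")

    best_v = _best_segment(read, vs, strip="tail")
    if best_v is not None:
        seg, aln, st, ident, ambiguous = best_v
        if ident >= params.v_floor_identity:
            rearr.v_call = seg.name
            rearr.v_identity = ident
            rearr.v_end = st[3]
            cys = seg.cys_codon
            if cys is not None:
                rearr.cys_pos = _map_germ_to_read(aln, 3 * cys)
            if ambiguous:
                rearr.flags.append("v_ambiguous")
        else:
            rearr.flags.append("v_below_floor")
    if rearr.v_call is None:
        rearr.flags.append("v_unassigned")
        return rearr

    best_j = _best_segment(read, db.functional_j(), strip="head")
    if best_j is not None:
        seg, aln, st, ident, ambiguous = best_j
        rearr.j_call = seg.name
        rearr.j_identity = ident
        rearr.j_start = st[2]
        rearr.j_end = st[2] + (len(seg.sequence) - st[4])
        if seg.motif_codon is not None:
            rearr.motif_pos = _map_germ_to_read(aln, 3 * seg.motif_codon)
        if ambiguous:
            rearr.flags.append("j_ambiguous")

    if rearr.chain == "heavy" and rearr.j_start is not None:
        junction = read[rearr.v_end:rearr.j_start]
        best = None
        for seg in db.functional_d():
            k = _longest_common_substring(junction, seg.sequence)
            if k >= params.d_min_match:
                cand = (-k, seg.name)
                if best is None or cand < best:
                    if best is not None and cand[0] == best[0]:
                        rearr.flags.append("d_ambiguous")
                    best = cand
        if best is not None:
            rearr.d_call = best[1]
    return rearr


def extract_cdr3(rearr: Rearrangement) -> Rearrangement:
    """Extract CDR3 between the FR3 cysteine and the J-motif F/W.

    The cysteine comes from the germline annotation mapped through the V
    alignment; the 3' anchor is the first in-frame F/W-G-X-G downstream.
    Both anchors are included in ``cdr3_aa`` and ``cdr3_length``;
    ``cdr3_length_imgt`` excludes them.  Missing anchors leave the
    rearrangement unproductive with an ``anchors_not_found`` flag.
    """
    if rearr.v_call is None or rearr.j_call is None or rearr.cys_pos is None:
        rearr.flags.append("anchors_not_found")
        rearr.productive = False
        return rearr
    read = rearr.nt_sequence
    # 3' anchor: the germline-annotated J motif mapped through the J
    # alignment, accepted when in frame with the cysteine; otherwise fall
    # back to scanning the translation for the first F/W-G-X-G.
    end = None
    if (rearr.motif_pos is not None and rearr.motif_pos > rearr.cys_pos
            and (rearr.motif_pos - rearr.cys_pos) % 3 == 0):
        end = (rearr.motif_pos - rearr.cys_pos) // 3
    aa_from_cys = translate(read[rearr.cys_pos:])
    if end is None or end >= len(aa_from_cys):
        m = _MOTIF_RE.search(aa_from_cys, 1)
        if not m:
            rearr.flags.append("anchors_not_found")
            rearr.productive = False
            return rearr
        end = m.start()
    cdr3 = aa_from_cys[:end + 1]
    rearr.cdr3_aa = cdr3
    rearr.cdr3_length = len(cdr3)
    rearr.cdr3_length_imgt = len(cdr3) - 2
    # productive: anchors found and no stop from the V frame through J end
    frame_start = rearr.cys_pos % 3
    stop_to = rearr.j_end if rearr.j_end is not None else len(read)
    coding = read[frame_start:stop_to - (stop_to - frame_start) % 3]
    rearr.productive = "*" not in translate(coding)
    return rearr


def match_germline(
    rearr: Rearrangement,
    threshold: float = 0.99,
) -> str | None:
    """Matched germline name iff V identity >= threshold (inclusive)."""
    if rearr.v_call is not None and rearr.v_identity >= threshold:
        return rearr.v_call
    return None


# --------------------------------------------------------------------------
# novel germline inference


def _global_identity(a: str, b: str) -> float:
    r = edlib.align(a, b, mode="NW", task="path")
    matches = cols = 0
    for n, op in _parse_cigar(r["cigar"]):
        cols += n
        if op == "=":
            matches += n
    return _identity(matches, cols)


def infer_novel_germlines(
    rearrs: list[Rearrangement],
    db: GermlineDatabase,
    threshold: float = 0.99,
) -> list[NovelGermlineCandidate]:
    """Promote recurrent, unexplained V sequences to germline candidates.

    Sequences whose V regions are identical (up to 3'-trim prefix
    differences) and that recombined with >= 2 distinct junctions, while no
    known germline explains them at >= ``threshold`` identity, indicate a
    common germline progenitor.  The candidate consensus is the longest
    supporting V region.
    """
    if len(rearrs) < 2:
        return []
    usable = [r for r in rearrs if r.v_call is not None and r.v_end]
    portions = [(r, r.nt_sequence[:r.v_end]) for r in usable]
    parent = list(range(len(portions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def _lcp_len(a: str, b: str) -> int:
        n = min(len(a), len(b))
        for k in range(n):
            if a[k] != b[k]:
                return k
        return n

    # Same-germline evidence: exact agreement over a shared prefix covering
    # >= 90% of the (alignment-estimated, hence noisy) shorter V region.
    # The junction is excluded later, at the divergence point.
    def _v_end_bound(r: Rearrangement) -> int:
        # the V region certainly ends before the aligned J start; the raw
        # v_end can overshoot badly when the nearest known V is distant
        return min(r.v_end, r.j_start) if r.j_start else r.v_end

    for i in range(len(portions)):
        for j in range(i + 1, len(portions)):
            ri_, rj_ = portions[i][0], portions[j][0]
            floor = int(0.9 * min(_v_end_bound(ri_), _v_end_bound(rj_)))
            if _lcp_len(ri_.nt_sequence, rj_.nt_sequence) >= max(floor, 50):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(len(portions)):
        groups.setdefault(find(i), []).append(i)

    def _lcp(a: str, b: str) -> int:
        n = min(len(a), len(b))
        for k in range(n):
            if a[k] != b[k]:
                return k
        return n

    candidates = []
    known = db.v
    for members in sorted(groups.values(),
                          key=lambda ms: portions[ms[0]][0].sequence_id):
        if len(members) < 2:
            continue
        # consensus V region: longest prefix on which two supporters that
        # eventually diverge (distinct junctions) still agree
        reads = [portions[i][0].nt_sequence for i in members]
        best_lcp = 0
        for x in range(len(reads)):
            for y in range(x + 1, len(reads)):
                k = _lcp(reads[x], reads[y])
                if k < min(len(reads[x]), len(reads[y])):
                    best_lcp = max(best_lcp, k)
        if best_lcp == 0:
            continue  # all supporters are full-length identical duplicates
        consensus = reads[0][:best_lcp]
        junctions = set()
        for i in members:
            r = portions[i][0]
            j_stop = r.j_start if r.j_start is not None else len(r.nt_sequence)
            junctions.add(r.nt_sequence[best_lcp:j_stop] + "|" + (r.j_call or ""))
        if len(junctions) < 2:
            continue
        nearest, nearest_ident = None, 0.0
        for seg in known:
            # compare over the mutual prefix: the consensus may carry a few
            # chance-shared junction bases past the true germline 3' end
            L = min(len(consensus), len(seg.sequence))
            ident = _global_identity(consensus[:L], seg.sequence[:L])
            if ident > nearest_ident:
                nearest, nearest_ident = seg.name, ident
        if nearest_ident >= threshold:
            continue
        cid = f"novel_{len(candidates) + 1}"
        supporting = sorted(portions[i][0].sequence_id for i in members)
        candidates.append(NovelGermlineCandidate(
            novel_germline_id=cid, consensus_nt=consensus,
            supporting_ids=supporting, distinct_junctions=len(junctions),
            nearest_known=nearest, nearest_identity=nearest_ident))
        for i in members:
            portions[i][0].novel_germline_id = cid
    return candidates


# --------------------------------------------------------------------------
# clonal clustering


def cluster_clones(
    rearrs: list[Rearrangement],
    params: RepertoireParams | None = None,
) -> list[Rearrangement]:
    """Single-linkage clonal families over shared V/J and similar CDR3.

    Sequences sharing ``v_call``, ``j_call`` and CDR3 length are linked
    when CDR3 amino-acid identity >= ``clone_cdr3_identity``.  Clone ids
    are deterministic: descending size, then first sequence id.  Sequences
    without a CDR3 become flagged singletons.
    """
    params = params or RepertoireParams()
    keyed: dict[tuple, list[Rearrangement]] = {}
    singletons: list[Rearrangement] = []
    for r in rearrs:
        if r.cdr3_aa and r.v_call and r.j_call:
            keyed.setdefault((r.v_call, r.j_call, len(r.cdr3_aa)), []).append(r)
        else:
            r.flags.append("clone_singleton_no_cdr3")
            singletons.append(r)

    clusters: list[list[Rearrangement]] = []
    for group in keyed.values():
        n = len(group)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        thr = params.clone_cdr3_identity
        for i in range(n):
            for j in range(i + 1, n):
                a, b = group[i].cdr3_aa, group[j].cdr3_aa
                same = sum(1 for x, y in zip(a, b) if x == y)
                if same / len(a) >= thr:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        comp: dict[int, list[Rearrangement]] = {}
        for i in range(n):
            comp.setdefault(find(i), []).append(group[i])
        clusters.extend(comp.values())
    clusters.extend([s] for s in singletons)
    clusters.sort(key=lambda c: (-len(c), min(r.sequence_id for r in c)))
    for k, cluster in enumerate(clusters):
        for r in cluster:
            r.clone_id = f"clone_{k + 1}"
    return rearrs


# --------------------------------------------------------------------------
# isotype and summary


def assign_isotype(
    rearr: Rearrangement,
    constant_refs: dict[str, str],
    params: RepertoireParams | None = None,
) -> Rearrangement:
    """Classify the constant-region tail 3' of J against reference 5' ends."""
    params = params or RepertoireParams()
    if not constant_refs:
        raise ValueError("constant reference set must be non-empty")
    tail_from = rearr.j_end if rearr.j_end is not None else len(rearr.nt_sequence)
    tail = rearr.nt_sequence[tail_from:]
    if len(tail) < 8:
        rearr.isotype = "unknown"
        return rearr
    best, best_ident = "unknown", 0.0
    for label in sorted(constant_refs):
        ref = constant_refs[label]
        L = min(len(tail), len(ref))
        r = edlib.align(tail[:L], ref[:L], mode="NW")
        ident = 1.0 - r["editDistance"] / L
        if ident > best_ident:
            best, best_ident = label, ident
    rearr.isotype = best if best_ident >= params.isotype_floor_identity else "unknown"
    return rearr


def summarize_repertoire(
    rearrs: list[Rearrangement],
    clans: dict[str, str] | None = None,
    match_threshold: float = 0.99,
) -> dict:
    """Usage counts, CDR3-length distribution, match fractions, clone sizes."""
    if not rearrs:
        log.warning("empty repertoire: empty summary")
        return {}
    df = pd.DataFrame([{
        "sequence_id": r.sequence_id, "v_call": r.v_call or "",
        "j_call": r.j_call or "", "cdr3_length": r.cdr3_length,
        "matched": match_germline(r, match_threshold) is not None,
        "clone_id": r.clone_id or "", "isotype": r.isotype,
    } for r in rearrs])
    v_usage = df[df.v_call != ""].v_call.value_counts()
    lengths = df.cdr3_length.dropna()
    out = {
        "n_sequences": len(df),
        "v_usage": v_usage,
        "cdr3_length_hist": lengths.astype(int).value_counts().sort_index(),
        "cdr3_length_mean": float(lengths.mean()) if len(lengths) else float("nan"),
        "cdr3_length_range": (int(lengths.min()), int(lengths.max()))
        if len(lengths) else (None, None),
        "matched_fraction": float(df.matched.mean()),
        "clone_sizes": df[df.clone_id != ""].clone_id.value_counts(),
        "isotype_usage": df.isotype.value_counts(),
    }
    if clans:
        clan_of = df.v_call.map(lambda v: clans.get(v, ""))
        out["clan_usage"] = clan_of[clan_of != ""].value_counts()
    return out


# --------------------------------------------------------------------------
# orchestration


def analyze_repertoire(
    sequences: dict[str, str],
    db: GermlineDatabase,
    chain: str | None = None,
    constant_refs: dict[str, str] | None = None,
    params: RepertoireParams | None = None,
) -> tuple[list[Rearrangement], list[NovelGermlineCandidate]]:
    """Full per-sequence analysis of a repertoire FASTA."""
    params = params or RepertoireParams()
    chain = chain or db.chain
    rearrs = []
    for sid in sequences:
        r = Rearrangement(sequence_id=sid, nt_sequence=sequences[sid].upper(),
                          chain=chain)
        assign_vdj(r, db, params)
        extract_cdr3(r)
        if constant_refs:
            assign_isotype(r, constant_refs, params)
        rearrs.append(r)
    novel = infer_novel_germlines(rearrs, db, params.germline_match_threshold)
    cluster_clones(rearrs, params)
    return rearrs, novel
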