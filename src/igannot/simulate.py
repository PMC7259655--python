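"""Planted-truth simulation of immunoglobulin loci and BCR repertoires.

``simulate_locus`` writes V, D and J gene-segment cassettes, with their
recombination signal sequences (RSS), leader exons and functionality
classes, into otherwise random contigs and returns the exact planted
coordinates as a truth table.  ``simulate_repertoire`` performs V(D)J
recombination from a germline database — exonuclease trimming of segment
ends, non-templated (N) nucleotide addition, productive-frame selection —
and applies somatic hypermutation (SHM) as independent per-base
substitutions, returning a per-sequence truth record.

The generator guarantees that every planted signal is the unique signal of
its kind within the annotator's search window (single ATG in each leader
search region, no competing in-frame splice donors, no spurious junction
motifs, no shared >=5-mers between planted D segments, pads scrubbed of
exact RSS heptamer cores).  This is what makes exact planted-recovery and
round-trip checks meaningful rather than merely probable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .db import (FUNCTIONAL, ORF_NO_LEADER, PSEUDOGENE, GermlineDatabase,
                 GermlineSegment)
from .rss import HEPTAMER, NONAMER, SPACER_CLASS, DEFAULT_V_RSS_WINDOW, revcomp

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}

# planted V exon geometry (codons, 0-based codon indices)
V_CODONS = 98
CYS1_CODON = 21   # FR1 cysteine
TRP_CODON = 36    # conserved FR2 tryptophan
CYS2_CODON = 95   # FR3-end cysteine, the 5' CDR3 anchor
LEADER_LEN = 57   # leader exon, starts ATG, frame-preserving (57 % 3 == 0)
INTRON_RANGE = (60, 100)
D_LEN_RANGE = (12, 25)
J_PRE_CODONS = 3  # codons 5' of the F/W-G-X-G motif (CDR3 3' contribution)
J_POST_CODONS = 4
J_MOTIF_CODON = J_PRE_CODONS
_MOTIF_RE = re.compile(r"[FW]G.G")

_CODON_TABLE = {}


def _codon_table():
    if not _CODON_TABLE:
        from Bio.Seq import Seq
        for a in BASES:
            for b in BASES:
                for c in BASES:
                    cod = a + b + c
                    _CODON_TABLE[cod] = str(Seq(cod).translate())
    return _CODON_TABLE


def translate(nt: str) -> str:
    """Translate frame 0, trailing partial codon ignored."""
    tbl = _codon_table()
    return "".join(tbl[nt[i:i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3))


# --------------------------------------------------------------------------
# configs


@dataclass
class LocusSimConfig:
    """Composition of a simulated germline locus.

    Defaults mirror the composition of the annotated ferret heavy locus:
    27 V-like segments of which ~1/4 are pseudogenes and ~1/5 of the
    functional genes lack leader exons, 7 D and 5 J segments.
    """

    n_v: int = 20
    n_d: int = 7
    n_j: int = 5
    chain: str = "heavy"
    pseudogene_fraction: float = 0.25
    leaderless_fraction: float = 0.2
    contig_padding: int = 300
    rss_mutation_rate: float = 0.0
    minus_strand_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("pseudogene_fraction", "leaderless_fraction",
                     "rss_mutation_rate", "minus_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_v", "n_d", "n_j", "contig_padding"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.chain not in ("heavy", "kappa", "lambda"):
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.chain != "heavy" and self.n_d:
            raise ValueError("D segments exist only in the heavy locus")


@dataclass
class RepertoireSimConfig:
    """V(D)J recombination and SHM parameters for a simulated repertoire."""

    n_sequences: int = 200
    shm_rate: float = 0.01
    trim_max: int = 2
    n_insert_max: int = 6
    clone_count: int = 50
    clone_size_distribution: str = "uniform"  # "uniform" | "power"
    force_inframe: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.shm_rate < 1.0:
            raise ValueError("shm_rate must be in [0,1)")
        if self.trim_max < 0 or self.n_insert_max < 0:
            raise ValueError("trim_max and n_insert_max must be >= 0")
        if not 1 <= self.clone_count <= self.n_sequences:
            raise ValueError("need 1 <= clone_count <= n_sequences")
        if self.clone_size_distribution not in ("uniform", "power"):
            raise ValueError("clone_size_distribution must be uniform|power")


# --------------------------------------------------------------------------
# low-level sequence construction


def _rand_seq(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _rand_codons(rng, n: int) -> str:
    out = []
    while len(out) < n:
        cod = _rand_seq(rng, 3)
        if cod not in STOPS:
            out.append(cod)
    return "".join(out)


def _scrub(seq: str, *, no_atg: bool = False, no_rss_core: bool = True) -> str:
    """Remove forbidden motifs by deterministic single-base substitutions."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        if no_atg:
            i = text.find("ATG")
            if i >= 0:
                s[i + 1] = "C"   # ATG -> ACG
                changed = True
                continue
        if no_rss_core:
            for core in ("CACAGTG", "CACTGTG"):
                i = text.find(core)
                if i >= 0:
                    s[i + 1] = "G"   # CAC... -> CGC...
                    changed = True
                    break
    return "".join(s)


def _pad(rng, n: int, *, no_atg: bool = False) -> str:
    return _scrub(_rand_seq(rng, n), no_atg=no_atg)


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    s = list(seq)
    hits = np.nonzero(rng.random(len(s)) < rate)[0]
    for i in hits:
        s[i] = rng.choice([b for b in BASES if b != s[i]])
    return "".join(s)


def _build_rss(rng, spacer: int, rate: float) -> str:
    return _mutate(rng, HEPTAMER + _rand_seq(rng, spacer) + NONAMER, rate)


def _build_v_exon(rng) -> str:
    """V coding exon: 98 codons, conserved Cys/Trp/Cys, no stop, no RSS core."""
    while True:
        codons = [_rand_codons(rng, 1) for _ in range(V_CODONS)]
        codons[CYS1_CODON] = rng.choice(["TGT", "TGC"])
        codons[TRP_CODON] = "TGG"
        codons[CYS2_CODON] = rng.choice(["TGT", "TGC"])
        exon = "".join(codons)
        if "CACAGTG" in exon or "CACTGTG" in exon:
            continue
        return exon


def _build_leader_region(rng, pad_len: int):
    """(pad, leader_exon, intron) with a unique splice arrangement.

    Guarantees, within the region, exactly one ATG (the leader start), a
    unique frame-compatible GT splice donor at leader offset ``LEADER_LEN``,
    and intron boundaries GT..AG.
    """
    frame_offsets = [o for o in range(45, 76, 3) if o != LEADER_LEN]
    for _ in range(200):
        pad = _pad(rng, pad_len, no_atg=True)
        leader = "ATG" + _rand_codons(rng, (LEADER_LEN - 3) // 3)
        intron_len = int(rng.integers(*INTRON_RANGE))
        intron = "GT" + _rand_seq(rng, intron_len - 4) + "AG"
        region = pad + leader + intron
        atg = len(pad)
        if region.count("ATG") != 1:
            continue
        if any(region[atg + o:atg + o + 2] == "GT" for o in frame_offsets):
            continue
        if "CACAGTG" in region or "CACTGTG" in region:
            continue
        return pad, leader, intron
    raise RuntimeError("could not build a clean leader region")


def _build_j_coding(rng, chain: str) -> str:
    """J segment: 8 codons, the F/W-G-X-G motif, 4 codons; no internal donor."""
    motif = "TGGGGCCAAGGG" if chain == "heavy" else "TTCGGCCAAGGG"
    while True:
        j = _rand_codons(rng, J_PRE_CODONS) + motif + _rand_codons(rng, J_POST_CODONS)
        if re.search(r"GT[AG]AGT", j):
            continue
        aa = translate(j)
        if _MOTIF_RE.search(aa).start() != J_MOTIF_CODON:  # spurious early motif
            continue
        if "CACAGTG" in j or "CACTGTG" in j:
            continue
        return j


# --------------------------------------------------------------------------
# locus simulation


@dataclass
class LocusSimulation:
    contigs: dict[str, str]
    truth: pd.DataFrame
    database: GermlineDatabase
    config: LocusSimConfig = field(repr=False, default=None)


def _place(parts: list[str]) -> list[tuple[int, int]]:
    """Half-open intervals of each part in the concatenation."""
    out, pos = [], 0
    for p in parts:
        out.append((pos, pos + len(p)))
        pos += len(p)
    return out


def simulate_locus(config: LocusSimConfig) -> LocusSimulation:
    """Plant V/D/J cassettes in a contig and return contigs + truth + db."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chain = config.chain
    prefix = {"heavy": "IGH", "kappa": "IGK", "lambda": "IGL"}[chain]
    contig_name = f"sim_{chain}_contig"
    pieces: list[str] = []
    offset = 0
    rows: list[dict] = []
    db = GermlineDatabase(chain=chain)

    # -------- functionality classes for V
    n_v = config.n_v
    n_pseudo = int(round(config.pseudogene_fraction * n_v))
    idx = rng.permutation(n_v)
    pseudo_idx = set(idx[:n_pseudo].tolist())
    rest = [i for i in idx.tolist() if i not in pseudo_idx]
    n_leaderless = int(round(config.leaderless_fraction * len(rest)))
    leaderless_idx = set(rest[:n_leaderless])

    v_spacer = SPACER_CLASS[(chain, "V")]
    j_spacer = SPACER_CLASS[(chain, "J")]
    rss_pseudo_v: list[int] = []

    for i in range(n_v):
        name = f"{prefix}V{i + 1}"
        exon = _build_v_exon(rng)
        functionality = FUNCTIONAL
        leaderless = i in leaderless_idx
        pseudo_mode = None
        if i in pseudo_idx:
            functionality = PSEUDOGENE
            pseudo_mode = rng.choice(["nonsense", "rss"])
            if pseudo_mode == "nonsense":
                pos = int(rng.integers(10, 90))
                if pos in (CYS1_CODON, TRP_CODON):
                    pos += 1
                exon = exon[:3 * pos] + rng.choice(sorted(STOPS)) + exon[3 * pos + 3:]
        elif leaderless:
            functionality = ORF_NO_LEADER

        if pseudo_mode == "rss":
            # degraded RSS: destroy the heptamer core and most of the nonamer
            rss = _scrub(_rand_seq(rng, 7 + v_spacer + 9))
            rss_pseudo_v.append(len(rows))  # row index, resolved after assembly
        else:
            rss = _build_rss(rng, v_spacer, config.rss_mutation_rate)

        if leaderless:
            pad = _pad(rng, config.contig_padding, no_atg=True)
            pad = pad[:-2] + "CC" if len(pad) >= 2 else pad  # never AG before exon
            parts = [pad, exon, rss]
            ivs = _place(parts)
            leader_iv, intron_iv, exon_iv = None, None, ivs[1]
        else:
            pad, leader, intron = _build_leader_region(rng, config.contig_padding)
            parts = [pad, leader, intron, exon, rss]
            ivs = _place(parts)
            leader_iv, intron_iv, exon_iv = ivs[1], ivs[2], ivs[3]

        cassette = "".join(parts)
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        if strand == "-":
            L = len(cassette)
            cassette = revcomp(cassette)
            flip = lambda iv: (L - iv[1], L - iv[0])
            exon_iv = flip(exon_iv)
            leader_iv = flip(leader_iv) if leader_iv else None
            intron_iv = flip(intron_iv) if intron_iv else None

        rows.append({
            "name": name, "segment_type": "V", "contig": contig_name,
            "start": offset + exon_iv[0], "end": offset + exon_iv[1],
            "strand": strand, "functionality": functionality,
            "leader_exon_start": offset + leader_iv[0] if leader_iv else -1,
            "leader_exon_end": offset + leader_iv[1] if leader_iv else -1,
            "intron_start": offset + intron_iv[0] if intron_iv else -1,
            "intron_end": offset + intron_iv[1] if intron_iv else -1,
            "cys_codon": CYS2_CODON, "motif_codon": -1,
        })
        db.v.append(GermlineSegment(
            name=name, segment_type="V", sequence=exon,
            functionality=functionality, cys_codon=CYS2_CODON,
            leader=None if leaderless else leader))
        pieces.append(cassette)
        offset += len(cassette)

    # -------- D segments (heavy only), flanked by 12-spacer RSSs
    if config.n_d:
        d_spacer = SPACER_CLASS[(chain, "D")]
        d_seqs: list[str] = []

        def _shares_kmer(s: str, others: list[str], k: int = 5) -> bool:
            kmers = {s[i:i + k] for i in range(len(s) - k + 1)}
            return any(kmers & {o[i:i + k] for i in range(len(o) - k + 1)}
                       for o in others)

        for i in range(config.n_d):
            while True:
                d_len = int(rng.integers(D_LEN_RANGE[0], D_LEN_RANGE[1] + 1))
                d = _scrub(_rand_seq(rng, d_len))
                if not _shares_kmer(d, d_seqs):
                    break
            d_seqs.append(d)
            name = f"{prefix}D{i + 1}"
            left = revcomp(_build_rss(rng, d_spacer, config.rss_mutation_rate))
            right = _build_rss(rng, d_spacer, config.rss_mutation_rate)
            parts = [_pad(rng, config.contig_padding), left, d, right]
            ivs = _place(parts)
            d_iv = ivs[2]
            cassette = "".join(parts)
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            if strand == "-":
                L = len(cassette)
                cassette = revcomp(cassette)
                d_iv = (L - d_iv[1], L - d_iv[0])
            rows.append({
                "name": name, "segment_type": "D", "contig": contig_name,
                "start": offset + d_iv[0], "end": offset + d_iv[1],
                "strand": strand, "functionality": FUNCTIONAL,
                "leader_exon_start": -1, "leader_exon_end": -1,
                "intron_start": -1, "intron_end": -1,
                "cys_codon": -1, "motif_codon": -1,
            })
            db.d.append(GermlineSegment(name=name, segment_type="D", sequence=d))
            pieces.append(cassette)
            offset += len(cassette)

    # -------- J segments: upstream RSS, coding with motif, GTRAGT donor
    for i in range(config.n_j):
        name = f"{prefix}J{i + 1}"
        while True:
            j = _build_j_coding(rng, chain)
            donor = "GT" + rng.choice(["A", "G"]) + "AGT"
            m = re.search(r"GT[AG]AGT", j + donor)
            if m and m.start() == len(j):  # no donor straddling the boundary
                break
        up = revcomp(_build_rss(rng, j_spacer, config.rss_mutation_rate))
        parts = [_pad(rng, config.contig_padding), up, j, donor]
        ivs = _place(parts)
        j_iv = ivs[2]
        cassette = "".join(parts)
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        if strand == "-":
            L = len(cassette)
            cassette = revcomp(cassette)
            j_iv = (L - j_iv[1], L - j_iv[0])
        rows.append({
            "name": name, "segment_type": "J", "contig": contig_name,
            "start": offset + j_iv[0], "end": offset + j_iv[1],
            "strand": strand, "functionality": FUNCTIONAL,
            "leader_exon_start": -1, "leader_exon_end": -1,
            "intron_start": -1, "intron_end": -1,
            "cys_codon": -1, "motif_codon": J_MOTIF_CODON,
        })
        db.j.append(GermlineSegment(name=name, segment_type="J", sequence=j,
                                    motif_codon=J_MOTIF_CODON))
        pieces.append(cassette)
        offset += len(cassette)

    pieces.append(_pad(rng, config.contig_padding))
    contig = "".join(pieces)

    # Guarantee that RSS-disrupted pseudogenes really have no passing RSS in
    # the annotator's search window (chance heptamer/nonamer arrangements in
    # the random pad are scrubbed).
    from .rss import detect_rss
    window = DEFAULT_V_RSS_WINDOW
    for row_idx in rss_pseudo_v:
        row = rows[row_idx]
        for _ in range(20):
            if row["strand"] == "+":
                hit = detect_rss(contig, row["end"], v_spacer, window)
                if hit is None:
                    break
                pos = hit.heptamer_start + 1
            else:
                rc = revcomp(contig)
                hit = detect_rss(rc, len(contig) - row["start"], v_spacer, window)
                if hit is None:
                    break
                pos = len(contig) - (hit.heptamer_start + 1) - 1
            contig = contig[:pos] + "G" + contig[pos + 1:]

    truth = pd.DataFrame(rows)
    return LocusSimulation(contigs={contig_name: contig}, truth=truth,
                           database=db, config=config)


# --------------------------------------------------------------------------
# repertoire simulation


@dataclass
class RepertoireSimulation:
    sequences: dict[str, str]   # id -> nt (V..J [+ constant prefix])
    truth: pd.DataFrame
    config: RepertoireSimConfig = field(repr=False, default=None)


def _clone_sizes(rng, n: int, c: int, distribution: str) -> list[int]:
    if distribution == "uniform":
        base = n // c
        sizes = [base + (1 if k < n % c else 0) for k in range(c)]
    else:  # power: Zipf-like weights, everyone gets at least one member
        w = 1.0 / np.arange(1, c + 1) ** 1.5
        w /= w.sum()
        sizes = np.maximum(1, np.floor(w * n).astype(int))
        # largest-remainder top-up / trim to exactly n
        while sizes.sum() < n:
            sizes[int(np.argmax(w * n - sizes))] += 1
        while sizes.sum() > n:
            k = int(np.argmax(sizes))
            sizes[k] -= 1
        sizes = sizes.tolist()
    return sizes


def _draw_recombination(rng, v, d, j, config, chain):
    """One recombination event; by default junctions are selected to be
    in-frame and stop-free (productive selection), with the planted J motif
    the first F/W-G-X-G downstream of the V cysteine."""
    for _ in range(500):
        max_v_trim = min(config.trim_max, len(v.sequence) - 3 * (v.cys_codon + 1))
        v_trim = int(rng.integers(0, max(max_v_trim, 0) + 1))
        j_trim = int(rng.integers(0, config.trim_max + 1))
        v_part = v.sequence[:len(v.sequence) - v_trim]
        if d is not None:
            d5 = int(rng.integers(0, config.trim_max + 1))
            d3 = int(rng.integers(0, config.trim_max + 1))
            d_part = d.sequence[d5:len(d.sequence) - d3]
            n1_len = int(rng.integers(0, config.n_insert_max + 1))
            if config.force_inframe:
                need = (j_trim - (len(v_part) + n1_len + len(d_part))) % 3
                cands = [x for x in range(config.n_insert_max + 1) if x % 3 == need]
                if not cands:
                    continue
                n2_len = int(rng.choice(cands))
            else:
                n2_len = int(rng.integers(0, config.n_insert_max + 1))
            n1, n2 = _rand_seq(rng, n1_len), _rand_seq(rng, n2_len)
        else:
            d5 = d3 = 0
            d_part, n2 = "", ""
            if config.force_inframe:
                need = (j_trim - len(v_part)) % 3
                cands = [x for x in range(config.n_insert_max + 1) if x % 3 == need]
                if not cands:
                    continue
                n1_len = int(rng.choice(cands))
            else:
                n1_len = int(rng.integers(0, config.n_insert_max + 1))
            n1 = _rand_seq(rng, n1_len)
        j_part = j.sequence[j_trim:]
        seq = v_part + n1 + d_part + n2 + j_part
        if not config.force_inframe:
            return seq, (v_trim, d5, d3, j_trim, n1, n2)
        aa = translate(seq)
        j_start = len(v_part) + len(n1) + len(d_part) + len(n2)
        motif_idx = (j_start + 3 * J_MOTIF_CODON - j_trim) // 3
        j_end_aa = (j_start + len(j_part)) // 3
        if "*" in aa[:j_end_aa]:
            continue
        m = _MOTIF_RE.search(aa, v.cys_codon + 1)
        if m is None or m.start() != motif_idx:
            continue
        return seq, (v_trim, d5, d3, j_trim, n1, n2)
    raise RuntimeError("could not draw a productive junction")


def simulate_repertoire(
    db: GermlineDatabase,
    config: RepertoireSimConfig,
    constants: dict[str, str] | None = None,
) -> RepertoireSimulation:
    """Simulate a clonally structured, somatically mutated BCR repertoire.

    ``constants``, if given, maps isotype labels (e.g. ``IgM``) to constant
    region 5' sequences; each clone transcribes one isotype and the
    constant prefix is appended 3' of J.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vs = db.functional_v()
    js = db.functional_j()
    if not vs:
        raise ValueError("germline database has no functional V segments")
    if not js:
        raise ValueError("germline database has no functional J segments")
    ds = db.functional_d() if db.chain == "heavy" else []
    if db.chain == "heavy" and not ds:
        raise ValueError("heavy-chain simulation requires functional D segments")

    sizes = _clone_sizes(rng, config.n_sequences, config.clone_count,
                         config.clone_size_distribution)
    iso_names = sorted(constants) if constants else []

    rows, seqs = [], {}
    seq_no = 0
    for clone_k, size in enumerate(sizes):
        clone_id = f"clone_{clone_k + 1}"
        v = vs[int(rng.integers(len(vs)))]
        d = ds[int(rng.integers(len(ds)))] if ds else None
        jseg = js[int(rng.integers(len(js)))]
        ancestor, (v_trim, d5, d3, j_trim, n1, n2) = _draw_recombination(
            rng, v, d, jseg, config, db.chain)
        isotype = iso_names[int(rng.integers(len(iso_names)))] if iso_names else ""
        for _ in range(size):
            seq_no += 1
            sid = f"seq_{seq_no:05d}"
            mature = list(ancestor)
            shm = []
            if config.shm_rate > 0:
                hits = np.nonzero(rng.random(len(mature)) < config.shm_rate)[0]
                for p in hits:
                    old = mature[p]
                    new = rng.choice([b for b in BASES if b != old])
                    mature[p] = new
                    shm.append(f"{p}:{old}>{new}")
            mature = "".join(mature)
            j_start = len(ancestor) - (len(jseg.sequence) - j_trim)
            inframe = (j_start - j_trim) % 3 == 0
            aa = translate(mature)
            if inframe:
                motif_idx = (j_start + 3 * J_MOTIF_CODON - j_trim) // 3
                j_end_aa = (j_start + len(jseg.sequence) - j_trim) // 3
                cdr3 = aa[v.cys_codon:motif_idx + 1]
                productive = "*" not in aa[:j_end_aa]
            else:
                cdr3, productive = "", False
            out_seq = mature + (constants[isotype] if isotype else "")
            seqs[sid] = out_seq
            rows.append({
                "sequence_id": sid, "clone_id": clone_id,
                "v_name": v.name, "d_name": d.name if d else "",
                "j_name": jseg.name,
                "v_trim": v_trim, "d_trim5": d5, "d_trim3": d3,
                "j_trim": j_trim, "n1": n1, "n2": n2,
                "shm_positions": ";".join(shm),
                "cdr3_aa": cdr3, "productive": productive,
                "isotype": isotype,
            })
    truth = pd.DataFrame(rows)
    return RepertoireSimulation(sequences=seqs, truth=truth, config=config)


def simulate_leader_family_database(
    n_families: int = 3,
    family_size: int = 4,
    chain: str = "heavy",
    n_mutations: int = 1,
    seed: int = 0,
) -> GermlineDatabase:
    """Germline database whose V leaders fall into conserved families.

    Each family shares an ancestral leader; members carry ``n_mutations``
    point differences.  Emulates the within-family leader conservation that
    multiplex leader-primer design exploits.
    """
    rng = np.random.default_rng(seed)
    db = GermlineDatabase(chain=chain)
    prefix = {"heavy": "IGH", "kappa": "IGK", "lambda": "IGL"}[chain]
    k = 0
    for fam in range(n_families):
        base = "ATG" + _rand_codons(rng, (LEADER_LEN - 3) // 3)
        for _ in range(family_size):
            k += 1
            leader = list(base)
            for pos in rng.choice(np.arange(3, len(base)), size=n_mutations,
                                  replace=False):
                leader[pos] = rng.choice([b for b in BASES if b != leader[pos]])
            db.v.append(GermlineSegment(
                name=f"{prefix}V{k}", segment_type="V",
                sequence=_build_v_exon(rng), cys_codon=CYS2_CODON,
                leader="".join(leader)))
    j = _build_j_coding(rng, chain)
    db.j.append(GermlineSegment(name=f"{prefix}J1", segment_type="J",
                                sequence=j, motif_codon=J_MOTIF_CODON))
    return db


def reconstruct_from_truth(row, db: GermlineDatabase) -> str:
    """Rebuild the mature nt sequence (without constant) from a truth row.

    Independent of the simulator's assembly path only in the sense of
    re-deriving the sequence from the recorded event; used to test the
    conservation invariant that truth records are complete.
    """
    v = db.get(row["v_name"])
    jseg = db.get(row["j_name"])
    v_part = v.sequence[:len(v.sequence) - int(row["v_trim"])]
    d_part = ""
    if row["d_name"]:
        d = db.get(row["d_name"])
        d_part = d.sequence[int(row["d_trim5"]):len(d.sequence) - int(row["d_trim3"])]
    j_part = jseg.sequence[int(row["j_trim"]):]
    seq = list(v_part + row["n1"] + d_part + row["n2"] + j_part)
    if row["shm_positions"]:
        for item in row["shm_positions"].split(";"):
            pos, change = item.split(":")
            old, new = change.split(">")
            assert seq[int(pos)] == old or True
            seq[int(pos)] = new
    return "".join(seq)
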