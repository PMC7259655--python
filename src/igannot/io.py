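"""File formats: FASTA, GFF3, AIRR-style rearrangement TSV, run configs."""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import yaml

_SEQ_RE = re.compile(r"^[A-Za-z.\-*]+$")


class FastaFormatError(ValueError):
    """Malformed FASTA; the message names the offending line."""


def read_fasta(path: str) -> dict[str, str]:
    """Order-preserving FASTA reader.

    Rejects duplicate ids and malformed records with the line number;
    sequences are uppercased; N and IUPAC codes are allowed.
    """
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    if not chunks:
                        raise FastaFormatError(
                            f"{path}: record {name!r} has no sequence "
                            f"(before line {lineno})")
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FastaFormatError(f"{path}: empty header at line {lineno}")
                if name in seqs:
                    raise FastaFormatError(
                        f"{path}: duplicate id {name!r} at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise FastaFormatError(
                        f"{path}: sequence before any header at line {lineno}")
                if not _SEQ_RE.match(line):
                    raise FastaFormatError(
                        f"{path}: invalid sequence characters at line {lineno}")
                chunks.append(line)
    if name is not None:
        if not chunks:
            raise FastaFormatError(f"{path}: record {name!r} has no sequence")
        seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --------------------------------------------------------------------------
# GFF3

_GFF_TYPES = {"V": "V_gene_segment", "D": "D_gene_segment", "J": "J_gene_segment"}


def write_gff3(candidates, path: str) -> None:
    """Write gene-segment candidates as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cand in sorted(candidates, key=lambda c: (c.contig, c.start)):
            attrs = [f"ID={cand.name or 'unnamed'}",
                     f"functionality={cand.functionality or 'unscanned'}"]
            if cand.rss:
                scores = ",".join(f"{h.heptamer_score}/{h.nonamer_score}"
                                  for h in cand.rss)
                spacers = ",".join(str(h.spacer_len) for h in cand.rss)
                attrs.append(f"rss_scores={scores}")
                attrs.append(f"rss_spacers={spacers}")
            if cand.seed_identity:
                attrs.append(f"seed_identity={cand.seed_identity:.4f}")
            fh.write("\t".join([
                cand.contig, "igannot", _GFF_TYPES[cand.segment_type],
                str(cand.start + 1), str(cand.end), ".", cand.strand, ".",
                ";".join(attrs)]) + "\n")


# --------------------------------------------------------------------------
# rearrangement TSV (AIRR-style)

REARRANGEMENT_COLUMNS = [
    "sequence_id", "v_call", "d_call", "j_call", "junction_aa",
    "junction_length", "cdr3_length_imgt", "productive", "v_identity",
    "isotype", "clone_id", "novel_germline_id",
]


def write_rearrangement_tsv(rearrs, path: str) -> None:
    """One row per sequence; missing calls are empty fields."""
    with open(path, "w") as fh:
        fh.write("\t".join(REARRANGEMENT_COLUMNS) + "\n")
        for r in rearrs:
            row = [
                r.sequence_id, r.v_call or "", r.d_call or "", r.j_call or "",
                r.cdr3_aa or "",
                str(r.cdr3_length) if r.cdr3_length is not None else "",
                str(r.cdr3_length_imgt) if r.cdr3_length_imgt is not None else "",
                "T" if r.productive else "F",
                f"{r.v_identity:.4f}" if r.v_call else "",
                "" if r.isotype == "unknown" else r.isotype,
                r.clone_id or "", r.novel_germline_id or "",
            ]
            fh.write("\t".join(row) + "\n")


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline invocation."""

    chain: str = "heavy"
    min_identity: float = 0.6
    min_heptamer_score: int = 5
    min_nonamer_score: int = 6
    germline_match: float = 0.99
    clone_cdr3_identity: float = 0.8
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.chain not in ("heavy", "kappa", "lambda"):
            raise ValueError(f"unknown chain {self.chain!r}")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0,1]")
        for name, hi in (("germline_match", 1.0), ("clone_cdr3_identity", 1.0)):
            v = getattr(self, name)
            if not 0 <= v <= hi:
                raise ValueError(f"{name} out of range")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
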