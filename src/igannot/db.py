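"""Named germline gene-segment databases for one immunoglobulin chain."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

CHAINS = ("heavy", "kappa", "lambda")

FUNCTIONAL = "functional"
ORF_NO_LEADER = "orf_no_leader"
PSEUDOGENE = "pseudogene"


@dataclass
class GermlineSegment:
    """One germline V, D or J segment.

    ``cys_codon`` (V only) is the 0-based codon index of the conserved
    second cysteine marking the FR3 end — the 5' CDR3 anchor.
    ``motif_codon`` (J only) is the 0-based codon index, in the segment's
    own frame, of the F/W of the F/W-G-X-G junction motif.
    """

    name: str
    segment_type: str  # "V" | "D" | "J"
    sequence: str
    functionality: str = FUNCTIONAL
    cys_codon: int | None = None
    motif_codon: int | None = None
    leader: str | None = None
    clan: str | None = None


@dataclass
class GermlineDatabase:
    """Clan-labelled germline segments for one chain/locus."""

    chain: str
    v: list[GermlineSegment] = field(default_factory=list)
    d: list[GermlineSegment] = field(default_factory=list)
    j: list[GermlineSegment] = field(default_factory=list)

    def __post_init__(self):
        if self.chain not in CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")

    def functional_v(self) -> list[GermlineSegment]:
        return [s for s in self.v if s.functionality == FUNCTIONAL]

    def functional_d(self) -> list[GermlineSegment]:
        return [s for s in self.d if s.functionality == FUNCTIONAL]

    def functional_j(self) -> list[GermlineSegment]:
        return [s for s in self.j if s.functionality == FUNCTIONAL]

    def get(self, name: str) -> GermlineSegment:
        for s in self.v + self.d + self.j:
            if s.name == name:
                return s
        raise KeyError(name)

    # ------------------------------------------------------------------ I/O
    def save(self, directory: str) -> None:
        """Write v/d/j FASTA plus a metadata TSV into ``directory``."""
        from .io import write_fasta

        os.makedirs(directory, exist_ok=True)
        for kind, segs in (("v", self.v), ("d", self.d), ("j", self.j)):
            if segs:
                write_fasta({s.name: s.sequence for s in segs},
                            os.path.join(directory, f"{kind}.fasta"))
        rows = []
        for s in self.v + self.d + self.j:
            rows.append({
                "name": s.name, "segment_type": s.segment_type,
                "functionality": s.functionality,
                "cys_codon": "" if s.cys_codon is None else s.cys_codon,
                "motif_codon": "" if s.motif_codon is None else s.motif_codon,
                "leader": s.leader or "", "clan": s.clan or "",
            })
        pd.DataFrame(rows).to_csv(os.path.join(directory, "segments.tsv"),
                                  sep="\t", index=False)
        with open(os.path.join(directory, "chain.txt"), "w") as fh:
            fh.write(self.chain + "\n")

    @classmethod
    def load(cls, directory: str) -> "GermlineDatabase":
        from .io import read_fasta

        with open(os.path.join(directory, "chain.txt")) as fh:
            chain = fh.read().strip()
        meta = pd.read_csv(os.path.join(directory, "segments.tsv"), sep="\t",
                           keep_default_na=False, dtype=str)
        seqs: dict[str, str] = {}
        for kind in ("v", "d", "j"):
            path = os.path.join(directory, f"{kind}.fasta")
            if os.path.exists(path):
                seqs.update(read_fasta(path))
        db = cls(chain=chain)
        for _, row in meta.iterrows():
            seg = GermlineSegment(
                name=row["name"], segment_type=row["segment_type"],
                sequence=seqs[row["name"]],
                functionality=row["functionality"],
                cys_codon=int(row["cys_codon"]) if row["cys_codon"] else None,
                motif_codon=int(row["motif_codon"]) if row["motif_codon"] else None,
                leader=row["leader"] or None, clan=row["clan"] or None,
            )
            getattr(db, seg.segment_type.lower()).append(seg)
        return db
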