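"""Degenerate multiplex primer pools against conserved leader and
constant regions of a germline database.

The amplification strategy mirrors nested multiplex RT-PCR of recombined
transcripts: forward primers bind conserved leader exons (or V 5' ends
when leaders are unknown), reverse primers bind constant-region 5' ends
(or J segments in ``ighj`` mode), and a secondary pool binds strictly
inside every primary amplicon.  Pools are built by greedy set cover over
degeneracy-bounded cluster consensus primers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .db import GermlineDatabase
from .rss import revcomp

IUPAC: dict[frozenset, str] = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
IUPAC_SETS = {v: k for k, v in IUPAC.items()}


@dataclass
class Primer:
    sequence: str                  # IUPAC nucleotide string
    target_region: str             # "leader" | "constant" | "j_segment"
    orientation: str               # "forward" | "reverse"
    degeneracy: int
    tm_estimate: float
    covered_germlines: list[str] = field(default_factory=list)
    binding_offset: int = 0        # offset of the binding site in the target


@dataclass
class NestedScheme:
    primary_pool: list[Primer]
    secondary_pool: list[Primer]
    uncovered: list[str] = field(default_factory=list)


def degenerate_consensus(window: list[str]) -> tuple[str, int]:
    """IUPAC consensus of equal-length, gap-free aligned sequences.

    Degeneracy is the product over positions of base-set sizes.
    """
    if not window:
        raise ValueError("empty window")
    L = len(window[0])
    if L < 1 or any(len(s) != L for s in window):
        raise ValueError("window sequences must share a positive length")
    out = []
    degeneracy = 1
    for col in zip(*[s.upper() for s in window]):
        if "-" in col or "." in col:
            raise ValueError("gapped column in consensus window")
        bases = frozenset(col)
        if not bases <= set("ACGT"):
            raise ValueError(f"non-ACGT symbol in column {col}")
        out.append(IUPAC[bases])
        degeneracy *= len(bases)
    return "".join(out), degeneracy


def expected_composition(primer: str) -> tuple[float, float]:
    """Expected (A+T, G+C) counts; degenerate positions contribute their
    base-set average."""
    at = gc = 0.0
    for ch in primer.upper():
        bases = IUPAC_SETS[ch]
        at += sum(1 for b in bases if b in "AT") / len(bases)
        gc += sum(1 for b in bases if b in "GC") / len(bases)
    return at, gc


def melting_temp(primer: str) -> float:
    """Wallace rule below 14 nt, GC-fraction formula otherwise."""
    if not primer:
        raise ValueError("empty primer")
    at, gc = expected_composition(primer)
    n = len(primer)
    if n < 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / n


def _mismatches(primer: str, site: str) -> int:
    """Mismatches of a degenerate primer against a concrete site."""
    return sum(1 for p, s in zip(primer, site) if s not in IUPAC_SETS[p])


@dataclass
class PrimerDesignParams:
    primer_len: int = 20
    max_degeneracy: int = 32
    max_mismatch: int = 1
    secondary_offset: int = 10     # 3' shift of nested secondary primers


def _greedy_pool(windows: dict[str, str], region: str, orientation: str,
                 params: PrimerDesignParams, offset: int) -> tuple[list[Primer], list[str]]:
    """Greedy set cover: grow degeneracy-bounded clusters, largest first."""
    uncovered = sorted(windows)
    primers: list[Primer] = []
    while uncovered:
        best = None
        for seed in uncovered:
            members = [seed]
            cons, deg = windows[seed], 1
            for other in uncovered:
                if other == seed:
                    continue
                trial = members + [other]
                cons_t, deg_t = degenerate_consensus([windows[m] for m in trial])
                if deg_t > params.max_degeneracy:
                    continue
                if any(_mismatches(cons_t, windows[m]) > params.max_mismatch
                       for m in trial):
                    continue
                members, cons, deg = trial, cons_t, deg_t
            key = (-len(members), sorted(members))
            if best is None or key < best[0]:
                best = (key, members, cons, deg)
        _, members, cons, deg = best
        primers.append(Primer(
            sequence=cons, target_region=region, orientation=orientation,
            degeneracy=deg, tm_estimate=melting_temp(cons),
            covered_germlines=sorted(members), binding_offset=offset))
        uncovered = [u for u in uncovered if u not in members]
    return primers, []


def _forward_windows(db: GermlineDatabase, params: PrimerDesignParams,
                     offset: int) -> tuple[dict[str, str], list[str], str]:
    """Forward binding sites: leader 5' ends, or V 5' ends without leaders."""
    windows: dict[str, str] = {}
    skipped: list[str] = []
    any_leader = any(s.leader for s in db.functional_v())
    region = "leader" if any_leader else "v_5prime"
    for seg in db.functional_v():
        source = seg.leader if any_leader else seg.sequence
        if source is None or len(source) < offset + params.primer_len:
            # leaderless genes in a leader-primed design cannot be covered
            skipped.append(seg.name)
            continue
        windows[seg.name] = source[offset:offset + params.primer_len].upper()
    return windows, skipped, region


def design_pools(
    db: GermlineDatabase,
    constants: dict[str, str],
    params: PrimerDesignParams | None = None,
    mode: str = "constant",
) -> NestedScheme:
    """Design a nested multiplex scheme for one chain.

    Forward primers cover every functional germline's leader (greedy set
    cover under the degeneracy and mismatch bounds); reverse primers derive
    from constant-region 5' ends (``mode="constant"``) or J segments
    (``mode="ighj"``).  Secondary primers bind ``secondary_offset`` nt 3'
    of the primaries, strictly inside each primary amplicon.  Germlines
    that cannot be covered are listed in ``uncovered``.
    """
    params = params or PrimerDesignParams()
    if mode not in ("constant", "ighj"):
        raise ValueError("mode must be 'constant' or 'ighj'")
    if mode == "constant" and not constants:
        raise ValueError("constant reference set must be non-empty")

    fwd1_windows, skipped, region = _forward_windows(db, params, 0)
    fwd2_windows, _, _ = _forward_windows(db, params, params.secondary_offset)
    primary_fwd, _ = _greedy_pool(fwd1_windows, region, "forward", params, 0)
    secondary_fwd, _ = _greedy_pool(fwd2_windows, region, "forward", params,
                                    params.secondary_offset)

    # reverse primers: revcomp of a window in the constant 5' end (or J);
    # the primary binds farther 3', the secondary closer to the junction.
    if mode == "constant":
        targets = {name: seq for name, seq in constants.items()}
        region_r = "constant"
    else:
        targets = {s.name: s.sequence for s in db.functional_j()}
        region_r = "j_segment"
    L = params.primer_len
    usable = {n: s.upper() for n, s in targets.items() if len(s) >= 20}
    skipped += [n for n in targets if n not in usable]
    rev1, rev2 = {}, {}
    off1 = off2 = 0
    if usable:
        minlen = min(len(s) for s in usable.values())
        if minlen >= 2 * L + params.secondary_offset:
            L_eff, off1, off2 = L, L + params.secondary_offset, 0
        elif minlen >= 2 * L:
            L_eff, off1, off2 = L, minlen - L, 0
        else:
            # short targets (J segments): two non-overlapping half-length
            # primers keep the nested arrangement
            L_eff = minlen // 2
            off1, off2 = minlen - L_eff, 0
        for name, seq in usable.items():
            rev1[name] = revcomp(seq[off1:off1 + L_eff])
            rev2[name] = revcomp(seq[off2:off2 + L_eff])
    primary_rev, _ = _greedy_pool(rev1, region_r, "reverse", params, off1)
    secondary_rev, _ = _greedy_pool(rev2, region_r, "reverse", params, off2)

    return NestedScheme(
        primary_pool=primary_fwd + primary_rev,
        secondary_pool=secondary_fwd + secondary_rev,
        uncovered=sorted(set(skipped)))


def verify_coverage(primer: Primer, windows: dict[str, str],
                    max_mismatch: int) -> bool:
    """Every claimed germline truly matches the primer within the bound."""
    return all(_mismatches(primer.sequence, windows[g]) <= max_mismatch
               for g in primer.covered_germlines if g in windows)


def enumerate_primer(primer: str) -> list[str]:
    """All concrete sequences of a degenerate primer (test-sized only)."""
    return ["".join(p) for p in product(*[sorted(IUPAC_SETS[c]) for c in primer])]
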