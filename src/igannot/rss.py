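"""Recombination signal sequence (RSS) motifs and detection.

An RSS is a conserved heptamer (consensus ``CACAGTG``) separated from a
conserved nonamer (consensus ``ACAAAAACC``) by a spacer of ~12 or ~23 nt.
The 12/23 rule pairs gene segments flanked by RSSs of different spacer
classes during V(D)J recombination.

Two orientations are distinguished on the coding strand:

* ``downstream`` — heptamer..spacer..nonamer reading left to right,
  as found 3' of V segments (heptamer abuts the coding end);
* ``upstream`` — the reverse complement arrangement
  revcomp(nonamer)..spacer..revcomp(heptamer) reading left to right,
  as found 5' of J segments (revcomp heptamer abuts the coding start).
"""

from __future__ import annotations

from dataclasses import dataclass

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# Canonical spacer classes per chain (12/23 rule), chosen once:
# heavy V uses a 23-spacer downstream RSS, D is flanked by 12/12, heavy J a
# 23-spacer upstream RSS; kappa V 12 / J 23; lambda V 23 / J 12.
SPACER_CLASS: dict[tuple[str, str], int] = {
    ("heavy", "V"): 23,
    ("heavy", "D"): 12,
    ("heavy", "J"): 23,
    ("kappa", "V"): 12,
    ("kappa", "J"): 23,
    ("lambda", "V"): 23,
    ("lambda", "J"): 12,
}

#: default scan window (nt) for a V segment's downstream RSS
DEFAULT_V_RSS_WINDOW = 40
#: default spacer-length tolerance around the nominal class
SPACER_TOLERANCE = 1
#: acceptance thresholds: matches-to-consensus counts
MIN_HEPTAMER_SCORE = 5
MIN_NONAMER_SCORE = 6


@dataclass(frozen=True)
class RSSHit:
    """A heptamer/spacer/nonamer match.

    Offsets are 0-based on the sequence that was scanned.  For a
    ``downstream`` hit ``nonamer_start == heptamer_start + 7 + spacer_len``;
    for an ``upstream`` hit the heptamer 7-mer occupies
    ``[heptamer_start, heptamer_start + 7)`` in reverse-complement reading
    and ``nonamer_start == heptamer_start - spacer_len - 9``.
    """

    heptamer_start: int
    spacer_len: int
    nonamer_start: int
    heptamer_score: int
    nonamer_score: int
    orientation: str  # "downstream" | "upstream"

    @property
    def total_score(self) -> int:
        return self.heptamer_score + self.nonamer_score


def _matches(observed: str, consensus: str) -> int:
    return sum(1 for a, b in zip(observed, consensus) if a == b)


def score_heptamer(seq7: str) -> int:
    return _matches(seq7, HEPTAMER)


def score_nonamer(seq9: str) -> int:
    return _matches(seq9, NONAMER)


def _passes(hept: str, h_score: int, n_score: int, *, require_cac: bool,
            min_heptamer: int, min_nonamer: int) -> bool:
    if require_cac and not hept.startswith("CAC"):
        return False
    return h_score >= min_heptamer and n_score >= min_nonamer


def detect_rss(
    seq: str,
    anchor: int,
    spacer_class: int,
    search_window: int = DEFAULT_V_RSS_WINDOW,
    *,
    orientation: str = "downstream",
    tolerance: int = SPACER_TOLERANCE,
    min_heptamer: int = MIN_HEPTAMER_SCORE,
    min_nonamer: int = MIN_NONAMER_SCORE,
    require_cac: bool = True,
) -> RSSHit | None:
    """Best-scoring RSS near ``anchor``, or None if nothing passes.

    ``downstream``: heptamer start is searched in
    ``[anchor, anchor + search_window)`` moving right.
    ``upstream``: the revcomp-heptamer *end* is searched in
    ``(anchor - search_window, anchor]`` moving left; ``heptamer_start``
    of the returned hit is the start of that 7-mer on ``seq``.

    Windows truncated at sequence ends are scanned as far as possible.
    Ties are broken toward the position closest to the anchor, then the
    spacer length closest to ``spacer_class``, then the shorter spacer.
    """
    if not 0 <= anchor <= len(seq):
        raise ValueError(f"anchor {anchor} outside sequence of length {len(seq)}")
    if orientation not in ("downstream", "upstream"):
        raise ValueError(f"bad orientation {orientation!r}")

    spacers = [spacer_class + d for d in range(-tolerance, tolerance + 1)]
    best: tuple | None = None
    best_hit: RSSHit | None = None

    if orientation == "downstream":
        positions = range(anchor, min(anchor + search_window, len(seq)))
        for h in positions:
            hept = seq[h:h + 7]
            if len(hept) < 7:
                break
            h_score = score_heptamer(hept)
            for sp in spacers:
                n0 = h + 7 + sp
                non = seq[n0:n0 + 9]
                if len(non) < 9:
                    continue
                n_score = score_nonamer(non)
                if not _passes(hept, h_score, n_score, require_cac=require_cac,
                               min_heptamer=min_heptamer, min_nonamer=min_nonamer):
                    continue
                key = (-(h_score + n_score), h - anchor, abs(sp - spacer_class), sp)
                if best is None or key < best:
                    best = key
                    best_hit = RSSHit(h, sp, n0, h_score, n_score, "downstream")
    else:
        # revcomp-heptamer ends at e (exclusive), scanning leftward from anchor
        positions = range(anchor, max(anchor - search_window, 0) - 1, -1)
        for e in positions:
            h0 = e - 7
            if h0 < 0:
                break
            hept = revcomp(seq[h0:e])
            h_score = score_heptamer(hept)
            for sp in spacers:
                n0 = h0 - sp - 9
                if n0 < 0:
                    continue
                non = revcomp(seq[n0:n0 + 9])
                n_score = score_nonamer(non)
                if not _passes(hept, h_score, n_score, require_cac=require_cac,
                               min_heptamer=min_heptamer, min_nonamer=min_nonamer):
                    continue
                key = (-(h_score + n_score), anchor - e, abs(sp - spacer_class), sp)
                if best is None or key < best:
                    best = key
                    best_hit = RSSHit(h0, sp, n0, h_score, n_score, "upstream")
    return best_hit


def upstream_rss_starts(seq: str, spacer_class: int, **kw) -> dict[int, RSSHit]:
    """All positions i such that an upstream RSS ends exactly at i.

    These are candidate 5' coding-segment starts (a D or J segment begins
    immediately right of the revcomp heptamer).  Returns ``{i: hit}``.
    """
    hits: dict[int, RSSHit] = {}
    for i in range(16 + spacer_class, len(seq) + 1):
        hit = detect_rss(seq, i, spacer_class, search_window=1,
                         orientation="upstream", **kw)
        if hit is not None and hit.heptamer_start + 7 == i:
            hits[i] = hit
    return hits


def downstream_rss_starts(seq: str, spacer_class: int, **kw) -> dict[int, RSSHit]:
    """All positions j such that a downstream RSS starts exactly at j.

    These are candidate 3' coding-segment ends (a V or D segment ends
    immediately left of the heptamer).  Returns ``{j: hit}``.
    """
    hits: dict[int, RSSHit] = {}
    for j in range(0, len(seq) - (16 + spacer_class) + 1):
        hit = detect_rss(seq, j, spacer_class, search_window=1,
                         orientation="downstream", **kw)
        if hit is not None and hit.heptamer_start == j:
            hits[j] = hit
    return hits
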