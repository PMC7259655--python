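"""Built-in reference fixtures.

The clan exemplar set shipped here is *synthetic*: three deeply divergent
ancestral V-like families standing in for curated clan I/II/III exemplar
sequences.  It provides a deterministic default for clan assignment demos
and tests; real analyses should supply curated exemplars as FASTA.
"""

from __future__ import annotations

import numpy as np

from .simulate import BASES, _build_v_exon, _mutate

DEFAULT_CLANS = ("I", "II", "III")


def synthetic_clan_exemplars(
    n_per_clan: int = 3,
    divergence: float = 0.05,
    seed: int = 7,
) -> tuple[dict[str, str], dict[str, str]]:
    """Generate synthetic clan exemplars.

    Each clan is an independent random V-like ancestor; exemplars are the
    ancestor mutated at ``divergence`` per base.  Returns ``(seqs, clans)``
    where ``clans`` maps exemplar name to clan label.
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    clans: dict[str, str] = {}
    for clan in DEFAULT_CLANS:
        ancestor = _build_v_exon(rng)
        for k in range(n_per_clan):
            name = f"synthetic_clan{clan}_{k + 1}"
            seqs[name] = _mutate(rng, ancestor, divergence)
            clans[name] = clan
    return seqs, clans
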