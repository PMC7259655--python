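# Methods

## Scope and model

The pipeline treats germline immunoglobulin annotation as a structural
pattern-recognition problem layered on homology search. A V, D or J gene
segment is accepted not on sequence similarity alone but on the canonical
architecture of its recombination signals and splice elements:

* **RSS model.** Each signal is scored as matches-to-consensus of the
  heptamer (`CACAGTG`, 7 positions) and nonamer (`ACAAAAACC`, 9 positions)
  separated by a spacer of nominal length 12 or 23 nt (tolerance ±1). A
  hit requires heptamer ≥ 5/7 with the first three bases `CAC` intact
  (these are essential for recombinase binding), nonamer ≥ 6/9, and the
  best-scoring arrangement in the window is reported with deterministic
  tie-breaks (total score, proximity to the anchor, spacer closeness to
  the nominal class, shorter spacer). Spacer classes follow the 12/23
  rule as conserved in mammals: heavy V 23 (downstream), D 12/12
  (flanking), heavy J 23 (upstream); kappa V 12 / J 23; lambda V 23 /
  J 12.
* **V discovery** is iterative: seed germlines (related species or
  previously recovered segments) are aligned to both strands with
  edit-distance (edlib) infix alignment; hits at or above the identity
  floor (default 0.6) are deduplicated by ≥50% interval overlap
  (tie-break: seed identity, length, leftmost) and join the seed pool for
  the next round, up to 10 rounds or convergence.
* **Leader exons** are located upstream of a V coding exon as the unique
  arrangement: `ATG`-initiated exon of 45–75 nt whose length preserves the
  reading frame (length ≡ 0 mod 3), a `GT` splice donor at the exon end,
  an intron of ≥50 nt ending `AG` immediately before the coding exon.
* **Functionality** follows a strict order: a candidate is a *pseudogene*
  if its coding exon contains an in-frame stop, shows a frame-shifting
  net indel against its best seed, lacks a passing RSS, or is missing
  critical residues (a cysteine within the last 8 codons — the FR3-end
  CDR3 anchor — and a tryptophan in codons 25–45); otherwise *functional*
  with a leader, *ORF-without-leader* without one.
* **D segments** are intervals of 8–40 nt flanked by an inward-facing
  upstream RSS and an outward-facing downstream RSS, both 12-spacer.
  Because this cassette is reverse-complement symmetric and
  identity-to-consensus scoring is invariant under reverse complement,
  the two strand interpretations tie exactly; the annotator reports `+`
  on ties. Strand for D is therefore a convention, not an inference.
* **J segments** require an upstream RSS of the chain's J class, an
  F/W-G-X-G motif in some reading frame of the coding interval, and a
  `GTRAGT` splice donor terminating it.

## Phylogenetics

Distances are Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), with gap-containing
columns removed pairwise before computing the mismatch proportion p; p ≥
0.75 raises a saturation error. During bootstrap resampling, saturated
pairs are instead capped at a large finite distance (5.0
substitutions/site) so replicate trees remain computable for deeply
divergent groups — the affected pairs are exactly those with no usable
phylogenetic signal under JC. Trees are Saitou–Nei neighbour joining,
unrooted; Q-criterion ties break toward the lexicographically lowest
label pair and negative branch-length estimates are clamped to zero (and
counted). The bootstrap resamples alignment columns with replacement,
builds an NJ tree per replicate, and reports the majority-rule (>0.5)
consensus with per-split replicate fractions as support. Clan assignment
builds one joint NJ tree over query segments plus clan exemplars from
pairwise global-alignment JC distances and gives each query the clan of
its nearest exemplar by patristic distance; exact ties fall back to JC
distance, and residual ties or unalignable queries are left unassigned.

The packaged clan exemplars are **synthetic** — three deeply divergent
random V-like ancestral families — suitable for demonstrations and tests
of the assignment machinery; real analyses should supply curated
exemplar FASTA (`name|clan` ids in the CLI).

## Repertoire analysis

V and J calls use semi-global (infix) alignment of each germline within
the read. The V alignment's trailing non-match run is stripped before
computing identity (the exonuclease-trimmed germline 3′ end has no
counterpart in the read and must not count as mismatches); the J
alignment's leading run is stripped symmetrically. Identity is matches
over aligned germline columns. D calls require a ≥5-nt exact match within
the junction window between V end and J start, the longest match winning.

CDR3 runs from the conserved FR3 cysteine — the germline-annotated codon
mapped through the V alignment — to the J-segment F/W of F/W-G-X-G, both
anchors included, matching the counting rule "from the conserved cysteine
to the conserved tryptophan/phenylalanine"; `cdr3_length_imgt` excludes
the anchors for interoperability. The 3′ anchor position is taken from
the germline J motif mapped through the J alignment when it is in frame
with the cysteine, falling back to scanning the translation for the
first motif occurrence; anchoring on mapped positions rather than read
residues keeps CDR3 extraction stable when hypermutation strikes an
anchor codon. A sequence is productive when anchors are found and the
V-through-J frame is stop-free.

Novel germline inference looks for recurrent V sequences that no known
germline explains: supporters must agree exactly over a shared prefix
covering ≥90% of the (alignment-estimated) V region — the estimate is
bounded above by the aligned J start, since raw V-end estimates against a
distant germline are noisy — must span ≥2 distinct junctions (ruling out
clonal duplicates), and the group consensus (the longest prefix on which
two eventually-diverging supporters agree) must be <99% identical to
every known germline over the mutual prefix. The consensus may carry one
or two junction bases that supporters share by chance past the true
germline end; recovery is therefore exact up to this boundary noise, and
the hold-out test scores recovery at ≥99% consensus identity.

Clonal families are single-linkage clusters over sequences sharing
V call, J call and CDR3 length, linked at ≥0.8 CDR3 amino-acid identity
(a community-standard threshold); clone ids are deterministic (size, then
first sequence id), and sequences without a CDR3 become flagged
singletons. Isotypes are assigned by best identity of the post-J tail
against constant-region 5′ references, floor 0.7.

## The synthetic-data generator

`simulate_locus` plants segment cassettes in i.i.d.-uniform background:
V = leader exon (57 nt, starting `ATG`) + intron (60–100 nt, `GT…AG`) +
coding exon (98 codons with Cys21/Trp36/Cys95 conserved) + downstream
RSS; D = 12–25 nt flanked by 12-RSSs; J = 3 codons + motif + 4 codons +
`GTRAGT` donor. Pseudogenes receive an in-frame stop or a degraded RSS;
leaderless genes omit the leader. Defaults (20 V with 25% pseudogenes and
20% leaderless among the functional, 7 D, 5 J, 300 nt padding) mirror the
composition of an annotated carnivore heavy locus.

The generator *guarantees recoverability of planted truth*: each leader
search window contains exactly one `ATG` and no competing frame-compatible
`GT` donor, J segments contain no internal donor and no spurious motif
before the planted one, planted D segments share no ≥5-mer between each
other, pads are scrubbed of exact RSS heptamer cores, and degraded RSSs
are verified to fail detection. These constraints make exact
planted-recovery and byte-exact round-trip tests meaningful; they also
mean the background is cleaner than real intergenic sequence, so passing
tests demonstrate correctness of the machinery, not expected sensitivity
on real genomes (real loci add repeats, segmental duplications and
diverged relics that only the identity floor addresses).

`simulate_repertoire` draws one recombination event per clone (uniform
trims ≤ 2 nt, uniform N-insert lengths ≤ 6 nt with uniform bases — the
junction model is deliberately the simplest that exercises the analysis)
and applies SHM as independent per-base substitutions. By default
junctions are selected to be in-frame and stop-free with the planted J
motif the first one downstream of the cysteine (productive selection,
as in sorted B cells); this makes truth CDR3s well-defined. Clone sizes
are uniform or Zipf-like (`power`). The resulting CDR3 lengths centre
near 13–14 aa, matching carnivore heavy-chain repertoires, though with a
narrower range than real data because junction-length variation is
bounded by `trim_max`/`n_insert_max`. Indel SHM, hotspot bias and
heavy/light pairing are not modelled.

## Primer design

Forward primer windows are the first 20 nt of each functional germline's
leader (or the V 5′ end when the database has no leaders). Pools are
greedy set cover: for each uncovered germline a cluster is grown by
adding windows while the IUPAC consensus stays within degeneracy ≤ 32 and
every member within ≤1 mismatch; the largest cluster (ties: name order)
is emitted as one degenerate primer. Reverse primers derive from constant
5′ ends or J segments; for targets shorter than two primer lengths, two
non-overlapping half-length primers preserve the nested arrangement.
Secondary primers bind 10 nt 3′ of primaries (forward) and 5′ of
primaries (reverse), so every secondary amplicon is strictly contained in
a primary amplicon. Melting temperatures use the Wallace rule
2(A+T)+4(G+C) below 14 nt and 64.9 + 41(GC − 16.4)/n otherwise, with
degenerate positions contributing their expected composition.
Cross-dimer and hairpin thermodynamics are out of scope.

## Numerical and testing choices

All randomness flows through `numpy.random.default_rng` seeds carried in
the config objects; identical configs give byte-identical outputs. Test
problem sizes are chosen to exercise the statistics at desk scale: the
planted-recovery property uses a 200-segment locus at 2% RSS mutation
(with the CAC-mandatory threshold, sensitivity ≥0.95 is attainable at
this rate; at 5% the mandatory heptamer core itself is destroyed with
probability ~0.14 per RSS, which no detector honouring the threshold can
recover), the round-trip check uses 500 SHM-free sequences, and SHM
parameter recovery uses three seeds of 300 sequences at 2% SHM. RSS
detection and neighbour joining are verified against independently
written brute-force oracles; NJ is additionally cross-checked against
scikit-bio's implementation on additive matrices.
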