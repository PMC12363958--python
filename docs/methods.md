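# Methods

## The construct model

A RETS design converts a (target transcript, cargo ORF) pair into two
transcripts that together encode a split group I intron ribozyme flanking
the two halves of the cargo message. The toolkit's model of that system is
purely sequence-level: segment grammar, base-pairing rules and exact string
arithmetic. No folding, thermodynamics or kinetics are modelled — the
underlying biology provides no usable rate or affinity parameters for
them, and every design decision the grammar encodes is checkable by exact
sequence comparison.

Fragment layouts (5'→3', DNA alphabet internally; RNA is a display
option):

```
fragment 1:  [5'UTR/leader + CDS up to junction]  p1_up(9)  GGATCA  guide_1
                             └─ last 6 nt = IGSBS, ends in T
fragment 2:  guide_2  TGATCC  p1_down(11)  IGS(6)  core(387)  [CDS after junction]
```

The ribozyme unit accounts as 6 (IGSBS) + 9 + 11 + 6 (IGS) + 387 = 419 nt,
split after residue 15 (IGSBS + upstream P1 half). `validate_scaffold`
enforces exactly this bookkeeping; the 419 total includes the 6
exon-derived IGSBS bases, the only reading under which the printed segment
lengths are self-consistent.

**Splice sites.** The one hard rule is that the upstream exon ends in U
(T). `start_codon` mode splits inside AUG after its U, so the 5'UTR must
contribute the IGSBS's first four bases — the leader therefore ends in
UUAC, giving the canonical IGSBS `UUACAU`. `internal` mode enumerates
every in-CDS junction preceded by T, annotated with its codon context
(e.g. `TT/T of F3`); no reading-frame restriction is imposed because
splitting works at any phase. When a single internal site is wanted, the
selector prefers the junction closest to the CDS midpoint (ties: smaller
coordinate), mirroring the practice of moving the split to the middle of
the gene.

**IGS derivation.** The IGS is the antiparallel complement of the IGSBS
with G substituted opposite the splice-site U, producing exactly 5
Watson–Crick pairs plus the single G·U wobble the ribozyme requires
(`UUACAU → GUGUAA`). No constraints are imposed on IGSBS positions 1–5;
the pairing pattern is surfaced in reports so a user can inspect
incidental wobbles in candidate sites.

**Guides and geometry.** A target window spans `2·L + 5`: two L-nt guide
binding sites separated by 5 target bases. Guide 1 (3' of fragment 1) is
antisense to the 5'-proximal sub-window and guide 2 to the 3'-proximal
one — the only orientation in which the two helper stems (GGAUCA/UGAUCC)
are juxtaposed across the spacer after annealing. Guides bind anywhere on
the sense target; strandedness is fixed.

## Safety screens

**RNAi (DICER duplex rule).** Each guide annealed to its sub-window forms
a perfect duplex of its full length; duplexes of ≥ 37 bp are efficient
DICER substrates, so `rnai_safety_check` fails at 37 (exclusive bound; 36
passes). The default guide length is 30 nt — the best-performing validated
length below the bound; 20, 25 and 50 nt are also validated choices and
200 nt illustrates the silencing-prone regime. `duplex_profile`
generalises the check to whole fragments versus a transcriptome: the
longest contiguous perfect antiparallel run per fragment × transcript
(computed as the longest common substring of the fragment's reverse
complement and the transcript, via binary search over rolling k-mer sets),
flagged at the same bound. A guide's duplex can extend a few bases past
its sub-window when spacer bases happen to match the helper stem; for a
30-nt guide the common worst case is 36 bp, still below the bound.

**Off-target cross-reactivity.** Complex formation tolerates imperfect
matches — family members at roughly 75% identity to the targeted region
can trigger splicing — so candidate windows are screened against a
reference transcriptome. The screen is ungapped seed-and-extend: exact
k-mers shared between the footprint and a transcript anchor a diagonal,
the footprint is aligned ungapped there, and three segments (each
sub-window and the full footprint) are scored; any segment at ≥ the
identity threshold (default 0.75) is reported, because a single arm
binding at that level is itself a liability. The configured seed (default
12) is internally capped at the pigeonhole bound `⌊len/(mismatches+1)⌋`
implied by the threshold and segment lengths, which makes the seeded
search provably as sensitive as an exhaustive scan — the suite asserts
exact agreement with a brute-force window-by-window oracle. The 0.75
default is motivated by the observed cross-reactivity level, not
prescribed; it is exposed as a parameter. `rank_windows` drops any window
with a hit and orders survivors by fewest near-threshold similarities
(within 0.15 below threshold, configurable), GC fraction closest to 0.5,
then smallest coordinate — fully deterministic.

## The splice simulator

`simulate_hybridization` is a strict structural checklist, not a binding
model: exact antiparallel matches of both guides on the candidate target
(all match coordinates listed), exactly 5 target bases between the two
binding sites, helper-stem complementarity, and the 5 WC + 1 wobble
IGS·IGSBS pattern. Competence is the conjunction; a single mismatch under
either guide breaks it. Mismatch tolerance is deliberately excluded — the
cross-reactivity risk is the screen's job, and conflating the two would
invent an unsupported tolerance function. `simulate_splice` returns the
ligated exons (`5'UTR + CDS`, byte-exact by construction) for a competent
complex, or a refusal naming the first failed condition. `verify_orf`
independently checks the product carries the CDS intact, in frame, at the
annotated start, with first-divergence and premature-stop diagnostics.

## Synthetic fixtures

The generator emulates the screening scenario the design rules address: a
target transcript, a paralog diverged over a 400-nt targeted region by
exactly `round((1−identity)·400)` uniform substitutions (default identity
0.75 → 100 substitutions, the family-member cross-reactivity level), and
i.i.d. decoy transcripts at a configurable GC fraction. Everything is
bit-reproducible from an integer seed. Divergence is substitution-only by
design, exercising exactly the ungapped detection model of the screen;
gapped divergence, expression levels and tissue context are out of scope,
so green tests certify the sequence logic, not in-vivo efficiency —
splice-site efficiency, guide secondary structure and binding energetics
are explicitly not modelled.

The packaged ribozyme segments and the 68-nt leader are synthetic
stand-ins (fixed, seeded-then-frozen bytes) with the correct segment
lengths and the functionally constrained termini (leader ending TTAC;
helper stems GGATCA/TGATCC). All design logic depends only on those
properties; real TtRz segments can be supplied in a YAML scaffold config.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; reports and GenBank output
  use 1-based inclusive.
* Ingest is strict: uppercase ACGT only (U normalised to T at FASTA
  ingest); degenerate codes are rejected rather than guessed at.
* All orderings (windows, hits, rankings) are deterministic; identical
  inputs produce byte-identical FASTA/GenBank/manifest outputs.
* Promoters/terminators (pUBQ1, p35s, tHSP) and the normalization cassette
  appear in the manifest as named placeholders only; they are standard
  parts orthogonal to the splice logic.
* Designs are named `Target:RETS:Cargo`.

## Problem sizes

The test suite and acceptance script use toy scales chosen to exercise
every rule while keeping brute-force oracles cheap: cargos of 20–120
codons, targets of a few hundred nt to ~1.2 kb, transcriptomes of a dozen
~1-kb records, 500 randomized end-to-end designs across guide lengths
20/25/30/50/200, and 1000 random splice sites for the wobble-rule check.
The algorithms themselves are linear or near-linear in transcriptome size
and handle realistic transcriptomes; only the quadratic test oracles
require small inputs.

## Known limitations

* No prediction of splice efficiency, dose–response or expression level;
  competence is boolean.
* The off-target screen is ungapped; paralogs diverged by indels can
  evade it (and the fixture generator accordingly plants substitutions
  only).
* How many real-world mismatches the assembled complex tolerates in vivo
  is unknown; the simulator does not guess, so off-target risk assessment
  rests entirely on the identity screen.
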