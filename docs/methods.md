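# Methods

## Candidate geometry

A design candidate is a 23-nt footprint on the target mRNA. The duplex is the
standard realization of "two ~21-nt strands with 2-nt 3' overhangs": sense
strand = footprint positions 2–22, guide strand = reverse complement of
positions 0–20, giving a 19-bp paired core flanked by 2-nt 3' overhangs on
both strands. Footprints are enumerated at every start `0 … L−23`; a target
therefore yields `L − 22` candidates and must be at least 23 nt. All
coordinates in the package are 0-based, half-open.

## Energy model and ranking

Duplex-end stabilities use the Xia et al. (1998) RNA/RNA Watson-Crick
nearest-neighbor ΔG°37 parameters, shipped as
`src/mshrna/data/xia1998_rna_nn.tsv` (16 top-strand dinucleotide keys, 10
unique values by Watson-Crick symmetry; initiation penalty +4.09 kcal/mol,
recorded but unused because it cancels in the end difference). Alternative
tables load from the same TSV format; the loader enforces exactly 16 finite
entries and Watson-Crick symmetry to 1e-9, and the run log records the
table's provenance label and a content checksum.

The score is `asymmetry = ΔG(guide-5' window) − ΔG(sense-5' window)` over a
terminal window of `window_bp` base pairs (default 5, configurable 2–10;
classic 5'-end asymmetry rules examine roughly the terminal 4 bp). End sums
use `math.fsum`, so each sum is correctly rounded independent of stack order
and the antisymmetry of the score under a sense/guide relabelling is exact in
floating point. Whole-duplex ΔG is deliberately not part of the ranking; the
window and table are the configuration surface for experimenting with other
energy statistics.

Composition filters (all overridable): 19-bp-core GC fraction in
[0.30, 0.65]; no homopolymer run of 5 or more in either strand; no run of 4
or more G in either strand. These are community defaults for functional,
synthesizable siRNAs, not values with a single canonical source.

Winner selection is greedy: sort passing candidates by asymmetry descending,
ties broken by smaller start, accept a candidate iff its 23-nt footprint is
disjoint from every accepted one, stop at n ∈ {1,2,3}. Greedy is linear-time
and deterministic; the test suite checks it against exhaustive subset search
whenever the global top-n are conflict-free. Position mode bypasses ranking
and names one candidate by its start; it designs a monovalent template (one
position names one siRNA).

## Template architecture

One repeat unit of transcript is `sense(21) + loop(9) + antisense(21) +
spacer(10)` = 61 nt, so valence 1/2/3 templates are 61/122/183 nt. The 61-nt
split is this package's choice; only the trivalent total (183) is fixed by
the published construct geometry, and loop/spacer lengths are configurable
with the caveat that changing them changes the totals. Arm order is
configurable (`sense-first` default, guide as the 3' arm; `guide-first`
swaps the arms within each hairpin).

Defaults: loop `UUCAAGAGA`, a widely used 9-nt shRNA loop; spacer `U×10`.
The poly-U spacer is maximally A/U-rich and provably passes the
complementarity screen for any filter-passing candidate: extending a stem
would require a ≥6-nt A run in an arm, which the homopolymer filter already
excludes. The screen itself rejects any loop or spacer with a ≥6-nt window
whose reverse complement occurs in either arm, since such a segment would
extend the stem and distort the hairpin.

The circular template is the DNA reverse complement of the concatenated unit
RNAs, in circle coordinates whose origin is the base encoding the first base
of unit 1's first arm; with that origin no feature annotation wraps. The
linear (synthesis) form opens the circle at the midpoint of unit 1's first
stem side — position 11 under defaults — leaving ≥5 bp of annealed duplex on
each side of the nick so T4 DNA ligase sees a nicked double helix and no
splint oligo is needed. Whether to nick a stem or a loop is a genuinely open
choice; the stem midpoint was chosen precisely for the unsplinted ligation,
and the position is recomputed from the architecture rather than hard-coded.

Rolling-circle transcription is simulated purely geometrically: the
polymerase walks the circle 3'→5' emitting complements, with no promoter,
initiation-bias or termination model. Phase 0 starts at the first base of
unit 1, so one lap reproduces the concatenated unit RNAs exactly, k laps
repeat them k times, and any phase is a rotation — these identities are the
round-trip oracle in the tests.

## Structure verification

`designed_fold` asserts the intended dumbbell directly from the feature
annotations — 19 Watson-Crick pairs per unit, everything else unpaired — and
reports `DEVIANT` with the offending positions if any asserted pair is not
complementary on the actual sequence. `max_pairing_fold` is an independent
Nussinov base-pair maximization (minimum loop 3, the steric minimum;
Watson-Crick only for DNA — G·T wobble excluded as a conservative choice —
Watson-Crick plus G·U for RNA) with a deterministic traceback (pairing
preferred over leaving a base unpaired; smaller partner index on ties), so
dot-brackets are reproducible. A constrained re-fold, in which designed-pair
positions may only take their designated partner, confirms that all designed
pairs coexist in one maximal structure. Energy-based folding (partition
functions, suboptimal ensembles) is deliberately out of scope: pair
maximization suffices to confirm the dumbbell topology.

Dot-brackets are reported in the nick-opened linear coordinates, where the
designed pairs are provably non-crossing (the nick splits unit 1's stem into
two nested hairpin halves).

## Synthetic fixtures

`make_fixture_transcript(length, gc_fraction, seed)` draws a uniform random
RNA with an exact (up to rounding) GC count, deterministically from the
seed. It emulates only sequence length and base composition of a real mRNA —
no codon structure, UTRs, splice isoforms, expression context or off-target
landscape — so passing tests demonstrate the correctness of the design
*geometry and scoring arithmetic*, not silencing efficacy on biological
targets. Tests use 200–300-nt fixtures; real mRNAs are longer, which only
increases the candidate pool.

## Numerical and degenerate-input choices

Ambiguity codes (N, IUPAC degeneracies) are rejected at parse time: design
output must be synthesizable verbatim. Inputs shorter than 23 nt cannot host
a candidate and error out; a target that cannot host the requested number of
disjoint passing footprints raises rather than silently downgrading the
valence (the selection primitive itself returns fewer with a warning, for
exploratory use). Multi-record FASTA input is processed record by record,
each independently. Selection and traceback tie-breaks are fixed as above so
two runs with identical config, input and table are byte-identical; the only
randomness in the package is the fixture generator's seeded RNG.

## Problem sizes in tests and the acceptance script

The acceptance script designs against 200–300-nt synthetic transcripts,
checks candidate geometry across 100 random fixtures (~5,000 candidates),
round-trips 50 random designs, compares greedy selection with exhaustive
subset search on 200 synthetic candidate sets (≤10 candidates each), and
compares the fold maximizer with brute-force structure enumeration on 200
random sequences of length ≤12 — sizes at which the exhaustive oracles are
exact yet the full pipeline still runs in under a second.

## Known limitations

No off-target screening (BLAST/seed-match), no SNP awareness, no
Reynolds/Ui-Tei composite scores, no target-accessibility folding, no
ligation thermodynamics or transcription-yield model, and no prediction of
Dicer processing of the multimer. The asymmetry window statistic is one
defensible reading of "rank by Gibbs free energy"; the table and window are
exposed as configuration for that reason.
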