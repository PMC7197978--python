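# mshrna

Design tools for RNA interference reagents: rank 21-nt siRNA duplexes along a
target mRNA by thermodynamic end asymmetry, pick non-overlapping winners, and
assemble the circularizable single-stranded DNA template whose rolling-circle
transcription produces a mono-, bi- or trivalent **multimeric shRNA**
(mshRNA) — one long transcript carrying one, two or three tandem hairpins,
each processed in vivo into a functional siRNA. The intended users are
molecular biologists preparing RNAi knockdown experiments who want an
inexpensive route to large amounts of silencing RNA: order one linear
oligonucleotide, circularize it with T4 DNA ligase, and transcribe it in
vitro around the circle.

## The design model

**Candidates.** A candidate is a 23-nt footprint `t = target[start, start+23)`
realized as the standard duplex geometry

```
sense  5'-t[2:23]            -3'
guide  5'-revcomp(t[0:21])   -3'
```

— two 21-nt strands sharing a 19-bp core with 2-nt 3' overhangs on both
sides. The guide (antisense) strand directs cleavage of the target.

**Ranking.** RISC loads preferentially the strand whose 5' end lies at the
*less stable* duplex end. Each end's stability is the nearest-neighbor sum

ΔG_end = Σ ΔG°37(stack) over the terminal *w* base pairs (*w* − 1 stacks,
default *w* = 5),

using the Xia 1998 RNA/RNA Watson-Crick parameters (shipped as a TSV,
replaceable via `--nn-table`). The score

asymmetry = ΔG_guide-5' − ΔG_sense-5'

is larger when the guide end is weaker; candidates are ranked by it after
composition filters (core GC in [0.30, 0.65], no homopolymer run ≥ 5, no
G-run ≥ 4). Winners are chosen greedily, best first, accepting a candidate
only if its 23-nt footprint is disjoint from all previous ones. Alternatively
a candidate can be selected directly by target position.

**Templates.** Each winner becomes one repeat unit
`sense(21) + loop(9) + antisense(21) + spacer(10)` = 61 nt of transcript; the
DNA circle is the reverse complement of the concatenated units, so one
transcription lap reproduces them exactly, and valence 1/2/3 gives a
61/122/183-nt template. The linear synthesis form opens the circle at the
midpoint of the first stem-encoding region, so the self-annealed molecule
presents a nicked duplex that ligase can seal without a splint. A
Nussinov-style base-pair maximization independently verifies the intended
dumbbell fold (19 pairs per unit).

## Worked example

```
mshrna make-fixture --length 300 --gc 0.5 --seed 7 --out target.fasta
mshrna design --input target.fasta --out-dir out/
```

writes five files: `candidates.tsv`, a template FASTA, a feature TSV, a
structure report and `run.log`. The candidate table scores all 278
footprints, e.g.:

```
target_id              start  sense                  guide                  dg_sense_end  dg_guide_end  asymmetry  flags  selected
fixture_L300_gc0.5_s7  0      CCCAUGCCGACAGCUACUCAU  GAGUAGCUGUCGGCAUGGGGC  -9.73         -8.00         1.73       g_run  no
fixture_L300_gc0.5_s7  2      CAUGCCGACAGCUACUCAUUC  AUGAGUAGCUGUCGGCAUGGG  -8.74         -7.64         1.10       -      no
```

The three selected winners start at positions 219, 150 and 4 with asymmetry
8.01, 5.44 and 4.66 kcal/mol — positive values mean the guide 5' end is the
weaker duplex end by that margin over the 5-bp window. The structure report
confirms the trivalent 183-mer folds as designed:

```
pair_count: 57
verdict: AS_DESIGNED
```

Simulate the transcription product and re-verify a synthesized template with:

```
mshrna simulate-rct --template out/<id>.template.fasta --laps 3 --out product.fasta
mshrna verify-structure --template out/<id>.template.fasta --out report.txt
```

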