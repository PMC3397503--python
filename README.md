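# biasscan

Sequence-based selection of phage-display antibody clones.

After an *in vivo* biopanning experiment with a semi-synthetic scFv library
(a fixed human framework with degenerate-oligonucleotide CDR3 loops, organised
as sub-libraries by chain and loop length), a few hundred colonies are picked
and sequenced instead of running a large binding screen.  `biasscan`
implements the downstream analysis that turns those sequences into a ranked
clone selection:

1. **QC** — reject colonies with missing framework anchors, internal stop
   codons, or off-design loop lengths (the colony-PCR screen, in software).
2. **Positional frequencies** — align CDR3s by loop length and tabulate the
   frequency `f_obs(p, a)` of each of the 20 amino acids *a* at each position
   *p*, numbered after the invariant `VR` prefix.
3. **Enrichment** — compare with the frequency `f_lib(p, a)` expected from the
   degenerate-codon design.  A cell is *hot* when
   `f_obs / f_lib >= 3` with at least 2 supporting observations; the hot sets
   form a per-length consensus such as `V R X X D/I R X Y X V E D`.
4. **Scoring & selection** — each clone scores the number of positions where
   it carries a hot residue; clones with `>= 3` matches (the average number of
   antigen contacts in a CDR3 loop) are selected on the *bias* criterion.
5. **Redundancy families** — clones whose CDR3 domains differ by `<= 2`
   mutations (length-stratified Hamming distance; loops of different lengths
   are incomparable) are grouped into families; any clone recovered at least
   twice is selected on the *redundancy* criterion, regardless of score.

A synthetic-data module simulates the whole experiment — library sampling,
binder spike-ins with known key residues, two rounds of three-fraction
biopanning, colony picks with QC artifacts — so the pipeline runs and is
tested end-to-end with no external data and full ground truth.

## Worked example

The packaged fixture reproduces the published worked example: the printed
per-length consensus and the thirteen clones selected from VH CDR3 lengths
10, 13 and 14.

```
$ biasscan fixtures table1
VH length 10: V R X X D/I R X Y X V E D
VH length 13: V R V A/C/N/Q M/N W E/L E X N E/W E E X X
VH length 14: V R E/S D/E/M W I/R/W P M/W G X E X X Y X N
L1.32F1     matches=5  reasons=bias             selected=1
B2.32.F1    matches=4  reasons=bias             selected=1
C7.31CF2    matches=4  reasons=bias             selected=1
G4.31.F1    matches=4  reasons=bias             selected=1
G8.31.F1    matches=4  reasons=bias             selected=1
D6.31.F2    matches=3  reasons=bias             selected=1
D6.32.F2    matches=3  reasons=bias             selected=1
E1.31.F2    matches=3  reasons=bias             selected=1
E6.32F2     matches=3  reasons=bias             selected=1
H4.32.F1    matches=3  reasons=bias             selected=1
H8.32.F1    matches=3  reasons=bias,redundancy  selected=1
I7.31.F1    matches=3  reasons=bias             selected=1
F8.32.F2    matches=2  reasons=redundancy       selected=1
selected: 13 of 13
```

Reading the output: `matches` is the number of loop positions carrying a hot
residue (e.g. clone `L1.32F1` matches the length-13 consensus at five
positions).  Twelve clones clear the 3-match bias cutoff; `F8.32.F2` scores
only 2 but was recovered twice as an independent colony, so it is selected on
redundancy alone — exactly the published selection set.

A full synthetic run:

```
$ biasscan simulate --out demo --seed 1
$ biasscan run --clones demo/clones_all.tsv --library demo/library.yaml \
      --out demo_report --rounds 2
```

`demo_report/consensus.tsv` then contains the consensus recovered from the
simulated round-2 picks (574 QC-passing clones at this seed):

```
chain  length_class  n_sequences  insufficient  consensus
VH     13            574          0             V R G Y X X W K D V A H X P E
VL     9             574          0             W E W I X T X P A
```

The hot VH cells are the residues of the spiked fold-50 binder family and of
the fold-5 binder class (see `demo/truth.json` for the ground truth); the VL
consensus is the founder light chain of the dominant family, i.e. whole-scFv
enrichment.

## Layout

- `src/biasscan/library_model.py` — degenerate-codon arithmetic, theoretical
  frequency tables, library YAML config.
- `src/biasscan/repertoire_io.py` — FASTA/TSV clone reading, anchor-based
  CDR3 extraction, QC filter, frequency-table round-trip.
- `src/biasscan/enrichment.py` — observed frequencies, fold-change ratios,
  hot-position calling, clone scoring and selection, titer normalization.
- `src/biasscan/families.py` — Hamming-distance redundancy clustering.
- `src/biasscan/synthetic.py` — library/biopanning simulator with ground truth.
- `src/biasscan/fixtures.py` — the transcribed published consensus/clone table.
- `src/biasscan/pipeline.py`, `src/biasscan/cli.py` — orchestration, reports,
  `biasscan` CLI.

See `docs/methods.md` for the model, parameter defaults, and limitations.
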