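# Methods

## The selection problem

A semi-synthetic scFv phage-display library diversifies only the two CDR3
loops of a fixed human framework.  Diversity is organised as sub-libraries,
one per (chain, loop length): VH loops of 5–17 randomized positions after an
invariant `V R` prefix, and five VL sub-libraries (two kappa, lengths 9–10;
three lambda, lengths 9–11), mixed in proportions reflecting natural CDR3
length usage.  After two rounds of biopanning, a few hundred colonies per
recovery fraction (F1 surface-bound, F2 intra-tissular, F3 internalized) are
picked and sequenced.  Because binding assays at that scale are expensive,
clones are ranked purely from sequence, on two signals:

- **Redundancy** — the same (or nearly the same) CDR3 recovered from
  independent colonies.  Against a ~1.5×10⁹-variant library this is
  vanishingly unlikely without selection.
- **Amino-acid bias** — positions where a residue's post-selection frequency
  exceeds its design frequency by at least a fold threshold.

## Expected frequencies from the degenerate-codon design

Each randomized position is synthesized as a degenerate codon (IUPAC
ambiguity codes).  Its amino-acid spectrum is computed exactly: enumerate the
Cartesian product of the per-symbol nucleotide sets, translate each concrete
codon with the standard genetic code, and tally as rational numbers.  Stop
codons are removed and the spectrum renormalized by default
(`stop_policy="renormalize"`), because the physical sub-libraries were
pre-screened for in-frame expression and cannot display stop-containing
clones; `keep_as_missing` instead reports the stop mass separately.  A codon
expanding only to stops is an error under renormalization.

The oligonucleotide design of the original library was never published, so
the default `LibrarySpec` uses NNK at every position as an explicit stand-in
(under NNK, 31 coding codons: e.g. Leu/Ser/Arg at 3/31, Trp at 1/31).  Real
designs, or explicit per-position frequency tables, can be supplied through
the YAML config and flow through the identical code path.  VL kappa and
lambda sub-libraries of equal loop length are pooled by mixing weight into a
single "VL" theoretical table, because sequenced clone records do not carry
the kappa/lambda label.

## Enrichment, hot positions, consensus

For one chain and loop length with *n* QC-passing sequences, the observed
frequency is `f_obs(p, a) = count(p, a) / n` and the fold-change is
`r(p, a) = f_obs / f_lib`.  A cell is called **hot** when

- `r(p, a) >= fold_threshold` (default 3, inclusive — "at least a factor 3"),
- `count(p, a) >= min_count` (default 2: a residue seen once can trivially
  exceed 3-fold at these depths), and
- `n >= min_class_n` (default 10; smaller classes are returned empty and
  marked "insufficient sequences" rather than analyzed).

Cells with `f_lib = 0` but observations (non-library residues: sequencing
errors or true mutations) get an infinite sentinel ratio, are excluded from
hot sets, and are reported separately.  No multiple-testing correction is
applied — the method is a plain fold-change rule; an uncorrected per-cell
binomial tail probability against `f_lib` is emitted for information only.
Consensus lines render the prefix, then per position either `X` (no hot
residue) or the hot set joined with `/` in alphabetical order.

A clone's **bias score** is the number of positions where it carries a hot
residue (multi-residue sets match any member).  A clone is **selected** when
its score reaches `min_matches` (default 3, the average number of CDR3
antigen contacts, taken here as a parameter) or when it is redundancy-flagged.

## Redundancy families

Distances are length-stratified Hamming distances: loops of different
lengths are incomparable (the pipeline aligns by length and the library
fixes lengths per sub-library; no gapped alignment).  Two clones are linked
when each domain required by the criterion (`vh_only`, `vl_only`,
`whole_scfv`) is within `max_mutations` (default 2 — the strict reading of
"fewer than 3 mutations per domain"; configurable to 3).  Families are the
connected components of the link graph (single linkage, default — recurrence
is transitive through shared domains) or greedily peeled maximal cliques
(complete linkage, for stricter families).  Representatives and family ids
are assigned by lexicographic clone id, so clustering is order-invariant and
deterministic.

## The synthetic generator

`generate_native_pool` samples background clones position-independently from
the theoretical tables, with length classes multinomial in the mixing
weights.  `simulate_biopanning` models selection as a multiplicative
per-round fitness — the simplest mechanism producing factor-5/factor-50
style round-over-round enrichment: in round *r* a clone carries
`base_copies × enrichment_factor**r` particles in its spike's target
fraction and `base_copies` elsewhere, and each (round, fraction) draws
`n_picks` colonies by multivariate hypergeometric sampling over particle
counts.  Physical particles are drawn without replacement, but a clone with
many particles is picked repeatedly — which is exactly the redundancy signal
the analysis looks for.  A `qc_fail_rate` share of colonies (default 0.05; a
free parameter, the experiment reported no rate) is corrupted with mid-loop
deletions or stop substitutions for the QC filter to catch.  All randomness
descends from one integer seed; datasets re-emit byte-identically.

The packaged demo scenario uses one VH length-13 and one VL length-9 NNK
sub-library, a background pool of 10⁴ clones at 10 particles each, two
rounds, and 200 picks per fraction per round.  Two spike configurations
mirror the two published enrichment regimes:

- a family of 5 near-identical clones (≤1 mutation from the founder) at
  per-round fold 50 targeting F3 — after two rounds it holds ≈55 % of the F3
  population, so all members appear among the 200 F3 picks and are flagged
  by redundancy clustering;
- 40 independent binder clones sharing three key residues (W at position 2,
  M at 5, H at 9 — each 1/31 under NNK) at per-round fold 5 targeting F1.
  Their combined final F1 share is ≈9 %, lifting the key cells to ≈3.7× their
  design frequency — just over the fold-3 line, the regime the rule is meant
  to detect — while non-key positions, drawn from the library spectrum, stay
  at ratio ≈1.  Key-residue recovery is therefore evaluated on the spike's
  target fraction (n ≈ 190 after QC); the pooled analysis, which dilutes a
  one-fraction signal threefold, is dominated by the fold-50 family instead.

Ground truth (`SimulationTruth`) records the spiked member sequences, every
colony id carrying one, and the hot cells the spikes imply at the sampled
depth, computed from expected shares (`share + (1−share)·p ≥ 3p`), keyed by
(chain, fraction, length class, position).

### What the simulation does and does not emulate

The pool is a 10⁴-clone stand-in for a ~1.5×10⁹-variant library.  Consequences:
at 600 round-2 picks, background clones are occasionally picked twice by
coincidence (birthday collisions), producing a background of small spurious
"families" that a real-diversity experiment would not show; selected-clone
counts from the demo therefore overstate redundancy among non-spiked clones.
Amplification bias between rounds, fraction cross-talk, sequencing error
beyond the injected artifacts, and any real binding chemistry are not
modelled.  Passing recovery tests shows the *analysis* detects the signals
its model generates at realistic depths — not that the fitness model is
faithful phage biology.

## Numerical and design choices

- Codon spectra are exact `Fraction`s; frequency tables are float64 and
  validated to row sums within 1e-9 (all-zero rows allowed and flagged).
- Frequency-table TSVs print 12 significant digits and round-trip losslessly
  at that precision; corrupt row sums are rejected naming the position.
- The fold rule is inclusive (≥3) and configurable; `fold_threshold ≤ 1` is
  rejected as meaningless.
- Anchor-based CDR3 extraction replaces the interactive annotation service
  used in the original workflow; it is valid because the library has a
  single fixed framework, and it is deterministic and offline.  Ambiguous
  (multiple) anchor matches are treated as missing, never silently resolved.
- Loop-length classes count only randomized positions after the invariant
  `VR` prefix; the prefix is stored, rendered in consensus lines, and never
  scored.
- Ties everywhere (family representatives, orderings, report rows) break by
  lexicographic clone id; reports are byte-reproducible.
- The selection report echoes every threshold; excluded length classes are
  logged, nothing is silently dropped.

## Problem sizes

Default test and acceptance runs use the demo scenario (10⁴-clone pool,
2 rounds × 3 fractions × 200 picks) with 50 replicate seeds per stochastic
arm, and the full 3375-codon IUPAC cube for exact oracle comparisons.  These
sizes keep a complete run in the tens of seconds on one CPU while leaving
the stochastic margins analyzed above (shares ≈9 % vs a 9.7 % threshold)
intact.

## Known limitations

- The NNK stand-in is not the original oligonucleotide design; absolute
  theoretical frequencies differ from the source library's, though the
  machinery is identical once a real design file is supplied.
- VL consensus calling is implemented and tested synthetically but has no
  published fixture to validate against.
- No indel-tolerant clustering: a clone with a real one-residue deletion
  lands in a different length class by construction.
- The binomial p-values are descriptive; the selection rule itself is the
  published fold-change heuristic, not a calibrated test.
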