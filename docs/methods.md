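# Methods

This note documents the models, defaults and numerical choices behind
`pptscreen`, and what the synthetic screen does and does not establish about
real data.

## The screen being modelled

A trans-splicing reporter carries two drug-resistance cassettes whose
correct processing depends on the splicing signals between them; the PPT
position holds an 11-nt random insert flanked by the constant sequences
`GGCGAAATCTAGA` (ending in an XbaI site) and `AGATCTACTTC` (starting with a
BglII site). Cells carrying the library are grown under a normal ("1x") and
an elevated ("5x") puromycin stringency in replicate, and the insert region
of every population is amplicon-sequenced. Inserts supporting processing
survive and enrich; inserts blocking it deplete. Drug concentrations are
deliberately abstracted to condition labels (`sel_1x`, `sel_5x`) and a
dimensionless stringency exponent: only the ordering of the two conditions
matters to the analysis.

## Enrichment statistics

Counts are normalised to reads per million (RPM) per population. With a +1
RPM pseudocount and the median over a condition's replicates,
`depletion = RPM_init / (median + 1)` and
`enrichment = median / (RPM_init + 1)`. The pseudocount guarantees finite
ratios; medians over three replicates make single-replicate jackpots
harmless; even replicate counts use the midpoint mean. All thresholds are
inclusive (`>=`) at full floating precision — no rounding is applied before
comparison. The ≥10-starting-reads gate applies to the depleted set, where
a depletion call from a near-absent insert would be meaningless; for the
enriched sets it is off by default (an insert absent from the starting
sample but abundant after selection is a genuine, strong enrichment signal)
with a config switch to apply it. These are threshold rules, not tests: no
variance model or multiple-testing correction is involved.

## Sequence features

A PPT is a maximal uninterrupted run of C/U — mixed C/U runs count the same
as pure U runs, matching the known equivalence of mixed pyrimidine tracts in
trypanosome splicing. When several maximal runs tie for longest, the
leftmost is reported, which makes the start-position histogram meaningful
for asking whether tracts sit toward the insert's 5' end. The "G, no PPT"
class is `g_count >= 1 AND longest run < 6`. Position frequency matrices
weight each sequence by an optional non-negative weight (the enrichment
factor, for selection-weighted logos); information content is
`2 + Σ_b f_b log2 f_b` bits with `0·log 0 = 0` and **no** small-sample
correction (logo tools differ in whether and how they correct; omitting it
keeps columns comparable across set sizes). Consensus is the per-position
plurality base, ties broken by the fixed order A<C<G<U and flagged. DNA (T)
is canonical internally; RNA (U) is the display alphabet.

## Read processing

Merging emulates fastq-join's defaults: candidate overlaps of ≥ 6 nt are
scored by mismatch fraction with a 0.08 ceiling; the lowest fraction wins
and ties go to the longest overlap. At conflicting overlap positions the
higher-quality base wins (mate 1 on exact quality ties) and the consensus
quality is the maximum of the two. Flank matching is exact by default
(`--flank-mismatches`-style relaxation is deliberately absent from the
default path): a sequencing error inside a 24-nt flank span simply drops the
read, which at error rate *e* loses the closed-form fraction
`1 − (1−e)^24` of merged reads — this prediction is itself verified by the
test suite. Inserts containing N are dropped and tallied. Counting is per
merged read, no deduplication, and both the raw-length and the exact-11-mer
count tables are kept, since either could be the basis of a published
count table.

## The synthetic screen

The generator exists so that every downstream stage can be tested against a
known truth; its defaults are frozen and constitute the package's reference
conditions.

**Library.** 30,000 distinct random 11-mers (a realistic
transformation-bottlenecked library; 4^11 ≈ 4.2M sequences exist), with
log-normal initial abundances of log-scale SD 1.25. This produces the heavy
skew characteristic of plasmid libraries passed through bacterial
transformation: at the default depth, most variants sit below 10 starting
reads while the top variants reach thousands-fold coverage.

**Fitness.** Survival is a logistic in four insert features:
`σ(−5.0 + 0.3·run + 0.3·pyr + 0.2·U − 0.3·G)` with *run* the longest
pyrimidine run, *pyr* the pyrimidine count and *U*/*G* the U and G counts.
The weights are anchored to the reporter's dose response — a 9-nt U tract
supports near-full activity (ratio to (U)11 = 0.92 ≥ 0.9) while a 3-nt
tract is severely impaired (0.071 ≤ 0.1) — and frozen. Any monotone smooth
function with those anchors would serve; the logistic keeps values strictly
inside (0,1).

**Selection.** One discrete Wright–Fisher round per condition (default):
a multinomial bottleneck sample of 10^6 cells, then reweighting of each
insert by `fitness^stringency`, then renormalisation. Stringencies default
to 0.75 (1x) and 1.5 (5x). The 10^6 bottleneck reflects culture-scale
populations — a much smaller bottleneck over a skewed 30k library would
drive most variants extinct by drift alone, which is not how the screen
behaved (populations recovered and kept replicating under drug). With these
frozen defaults the simulated screen lands in the magnitudes the real
screen printed (≈1.5k doubly-depleted and ≈250 doubly-enriched inserts of
30k), enrichment under the stronger stringency rank-recovers true fitness
at Spearman ρ ≈ 0.89 (stronger condition strictly better than the weaker,
≈ 0.85), and the enriched intersection's base composition comes out ≈ 43% U
/ 38% C (computed by `scripts/acceptance.py`). Blasticidin pre-selection is
not modelled separately; it would amount to an optional pre-round with its
own stringency.

**Sequencing.** Reads per population are one multinomial draw of `depth`
(default 10^6) over the population's true frequencies; read 1 covers the
amplicon 5' end and read 2 the reverse-complemented 3' end (75 nt each over
an 85-nt amplicon, so mates overlap by 65 nt). Substitution errors are
uniform per base (default 10^-3; Phred qualities are constant and
consistent with the error rate). One named RNG stream is derived per
(stage, population) from the master seed via CRC32 of the label, so adding
populations never perturbs existing ones and identical seeds give
byte-identical FASTQ. The amplicon context outside the flanks is a fixed
synthetic stand-in for the reporter's plasmid backbone (the real context
adds nothing to the analysis, which only needs the flanks).

**What the simulation does not emulate.** No PCR duplicates or jackpots, no
indels, no quality-score variation along the read, no chimeras, no clone
deletion events, and fitness is by construction a clean function of four
summary features. Passing the round-trip and recovery tests therefore shows
the pipeline is correct and sensitive under these conditions; it does not
show that a real screen's noise floor is reached, nor can it validate the
anomalous G-rich consensus phenomenon, which is outside any
composition-driven fitness model.

## Motif scanning

Coordinates are 0-based half-open everywhere; an acceptor site stores the
0-based coordinate of the G of the AG, and the upstream window is the 50
bases (configurable) ending immediately before the A, reverse-complemented
for minus-strand sites; truncated windows are returned short and flagged.
"Related sequences" means the Hamming neighbourhood of the query (default
radius 1, substitutions only, both strands); minus-strand hits are reported
in plus coordinates with the strand-oriented matched sequence. Genome-scale
scans work on any FASTA but the test suite is self-contained and uses
synthetic contigs only.

## Problem sizes and numerical notes

The test suite runs the full-scale round trip (30,000 variants × 7
populations × 10^6 error-free reads, byte-exact agreement required) and
three-seed selection-recovery checks at full screen size; oracle-equivalence
checks use ≥10,000 random instances per primitive. `scripts/acceptance.py`
uses the full-size screen for the recovery metrics and a 5,000-variant,
10^5-read round trip — large enough that any systematic extraction or
counting defect would surface as a nonzero mismatch count. Frequency
vectors are validated to sum to 1 within 1e-9 after every selection round;
RPM columns to 10^6 within 1e-6 relative. Degenerate inputs are defined,
not rejected: empty inserts count as length-0 sequences, depth 0 yields
valid empty FASTQ, and all-zero replicate medians fall back to the
pseudocount denominators.

## Known limitations

* Enrichment ratios conflate initial abundance with fitness for inserts
  near the detection limit; the pseudocount bounds but does not remove this.
* Exact flank matching discards all reads with flank errors rather than
  rescuing them; at 1% per-base error that is ~21% of merged reads.
* The ordering rule (5x median ≥ 1x median) compares medians across
  conditions without variance weighting, exactly as the screen defined it.
* The supplementary-table importer requires a user-supplied column mapping;
  published spreadsheet layouts vary too much to hard-code.
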