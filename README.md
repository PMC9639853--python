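# pptscreen

Analysis pipeline for **trans-splicing polypyrimidine-tract (PPT) selection
screens** in *Trypanosoma brucei*, with a synthetic-screen generator that
provides ground truth for every stage.

In kinetoplastids every mRNA is matured by spliced-leader *trans* splicing at
an AG acceptor site, guided by an upstream polypyrimidine tract. A reporter
with 11 random nucleotides in the PPT position, selected under two puromycin
stringencies (drug resistance requires correct processing), turns splicing
efficiency into survival: sequencing the insert region of the starting and
selected populations reveals which 11-mers support processing (enriched) and
which prevent it (depleted). `pptscreen` implements the full computational
side of such a screen, for experimentalists running reporter selections and
for anyone who wants a tested, simulated testbed for amplicon enrichment
statistics.

## What it computes

Given paired amplicon FASTQ per population (or a per-insert count table):

1. **Read processing** — fastq-join-style overlap merging (min overlap 6,
   mismatch fraction ≤ 0.08; higher-quality base wins conflicts), exact
   extraction of the insert between the fixed flanks `GGCGAAATCTAGA` and
   `AGATCTACTTC` (both strands searched), and per-population counting with
   an 11-mer length filter.
2. **Enrichment statistics** — reads per million (RPM) per population, then
   with a +1 pseudocount and medians over replicates *r*:

   ```
   depletion  = RPM_initial / (median_r RPM_r + 1)
   enrichment = median_r RPM_r / (RPM_initial + 1)
   ```

   Selected sets: depleted ≥ 5-fold under **both** stringencies with ≥ 10
   starting reads; enriched ≥ 5-fold per condition; the intersection set
   additionally requires the 5x median RPM ≥ the 1x median RPM; and a
   "stronger at 5x" set (5x enrichment ≥ 2 × 1x enrichment).
3. **Sequence features** — longest contiguous C/U run (the PPT), base
   counts, the "G, no 6-nt PPT" class, enrichment-weighted base
   compositions, position frequency matrices with per-position information
   content `IC = 2 + Σ_b f_b log2 f_b` (bits), plurality consensus strings
   and PPT start-position histograms.
4. **Motif scanning** — Hamming-neighbourhood search of a consensus in
   genome FASTA or in the 50 nt upstream of splice-acceptor coordinates
   (BED), with PPT co-occurrence reporting.
5. **Simulation** — a Wright–Fisher selection simulator over a skewed random
   11-mer library with a logistic sequence-fitness function, producing
   paired FASTQ with configurable depth and error rate plus a truth table.

## Worked example

Simulate a small screen and analyse it end to end:

```bash
pptscreen simulate --outdir sim --seed 4 --n-variants 150 --depth 8000 --error-rate 0
pptscreen run --samples sim/samples.tsv --outdir out
```

The `run` command prints the headline counts of the report bundle, e.g.

```json
{
  "n_inserts": 150,
  "n_depleted": 7,
  "n_enriched_1x": 4,
  "n_enriched_5x": 9,
  "n_enriched_both": 4,
  "n_stronger_at_5x": 5
}
```

meaning: of 150 distinct 11-mers, 7 dropped ≥ 5-fold under both drug
stringencies (processing-blocking inserts), 4 were ≥ 5-fold enriched under
both conditions with ordered medians (strong PPT-like inserts), and 5 were
at least twice as enriched at the higher stringency. `out/` contains the
count matrices, the per-insert score table (`enrichment_records.tsv`),
selected-set lists, feature table, PFMs with information content,
`summary.json` (including unweighted and enrichment-weighted base
compositions per set and the G-no-PPT consensus) and a checksummed
`manifest.yaml`.

A published per-insert count spreadsheet can be analysed the same way via
`pptscreen import-supp --path table.xlsx --mapping mapping.yaml --out counts.tsv`
followed by `pptscreen run --counts counts.tsv --outdir out`.

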