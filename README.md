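# oxloh

Genome-wide analysis of oxidative-stress-induced mitotic recombination in
hybrid diploid yeast: loss-of-heterozygosity (LOH) calling from two-allele
SNP-array profiles, recombination-event classification, and the rate,
tract-length, and double-strand-break (DSB) statistics of the
sectored-colony assay.

## Who this is for

Researchers mapping mitotic recombination in a hybrid diploid (e.g. a
W303 × YJM789 *Saccharomyces cerevisiae* cross, heterozygous at ~55,000
SNPs, ~15,000 of them assayed on an array). In such a strain every
recombination event leaves a diagnostic LOH or copy-number footprint, and
a red/white colony-sectoring system turns reciprocal crossovers into
countable colonies. `oxloh` implements the full desk side of that assay —
everything between raw hybridization ratios and the numbers in a results
section — plus a synthetic-data layer that simulates the assay end to end,
so every stage is testable without any array scan.

## The model

**Calling.** Each SNP has two allele-specific probes; the normalized
hybridization ratio of sample vs. fully heterozygous control clusters at
≈0.3 / 1.0 / 1.5 for 0 / 1 / 2 copies of that allele. Ratios are
normalized to the array-wide mean, scanned with a 9-SNP moving window to
detect state transitions, and every transition is then re-located at
single-SNP resolution from the unsmoothed calls. Breakpoints are reported
as the open interval between the two flanking informative markers.

**Classification.** For the two sectors of a colony, summing haplotype
copies across sectors types each conversion tract: 3:1 (one chromatid
converted — DSB after replication, G2, or a nick) or 4:0 (both sister
chromatids converted — DSB on the unreplicated, G1 chromosome).
Reciprocal terminal LOH between sectors is a crossover (CO); terminal LOH
in one sector only, copy-neutral, is break-induced replication (BIR);
interstitial tracts are conversions (CON). Unsectored isolates yield
CO_or_BIR for terminal LOH, CON_CO when an interstitial tract of one
haplotype lies adjacent to a terminal event of the other, and
del/dup/trisomy/monosomy/UPD from copy-number and whole-chromosome
states.

**Rates.** A crossover produces a sectored colony in only half of
chromatid segregations, so the crossover rate is 2 × the sectored
frequency, observed unselected crossover counts are doubled (the hidden
half subtracted from the conversion-only tally), genome-wide totals are
scaled by 1/v² for survivor viability v, and fluctuation-assay counts are
converted to rates by the Lea–Coulson method of the median
(r̃/m − ln m = 1.24). DSBs per genome come from a circular-chromosome
reporter under Poisson breakage: λ = −ln(1−f)/L for linearized fraction f
of a circle of length L, background-subtracted.

## Worked example

```python
import oxloh as ox

genome = ox.build_genome("default", seed=1)        # 16 chromosomes, 15,000 SNPs
spec = ox.PlantedEvent("G1_DSB_CO", "chrIV", break_kb=1278.0,
                       tract_d1=13.0, tract_d2=15.0, donor="W")
d_red, d_white = ox.plant_event(genome, spec, seed=2)
segs_red = ox.call_pipeline(ox.render_profile(d_red, 0.1, seed=3), genome)[2]
segs_white = ox.call_pipeline(ox.render_profile(d_white, 0.1, seed=4), genome)[2]
for ev in ox.classify_sector_pair(ox.SectorPair(segs_red, segs_white, genome)):
    print(ev.type, ev.chromosome, ev.phase,
          [(t.tract_class) for t in ev.tracts], ev.co_breakpoint)
```

prints

```
CO chrIV G1 ['3:1', '4:0'] (1277.553, 1278.673)
```

— one crossover on chromosome IV whose conversion tract has a 3:1 region
followed by a 4:0 region. The 4:0 region means both sister chromatids
were repaired, so the initiating DSB preceded replication (phase G1); the
crossover breakpoint lies between the markers at 1277.6 and 1278.7 kb,
bracketing the planted break at 1278 kb within one inter-marker interval.

The `examples/` directory holds one short script per capability
(simulation + calling, sector classification, fluctuation assays, DSB
quantification, enrichment and spectra); each prints the numbers it
computes and what they mean. A thin CLI
(`oxloh simulate|call|classify|stats|dsbquant|all --config cfg.yaml`)
chains the stages over TSV files for shell use.

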