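# Methods

## The assay being modelled

A hybrid diploid yeast carries two diverged parental haplotypes (labelled
W and Y) that are heterozygous at a dense set of SNPs. Mitotic
recombination converts heterozygous regions to homozygosity (LOH), and a
two-colour SNP array reads out, for every assayed SNP, the copy number of
each parental allele as a normalized hybridization ratio. A colony-level
sectoring system (a heterozygous ochre-suppressor marker) makes
reciprocal crossovers visible as half-red/half-white colonies, so that
both daughter cells of the division in which an event occurred can be
arrayed separately. `oxloh` implements the computational side of this
assay and a synthetic-data layer that emulates it.

## Synthetic data

`build_genome` produces a 16-chromosome map with S288C-like lengths
(12,070 kb total) and 15,000 markers placed uniformly at random,
allocated to chromosomes in proportion to length (≈1.24 markers/kb).
Feature tracks (Ty, LTR, tRNA, G4, tandem repeat, high-GC) are seeded
random placements with realistic element sizes and copy numbers — they
are synthetic stand-ins for annotation, adequate for testing the
enrichment machinery but carrying no real genomic positions. The rDNA is
one 920 kb interval on chromosome XII (7.62% of the genome), sized so the
uniform expectation for 105 terminal events is ≈8.

`plant_event` expresses each recombination mechanism as per-marker
(cnW, cnY) copy numbers in the two daughters:

* **G1_DSB_CO** — a DSB before replication breaks both future sisters;
  each is repaired against the homolog with its own tract length, and the
  exchange resolves as a crossover. One daughter is homozygous-donor from
  (break − tract₁) to the telomere; the other carries a donor tract over
  (break − tract₂, break) and the reciprocal haplotype distally. The
  merged tract therefore has a 3:1 flank and a 4:0 core.
* **G2_DSB_CO** — one broken chromatid, a 3:1 tract, reciprocal terminal
  LOH. `segregate_g2_crossover` additionally draws the chromatid
  segregation pattern: the two recombinant chromatids separate (visible,
  sectored) in half of mitoses and co-segregate (invisible) in the rest.
* **BIR** — one daughter copies the donor homolog from break to telomere
  (copy-neutral terminal LOH); the other daughter is untouched.
* **CON_only** — interstitial tract, optionally on both chromatids (4:0).
* **del/dup/trisomy/monosomy/UPD** — copy-number and whole-chromosome
  states in one daughter.

Tract lengths in the random generator (`sample_events`) follow a
log-normal with median 13 kb and log-sd 1.1 (10–90 percentiles ≈3–53 kb);
only the median is constrained by observation, the shape is a documented
stand-in. Tracts are additionally floored at 6 kb and widened until they
span ≥6 markers: a tract spanning fewer SNPs than half a detection window
cannot be observed by this assay at all, and the generator — like the
assay — only produces detectable events. Recovery statistics computed on
these events therefore measure calling and classification accuracy, not
the (separately documented) detectability floor.

Hybridization ratios are drawn per allele from a Gaussian centred on the
dosage centroid, truncated at 0. Centroids are 0.3 / 1.0 / 1.5 for
0 / 1 / 2 copies; ≥3 copies extrapolate with a sub-linear slope of 0.4
per extra copy (two-colour arrays compress at high dosage; the exact
response above 2 copies is a package choice). The noise model is
deliberately simple — no dye bias, no spatial artifacts, no
probe-specific variance — so passing tests show the pipeline's behaviour
under well-behaved noise, not robustness to real array pathology.

## Calling

1. **Normalization** divides every allele value by the array-wide mean
   (mean of the output is exactly 1; scale-invariant).
2. **Detection** runs a 9-marker centred moving average per chromosome
   (truncated windows at the ends) and assigns each smoothed value to the
   nearest centroid, per allele independently (decision boundaries are
   centroid midpoints, 0.65 and 1.25 for the first two). Runs shorter
   than half a window on the smoothed track are transients of the moving
   average as it crosses between centroids, and are absorbed into the
   longer flanking run before boundaries are taken seriously. This is the
   package's reconstruction of how a windowed scan flags transitions; the
   choice of "window mean crosses a centroid midpoint" as the flagging
   rule is ours.
3. **Refinement** re-locates every detected boundary at single-marker
   resolution: unsmoothed ratios within ±window markers of the smoothed
   boundary are scored by L1 distance to the two adjacent states'
   centroids, and the split minimizing total misassignment wins (leftmost
   on ties). Reported breakpoints therefore always come from unsmoothed
   markers, as open intervals between the last marker of the old state
   and the first marker of the new.
4. **Segmentation** run-length-encodes the per-marker states; runs
   shorter than `min_markers` (default 2) are absorbed into the longer
   flank (ties go to the centromere-proximal flank — stable and
   reproducible). Segments tile each chromosome's markers exactly.

At noise_sd 0.1 (default) the per-allele miscall probability at an
unsmoothed marker is ≈1%, and on the smoothed track effectively zero, so
detection produces no false segments and refinement errs by at most about
one marker. Consequences of the design: events spanning fewer than ~5
markers are invisible (cf. the <2 kb tracts real arrays miss because no
SNP falls inside), and recovery degrades monotonically with noise. No
HMM is used: the windowed-scan-plus-refinement procedure is itself the
method being modelled, and substituting a different segmentation model
would change what the downstream statistics mean.

## Classification

Sector pairs are classified per chromosome from per-marker joint states.
Copy-number aberrations are split out first (copy conservation is checked
before tract typing — a non-copy-neutral marker is never typed as a
conversion). Whole-chromosome calls (trisomy/monosomy/UPD) require ≥90%
of a chromosome's markers in the aberrant state *and* a clean-baseline
sister sector; the second condition distinguishes true aneuploidy/UPD
from a crossover breaking near the centromere-proximal end, whose sister
carries the reciprocal pattern. Remaining copy-neutral non-baseline
blocks (merged across baseline gaps shorter than `min_markers`) become:

* **CO** if the block ends in reciprocal homozygosity running to the
  telomere — the contiguous 3:1/4:0 region proximal of the reciprocal
  zone is attached as the conversion tract, and the breakpoint interval
  is the marker pair flanking the tract/reciprocal junction;
* **BIR** if terminal, 3:1 throughout, and one sector is heterozygous;
* **CON** otherwise.

Initiation phase: any 4:0 sub-region ⇒ G1 (both sisters repaired, so the
DSB preceded replication); all-3:1 ⇒ G2-or-nick; no typed tract ⇒ NA.

Unsectored isolates lose segregation information: terminal copy-neutral
LOH is `CO_or_BIR`; an interstitial tract of one haplotype within
`adjacency_kb` (default 25 kb — "adjacent or close" is not quantified
anywhere authoritative, so this is configurable) of a terminal event of
the opposite haplotype merges into one `CON_CO` event, symmetric in
haplotype labels and segment order. Terminal events spanning ≤2 markers
carry a `short_terminal` flag (too close to the telomere to type).

## Rates and statistics

* **Sectored frequencies** use Wilson 95% intervals by default
  (Clopper–Pearson via `ci_method="beta"`); intervals such as
  4.4–5.7 × 10⁻³ for 197/39417 follow directly from the counts.
* **Method of the median** (Lea–Coulson): solve r̃/m − ln m = 1.24 by
  bracketed root-finding in log m (tolerance 10⁻¹⁰); rate = m / N.
  Confidence limits transform the distribution-free binomial
  order-statistic interval of the sample median through the same
  equation. A zero median yields a flagged upper bound (P(0) ≥ ½ ⇒
  m ≤ ln 2). Against counts drawn from the continuous Luria–Delbrück
  model the estimator is median-unbiased to ~1%; against the package's
  own synchronous-division simulator it reads ~15–20% low, because that
  growth model quantizes clone sizes to powers of two. Both facts are
  asserted in the tests at their own tolerances.
* **Crossover corrections**: rate = 2 × sectored frequency; observed
  (CO, CON) counts correct to (2·CO, CON − CO), with a negative corrected
  conversion count flagged rather than clamped. Genome-wide totals divide
  by viability² and optionally double for crossover-unassociated
  conversions. The genome fraction of the assayed interval is an explicit
  argument — the reported per-dose figures imply slightly different
  fractions, so no single value is baked in.
* **Tract lengths** are midpoint-to-midpoint distances between the two
  flanking breakpoint intervals; medians carry percentile-bootstrap 95%
  limits (default 10⁴ resamples, seeded), clamped to bracket the sample
  median.
* **Hotspot tests** are per-interval two-sided binomial tests of the
  observed share against interval weights, Bonferroni-adjusted.
* **Feature enrichment** compares the number of events overlapping a
  track with a null that re-places each tract uniformly on its own
  chromosome, preserving length; one shared set of placements serves all
  tracks. The two-sided empirical p uses the distance from the null mean
  with add-one correction — on the discrete overlap-count distribution,
  doubling the smaller tail is measurably over-conservative (null
  fraction of p < 0.05 ≈ 0.025 rather than 0.05), while the centred form
  calibrates within the tested band. Bonferroni across tracks; empty
  tracks are skipped with a warning, not an error.
* **rDNA expectation**: expected = n_terminal × rDNA genome fraction,
  P(0) = e^(−expected) under Poisson placement.
* **Spectrum comparison**: 6-class chi-square for overall homogeneity;
  per class, a Fisher exact test on the class-vs-rest 2×2 table — chosen
  over a one-sample binomial of one spectrum against the other's share
  because the comparison should be symmetric in the two spectra.

## DSB quantification

The reporter is a circular chromosome (default 320 kb) that enters a
pulsed-field gel only when linearized; a linear chromosome carrying the
same probe is the loading control. With breaks Poisson along the
molecule, the linearized fraction is f = 1 − e^(−λL), so
λ = −ln(1−f)/L and DSBs/genome = λ × 12,070 kb (haploid reporter
strain). The fraction is the lane's linear/control ratio divided by the
same ratio at complete linearization — from a calibration lane if
supplied, otherwise self-calibrated as (linear + well)/control. The
single-hit commitment (any break linearizes; multiple breaks still
produce gel-entering fragments counted as linear signal) is this
package's reconstruction of the classic band-ratio method, which is not
given as formulas anywhere. Background (untreated-lane) breakage is
subtracted on the λ scale, so f = f_background gives exactly zero.
Saturated lanes (f → 1) raise rather than returning an unbounded number.

## Problem sizes and tolerances in the test suite

Round-trip recovery runs 500 planted events across all mechanisms on the
full 15,000-marker genome (exact recovery required at zero noise; ≥95%
with breakpoints within one inter-marker interval at noise_sd 0.1).
Segregation uses 10⁴ draws (ratio 2.0 ± 0.04) with classifier
verification on a 25-draw subsample. Null calibrations use 1,000
replicates (hotspot: 10 intervals × 100 events; enrichment: 199
permutations per replicate), asserting the fraction of null p-values
below 0.05 is 0.05 ± 0.02. Breakage consistency uses 10⁵ molecules at
λL ∈ {0.1, 0.5, 1, 2} within 3 SE (delta method). Fluctuation recovery
uses 60 cultures at m ≈ 100 within ±30%. All stochastic procedures take
explicit seeds and are bitwise-reproducible.

## Known limitations

* Array noise is i.i.d. Gaussian; real two-colour arrays have
  probe-specific and spatially correlated error, so real-data recovery
  rates will be worse than the simulated ones.
* No heteroduplex/mismatch-repair strand-level modelling, and no
  reconstruction of multi-step rearrangement histories.
* The synchronous-division fluctuation model biases Lea–Coulson rate
  recovery downward by ~15–20% (see above).
* Feature tracks in the default genome are randomly placed; enrichment
  results on them validate machinery, not biology.
* The conversion-tract length distribution beyond its median is a
  log-normal stand-in.
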