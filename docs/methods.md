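# Methods

This note documents the models and conventions implemented in pirnakit, the
defaults and why they were chosen, and what the synthetic data can and
cannot demonstrate.

## piRNA target prediction

piRNAs (21U-RNAs) are 21-nt guides; a candidate site is any 21-nt transcript
window, evaluated antiparallel: guide position *i* (1-based, 5′→3′) pairs
with window position 22−*i*. Pairs are classed Watson–Crick (A:U, U:A, G:C,
C:G), G:U wobble, or mismatch. Acceptance under the default stringent rule:

* guide position 1 is wholly exempt — neither a mismatch nor a wobble there
  counts toward any budget (the 5′ U is anchored in the PIWI protein);
* seed, guide positions 2–8: zero mismatches, at most one G:U wobble;
* non-seed, positions 9–21: at most two mismatches plus at most one
  additional G:U wobble. A wobble is never counted as a mismatch.

The seed bounds follow the 2–8 convention of the targeting-rules literature
and are configurable (`TargetingConfig.seed_start/seed_end`). Because the
prose form of the rule does not pin whether the two-mismatch budget is
global or non-seed-only, both readings exist: the default keeps the seed
constraint separate; `global_mm_budget=True` instead applies ≤ 2 mismatches
jointly to all counted positions (2–21) while retaining the wobble caps.

Coordinates are 0-based half-open on the transcript. A site's `center` is
the transcript base pairing guide position 11 — the window midpoint — since
no anchor is dictated by the rule itself; the metaprofile window is anchored
there. Windows containing N are skipped and counted in the log. All
sequence input is normalized to the RNA alphabet (T→U) on read.

`scan_transcriptome` concatenates transcripts with N spacers and applies a
vectorized seed prefilter (windows whose seed already exceeds the mismatch
cap are discarded before full evaluation); this is an optimization only and
its exact equivalence to the naive per-window scanner is itself a tested
property.

## 22G-RNA quantification

22G-RNAs are operationally defined as antisense reads with a 5′ G and
length 21–23 nt (the class name fixes neither bound; a strict-22 mode is
available). Alignment records carry a `count` multiplicity and a leftmost
(BED-like) 0-based `start`; the biological 5′ end of an antisense read is
`start + length − 1`. Multi-mapping reads are taken as given — each record
keeps its own count, with no fractional reassignment.

Per-gene RPM sums filtered counts over a gene's transcripts and scales by
10⁶/library size. Replicates are averaged on the RPM scale before fold
changes. IP enrichment is log2((IP + c)/(input + c)) with pseudocount
c = 1 RPM (configurable); genes with IP RPM ≤ 1 are excluded (the filter is
a strict "greater than"), and the target set is log2fc ≥ 1 (2-fold).
Statistical testing of fold changes (Wald tests, adjusted p-values) is
deliberately out of scope; the fold-change classification alone is
implemented.

## Metaprofiles

Coverage tracks reproduce bigwig semantics natively: every position covered
by a read accumulates the read's RPM; replicate tracks are averaged
elementwise. A 5′-end counting mode exists as an option; coverage is the
default since the quantity profiled is density along the transcript.
The site × offset matrix samples each track at `center + offset` for
offsets −100…+100; cells outside the transcript are masked and excluded
from means. Offsets are reported in transcript orientation, so the
5′/upstream side of a site is negative. Overlapping sites contribute
independent rows. Quartile stratification ranks sites by piRNA abundance
(deterministic tie-break on transcript id and start) and splits them into
four equal-as-possible groups, Q1 least abundant to Q4 most abundant.

## Category enrichment

For n targets, a category of size m, and N protein-coding genes, expected
overlap is n·m/N and the enrichment factor is observed/expected. N defaults
to 20,447 but is a parameter. No significance machinery is attached — the
factor is the deliverable; ontology-wide testing belongs to dedicated
enrichment suites.

## smFISH spatial quantification

Spot detection filters the stack with a negated 3D Laplacian of Gaussian
(sigma given in µm and scaled per axis by the voxel size, handling
anisotropy), finds 26-connected local maxima above a threshold, and
suppresses maxima closer than `min_distance` (µm), keeping the stronger.
The threshold is expressed in filtered-response units; the default "auto"
mode uses 8 robust (MAD-based) standard deviations of the response — in a
~10⁶-voxel stack the expected number of noise exceedances beyond 8σ is well
below one, while diffraction-limited spots at workable SNR respond at tens
of σ. Detected positions are voxel centers; subvoxel refinement is not
implemented.

The germline axis is consumed as a drawn polyline; each spot within
`max_dist` of the axis takes the loop-centered signed arc length of its
nearest vertex (nearest-segment projection available as an option). Points
before the loop in polyline order are distal (negative), after it proximal
(positive); mirroring the polyline negates every position. Binned profiles
share one grid with an edge at the loop; mean ± SD is taken across
germlines.

Cross-channel colocalization builds the full Euclidean distance matrix and
solves the assignment problem (`scipy.optimize.linear_sum_assignment`),
matching min(|A|,|B|) pairs; surplus spots are reported unmatched, and
matched fractions as a function of distance threshold use min(|A|,|B|) as
denominator. Foci density is count/area for a user-outlined region;
segmentation itself (and registration/deconvolution) is assumed done
upstream.

## Probe filtering

Candidates are all 30-mers of the target sequence. The chain is: GC filter
(35–85%, bounds inclusive) defining the pool; then three independent
filters on that pool — homopolymer (runs of 7+ discarded), off-target
(≥ 1 genomic window within 5 mismatches on either strand, windows
overlapping the intended locus exempt since self-hits are not off-targets),
and melting temperature (deviation > 10 °C from the GC-passing pool's
mean). The three later filters commute; the survivor set is the output.
Final probe-set selection/optimization is out of scope.

Tm models the DNA probe : RNA target hybrid with a nearest-neighbor table
(Sugimoto-style RNA/DNA parameters pinned in `probes.NN_DNA_RNA`, duplex
initiation ΔH = 1.9 kcal/mol, ΔS = −3.9 cal/mol/K), the two-state formula
Tm = ΔH·1000/(ΔS + R·ln(C/4)) at oligo concentration C = 5·10⁻⁸ M, a
16.6·log10([Na⁺]) monovalent-salt correction with [Na⁺] = 1.04 M, and a
linear formamide correction of 0.72 °C per % at 25%. These constants are
pinned so the duplicate-formula oracle in the tests is meaningful; they are
the implementation's documented choice, not a claim about any particular
external tool's internals. The brute-force off-target scan is intended for
desk-scale synthetic genomes (≤ 10⁶ nt), not whole-genome probe design.

## Synthetic data: what it emulates

`SimConfig` fixes the study conditions; every generator is deterministic
given the seed and emits machine-readable truth tables.

* **Transcriptome** — uniform-random RNA of 1,000–1,800 nt, 1,000 genes:
  400 spermatogenic (200 designated piRNA targets), 200 oogenic, 400 other.
* **piRNA pool** — one distinct 21U guide per target site (2 sites per
  target gene, 400 guides), abundances lognormal with σ = 1.2 around a
  20-RPM median (a long-tailed pool). Exact reverse complements are
  embedded at the truth sites of target genes and of non-target
  spermatogenic genes; 50 "violating" embeddings (three same-base non-seed
  mismatches, which can never be wobbles) serve as scanner negative
  controls.
* **Libraries** — multinomial draws of 10⁶ reads, 2 replicates, for
  {input, IP} × {wild-type, piwi mutant}. Target genes hold 15% of the
  input library; 80% of that mass sits at the embedded sites, allocated
  across sites proportionally to piRNA abundance (so quartile stratification
  has a real effect to find). Site reads are antisense 22-mers with 5′ ends
  at geometric offsets (p = 0.05, truncated at −100) upstream of the site
  center; everything else is uniform. The IP is modeled as a composition
  shift: target genes get exactly `ip_enrichment_fold` (4) times their
  input RPM and non-target genes absorb the complement — as in a real IP,
  where non-bound species are proportionally depleted. A naive
  rate-rescaling would make the realized fold depend on the targets' library
  share and could not reproduce a clean 4-fold. The piwi mutant divides the
  target-gene share by `mutant_depletion_fold` (default 50, a piwi-null-like
  near-complete loss of piRNA-dependent 22Gs; recovery tests that probe a
  specific fold pass it explicitly).
* **Germlines** — a U-shaped polyline (100-µm arms, 15-µm bend, 2-µm
  steps) with the loop as the leftmost point; the spermatogenic channel
  draws axial positions uniformly from +20…+60 µm (proximal, held off the
  loop), the oogenic channel from −60…−5 µm, with ≤ 3 µm isotropic jitter
  off the axis.
* **Images** — Gaussian spots of amplitude SNR·√background on a
  100-count Poisson background, voxel size 0.3 × 0.13 × 0.13 µm, PSF sigma
  0.35 × 0.15 × 0.15 µm, spots at voxel centers with enforced separation.

Problem sizes throughout (10⁶ reads, 1,000 genes, 10⁵-nt probe genome,
20-spot stacks) are desk-scale choices that keep the full suite and the
acceptance script in the minutes range on one CPU while leaving every
recovery test statistically comfortable.

### What passing tests do not show

The generator makes no attempt to match real *C. elegans* base composition,
splicing, genomic multi-mapping structure, RdRP sequence biases, chromatin
context, real PSFs/optical aberrations, or segmentation noise in drawn
axes. Recovery results therefore validate the implementations against their
own stated models — they are not evidence about effect sizes in real
sequencing or imaging data. In particular the exact-composition IP model
sidesteps normalization ambiguities that real IP/input comparisons do have,
and spot-detection metrics at SNR 10 with well-separated spots are an upper
bound on crowded, aberrated real stacks.

## Numerical conventions and degenerate inputs

* Fold changes use pseudocount 1 RPM; 0-RPM genes are therefore defined
  unless excluded by the IP filter.
* Masked (out-of-transcript) metaprofile cells are excluded from means, not
  zero-filled.
* Quartile ties break deterministically by (abundance, transcript id,
  start); `np.array_split` handles group sizes when n is not divisible
  by 4.
* Transcripts shorter than 21 nt scan to an empty site list (not an
  error); an empty piRNA list or duplicate transcript ids are errors.
* Spot detection on a blank image returns an empty table; 2D input
  requires an explicit `allow_2d` flag.
* Matching with one empty cloud warns and returns an empty result; unequal
  clouds match at min cardinality.
* Probe enumeration of a sub-30-nt target warns and returns no candidates;
  a Tm deviation of exactly 10 °C is kept, as is a GC fraction exactly at a
  bound.
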