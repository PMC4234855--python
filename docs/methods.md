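# Methods

This note records the model underlying `peakscale`, the parameter
defaults and why they are what they are, the numerical choices that make
runs bit-reproducible, what the synthetic generator does and does not
emulate, and the design decisions taken where the procedure left genuine
latitude.

## Signal model and procedure

The unit of evidence is an aligned read reduced to its 5′ position and
strand; at most one read is kept per (position, strand) pair (PCR
duplicates), a cap that is configurable. Reads are extended to the
library fragment length (default 200 bp) in the strand direction, and the
per-nucleotide count of covering fragments is the read-depth (RD)
profile; separate plus/minus-strand profiles feed the strand concordance
test. Coordinates are 0-based half-open everywhere, including BED and
bedGraph output.

**Control normalization.** The control profile is scaled by the slope of
a zero-intercept least-squares fit of 10 kb-binned ChIP totals on control
totals, pooled genome-wide (the closed form ρ = Σwc/Σc²). A single
genome-wide ρ is used; the fit has no intercept, so all-zero control
bins contribute nothing and an identically-zero control is an error.
Because planted/true enrichment inflates the ChIP bins, ρ slightly
exceeds the background ratio; the binomial test tolerates this mild
conservatism.

**Mappability.** The multi-mappability value of a position is the
average multiplicity with which read-length fragments overlapping it map
to the genome. The builder counts exact occurrences of every fragment on
both strands (the occurrence count of a fragment is its count among
forward k-mers plus its count among k-mers of the reverse-complemented
genome), caps at 5 hits, lays the count down as depth over the fragment
footprint, and divides by the number of fragments overlapping each
position — so uniquely mappable sequence gets exactly 1. Exact counting
is deterministic and exact at the genome sizes this package generates
(megabases); profiles for real genomes, built with mismatch-tolerant
aligners, are read from bedGraph instead. Positions with accumulated
value 0 (chromosome tips shorter than a fragment) carry no evidence and
are treated as non-mappable. The mappability cutoff m̄ defaults to 1.2,
the empirical floor over exons and promoters in well-mapped genomes, and
is configurable because it depends on genome and read length; the
mappable test is strict (`0 < m < m̄`).

**Correction filter.** x̃ᵢ = max(xᵢ, median of x over mappable positions
within ±l_c/2). The filter is a masked dilation: output ≥ input
everywhere, windows with no mappable position pass through unchanged.
l_c defaults to 2000 bp (matched to typical non-mappable stretch
lengths); it must be even so the window is symmetric. The input is
floored to integers before filtering so that all downstream medians are
over small integer alphabets. Note a consequence of the windowing: a
non-mappable block wider than l_c cannot be filled at its centre, since
no mappable position remains in the window there.

**Decomposition.** Median filtering at window lengths
⌊l_start·σᵏ⌋ ≤ l_end, σ = 1.5 (σ = 1.1 for fine spectrum scans). Each
scale filters the corrected profile independently (not cascaded). The
median window at position i is [i−w/2, i+w/2] inclusive with integer
halving, truncated at chromosome ends; the median of an even-sized
(truncated) window is the lower middle element. The sliding histogram
implementation (one insert, one delete, and a short median-pointer walk
per shift) is exactly equal to a naive sort-based median and is the
performance backbone — a property test pins the equality.

**Candidate regions and the γ filter.** Local extrema of the smoothed
signal are read off derivative sign changes (derivative = difference of
consecutive values); a plateau yields one extremum at its first
position, and chromosome boundaries act as implicit minima so terminal
enrichments are not lost. Candidates are the stretches between
consecutive minima; they tile the chromosome, and stretches whose
smoothed maximum is zero (flat background) are dropped. The smoothing
statistic of a candidate is max(raw)/max(smoothed) ≥ 1; candidates above
γ = 4 have lost their peak to over-smoothing and are removed. (Stated
with the ratio in this orientation, the filter keeps regions whose
smoothed peak retains at least a quarter of the raw peak; the opposite
orientation of the ratio with the same threshold would remove every
region, since a median-filtered maximum can never exceed the raw
maximum.)

**Poisson trimming.** Background is fit per 1 Mb window as the mean of
the corrected profile (zeros included, trailing windows use their real
length); τ is the smallest integer whose Poisson CDF strictly exceeds
0.95. Candidate ends are moved to the first/last position strictly above
the local τ; candidates that never exceed τ are removed. Trimming is
evaluated against the smoothed profile of the candidate's own scale: the
smoothed signal is the scale-s estimate of local enrichment, so the
threshold crossing marks where enrichment at that length scale ends.
Trimming against the unsmoothed profile was tried and rejected: by
construction ~5% of raw background positions clear τ, so every wide
candidate contains chip-selected noise islands whose post-selection
p-values are wildly anti-conservative — a global-null run called
regions covering 1% of the genome at q ≤ 0.05. With smoothed-profile
trimming the null run calls ~0.15%.

**Significance.** For a region of length L, counts are fragments
overlapping it, the control count scaled by ρ. The one-tailed binomial
test normalizes counts to a common window, n′ = round(n/L·l_pval)
half-up, and evaluates the upper Binomial(n′_chip+n′_ctrl, ½) tail
strictly above n′_chip (an `inclusive` flag switches to P[X ≥ n′]; both
normalized counts zero gives p = 1). In the calling stages the test
window is capped at the region's own length — normalization may scale
counts down (damping saturation for regions longer than l_pval, the
parameter's purpose) but never up, because upscaling a short region
multiplies its evidence without adding information and demonstrably
destroys FDR control under a global null. SSERs are kept at raw
p ≤ 0.05; multiple-testing correction is applied only to the final
merged set, as BH step-up q-values (sorted p·N/rank, monotonized from
the largest rank, clipped at 1) thresholded at q ≤ 0.05.

**End refinement and strand test.** Merged-region ends are refined by
two argmin passes (start against the fixed end, then end against the new
start) of the binomial P-value with the test window equal to the
sub-region's own length, ties broken toward the wider region. The
objective is evaluated in log space: the double-precision tail
underflows to exactly 0 inside strong regions, which would flatten the
objective and silently disable trimming; when `sf` underflows, the tail
is taken from its leading term with a geometric-series remainder bound
(tight in the far tail, which is the only place underflow occurs).
Regions whose plus/minus strand signal totals differ by more than a
factor of 2 — min(S⁺/S⁻, S⁻/S⁺) < 0.5, including single-strand and
empty regions — are discarded as artifacts; genuine fragment coverage
is strand-balanced.

**Summits, troughs, pileup scale.** The summit is the leftmost maximum
of the corrected profile in the region. The trough is the signal minimum
strictly between the region's two tallest interior local maxima,
scanning valley positions in order of increasing signal and reporting
the first whose surrounding 50 bp has mean multi-mappability below m̄ —
a dip explained by mappability is not a nucleosome-free region. Regions
with fewer than two maxima have no trough. The pileup scale of a
position is the number of SSERs (pooled over scales) covering it; its
genome-wide histogram is the scale spectrum, and each reported region
carries the pileup value at its summit as a broadness annotation.

**Parameter advisor.** For an uncharacterized dataset scanned with a
fine schedule: l_spectrum is the window length at the spectrum's global
maximum (unenriched positions excluded); l_end = min(2·mean gap between
adjacent merged SSER regions, l_spectrum); l_begin is the smallest
window holding at least 1% of all SSERs (the "significant fraction"
needed a number; 1% is configurable); l_pval is bounded by both. The
detection rules behind these: a median filter preserves an enrichment of
width w only for windows < 2w, and separates enrichments a gap g apart
only for windows < 2g.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| σ | 1.5 | scale multiplier; 1.1 for spectrum scans |
| γ | 4 | over-smoothing statistic cutoff (inclusive: ~90–98% of SSERs pass on real marks) |
| l_c | 2000 bp | correction median window |
| m̄ | 1.2 | mappability cutoff |
| l_pval | 1750 bp (broad), 1500 (punctate), 200 (TF) | binomial test window |
| fragment length | 200 bp | read extension; not inferable from single-end BED, so configurable |
| q cutoff | 0.05 | BH threshold on the final set |
| background window | 1 Mb | Poisson background fit |
| duplicate cap | 1 per (position, strand) | PCR duplicate filter |

Presets: broad = (l_start 1000, l_end 16000, l_pval 1750); punctate =
(100, 2000, 1500); tf = (100, 200, 200). The broad preset refuses to run
without a mappability profile (broad domains fragment without the
correction); the TF preset runs without one, with a warning, since
single-summit punctate peaks are not segmented by mappability holes.

## Synthetic data: what it emulates, what it does not

The generator draws a random uniform-composition genome, copies exact
repeat blocks to recorded positions, and samples fragments as a per-base
Poisson process on fragment midpoints: background 0.05 fragments/bp,
multiplied inside planted regions by the fold (rectangular) or by a
triangle peaking at the fold (peaked). Each fragment emits one read at
its 5′ or 3′ end with equal probability. Multi-mapping loss is emulated
by re-assigning each read whose 5′ end lies in a repeat copy to the same
offset in a uniformly chosen copy of its family — exactly the artifact
the correction filter exists to repair, including the side effect that
enrichment inside a repeat bleeds into its background copies (such
bleed-through calls are genuine properties of the simulated signal, not
caller errors). Default study conditions: one 5 Mb chromosome, ten
regions planted at 8-fold across 200 bp–20 kb, read length 36, fragment
200, matched control depth, one repeat family rooted inside the 16 kb
region and one in plain background. With a fixed seed the fixture is
bit-reproducible.

Not modelled: sequencing error, GC and chromatin-accessibility bias,
overdispersed (non-Poisson) background, fragment-length variation, and
mismatch-tolerant multi-mapping. Passing tests therefore demonstrate
correct behaviour under Poisson background with exact repeats; real
data's overdispersion makes the Poisson τ more permissive than nominal,
and real mappability is messier than exact k-mer multiplicity.

## Verification strategy and problem sizes

Every nontrivial operation is checked against an independent oracle:
sliding medians against per-position sorted medians, mappability against
string-scanning occurrence counts, the normalization slope against a
dense grid search, BH against the statsmodels reference, end refinement
against exhaustive sub-interval search, pileup against per-position
membership counting. The quantitative contracts are measured by
simulation at these sizes, chosen to make Monte-Carlo error small
relative to the quantities checked: 100,000 draws per background mean
for the Poisson threshold's 5% false-positive bound; 500 replicates of
10,000 uniform p-values for BH FDR control (under independence the BH
expectation sits exactly at the nominal 0.05, so the estimate is
compared against 0.05 plus two standard errors of the replicate mean);
the full pipeline on the default 5 Mb fixture for planted-region
recovery (coverage F ≥ 0.8) and on its null twin for specificity
(called coverage ≤ 0.5% of the genome).

## Known limitations

* Exact multi-mappability ignores mismatches, so it understates the
  multiplicity of near-identical repeats; real-genome profiles should be
  built externally and loaded.
* The Poisson background is fit per fixed 1 Mb window including enriched
  signal, which inflates τ in dense regions; no local re-estimation is
  done.
* The binomial tail with a zero control count is exactly 0 as defined,
  so P-value-minimizing refinement prefers control-free stretches; with
  default fragment lengths and realistic control depth a zero overlap
  count over a sub-region is vanishingly rare, but very sparse controls
  with short fragments would degrade end refinement.
* A non-mappable block wider than l_c is only partially filled by the
  correction filter (no mappable positions remain in central windows).
* Chromosomes are processed dense in memory (~8 bytes/bp per profile);
  fine for desk-scale genomes, unoptimized for mammalian ones.
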