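# Methods

This note documents the models, statistics and numerical choices behind
`splicescreen`, and what the synthetic-screen generator does and does not
emulate.

## The screen being modelled

A pooled tiling screen maps splicing-regulatory elements (SREs) on a
pre-mRNA region by expressing, one per cell, guide RNAs that direct
catalytically dead RfxCas13d (dCas13d) to every possible position of a
dual-fluorescence splicing reporter. Binding sterically masks the
underlying element: occluding an intronic silencer raises inclusion of the
monitored cassette exon, occluding an enhancer lowers it. Cells carry a
reporter in which tdTomato is translated upon exon inclusion (Dual-IN) or
exclusion (Dual-EX) while eGFP is constitutive, so the tdTomato/eGFP ratio
tracks percent-spliced-in (PSI). BFP marks dCas13d expression. BFP-positive
cells are FACS-fractionated on that ratio; the top 5% and bottom 5% bins
plus the unsorted population are deep-sequenced over the guide cassette,
and guides enriched in either extreme bin point to functional elements.

## Library design

The designer tiles every window of the reporter region with spacers of the
requested lengths (defaults 22 and 25 nt) at a 1-nt step; the spacer is the
reverse complement of the target window. For a region of length `n` and
spacer length `L` this yields `n − L + 1` guides, i.e. 814 22-mers and 811
25-mers on an 835-nt region, plus non-targeting (NT) controls drawn by
uniform ACGT rejection sampling until neither the spacer nor its reverse
complement occurs in any forbidden sequence (the reporter by default; a
genome-scale exclusion list can be supplied by the caller). The retry cap
is 10,000 draws per control; windows containing N are emitted but flagged
so the count law stays exact.

Display names follow the splice-junction convention: `E[a,b]` inside the
cassette exon (1-based from the exon start), `D[a,b]` for the 5ʹ-splice-site
/ downstream-intron window (intron base 1 is the first intronic base,
exonic bases count negatively back from the exon end, no zero), `A[a,b]`
for the upstream-intron / 3ʹ-splice-site window (exon base 1 is the first
exonic base, intronic bases negative), and `abs[a,b]` elsewhere. Internal
coordinates are 0-based half-open; names are parseable back to coordinates
and are used as stable guide identifiers (`{name}_{length}`).

The position attributed to a guide for plotting and SRE localisation is its
5ʹ-most target coordinate, which pairs with the 3ʹ end of the spacer.

## Spacer counting

Reads are assigned by exact match on the sequenced strand. The default
`anchored` mode locates the direct repeat (DR) anywhere in the read and
requires the following bases to equal a library spacer, confirmed by the 3ʹ
backbone anchor; candidate lengths are tried longest-first so a read
carrying a 25-nt spacer is never credited to a nested 22-mer. `substring`
mode (for pre-trimmed data) accepts an exact substring occurrence with the
same longest-match rule and leaves equal-length ambiguities unassigned.
Per bin, assigned + unassigned always equals the read total; RPM is
`n / N × 10^6` over the bin total. For small mixed pools the module also
computes ratio-based enrichments
`log2(RPM_bin/RPM_unsorted)` with an optional pseudocount, and their
top-vs-bottom difference.

## Enrichment statistics

For guide `g` with counts `n` in a sorted bin vs the unsorted reference
(bin totals `N`), the enrichment score is a binomial z-statistic. The
default `per_guide` form compares the guide's own reads between the two
samples:

    r   = n_bin / (n_bin + n_ref)
    r0  = N_bin / (N_bin + N_ref)
    s   = sqrt(r (1 − r) / (n_bin + n_ref))
    e   = (r − r0) / s

An alternative `as_printed` form pools over the library
(`r = n_bin/(N_bin+N_ref)`, `s = sqrt(r(1−r)/(N_bin+N_ref))`); it carries a
large guide-independent offset that the subsequent centering removes, and
is retained behind a flag for audits. Scores with a degenerate proportion
(`r ∈ {0,1}`, zero standard error) are explicit missing values.

Scores are normalised to robust Z-scores, `z = (e − m)/σ`, where `m` is the
median and `σ = MAD/0.6745` the scaled median absolute deviation of `e`
across all guides with a defined score, controls included (recorded in the
run metadata). A zero MAD aborts with a diagnostic rather than silently
regularising, since it indicates a degenerate input, not a tolerance issue.
Because the scale is estimated from the empirical spread of the library,
the Z-scores are self-calibrating: extra-binomial dispersion from the
cell-sampling bottleneck inflates `e` and `σ` alike and cancels.

A guide is quantifiable in a comparison (`w = 1`) when both compared counts
are ≥ 5 and at least one RPM is ≥ 20. Within a replicate the two sorted
bins combine by Stouffer's method, `z_rep = (z_t w_t − z_b w_b)/sqrt(w_t + w_b)`
(missing when both weights are zero); across replicates the final score is

    Z = Σ_bins sign(bin, reporter) · z · w / sqrt(W),   W = Σ w,

with sign(top, IN) = +1, sign(bottom, IN) = −1 and the reverse for the
Dual-EX reporter, so positive Z always means splicing activation. The
canonical design is four replicates (2 IN + 2 EX, up to W = 8), but any
replicate set is accepted. Guides with W ≥ 4 receive two-sided normal
p-values and Benjamini–Hochberg FDR computed over exactly that filtered
set; hits are activators (Z > 0) or inhibitors (Z < 0) at FDR ≤ 0.01
(the threshold compares inclusively).

The per-replicate combination is accumulated as one fused term per
replicate so that two exact symmetries hold bitwise, and are tested:
swapping the top/bottom columns of every replicate negates Z, and
relabelling a replicate's reporter while swapping its bins leaves Z
unchanged.

## Fluorescence PSI quantification

Per event, `M = log2(tdTomato) − log2(eGFP)` and
`A = (log2(tdTomato) + log2(eGFP))/2`. On this scale
`log2(PSI) = M + c` with `c` an unidentifiable reporter constant, so the
package never reports absolute PSI from fluorescence; the deliverable is
`Δ = median M(sample) − median M(control)`, where `c` cancels and which is
directly comparable to RT-PCR fold changes. Medians (with MAD spread) are
used rather than means because event distributions are heavy-tailed.
Events are gated on viability and a BFP threshold; non-positive intensities
are dropped and counted. Summaries from fewer than 2,400 events carry a
warning. Input is a plain CSV export (eGFP, tdTomato, BFP, viable); binary
FCS parsing and compensation are out of scope.

## Spacer-length shift analysis

Each 25-nt guide tiled at a 1-nt step is fully covered by four 22-nt
guides. Because the spacer is antisense, the spacer 5ʹ end pairs the
3ʹ-most target base: shift 0 is the 22-mer sharing the gRNA 5ʹ end (target
footprints share their 3ʹ end), shift 3 shares the gRNA 3ʹ end (same target
start); in target coordinates the 25-mer footprint `[s, s+25)` pairs at
shift `k` with `[s+3−k, s+25−k)`. Per shift, concordance is the squared
Pearson correlation of the final combined Z-scores over pairs where both
are defined (n reported alongside; fewer than 3 pairs gives a missing R²).
Pairs broken by the quantifiability filters are dropped per shift, not
imputed. By default one R² is computed on the cross-reporter combined Z;
per-replicate correlation is available by passing that column instead.

## Synthetic screen generator

The generator defines the study conditions for all simulation-based tests.

**Effect model.** Ground truth is a set of SREs, each an interval with a
signed effect on logit-PSI per unit overlap (silencers negative, enhancers
positive). A guide shifts PSI by
`logit(psi_g) = logit(baseline) − Σ effect · overlap_frac · potency(length)`,
`overlap_frac = |footprint ∩ sre| / |sre|`; the logit scale keeps PSI in
(0,1) and linearity in overlap is a deliberate simplification. The
*effective* footprint is the 22 3ʹ-most target bases of the protospacer
(`footprint_extent = 22`), anchored where the spacer 5ʹ end pairs —
reflecting that the spacer 5ʹ end plus the upstream scaffold positions the
ribonucleoprotein. This anchoring is what makes shift-0 22-mers the best
proxies of a 25-mer's effect; with full-length footprints shifts 0 and 3
would be symmetric by construction. Potency is 1.0 for 25-mers and 0.7 for
22-mers, encoding the longer spacer's stronger modulation.

**Demo conditions.** An 835-nt region laid out as exon6 [0,60), intron6
[60,260), exon7 [260,314) (54 nt, the cassette), intron7 [314,775), exon8
[775,835); baseline PSI 0.4; a proximal intronic silencer at intron-7
positions 10–34 (effect −3) and a distal intronic enhancer at positions
333–357 (effect +3), mirroring the qualitative map of a proximal
ISS-N1-like and distal ISE-D1-like element without claiming measured
magnitudes. The null configuration has no SREs.

**Cells, sorting, sequencing.** Single-integration only (one guide per
cell, the low-MOI regime); 1,000 cells per guide; eGFP lognormal
(log2 mean 13, sd 0.5); tdTomato = 2^c · tracked · eGFP · 2^ε with
tracked = psi (IN) or 1 − psi (EX) and ε ~ N(0, 0.5) on the log2 scale;
40% of cells BFP-positive (lognormal BFP with well-separated positive and
negative modes, gate at 2^8.5); 95% viable. Among gated cells, the top and
bottom 5% strict empirical quantiles of M (ties broken by event index)
form the sorted bins and the whole gated population is the unsorted
sample; each bin yields 10^6 reads drawn multinomially over its guide
composition, optionally emitted as FASTQ with each spacer embedded in the
full cassette (adapter + DR + spacer + backbone). All randomness flows
from one seed through spawned per-replicate generators; runs are
deterministic given the seed.

**What is not modelled.** PCR amplification bias, copy-number variation,
growth/dropout between transduction and sort, multi-integration cells,
spectral spillover, and dCas13d-silencing dynamics beyond the flat
BFP-positive fraction. Passing recovery tests therefore demonstrates that
the statistics recover effects under idealised binomial/multinomial
sampling with realistic depths — not robustness to those real-data
artefacts.

**Recovery evaluation.** Against ground truth, sensitivity is the called
fraction (FDR ≤ 0.01) among on-target guides with ≥ 80% SRE overlap of the
effective footprint, the false-positive rate is the called fraction among
NT controls, and sign accuracy checks that called true positives carry the
expected direction (silencer-blocking positive, enhancer-blocking
negative).

## Problem sizes used by the test suite

Simulation-backed tests run the full 1,937-guide library with four
replicates and 10^6 reads per bin: 20 seeds for null calibration, 20 seeds
for the shift-ordering property, and 3 seeds for demo-truth recovery;
FASTQ round-trips use 2,000 reads per bin. Smaller step-25 libraries are
used where only plumbing is exercised.

## Numerical and design choices

- Missing statistics are explicit NaN sentinels gated by 0/1 flags; a NaN
  never enters a comparison.
- The median/MAD pool includes every guide with a defined score (controls
  included); the choice is recorded in the output metadata.
- `per_guide` is the default enrichment reading; `as_printed` is exposed
  for fidelity audits.
- FDR thresholding is inclusive (≤).
- On-disk tables are TSV with `.` for missing values and 6 significant
  digits; full precision is kept in memory.
- Naming of guides at splice junctions skips position zero on both sides;
  the parser inverts the convention exactly and the round-trip is tested.
- The counting contract for nested spacers (longest match wins) is this
  package's definition; deposited data counted with other tools may
  resolve such reads differently.
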