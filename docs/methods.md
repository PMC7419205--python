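# Methods

This note records the models, numerical choices and known limitations of
the package, in the order data flows through the pipeline.

## Synthetic genome evolution (`simcore`)

**Gene order.** An ancestral genome of `n_genes` genes is laid out
round-robin over `n_chromosomes`. A WGD duplicates every chromosome; each
*new* gene is then lost independently with probability `loss_prob`
(i.i.d., no biased fractionation — the simplest model that yields the
expected depth-ratio signatures; after two WGDs with 20% loss the modal
locus keeps 4 copies with probability 0.8·0.8² ≈ 0.51). Fissions split a
chromosome at a uniform rank, fusions concatenate two random chromosomes;
tandem duplication inserts a rank-adjacent copy with probability
`tandem_prob`. Every gene carries a truth record (ancestral locus, event,
parent), which is also how simulated homology tables are emitted — anchor
detection quality, not homology search, is what the synteny tests probe.

**Sequence divergence.** The generative model inverts the dating formula:
paralogs split T years ago should measure an NG86 Ks centred on 2rT.
Synonymous evolution is simulated as a continuous-time Markov chain on
codons whose moves are single-nucleotide synonymous changes at unit rate.
The rate matrix is symmetric, so the uniform distribution over sense
codons (the ancestral codon distribution) is stationary and the chain is
reversible; the expected pairwise NG86 Ks between two sequences separated
by path time s is then a closed-form monotone function g(s), computed once
by eigendecomposition. Each duplication node of a locus's event tree is
placed at time-depth such that every pair split at age T has total path
time g⁻¹(2rT) — an ultrametric construction that makes **every** pairwise
Ks unbiased, sisters and cross-event pairs alike. (Per-branch distance
targeting cannot achieve this: the JC-corrected NG86 metric is convex, not
additive, along branches — measured bias +1.4% at Ks 0.4 growing to +11%
at Ks 1.0 — which is why this construction was adopted.) Dispersion
`ks_sd` (default 0.12, a modelling choice; no empirical dispersion is
available for block-level Ks around a WGD peak) enters as a per-branch
K-space jitter of sd √2·ks_sd, giving sister pairs a Ks sd of ~`ks_sd`
on top of the intrinsic finite-sequence noise (~0.085 at Ks 0.65 for
300-codon genes). Individual pairs are therefore *not* pinned to a target;
the simulator's contract is distributional: over ≥300 pairs the mean
measured Ks is within sampling error of 2rT (tested). Nonsynonymous
positions are never touched, so Ka ≈ 0 and Ks measurement is not
confounded. Default gene length is 300 codons (~900 bp, near a typical
plant mean CDS), giving ~225 synonymous sites per pair.

A small residual (+~1% at Ks ≈ 0.95) remains in *measured* Ks: the
Jukes–Cantor correction is convex in the mismatch proportion, so the
estimator itself has a Jensen bias at finite sequence length. This is a
property of the NG86/JC estimator, not of the generator, and affects real
analyses equally.

**LTR pairs.** Each element draws an insertion age from a truncated normal
(mode and sd configurable); both copies of one ancestral random LTR evolve
independently under the exact Jukes–Cantor transition matrix at distance
r·T, so the expected pairwise mismatch is 0.75(1 − e^(−8rT/3)) and the
expected K is 2rT. No indels are simulated: λ is an alignment-level
quantity and indel policy belongs to the dating module.

**Reads.** Error-free, uniformly positioned on both strands,
`round(coverage·G/L)` reads of length L. No heterozygosity or repeat
structure — the survey's error-spike handling is exercised with a
constructed histogram instead.

What passing tests on these data do **not** show: robustness to
misannotated gene models, fractionation bias, codon-usage bias,
transposon nesting, sequencing error, or heterozygous k-mer peaks.

## Synteny (`synteny`)

Anchors: per query, the `top_k` (default 5) best hits with score ≥
`min_score`, self-hits removed, symmetric closure applied. Chaining:
within each chromosome pair, dynamic programming over anchor ranks finds
the maximal-score chain (both orientations; consecutive anchors ≤
`max_gap` = 25 ranks apart on both genomes; score = anchors − 0.5 per
gapped junction — deliberately simple enough for an exhaustive oracle to
verify up to 20 anchors). The best chain is extracted, its anchors
removed, and the search repeats until no chain of ≥ `min_anchors` = 5
remains; each anchor belongs to at most one block. Defaults follow common
collinearity-tool practice; all are exposed.

Duplicate classes (precedence order): in a block → `wgd_segmental`;
same chromosome, |Δrank| = 1 → `tandem`; |Δrank| ≤ 10 → `proximal`;
otherwise `dispersed`.

Depth: a gene's depth is the number of distinct blocks (≥ 5 anchors)
whose rank span on its genome covers it; modal depths over covered genes
give the ratio, formatted outgroup-first (`modal_b:modal_a` with genome
*a* the reference/outgroup; smallest-first for self-comparisons). Modal —
not mean — depth is reported, matching the integer ratios the structural
argument relies on.

## Ka/Ks (`kaks`)

NG86 counting with Jukes–Cantor correction, implemented from first
principles and cross-checked in the tests against an independent
implementation. Conventions: substitutions creating a stop codon count as
nonsynonymous in site counting; difference counts average over all
minimal pathways, excluding pathways through stop codons (if every
pathway is blocked, all pathways are averaged with stop steps counted
nonsynonymous). Saturation (ps or pn ≥ 3/4) is flagged rather than
returning infinities. Codon alignment goes through protein space (global
alignment, BLOSUM62, gap open −10 / extend −0.5) and is back-translated,
so gaps occupy whole codons; a trailing stop codon is tolerated and
dropped, an internal stop is an error naming the sequence. The downstream
Ks window keeps 0.01 ≤ Ks ≤ 2.5 (drops allelic near-zero pairs and
saturated pairs; configurable).

This module deliberately implements the counting method rather than a
maximum-likelihood codon model: it is closed-form, exactly testable
against hand-computed fixtures, and consistent with the simulator's
mutation process, so dating is unaffected. Numeric equality with ML
estimators is not claimed.

## Ks distributions and peak fitting (`peaks`)

One value per block — the median Ks of its unsaturated in-window pairs;
blocks with < 3 usable pairs are dropped. Density: Gaussian KDE on a
512-point uniform grid over the Ks window, Silverman bandwidth by default
(absolute bandwidth configurable), renormalised to unit mass over the
window (boundary correction). Peaks: for k = 1..`max_components` (default
4), least-squares fit of a k-Gaussian sum to the density curve —
faithful to fitting the *curve*, not EM on raw values; an EM fit is
provided as a cross-check. Multi-start initialisation places means at the
k largest local maxima plus one evenly spaced start; weights, means and
sds are bounded (σ ≥ 2× bandwidth: a KDE cannot contain structure
narrower than its kernel, so narrower components are sub-resolution
artefacts).

Component-count selection: classical information criteria evaluated on
the 512 grid ordinates over-fit badly, because KDE residuals are smooth
and strongly autocorrelated — extra Gaussians chase sampling wiggles. The
default criterion is therefore a noise floor: pointwise,
Var f̂(x) ≈ f(x)·R(K)/(n·h) with R(K) = 1/(2√π) for a Gaussian kernel;
the smallest k whose residual RMS is within the curve's expected sampling
RMS is selected (ties toward fewer components; AICc/BIC remain available
via `criterion=`). The fit is deterministic given the curve and settings.

Known limitation: with few blocks (tens), Silverman's rule over-smooths
tightly clustered medians and overlapping component tails pull the fitted
means slightly together — on the two-WGD demo this shifts the younger
peak by about −7% (still inside the pipeline's 10% recovery bound). More
blocks, per-pair distributions, or a smaller bandwidth mitigate it.

## Dating (`dating`)

ρ = Ks_out(reference)/Ks_out(species) from ortholog peaks against a
common outgroup; corrected Ks = observed × ρ; ρ is exactly idempotent.
Rate calibration r = Ks/(2·age); WGD age T = Ks_peak/(2r), reported in Ma
(internal arithmetic in years, double precision; an optional bootstrap CI
resamples block medians and re-locates the nearest density mode). Whether
"the peak" means the fitted component mean or an arithmetic mean over
blocks is exposed to the caller; the fitted mean is the default
throughout.

LTR dating: global nucleotide alignment (match 5 / mismatch −4, gap open
−10 / extend −0.5), λ = mismatches over non-gap columns,
K = −0.75·ln(1 − 4λ/3), T = K/(2r) with r defaulting to 1.51×10⁻⁹.
λ ≥ 3/4 is flagged saturated and left undated. The burst profile is the
KDE mode over per-element K (a cohort with identical K values is a point
mass; its mode is returned directly). The burst statistic is the mode of
**K** (the corrected distance), not raw λ: at these divergences the two
differ by under 2%, and dividing the K-mode by 2r reproduces the
associated burst age exactly.

## Genome survey (`survey`)

Canonical k-mers (lexicographic min of k-mer and reverse complement;
k odd, 11–31, default 17; k-mers containing non-ACGT skipped) are counted
in one pass with 2-bit integer encoding. The error cutoff is the first
depth at which counts rise (the trough before the coverage peak; a
histogram that only falls has no peak and is an error). The peak depth is
the count argmax above the cutoff, then refined by a least-squares
parabola over a ±max(2, peak/6) window — single-bin counts are
multinomial-noisy while the underlying coverage curve is smooth, and the
refined vertex tracks the true k-mer coverage λ_k = C·(L−k+1)/L, removing
the integer quantisation that would otherwise dominate the estimate at
moderate coverage. Genome size = occurrences above the cutoff / refined
peak depth. On 30× error-free reads from 100 kb this is accurate to ~1–3%
and invariant to k ∈ {17, 21} within 1%.

## Orchestration (`pipeline`, `io`, `cli`)

Coordinates are 0-based half-open internally; GFF3 converts at the
boundary (1-based inclusive), BED is native. Ranks are assigned by start
position per chromosome on load. Runs are configured by a YAML mapping
(unknown keys rejected; stage dependencies checked before any work);
every TSV/JSON output carries the tool version, a config digest and the
seed, and a rerun with identical config and seed is byte-identical. All
stochastic behaviour flows from the single seed; stages derive
independent RNG streams and never share state implicitly. Exit codes: 0
success, 2 configuration error, 3 data error.

## Problem sizes used in the shipped checks

Depth ratios: 1000 ancestral genes on 5 chromosomes. Mixture dating: 3000
block-median draws. LTR burst: 2000 elements × 1000 bp. Survey: 100 kb at
30×. End-to-end recovery: 1000 genes, 300 codons per gene. These sizes
give comfortable separations between the tested tolerances and the
estimators' sampling noise while keeping any single check within tens of
seconds on one CPU.
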