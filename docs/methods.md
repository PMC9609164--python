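# Methods

This note records the models behind each stage, the defaults and why
they were chosen, the numerical shortcuts, and what the synthetic data
do and do not establish about real trio genomes.

## De novo discovery and zygosity

A candidate de novo variant is a biallelic site where the proband
carries an alt allele present in neither parental genotype and all
three samples have genotype quality GQ ≥ 20. The filter battery removes
candidates with fewer than 5 alt-supporting reads, with alt support on
only one strand, flagged as adjacent to an indel or inside a repeat
mask (both consumed as input flags — alignment-level evidence is out of
scope), and every member of any chain of candidates pairwise within
20 bp on one chromosome (chain grouping by transitive closure; clusters
of calls at that distance are overwhelmingly alignment artefacts). The
per-record rules commute; the cluster rule runs after them and its
result is independent of input order.

Zygosity uses the proband variant-read fraction VR/TR: *post-zygotic*
iff VR/TR < 0.35 or VR/TR > 0.65 **and** both parents show zero alt
reads; otherwise germline. The boundaries are strict, so VAF exactly
0.35 or 0.65 is germline. The 0.35–0.65 band corresponds to the
expected VAF range of a heterozygous germline variant at realistic
depth; mutations from the first post-zygotic divisions are expected at
VAF ≈ 0.10–0.35. Zero proband depth is an error, not a silent skip.

The post-zygotic enrichment test is a pooled two-proportion z-test
without continuity correction (two-sided normal p). On the bundled
cohort counts (36/470 vs 11/361) it reproduces p = 0.004 at three
decimals. The normal approximation is only asserted against the exact
conditional (Fisher) oracle at counts large enough for it to hold;
at very small expected counts (e.g. 5/50 vs 2/50) the two legitimately
disagree.

The paternal-age effect is ordinary least squares of germline count on
paternal age with a t-based 95% CI. On the bundled ten families the
slope is ≈ 2.05 DNMs/year. (Published summaries of comparable cohorts
have reported slightly smaller effects from unspecified models;
OLS on the bundled table is the documented, reproducible choice here.)

Mutation rates: unphased rate = N/(2·H) per bp with H the mappable
haploid genome (2.91×10⁹ non-N GRCh38 bases); per-parent rates
extrapolate N by the phased-fraction ratio before dividing by H.

## Haplotype phasing

Read-backed physical phasing is consumed as input (block tables with a
hapA/hapB allele per child-het site); this package adds the pedigree
layer. An *informative site* is a child-heterozygous site where exactly
one assignment of the two alleles to the parents is
Mendelian-consistent (e.g. father 1/1 × mother 0/0, or father 0/1 ×
mother 1/1 where the ref must be paternal). This restriction to forced
configurations is the package's own definition; ambiguous sites are
silently uninformative and Mendelian-violating sites are excluded and
logged. A block is assigned an origin when it covers ≥ 20 informative
sites and ≥ 90% of their votes agree; exact 50% ties are unassigned.
Raising either threshold can only shrink the assigned set.

Tandem duplications are phased from child-het sites inside them: the
allele on the duplicated haplotype is present in 2 of 3 copies
(expected fraction 2/3). Each site is tested one-sided (exact binomial,
fraction > 0.5, α = 0.05 per site) for either allele; significant sites
vote for the parental origin of the over-represented allele and the
majority wins, with ties or no significant site giving *unassigned*.
This binomial-vote scheme is a documented stand-in for read-based CNV
phasing procedures that are not reproducible from their description.

## Breakpoint-proximity clustering

Each CNV contributes a window [start − f, end + f] (default flank
f = 4 Mb, giving ~9 Mb per ~1 Mb event), clipped to the chromosome;
overlapping windows are merged so no mutation is double-counted.
Under the uniform null, λ = N·W/G with N the genome-wide DNM count,
W the merged window length and G the mappable genome — diploid
(2 × 2.91 Gb) for unphased counts, haploid with per-parent extrapolated
counts for the phased variant. The p-value is the inclusive upper tail
P(Poisson(λ) ≥ observed). Observed = 0 gives p = 1; λ = 0 with a
positive observation is flagged degenerate with p = 0 rather than
raising. Distances to breakpoints are point-to-endpoint on the same
chromosome, +∞ across chromosomes.

The test is discrete: its achievable size at α = 0.05 is P(X ≥ c) for
the smallest c with tail < α, slightly below α. The calibration check
therefore compares the empirical rejection rate to this discrete
nominal size (within three binomial standard errors over 1000 uniform
replicates at N = 300, where the size is ≈ 0.049), not to 0.05 itself.

## Mutational signatures

Spectra use the 96 pyrimidine-strand trinucleotide channels in the
lexicographic label order of the standard catalog files; purine-
reference substitutions are reverse-complemented. Refitting solves
min‖m − Sx‖₂, x ≥ 0 by NNLS. Strict refitting guards against
overfitting in two flag-selectable modes, because the two published
descriptions of "best subset" differ: (a) *strict* — iteratively drop
the lowest-exposure signature and refit while the reconstruction cosine
falls by less than `max_delta` per removal (default 0.004, the
delegated R package's default; the last signature is never dropped);
(b) *best_subset* — exhaustively score the best subset of each size and
stop growing when one more signature improves the cosine by less than
`max_delta` (combinatorial budget 20 000 subsets, beyond which it falls
back to backward elimination). A CNV ± 1 Mb exclusion filter supports
reassessment without junction-context bias. Published catalogs are
*inputs* in the standard TSV layout; the bundled
`synthetic_catalog` (Dirichlet-random probability columns) exists only
for demonstrations and tests and is labelled synthetic.

## Read-depth copy number

Per-bin (1000 bp) mean depth is divided by the chromosome median and
log2-transformed; zero-depth bins are floored at −5 and flagged so loss
calls stay finite. Segmentation is recursive circular binary
segmentation: the best arc by the circular t-like statistic
|mean(arc) − mean(rest)| / (s·√(1/k + 1/(n−k))) (arcs up to n/2 suffice
— an arc and its complement share split points), accepted when a
permutation test rejects homogeneity at α = 0.01 with 1000
permutations, minimum width 3 bins, deterministic under a fixed seed.
Two numerical shortcuts keep this O(n²) search fast without changing
any decision that is not already overwhelming: the arc search is
numba-compiled, and the permutation loop stops early when the
exceedance count alone pushes p past α, after 200 clean permutations,
or when the Bonferroni parametric bound over all arcs is below α/10.
Degenerate inputs (constant or shorter than twice the minimum width)
return one segment.

Segment means are arithmetic means of the bin log2 values, so the
length-weighted segment means reconstruct the profile mean exactly.
Calls are strict: gain iff mean > 0.58, loss iff mean < −1, adjacent
same-call segments merged. Because log2(1.5) ≈ 0.585 leaves only
0.005 of margin for a heterozygous duplication, two effects matter at
that scale: the concavity bias of averaging log2 values
(≈ 1/(2·μ·ln2) per bin) and the median's offset when an event occupies
a visible fraction of a chromosome (the mixture median exceeds the
neutral mean). Both are shared with the copy-neutral baseline, so the
explicit, opt-in `recenter_segments` step — subtract the longest
segment's mean before calling — cancels them; `call_cnv` itself applies
the thresholds verbatim. The pipeline and recovery tests use
recentering; single-segment profiles are never recentred.

BAF is alt/(ref+alt) at het sites; an AOH run is a maximal window
spanning ≥ 2 Mb in which fewer than 5% of sites have BAF in [0.2, 0.8].
A maximal window may absorb a bounded tail of flanking sites beyond a
pure homozygous stretch — that is a property of the fraction-threshold
definition, not an artefact.

## Junction analysis

For a tandem duplication the junction joins the distal breakpoint back
to the proximal one, so the exact microhomology is the longest k with
ref[end−k:end] = ref[start−k:start] (search window 30 bp); it is
symmetric in the two flanks by construction. When an observed junction
read is supplied, its longest prefix ending at the distal breakpoint
and longest suffix starting at the proximal one are stripped and any
remainder is reported as a templated-nowhere insertion (insertion and
homology being mutually exclusive). Microhomeology (reported only when
exact homology < 5 bp) is the longest flank alignment with identity
≥ 0.8 whose outermost base matches — without that anchoring rule, an
alignment extended by one mismatched base would outrank its own
trimmed, higher-identity core.

The six non-B motif detectors are fixed pattern rules, configurable as
module constants: G4 = G₃₊(N₁₋₇G₃₊)₃; Z-DNA = ≥ 10 bp of alternating
purine/pyrimidine with no A·T step; A-phased = ≥ 3 A₄₋₉ tracts with
centres 10 ± 1 bp apart; direct repeat = unit ≥ 10 bp, ≥ 2 copies,
spacer ≤ 10 bp; inverted repeat = arms ≥ 6 bp reverse-complement, loop
≤ 100 bp; mirror repeat = arms ≥ 10 bp, loop ≤ 100 bp. Scans cover
± 50 bp of each breakpoint on both strands (strand-symmetric classes
are scanned once); hits are maximal and non-overlapping per class.
These rules are deliberately simple detectors, not a reimplementation
of any web service's scoring.

## Quantitative phenotyping

IC(t) = −ln(n_t/N) after propagating entity annotations to all
ancestors; the root has IC 0 and IC is non-decreasing toward leaves
(asserted on load via `check_ic_monotone`). Lin similarity is
2·IC(MICA)/(IC(t₁)+IC(t₂)), zero when both ICs vanish. Terms missing
from the corpus are dropped with a record rather than given infinite or
zero IC; a set with nothing left is an error naming the dropped terms.

Set similarity is the *symmetric* best-match average — the asymmetric
variant is equally defensible and the symmetric choice is recorded as a
package decision. A consequence worth knowing: the best k-gene score is
*not* guaranteed non-decreasing in k (the gene→proband direction
averages over more terms, and k-combinations do not nest (k−1)-ones),
so the MPV search records the per-k best scores without asserting
monotonicity. The MPV flag fires when the best k-gene score exceeds the
best (k−1)-gene score by more than 5% *relative* — the reading forced
by the published worked example, where 0.60 → 0.64 (+6.7%) counts as
an improvement above the cutoff while the absolute difference (0.04)
would not. Case clustering is Ward (D2 convention) on 1 − similarity
with deterministic label ordering. Absolute similarity scores depend on
the ontology and annotation release and are not reproducible from
summaries; the package therefore validates the machinery on toy
ontologies with hand-computable ICs.

## The synthetic trio generator

The generator emulates the study design: a diploid trio whose proband
carries K = 8 de novo tandem duplications (size ~N(1 Mb, 40 kb),
junction microhomology uniform 0–5 bp, engineered so junction analysis
recovers it exactly, parent of origin Bernoulli(½)); 84 germline de
novo SNVs (true VAF 0.5, paternal with probability 0.8); 7 post-zygotic
SNVs (VAF uniform 0.10–0.35, parental alt depth zero by construction);
inherited SNPs at density 1/1500 bp with Hardy–Weinberg parental
genotypes and tracked transmission; haplotype blocks (~40 het sites
each) with random hapA/hapB orientation; and read evidence — alt depth
binomial(depth, VAF), strand split binomial(alt, ½), depth
Poisson(35), GQ = min(99, 3·depth). Child allele fractions at het sites
inside a duplication shift to 1/3 or 2/3 (and depth to 1.5×) according
to which haplotype is duplicated. Planted DNMs keep ≥ 21 bp mutual
separation so the cluster filter, correctly, has nothing to remove.
Substitutions are transitions with probability 2/3, giving the planted
Ti:Tv of 2. One seed fans out into per-component substreams, so equal
seeds give byte-identical outputs.

The default genome is a scaled-down stand-in — eight 6 Mb chromosomes —
so a full simulation runs in seconds; duplication sizes stay at the
realistic ~1 Mb and the breakpoint-enrichment distance is scaled to
1 Mb (factor 6, matching the observed ~6-fold regional excess) so the
enriched windows stay a minority of the genome. Clustering
calibrations that need realistic window-to-genome ratios use the
position-only sampler (`sample_dnm_positions`) at real GRCh38
chromosome lengths, which requires no sequence. Binned depth uses a
fragment-count noise model (reads per 1 kb bin Poisson with mean
depth·bin/read-length, read length 150 bp), matching the variance of
real binned coverage rather than per-base Poisson.

What passing the round trip shows: the stage logic — filters,
thresholds, vote rules, statistics — is internally consistent and
recovers planted truth under binomial read noise. What it does not
show: robustness to alignment artefacts, mapping bias, GC waves,
sequencing error, indel realignment or caller idiosyncrasies, none of
which the generator emulates (read-level simulation is a non-goal).

## Problem sizes

The test suite runs a full default simulation once (shared fixture) and
smaller configurations elsewhere; the calibration checks use 1000
uniform replicates at 300 mutations (clustering type I), 200 replicates
for power, 100 seeds for signature recovery, 2000 draws for mosaic
sensitivity, and a 1000-bin profile against the exhaustive
two-changepoint oracle for segmentation. `scripts/acceptance.py` runs
the cohort statistics plus one full pipeline round trip; both complete
in well under a minute on a single CPU.

## Known limitations

Deletion and inversion junction geometries are an extension point (the
junction module handles tandem duplications, the depth module calls
losses but the generator only plants gains by default). The dnCNV
phasing scheme is a stand-in, as noted. The cluster filter removes true
mutations that genuinely fall within 20 bp of each other; the published
filter makes the same trade. Multi-allelic sites are assumed decomposed
upstream. X-chromosome inheritance is not special-cased.
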