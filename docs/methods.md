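# Methods

This document describes the models, parameters, numerical choices and known
limits of each pipeline stage. Coordinates are 0-based half-open everywhere
inside the package; conversion to the 1-based conventions of VCF and GFF3
happens only in `formats`.

## Coding-effect classification and Hn/Hs (`coding_effects`)

A biallelic SNV inside an annotated CDS is classified by substituting the
alternate base into its codon (complemented first for minus-strand genes) and
comparing translations under the standard genetic code: synonymous,
nonsynonymous, nonsense (new stop) or stop-loss. When transcripts overlap, a
site is counted once at its most severe effect.

**Damage filtering.** Post-mortem cytosine deamination produces apparent
C→T (and, read on the other strand, G→A) substitutions. Any SNV whose
unordered allele pair is {C,T} or {A,G} is flagged; damage-excluded
summaries drop all flagged sites. This removes all four transition pairs, so
it is deliberately over-conservative: real transitions are discarded along
with artefacts, which lowers absolute counts but not cross-sample
comparisons, since both samples lose the same classes.

**Site counting.** Callable synonymous/nonsynonymous site totals are
fractional, Nei–Gojobori style: each codon position contributes the fraction
of its three possible changes that are synonymous (changes creating a stop
count as nonsynonymous); the two fractions sum to exactly 3 per codon. The
terminal stop codon is excluded; a CDS with an internal stop is skipped and
logged.

**Heterozygote undercalling.** Low coverage misses heterozygotes. Observed
counts are corrected as `hom + het/(1 − FNR)` with default false-negative
rates of 0.30 for SNVs and 0.005 for deletions (the values estimated in the
study from downsampling the higher-coverage genome). Per-class
heterozygosity is H = het sites / fractional callable sites, with binomial
standard error √(H(1−H)/L).

## Deletion calling (`deletion_caller`)

Per-base depth is modelled piecewise-constant within 20 kb windows: one mean
(null) versus a background mean plus a single tract of different mean whose
boundaries lie on a 100 bp grid, with tract length 1–10 kb. The statistic

    Λ = n · ln(RSS₁ / RSS₂)

(residual sums of squares under the one- and two-mean fits, n = unmasked
positions) is referred to χ² with df = 1. Reference `N` positions are masked
out of both RSS terms; windows more than half masked are skipped. Only
depressed tracts (tract mean < background) are calls; the symmetric fit would
otherwise report amplifications as deletions. Genotype: homozygous iff tract
mean < 10 % of the local background (median of the flanking ±20 kb),
otherwise heterozygous; tracts with ≥ 50 % zero-coverage positions are
flagged as possible runs of unresolvable homozygous sub-deletions.

**Window tiling (design decision).** A single non-overlapping tiling misses
events in two ways: a window holding two deletions can call at most one (and
the best two-mean fit can even select the normal stretch *between* them),
and events straddling a tile boundary fragment. The scan therefore fits two
tilings offset by half a window — every event up to the 10 kb maximum (half
the window) then lies wholly inside some window — and reduces overlapping
tracts from the two phases to the highest-Λ view (non-maximum suppression),
merging only abutting fragments. On the 100-planted-deletion benchmark this
raised recall from 89 % to 100 % with zero false positives.

**Multiple testing (design decision).** The Bonferroni denominator is the
total number of candidate tract placements evaluated genome-wide (~14 000
per window), not the number of windows. Each window reports the *maximum* Λ
over thousands of correlated placements, which is stochastically much larger
than a single χ²(1) draw; dividing α only by the window count would not
control the family-wise error rate. The stricter threshold costs no power
here: planted-deletion Λ values are O(10³) against a threshold of ~35. The
null FWER is verified empirically in the test suite (0/20 one-megabase null
genomes produced any call).

**Cross-sample filters.** Intervals called homozygous-deleted in *every*
sample (matched at ≥ 50 % reciprocal overlap) are removed as insertions in
the reference assembly rather than deletions in the samples.
Coverage sensitivity is estimated by binomially thinning the depth track to
a target mean and measuring recall of the full-depth calls.

## Retrogene detection (`retrogene_detector`)

A retrocopy is an intron-less reverse-transcribed gene copy; genomic reads
from it align contiguously across exon–exon junctions of the parent
transcript. The caller keeps transcript-space alignments that cross a
junction with ≥ 10 *aligned* bases on each side (soft-clips do not count),
drops any read whose best genomic alignment score (`AS` tag, maximum over
hits) is ≥ its transcript score — a tie means the intact locus explains the
read, so ties discard — and calls a gene when surviving reads cover ≥ 2
distinct junctions with ≥ 3 distinct read names. Reads without an `AS` tag
are rejected and counted. Reads with no genomic alignment at all are kept.

## Forward simulation (`demography_sim`)

Independent biallelic sites ("free recombination") in two classes: neutral,
and selected with per-site coefficients drawn once from a gamma DFE —
s = −Gamma(shape 0.23, mean 0.043), the human amino-acid DFE used by the
study — with dominance h = 0.5 and mutation rate μ = 3.8×10⁻⁸ per site per
generation. Per generation: deterministic selection with genotype fitnesses
(1, 1+hs, 1+s), symmetric recurrent mutation, then binomial resampling of
2N gametes. Heterozygosity per site is 2q(1−q). Population size follows a
piecewise-constant trajectory (past → present); burn-in at the first epoch's
size is at least 10 N generations.

**Rescaling.** Q-rescaling (N→N/Q, t→t/Q, μ→μQ, s→sQ) keeps Nμ and Ns
invariant. Validity guards: μQ < 0.1 is enforced, and a fixed |s|·Q ≥ 1 is
rejected. Gamma DFE tails always exceed |sQ| = 1 at Q = 10, so DFE draws
are clamped to s = −1 (lethal when homozygous) — such sites are rare and sit
at mutation–selection balance where H is O(μ) either way.

**Closed forms.** Pure-drift decay: H multiplied by (1 − 1/2N)^t per epoch.
Neutral equilibrium under symmetric biallelic mutation: the diffusion
stationary distribution is Beta(4Nμ, 4Nμ), giving E[2p(1−p)] =
4Nμ/(1 + 8Nμ); the test suite verifies this against the exact discrete
Wright–Fisher Markov chain (power iteration of the full transition matrix).
Mutation–selection balance: H ≈ 2μ/(h|s|), valid for 2Nh|s| ≫ 1.
Replicate summaries report the ratio of class means with a percentile
bootstrap CI over replicates.

Note the drift decay law omits new mutational input; over a crash epoch the
omitted term is ≈ 4N_crash·μ·(1 − decay). The decay acceptance test uses
parameters where this term is an order of magnitude below the Monte-Carlo
error and adds it explicitly to the tolerance.

## Synthetic corpus (`synthetic_data`)

Defaults emulate the study's observation conditions in miniature: a 1 Mb
contig with 40 non-overlapping multi-exon genes on both strands (every CDS
is ATG…stop with no internal stop), 60/60/12 planted
synonymous/nonsynonymous/nonsense SNVs (verified against the classifier at
planting time, never inside deletions), intergenic background SNVs at
5×10⁻⁴/bp, 20 deletions of 1–10 kb of which 25 % are homozygous (the study
observed 23–24 %), 5 retrocopies, and 15X mean depth with negative-binomial
overdispersion (the ancient libraries were 11X and 17X). Depth is zero over
homozygous deletions and binomially halved over heterozygous ones. Reads are
60 bp (short, as for degraded ancient DNA) and receive C→T/G→A damage at
2 % per base — damage affects reads only, never truth genotypes, so the
damage filter is exercised as a genuine confounder. Retrocopy junction reads
get a full-length transcript alignment and a soft-clipped genomic alignment
of their longest exon piece; background genomic reads falling inside one
exon get an equal-scoring transcript alignment, so the tie-discard rule is
exercised too. Alignment scores are aligned bases − 5 per mismatch.

Limits: one contig, uniform base composition, no indel errors or mapping
noise, deletions are exact depth steps, and retrocopy insertion sites emit
junction reads but the insertion is not spliced into the reference sequence.

Everything is seeded via `default_rng([seed, stage])`; the same
configuration yields a byte-identical corpus (sha256 manifest checked in the
tests).

## Census and statistics (`census_report`)

The census table reports per sample: deletions (raw, FNR-corrected,
homozygous, zero-flagged), genes with deleted exons (hom/het split),
retrogenes, premature stops (raw, corrected, damage-excluded). Missing
stages yield NA, never zero. Excess tests are Pearson 2×2 χ² with df = 1 and
*no* Yates continuity correction (matching the study's χ² = 12.717 style
values); a zero expected cell yields a flagged, undefined p. Deletion size
distributions are compared with the two-sided Wilcoxon rank-sum test,
reporting both the Mann–Whitney U and the R-style W = U + n₁(n₁+1)/2 (the
study reports W). Sharing across samples: deletions at ≥ 50 % reciprocal
overlap, premature stops at site and gene level, retrogenes by gene.
Reports are deterministically ordered; same inputs give byte-identical
files.

## Problem sizes used in the tests

- Deletion recall benchmark: 10 Mb, 100 homozygous 1–10 kb deletions, 15X
  (recall 100 %, no false positives; threshold ≥ 95 %).
- Null FWER: 20 × 1 Mb null genomes, α = 0.05 (observed 0 with calls;
  bound ≤ 3 of 20 rejects control at the 1.6 % level).
- Equilibrium Hn/Hs: N = 10⁴, Q = 10, 460 replicates × 100 sites per class,
  100 000-generation sampling window (≈ 40–60 s).
- Exhaustive change-point oracle: 50 random 20 kb windows.
- Exact-vs-diffusion neutral equilibrium: 2N = 200 Markov chain.
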