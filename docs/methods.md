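# Methods

This note records the models, conventions, and design choices behind
`msatpop`, in the order the pipeline runs.

## Data model

A `GenotypeTable` holds one unordered pair of integer allele sizes per
sample per locus; `(0, 0)` codes a missing locus and the code 0 never
appears inside a scored pair. Pair order is non-semantic — pairs are stored
sorted — and population labels (site and/or lineage) are optional; without
them the table is one group. At the STRUCTURE file boundary missing becomes
−9 and allele sizes may be recoded to 1..n per locus (the map is written to
a sidecar JSON so the file round-trips); Genepop uses 3-digit-per-allele
encoding (allele sizes are fragment lengths > 99, so 2-digit encoding would
be lossy) and does not store population names, only the block partition.

## Synthetic genotypes

The generator mirrors a multi-lineage clonal survey. For each of K
lineages, per-locus allele frequencies are drawn from a symmetric Dirichlet
(concentration 1 by default — diffuse, so loci vary in evenness). Each
genet's founding genotype is drawn per locus under Hardy–Weinberg with
optional inbreeding f: with probability f one allele is drawn and
duplicated (identical by descent), giving E[heterozygosity] = 2pq(1 − f) at
a biallelic locus. Ramet counts per genet default to a truncated geometric
on 1..8 (p = 0.5): many singleton genets, a few large clones, the
empirically typical G < N pattern. Ramets copy the genet genotype and then
acquire scoring errors: each locus independently with probability 0.01, one
allele moved ±1 step on the 4-bp fragment-length ladder (a stutter-like,
small displacement that keeps clone mates within a few loci of each other),
with at most 3 perturbed loci per ramet so planted clones stay inside the
≤ 3-locus clonality threshold — tests exceed the cap deliberately when
probing failure modes. Missing data (rate 0.01) zeroes whole loci last.
Allele sizes start at 100 in steps of 4; this is cosmetic realism only.

The true per-ramet error process of coral genotyping is unknown; the
±1-step model is a declared stand-in, chosen so that errors are detectable
as small locus differences rather than novel-allele jumps. The generator
does not model allelic dropout, null alleles, or across-locus error
correlation, so passing tests demonstrate correctness of the estimators
under their stated assumptions, not robustness to those artifacts.

Simulated reads (default 300 bp, i.i.d. background) carry one planted
perfect tandem repeat each; shared loci between the two lineage read sets
reuse one set's flanks with per-base substitution divergence d (a
substitution always changes the base, so flank Hamming distance is exactly
Binomial(len, d)). No quality scores, indels, or paired ends are simulated.

## Clonality

Pairwise distances count differing unordered pairs over loci scored in both
samples. Samples are linked when ≤ `max_diff` (default 3) comparable loci
differ *and* the pair shares at least ⌈2/3 · n_loci⌉ scored loci — the
comparable-fraction guard prevents merging samples that overlap at too few
loci to judge. MLLs are connected components (single linkage): the standard
MLL convention, order-invariant, at the cost of possible chaining, which is
why the full difference matrix is exported for audit. Consensus genotypes
take the modal pair per locus among scored ramets; an exact tie is recorded
as missing rather than guessing. P_GEN multiplies per-locus Hardy–Weinberg
genotype probabilities using plain allele frequencies computed on the
clone-corrected (consensus) rows; an F_IS-corrected variant is deliberately
not the default since the choice is invisible in typical reports. P_SEX is
the exact upper binomial tail via the survival function (numerically stable
for the ~1e-70 values real panels produce).

## Diversity indices

H_E is the plain 1 − Σp² (the GenAlEx "He"); the unbiased 2n/(2n−1) variant
is an option. Group means are unweighted across loci; monomorphic loci stay
in the H_O/H_E means but are excluded from the F_IS mean (F_IS is undefined
at H_E = 0). P_ID per locus is computed as 2(Σp²)² − Σp⁴, algebraically
equal to the genotype enumeration Σ_g P(g)², and multiplied across loci.
Indices are withheld for groups with fewer than `min_mll = 8` lineages —
below that the frequency estimates are too noisy to report. Duplicate loci
(identical genotype columns over commonly scored samples) are removed
before any index, keeping the earlier locus by input order.

## Linkage disequilibrium

The G statistic on the genotype × genotype contingency table, with a
permutation null (default 999 reassignments of the second locus across
samples). Permutation preserves both margins, so only the Σ O ln O term is
recomputed per permutation — this makes thousand-pair calibration runs
cheap. The +1-corrected p-value (1 + #{G* ≥ G}) / (n_perm + 1) is valid by
construction and never zero. Pairs with fewer than 5 jointly scored samples
are skipped with a reason. Testing is done on clone-corrected data by
default; per-pair random streams are spawned from one root seed so results
are independent of iteration order. A Bonferroni-adjusted p is reported
alongside the raw p; no adjustment is forced.

## Admixture-model clustering

Collapsed Gibbs updates exactly as in the classic admixture formulation
with independent allele frequencies: λ fixed at 1 (uniform Dirichlet on
cluster frequencies), one shared α for the symmetric Dirichlet on Q,
updated by a Gaussian-proposal Metropolis step (sd 0.25) under a uniform
prior on (0, 10]; a fixed-α mode exists for tests. Missing alleles are
excluded from all counts. Ln P(D) is the mean of the post-burn-in
log-likelihood trace minus half its population variance. Chains record
every post-burn-in sweep (thinning 1; memory is trivial at these sizes).

Default chain lengths are desk-scale (burn-in 5,000, 20,000 recorded
sweeps via the API; the pipeline demo uses shorter chains still) — chain
length is a setting, not part of the algorithm, and the validation
experiments in this repo use burn-in ≈ 300 and ≈ 700 recorded sweeps on
50–60 samples × 8 loci, which the recovery tests show is ample at the
strong divergence they simulate. Replicate runs are aligned by exhaustive
search over the k! label permutations (k ≤ 8) minimizing the summed |ΔQ|;
for larger k the Hungarian algorithm on the column-decomposable cost gives
the same optimum. ΔK uses the replicate means for the second difference
(the STRUCTURE-HARVESTER convention) and the across-replicate sample
standard deviation; it is undefined at boundary K and where s(K) = 0, and
argmax ties break toward smaller K (parsimony).

## SSR discovery

Only perfect (uninterrupted) repeats are reported: maximal period-m
segments with motif length 4 or 5, copy thresholds 10 and 8. Motifs must be
primitive — an (ACAC)×k run is a dinucleotide repeat and is not reported at
the 4-mer scan — and homopolymers are excluded with them. Non-ACGT
characters terminate runs. When a maximal periodic segment contains a
fractional copy (e.g. background that happens to extend the period), the
reported window drops the leading remainder and anchors at the segment's
right edge; overlapping reports of different motif lengths resolve to the
longer run, ties to the smaller start. Retention keeps 10–15 / 8–12 copies
on reads ≥ 100 bp with ≥ 20 bp flanks on both sides and drops
compound-repeat reads entirely, since multi-repeat amplicons defeat
fragment analysis.

Cross-lineage matching replaces an alignment search: candidate pairs share
a primitive motif up to rotation (forward strand; reads are unoriented, and
joint-strand canonicalization is off by default), flanks are compared
without gaps anchored at the repeat boundaries, and a match requires an
exact 15-mer seed in either flank pair plus ≥ 0.9 identity over ≥ 30
aligned bases on both sides. These thresholds are declared defaults, not
inferred from any reference tool.

## Numerical conventions and degenerate inputs

Probabilities are accumulated in log space where underflow is possible
(P_GEN, the sampler likelihood, with a 1e-300 floor before logs). Empty
sequences yield empty locus lists; a locus scored in nobody is flagged
undefined and excluded from products and means; a single genotype category
at a locus gives G = 0 and p = 1. `assign_mll` refuses `max_diff` ≥ n_loci
(everything would merge). All randomness flows through
`numpy.random.Generator` seeded explicitly; fixed seeds reproduce outputs
byte-identically, and the pipeline manifest records every seed and
parameter.

## Known limitations

Single-linkage MLLs can chain through intermediates; whether the ≤ 3-locus
rule should be transitive is a judgment call, made here for order
invariance and documented via the exported difference matrix. P_SEX uses
round-robin-free plain frequencies; the F_IS-corrected variant exists but
is off by default. The LD test is genotypic (unphased) only. The clustering
model omits correlated allele frequencies, LOCPRIOR, and linkage; the
Evanno statistic cannot select K = 1 by construction. The repeat scanner
does not model imperfect or interrupted repeats, and primer design / read
merging are out of scope.
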