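# Methods

`gbscoal` re-implements, as a tested library, a complete analysis path for
paired-end genotyping-by-sequencing (GBS) data in a species complex: read
merging, de-novo locus assembly with replicate-based quality control, SNP
distance/ordination analyses, distance-based gene trees, and coalescent
summary species-tree estimation. Because such analyses are normally run on
unreleased sequencing data, the package carries its own generator of
synthetic datasets with known truth; every downstream stage is validated
against that truth.

## The synthetic-data generator

The generator emulates the data-generating process of a paired-end GBS
library prepared from a group of closely related species.

**Gene trees.** A rooted, binary species tree with branch lengths in
coalescent units defines the model. Within every species-tree branch, the
`k` lineages present coalesce as a pure-death process with
Exponential(k(k−1)/2) waiting times; remaining lineages coalesce above the
root. Each sample contributes one lineage per chromosome copy — two for
diploids and four for tetraploids, which are treated as autopolyploids.
Species trees are expected to be time-ultrametric in coalescent units; node
ages are reconstructed as the maximum root-ward distance to a descendant
tip. The simulator is validated against the closed-form rooted-triplet
probability: a triplet whose species-tree internal path has length `T`
matches the species topology with probability `1 − (2/3)e^{−T}`.

**Sequences.** Each locus draws a restriction-fragment length and evolves a
uniform-random root sequence along its gene tree under the Kimura
two-parameter (K80) model, parameterised by a transition/transversion ratio
`kappa` (default 2) and a rate scale `mut_rate` (expected substitutions per
site per coalescent unit, default 0.01). No indels are simulated; the
assembly stage is correspondingly ungapped.

**Fragments and reads.** Real libraries with imperfect size selection
produce a large fraction of fragments short enough for the paired reads to
overlap; the generator draws a fragment from the "mergeable" length range
(up to `2·read_len − min_overlap`) with probability `p_short` (default
0.56, the merged-pair fraction observed in real paired-end GBS runs) and
from the longer range otherwise, triangularly within each range. Because
GBS adaptors ligate to either fragment end, each read pair is emitted
flipped end-for-end with probability 0.5. Depth is drawn per allele
(per chromosome copy) from a negative binomial with mean `depth_mean` and
dispersion `depth_dispersion`; real runs report only mean depths, so the
dispersion is an explicit knob (default 0.5, strongly overdispersed).
Sequencing errors are applied per base at rate `seq_error`; qualities are a
constant Q40 except at error sites, which draw Q5–Q20 so the low-quality
filters have signal to act on.

**Allelic dropout.** A restriction site can be destroyed by mutation, in
which case the fragment is never sequenced in that lineage or any of its
descendants. This is implemented as a per-gene-tree-edge loss probability
(`dropout_prob`); loss is hereditary, and the truth set records both the
dropped tips and the mutated-edge clades so heredity is directly testable.

**Replicates.** Technical replicate samples share haplotypes and dropout
state with their source and redraw only depth and sequencing errors — the
information structure that makes replicate-based error rates meaningful.

What the generator does *not* model: indels, paralogous gene families
(beyond what deep coalescence produces), PCR duplicates, barcode chemistry,
and empirical fragment-size distributions. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not robustness to every artefact of real libraries.

## Read preparation

Pairs containing uncalled bases are discarded, as are pairs in which more
than `max_fraction_low_quality` (default 0.25) of either mate's bases fall
below Q10. Overlap merging reverse-complements mate 2 and scores every
overlap of at least 16 bp (the conventional minimum) by matches minus
mismatches, requiring a mismatch fraction at or below 0.1; ties go to the
longest overlap, disagreements are resolved toward the higher-quality base,
and agreements keep the larger of the two qualities. This is a
deterministic contract rather than a re-implementation of any specific
merging tool's significance test: on error-free data the merge decision is
exactly determined by fragment length. Unmerged pairs are retained and
later joined head-to-tail (read1 + revcomp(read2)) for the paired assembly
path; a flipped pair joins to the exact reverse complement of its unflipped
form, which reverse-complement clustering reunites.

## Locus assembly

Six parameters control assembly (defaults in parentheses): minimum depth
for a statistical base call `d` (6), maximum low-quality sites per read and
ambiguous sites per consensus `n` (4), clustering identity threshold `c`
(0.88), maximum individuals sharing a heterozygous site `h` (3; a value
below 1 is read as a proportion of samples, rounded up), maximum alleles
per locus per sample `pl` (2), and minimum reads per dereplicate `mr` (1).
A locus-level minimum sample coverage fraction completes the set.

Within a sample: reads failing the `n` filter are dropped, identical reads
are collapsed in canonical orientation (the lexicographic minimum of the
sequence and its reverse complement) with counts, and dereplicates below
`mr` are discarded. Greedy centroid clustering processes dereplicates in
descending count (ties lexicographic); a query joins the first centroid
with identity ≥ `c`, scanning centroids of the query's own length first and
both orientations always. Identity is an ungapped positional match fraction
over the shorter sequence; indel-tolerant alignment is deliberately out of
scope because the generator is indel-free.

Base calling compares, per column with depth ≥ `d`, the two most frequent
bases under an error-only binomial model (error rate estimated from
near-identical dereplicates, floor 1e-4, fallback 0.001) and a 50:50
heterozygote model, the higher likelihood winning; columns below `d` become
N. Heterozygous columns are phased by read co-occurrence: base patterns
across the heterozygous columns need at least two supporting reads, minor
bases without a supported pattern are demoted (suppressing single-error
false heterozygotes at low depth), and a sample whose cluster yields more
than `pl` supported alleles is discarded from that locus, as is a consensus
with more than `n` ambiguous sites.

Across samples the same greedy clustering (ordered by depth) groups
per-sample consensuses into candidate loci; if two clusters from one sample
land in one locus the deeper is kept and the collision is logged as a
potential paralog. Finally, loci are dropped when any site is heterozygous
in more than `h` individuals (collapsed paralogs produce exactly this
signature) or when sample coverage falls below
`ceil(min_sample_coverage · n_samples)`.

## Replicate-based quality control

For a replicate pair, *locus error* is the number of loci recovered in
exactly one replicate divided by the loci containing at least one of the
pair (the union denominator keeps the rate symmetric and bounded); *allele
error* is the fraction of shared loci whose full allele sequences differ;
*SNP error* is the fraction of genotype calls differing at SNP positions
genotyped in both replicates. Shared loci with no overlapping SNP calls
contribute zero discordance; only a pair sharing no loci at all has
undefined rates. The one-at-a-time parameter sweep assembles the data once
per (parameter, value), records loci, SNPs, the three error rates and
per-population K80 distance summaries, and ranks values per parameter by a
weighted rank sum over (−loci, −SNPs, locus error, allele error, SNP error,
mean intra-population distance) — rank-based because the criteria have
incomparable units. Ties resolve toward the default; the selection is
advisory and user override is expected.

## SNP distances and ordination

SNPs from the merged and unmerged assemblies are combined into one matrix
(cells are IUPAC codes; tetraploid genotypes collapse to their distinct
allele set), and sites genotyped in under 50% of samples or with identical
non-missing genotypes are removed. K80 distances use pairwise deletion:
per pair, transition and transversion proportions are computed over sites
where both samples have an unambiguous base, and
`d = −½ ln((1−2P−Q)√(1−2Q))`; saturated or non-overlapping pairs are
flagged undefined rather than silently zeroed. Neighbour-joining and
principal coordinates analysis are delegated to scikit-bio behind this
module's interface; PCoA reports positive-eigenvalue axes only. Unlinked
SNP selection takes one biallelic site per locus, either uniformly at
random or biased toward sites whose rare allele occurs in at least two
samples (largest minor-allele count first, singletons only as fallback),
optionally requiring presence in at least one sample of every taxon — the
input preparation used by biallelic-SNP coalescent methods.

## Gene trees and rooting

Per-locus trees are built from the locus alignment (IUPAC consensus rows)
with K80 + neighbour-joining; internal branches below 1e-8 collapse to
polytomies, which the summary methods treat as unresolved rather than
forcing arbitrary resolutions. This distance-based choice replaces
likelihood tree search deliberately: the summary methods consume
topologies, and the statistical-consistency tests hold under it. A Newick
import path allows externally estimated gene trees to be substituted.
Site-bootstrap trees (default 150 per locus) are computed the same way.
Rooting follows an ordered outgroup hierarchy: the highest-priority group
with any tip present roots the tree — on the pendant edge for a single tip,
on the edge making the group monophyletic when one exists, otherwise on the
edge with the greatest Jaccard overlap between one side and the group (ties
to the first edge in preorder). Trees containing no hierarchy member are
discarded, and bootstrap pools are rooted (and filtered) before any
bootstrap resampling draws from them.

## Summary species trees

*Average internode distances.* For every gene tree, the distance between
two tips is the number of internal nodes on the unrooted path between them;
cross-species tip pairs are averaged over all trees containing both
species, and neighbour-joining on the averaged matrix gives a species
topology. Branch lengths from this method are meaningless and are
discarded.

*Rooted-triplet pseudo-likelihood.* Rooted gene trees are reduced to
triplet topology counts over all cross-species tip combinations (one tip
per species; a singleton map reproduces the samples-as-lineages
configuration). Under the multispecies coalescent, a triple with species
internal path length `T` matches with probability `1 − (2/3)e^{−T}`. The
pseudo-log-likelihood sums per-triple multinomials; internal branch lengths
are maximised jointly with bounded L-BFGS-B (cap `T_max = 10` coalescent
units, reported when hit) — a joint quasi-Newton step in place of
coordinate ascent, converging to the same bounded optimum and verified
against the 3-species closed form `T̂ = −ln(3(1−p̂)/2)` to 1e-6. Topology
search is rooted-NNI hill climbing with three runs (later runs perturb the
start by two random NNI moves); terminal branch lengths are not estimable
from triplets and are displayed as a nominal 1.0.

*Quartet score.* The number of resolved cross-species quartets in the gene
trees that agree with a candidate topology, normalised by the number
examined; maximisation is by exhaustive enumeration, provided for up to 9
species ((2n−5)!! growth makes heuristic search a non-goal here).

*Multi-locus bootstrap (MLBS).* Each of (default) 100 replicates draws L
loci with replacement; each draw consumes one tree from that locus's
precomputed pool of (default) 150 bootstrap trees *without replacement*
within the replicate, emulating site resampling. Drawing a locus more often
than its pool size is a hard error advising a larger pool. Support for
every internal branch of the point estimate is the percentage of bootstrap
species trees containing the same bipartition (clade, for rooted
estimates).

## Validation scale and numerical choices

The acceptance suite exercises the pipeline at desk scale: simulator
calibration with 10,000 gene trees per branch length; 200 randomized
error-rate fixtures checked exactly against a brute-force oracle; a clean
(error-free, high-depth, dropout-free) 10-species × 3-sample, 300-locus
dataset assembled losslessly with zero replicate error; a
clustering-threshold sweep on data with ~6% within-locus divergence;
exhaustive NJ recovery over all unrooted topologies up to 8 taxa; PCoA
recovery of planted configurations to Procrustes error < 1e-9; and
statistical consistency of all three summary methods on 5-species
simulations (internal branches ≥ 0.5 coalescent units, 2000 gene trees,
40 seeds, ≥ 95% recovery required), including identical summary topologies
from end-to-end assemblies at clustering thresholds 0.82 and 0.91. These
problem sizes are the package's validation design; larger runs only
tighten the Monte-Carlo error.

Numerical details: optimizer tolerances ftol 1e-14/gtol 1e-12; probability
clamping at 1e-300 inside the pseudo-likelihood; NJ input symmetrised and
negative NJ branch lengths clamped to zero; polytomy collapse epsilon 1e-8;
all randomness flows through seeded `numpy` generators, and identical seeds
reproduce byte-identical FASTQ output.

## Known limitations

Ungapped comparison breaks on indel-rich real data; the greedy clusterer is
order-dependent by design (documented, deterministic) and quadratic in the
worst case; the error-rate estimate for the base caller assumes most
within-dereplicate mismatches are errors, which overestimates the rate in
extremely polymorphic samples; MLBS pools formed after rooting mean loci
unrootable in some bootstrap replicates simply shrink that locus's pool;
and the triplet method shares the known sensitivity of rooted-triplet
pseudo-likelihood to non-random missing lineages (visible in validation
when high clustering thresholds make outgroup loci drop out).
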