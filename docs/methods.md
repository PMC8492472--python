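# Methods

This note documents the models and procedures implemented in `allokit`, the
defaults they use, and the design decisions taken where more than one
reasonable choice existed.

## Subgenome assignment from gene-tree topology

A heptad family contains one gene from each of three diploids — zebrafish,
the outgroup *P. guichenoti* and the progenitor-like *P. tetrazona* — and
two genes from each allo-tetraploid (common carp, goldfish). The classifier
roots the family tree on the zebrafish leaf and searches for a clade whose
leaf set is exactly {one *P. tetrazona* gene, one carp gene, one goldfish
gene} with a sister clade holding exactly the remaining carp and goldfish
genes. When found, the tetraploid members of the *P. tetrazona*-containing
clade are labelled subB (they descend from the progenitor lineage shared
with *P. tetrazona*), the sister pair subA; any other shape is *complex*
and carries no labels. The classification is invariant to leaf order and
internal-node rotation, which the test suite checks exhaustively over all
10,395 labelled rooted-binary shapes on seven leaves against an independent
split-membership brute force.

`min_support` (default: off) optionally requires the two defining internal
branches to reach a bootstrap threshold; 50 is the conventional choice.
Supports are otherwise ignored, because family retention is decided by
topology alone.

Chromosomes are assigned A/B by majority vote of the labelled genes they
host. Votes from genes on `scaffold:*` tokens (unanchored sequence) are
discarded. When homoeologous chromosome pairs are supplied, each pair is
constrained to exactly one A and one B member: a tied or conflicting
member takes the complement of its partner, flagged `tie_broken`. A gene
whose label disagrees with its host chromosome's subgenome is a
homoeologous-exchange (HE) event; HE validation compares per-kb-normalised
progenitor read counts between exchanged and hosted genes with a one-sided
Mann–Whitney test (exact null when both groups have ≤ 8 genes), at
α = 0.05. Normalisation per kb is applied because the compared gene sets
have unequal lengths, which raw read counts would confound. Region-level HE
candidates are additionally flagged from windowed log2(depth_A/depth_B)
profiles when a window's sign inverts relative to the chromosome-wide
median by more than one log2 unit (two-fold); the threshold is a package
choice, as only the direction of the comparison is canonical.

## Ka/Ks estimation and molecular-clock dating

The pairwise estimator is Nei–Gojobori (1986). Per codon position, the
synonymous site fraction is the proportion of the three single-nucleotide
neighbours encoding the same amino acid; substitutions creating stop
codons count as nonsynonymous, so S + N = 3 per codon exactly. Site counts
are averaged over the two sequences. Observed differences average the
synonymous/nonsynonymous split over all minimal mutational pathways
between the two codons, weighting pathways equally and skipping pathways
through stop codons (if every pathway is blocked, all are used). The
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) maps the per-site
proportions to rates; saturation (p ≥ 3/4) yields an undefined rate, and
Ka/Ks is reported as undefined (None) rather than an infinite number
whenever Ks is undefined or zero. Gap- or ambiguity-containing codons are
dropped pairwise; internal stop codons are an error.

NG86 is deliberately preferred over the Yang–Nielsen
maximum-likelihood style estimator: it is fully specified, exactly
checkable against a brute-force neighbour/pathway enumeration (the suite
does this on 1,000 random short alignments), and the downstream surface —
the Ks mode and its clock conversion — is robust to the estimator choice
at these divergence scales. A YN-style estimator can be slotted in behind
the same interface if codon-frequency and ts/tv corrections are needed.

Ks modes are kernel-density estimates: Gaussian KDE with Silverman's
bandwidth (an absolute bandwidth can be supplied) evaluated on a 512-point
grid over [0, max]; the mode is the grid argmax and all interior local
maxima are reported as diagnostics for multimodal distributions. At least
30 finite values are required, below which a mode is too unstable to
report. Divergence dates use T = Ks_mode / (2r) / 10⁶ Ma with the cyprinid
synonymous clock r = 3.51×10⁻⁹ substitutions/site/year as default; the
factor 2 reflects substitutions accruing on both diverging lineages (the
published dates confirm this convention: mode 0.19 → 27 Ma). Times are
reported at one decimal with half-up rounding.

Percent identity comes from Biopython global alignment (match 2 /
mismatch −3 / gap −5/−2 for nucleotides; BLOSUM62 with −11/−1 for
proteins), as matches over alignment columns. Subgenome selection symmetry
is a two-sided Mann–Whitney U on Ka/Ks ratio sets with undefined ratios
excluded; the exact null distribution is used when both groups have ≤ 8
values and no ties.

## Ancestral regions, rearrangements and Dollo losses

An alignment block (from MAF, converted to forward-strand 0-based
half-open coordinates on read) becomes an ancestral region (AR) when it is
longer than 1 kb and at least four of its genome rows map, through the
user-supplied homoeolog map, to the same ancestral chromosome; that
chromosome is the AR's, and the majority strand among agreeing rows its
orientation (a strand tie resolves to '+' with a flag). The homoeolog map
is an explicit input: the 25 reconstructed ancestral chromosomes imply a
many-to-one mapping from the 50 tetraploid chromosomes, but the mapping
itself is data, not a constant. Each of the seven genome rows (three
diploids plus two subgenomes per tetraploid) counts independently toward
the four-genome support. Reported AR coordinates snap outward to 1-kb
boundaries, matching the reconstruction resolution.

Per genome, the translocated fraction is the share of ARs whose row maps
to a different ancestral chromosome; the inverted fraction is computed
over non-translocated ARs only, comparing row strand with AR orientation.
Retention/loss densities divide the retained (supporting) and lost AR loci
by the subgenome size in Mb, against an explicit universe of ancestral
loci; two genomes' retained/lost tables are compared by a 1-df χ² with
continuity correction.

Gene-family losses are mapped by Dollo parsimony: a family originates once
at the most recent common ancestor of the taxa containing it, and the
losses are the minimal set of branches below that origin whose removal
explains all absences — equivalently, one loss per maximal all-absent
subtree. Branches are named by the leaf set below them. The test suite
checks the minimal-loss count against an exhaustive subset search on 1,000
random presence patterns.

## Homoeolog expression divergence

All distance computations use log2(TPM+1) profiles; raw-TPM Euclidean
distance would be dominated by single high-expression tissues. The
expression floor defaults to TPM ≥ 1 ("expressed"); every count that
depends on it takes it as a parameter.

- *Dominance*: in each tissue/condition, the homoeolog with strictly
  higher TPM wins; equal values (including double zeros) are ties and
  excluded, as are pairs with both copies below the floor. Counts are
  tested against 50:50 by χ². A pair-level call (majority of contexts) is
  also provided and is what the dominance-bias recovery uses.
- *Conservation*: a homoeolog is conserved when its Pearson correlation
  with the outgroup orthologue exceeds 0.66 at p ≤ 0.05 across the nine
  shared tissues. At n = 9 the two-sided 5 % critical value of r is 0.666,
  so the two thresholds are mutually consistent; the p-value uses the t
  transform with n−2 degrees of freedom.
- *Divergence*: a pair is divergent when its homoeolog–homoeolog Euclidean
  distance reaches the top decile across pairs or the correlation falls
  below 0.66. Zero-variance profiles have undefined correlation and are
  classified diverged with a flag.
- *Clustering*: agglomerative, average linkage, Euclidean metric, cut to
  exactly k groups (k = 8 for expression patterns, k = 10 for
  alternative-splicing counts, where raw counts are used unlogged);
  deterministic by construction.
- *Functionalization* precedence: (1) non-F when one copy stays below the
  floor in every context; (2) neo-F when exactly one copy is conserved
  with the outgroup and the copies sit in different clusters; (3) sub-F
  when neither copy is conserved but their summed (pseudo-ancestral)
  profile is; (4) coexpressed when both sit in one cluster; (5) otherwise
  neo-F. The sub-F operationalisation — individually diverged copies whose
  sum still tracks the ancestral profile — is one defensible reading of
  subfunction partitioning; it is flagged in output metadata and swappable.
- *Dosage*: the pseudo-ancestral gene is the per-context sum of both
  homoeolog TPMs, compared with the diploid orthologue by Wilcoxon
  signed-rank (all-zero differences give p = 1).
- *DEG balance* consumes externally produced differential-expression flags
  (e.g. DESeq2 at FC ≥ 2, FDR ≤ 0.05) and tests the 2×2 DE-by-subgenome
  table with a continuity-corrected χ², alongside the count of pairs with
  exactly one DE copy. Trans-splicing fusion calls are likewise consumed,
  and classified intra-A/intra-B/inter-subgenome by the host chromosomes
  of the two partners.

## Windowed population genetics

Windows are 0-based half-open, 100 kb with a 50-kb step by default;
terminal windows shorter than half the window size are dropped, retained
partial windows flagged. Per site, the observed allele number n (twice the
called diploids) is used throughout, so missing genotypes shrink n rather
than biasing frequencies.

π sums the unbiased per-site heterozygosity 2c(n−c)/(n(n−1)) over window
sites divided by window length; θw = S/(a_n·L) with a_n = Σ_{i<n} 1/i.
Tajima's D uses the standard variance constants; Fu & Li's statistics are
the star variants D* and F* (no outgroup polarisation is performed),
following Fu & Li (1993) with the Simonsen et al. (1995) corrections, with
singletons counted as alleles observed exactly once. Windows with S = 0
report π = θw = 0 and missing D statistics. The implementation reproduces
tskit's π and Tajima's D to machine precision on coalescent simulations,
and the neutral calibration (|mean D| < 0.3 over 200 constant-size
coalescent replicates of 20 diploids) is part of the suite.

Fst is the weighted Weir–Cockerham (1984) estimator: per-site variance
components a, b, c from allele frequencies and observed heterozygosity,
aggregated per window as Σa/Σ(a+b+c); negative window estimates are
truncated to 0 with a flag before Z-transformation. ZFst standardises the
window Fst values to mean 0 and sample standard deviation 1 (n−1
denominator).

Sweep calling is the joint top-quantile rule: with the π ratio oriented as
π(pop2)/π(pop1) — so diversity loss in the focal, domesticated-like
population 1 produces large ratios — windows in the top 5 % of both the π
ratio and ZFst are called selected in population 1, and windows in the
bottom 5 % of both selected in population 2. Thresholds are empirical
quantiles of the scanned windows, reported alongside the calls, never
hard-coded: published cutoffs of this kind (e.g. π ratio ≥ 1.165,
ZFst ≥ 1.61) are data-derived top-5 % values, not constants. Degenerate
inputs (no spread in either statistic) produce no calls, flagged.

LD decay uses composite r²: the squared Pearson correlation of unphased
genotype dosages between site pairs within a chromosome, averaged per
distance bin; the half-decay distance is the first bin midpoint whose
mean r² falls to half the maximum bin mean. Monomorphic sites are
excluded, missing dosages dropped pairwise.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic under a fixed seed, record their planted
truth beside the data, and default to the study conditions of the system
they emulate.

**Heptad families** evolve a random stop-free codon sequence (200 codons
by default) down the fixed species topology
(zebrafish,(Pg,((Pt,(ccB,gfB)),(ccA,gfA)))). Per branch, substitutions are
proposed one nucleotide at a time with transition/transversion weight
κ = 2; proposals creating stops are rejected, synonymous proposals
accepted, nonsynonymous accepted with probability ω = 0.1. A branch ends
when the accepted synonymous events reach a Poisson draw with mean
(branch Ks) × (synonymous sites), so realised synonymous divergence tracks
the requested per-branch Ks directly and the NG86/KDE pipeline recovers
the planted modes within ±0.01 at 2,000 families. Default branch targets
are the observed cyprinid scales: A-vs-B 0.19, Pt-vs-B-ancestor 0.18,
carp-B/goldfish-B 0.10, carp-A/goldfish-A 0.095 (outgroup depths 0.13 and
0.21 for *P. guichenoti* and zebrafish). Families sit on one of 25
homoeologous chromosome pairs; with probability `he_rate` one tetraploid
gene per family relocates to the partner chromosome (a planted HE), and a
fraction `topology_noise` of families is emitted on a non-canonical
topology (both carp copies sister inside the Pt clade) with no truth
labels. The generator emits the true trees; it does not emulate
gene-tree-inference error beyond the explicit topology noise, nor
alignment error, paralogy, or rate variation among sites — so perfect
label recovery on noiseless data validates the classifier's logic, not
robustness to phylogenetic noise.

**Expression panels** draw each pair a tissue archetype (a one-hot +4
log2-boost over a baseline of 3, eight archetypes over nine tissues by
default), add a pair-level magnitude and Gaussian log-space noise
(σ = 0.15). Conserved pairs (70 % by default) keep the outgroup's
archetype in both copies; diverged pairs swap one copy to a different
archetype, which simultaneously lowers its outgroup correlation below 0.66
and raises the pair distance. The subB copy is boosted two-fold with
probability `dominance_bias` (default 0.55, a mild B-ward bias), subA
otherwise. The panel does not emulate count noise, library-size effects,
or tissue correlation structure; it is a geometry on which threshold rules
(r = 0.66, top-decile distance, floor) act exactly as designed.

**Alignment blocks** place 7-row blocks (lengths uniform on 0.5–5 kb,
deliberately straddling the 1-kb AR cutoff) on 25 ancestral chromosomes;
each row independently translocates or inverts with the requested rates.
No nested or overlapping rearrangements, no alignment gaps.

**Two-population genotypes** draw per-window site counts from Watterson's
expectation at the background diversity (2×10⁻³/site by default) and
frequencies from the neutral 1/i spectrum shared by both populations
(Fst ≈ 0). Planted sweep windows perturb population 1 by a Balding–Nichols
Beta draw with F = max(fst_sweep, 1 − π_sweep/π_background), which both
reduces its expected diversity to π_sweep (5×10⁻⁴ by default) and
elevates differentiation at least to the requested Fst. Defaults: 20
diploids per population, a 10-Mb chromosome (100 windows), 5 sweep
windows. Sites are exchangeable within windows — there is no linkage,
recombination map, or demography — so Tajima's D on these windows is not
coalescent-calibrated (the neutral D calibration uses real coalescent
simulations instead), and sweep recovery measures the joint-quantile
logic, not power under realistic genealogies.

## Numerical conventions

Internal coordinates are 0-based half-open everywhere; conversions happen
only at the VCF (1-based) and MAF (strand-local) boundaries, with
reverse-strand MAF rows mapped by start′ = srcSize − start − size.
Reported percentages round half-up at the printed precision (one decimal
for percentages, two for Mb means). VCF parsing keeps biallelic SNPs only,
dropping other records with a logged count and preserving missing
genotypes. Chi-square tests on 2×2 tables use 1 df with continuity
correction; identical tables short-circuit to p = 1. Ties in rank tests
fall back from the exact to the tie-corrected asymptotic null.

## Known limitations

- The Ka/Ks estimator ignores transition/transversion bias and codon
  frequencies (NG86); absolute Ka/Ks levels shift slightly under strong
  bias even though Ks modes, and everything dated from them, are stable.
- Chromosome assignment assumes exactly two subgenomes and one diploid
  progenitor pair; higher ploidies are out of scope.
- Complex (non-canonical) families are excluded from all downstream
  counts, mirroring the analysis design; no attempt is made to rescue
  partial labels from them.
- The LD computation is quadratic in sites per window of distance; for
  genome-scale VCFs, thin sites or restrict `max_distance`.
- Fu & Li's D*/F* use total singleton counts without outgroup
  polarisation; they are star variants by construction.
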