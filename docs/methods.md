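# Methods

`phagoscope` implements a shotgun-metagenome phagobiota analysis: phage
abundance is quantified by classifying assembly contigs against a phage
genome database and recruiting reads back to the phage-like contigs;
bacterial hosts are profiled from clade-specific marker genes; community
structure is summarised with alpha/beta diversity statistics; and the
phage/bacteria abundance ratio ("lytic potential") with a lytic/temperate
lifestyle split provides the host-level interpretation.  A synthetic-cohort
generator with full ground truth makes every stage testable end to end.

## Phage quantification

Contigs longer than 200 bases (strictly: 201 and up) are searched against
the phage database; a contig is assigned to the best-scoring phage when the
hit's e-value is below 1e-5 and the alignment covers strictly more than
half the contig.  All reads are then re-mapped to the assigned contigs;
each read counts toward at most one contig (best alignment score, ties
broken toward the lexicographically smaller phage id, then contig id).
Counts are combined per phage per sample.  The detection threshold requires
at least 2 reads per (phage, sample) cell, each aligned with identity
strictly above 90% over strictly more than 100 bases; the two clauses of
the threshold are harmonised into this single rule, and the length clause
can be disabled for reads at or below 100 bases.  Counts are normalised to
relative abundance within the phage domain (phages among phages); taxa
whose relative abundance stays below 1e-4 in every sample are removed, and
the presence screen calls a species present in a group when at least 2 of
the group's samples reach 1e-4 (0.01%).

The choice of phage-domain-relative (rather than whole-metagenome-relative)
normalisation is deliberate: the ratio framework below compares
domain-relative phage abundance to domain-relative host abundance, which
makes the "integrated prophage" calibration point (ratio 1) attainable and
is robust to the unknown total phage DNA load of a sample.  A switch
(`normalize_by="total_reads"`) divides by each sample's full read count
instead for workflows that want whole-metagenome-relative values.

## Alignment engine

A seed-and-extend local aligner substitutes for BLAST/Bowtie2 at desk
scale.  Scoring is BLASTN-like: match +1, mismatch -2, gap open -3, gap
extend -1 (a gap of length L costs 3 + L).  The affine-gap (Gotoh)
dynamic programme is exact; for small query x database sizes every subject
is aligned exhaustively, so the best score equals full Smith-Waterman, and
for larger databases k-mer seeds (k = 13) restrict the DP to diagonal
windows.  The batch read mapper adds two fast paths that preserve the
results that matter downstream: reads that occur verbatim in a subject are
resolved by exact substring search, and reads whose seeds agree on a single
diagonal get the optimal *gapless* local alignment on that diagonal
(maximum-scoring segment).  With substitution-only sequencing errors these
coincide with the full DP optimum; with indels the windowed DP fallback
handles multi-diagonal seed patterns.  Percent identity counts matches over
all alignment columns including gaps, and the ambiguous base N never
matches.

E-values follow the Karlin-Altschul form E = K m n exp(-lambda S) with
K = 0.1 and lambda solved numerically from the match/mismatch matrix under
uniform base frequencies (lambda = 1.333 for the default scoring); gap
penalties do not enter the lambda calculation (ungapped scale).  These
defaults stand in for unstated BLAST internals and are configurable.

## Bacterial marker profiling

The profiler maps reads to a database of clade-specific marker genes and
estimates genus abundance as mean per-base marker coverage: total aligned
bases on the genus's markers divided by their total length, then normalised
to sum to one per sample.  Family abundance is the exact sum of member
genera.  Reads with qualifying alignments to markers of more than one genus
are discarded (clade-specific markers should not share reads); because the
exact-match fast path reports only top-scoring subjects, this discard rule
operates on best-score hits — genuinely shared sequence still triggers it,
while a read one mismatch away from a second clade's marker is credited to
its best clade.  An adapter ingests externally produced MetaPhlAn-style
tabular profiles, normalising percent values to fractions and flagging
clades without a genus rank.

## Diversity statistics

All indices are computed from their formulas on integer read counts after
detection thresholding (richness estimators are undefined on fractions):
Shannon H = -sum p_i ln p_i (natural log; the base is a convention choice),
Simpson D = 1 - sum p_i^2 and inverse Simpson 1/sum p_i^2, classic Chao1
S_obs + F1^2/(2 F2) with the F2 = 0 fallback S_obs + F1(F1-1)/2, and ACE
with the standard rare/abundant split at 10 individuals and
gamma^2 = max(S_rare/C_ace * sum i(i-1)F_i / (N_rare(N_rare-1)) - 1, 0);
when every rare individual is a singleton (C_ace = 0) ACE is undefined and
Chao1 is returned with a warning.

Beta diversity: Bray-Curtis BC(x,y) = sum|x_i - y_i| / sum(x_i + y_i)
(all-zero pairs are NaN with a warning), and a Spearman-based
dissimilarity d = (1 - rho)/2 mapping identical rank order to 0 and
reversed ranks to 1 — the plot-scale convention of the figure this mirrors
is ambiguous, and this symmetric transform is adopted as the natural one.
PCoA is classical scaling: double-centre -D^2/2, eigendecompose, keep axes
with positive eigenvalues (tolerance 1e-12 relative to the leading
eigenvalue); on Euclidean inputs the retained space reproduces the
distances to 1e-8.

Group tests: Mann-Whitney uses exact enumeration of all group assignments
when the combined sample size is at most 12 (ties handled by the
permutation distribution of U, two-sided p as twice the smaller tail) and
the tie-corrected normal approximation otherwise — without a continuity
correction, which keeps the type-I error near nominal at moderate n.
One-way ANOVA is the fixed-effects F test.  PERMANOVA computes the
pseudo-F from the squared-distance partition (equivalent to the
Gower-centred trace form) and estimates p with the add-one permutation
estimator (1 + #{F_perm >= F_obs}) / (1 + B), B = 999 by default, from
label permutations drawn with an explicit seed; the permutation loop is
vectorised over all permutations.  The add-one estimator never returns
p = 0 and is exactly calibrated at the achievable p-value lattice.

## Lytic potential

Phages are clustered by annotated host genus (falling back to the host
implied by "<Genus>_phage_<name>" naming; unresolvable phages pool into
"unassigned_host"; clustering conserves total abundance exactly).  For a
host genus, R = A_phage / A_host divides the phage cluster's domain-relative
abundance by the genus's domain-relative abundance, per sample and per
group (group level uses group means, matching per-group bar summaries;
both are emitted because the source convention is ambiguous).  log10 R
near 0 (within +-0.3) is read as a stably integrated prophage, below as a
prophage absent from part of the host population, above as partial lytic
activity.  Zero abundances produce explicit statuses (host_absent,
phage_absent, both_absent) instead of infinite ratios.

Lifestyles are assigned by longest-pattern substring lookup in an
overridable table; the shipped table covers the strictly virulent c2 and
936 groups of lactococcal phages (c2, bIL67; sk1, jj50, phi7, CB13,
bIL170, P008, 645) as lytic and the P335 group and bIL285-like prophages
(P335, TP901, Tuc2009, ul36, r1t, BK5-T, bIL285/286/309) as temperate;
phages matching nothing are "unknown", excluded from the lytic/temperate
sums with a warning.  Fold change is control mean over case mean with a
seeded percentile bootstrap CI (1000 resamples); a zero case mean reports
an infinite status with only the CI lower bound.  Per-phage case/control
log10 ratios use a pseudocount of half the smallest nonzero abundance.

## Synthetic cohorts

The generator emulates a two-group faecal-metagenome study: 31 case and 28
control samples by default.  Per taxon, abundance is an independent
log-normal; case samples are multiplied by configured effect factors before
closed (sum-to-one) normalisation within each domain (bacteria; phages).
The log-normal gives heavy-tailed compositions like real metagenomes;
closed normalisation means a strong depletion slightly deflates the
measurable relative-abundance fold change (a 10x depletion of a 10% genus
yields a true relative fold near 9.1), which the recovery tolerances
account for.

Genomes are uniform-random DNA; each bacterial species carries
non-overlapping, evenly spaced marker loci whose cross-genus uniqueness is
enforced by rejection sampling.  Temperate phages are integrated as
prophages (one copy per host genome, uniform offset), growing the host
genome by exactly the phage length; lytic phages are never integrated.
Reads are drawn per sample with count ~ Poisson(depth * L / read_length)
where L is the total length of genomes with positive sampling weight;
genome weights are abundance x length, with the free-phage pool scaled to
`phage_dna_fraction` (default 0.05) of bacterial DNA mass and temperate
phages contributing a `free_particle_fraction` (default 0.5) of their
abundance as free particles — total-DNA extraction sequences both the
integrated and the free state, but the mixture is not observable, so it is
a parameter.  Reads are reverse-complemented with probability 0.5 and
substituted per base at the configured rate (default 0.005); qualities are
constant (the method uses none).  Contigs are uniform-length fragments of
every genome (defaults 120-600 bases, so sub-200 pieces exercise the
length filter); paired-end layout is emulated as two independently
positioned mates.

Default scenario sizes are chosen so a full cohort analysis runs in
seconds: genomes of 3-4 kb with 6 markers of 200 bases, phages of 2.5 kb,
read length 110 (keeping the >100-base detection clause active on
full-length read alignments), depth 5x, per-taxon log-normal sigma 0.3-0.5
(moderate inter-individual variability), Lactococcus-like base share 0.10
with a 0.1 case factor, and its strictly lytic phage boosted 10x in cases.
What the generator does **not** emulate — indel errors, GC and coverage
bias, chimeric misassembly, strain-level variation, realistic genome sizes
and database incompleteness — bounds what green tests show: they validate
the counting rules, statistics and parameter recovery under the stated
noise model, not performance on real gut metagenomes.

## Numerical and design choices

* Strict inequalities throughout the filters (">200 bases" admits 201;
  ">90%" excludes 90.0; ">50%" excludes exactly half).
* Counts are per mate; pairs count as two reads.
* Best-hit assignment for multi-mapping contigs and reads; deterministic
  tie-breaking (lower e-value, then lexicographic ids).
* All randomness flows from explicit integer seeds; pipeline outputs carry
  version, seed and a configuration hash in their headers, and re-running
  an identical configuration reproduces byte-identical TSVs.
* Interchange coordinates are 0-based half-open; BLAST tabular input is
  converted from its 1-based inclusive convention on read.
* Diversity p-values are reported from Mann-Whitney, ANOVA and PERMANOVA
  side by side rather than privileging one test.

## Known limitations

The aligner's seeded mode can miss homology with no shared 13-mer (short
or highly diverged matches); the gapless fast path can underscore reads
whose best alignment requires a gap (impossible under the built-in error
model, rare at real substitution-dominated error rates).  The marker
profiler is a functional stand-in for external marker-based profilers, not
a replica of any tool's catalogue or smoothing.  The lifestyle table covers
the named lactococcal phage groups only; everything else is "unknown" by
design and should be overridden for other systems.  Full-scale cohorts
(billions of reads) are out of scope: the adapters for BLAST outfmt-6 and
SAM output exist so external aligners can be slotted in at that scale.
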