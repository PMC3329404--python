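# Methods

This note documents the models and procedures famsurvey implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Family identification and classification

Membership is decided from domain evidence alone: a locus belongs to the
family when its representative transcript — the longest protein, ties broken
by the lexicographically smallest transcript id — carries at least one WD40
domain hit of source `smart` or `pfam` in the domain-annotation table. A
sequence-similarity pre-screen is deliberately not re-implemented: any
similarity search permissive enough to gather candidates is superseded by the
domain confirmation step, so the table of scanner hits is the authoritative
input. The built-in GH…WD detector (`scan_wd40_repeats`) exists so the
synthetic pipeline can run without external scanners: it anchors a repeat at a
GH dipeptide and extends to the first downstream WD whose separation lies in
[20, 50] residues (the ~40-residue repeat core), greedily left to right
without overlap. It is a dipeptide-anchor heuristic, documented as
non-equivalent to profile-HMM scanning, and defaults to `min_repeats = 1`
(one detected repeat suffices for membership).

Subfamilies A–K are a rule table over the non-WD40 domains of a protein,
evaluated B→J, then K (any other extra domain), then A (WD40 only). The order
matters only when a protein carries domains diagnostic of two subfamilies; no
published precedence exists for that case, so the first matching rule wins and
the catalog row is flagged `ambiguous=true`. The zinc-finger rule (subfamily
I) matches by name prefix (`zf*`, `znf*`, or containing "zinc") because
zinc-finger domain nomenclature is a family of names rather than one label.

Physicochemical properties follow ProtParam definitions. Molecular weight is
the sum of average residue masses plus one water; the residue masses and the
DIWV dipeptide instability weights are taken from Biopython's published
tables. Theoretical pI uses a Bjellqvist-style pKa set (N-terminus 7.5, K
10.0, R 12.0, H 5.98; C-terminus 3.55, D 4.05, E 4.45, C 9.0, Y 10.0),
recorded as named constants and overridable per call; the net-charge function
is strictly decreasing in pH, so bisection on [0, 14] to |charge| < 1e-4
finds the unique root. Unknown residues (`X`) contribute the mean residue
mass to MW, no side-chain charge, and zero DIWV weight; the instability index
is undefined below two residues and raises.

## Duplication structure

Tandem duplicates are family genes on one chromosome separated by at most
`max_intervening = 5` annotated genes, counted over all genes regardless of
family membership or strand — the criterion refers to gene order on the
chromosome, not to family-internal spacing. Groups are connected components
of this relation (equivalently, maximal chains of consecutively linked family
genes); singletons are not reported. Inter-gene distance is the gap between
spans (zero for overlapping or juxtaposed genes), not start-to-start.

Segmental duplicates are assigned through precomputed collinear duplication
blocks supplied as input (block id plus two anchor spans); no de novo synteny
detection is attempted. For each block the nearest family gene within
`max_offset = 500 kb` of each anchor is taken, a pair is emitted when both
sides match, and a gene joins at most one pair with the closest block
winning. Duplicate protein similarity is global Needleman–Wunsch identity
(matches / alignment columns) under BLOSUM62 with gap open 10 and extend 0.5,
computed by Biopython's pairwise aligner; this replaces the proprietary
alignment tool used historically for such surveys, so published similarity
ranges are not comparable values.

## Expression analysis

Probe collapse keeps, per gene, the probe set with the higher mean signal
across all samples — one probe per gene, not a per-sample maximum, which
would splice different probes into one profile. A probe mapped to several
genes contributes its row to each. Detection flags gate expression: a gene is
expressed when flagged P in at least one sample; with no flags supplied all
genes pass, with a logged warning.

Clustering operates on log2 replicate-averaged signals with complete linkage
on euclidean distances (scipy's agglomeration). The number of flat groups is
user-set (default 2, refinable to 5): published subgroup boundaries in such
surveys are visual conventions, not reproducible counts. Tie-breaking at
equal merge distances follows scipy's deterministic order; exact ties have
probability zero for continuous signals.

Differential expression runs per gene and condition against the reference
(the seed tissue for the developmental series, CK for hormones): an
equal-variance two-sample t-test on log2 replicate signals (Welch available
behind `equal_var=False`), with the linear fold change computed on raw
replicate means. Log transformation stabilizes variance for the test while
fold changes stay on the familiar linear scale. Calls are strict: up needs
FC > 2 and p < 0.05, down FC < 0.5 and p < 0.05; FC exactly 2 is never
called. No multiple-testing correction is applied by default — the joint
fold-change-and-p criterion is the convention this workflow reproduces — and
the t-test on a single replicate raises rather than guessing.

## Co-expression network

The edge threshold is calibrated, not asserted: among `n_sample_genes = 1000`
randomly sampled profiles, all pairwise Pearson correlations form the
observed distribution; independently permuting each sampled profile (a fresh
permutation per gene, destroying all co-expression while preserving
marginals) and recomputing all pairs forms the null. The threshold is the
smallest r whose null exceedance is ≤ `alpha = 0.001`, implemented as the
(m+1)-th largest null value with m = ⌊α·n_pairs⌋. Only the positive tail is
used — the workflow treats co-expression as positive correlation — and a
symmetric |r| variant is a documented possible extension, not the default.
No fixed threshold (such as 0.8) is hard-coded; with 24-condition profiles
the calibration lands near 0.6, and it moves with the number of conditions
exactly as the r-distribution's null width does.

Seed genes must vary: SE = sd(per-condition mean raw signals)/√(#conditions)
must exceed 500 signal units (strictly), excluding constitutive profiles
whose correlations would reflect shared flatness rather than co-regulation.
SE is computed on condition means (replicates averaged first) because the
500-unit scale refers to per-tissue summary signals; an all-replicate-columns
variant would mix replicate noise into the criterion. Edges connect a seed to
any gene with r ≥ threshold and a significant correlation t-test
(p < 0.05, df = n−2); seed–seed edges are allowed so family-internal
feedback structure is visible. Class-annotated subnetworks are induced
subgraphs on family nodes plus requested classes.

When several expression matrices are combined (e.g. two genotypes), each is
log2-transformed first and columns are concatenated, keeping one code path
for pooled experiments.

## Enrichment

Per term: one-sided Fisher's exact test, P(X ≥ k) for
X ~ Hypergeometric(N, K, n), over a flat gene→term table; terms annotating
fewer than 2 background genes are skipped. The Benjamini–Yekutieli step-up
adjustment (adj_i = min_{j≥i} p_(j)·m·c(m)/j with the harmonic factor
c(m)) controls FDR under arbitrary dependence between terms, which matters
because term memberships overlap. No ontology-graph propagation is performed:
the annotation is taken as given, a documented limitation when terms have
is-a structure.

## Synthetic data

The generator emulates the study conditions of a desk-scale family survey: a
12-chromosome genome of 150 genes each carrying 200 family genes; nine tandem
clusters (one triple, eight pairs) whose member gaps fall in 3–35 kb; twelve
segmental pairs on distinct chromosomes with block anchors centred on the
planted duplicates and substitution-mutated partner proteins at target
identities of 75–95%; a 24-tissue × 2-replicate developmental series; and a
pooled-time-point hormone experiment (CK + NAA/GA3/KT × 2 replicates) whose
25 responders follow a fixed overlap plan (4 responsive to all three, 11 to
two, 10 to one).

Signals are multiplicative on a log-normal baseline chosen to mimic the
magnitude of microarray summary signals (background genes exp N(6.7, 1.0) ≈
800 units; module genes exp N(8.0, 0.4) ≈ 3000, the highly expressed regime
in which the 500-unit SE filter retains variable genes). Module members share
a latent per-tissue profile (sd 1.0 in natural log) plus independent noise
(`module_noise_sd = 0.15`); other genes get independent per-tissue effects
(sd 0.5); replicate noise is log-normal with sd 0.1. Differentially expressed
and hormone-responsive genes are planted on flat baselines with a 4-fold
multiplier in their target stage or treatment, isolating the planted effect
from incidental tissue variation. Detection flags threshold the noise-free
signal (absent < 100, marginal < 300) rather than re-implementing a
summarization algorithm: flags are inputs downstream, not outputs. The probe
map plants the survey's probe pathologies — genes with two probe sets
(higher-mean wins), probes shared by two genes (identical collapsed rows),
16 family genes without probes, and two family genes absent everywhere.

Random protein segments are drawn from an 18-letter alphabet without H or D,
so GH/WD dipeptides occur exactly where planted; promoters are uniform random
2-kb sequences with elements of the responding hormone classes inserted at
recorded strand and position; the term table gives every gene 1–3 background
terms and concentrates one planted term per module (85% of members, 2% of
others). None of this models sequence evolution, codon structure, realistic
residue composition, probe-level physics, or correlated annotation — passing
recovery tests therefore demonstrates the correctness of the analysis logic
under its stated model, not performance on real arrays or genomes.

Determinism: every stage derives its generator from the configured seed
(`default_rng([stage, seed])`), so identical configurations produce
byte-identical files regardless of call order.

## Problem sizes and runtime

The default synthetic dataset (1800 genes, ~1820 probes, 48 + 8 samples)
generates in under a second; the full pipeline runs in a few seconds. The
permutation calibration samples 1000 genes (499 500 pairs per distribution),
enough that the α = 0.001 positive tail is estimated from ~500 null
exceedances. Oracle-equivalence tests use 100 random layouts for tandem
grouping, matrices up to n = 50 for clustering, backgrounds up to N = 25 for
exact hypergeometric enumeration, and sequences up to length 8 for exhaustive
alignment scoring.

## Known limitations

- The GH…WD detector is a planted-structure recovery tool, not a domain
  caller; real surveys should supply scanner output tables.
- Flat annotation only; no GO-graph propagation.
- Positive-correlation edges only by default.
- The subfamily rule order B→J is a convention; genuinely multi-diagnostic
  proteins are flagged rather than resolved.
- Block anchors are inputs; the package does not infer collinearity.
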