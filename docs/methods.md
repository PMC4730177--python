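# Methods

This note documents the models, algorithms, numerical choices and known
limitations of nifscape, module by module.

## Synthetic communities (`synthcomm`)

**Reference panel.** NifH reference peptides are evolved on a two-level
star phylogeny rather than drawn from a real alignment: a random
108-residue root peptide spawns cluster ancestors (one per canonical
cluster, default I and III) at `divergence` substitutions/site, taxa
diverge from their ancestor at 0.4·divergence, and a BchL-like outgroup
diverges at min(3·divergence, 0.45). Substitution counts are
deterministic (round(rate·W), positions without replacement, never to
the same residue), which gives controllable, verifiable distance
ordering: within-cluster < between-cluster < any outgroup distance. The
constructor checks this ordering and that every peptide translates
exactly from its (randomly codon-degenerate) nucleotide sequence. This
is a caricature of real NifH evolution — no rate heterogeneity across
sites, no codon bias — and is intended to make downstream inferences
checkable, not to mimic real NifH sequence space.

**Read simulator.** A habitat is a name, a richness, a replicate count,
a depth range, a lognormal abundance shape parameter σ, and optional
per-taxon fold changes. Relative abundances are one lognormal draw per
habitat (shared across replicates); replicate counts are multinomial.
Reads are the full in-frame nucleotide window flanked by fixed literal
primer sites (a disambiguated realization of the nifH1/nifH2 priming
convention). The error model applies i.i.d. substitutions inside the
amplified region and, with per-read probability `indel_rate`, one
single-base insertion or deletion inside the read's longest homopolymer
run — the minimal faithful caricature of 454 pyrosequencing error that
forces frameshift correction to matter. Substitutions are not applied to
the primer flanks; flank errors would only re-exercise the exact-match
cropping rule. Qualities are constant per read, drawn around a
configurable mean, because the QC rule uses only the mean. Not emulated:
chimeras, paired ends, flowgram-level noise, length truncation.

**Study-scale defaults.** `study_soil_habitats()` fixes the two-soil
contrast at the study design scale: desert soil with 118 taxa and a
strongly uneven community (σ = 2.0), agricultural soil with 290 taxa and
a more even one (σ = 1.2), both at the 5217-read soil normalization
depth; `study_plant_habitats()` gives three rhizospheres at 553 reads.
The σ values encode the qualitative evenness contrast between a
dominance-structured desert community and a diversified agro-ecosystem;
they are set once here and are not fitted to reproduce any particular
index value.

**qPCR simulator.** Ct = intercept + slope·log₁₀(copies) + N(0, σ_Ct),
measured in (duplicates × runs) = (2, 3) per sample, the replicate
design of the study protocol. The ten-fold dilution standard is measured
with the same replicate design (6 measurements per point): standards run
alongside samples on every plate, and a single noisy measurement per
point would propagate ≈0.03 log₁₀ of curve-fit error into every sample,
swamping the quantification bias one wants to measure.

## Preprocessing (`preprocess`)

QC thresholds are inclusive (retain mean Q ≥ 20 and length ≥ 200 nt);
filtering is idempotent and order-preserving, and every rejected read
carries a machine-readable reason. Primer cropping removes exactly one
terminal copy of each primer; internal occurrences are untouched; reads
lacking the forward primer are dropped.

**Frameshift-corrected translation.** Each cropped read is aligned in
infix mode (edlib, banded edit distance) against every panel nucleotide
sequence; the closest reference wins (first in panel order on ties).
Rather than searching three peptide frames and inserting repairs
guided by a protein alignment, the implementation repairs directly from
the nucleotide alignment: read insertions are deleted and read deletions
are restored from the reference, up to `max_repairs` (default 2) bases,
after which the repaired read is translated in the reference frame.
For single-base homopolymer indels the two approaches coincide, but the
nucleotide route is exact about *where* the frame breaks and needs no
scoring heuristics. Reads are rejected when edit distance exceeds
(1 − 0.7)·length (random DNA aligns near 50% identity in infix mode, so
a 0.7 identity floor separates genuine nifH reads from junk), when more
than `max_repairs` indels would be needed, or when the repaired
translation still contains a stop codon. Reference coordinates are
0-based half-open throughout; clipping keeps only fragments covering the
full [0, 108) window. Substitution errors are *not* corrected — they
pass through as peptide mismatches, exactly as a frameshift-only
corrector behaves.

Depth normalization subsamples uniformly without replacement,
deterministically per (seed, sample) — the per-sample RNG is keyed by
the seed and a stable byte-sum of the sample name, so results do not
depend on dict iteration order. Samples below the target depth cause an
up-front failure naming every offending sample.

## OTU clustering (`cluster`)

Distances are amino-acid p-distances (mismatches / compared positions;
positions with '-', '.' or 'X' in either sequence are excluded from the
denominator). Clustering is agglomerative complete linkage halted at the
cut-off, so the maximum intra-OTU distance never exceeds the cut-off —
the behaviour of the RDP-style distance clustering the field uses at the
0/4/8% levels. Ties in the merge queue (frequent, since p-distances on a
108-aa window are multiples of 1/108) are broken by the
lexicographically smallest pair of cluster labels, each cluster labelled
by its smallest member id; this makes partitions fully deterministic and
lets tests require *identity* with a brute-force oracle, not just
agreement up to tie order. `cluster_fragments` dereplicates identical
peptides before clustering: duplicates sit at distance zero and merge
first at any cut-off, so clustering unique sequences and re-expanding
carriers provably yields the fragment-level partition at a fraction of
the cost. Representatives are the most abundant distinct peptide per
OTU (ties: lexicographically smallest peptide, then smallest fragment
id). OTU tables order columns by decreasing total abundance.

## Diversity (`diversity`)

Shannon H′ is reported in nats (the log base is a convention; it is
recorded here and in output metadata). Chao1 uses the bias-corrected
form S_obs + F₁(F₁−1)/(2(F₂+1)), which is defined even without
doubletons and collapses to S_obs when F₁ ≤ 1. Rarefaction is the exact
hypergeometric expectation (log-gamma arithmetic, stable at depth 5217).
Coverage is declared as 100·S_obs/Chao1. Games–Howell uses
q = |Δmean|/√(SE²/2) against the studentized range with
Welch–Satterthwaite degrees of freedom (floored at 1 for degenerate
zero-variance, n = 2 groups); with k = 2 it reproduces the Welch t-test
p-value exactly, and the implementation is cross-checked against an
independent reference implementation in the test suite. Compact letter
displays use greedy insert–absorb on the pairwise p matrix.

## Community comparison (`compare`)

The fingerprint arm consumes pre-extracted lane intensity vectors (gel
image processing is out of scope): Pearson correlation as the
curve-based similarity, UPGMA on distance 1 − r with ultrametric heights
d/2 and the same lexicographic tie rule as OTU clustering, classical
Torgerson MDS (double-centering + spectral decomposition; negative
eigenvalues are truncated at zero), and a permutation test whose
statistic is mean within-group minus mean between-group similarity with
the +1-corrected p-value (never exactly zero). An optional ±1-bin
cross-correlation alignment before Pearson (off by default) approximates
gel position tolerance.

**Differential abundance.** Abundant OTUs (pooled count ≥ 8) are tested
with a two-sample t statistic on relative abundances against a label-
permutation null; sparse OTUs use a two-sided Fisher's exact test on the
pooled 2×2 table; q-values are Benjamini–Hochberg across all OTUs
(White et al.'s permutation-FDR is the obvious alternative; BH was
chosen as the standard, deterministic default). With 4 + 4 replicates a
per-OTU permutation null has only 35 distinct |t| classes — the smallest
achievable two-sided p is ≈ 0.029, which makes per-OTU p-values useless
for FDR control. The implementation therefore pools null t statistics
across OTUs whenever the smaller group has fewer than 8 replicates (the
small-sample convention for permutation-based differential-abundance
tests), and pools *leave-one-out*: the tested OTU's own permuted
statistics are excluded from its null, so a strongly differential OTU
does not inflate its own null tail (self-pooling costs ~30 percentage
points of power in our simulations). Calibration under the global null
is ~5% at α = 0.05. Known limitation: with one true effect hidden among
m null OTUs, BH demands p ≤ 0.05/m, so the power to detect a 5-fold,
5%-abundance enrichment at 4 vs 4 replicates and CV 0.3 is ≈ 80% for a
10-OTU table and decays as the table grows; this is a property of the
test under these sample sizes, not of the implementation.

**Profile network.** An OTU enters the network when its mean relative
abundance differs by more than 1% of the normalized dataset between some
pair of plants. Its profile is the "high set": plants within a factor 2
(the ratio threshold) of the top plant mean, accepted only when every
high-set mean exceeds 2× every excluded plant mean. The published rule
is stated only for pairwise ratios; this subset generalization
reproduces the shared profiles seen in multi-plant networks and is a
declared design choice. OTUs that change but admit no valid split are
kept as "unassigned-altered", so excluded ∪ assigned ∪
unassigned-altered always partitions the OTU set. The rule depends only
on relative abundances and is therefore invariant to sequencing depth.
The graph is bipartite (OTU nodes ↔ plant profile nodes) with mean
relative abundances as edge weights and Metastats q ≤ α annotations per
plant pair.

## Phylogeny (`phylo`)

Protein distances are p or Poisson-corrected (−ln(1 − p), the default; a
simplification relative to empirical substitution models, recorded in
output metadata). Neighbor joining follows Saitou–Nei with the Q
criterion, lexicographic tie-breaks on subtree labels, and the standard
branch-length formulas; negative estimates are clamped to zero and the
final three subtrees join at a trifurcating root. On additive matrices
the implementation recovers topology and path lengths exactly (the
consistency guarantee of NJ), which the tests exercise on random trees
of 5–12 taxa. Bootstrap support resamples alignment columns with
replacement, rebuilds the tree per replicate (falling back to
p-distance if a replicate saturates the Poisson correction), and maps
bipartition frequencies onto the point-estimate tree. Outgroup rooting
places the root at the midpoint of the outgroup's pendant edge and
preserves all leaf-to-leaf path distances; branch-length refitting after
consensus (the fitch step of the original PHYLIP pipeline) is replaced
by reporting NJ lengths with supports, a declared simplification.
Canonical cluster assignment takes the nearest panel reference by global
alignment identity; the outgroup never donates a cluster label, taxon
labels attach only at ≥ 95% identity, and OTUs under 1% relative
abundance are reported as not designated while keeping their internal
assignment (the display convention for phylogram annotation). Newick
output (6-significant-digit lengths, supports as internal labels) parses
and re-serializes byte-identically.

## qPCR (`qpcr`)

The standard curve is an OLS fit of Ct on log₁₀(copies), requiring ≥ 3
points spanning ≥ 2 decades, with efficiency 10^(−1/slope) − 1 and a
stored Ct range; sample Cts outside that range ± 1 cycle flag the result
as extrapolated. Copies per gram are
10^((Ct − intercept)/slope) · dilution · suspension / mass; exact
suspension and dilution factors vary per microhabitat protocol and are
left as configuration values. Replicates aggregate as the mean of
per-run log₁₀ estimates (duplicates average within run first), with a
t-based 95% half-width across runs — the aggregation order is a declared
choice. Habitat contrasts use Welch's t for two groups and Games–Howell
for more, with compact letters.

## Pipeline (`pipeline`, CLI `nifscape`)

One master seed; each stage derives its own seed as
SHA-256(seed:stage-name) mod 2³¹, so any stage reproduces independently
of which others run. The manifest records per-stage parameters and
SHA-256 checksums of every output; reruns with the same config are
byte-identical. Stage order is validated before execution, as is the
feasibility of the normalization depth against configured read depths.

## Problem sizes used in tests and the acceptance script

Simulations are sized to make each check statistically meaningful at
interactive cost: the clustering oracle covers 200 random instances of
≤ 12 fragments (where exhaustive agglomeration is cheap), NJ recovery 50
random trees, frameshift recovery 2000 reads, permutation calibration
1000 null datasets at 199 permutations each, Metastats calibration 1000
pooled null tests and power 100 simulations (10-OTU tables at the
5217-read soil depth, 2000 permutations), and the two-soil contrast one
full read-level run at 5217 reads per library plus 100 abundance-model
replicates for the ordering rate. The 100-replicate ordering check
samples taxon counts multinomially from the generator's abundance model,
which is distributionally identical to running the noiseless read
pipeline to the 0% OTU table (the read-level equivalence is asserted
separately in the pipeline tests); the read-level path is still run in
full for the reported single-run values.
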