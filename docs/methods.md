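# Methods

This note documents the models, conventions and numerical choices behind
`intertaxon`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

Intervals are 0-based half-open internally; VCF, GFF3 and human-facing
reports use 1-based inclusive positions; BED output is 0-based half-open.
FASTA IO goes through Biopython, VCF parsing through cyvcf2, GFF3 through
gffutils. Truth sets from the simulator are emitted as BED (intervals), VCF
(variants) and JSON (rearrangement events).

## Synthetic lineage generator

The generator reproduces the statistical structure the delineation analysis
assumes; it is deliberately minimal and every distribution is a configurable
stand-in, since the delineation method itself prescribes none.

* **Sequence model.** The ancestor is i.i.d. nucleotides at a target GC
  (default 0.40, a typical yeast value). A lineage evolves by a
  Binomial(L, d) number of substitutions at uniformly chosen sites, each to a
  uniformly chosen different base; no indels, so lineages stay
  coordinate-matched until rearrangements are applied. Back-mutation is
  allowed: two branches at per-branch fractions p and q differ at an expected
  fraction p + q − (4/3)pq, i.e. ≈ 6.84% realized for p = q = 3.5%, a <2%
  relative deflation accepted by the tests. No recombination, selection or
  coalescent demography is modelled — recovery results say nothing about
  estimator behaviour under linkage or skewed genealogies.
* **Default conditions.** Branch divergence 3.5% (≈7% pairwise, the
  sister-species scale), introgression tracts in the 2–79 kb range,
  mean coverage 30× (within the 20–40× regime) with per-window Poisson
  noise, crosses of 96 dissected spores, logistic growth sampled every 0.5 h.
* **Rearrangements.** Reciprocal translocation swaps terminal segments of
  two chromosomes; non-reciprocal translocation moves an internal segment
  one-way; inversion reverse-complements an interval; deletion removes one.
  Base count is conserved except by deletions. Truth records old and new
  coordinates.
* **Spore-viability model.** Expected viability = v₀ · e^(−α·d) · 0.5^s,
  with v₀ = 90% (healthy intraspecies baseline), α = 39 per unit divergence
  and s the number of heterozygous reciprocal translocations. α was set once
  so that viability falls from ~90% at d = 0 to ~6% at d = 0.07, matching
  the contrast between intraspecies and interspecies crosses; the 0.5^s
  factor is the classical 50% loss of balanced meiotic products per
  heterozygous reciprocal translocation. Observed counts are
  Binomial(n, expected/100).
* **Randomness.** Every operation draws from
  `default_rng([seed, crc32(operation), ordinal])`, so a stage can be rerun
  in isolation and a whole dataset is byte-reproducible from one integer.

## OANI

Fragments are consecutive, non-overlapping 1020-bp windows per chromosome
(remainder dropped) — the fragment convention of orthology-based ANI.
Candidate subjects are prefiltered by shared 15-mers (either strand); each
query fragment is aligned with edlib against the best candidates and the
maximal-identity subject passing a 0.35 query-coverage filter is its best
hit, ties breaking to the lower subject index. Orthologous pairs are
reciprocal best hits; OANI = 100 × mean over pairs of the symmetrised
identity (mean of the two directional identities), which makes
OANI(A,B) = OANI(B,A) exact.

Identity is matches / alignment columns, gap columns included. The query is
aligned as an infix of the subject fragment *plus one fragment length of
flanking genomic context* (edlib HW mode). This local-style alignment is the
one numerically consequential choice: rearrangement breakpoints shift the
fragment grid out of phase between two genomes, and a strict
fragment-vs-fragment global alignment then understates identity by several
points on translocated chromosomes, while infix alignment against padded
context is phase-insensitive. A brute-force all-vs-all global path (no
prefilter, no context) is retained and tested as the oracle for reciprocal
pairing on small genomes.

At 7% pairwise divergence the procedure yields OANI ≈ 93.2%; identity
tracks 1 − d closely because the mutation model has no indels. Zone calls
use the 95–96% band inclusively: < 95 distinct, > 96 conspecific, otherwise
ambiguous. Zero orthologous pairs raises an error rather than reporting 0.

## Population genetics

Genotypes are alt-allele dosage per sample; diploid genotypes collapse to
allele counts (0/1 het contributes one of two alleles) and frequencies count
haplotypes. π uses the unbiased per-site form Σ 2p(1−p)·n/(n−1)/L, which
equals the mean pairwise difference exactly; θ_w = S/(a_n·L). F_ST is the
Hudson-style ratio of averages,
N = (p_a−p_b)² − p_a(1−p_a)/(n_a−1) − p_b(1−p_b)/(n_b−1) over
D = p_a(1−p_b) + p_b(1−p_a), summed before dividing; the estimator name is
carried in the result because different packages default to different
estimators and the choice matters at these divergences. Sites with D = 0
are uninformative and skipped; fixed differences give exactly 1.

Variant filtering follows the strict conventions: per-genotype depth > 10,
site QUAL ≥ 30, no missing genotypes. Thinning is the greedy first-kept
scan (keep a site if ≥ spacing from the last kept site), which is idempotent.

Divergence time: N_θ = d/(2μ) generations, μ default 1.84 × 10⁻¹⁰. The
conversion to years divides by a generations-per-year range, default
[164, 1870] (≈0.45–5.1 generations/day) — a reverse-engineered bracket for
wild yeast turnover, exposed as a parameter and never treated as data.
Whether d should be net pairwise divergence or a Watterson-scale θ is
genuinely ambiguous in the source analyses; the function takes the pairwise
divergence fraction and documents that choice. The neighbor-joining utility
delegates to scikit-bio and recovers additive matrices exactly.

## Introgression scan

Windows tile every reference position exactly once (terminal window may be
short); a 1-based SNP at p belongs to window ⌊(p−1)/w⌋, so position 1000
falls in the first 1-kb window. Flagging is snp_count ≤ 0 (exact zero by
default) AND coverage strictly > 20×. Consecutive flagged windows merge
(gap bridging off by default); tracts must reach 2 kb — the floor inferred
from the smallest reported real signal — and contain at least one full-width
window, so a lone short terminal window never becomes a tract. At the
simulated coverage regime (Poisson mean 30× per kb) the coverage filter is
effectively always passed inside real tracts, and at ≥2% divergence the
probability of a false zero-SNP window is (1−d)^1000 < 10⁻⁸, which the
10-seed clean-control test exercises.

## Structural variants

The caller consumes alignment blocks (9-column TSV, 1-based inclusive), not
raw assemblies, so any aligner can feed it; a built-in anchor aligner keeps
the pipeline self-contained: k-mers (k = 21) unique in both genomes are
matched (both strands) and chained while reference chromosome, strand and
diagonal (ref−query for +, ref+query for −) stay within a 100-bp tolerance
and query gaps stay under 2 kb; chains shorter than 200 bp or with fewer
than 2 anchors are discarded, and block identity is estimated from sampled
500-bp alignments.

Classification per query contig: the primary reference chromosome is the
majority of aligned bases; maximal runs on non-primary chromosomes are
translocations (size = reference span); mirrored translocation pairs
(segment of A on the B-contig and vice versa) are linked as reciprocal, the
rest labelled non-reciprocal. Inversions are embedded runs of the minority
strand — minority decided by run count, not span, since a genuine inversion
can exceed half its chromosome. Adjacent same-chromosome blocks with a
reference gap ≥ 50 bp and query gap < 200 bp are deletions (converse:
insertions); deletions/insertions whose interval is explained by a
translocated segment are suppressed as moves, not losses. Duplications are
two disjoint query intervals with ≥ 0.9 reciprocal overlap on one reference
interval. The 200-bp gap tolerance absorbs breakpoint fuzz from anchor
sparsity; recovered event sizes are accurate to that order. Downstream
filtering keeps events strictly > 1 kb and drops calls overlapping
user-supplied exclusion intervals (rDNA coordinates are genome-specific and
must be provided). Gene annotation counts ≥1-bp overlaps with GFF3 gene
features.

## Crosses and phenotype

Viability percentages carry exact Clopper–Pearson 95% intervals (reported,
not used for classification). Classification thresholds default to
< 20% reproductively isolated and > 50% compatible — derived from the
observed contrast between interspecies (~5–6%) and intraspecies (50–81%)
crosses, and configurable. The regression of viability on nucleotide
identity (percent) is ordinary least squares with adjusted
R² = 1 − (1−R²)(n−1)/(n−2) and a two-sided t test on the slope; a flat
response is reported as slope 0, R² 0, p 1 rather than NaN.

Growth curves are fitted to N(t) = K/(1 + ((K−N0)/N0)e^(−rt)) by
least squares (positivity bounds, data-driven start values); the AUC is the
closed-form integral over the observation window, computed in a log1p form
stable for large rt. Non-growing or non-converging curves fall back to the
trapezoidal empirical AUC with a provenance flag. Cells of the phenotype
matrix are replicate means; z-scoring is per condition with sample SD
(ddof = 1) and refuses zero-variance columns by name. Clustering is
average-linkage Euclidean on rows pre-sorted by strain id for deterministic
tie-breaking; ANOVA is the standard one-way F with compact letters from
Holm-corrected pairwise Welch tests (a deliberate choice — the post-hoc
behind published letter displays is often unstated; Welch avoids assuming
equal variances).

## Verdict integration

The report applies a fixed rule table (documented in `intertaxon.report`)
rather than a weighted score: the OANI zone is the primary criterion,
viability class the confirming one, and phenotype/SV/introgression evidence
only corroborates. Conflicting evidence (e.g. distinct-zone OANI with
viable spores) yields "ambiguous" — the table never guesses. This makes the
verdict monotone: improving OANI or viability can never flip a conspecific
call to distinct, a property the tests check over a grid.

## Problem sizes

Tests and the acceptance script run on reduced scales chosen to preserve the
statistics being checked: 500-kb single-chromosome genomes for the
OANI–divergence correspondence (≈490 fragments, binomial SE on OANI well
under 0.1 point), 6 × 80-kb chromosomes for the five-event rearrangement
architecture (a 1/10-scale version of the real event sizes), 120-kb
chromosomes for the 70/49/19-kb introgression set, and a 2 × 60–150-kb
genome for the end-to-end pipeline. These sizes keep the full suite under a
minute while leaving every detection margin (window counts, anchor
densities, fragment counts) far from its breaking point.

## Known limitations

* The mutation model's uniform substitutions make alignment identity ≈ 1 − d;
  real genomes with indels and rate heterogeneity will show OANI a little
  lower at the same SNP divergence, so absolute OANI values from real
  assemblies are not promised to match simulated ones — only the band logic.
* The anchor aligner assumes mostly-unique k-mers; highly repetitive genomes
  need an external aligner's blocks instead.
* Fragment pairs, not synteny, define orthology; segmental duplications can
  pair paralogously (the reciprocal-best rule keeps each fragment in at most
  one pair, limiting the damage).
* The viability model treats only reciprocal translocations as mechanical
  viability halvers; real non-reciprocal events and inversion heterozygosity
  also depress fertility.
* Year conversions of divergence times inherit the full uncertainty of the
  generations-per-year bracket; only the generation count is a measurement.
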