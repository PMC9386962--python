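# Methods

## Statistical model and estimators

### Alignment statistics

All alignment statistics use *complete deletion*: any column containing
a gap (`-`) or a base outside A/C/G/T is removed first, and the
effective length L_eff reflects that. This is deterministic, matches
common alignment-tool defaults, and suits inputs that are trimmed to
clean blocks; the alternative (pairwise deletion) would make π and S
depend on different site sets.

- **Segregating sites S** — retained columns with ≥ 2 distinct bases.
  A column with 3+ alleles counts once toward S; pairwise differences
  are still counted per pair regardless of allele identity.
- **Nucleotide diversity** — k̄ is the mean pairwise difference count
  over all C(n,2) sequence pairs, computed column-wise from allele
  counts (per column, discordant pairs = C(n,2) − Σ_allele C(c_a,2)),
  which is integer arithmetic and exactly equals pair enumeration;
  π = k̄ / L_eff.
- **Watterson's θ_W** = S / (a₁ L) with a₁ = Σ_{i<n} 1/i.
- **Tajima's D** = (k̄ − S/a₁) / √(e₁S + e₂S(S−1)) with the standard
  normalising constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ computed from n.
  When S = 0 the statistic is undefined and reported as missing (NaN),
  never as 0 — zero is a meaningful value (π-based and S-based
  estimates in balance). Note that for n ≤ 3 the variance term is
  identically zero, so D is only defined for n ≥ 4.

### Windowed Tajima's D over genotypes

Windows are non-overlapping by default (step = window size, default
30,000 bp); a sliding step is configurable but the non-overlapping
reading is the simplest reproducible one and avoids pseudo-replication.
Within a window and population, genotypes are treated as allele counts
(heterozygote phase never affects the alternate-allele count j), with
n_chr = 2 × called individuals per site: S counts sites with
0 < j < n_chr and the pairwise-difference sum adds
2j(n_chr − j)/(n_chr(n_chr − 1)) per site. D's constants need a single
n; the per-window modal n_chr is used, which is exact when genotypes
are fully called (the generator's default) and a mild approximation
under missingness. Every window up to the contig end is reported;
S = 0 windows carry a missing D.

### Per-site F_ST and π

The two-population Weir–Cockerham variance components are

    n̄  = (n₁+n₂)/2                       n_c = Σnᵢ − Σnᵢ²/Σnᵢ
    p̄  = Σnᵢpᵢ/(2n̄)                      s²  = Σnᵢ(pᵢ−p̄)²/n̄
    h̄  = Σnᵢhᵢ/(2n̄)
    a  = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
    b  = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄)]
    c  = h̄/2

with pᵢ the per-population reference-allele frequency and hᵢ the
*observed* heterozygosity from genotype counts (required by the
individual-level estimator; a Hardy–Weinberg expectation would change b
and c). F̂_ST = a/(a+b+c); a globally monomorphic site has a+b+c = 0 and
a missing estimate. Negative estimates are reported as computed:
clamping at zero would bias per-gene averages upward.

Per-population per-site diversity is the unbiased heterozygosity
2j(n_chr−j)/(n_chr(n_chr−1)) — exactly the mean pairwise difference
among the 2N haplotypes implied by the genotypes.

## Filters

- **Hard filter** — remove iff DP < 10 OR QD < 5 OR MQ < 40 OR SOR > 3.
  The inequalities are strict (the removal condition is what is
  specified, not the retention condition), so DP = 10, QD = 5, MQ = 40
  and SOR = 3 all pass. A record missing an annotation fails that
  field's check (an unannotated site cannot be shown to pass). All
  violated conditions are reported as reasons; the removal ledger counts
  each record once under its full reason set, so ledger counts sum to
  the input count.
- **MAC filter** — retain iff min(alt, total − alt) ≥ 8, counted over
  called genotypes of both populations combined; the boundary (MAC
  exactly 8) is retained. Records with no called genotype are dropped
  with a logged reason.
- The two filters each depend only on the record, so they commute; the
  pipeline applies hard-then-MAC but the order is immaterial (verified
  by a property test).

## Gene-level outlier scan

Sites (1-based) are assigned to BED intervals (0-based half-open):
position p belongs to [start, end) iff start ≤ p−1 < end. A site inside
two overlapping genes contributes to both — without a transcript-aware
annotation there is no principled way to pick one. Sites in no interval
are dropped from the scan and counted.

Per gene: mean F_ST over non-missing per-site values (negatives
included; a gene with all-missing F_ST is ineligible for that decile);
mean π per population over **all** assigned sites, including sites
monomorphic within one population (π = 0) — excluding those would
inflate the monomorphic population's apparent diversity; and
R = −log₁₀(π̄_HA/π̄_LA).

**Ratio sentinels.** π̄_LA = 0 makes R undefined — the gene is
ineligible for the ratio decile (the ratio carries no information).
π̄_HA = 0 with π̄_LA > 0 gives R = +∞, ranked above every finite value:
zero HA diversity is the strongest possible signal.

**Decile rule.** "Top 10%" is implemented as a rank cut: with N
eligible genes, k = ⌈(1−q)·N⌉ (q = 0.90 by default), the threshold is
the k-th largest eligible value, and every eligible value ≥ threshold is
flagged — so ties at the threshold are all included and 20 distinct
values yield exactly 2 flags. This interpolation-free rule is
deterministic and treats ties symmetrically; quantile interpolation
would flag fractional genes and break the exhaustive-enumeration
cross-check.

**Stage order.** (1) both decile flags; (2) half-diversity:
π̄_HA ≤ 0.5·π̄_LA, boundary passing; (3) minimum SNP count:
n_snps ≥ 5, a gene with exactly 5 passing. Deciles are computed over
all genes with ≥ 1 retained SNP and the SNP-count filter comes last, so
the dual-decile survivor count is comparable before and after it. The
final candidate list is sorted by mean F_ST descending, then gene id
(a presentation choice; the candidate *set* is what matters).

## Synthetic-data generator

The genotype simulator emulates the sampling design the scan assumes:
two diploid cohorts (HA, LA; 20 + 20 by default), per-gene SNP clusters
(k ~ max(1, Poisson(10)) sites per gene — SNP density in real
transcriptome panels varies widely, and 10 per gene keeps per-gene
averages meaningful while leaving a realistic minority of genes below
the 5-SNP floor), and allele frequencies under the Balding–Nichols
model: ancestral p ~ Uniform(0.05, 0.95), then per population
p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so E[p_pop] = p and the expected
Weir–Cockerham F_ST is ≈ F. Neutral genes use F = 0.05; a 5% fraction
of genes is "selected" and uses F = 0.5, plus a fixation push of the HA
frequency

    p_HA ← 1 − (1 − p_HA)^(1/d)   if p_HA > 0.5
    p_HA ← p_HA^(1/d)             otherwise

with d = ha_diversity_factor = 0.3: the exponent 1/d > 1 shrinks the
distance to the nearer boundary, monotonically depressing expected HA
heterozygosity (d = 1 is the identity). This is a cheap monotone
surrogate for a selective sweep, not a sweep simulator: it produces the
joint elevated-F_ST / depressed-HA-π signature without linkage,
hitchhiking or allele-frequency trajectories.

Genotypes are Binomial(2, p_pop) per individual, fully called by
default (a missingness option exists, default 0). Site annotations
straddle the hard-filter thresholds: passing values are drawn uniform
within the passing range, 5% of passing draws per field sit exactly on
the boundary (DP = 10, QD = 5, MQ = 40, SOR = 3), and with probability
4 × 5% a record is made to violate exactly one field (including
near-boundary violators such as DP = 9 and SOR = 3.01), so the filter's
inequality semantics are pinned by data. Output is VCF 4.2 (one contig
per gene, 1-based positions, unphased 0/0‑0/1‑1/1 genotypes,
DP/QD/MQ/SOR as INFO floats), a 4-column BED (0-based half-open), a
sample→population table and a per-gene truth table. Identical config
and seed give byte-identical files.

The neutral-alignment generator drops S ~ Poisson(θ·L·a₁(n))
segregating sites onto distinct columns, derived-allele counts i drawn
with probability ∝ 1/i (the neutral frequency spectrum) and carriers
chosen uniformly; E[θ̂_W] = θ by construction, which the calibration
test exploits. If the Poisson draw exceeds L it is capped at L with a
warning (only reachable at unrealistically high θ·L).

### What the generator does and does not show

Passing tests on these data demonstrate estimator correctness, filter
semantics and the scan's ranking logic under an exchangeable-F model
with free recombination (every SNP independent). They do not
demonstrate performance on real data, which has linkage, shared
demographic history, genotyping error correlated with coverage, and
transcriptome-specific ascertainment. One interaction matters even
in simulation: at strongly differentiated genes (F = 0.5) the Beta
distribution is U-shaped, so both populations are often near-fixed —
for the *same* allele once the HA push is applied — and such sites fail
the combined MAC ≥ 8 filter. Selected genes therefore retain a mean of
only ≈ 3.5 of their ≈ 10 simulated SNPs, and many fall under the 5-SNP
floor: at the default configuration the scan recovers selected genes
with precision ≈ 1.0 but sensitivity ≈ 0.3–0.4 (both measured by
`scripts/acceptance.py`). This is a real property of MAC-filtered
outlier scans — near-fixed differences are exactly the sites a MAC
filter discards — and the truth table plus stage ledger make the
attrition visible rather than hiding it.

## Numerical choices and degenerate inputs

- Tajima's D with S = 0 → NaN, with the reason logged. n < 2 → error.
- Empty VCF body → empty record list (valid); a VCF sample absent from
  the population table → error naming the sample; multi-allelic records
  are dropped with a logged count (the scan is defined on biallelic
  SNPs; splitting would create artificial sites).
- F_ST with an uncalled population → error; globally monomorphic →
  missing with zero components.
- Fewer eligible genes than 1/(1−q) → decile thresholds still computed,
  with a degenerate-decile warning.
- BED parsing rejects malformed lines with their line number; negative
  or empty intervals are malformed.
- All package randomness flows through `numpy.random.default_rng`
  seeded from the single configured seed; the pipeline driver hashes
  every output (SHA-256 manifest) so end-to-end determinism is
  checkable byte-for-byte.

## Problem sizes

The test suite and the acceptance script use 1,000-gene simulations
(≈ 10,000 SNPs, 40 diploids) for recovery measurements, 500 replicates
for the Watterson calibration, and exhaustive enumeration up to
n_chr = 12 / alignments of n ≤ 8, L ≤ 50 for oracle-equivalence checks
— sizes at which brute-force oracles are exact and the full suite runs
in well under a minute on one core.

## Known limitations

- No coalescent machinery: no linkage, recombination, demography or
  selection dynamics in the generator; independence across SNPs is a
  best-case regime for the scan's ranking.
- Windowed D under heavy missingness approximates n by the modal
  per-site chromosome count.
- The scan's decile thresholds are in-sample ranks, not outlier tests
  against a null distribution; candidate lists are enrichment
  hypotheses, not significance calls.
- Tajima's D significance is out of scope (no beta-distribution
  approximation of its null).
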