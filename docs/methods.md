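# Methods

This note records the models, conventions and design choices behind each
module, what the synthetic-data generators emulate, and the limits of what
passing tests demonstrate.

## Statistical kernel (`stats`)

All stage verdicts route through one small set of primitives so their
contracts are tested once:

* **Welch's t** (unequal variances, Welch–Satterthwaite df). Degenerate
  contract: two zero-variance samples give p = 1 when means agree and p = 0
  otherwise — this is what makes the zero-noise recovery tests exact rather
  than undefined. The vectorized row-wise form applies the same contract.
* **Benjamini–Hochberg** step-up, input order preserved, capped at 1.
  BH is *not* idempotent in general (re-adjusting an adjusted vector can
  raise values further); the tested invariants are the true ones: never
  lowers a p-value, monotone in the rank order of the raw values.
* **Spearman** with average ranks; p from the t-approximation for n ≥ 10
  and full permutation enumeration below (exact enumeration is cheap at
  n ≤ 9, and small-n cross-species comparisons are where the approximation
  is worst). Constant input is flagged degenerate (ρ undefined, p = 1).
* **Exact binomial** tail tests; p₀ must lie strictly inside (0, 1) —
  callers floor/cap (see TE enrichment).
* **2×2 chi-square**: Pearson, 1 df, no continuity correction. Genomic
  contingency tables here have hundreds of counts per margin, where the
  correction is needlessly conservative and uncommon in practice.
* **Mann–Whitney U**: exact enumeration when combined n ≤ 20 and tie-free,
  otherwise the tie-corrected normal approximation; threshold configurable.
* **Two-way ANOVA** with type-II sums of squares (statsmodels OLS). Designs
  in this package are near-balanced, so the SS-type choice is low-impact;
  type II avoids order dependence. An empty cell degrades to an additive
  fit with the interaction flagged undefined.

## Paralog specialization (`paralogs`)

* Pairs where either gene has > 20 paralog partners are removed before any
  analysis — large interconnected families inflate pairwise counts.
* Age bins: very ancient > 473.3 My, ancient 111–473.3 My (upper boundary
  inclusive), recent/very recent ≤ 111 My (111 itself falls here). The
  boundaries are arguments everywhere.
* The built-in differential engine is a pluggable stand-in: per-gene Welch
  tests on log2(normalized + 0.5) per diapause×development contrast, BH
  across genes within each contrast. Any external table with the same
  schema (gene, contrast, log2_fold_change, padj) produces byte-identical
  downstream calls; count-model engines can be substituted that way.
* Specialization rule: one gene significantly up in ≥ 1 contrast, the
  partner significantly down in ≥ 1 contrast (any contrast, not necessarily
  the same one) *or* with development median > diapause median, pooled over
  all samples of each phase. If both genes qualify as diapause-up the pair
  is not specialized — specialization means opposing roles. The strict
  variant drops the median clause; the mouse variant requires up/down
  versus **both** development stages.
* Enrichment bootstrap: subsampling 50% of pairs *without* replacement,
  10,000 draws. Because the four strata counts of a draw follow a
  multivariate hypergeometric distribution, draws are sampled from it
  directly — exactly equivalent to index subsampling and orders of
  magnitude faster. With-replacement resampling sits behind a flag.
* The chi-square table is (specialized yes/no) × (in bin yes/no) counted
  over pairs.
* Same-/different-chromosome comparison: pairs with either gene on an
  unplaced scaffold are excluded; the association between specialization
  and co-location is tested with a 2×2 chi-square (Fisher's exact when a
  cell is empty). A rank test on binary labels is not well formed, so a
  contingency test is the package's choice for this comparison.

## Peak conservation (`peaks`)

* All coordinates are 0-based half-open (BED) internally and in files.
* The alignment block map stores equal-length gapless focal↔target interval
  pairs; minus-strand blocks reverse coordinates. Projection clips to block
  intersections; fragments adjacent on the target (gap 0) are merged, and
  *split* means genuinely disjoint target loci. A MAF reader flattens
  alignments to such blocks by cutting at every gap column.
* Stringencies: relaxed = ≥ 1 bp overlap; strict = ≥ 25% and very strict =
  ≥ 50% of the focal peak covered by the **union** of that species'
  projected peaks; boundaries inclusive; coverage is of the focal peak only
  (not reciprocal).
* Categories: focal-only → very recent; + African killifish → recent;
  + outgroup → ancient/very ancient. A peak shared with an outgroup but no
  other African killifish also goes to ancient/very ancient: outgroup
  presence rules out a focal-lineage innovation regardless of African
  losses. Sequence conservation reuses the category logic with "conserved"
  meaning an aligned block exists.
* Diapause-specific peaks: up-significant in ≥ 1 diapause contrast by ≥ 1
  of the two methods AND non-significant in the development contrast under
  **both** methods (a flag flips the development clause to ≥ 1).
* Nearest-gene assignment measures the distance from the peak to each TSS
  (0 if the TSS is inside the peak); ties break by smaller gene start then
  lexicographic id, so runs are reproducible. Region annotation has
  precedence promoter > exon > intron > distal intergenic with a
  strand-aware promoter window, default (−2000, +500) around the TSS.

## Motif conservation (`motifs`)

* Scores are natural-log odds against a uniform 0.25 background with a
  0.001 probability floor per cell (prevents −∞ at near-degenerate
  positions, mirroring common motif-tool practice). Detection thresholds
  are stored per motif file and never re-derived.
* Windows containing N are non-scorable. Scanning reports every
  above-threshold offset on both strands; minus-strand hits record the
  plus-strand left edge and the reverse-complement match.
* Cross-species assessment: the hit interval is projected per species; a
  split or absent projection is ALIGNMENT_ABSENT (no realignment engine is
  in scope). Aligned sequences are reverse-complemented for minus-strand
  blocks before scoring. Sub-threshold aligned sites with an identical
  above-threshold motif within ±100 bp (configurable; the biologically
  right window is genuinely uncertain) are EXCLUDED_NEARBY.
* Conservation fractions use CONSERVED / (CONSERVED + NOT_CONSERVED):
  excluded and unaligned sites are neither wins nor losses. A flag reports
  the stricter convention that counts exclusions in the denominator, and
  both a per-species unweighted average and a pooled fraction are returned.
* Origin: TE-derived iff ≥ 1 bp TE overlap; sharing: shared iff conserved
  in ≥ 1 non-focal species. The per-species four-way TE/motif
  co-conservation uses TE presence at the aligned locus and the site's
  conservation verdict.

## TE enrichment (`te`)

* Backgrounds: genome (base-pair fraction covered by the family, copies
  merged), all accessible chromatin, or size-matched control loci shifted
  10 kb downstream (increasing coordinates — peaks are unstranded; the
  offset and its sign are configurable). Control loci running past the
  chromosome end are dropped with a warning.
* Rates for interval backgrounds are region-level (fraction of intervals
  with ≥ 1 bp overlap) to match the count-based binomial on target regions;
  the base-pair mode exists for the genome background.
* Background rates are floored into (0, 1) by 1/(10·n_background) so the
  binomial stays defined; floored rows are flagged and excluded from
  headline summaries.
* Two one-sided exact binomials are computed; the reported p is
  min(1, 2·min(p_greater, p_less)) — the Bonferroni combination of the two
  one-sided tests, a valid two-sided p — with direction carried by the fold.
  Reporting the raw smaller one-sided p would double the type-I error and
  break the null calibration the tests enforce. BH runs across families
  within a background.

## Knockout analysis (`ko`)

* DEGs require FDR < 0.1 against **both** controls with concordant
  fold-change sign (discordant double-significance is almost surely
  artifact). BH stands in for covariate-weighted multiple-testing
  correction — no covariate model is in scope, and the DEG-set logic under
  test does not depend on the weighting scheme.
* Program shift: Spearman of knockout-vs-control diapause fold changes
  against control diapause-vs-development fold changes over the DEG set
  (intersection; a flag widens to the union). p ≥ α → NO_EFFECT, else the
  sign of ρ gives ENHANCED/REVERSED.
* Specialization shift: per specialized pair and genotype, the median log2
  expression of the diapause-role and development-role genes enters a
  role × genotype two-way ANOVA; the interaction term is the reported test
  of whether the specialization gap changes under knockout.

## Lipidomics (`lipids`)

* Names parse as `CLASS(c1:d1/…)`; a single `c:d` token is summed notation
  kept as one pseudo-chain, excluded from per-FA composition and from
  very-long-chain calls (undetermined rather than guessed). `O-`/`P-`
  prefixes are chain attributes.
* Median normalization: factor = grand median of per-sample medians over
  non-TG/DG lipids ÷ the sample's own such median, applied to **all**
  lipids (TG/DG are excluded only from the factor). Idempotent; the
  post-condition (equal non-excluded medians) is asserted in tests.
* Classification: Welch tests on log concentrations (lipid intensities are
  multiplicative, so t-assumptions hold on the log scale) for all four
  diapause×development pairs plus the development pair, BH across lipids
  within each comparison. Diapause-specific = significant in ≥ 1
  diapause-vs-development pair with a consistent direction across all
  significant pairs AND a non-significant development pair; a strict mode
  requires all four pairs.
* Very-long-chain = any resolved chain ≥ 22 carbons. SFA/MUFA/PUFA = 0, 1,
  ≥ 2 double bonds. FA composition weights each chain occurrence by its
  parent lipid's molar concentration; fractions sum to 1 per sample and are
  scale-invariant.

## Synthetic universes (`simulate`)

Every generator takes one explicit seed, draws from a single RNG, and
reproduces byte-identical outputs. Planted fractions are deterministic
quotas (exact counts, RNG-chosen membership) so small-n recovery is exact;
`stochastic=True` switches to Bernoulli draws for calibration studies.

Study-scale defaults, chosen to mirror the data the pipeline is built for:
five expression conditions (two development stages, three diapause
timepoints), three replicates each; log-normal expression noise on
normalized values (the classifiers consume normalized quantities, so
count-level simulation adds nothing to the logic under test); a five-species
peak universe (one focal, two African killifish, two outgroups); knockout
designs with ≥ 3 embryos per genotype×state and control programs of SD 2
log2 units; lipid tables of 431 species across 14 classes with 350 planted
diapause-specific lipids, fold change 2, CV 0.2, 4 samples per condition.

What the generators do **not** emulate: read-level noise and mapping bias,
count overdispersion, correlated replicates, assembly and alignment error,
TE nesting/fragmentation, incomplete lipid annotation, batch effects.
Passing recovery tests therefore demonstrates the correctness of the
decision logic and statistics under their stated models — not robustness to
these real-data pathologies, which enter upstream of this package's inputs.

## Problem sizes and numerical conventions

Recovery and calibration runs use 1,000–5,000 entities per universe and
100–1,000 replicates per calibration, sizes at which the quantities under
test have comfortably converged while a full validation pass stays within a
few minutes on one CPU. Tolerances: exact assertions for quota recovery and
truth tables; 1e-9 for scoring oracles; 2% for bootstrap-vs-full ratios;
binomial-width bands for calibration rates. Ties and degenerate inputs are
handled by explicit documented contracts (deterministic tie-breaks, flagged
degenerate results) rather than silent NaNs.
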