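# Methods

This note documents the models implemented in `deepeye`, the parameter
defaults and why they were chosen, the numerical details that matter for
reproducing results, and the limits of what the synthetic-data tests can
show.

## Synthetic data

The generator reproduces the *statistical structure* the analyses assume,
not sequence evolution.

**Structured panels (Balding–Nichols).** Per site, an ancestral frequency
p is drawn uniformly from `ancestral_af_range` (default 0.05–0.95); each
species' frequency is Beta-distributed with mean p and variance
p(1−p)·F_ST (shape parameters p(1−F)/F and (1−p)(1−F)/F); haplotype
alleles are independent Bernoulli draws. F_ST = 0 short-circuits to the
ancestral frequency exactly. Sites are unlinked — linkage exists only
where a sweep is implanted — so kinship estimated from these panels
captures drift structure without LD confounding. The canonical
association-study condition is 3 species × 20 diploids, 5,000 sites on a
5-Mb chromosome, F_ST = 0.1, loosely emulating a multi-species panel of
moderate differentiation. Positions are uniform without replacement,
sorted; chromosomes receive sites proportional to length
(multinomially).

**Sweeps.** `implant_sweep` copies one donor haplotype (a random
derived-allele carrier at the core) into ⌈carrier_fraction · n⌉ target
haplotypes, each copy truncated at an independently drawn exponential
breakpoint on each side of the core (mean `decay_length`, the continuous
limit of the geometric model). Outside the copied segment the original
haplotype is retained; other populations are untouched; the core derived
frequency in the target therefore reaches at least the carrier fraction.
This is the simplest generative model with a controllable
extended-homozygosity footprint; `decay_length` (default 50 kb) is its one
knob.

**Traits.** y = Σ βⱼxⱼ + g + e with diploid dosages x,
g ~ MVN(0, σ_g²K) drawn through a Cholesky factor of the supplied kinship
(jitter 10⁻¹⁰·tr(K)/n), and iid residuals. Brownian traits on a tree are
MVN(0, σ²C_λ) with C the shared-branch-length matrix and C_λ the
off-diagonal-scaled version.

**Gene models.** Non-overlapping genes (3–8 kb, three CDS exons, a 500-bp
3′ UTR at the 3′ end, 5-kb flanks) are placed in evenly spaced slots with
random jitter. SNP labels follow position: CDS → missense or synonymous
(configurable ratio, default 0.5); intron, with `splice-region&intron`
within 3 bp of a CDS edge; 3′ UTR; upstream/downstream within the flank by
strand; otherwise intergenic. A SNP may carry labels from several genes.

**Depths and counts.** Depths are Gaussian around per-sample means
(scale 0 allowed: depths equal the mean exactly), doubled at planted
duplication sites; the stated per-sample moments are attached as the
genome-wide moments so planted anomalies score deterministically
(z ≈ mean/sd). Counts are NB with per-gene lognormal baselines, group
means shifted by 2^log2FC, and designated opsin genes whose means are set
proportional to configured TPM shares (times CDS length/1000, so the
share survives length normalization).

**Seeds.** Every operation is a pure function of its spec and seed; a
bundle derives stage seeds from one global seed by fixed offsets
(`SEED_OFFSETS`), so any stage can be rerun independently.

## Variant QC

The depth-deviation score is the signed mean per-sample z-score of the
focal site's depth against that sample's genome-wide mean and SD. Signed
(not absolute) is the default because the target is *excess* depth from
collapsed duplications, and only the upper tail (> 1.5, strict) filters;
an absolute variant sits behind `dd_absolute`. Allele balance pools
ref/alt reads across heterozygotes and applies an exact two-sided binomial
test against 0.5; no heterozygotes means the rule is skipped for that
site. Strand-bias and excess-heterozygosity statistics are consumed as
per-site INFO fields — they originate inside the variant caller and
cannot be recomputed without alignments. All threshold comparisons are
strict in the stated direction (fail iff MQ < 50.0, etc.), and only
biallelic SNPs pass. Loosening any threshold can only retain more sites
(tested as a monotonicity property).

## Distances and trees

Pairwise distance is the allele-sharing distance on dosages,
dᵢⱼ = mean over jointly non-missing sites of |gᵢ−gⱼ|/2 — normalized
per site so windowed averages are on a common scale. NJ is the standard
Saitou–Nei algorithm with Q-criterion; ties break by scan order (first
minimum), so results are deterministic. Negative branch lengths are
clamped to zero with the deficit moved to the sister edge; the raw length
is kept on each node (`raw_length`). Exactness on additive inputs is
verified against scikit-bio's NJ and on 100 random trees (path-distance
error ≤ 10⁻⁹).

Window bootstrap: per-window difference sums and jointly-non-missing
counts are precomputed; a replicate draws windows with replacement and
forms the count-weighted average distance matrix — weighting prevents
sparse windows from dominating. Support of an internal edge is the
fraction of replicate NJ trees containing its bipartition. The replicate
count is configurable (default 100, a common choice where none is
dictated). Rooting places the root at the midpoint of the outgroup's
pendant edge.

The distance-versus-trait regression uses all unordered pairs and reports
the nominal OLS p-value; pairs are not independent and no correction is
applied — the quantity is a descriptive effect size (R²), as commonly
used.

## Pagel's λ

λ ∈ [0, 1] multiplies the off-diagonal entries of the Brownian covariance
C; μ and σ² are profiled in closed form by GLS through a Cholesky factor
of C_λ (jitter 10⁻¹⁰·tr(C)/n on failure). Optimization is a 101-point
grid plus golden-section refinement; the reported optimum is also checked
against λ = 0, 1 and the best grid point, so logLik(λ̂) ≥ max over the
grid. ML (not REML) matches the common default; the estimate is invariant
to affine trait transformations. The upper bound is fixed at 1.0 so C_λ
stays positive definite for non-ultrametric trees. Star trees make the
likelihood flat in λ; the result is flagged. Recovery behavior at the
canonical condition (100-tip random trees): median λ̂ = 1 under Brownian
simulation, ≈ 0 after tip permutation.

## Mixed-model association

The model is y = Wα + xβ + u + ε, u ~ N(0, vr·τ⁻¹K), ε ~ N(0, τ⁻¹I),
W an intercept, K the centered relatedness matrix X_cX_cᵀ/p (missing
dosages mean-imputed, consistent with an imputed callset). K is
eigendecomposed once; y, the intercept and all SNP columns are rotated
into the eigenbasis, making each variance ratio a diagonal weighted
least-squares problem with closed-form profile ML. Two numerical details
matter:

- **The intercept must be rotated too** (U′1): the centered K has an
  exact zero eigenvalue whose eigenvector is the constant vector, so the
  rotated intercept lives entirely in that coordinate. Treating the
  intercept as a constant vector in rotated coordinates corrupts the
  profile likelihood severely at large variance ratios.
- **The SNP model is computed as the intercept-only residual minus the
  regression gain** (rss_alt = ryy − r²ₓᵧ/rₓₓ, evaluated via log1p), so at
  any shared variance ratio the alternative's likelihood is ≥ the null's
  by construction, and LRT ≥ 0 holds to machine precision. The per-SNP
  optimizer also evaluates the null's fitted ratio as a candidate, which
  guarantees nesting across different optima.

vr is maximized over log₁₀ vr ∈ [−5, 5] by a 50-point grid plus three
rounds of 9-point local refinement (vectorized across SNPs; width shrinks
×4 per round, final resolution ≈ 0.003 decades). The null is fitted once
per dataset; LRT = 2(l₁−l₀) is referred to χ²₁. Calibration at the
canonical structured-null condition: KS uniformity comfortably passes and
λ_GC ≈ 1.0–1.06.

The power study condition uses a causal SNP with expected variance share
0.40: at n = 60 with 5,000 tests, a share at the 25% floor leaves the
causal variant statistically indistinguishable from the extreme null
order statistics (top-hit rate ≈ 55%), so the condition is set comfortably
inside the "strong monogenic effect" regime the scenario describes; the
realized marginal R² still exceeds 0.25 in the replicates (median ≈ 0.40).

Outlier selection is count-based: k = ⌊qM⌋ smallest p-values, ties at the
boundary broken by genomic order, reproducing 190 and 475 outliers at
q = 10⁻⁴ and 2.5×10⁻⁴ for M = 1,900,366.

## LD pruning and PCA

Pruning scans 50-SNP windows advancing by 10; within a window, pairs of
retained SNPs are visited in index order and the later SNP of any pair
with r² > 0.1 is removed — removals never re-create earlier violations,
so one lexicographic pass settles a window. PCA centers columns and
scales by √(2f(1−f)); PC1's sign anchors to the trait when supplied. The
genome-wide PCA applies MAF ≥ 0.05 then pruning; an outlier-set PCA
applies neither.

The outlier-versus-genome-wide contrast is exercised on panels where ~20
causal SNPs share a high/low frequency pattern across two non-sister
species groups (mutual LD among the causal set, weak alignment with
overall structure). Under that architecture PC1 of the causal set
explains the trait far better (median R² ≈ 0.87 vs ≈ 0.5) in every seed.

## MAF-matched enrichment

MAF bins are half-open intervals (b·w, (b+1)·w] of width 0.05 over
(0, 0.5]. Each permutation draws, within each bin, as many control SNPs
(without replacement) as the test set holds there — so every null draw
matches the test set's MAF histogram exactly. Per effect, a SNP counts
once per label it carries. The empirical P uses the strictly-greater rule
(ties favor non-significance) and is reported as "< 1/n_perm" at zero
exceedances; the fold ratio divides by the null mean. The control set is
the full callset and may contain the test SNPs. Null draws are generated
by per-bin random-key `argpartition` in blocks, which keeps 1,000
permutations against a 100,000-SNP control set at about a second.

Segregation: per site, species with derived AF > 0.5 (computed only for
species with ≥ 2 samples) vote for their eye-size group; majority assigns
the site, ties leave it unassigned. Gene classes × dominance groups form
a Pearson χ² (no continuity correction); a per-class 50:50 goodness-of-fit
χ² is reported alongside because the exact contingency construction
behind published values of this kind is ambiguous — both are computed,
neither is asserted against any external number.

## Haplotype scans

EHH for a core allele is Σₖ nₖ(nₖ−1)/(n_c(n_c−1)) over distinct extended
haplotypes among the carriers, evaluated marker by marker outward
(haplotype groups refined incrementally; run-length counting on sorted
group ids, relabeled every 48 steps to avoid integer overflow). iHH is
the trapezoidal integral over physical distance, both sides summed,
stopping at the first marker with EHH < 0.05 (that final trapezoid
included); if a chromosome border is reached first, the site is missing
under the default border-discard rule. Constants (limehh 0.05, limhaplo
2, border discard, frequency bins 0.025, MAF 0.05) are the standard
defaults of EHH tooling and sit in `EHHConfig`. Physical distance is used
throughout (no genetic map).

iHS = ln(iHH_A/iHH_D), standardized within derived-frequency bins —
bin means 0 and SDs 1 exactly by construction. Negative standardized iHS
marks long derived haplotypes. EHHS uses all haplotypes with groups
seeded by the core-site partition and the curve normalized by the core
homozygosity; XP-EHH = ln(iES_A/iES_B) is exactly antisymmetric under the
population swap and zero for identical panels, and is standardized
genome-wide (both raw and standardized are emitted, since published plots
of this statistic do not always say which is shown). Positive XP-EHH
means longer haplotypes in population A; with A the small-eyed and B the
big-eyed population, negative scores point to selection in the big-eyed
group.

The empirical null samples 30-kb windows with replacement (chromosome
proportional to usable length, start uniform, fully inside), recording
each window's max and min score; empty windows are dropped and counted.
Candidate windows centered on nonsynonymous outliers are ranked by the
fraction of null extremes ≤ theirs (ties counted), flagged above 0.95 or
below 0.05.

**Scan study conditions.** The within-population sweep scenario uses one
population of 30 diploids, 8,000 sites on a 20-Mb chromosome, carrier
fraction 0.8, decay 50 kb, core chosen at initial derived frequency
0.05–0.25. The genome is long relative to the sweep because the
criterion is membership in the genome-wide top 1% of |iHS|: the sweep's
~100–200-kb footprint of elevated scores must itself stay below ~1% of
scored sites for that tail to be meaningful (on a 5-Mb genome the
footprint floods the tail and the criterion is unattainable for any
correct implementation). The cross-population scenario (2 × 25 diploids,
6,000 sites on 5 Mb, F_ST 0.05, completed sweep in one population) is
insensitive to footprint size because the criterion is a window-null
quantile, so it runs at the smaller scale. Both detect the sweep in
20/20 seeds at these conditions.

## Expression

TPM uses CDS length (counting was CDS-restricted): rate = count/(kb),
TPM = rate/Σrate × 10⁶ — columns sum to 10⁶ identically. The low-count
filter (≥ 5 counts in ≥ 3 samples, protein-coding only) is idempotent.

The DE stage is a deliberate simplification of the full shrinkage-based
tools: median-of-ratios size factors; per-gene method-of-moments
dispersion on normalized counts around group means, floored at 10⁻⁸; NB
group means by a vectorized Newton solve of the score equation (monotone
in the mean, so it converges from the moment start); Wald statistic on
the log fold change from the Fisher information, referred to a
**t distribution with n₁+n₂−2 df** — with 5-vs-5 designs and noisy
dispersion estimates the normal reference is visibly anti-conservative,
and the t reference restores null uniformity (KS p ≈ 0.5 at 2,000 null
genes) while leaving effect estimates untouched (planted log2FC = 4.5
recovered to ±0.05 on average over 50 replicates). There is no dispersion
shrinkage across genes and no fold-change shrinkage; the stage is
validated by simulation only and is never asserted to match any published
per-gene statistic. Group swap negates every log2FC exactly. The top-DE
rule is strict: adjusted P < 0.05 and |log2FC| > 4.5 (fold change
> 2^4.5 ≈ 22.6).

Opsin palettes: rod share = rh1/total opsin TPM; cone shares relative to
total cone TPM with rh2aα+rh2aβ summed into rh2a; opsins under 1 TPM are
flagged virtually absent; group summaries print median [min–max].

## Pipeline

Orchestration is plain in-process Python: a YAML config (unknown keys and
stage parameters rejected by name), stages executed in listed order
against a shared artifact context, plain-text outputs, and a JSON
manifest with SHA-256 checksums — identical config + seed reproduces
identical checksums. There is no workflow engine and no resumability
beyond rerunning; stage failure halts with the stage named and retains
partial artifacts.

## What the synthetic tests do and do not show

Passing these suites demonstrates that each statistic is computed
correctly (against enumeration, closed forms, and independent oracles),
that the inference stages are calibrated under their own model
assumptions, and that detection works when the signal matches the
generative model. Real data differ in ways the generator does not
emulate: background LD and recombination-rate variation (sites here are
unlinked outside sweeps), demography beyond island-model differentiation,
genotyping error correlated with depth, soft or overlapping sweeps, and
dispersion heterogeneity beyond the per-gene NB. Conclusions about power
on real data therefore do not follow from these tests; conclusions about
correctness of the implementations do.
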