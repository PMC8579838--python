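# Methods

This note records the models and procedures `fmtrack` implements, the
parameter choices that matter, and what the synthetic-data validation
does and does not demonstrate.

## Engraftment accounting

The unit of analysis is the ASV — an exact denoised 16S sequence — so
identity between donor and recipient samples is exact identifier match;
no fuzzy matching is attempted (all samples of such a study are
processed together, so identical sequences receive identical ids).

**Origin labels.** For one donor–recipient pair the ASV universe is the
union of the pooled donor sample's ASVs and the recipient baseline
(pre-antibiotic, D-1) ASVs. Presence in a sample means count ≥
`min_count` (default 1; configurable via `PresenceRule` — a higher
threshold trades sensitivity for robustness to index-hopping noise).
Baseline ("indigenous") presence is the **union** over recipient
baseline samples: one animal carrying the ASV before treatment is
enough to call it indigenous. This union convention matches pooling all
recipients' baselines into a single community when comparing against
donors; the prevalence rule below is deliberately stricter.

**Transfer rule.** At a post-FMT timepoint with *n* recipient animals,
an ASV is prevalent iff present in at least ⌈*p*·*n*⌉ animals
(default *p* = 0.5). The ceiling makes "at least half the rats" a whole
number of rats: 3 of 6, and 3 of 5. Transferred = prevalent and
donor-origin (donor-only or shared); remaining = prevalent and
indigenous-only; prevalent novel ASVs are reported separately and never
enter the three origin classes. The rule is applied uniformly to all
three classes — whether the original analyses applied the prevalence
rule to the "remaining indigenous" column is not documented anywhere we
know of, so uniformity was chosen as the simplest defensible reading
(configurable).

Shared ASVs are inherently ambiguous in origin; they are counted in
their own "from both" column and never folded into donor-only
percentages.

**Rates.** `transfer_rate` reports 100·k/N rounded half-up to one
decimal (half-up matches how such percentages are conventionally
printed; banker's rounding would turn 6.25% into 6.2%). Family-level
rates use as denominator the donor-present ASVs of the family
(donor-only + shared), excluding families absent from the donor.

## Tables

**Prevalence filter.** An ASV is kept iff it has ≥ `min_count`
(default 4) reads in at least ⌈f·N⌉ of the N samples that are not
role-excluded (default: the pooled donor samples are excluded from the
denominator and from qualifying, but their counts stay in the output).
Default f = 0.065. Ceiling was chosen for the fractional threshold
because a criterion over a discrete sample count must be attainable;
floor would make the filter vacuous for small N. The filter is
idempotent.

**Rarefaction.** Subsampling without replacement (multivariate
hypergeometric), the standard convention: each retained sample sums
exactly to the target depth (default 16,639) and no count can exceed
its input. Each sample gets an independent substream spawned from the
seed, so a sample's rarefied counts do not depend on which other
samples are present. Samples below the depth are dropped with a
warning; if none qualifies, the error lists the shortfalls.

**Taxonomy.** Seven ranks; empty/NA ranks are normalised to
`Unclassified_<nearest classified parent>` so that rank aggregation has
total support and unclassified groups keep a readable label (e.g.
`Unclassified_Ruminococcaceae`).

## Diversity

Shannon uses natural log (nats), the ecology convention. Simpson is
reported as 1 − Σp² (the complement form most microbiome packages
plot); the reciprocal form is available by flag. Alpha diversity is
intended to be computed on the rarefied table; beta diversity on
relative abundances of the filtered, unrarefied table (relative
abundances make rarefaction unnecessary for weighted UniFrac). Both are
just functions of whatever table is passed, so either choice can be
overridden.

The group comparison assesses normality per group with Shapiro–Wilk at
α = 0.05; both normal → two-sample t test, otherwise Wilcoxon rank-sum
with mid-rank tie handling. Constant (zero-variance) groups are routed
to the rank-sum branch, since Shapiro–Wilk is undefined on constant
data.

**Weighted UniFrac** is computed by a single postorder pass
accumulating, per branch, the fraction of each sample's reads on tips
below the branch; raw distance is Σ b·|p_A − p_B| and the normalized
variant divides by Σ b·(p_A + p_B), bounding it in [0, 1]. Normalized
is the default (bounded, comparison-friendly); the raw variant is a
flag. The test suite checks both against an explicit branch-by-branch
oracle (1e-10) and against scikit-bio.

**PCoA** is classical scaling: double-centre −d²/2, eigendecompose,
order by eigenvalue. Negative eigenvalues — the non-Euclidean residue
of a dissimilarity — are dropped and excluded from the
explained-variance denominator, so explained proportions are
non-increasing and sum to 1 over the retained axes. Eigenvector sign is
arbitrary (coordinates are defined up to reflection).

**PERMANOVA** partitions Σ d²/n into within- and between-group parts;
pseudo-F = (SS_B/(a−1))/(SS_W/(N−a)). The p-value uses the
(1 + b)/(1 + m) permutation estimator, which can never be exactly zero
and is exact under exchangeability. R² is a function of the distances
and labels only, so it does not depend on the permutation seed. The
suite verifies the type-I error over 500 null simulations and agreement
with exhaustive enumeration at n = 8.

## ANCOM

For each taxon i, every log-ratio log((x_i + c)/(x_j + c)), j ≠ i, is
tested between the two groups with the two-sided Wilcoxon rank-sum
test; the m − 1 p-values of taxon i are corrected by Benjamini–Hochberg
and W_i counts rejections at α = 0.05. A taxon is significant iff
W_i/(m − 1) **strictly exceeds** the cutoff (default 0.7) — at the
boundary the evidence is deemed insufficient. Pseudocount c = 1 is
added before every log, which keeps zeros finite at the cost of mild
attenuation for very low counts; at count magnitudes in the hundreds
its effect on W is at most ±1 rank flip (tested). The per-ratio test,
correction and cutoff are all configurable; these defaults are this
package's declared choices, not a reconstruction of any particular
historical run. Only the two-group design is supported. Effect sizes
are CLR mean differences: per sample, log(x + c) minus the sample mean
(rows sum to zero by construction).

## Synthetic-data generator

The generator emulates the statistical structure of a two-donor,
two-recipient-group rat FMT study:

* **Communities** are family-structured: each family has a target
  relative abundance and a richness; within a family, ASV proportions
  are Dirichlet with total concentration 50 (α_i = 50/n_fam — skewed,
  so a family has dominant and rare members, as 16S data do), rescaled
  to the family target. Reads are multinomial at a depth drawn
  uniformly from [20,000, 60,000], so the conventional rarefaction
  depth of 16,639 is always feasible.
* **Default compositions**: the bypass-type donor has 415 ASVs with
  Proteobacteria at 22.1% (Enterobacteriaceae 14.2%); the sham donor
  379 ASVs with Proteobacteria 3.6%; recipient baselines 158 ASVs with
  Proteobacteria 0.012%. Families with published per-family donor ASV
  counts use those; the remaining families were chosen once to reach
  the totals and a proportion sum of 1.
* **Shared membership**: the sham donor reuses 45% of its per-family
  richness from the bypass donor's pool and the recipients reuse 12%
  from the donor pools, giving the characteristic Venn structure
  (most ASVs unique to each community, a small donor–recipient
  overlap).
* **Knockdown**: each recipient draws an independent Bernoulli(0.1)
  survival per ASV; blooming families (default Lactobacillaceae, ×5)
  are up-weighted. Surviving indigenous weights are renormalised for
  the post-antibiotic (D0) sample and persist through the time course.
* **Engraftment truth**: per group, a configurable fraction (defaults
  0.35 bypass / 0.12 sham) of donor ASVs absent from the recipient pool
  engraft, with arrival days staggered so transfer counts rise over the
  course; each engrafting ASV has a per-recipient carriage probability
  (default 0.9) and a relative-abundance scale drawn from
  [0.001, 0.004]. The bypass truth additionally assigns a washout to
  four Enterobacteriaceae ASVs (colonise at D1, gone from D6),
  reproducing transient colonisation. Post-FMT samples mix surviving
  indigenous weights with the active engrafted scales and draw
  multinomially.
* **Tree**: random bifurcating, exponential branch lengths, family
  members coalescing first so family signal is phylogenetically
  coherent. Byte-identical Newick given the same seed.

Everything is driven by `numpy` SeedSequence substreams, one per
sample, so the whole experiment is byte-reproducible from a single
seed.

**What passing tests show — and don't.** On this generator, transfer
detection recovers the truth with sensitivity and specificity above
0.95 under the strong-engraftment regime (carriage 0.9, abundance scale
≥ 0.1%; 20 seeds), and the Enterobacteriaceae washout profile is
recovered in ≥ 19/20 seeds. Real data differ in ways the generator
does not model: antibiotic survival is correlated across animals
(making "remaining indigenous" counts higher and more stable than the
generator's per-animal independent survival produces), engrafted
abundance depends on donor abundance and ecological interactions,
depths are not uniform, and sequencing error/chimeras are absent. The
generator validates the accounting logic, not ecological realism.
Detection performance degrades as carriage approaches 0.5 because the
⌈n/2⌉ prevalence rule then sits at the carriage binomial's centre —
e.g. at carriage 0.5 a truly engrafting ASV clears 3-of-6 only about
two-thirds of the time.

## Problem sizes in the test suite

Pipeline plumbing tests run on a reduced 3-family design (30 ASVs per
community) chosen to exercise every code path; scientific checks run at
the full default design (415/379/158 ASVs, 6+5 recipients, 7
timepoints): 20 seeds for ground-truth recovery, 500 null simulations
(199 permutations each) for PERMANOVA calibration, 50 seeds for the
ANCOM null false-positive rate, 10 seeds at depth 50,000 for donor
composition fidelity.

## Known limitations

* Only two-group, single-factor designs; no repeated-measures modelling
  across timepoints (each timepoint is tested independently).
* No strain-level tracking or probabilistic source attribution; the
  labels are set-membership claims about exact ASV identity.
* Unweighted/generalised UniFrac and constrained ordination are out of
  scope; BIOM-HDF5 is not read (plain TSV/Newick only).
* ANCOM here is the classic W-statistic form; no bias correction
  (ANCOM-BC) or covariate adjustment.
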