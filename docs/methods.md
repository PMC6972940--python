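# Methods

This note documents the models and procedures implemented in
`coremark`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical decisions
that were genuinely open.

## 1. Repeat masking

Alignment-based core-genome construction and primer-uniqueness checks
both assume that a sequence occurs once per genome, which repeats
violate. Masking is k-mer-frequency based: canonical (strand-collapsed)
31-mers are counted over the pooled reference-plus-assemblies corpus,
and any base covered by at least one window whose count exceeds 2 is
replaced by `N`. Windows containing non-ACGT symbols are skipped.

Defaults: `k = 31`, `max_freq = 2`. Canonical counting is used because
downstream alignment is strand-symmetric. Counting over the pooled
corpus is the default (a repeat private to one assembly still threatens
transferability); per-genome tables are available via
`coremark mask --per-genome`. Masking is positional
(coverage-by-frequent-window), never whole-sequence, so output lengths
equal input lengths and masking is idempotent.

## 2. Collinear chaining and one-to-one blocks

Input is pairwise alignments in PAF (0-based half-open, consumed
natively; all internal intervals are half-open, BED-compatible).
Anchors are grouped per (reference chromosome, query sequence, strand)
and chained by sparse dynamic programming maximizing summed match
counts. Anchor *b* may follow *a* when

* reference and query gaps are both non-negative and at most
  `max_gap` (default 1 Mb),
* query order is increasing on `+` and decreasing on `−`,
* the gap imbalance `|t_gap − q_gap|` is at most `max_gap_diff`
  (default 1 kb).

The imbalance rule is the load-bearing one: a balanced pair of large
gaps is just diverged sequence between anchors, but a strongly
unbalanced gap *is* an insertion/deletion — exactly the
presence/absence variation the core/dispensable partition is trying to
detect — so it terminates the collinear block instead of being
absorbed into its bounding interval. Without it, a chain happily
bridges a 50-kb deletion (reference gap 50 kb, query gap 0) and the
block would wrongly cover dispensable sequence.

After the best chain per group is extracted its anchors are removed and
the search repeats, so each anchor joins at most one chain. Chains with
fewer than `min_anchors = 3` anchors are dropped. Ties in chain score
are broken by (chromosome, start, query) lexicographic order for
reproducibility.

One-to-one selection is greedy by descending chain score: a chain is
accepted only if its reference span and query span each overlap
already-accepted spans of the same assembly by at most
`overlap_tol = 0.1` of its own length. Accepted chains are collapsed to
their bounding intervals — this is what smooths over small local tandem
duplications — and blocks whose reference span is ≤ 10 kb are
discarded. Greedy-by-score is a heuristic; on small instances it agrees
with exhaustive search (verified in the test suite), but it is not
guaranteed optimal in general.

## 3. Coverage profile, core genome, decay model

An interval sweep produces a run-length-encoded per-base count of
assemblies covering each reference position; the counts partition the
reference exactly. The core genome is the set of maximal intervals at
the full assembly count.

The expected core shrinks as assemblies are added. The series of mean
core sizes against panel size k (averaged over up to 100 random
assembly orderings, fixed seed; each ordering yields the whole prefix
series in one pass) is fitted by least squares to the three-parameter
exponential decay

    y(k) = A + B·exp(−c·k)

with non-negativity bounds, initialized from the data. `A` is the
predicted plateau; `n_converge` is the smallest integer k with
`B·exp(−c·k) ≤ ε·A` (ε = 0.01), solved in closed form from the fitted
parameters. A series constant to machine tolerance returns the
degenerate fit (A = mean, B = 0, c flagged NaN); a non-convergent
optimizer is flagged, never silent. The three-parameter form was chosen
over the two-parameter `B·exp(−c·k)` because the quantity of interest
is precisely a non-zero asymptote.

Per-window (default 1 Mb) mean coverage is compared against feature
tracks (gene density, TE density, supplied as BED) by two-sided
Spearman rank correlation with midrank tie handling.

## 4. Marker design

Candidate regions are the core intervals, annotated with panel
statistics from a multi-sample VCF: `diversity` = variant records
starting in the region / region length; `missing_rate` = mean
missing-genotype fraction over the region's sites (0 for variant-free
regions).

Filtering removes regions by strict inequality: length < 200 bp,
diversity > 7% or < 2%, or missing rate > 50%. The alternative
`percentile` mode replaces the absolute diversity band with the
empirical 25th–75th percentiles; the absolute band is the default and
the two modes are not composed.

Spacing: the reference is tiled into 200-kb bins; in each bin one
candidate is drawn with probability proportional to
`1 + gene_weight·gene_density` (`gene_weight = 1`; the strength of the
gene-richness preference is not quantified upstream, so it is a plain
linear weight). A 1-Mb window containing no qualified candidate falls
back to the core region with the highest assembly coverage in that
window, polymorphism filters notwithstanding, so the panel keeps
physical coverage for mapping.

Amplicon design scans each selected region for a primer-window pair
such that both windows are free of panel variants (a variant counts as
"in" a window whenever its reference-allele span intersects it,
indel-aware), free of masked bases, and unique in the masked reference,
with the enclosed amplicon between 270 and 330 bp. Among feasible
pairs, the design maximizes the number of panel variants between the
primers (more variants → more distinguishable haplotype alleles), ties
to the leftmost, shortest amplicon. Primer length is fixed at 20 bp
within the allowed 18–27 range: conservation constraints only tighten
with length, and specificity is enforced separately by the uniqueness
screen, so nothing in this model distinguishes primer lengths.
Uniqueness is checked at k = 31 — longer than a primer — as: the 31-mer
anchored at the forward primer's 5′ start, and the 31-mer ending at the
amplicon's 3′ end, must each occur exactly once in the masked
reference. Regions with no feasible pair are reported as failures, not
errors. Primer thermodynamics (Tm, GC, dimers, RNase H2 blocker
chemistry) are deliberately out of scope; that is a vendor step.

Marker ids are `chrom_pos` with the 1-based amplicon start
(e.g. `chr2_4825658`).

## 5. Microhaplotype genotyping

**Demultiplexing.** A read pair is assigned to a marker iff R1 begins
with its forward primer and R2 with its reverse primer, each within
`max_mismatch = 1` substitution (no indels) and with the five
3′-terminal primer bases matching exactly — mirroring RNase H2 primer
activation, which requires a perfect match at the cleavage site.
Primers are trimmed; the R1 insert and reverse-complemented R2 insert
are merged when they overlap ≥ 10 bp with ≤ 1 mismatch (the overlap
implied by the expected amplicon length is tried first, ± 3 bp to
absorb indels, then all overlaps longest-first), otherwise joined with
a `+` sentinel. Unassigned pairs are tallied per sample.

**Collapsing.** Sequencing errors make every marker accumulate a long
tail of singleton haplotypes. Per marker, all haplotypes are aligned
(edit distance, unit gap costs) to the most frequent one, and variant
columns are derived (substitutions, deletions, and insertion slots
attached to the preceding column). Columns are discarded when they

1. fall inside a homopolymer run ≥ 4 bp of the dominant haplotype
   (indel-error hotspots), or
2. are monomorphic at the called-genotype level across the family —
   per-column diploid calls are made from column-allele read counts
   with the same depth/fraction thresholds as final calling; a column
   whose minor symbol never reaches a callable fraction in any sample
   is sequencing noise and carries no haplotype information, or
3. have called parents and progeny whose segregation fails the
   family's Mendelian χ² at `seg_alpha = 1e-3` (columns with an
   uncalled parent are kept: untestable is not failing).

If no column survives the segregation screen, the single
non-homopolymer column with the largest minor-allele read frequency
(MAF = 1 − majority frequency) represents the marker. Haplotypes are
re-keyed on the retained columns, each class named by its most frequent
member; per-sample counts are summed, so read counts are conserved
exactly.

**Calling.** Per sample and marker: total depth < `min_depth = 5` →
missing; alleles at count fraction ≥ `min_frac = 0.2` kept, top two by
count; one survivor → homozygote, two → heterozygote, three or more →
missing with an `ambiguous` flag. These two thresholds are package
defaults (exposed in the API and CLI); they are not published values.
Markers missing in > 75% of samples are removed; single-allele markers
are flagged monomorphic but retained. The `hapgeno` TSV dialect
(`i/j:di,dj` cells indexing a ranked allele sidecar) round-trips
losslessly, and the pseudo-allele VCF recodes the four most frequent
alleles per marker as A/C/G/T in descending family frequency (ties by
haplotype string), emitting carriers of rarer alleles as missing.

## 6. Mendelian QC and hemizygosity

Expected offspring class probabilities come from exhaustive gamete
enumeration (2 × 2 unions at ¼ each) over unordered observable
genotypes. A genotype carrying one null allele (Ø) is observed as
homozygous for its visible allele; Ø/Ø is unobservable and the
remaining probabilities are renormalized — observed counts come from
called genotypes, so an unobservable class is missing data, not a
class. Cross types: F1/BC unite gametes of the two given parents (pass
the recurrent parent and the F1 explicitly for a backcross); F2 selfs
parent 1.

Goodness of fit is Pearson χ² with df = classes − 1 and upper-tail p.
Default distortion tolerances follow the mapping pipeline they mirror:
1e-3 for F1/BC and 1e-10 for F2. An observed class that the model
cannot produce yields verdict `failed` (p = 0), not an exception.

The hemizygosity scan re-tests a distorted or monoallelic marker under
every model that replaces one parental allele with Ø (either parent)
or one allele in each parent (never both alleles of one parent), and
reports the model with maximal p; the marker is *rescued* when a null
model restores Mendelian fit at the tolerance.

Classification is sequential and mutually exclusive: mean family depth
< 1 → `failed`; ≤ 1 distinct progeny allele → `monomorphic`; χ² below
tolerance → `distorted`; else `mappable`. Markers whose parents are
uncalled cannot be tested and are classed mappable with χ² = NaN. The
primer-mismatch audit flags a marker/parent pair when any variant in
that parent's VCF intersects either primer window, and summarizes the
flagged fraction among hemizygosity-rescued versus other markers. The
reported MAF diagnostic for distorted markers is descriptive only: the
simple one- and two-null models yield minor allele frequencies of 0.375
or 0.25 rather than a single universal value, so no assertion is
attached to it.

IBS between two samples is the mean over shared non-missing markers of
(shared alleles)/2 ∈ {0, ½, 1}; 1 − IBS is the genetic distance, and
classical metric MDS (double-centering + eigendecomposition, top three
coordinates by eigenvalue) provides the family-outlier view. Samples
sharing no markers with some other sample are excluded with a warning.

## 7. Mixed-model association

The model is `y = Xα + Pβ + u + ε` with Var(u) = σ_g²·K and
Var(ε) = σ_e²·I, K the double-centered IBS kinship. With
K = U·diag(s)·Uᵀ the model whitens to weighted least squares with
weights 1/(s_i + δ), δ = σ_e²/σ_g². δ is estimated once by REML on the
covariates-only model — a log₁₀ grid over [−6, 8] plus golden-section
refinement — then held fixed for all marker tests ("population
parameters previously determined"); exact per-marker REML is
deliberately not the default, trading a small power loss for a
per-marker cost of one F-test. When the optimum sits at the upper grid
boundary the genetic variance is indistinguishable from zero, the
weights collapse to identity, and every test reduces *exactly* to OLS
(this limit is asserted in the tests). Markers are coded as
genotype-class indicators by default (correct for multiallelic
haplotype alleles; dosage coding available for biallelic input);
samples with missing genotypes are dropped per marker, with the
rotation recomputed on the subset kinship. R² is the reduction in
generalized (whitened) residual sum of squares; the Bonferroni
threshold is −log₁₀(α/N) — for N = 1712 and α = 0.05, 4.53.

Genotype–phenotype concordance for a categorical trait enumerates all
assignments of marker alleles to the dominance-ordered phenotype labels
(default M > H > f, the most recessive label expressed only when
homozygous) and reports the assignment maximizing agreement, with its
agreement fraction.

## 8. The synthetic-data generator

The generator defines the study conditions for every property test.

* **Pan-genome** (defaults: 2 Mb reference, 5 assemblies, SNP rate
  0.02, 30% dispensable, 5% repeats): assemblies are the reference with
  independent substitutions minus per-assembly dispensable intervals
  (uniformly placed, 5–50 kb, ≥ 20 kb apart). The inter-interval gap
  floor is a realism choice: without it, placement creates sub-10-kb
  collinear slivers that the > 10 kb block filter discards *by design*,
  which would conflate generator artefacts with method error in the
  recovery tests. Repeat tracts are tandem arrays of a ≤ 100 bp unit.
  Truth PAF anchors tile exactly the kept segments (~5 kb each), split
  at every dispensable boundary, so the synteny stage is testable
  without running an aligner.
* **Panel variants**: biallelic SNPs at a target density (default
  0.032/base, matching genus-scale core-genome diversity), uniform
  [0.05, 0.95] site allele frequencies, Hardy–Weinberg genotypes,
  independent per-genotype missingness.
* **Families**: gametes recombine with Poisson crossover counts at
  `recomb_rate` cM/Mb (default 3, a typical plant genome-wide rate).
  Null alleles are haplotype slots replaced by Ø: they transmit
  normally, produce no reads, and can also be manifested as
  primer-site variants in per-parent VCFs for the mismatch audit.
* **Reads**: per-marker mean depth is 10^Normal(1.7, 0.5) in log₁₀
  (≈ 50× median, most markers within 1–100×; the real panel's depth
  histogram is log₁₀-roughly-normal, and lognormal is an assumption
  with both parameters exposed). Each allele copy contributes
  Poisson(depth/2) pairs; substitution errors default to 0.005/base and
  homopolymer runs ≥ 4 gain or lose one base at 0.002/run. Qualities
  are constant Q40; quality modelling is out of scope.

Determinism is a contract: every output draws from an RNG stream seeded
by `seed + crc32(role)`, so equal seeds give byte-identical files and
new outputs never perturb existing ones.

**What passing tests do not show.** The generator has no inversions or
translocations (presence/absence only), no PCR chimeras or index
hopping, no base-quality structure, no reference bias, and its SNPs are
independent (no LD beyond family linkage). Recovery and calibration
results on this data therefore validate the algorithms' logic, not
their behaviour on real sequencing artefacts; the published data-scale
quantities (a ~40 Mb plateau, genus-wide transfer rates, real-family
map statistics) require the original genomes and families and are out
of desk-scale reach.

## 9. Problem sizes used in the checks

The automated checks run at deliberately modest scales chosen to
exercise every code path: pan-genomes of 0.4–2 Mb with 3–5 assemblies;
families of 100–150 progeny; 50-marker panels with full read
simulation (~250k read pairs); 1000 unlinked markers for χ²
calibration (markers on one chromosome are linked, so the calibration
property uses one marker per chromosome to keep trials independent);
500 markers / 100 samples for the association null; 20 replicates for
power and decay-recovery properties.

## 10. Known limitations

* Greedy one-to-one selection and greedy chain extraction are
  heuristics (exact on the small instances tested, not guaranteed).
* The collapse step's per-column genotype calls reuse the final-calling
  thresholds; very low-depth samples can leave error columns untestable
  (kept), inflating the post-collapse allele catalogue — harmless for
  calls, visible in allele counts.
* `sex_concordance` enumerates 3^a allele assignments; it is intended
  for the handful of alleles a single marker carries.
* The MLM fits a single random effect; no multi-locus or multi-trait
  models, and no imputation anywhere.
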