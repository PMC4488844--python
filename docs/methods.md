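# Methods

This note records the models, rules and numerical choices behind each stage
of the pipeline, the assumptions of the synthetic-data generator, and the
design decisions taken where the underlying study design left them open.

## Variant representation

All joins key on `(chrom, pos, ref, alt)` with 1-based VCF coordinates.
Multi-allelic records are split on read into one site per alternate allele;
a sample's genotype for a split site is its count of that specific allele,
so splitting never changes the total number of non-reference
(sample, allele) observations. Genotypes are unphased; compound-het phase is
inferred from parental genotypes only, never from VCF phase separators. Sex
chromosomes are treated as diploid: the candidate tables this package
reproduces are autosomal, and hemizygous logic (including how X-linked sites
should enter the dominant model) is a known limitation rather than a silent
assumption.

## Filter cascade

Four per-site predicates, applied in order, each idempotent and returning a
subset of its input (the database and predictor stages therefore commute):

1. **Functional class** — retained: missense, nonsense, canonical splice
   (±1/±2 intronic positions, encoded upstream into the functional class),
   frameshift and in-frame indels. Synonymous and other non-coding classes
   are removed. A missing class is a hard error: the cascade refuses to
   guess about unannotated sites.
2. **Database membership** — a site flagged in any of dbSNP137, 1000
   Genomes, ESP6500, HGVD or the in-house panel is removed. Membership is
   binary; frequency is deliberately not consulted at this stage.
3. **Predicted deleteriousness** — a *missense* site is removed iff SIFT
   says tolerated **and** PolyPhen-2 says benign. `possibly_damaging`
   counts as not-benign, a missing verdict never triggers removal, and
   non-missense classes pass through untouched (the predictors only score
   missense changes). This "harmless by both" direction is intentionally
   conservative: one dissenting predictor keeps a site alive.
4. **Strand bias** — a two-sided Fisher exact test on the 2×2 table
   (ref fwd/rev vs alt fwd/rev); sites with p below α are removed. The
   underlying study did not state whether a test or a ratio heuristic was
   used, so a Fisher test was chosen and α (default 10⁻³) is exposed as
   configuration. Sites with zero alternate reads cannot be tested and are
   retained with a warning.

The per-stage input/output counts are recorded as an audit funnel.

## Segregation models

Trio families (one affected offspring, two parents): **de novo** requires
child het or hom-alt with both parents hom-ref — a hom-alt child under
hom-ref parents is reported as a single de novo candidate rather than two
events; **homozygous recessive** requires child hom-alt with both parents
het; **compound heterozygous** requires two sites in one gene, child het at
both, one site transmitted only by the father (father carrier, mother
hom-ref) and the other only by the mother. Cis configurations (both sites
from one parent) are rejected; with multiple qualifying sites per parent the
full paternal × maternal cross-product of pairs is reported.

Multiplex pedigrees: **dominant** requires every genotyped affected member
to carry at least one alternate allele and every genotyped unaffected member
to carry none; members with unknown affection are ignored, and the proband
must itself carry the variant. Strict absence in unaffecteds is the default
(reduced penetrance would need a switch, which the segregation call
deliberately does not hide behind).

Missing genotypes are disqualifying in trio models (a de novo call with an
ungenotyped parent is no call at all) but treated as unknown in the dominant
predicate, where multi-generation pedigrees are typically only partially
sequenced. Within one family a site is never assigned two models: the trio
predicates are mutually exclusive by construction, and a compound-het pair
is suppressed if either member already carries a single-site model.

## Sample and variant QC

Variant QC removes sites with call rate < 0.80, Hardy–Weinberg exact
p < 10⁻⁶, or MAF at or above the configured ceiling, logging which rule
fired per site. HWE is the exact conditional test (probabilities of all
heterozygote counts as or less likely than observed, given the allele
counts), evaluated in controls only when labels are available — case
enrichment legitimately distorts HWE, and filtering on it would throw away
signal. Relatedness uses the method-of-moments IBD decomposition of
identity-by-state counts given allele frequencies; the raw moment components
are noisy and may stray slightly outside [0, 1], so only the final
PI_HAT = P(IBD=2) + ½·P(IBD=1) is clamped (clamping the components
individually biases near-zero estimates upward). Estimates from fewer than
50 informative sites carry a warning. Population outliers are flagged beyond
σ (default 6) standard deviations on any of the first components (default 2)
of a PCA of the standardized genotype matrix, with missing genotypes imputed
to the site mean.

## Association testing

Qualifying variants for the gene-based test: MAF below 0.01 and either a
missense called damaging by SIFT *or* by PolyPhen-2, or a canonical
splice-site variant — a single damaging verdict suffices here, unlike the
cascade's exclusion rule, because the two stages answer different questions
(discovery exclusion vs. burden aggregation). Genes with fewer than two
qualifying variants are skipped with the reason logged.

SKAT-O: with intercept-only binomial null model (no covariates are modeled;
none are measured in this design), score vector s = Zᵀ(y − μ̂) over weighted
genotypes Z = G·diag(w), w_j = Beta(MAF_j; 1, 25) density. For each ρ in
{0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1} (the method's published default
grid), Q_ρ = (1 − ρ)‖s‖² + ρ(Σs)² follows a mixture of 1-df chi-squares
with eigenvalues of R_ρ^{1/2} ZᵀPZ R_ρ^{1/2}. Numerical strategy: per-ρ
survival probabilities are first approximated by kurtosis-matched
noncentral-χ² moment matching, and the smallest two are refined by Imhof
characteristic-function inversion (adaptive quadrature, falling back to
moment matching if the integral misbehaves or the tail probability falls
below 10⁻¹⁰ where oscillatory cancellation dominates). The omnibus p-value
of the minimum-ρ statistic decomposes Q_ρ into a shared χ²₁ component and an
orthogonal mixture, and integrates the joint acceptance region over the χ²₁
variable with 256-node Gauss–Legendre quadrature on (0, 40), using the
moment-matched CDF for the orthogonal part; the result is capped at
(grid size) × min-p. With a single-ρ grid the test reduces exactly: ρ = 1 is
the weighted burden score test, ρ = 0 is SKAT, both verified against
independently constructed oracles.

λ_GC is the median Cochran–Armitage trend χ² divided by the 1-df χ² median
(≈ 0.455); monomorphic sites yield undefined statistics and are excluded
from the median. Benjamini–Hochberg q-values come from the standard step-up
procedure (q ≥ p, monotone in p-rank).

## PPI enrichment

The commercial pathway knowledge base used in the original analysis is
proprietary; the package instead accepts any user-supplied undirected edge
list, and its greedy network growth (start from the highest-degree
unassigned query gene, expand by the neighbor contributing the most
unassigned query genes, max 35 nodes, max 10 networks) is an open heuristic
documented as *not* identical to the commercial ranking algorithm. Network
score is −log₁₀ of the right-tail hypergeometric probability of the
network's query-gene count; the universe defaults to the supplied graph's
node count. Hub enrichment is a two-sided Fisher exact test of hub adjacency
in candidates vs. all other non-hub genes. The two-sided Fisher convention
sums all tables with the observed margins whose probability does not exceed
the observed table's.

## Conservation

A residue is conserved iff its alignment column carries the identical amino
acid in every row with no gaps — strict identity, not similarity groups,
because the downstream claim ("evolutionarily conserved amino acid in seven
organisms") is about the residue itself. Protein-change strings map to
columns through the human row's ungapped residue numbering; a gap anywhere
in the column breaks conservation. Labels are invariant to row order.

## Synthetic cohort generator

The generator emulates the study's statistical structure at reduced scale:

* **Families.** Trios are an affected child with two unaffected parents;
  multiplex families have five members (affected parent, unaffected parent,
  affected proband, unaffected sib, unknown-status sib). Each family gets
  2,000 background sites by default — a scaled stand-in for the ~10⁴ coding
  variants of a real exome, chosen so the full 200-family recovery study
  runs in seconds while still exercising every filter branch. Background
  MAFs are Beta(0.2, 2) (rare-skewed, with a common tail); founders are
  Hardy–Weinberg draws and offspring receive one allele per parent, so
  background Mendelian errors are impossible by construction and the only
  transmission-violating sites are the planted ones.
* **Annotations.** A background site is database-flagged iff its MAF
  exceeds 10⁻³ — deterministic, so filter outcomes are predictable from the
  manifest. Unflagged background missense sites are annotated
  tolerated/benign; planted sites are database-absent with damaging
  verdicts; two per-family "decoy" sites are damaging and database-absent
  but fully strand-skewed, so the strand-bias stage has real work. Under
  these defaults the cascade's survivor set equals the planted set exactly,
  which is what makes sensitivity/label-accuracy assertions sharp. Real
  data are messier in exactly the ways this construction removes: predictor
  verdicts correlate imperfectly with pathogenicity, databases contain
  pathogenic variants, and sequencing introduces genotyping error — so the
  recovery results certify the *logic*, not expected field performance.
* **Case/control panel.** 161 cases / 587 controls by default, 44 genes of
  rare (MAF ∈ [5·10⁻⁴, 8·10⁻³]) damaging variants under Hardy–Weinberg in
  controls; the enriched gene either multiplies carrier odds in cases
  (default OR = 10) or reproduces an explicit per-variant carrier
  configuration, e.g. the published (4/1, 1/0, 1/1) case/control het
  counts. No linkage disequilibrium or demography is simulated.
* **PPI graph.** Erdős–Rényi background (200 genes, density 0.02) plus
  guaranteed edges: 7 of 11 candidates adjacent to a seed and exactly 5
  adjacent to the calmodulin hub, mirroring the study's foreground counts.
* **MSA.** Seven species; planted columns are identical across rows, all
  other columns are forced to vary in at least one row.

All generators are pure functions of (config, seed); per-family RNG streams
are spawned from (seed, family index) so outputs are independent of call
order and byte-identical across runs.

## Problem sizes in the verification suite

The acceptance checks run the planted-recovery study at 200 families ×
1,000 background sites, SKAT-O calibration at 500 null genes × 1,000
samples (empirical type-I error compared against the central 95% interval
of Binomial(500, 0.05)), λ_GC on 2,000 common sites × 600 samples, and the
exact-test oracle sweeps exhaustively over all 2×2 tables with total ≤ 16
(plus 200 random tables with margins ≤ 15) and all HWE genotype
configurations with total ≤ 30 (plus random configurations up to ~60).
These sizes were chosen as the smallest at which the binomial/median noise
floors are well inside the asserted tolerances.

## Known limitations

* Hemizygous (X-linked male) genotypes are treated as diploid.
* The dominant model assumes full penetrance in genotyped unaffecteds.
* SKAT-O's omnibus integral uses a moment-matched CDF for the orthogonal
  mixture component; deep-tail omnibus p-values (≪ 10⁻¹⁰) are reported at
  moment-matching accuracy.
* The PPI network-growth heuristic approximates, but does not reproduce,
  proprietary pathway-tool rankings; only counts over user-supplied edge
  lists are meaningful.
* The unrelated-case screen reports predictor verdicts without filtering on
  them, by design: on a small pre-prioritized gene panel, predictor-benign
  variants remain reviewable hits rather than silent exclusions.
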