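# Methods

This note documents the models, conventions and numerical choices behind
`poolsweep`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and what the
tests do and do not demonstrate.

## Data model

A `VariantTable` is a sites × samples grid of pooled ref/alt read counts.
Allele frequency is a *derived* quantity: `af = alt/(ref+alt)` where depth
reaches `min_depth` (default 10 reads) and missing (NaN) elsewhere. Missing
is never conflated with zero — the artifact filters depend on the
distinction between "no data" and "allele absent". Coordinates are 1-based
inclusive throughout, matching the conventions of the source annotation.
Two alternate bases at one position are two distinct sites; when a
multi-allelic VCF record is decomposed, reads supporting non-focal
alternates are assigned to the reference count, so each decomposed site's
frequency refers to its own base change.

## Artifact filters

The filters encode two biological arguments about clonal E&R data:

1. **Constancy.** In a clonal genome under strong directional selection,
   hitchhiking links every real polymorphism to the selected background, so
   no real variant should hold a constant frequency through time. Per
   replicate, the pooled success probability p̂ = Σalt/Σdepth is estimated
   over the trajectory and each time point receives an exact two-sided
   binomial p-value against p̂. The two-sided convention is
   minimum-likelihood (sum of all outcome probabilities not exceeding the
   observed one), the default of mainstream exact binomial tests. The
   per-site family of (replicate × time point) p-values is
   Benjamini–Hochberg adjusted; the site is removed iff no q-value falls
   below `fdr_alpha` (0.05). The per-site family makes each verdict
   independent of which other sites were called. Ancestor samples are
   excluded: the question is change over time within evolutionary lines.
   The exact p-value is computed by a vectorized pmf scan (with a 1e-7
   relative tolerance on pmf ties, as in standard implementations); the
   test suite checks it against both brute-force summation and
   `scipy.stats.binomtest` exhaustively at small n.
2. **Batch-wide polymorphism.** Mapping artifacts (paralogy, repeats) tend
   to appear as intermediate-frequency "polymorphism" in *every* library of
   a sequencing batch, which is essentially impossible for real variants
   across independent replicates and time points. A site is removed when,
   in at least one batch with ≥ 2 informative samples, every frequency
   estimate lies in `(af_lower, af_upper]` = (0.01, 0.99]. Requiring two
   informative samples prevents a single observation from establishing
   batch-wide consistency; evaluating per batch (rather than jointly over
   all batches) is the stricter reading of the rule, and a joint evaluation
   is available simply by giving all samples one batch id.

Flags (QUAL, missingness, constancy, ubiquity) are computed independently
on the QUAL-passing table rather than sequentially, so per-criterion
removal counts are reportable and may overlap; the retained set is
identical either way. The missing-data rule removes sites with *more than*
`floor(0.10 × n_samples)` missing estimates — with 35 samples, "more than
3".

## Population statistics

* **Diversity**: π = Σ 2p(1−p)/L_eff per sample over non-missing sites,
  with L_eff = 3×10⁵ the number of reliably evaluated genome positions;
  fixed differences (p = 1) count as polymorphic relative to the reference
  but add nothing to π.
* **Effective selection coefficient**: s_eff = ln(f_end/f_start)/Δg, the
  per-generation log growth relative to a constant-frequency lineage. This
  is a *normalized measure of frequency change*, not an estimate of the
  Wright–Fisher fitness parameter: once a sweep leaves the exponential
  phase the log-ratio saturates and under-reads the true s (visible in the
  recovery benchmark below). Frequencies are floored at 0.002 — the pooled
  caller's detection threshold — which gives alleles absent at the first
  time point a finite, conservative estimate. A logit-scale form
  (ln of odds ratio per generation, the classic invasion-rate estimator)
  is available via `form="logit"`. The day-to-generation conversion
  defaults to 75/52 generations per day.
* **Repeatability**: the number of replicates whose last sequenced time
  point carries the variant at frequency > 0; the mean s_eff is averaged
  over exactly those replicates.
* **Group tests**: "t-test" is implemented as Welch (unequal variances,
  Satterthwaite df) — on the published per-replicate diversities this
  reproduces the printed p = 0.13 where a pooled-variance test would give
  ≈ 0.10. The Mann–Whitney test is exact (full enumeration, mid-rank ties,
  two-sided p = twice the smaller tail, capped at 1) up to n+m = 12 and a
  tie-corrected normal approximation beyond. The Poisson log-linear
  comparison is the Wald test of the group coefficient,
  β = ln(mean_b/mean_a), SE = √(1/Σa + 1/Σb); the suite verifies equality
  with a statsmodels GLM fit.

## Effect classification and the mutational null

Classification uses the standard genetic code (translation table 1, the
table used by the PBCV-1 annotation). For each ORF covering a site, the
genomic position is mapped through the ORF's segments (reverse complement
on the minus strand) to its codon; the changed codon is compared before and
after. Stop gained/lost outrank start lost only lexically — all three are
one severity tier, above nonsynonymous, above synonymous — and overlapping
ORFs are resolved by taking the maximum severity with ties broken by the
lowest ORF start, so each SNP gets exactly one deterministic class. ORFs
whose CDS length is not a multiple of 3 are excluded from classification
(but kept in enrichment scans). Upstream-ATG creation ("start gained") is
not modeled: no UTR model exists for this genome.

The null spectrum enumerates all 3L possible substitutions and classifies
each, giving the expected class distribution under a uniform per-position
mutation probability. Observed and null spectra form a 2×K table tested
with Pearson's X²; because observed totals are small, the p-value is the
add-one Monte-Carlo estimate (1+hits)/(n_mc+1) over tables resampled with
both margins fixed (multivariate hypergeometric sampling of the first row).
Classes empty in both rows are dropped. Start/stop classes can be lumped
into one bin (`EffectSpectrum.lumped()`) to match coarser reporting
granularity; both granularities are exported.

## Gene-level enrichment scan

Each ORF is tested for an excess of variable sites against a uniform
scatter of the m_total genome-wide sites over the full reference length
(330,611 bp — the total genome, not the smaller reliably-evaluated count).
Two table conventions are implemented:

* `hypergeometric` (default): the one-sided enrichment tail
  P(X ≥ m_orf), X ~ Hypergeom(L_G, m_total, L_orf) — the statistically
  standard Fisher upper tail on the partitioned 2×2 table.
* `counts_vs_lengths`: Fisher's exact test on [[m, M−m], [L, L_G−L]] —
  site counts against interval lengths. This is the convention under which
  the published per-gene values for this dataset reproduce (together with
  counting the one intergenic site in the genome-wide total), so it is kept
  for replication; it treats lengths as if they were counts and is slightly
  conservative here.

Both conventions identify the same three significant genes at FWER 0.05
over 812 ORFs. Holm's step-down correction is applied over all ORFs tested;
an ORF with no variable sites has raw p = 1 regardless of its length, so
unlisted ORFs enter the family with nominal lengths without affecting any
verdict. A site inside overlapping ORFs counts for each. Neighbor counts
(SNPs within 500 bp, focal site included) summarize spatial clustering.

## Simulator

Genotype-class Wright–Fisher, clonal (no recombination — consistent with
superinfection exclusion in this virus): a class is a set of mutations with
fitness Π(1+sᵢ); each generation the class counts are multinomial at the
current population size with probabilities ∝ count × fitness, then a
Poisson(N·μ·L) number of new single-site mutations is attached to parents
drawn by frequency. Demography is either constant N or a stylized
crash/regrowth cycle (default: to N_min = 100 every 15 generations) — the
predator–prey dynamics of the real system are not modeled. Pooled
sequencing draws depth ~ Poisson(1000) and alt reads ~
Binomial(depth, f(1−e)+(1−f)e) with symmetric error e = 10⁻³. Artifact
sites of both filterable kinds are injected with known labels. Caller
behavior is not modeled; simulated sites get QUAL 1000 unless configured
otherwise.

Deliberate scalings, chosen once as the desk-scale study conditions:

* **Population size 10⁵**, not the experimental census ~10¹⁰: at these
  sizes the modeled sweeps behave deterministically, so the census scale
  would change nothing but the cost of the multinomial. A deterministic
  (infinite-N) mode exists; its trajectories follow the exact
  discrete-generation logistic f(g) = f₀(1+s)^g / (1−f₀+f₀(1+s)^g) — note
  (1+s)^g, not e^{sg}: a per-generation multiplicative fitness of 1+s
  compounds geometrically, and the continuous-time form agrees only to
  first order in s.
* **Benchmark scenario** for the filter cascade: 20 beneficial variants
  per replicate injected as standing variation at f₀ = 0.005 with s = 0.1,
  plus 20 constant-frequency and 20 batch-wide polymorphic artifacts,
  6 replicates in two 3-replicate batches, time points at generations
  {0, 15, 30, 45, 60, 75}. The injection frequency keeps early estimates
  below the 0.01 polymorphism bound so genuine sweeps are not mistaken for
  batch-wide artifacts, mirroring real sweeps that start below detection.
  The 20 sweeps in one clonal population interfere; each ends near 5%
  frequency, which is exactly the regime in which the constancy filter
  must still detect change.
* **Recovery scenario** for s_eff: a single s = 0.10 sweep from f₀ = 0.01
  sampled at generations 0 and 25, i.e. read off the near-exponential
  phase. The median estimate lands near 0.09: the deterministic log-ratio
  over that window is 0.092, so the estimator's saturation bias — not
  noise — sets the gap from 0.10.

What the simulator does *not* emulate: coevolutionary feedback on selection
coefficients, infection kinetics and burst-size offspring variance,
within-host bottlenecks, read-level errors (mapping, indels) and caller
QUAL behavior. Passing the benchmark therefore shows the statistical
machinery is calibrated for binomial sampling noise around the modeled
dynamics; it does not certify performance against mapping artifacts beyond
the two stylized classes injected.

## Numerical conventions and degenerate inputs

* Exact binomial two-sided p: minimum-likelihood with 1e-7 relative slack
  on pmf ties; p̂ ∈ {0, 1} gives p = 1 at the degenerate observation.
* A site observed at a single time point cannot reject constancy (p = 1)
  and is removed — no evidence of change is treated as artifact, matching
  the filter's logic.
* BH and Holm corrections come from `statsmodels.stats.multitest`;
  q-values are monotone in p and q = p for a singleton family.
* Welch's t with zero variance in both groups returns 1 at equal means and
  0 otherwise; Mann–Whitney on identical multisets returns 1.
* Monte-Carlo p-values use the add-one estimator, which cannot fall below
  1/(n_mc+1) and is never anti-conservative.
* All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical outputs.

## Known limitations

* The filters assume the constancy null within replicates; systematic
  time-correlated coverage biases would violate it.
* s_eff is a summary of frequency change, biased toward zero for sweeps
  past their exponential phase and bounded by the frequency floor for
  alleles absent at the start.
* The enrichment scan conditions on the observed number of variable sites
  and a uniform site-placement null; it does not model mutational target
  size differences between genes.
* GFF3 reading supports CDS-per-parent gene models (as in viral
  annotations); complex eukaryotic gene models with alternative isoforms
  are out of scope.
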