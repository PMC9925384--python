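# Methods

`cryptomes` implements a crypt-resolved somatic-mutation analysis for
normal intestinal epithelium: each microdissected crypt is a near-clonal
cell population, so its true somatic variants sit at VAF ≈ 0.5 and can be
separated from germline variants and sequencing artifacts by simple,
well-characterized statistical filters. This note records the models,
the defaults that matter, and the choices made where the design was
genuinely open.

## Synthetic cohorts

`simulate.generate_cohort` produces fully labelled cohorts with the
statistical structure the downstream analyses assume:

* **Crypt relatedness.** Each patient's crypts are related by a random
  binary fission history: k−1 fission ages drawn uniformly from
  `fission_age_range` (default 0–10 years), each splitting a uniformly
  chosen extant lineage. The default range is deliberately early-life:
  crypts from one biopsy typically share only embryonic/childhood
  ancestry, so most mutations are private. The fission prior is a free
  modelling parameter, not an estimate; no generative prior for fission
  is established for these tissues.
* **Mutation accrual.** Each branch accrues SBS count ~
  Poisson(region rate × branch years), with per-region defaults of
  51/50/42 mutations per year (duodenum/jejunum/ileum) and indels at
  `id_rate_per_year` (default 3). Channels are drawn from a signature
  mixture (default SBS1 0.33 / SBS5 0.55 / SBS18 0.12, matching the
  ubiquitous-signature composition of normal intestinal crypts), and
  positions are placed by context-matched rejection sampling so that
  genome spectra are faithful even on short synthetic references.
* **Episodic APOBEC.** With probability `apobec_episode_prob` (default
  0.15, near the observed 16% of positive branches) a branch gains a
  burst of `apobec_burst_size` SBS2/SBS13 mutations (default 300, ≈10%
  of a late-life crypt burden), including `kataegis_per_burst` clusters
  of 6 mutations within 2 kb.
* **Confounders.** Germline heterozygous variants are present in every
  crypt of a patient at VAF 0.5 (0.95 on chrX for the optional male
  mode, exercising the sex-chromosome branch of the germline test).
  Systematic artifacts are shared low-VAF sites across *all* cohort
  samples, drawn beta-binomially (mean `artifact_vaf` = 0.03, rho 0.02)
  so the overdispersion filter has a true signal to find.
* **Observation.** depth ~ Poisson(`mean_depth`, default 25), alt ~
  Binomial(depth, carrier VAF); non-carrier crypts have exactly zero
  alt reads (no sequencing-error reads are simulated). Site uniqueness
  is enforced within a patient; different patients may rarely hit the
  same site.

What the generator does **not** emulate: read-level errors and mapping
artifacts (read metrics are summarized, not simulated from alignments),
copy-number/structural variation, subclonal crypts, and chromatin- or
replication-timing-dependent mutation rates. Passing tests therefore
demonstrate correctness of the statistical machinery under the model's
assumptions, not robustness to every failure mode of real LCM data.

## Variant filtering

Three stages in fixed order. (1) Read metrics: median alignment score
≥ 140 and clipped fraction < 0.5; indels additionally require caller
quality ≥ 300 and ≥ 15 supporting reads. Variants with missing metrics
are excluded as unevaluable rather than passed. (2) Germline: per
patient, alt/depth are aggregated across crypts and tested one-sided
(alternative "less") against an exact binomial null with p₀ = 0.5
(0.95 on male sex chromosomes); BH adjustment runs over the patient's
full tested family and somatic requires q < 1e-5. Only variants
observed in a patient (aggregate alt > 0) are tested for that patient.
A consequence worth knowing: truncal somatic variants carried by every
crypt of a patient are statistically indistinguishable from germline
and are (correctly, per the method) classified germline. (3) Rho: the
beta-binomial overdispersion is maximized on a 64-point log-spaced grid
over [1e-6, 0.89] with the mean fixed at the pooled VAF — the 1-D
estimator used by Shearwater-style unmatched filters — and rho < 0.1 is
an artifact. A pooled VAF of exactly 0 or 1 leaves rho undefined; the
lower grid boundary is returned with a degenerate flag and the variant
is not called an artifact.

## Burden modelling

Detection sensitivity is P(alt ≥ t) under depth ~ Poisson(coverage) and
alt ~ Binomial(depth, median VAF), t = 4 for SBS and 5 for indels,
estimated by 100,000 Monte-Carlo draws and checked in tests against the
exact Poisson-binomial tail (at VAF 0.5, 25×, t = 4 the value is
0.99845). Burdens divided by sensitivity enter a linear mixed model:
fixed intercept, per-region age slopes, optionally an age × celiac
term; random intercept + age slope per patient (falling back to
intercept-only, then OLS, on singular fits — the richer structure is
the biologically meaningful one since patients differ in rate). CIs are
normal-approximation Wald intervals; nested comparisons use ML-based
likelihood ratios. QC modes: burden modelling drops samples under 15×
coverage and an explicit exclusion list; dynamics modelling additionally
drops celiac patients, children (< 18 y) and chemotherapy-exposed
patients, whose crypts may violate constant-rate/fixed-size assumptions.

## Phylogeny

Tree building is a greedy perfect-phylogeny construction on binary
genotypes (carrier iff VAF ≥ 0.25 and alt ≥ 3 — separating clonal ≈0.5
from absent at 25×): variants are grouped by crypt-sharing pattern,
patterns ranked by support, and each accepted if laminar with the
accepted family, so conflicts resolve toward the better-supported
pattern. Mutations are then assigned to branches by maximum likelihood
under a binomial read model with expected VAF = clone VAF inside the
branch's clade and an error floor of 1e-3 outside (the floor is needed
for a proper likelihood and is not estimated from data); ties break
toward the root. Branch SBS1 burdens divided by the patient's SBS1
per-year rate give node ages; a fission event on a branch is bounded by
the parent's and child's ages.

## Signature attribution

Attribution-only EM against a supplied reference catalog (multinomial
mixture, uniform initialization, relative log-likelihood tolerance 1e-8,
≤ 1e4 iterations; the update is deterministic and its log-likelihood
non-decreasing). De novo extraction is out of scope: for these tissues
attribution against a known catalog reconstructs every observed spectrum
above 0.8 cosine, so no new signature is needed. The threshold ladder:
two-round fitting prunes signatures ≤ 10% and refits; per-individual
permission requires a ≥ 5% share on some branch with > 200 assigned
mutations (with no such branch, only the ubiquitous SBS1/SBS5/SBS18 are
permitted, flagged); final exposures are re-fitted by EM restricted to
the permitted set (preserving likelihood optimality rather than
proportionally rescaling), and a branch reports signatures above a 5%
share, applied after re-attribution. APOBEC positivity is SBS2 + SBS13
≥ 5% of burden. Exome APOBEC counts are scaled ×50 for genome
comparison. Note a numerical property of EM: on a spectrum generated by
a single signature, convergence to the exact boundary (100%/0%) is slow
when catalog entries overlap; with the default tolerances a pure
component resolves to ≳ 99%, and exact-boundary recovery is only
expected for orthogonal catalogs.

The shipped catalog is synthetic: ten 96-channel vectors carrying the
characteristic peaks of SBS1/2/5/13/17b/18/35/40/41/88 (NpCpG>T clock,
TpC APOBEC, flat, oxidative C>A, colibactin, …) adequate for simulation
and testing. For real data, supply COSMIC vectors as a TSV; the catalog
is data, not code.

## Kataegis

Mutations within 10 bp merge into one mutagenic event; runs of events
with all adjacent gaps < 10 kb are candidates, restricted to spans of
10–10,000 bp. A run wider than the cap — typically a dense cluster that
chains a distant straggler through a sub-10 kb gap — is split
recursively at its largest internal gap rather than discarded, so
genuine clusters are not silently lost to chance chaining. For r+1
events spanning k unmutated bases, P = Σ_{j≤k} C(j+r−1, j)(1−p)^j p^r —
the negative-binomial CDF of failures before the r-th success —
evaluated through the regularized incomplete beta function (the printed
formula's reuse of k as both bound and exponent is resolved as this
CDF). The per-individual rate p is total passing substitutions divided
by the callable genome (default 2.9e9; synthetic runs pass their genome
length). Bonferroni correction is per sample over its candidate
clusters; adjusted P < 1e-4 is kataegis, and clusters with identical
member positions in several crypts of one patient count once.

## Stem-cell ABC

The crypt is maintained by `n_stem` equivalent stem cells under neutral
Moran replacement at `replacement_rate` per cell per year. The
genealogy is simulated backward via the model's coalescent dual
(pairwise rate 2λ/(N−1), capped at crypt founding), which is exactly
distributed as the forward process for every quantity used and orders
of magnitude faster — necessary for rejection ABC at 50,000 simulations
per crypt. Mutations accrue at a constant per-year rate on each branch
including the truncal stretch above the MRCA; a mutation carried by a
fraction f of lineages sits at VAF f/2 and is read through
Poisson-depth binomial sampling. Inference is plain best-1% rejection
(no kernel weighting — none is specified for this procedure, and
rejection is the simplest member of the family) on the Euclidean
distance between unit-mass 20-bin VAF histograms on (0.05, 0.55]; a 1-D
Wasserstein alternative is selectable. Default priors: n_stem uniform on
{1..20}, replacement rate uniform on [0.1, 10]/year — uninformative
ranges spanning published estimates for intestinal crypts; both are
configurable. The per-crypt mutation rate is supplied by the caller
(in the full pipeline, the patient's LMM rate divided by detection
sensitivity).

## APOBEC context and expression

TpCpA mutations are classified YTCA/RTCA by the −2 base on the
pyrimidine strand; backgrounds are tetranucleotide counts (both strands)
in ±20 bp windows around each C mutation — the window is configurable
since the convention is inherited from hypermutation-analysis practice
rather than printed. Enrichment(YTCA) = (mut_YTCA × ctx_C)/(mut_C ×
ctx_YTCA); Fisher tests compare the YTCA:RTCA split among mutations to
the background context counts, one-sided in each direction (the
alternative framing — cohort vs cohort — can be formed from the same
tallies).

Expression comparison normalizes gene × cell counts to relative counts
(per-cell total scaled to 1e4), averages over all cells including zeros,
and reports small/large ratios (infinite when the large-intestine mean
is zero, as in published tables). Per-gene negative-binomial GLMs (log
link, ML dispersion, one model per gene) test the tissue coefficient
two-tailed, controlling log total counts, feature count and the other
APOBEC family members; non-convergent fits fall back to a
quasi-likelihood Poisson GLM, flagged. BH correction runs across the
tested gene family. Bulk nTPM rows are consumed as given and only
ratioed.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale: synthetic genomes of
1.2–3 ×10⁵ bases, cohorts of 2–5 patients × 4–8 crypts at 25×,
kataegis scans on 10⁷-base coordinate spaces at study-realistic per-base
rates (~3×10⁻⁵), ABC at 5,000 simulations × 25 replicate crypts, and
LMM recovery over 50 replicate cohorts of 20–24 patients. These sizes
preserve each method's operating regime (depth, VAF structure, cluster
density, per-branch mutation counts) while keeping a full run in
minutes. Ties in ML branch assignment break toward the root; EM runs
from a uniform start and needs no seed; all simulation randomness flows
from explicit integer seeds through `numpy.random.default_rng`.

## Known limitations

* The germline filter cannot rescue truncal somatic variants shared by
  all of a patient's crypts (inherent to the unmatched design).
* The perfect-phylogeny builder drops minority conflicting patterns
  instead of modelling genotyping error explicitly; at 25× with clonal
  crypts conflicts are rare, but heavily subclonal samples would need a
  probabilistic tree method.
* The NB expression model fits per-gene dispersions independently; no
  information is shared across genes.
* Stem-cell inference assumes neutrality, constant rates and a fixed
  1,000-cell crypt; samples violating these (disease, chemotherapy,
  childhood growth) should be excluded via the dynamics QC mode.
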