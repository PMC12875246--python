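# Methods

## Data model

A study is a set of taxon pairs, each an aligned set of mitochondrial
sequences split into two demes (Old World / New World). Deme membership is
metadata in the manifest, never parsed from sequence ids. Residues are
A/C/G/T with `N` and `-` treated identically as missing; other IUPAC
ambiguity codes are accepted on input and mapped to missing. All pairwise
statistics use pairwise deletion: a site is excluded for a given sequence
pair iff either member is missing there, matching the convention of the
standard distance software in this field and preserving data at high
coverage. Complete-column deletion is deliberately not used.

## Statistics

* **π** is the unbiased mean over distinct sequence pairs of per-site
  mismatch proportions. For haploid panels this equals the classical
  estimator. Note a consequence worth knowing: for two demes of literally
  identical composition, π_between (which counts identical cross pairs) is
  smaller than within-π (which excludes self pairs), so D_A and F_ST are
  negative there; they are zero in expectation under label exchange, which is
  the relevant null.
* **Jukes–Cantor**: d = −(3/4)·ln(1 − 4p/3); with gamma rate heterogeneity
  of shape a, d = (3/4)·a·[(1 − 4p/3)^(−1/a) − 1]. The shape parameter used
  by the original distance computations is not recoverable, so plain JC is
  the default and the shape is exposed as configuration (`gamma_shape`).
* **Watterson's θ_W** = S/(a_n·L_eff), S counting columns with ≥ 2 distinct
  non-missing bases, L_eff counting columns with ≥ 2 non-missing sequences.
  **Tajima's D** uses the standard variance normalization with the mean
  pairwise difference count taken over distinct pairs (pairwise deletion);
  it is undefined (reported missing) when S = 0 or n = 2.
* **F_ST** is Hudson/Slatkin/Maddison 1 − H_w/H_b, H_w the unweighted mean
  of the two within-deme π, H_b the mean between-deme distance; undefined
  when H_b = 0; negative values are legitimate. Significance comes from
  permuting deme labels over the pooled sequences preserving deme sizes;
  p = #(F_ST* ≥ F_ST)/n with ties counted as exceeding (conservative) and
  permutations with undefined F_ST counted as non-exceeding. p is reported
  as k/n by default because the source tables print p = 0.000, impossible
  under the (k+1)/(n+1) convention, which remains available via a flag.
  Default 10,000 permutations. Multiple testing uses Benjamini–Hochberg
  step-up (statsmodels) at q = 0.05.

## Divergence dating

Rates are pairwise percent divergence per Myr — both lineages accumulating —
so t = d/rate with no factor of two; the rate table must be populated in this
convention. Passerine-calibrated base rates are rescaled to other orders by
the ratio of order-level rates. A pair whose order lacks a table entry fails
loudly; silently falling back to the passerine rate would miscalibrate
exactly the taxa the scaling exists for.

## Coalescent model and scaling

Two demes exchange migrants symmetrically and merge into a single ancestral
deme at time τ. Time is in units of 4·N_ref generations of a reference
population; a lineage pair in a deme of relative size x coalesces at rate
1/x; each lineage migrates at rate mig/2; mutations fall at θ/2 per site per
lineage per unit time (θ = 4·N_ref·μ of the reference). Hence for singleton
samples without migration E[per-site between-deme divergence] = θ(τ + anc),
the identity the simulator is tested against. Recombination is fixed at zero
(mitochondrial locus), so one genealogy underlies each pair; multi-gene
mitochondrial data are treated as one linked locus.

Mutation models: `infinite_sites` (each event a fresh column) and
`finite_sites_jc` (uniform columns, uniform non-identical substitution
applied in age order along lineages). At the divergence levels studied here
(per-site p ≲ 0.05) the two agree closely; the batch kernel used for the
ABC reference table computes the six summary statistics branch-wise under
infinite sites without building alignments (a mutation on a branch with d
descendant leaves contributes d·(n−d) pairwise mismatches, etc.), which is
what makes 10^5–10^6 replicates per run affordable. The synthetic-data
generator defaults to finite-sites JC so generated FASTA resemble real data.
The kernel and the alignment-building path are cross-checked against each
other (moment agreement) and the genealogy process against msprime
(Kolmogorov–Smirnov on T_MRCA) in the test suite.

## Hierarchical ABC

Hyperprior: Ψ uniform on {1..Y}; Ψ event times i.i.d. U(0, upper_tau]
(default 0.2); pair→event assignment uniform conditioned on every event
being used. That conditional law is sampled exactly — a uniform set
partition into Ψ blocks via the Stirling recursion
S(n,k) = k·S(n−1,k) + S(n−1,k−1), then a random block→event bijection —
because naive redraw-until-valid has acceptance probability psi!·S(Y,psi)/psi^Y,
which underflows for Ψ ≈ Y beyond ~15 pairs.

Per-pair nuisance priors (the within-pair sub-parameterization is this
package's own declaration): descendant deme sizes x_a, x_b ~ U(0, upper_size]
as fractions of the reference population; ancestral size u·(x_a+x_b)/2 with
u ~ U(0, upper_anc] — the ancestral bound is *relative to the pair's current
size* (default 0.5); migration ~ U(0, upper_mig] (default 10). The default
upper_size = 0.25 reflects that the test is run on pairs pre-screened as
differentiated (significant F_ST or reciprocal haplotype clades): their
lineages have largely sorted within the bounded τ window, which requires
demes small relative to the reference time scale. Widening upper_size to 1
wastes most prior mass on demes that cannot sort within τ ≤ 0.2 and empties
the neighborhood of such observed data.

Summary statistics per pair: (π_a, π_b, π_between, D_A, pooled θ_W, pooled
Tajima's D), with Tajima's D imputed as 0 on monomorphic draws to keep the
vector dimension fixed. Rejection standardizes each column by the reference
table's mean/SD, drops zero-variance columns, and accepts the
⌈tolerance·n_reps⌉ closest rows by Euclidean distance (ties broken by row
index). Because taxon pairs are exchangeable under the hierarchical prior,
per-pair statistic blocks of both the observed and simulated vectors are
aligned by descending π_between before the distance is computed; without
this alignment the distance carries essentially no information about Ω (a
draw whose deep pair sits at a different index is penalized as badly as a
genuinely wrong draw). Manifest-order distances remain available
(`sort_pairs=False`).

Posterior reports: Ψ probabilities (relative frequencies of accepted draws),
E(τ) and Ω = Var(τ)/E(τ) per accepted draw (population variance; all-equal τ
gives exactly 0), and the Bayes factor
BF = [P_post(Ω ≤ ε)/P_post(Ω > ε)] / [P_prior(Ω ≤ ε)/P_prior(Ω > ε)] at
ε = 0.01, with prior Ω mass from fresh hyperprior draws (default 10^5),
never reused from the reference table.

`theta_upper` (the reference mutation scale) defaults to twice the largest
observed pooled θ_W across pairs when a study is run end-to-end on real
data. For strongly sorted pairs this data-driven scale can map observed
divergences outside the bounded τ prior (pooled θ_W for a sorted pair is of
the order of the divergence itself, so divergence/θ_upper ≈ 0.7 > 0.2); a
generously larger explicit bound is then appropriate. Recovery experiments
sidestep the issue by construction: pseudo-observed studies are generated in
the model's own units and analyzed with theta_upper set to the same
reference constant, the standard design for a Bayesian recovery study.

## Synthetic-data generator

`generate_study` draws each pair from the coalescent above. Defaults — 5+5
sequences, one ND2-length locus (1,041 bp; 500 bp in the scaled-down
experiments), reference scale θ_ref = 0.2, deme sizes 0.02·N_ref, relative
ancestral size 0.25, migration 0 — were chosen once to emulate the
differentiated pairs the hABC stage targets: within-deme π ≈ 0.4%,
between-deme divergence ≈ 1–4%, F_ST ≈ 0.5–0.9, i.e. the levels the study
reports for its significant pairs. Depth labels (population/subspecies/
species) are assigned by true-τ terciles purely to exercise the group-
summary code path; no biological claim attaches to them. What the generator
does **not** emulate: sequencing error (the Sanger-vs-Illumina comparison is
consumed as data, not modeled), base-composition and codon structure, rate
heterogeneity across sites, within-deme geographic structure, and
recombination (absent in mtDNA anyway). Passing recovery tests therefore
show the inference machinery is sound under the model's own assumptions,
not that real data satisfy those assumptions.

## Scaled-down problem sizes

The recovery experiments use Y = 8 pairs, 5+5 samples, 500-bp loci, 10^5
reference-table replicates at acceptance fraction 0.001, and 10 repetitions
per truth scenario — sizes chosen so the whole suite runs comfortably on one
CPU while leaving the qualitative behaviour (Ψ-mode recovery for
simultaneous truth, Ω separation for staggered truth) clearly resolved.
Paper-scale runs (10^6–3·10^6 replicates, 19+ pairs) are supported through
the same chunked, seed-derived reference-table builder.

## Numerical and degenerate-input conventions

JC correction raises a saturation error at p ≥ 3/4. Demes of one sequence
contribute π = 0 with a warning. Tajima's D is missing when S = 0 or n = 2
(variance normalization degenerates) and 0-imputed only inside ABC summary
vectors. Sequence pairs sharing no comparable site are excluded with a
warning; a statistic with no usable pair raises. F_ST permutation ties count
toward the numerator. All randomness flows from explicit seeds (one root
seed per run; child seeds via the generator), so identical configurations
produce bit-identical outputs, including FASTA bytes.

## Known limitations

* Single effectively-linked locus: one genealogy per pair, so coalescent
  noise does not average away; Ψ is a weak event counter when events are
  closely spaced (the dispersion index Ω is the operative test statistic).
* The data-driven theta_upper default and the bounded τ prior interact
  poorly for strongly sorted pairs (see above).
* The rejection posterior has no post-acceptance regression adjustment, by
  design (simple rejection).
* Dating assumes a strict clock and rates in pairwise percent per Myr;
  calibration uncertainty is not propagated.
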