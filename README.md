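# beringia

Comparative divergence analysis for trans-Beringian taxon pairs: sister
populations, subspecies, or species separated by the Bering–Chukchi divide.
Given per-pair two-deme mitochondrial alignments (Old World vs New World),
the package computes the standard pairwise population-genetic statistics,
converts distances to divergence dates with order-calibrated rates, and tests
whether the whole panel of pairs diverged simultaneously or at staggered
times using a hierarchical approximate Bayesian computation (hABC) over a
two-deme isolation-with-migration coalescent. It is aimed at comparative
phylogeographers working with co-distributed pairs split by a common barrier.

## What it computes

**Per-pair statistics** (`beringia.popgen_stats`): mean pairwise p-distance
with pairwise deletion of missing data; Jukes–Cantor distance
d = −(3/4)·ln(1 − 4p/3), optionally gamma-corrected
d = (3/4)·a·[(1 − 4p/3)^(−1/a) − 1]; nucleotide diversity π (unbiased mean
over distinct sequence pairs); net nucleotide divergence
D_A = π_between − (π_a + π_b)/2; Watterson's θ_W = S/(a_n·L); Tajima's D;
Hudson-style F_ST = 1 − H_w/H_b with a deme-label permutation test; and
Benjamini–Hochberg FDR across pairs.

**Divergence dating** (`beringia.divergence_dating`): t = d / rate, with
rates in % pairwise divergence per Myr; passerine-calibrated base rates are
rescaled to other avian orders by the ratio of ordinal rates,
rate_scaled = rate_base × (rate_order / rate_passerines).

**Hierarchical ABC** (`beringia.habc`): the number of divergence events
Ψ ~ U{1..Y} across Y pairs, event times τ ~ U(0, 0.2], per-pair nuisance
demography (deme sizes, ancestral size relative to current, migration up to
10) from uniform priors; a fast two-deme coalescent simulates a reference
table of per-pair summary statistics (π within/between, D_A, pooled θ_W and
Tajima's D); simple rejection (standardized Euclidean distance, fixed
acceptance fraction) yields the posterior over Ψ, E(τ), the dispersion index
Ω = Var(τ)/E(τ), and a Bayes factor for Ω ≤ 0.01 vs Ω > 0.01. Ω near zero
means simultaneous divergence.

**Synthetic studies** (`beringia.synthetic_data`): complete studies with
known truth (Ψ, τ vector, demography) written as FASTA + manifest + truth
JSON, plus packaged transcriptions of the study's printed tables used by the
summary operations.

## Worked example

```bash
python analysis/01_printed_tables.py
python analysis/02_simulate_study.py
python analysis/03_pair_statistics.py
python analysis/04_divergence_dating.py
python analysis/05_habc_test.py
```

The first script recomputes the published summaries from the packaged tables
and prints:

```
Full-mitogenome JC distance (%) by taxonomic depth:
             n  mean    sd   min   max
all         39  1.39  1.19  0.05  3.82
species     12  2.25  1.11  0.43  3.82
subspecies  11  1.80  1.09  0.30  3.19
population  16  0.47  0.51  0.05  1.99

Pairs significant by F_ST permutation (p < 0.05): 13 of 39
Clade-flagged pairs: 10; union (differentiated subset): 19
Sanger vs Illumina nucleotide diversity ...: 0.025 vs 0.015 (ratio 1.67)
```

Species pairs average 2.25% mitogenome divergence against 0.47% for
populations; 13 of 39 pairs are significantly differentiated by F_ST, and
adding the 10 pairs with reciprocal OW/NW haplotype clades gives the 19-pair
subset carried into the hABC stage. The Sanger-era data report 1.67× higher
diversity than high-coverage data from the same specimens — a sequencing-
error artifact that inflates historic divergence estimates.

The hABC stage on two synthetic 8-pair studies (known truth) prints:

```
simultaneous study (true psi = 1):
  psi posterior mode = 1, P(psi=1) = 0.570
  E(tau) mean = 0.0238; omega median = 0.0000; P(omega > 0.01) = 0.290
  Bayes factor (omega <= 0.01 vs > 0.01) = 5.74
staggered study (true psi = 2):
  psi posterior mode = 8, P(psi=1) = 0.000
  E(tau) mean = 0.0903; omega median = 0.0439; P(omega > 0.01) = 1.000
  Bayes factor (omega <= 0.01 vs > 0.01) = 0.0
```

With a single shared event the posterior mode lands on Ψ = 1 and Ω collapses
to zero (Bayes factor > 1 favors simultaneity); with two widely separated
events all posterior Ω mass exceeds 0.01 and the Bayes factor drops to 0.
Note the staggered Ψ mode is not 2: Ψ counts are unreliable when events are
unevenly spaced, which is why the dispersion index carries the test.

A CLI mirrors these stages (`beringia simulate|stats|date|select|habc|run-all|fixtures`).

## Layout

- `src/beringia/` — the library (io, statistics, dating, coalescent, hABC,
  synthetic data, pipeline, CLI)
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite (unit, property and end-to-end/statistical tests)
- `docs/methods.md` — model assumptions, parameter choices, limitations
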