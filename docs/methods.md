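# Methods

This note documents the statistical machinery implemented in `chemotaxa`,
the assumptions behind each stage, the defaults and why they were chosen,
and what the synthetic-study generator does and does not emulate.

## 1. CHC preprocessing

**Retention indices.** `kovats_index` implements the linear
(van den Dool–Kratz) retention index,
RI = 100·(n + (rt − rt_n)/(rt_{n+1} − rt_n)), appropriate for
temperature-programmed GC runs. The isothermal logarithmic form is not
offered; CHC work is overwhelmingly temperature-programmed.

**Substance grammar.** Annotations are parsed from a deliberately small
shorthand (`13,23-DiMeC37`, `C41:2`, `13-MeC37:1`; EBNF in the README)
rather than free-text IUPAC names. The class label is always derived from
the (methyl count, double-bond count) pair, so annotations cannot
contradict structure.

**Filtering.** A hydrocarbon is retained if in *at least one* chemotype
group its mean proportion is ≥ 0.1 % and it occurs in ≥ 20 % of that
group's samples; non-hydrocarbons are always removed. Thresholds are
applied within groups but the retained set is shared — a substance
abundant in only one chemotype stays in the joint table, which is what a
between-chemotype comparison needs. Polyunsaturated substances (≥ 2 double
bonds) failing both thresholds are rescued when a retained unsaturated
substance of the same chain length exists anywhere in the table: double
bond counts of homologous alkenes vary between colonies, and dropping a
rare diene while keeping its monoene homologue would delete signal, not
noise. The rescue condition is evaluated against the base-pass retained
set (not iterated), which makes filtering idempotent. Filtering operates
on row-normalized proportions, so raw or closed tables behave identically.

**Closure and aggregation.** `normalize_closure` closes rows to 1 (error
on all-zero rows, naming the sample); `aggregate_by_class` pools
proportions per (class, chain length) and per class, conserving row sums
exactly.

## 2. The chemotype network

The algorithm quantifies the separation of CHC profiles in discrete steps
by borrowing the haplotype-network idea:

clr → covariance PCA → per-axis category budget → integer category
sequences → L1 distances → minimum spanning network.

Numerical conventions, all fixed for reproducibility:

- **Zeros before clr** use multiplicative replacement with δ = 1e-5:
  zeros become δ, non-zero parts shrink by (1 − z·δ) where z is the number
  of zeros in the row, keeping rows closed. δ sits well below the 0.1 %
  filter floor, so replaced values never rival real signal. An
  `error_on_zero` strategy is available when silent replacement is
  unwanted.
- **"Eigenvalue" means percentage of variance explained.** The /5 category
  rule is only unit-free on that scale; raw covariance eigenvalues would
  make the budget depend on measurement units.
- **Category budget:** axes < 5 % dropped; 5–10 % gives k = 2; otherwise
  k = round(e/5). A literal reading of "normalize the score to [0, 1] and
  round" yields only two categories regardless of k; scores are therefore
  multiplied by (k − 1) before rounding so that k ordered categories are
  realized, with the axis minimum at category 0 and the maximum at k − 1.
- **Rounding is half-to-even** everywhere a rounding step is specified
  (numpy's `rint`), including ties between adjacent categories.
- **MST determinism:** Kruskal over edges sorted by (weight, label pair);
  tied alternative links (non-tree edges whose weight equals the maximum
  edge weight on the tree path between their endpoints) are off by
  default and flagged `is_mst_edge=False` when requested.
- **Two-group readout:** cutting the single heaviest MST edge (ties broken
  by label pair) partitions the samples; under the reference scenario this
  recovers the generating chemotypes with adjusted Rand index 1.

The PCA uses SVD with a deterministic sign convention (largest-|loading|
entry positive per axis), so scores and loadings are platform-stable.

## 3. Compositional statistics

**Bray–Curtis** d(x,y) = Σ|x_i − y_i| / Σ(x_i + y_i) on non-negative rows
(scipy's implementation); pairs of all-zero rows are an error.

**PERMANOVA** is the one-way pseudo-F on squared distances:
SS_total = (1/n)Σ_{i<j} d²_ij, SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²_ij,
F = ((SS_total − SS_within)/(g − 1)) / (SS_within/(n − g)); p-values
permute whole rows with the add-one convention
p = (1 + #{F* ≥ F})/(n_perm + 1), so p is never exactly 0. SS_within = 0
(all within-group distances zero) maps to F = ∞, which compares correctly
against permuted statistics. Only one-way designs are implemented; every
analysis in scope is one-factor. With Euclidean distances on univariate
data the pseudo-F equals the classical ANOVA F (verified in the tests).

**Zero-distance jitter.** When a substance class is absent from several
samples, identical all-zero rows make PERMANOVA degenerate; seeded
N(1e-8, 1e-8) draws, truncated at zero to preserve non-negativity, are
added to the affected class columns for all samples.

**Mantel** correlates strictly-lower-triangle entries (Pearson), permuting
rows and columns of the second matrix jointly; the alternative is
one-sided ("greater"), matching the convention of the standard vegan-style
implementations, with the add-one p.

**Geographic distances** default to plain Euclidean distance in degree
space — deliberately, because the isolation-by-distance analyses this
package reproduces used degree-space distances; a haversine great-circle
option exists but is off by default.

## 4. Morphometrics (multivariate ratio analysis)

**Reliability.** One-way random-effects ICC(1,1) per variable:
(MS_between − MS_within)/(MS_between + (k−1)·MS_within) over k technical
repeats; variables under 0.85 are dropped and repeats averaged afterwards.
ICC(1,1) is the variant computed by the commonly used `ICCest` default;
duplicated identical repeats give exactly 1.

**Size and shape.** Isometric size is the geometric mean of an
individual's measurements. Shape is obtained by projecting log
measurements onto the orthocomplement of the isometric direction
u = (1,…,1)/√p and running a covariance PCA there. Multiplying an
individual's measurements by any positive constant moves it exactly along
u, so shape scores are invariant to isometric rescaling — the defining MRA
property, asserted to 1e-9 in the tests. Size and shape components
together reconstruct the log data exactly.

**Ratio spectrum.** Variables are ordered by loading on a chosen shape
axis; the two extremes give the axis's best single-ratio interpretation.
Percentile bootstrap CIs (default 68 %, 1,000 replicates) resample
individuals and refit; each replicate's loading vector is sign-aligned to
the original axis by the sign of their dot product — without this the CI
would mix ±v solutions and be meaningless.

**Group tests.** The two-factor MANOVA uses sequential (type-I) SSCP
matrices with species entered before sampling location, Pillai's trace,
and the standard F approximation; the residual SSCP of the full additive
model is the error term. Pillai was chosen as the robust default; with a
single response the procedure collapses exactly to sequential two-way
ANOVA. Size comparisons use Welch's t with Satterthwaite df.

## 5. COI population genetics

**Haplotypes.** Complete deletion: alignment columns containing N or a gap
in any sequence are excluded; identical remaining sequences merge, labels
H1, H2, … by decreasing frequency then first occurrence.

**Networks.** The haplotype network is a minimum spanning network over
Hamming distances (reusing the chemotype-network machinery), with an
optional `max_link` cutoff that removes long edges and can disconnect
clades. This deliberately replaces TCS statistical parsimony: the
connection-probability calculus is not reproduced, but the qualitative
readout — clade separation and mutational step counts — is preserved, and
the MSN is exactly reproducible. Treat the networks as descriptive, not as
parsimony-probability statements.

**TN93 distances** follow Tamura & Nei (1993) from the transition
proportions P1 (purine), P2 (pyrimidine), transversion proportion Q and
empirical base frequencies pooled over the two sequences of each pair,
with pairwise deletion of ambiguous sites. Saturated pairs (a log argument
≤ 0) are returned as NaN and listed. In the equal-frequency,
small-divergence limit TN93 reduces to Jukes–Cantor (tested to 1e-6), and
the distance never falls below the raw p-distance.

**ΦST.** Pairwise ΦST comes from a two-level AMOVA treating the number of
differing sites as the squared inter-individual distance (the standard
convention for sequence AMOVA): σ²_among = (MS_among − MS_within)/n_c with
n_c = (n − Σn_p²/n)/(P−1), ΦST = σ²_among/(σ²_among + σ²_within).
Estimates may be negative; a pair with no molecular variance at all is
undefined (NaN) rather than forced to 0. Significance permutes individuals
between the two populations (add-one p); populations with fewer than two
samples get an estimate but no p. Fixed differences give ΦST = 1 exactly.

**Tajima's D** uses the textbook constants (a1, a2, b1, b2, c1, c2,
e1, e2) with π the mean pairwise difference count and S the number of
segregating sites over complete-deletion columns; S = 0 is an explicit
"no segregating sites" error. The p-value uses Tajima's (1989) beta
approximation: D is rescaled to [D_min, D_max] with
D_min = (2/n − 1/a1)/√e2 and D_max = (n/(2(n−1)) − 1/a1)/√e2 and compared
to the beta density with mean 0 and variance 1; the reported p is
two-sided. This approximation replaces coalescent-simulation p-values;
for borderline calls a simulation-based check is advisable.

## 6. Environmental association

The 2×2 partner co-occurrence table is tested with Pearson's chi-squared
and Yates continuity correction (the convention required to reproduce the
published statistic from the published counts); the correction can be
switched off.

The 19 climate variables mix units (mm, °C), so the climate PCA is
correlation-based (variables standardized); constant variables are
rejected by name.

Occurrence models are binomial GLMs with logit link fitted by IRLS
(statsmodels backend; convergence tolerance 1e-10, 100 iterations). The
published description says "mixed models" but names no random effect, and
the reported df = 1 chi-squared term tests are exactly what fixed-effects
GLM analysis of deviance produces, so the models here are fixed-effects
GLMs. Quasi-separation is detected from runaway coefficients or
non-finite standard errors and flagged rather than raised. Backward
stepwise reduction drops, at each step, the eligible term whose removal
lowers AIC most, never removing a main effect while its interaction
remains, with deterministic tie-breaking by term order. Term tests are
analysis-of-deviance chi-squared tests between nested fits. The AIC is
statsmodels' binomial AIC; only AIC *differences* are ever interpreted, so
the additive constant convention is immaterial.

## 7. The synthetic study generator

The generator produces inputs with the statistical structure the analyses
assume — it is a calibration instrument, not a simulator of
chromatography or molecular evolution in detail.

- **CHC profiles** are logistic-normal: per-chemotype mean log-abundance
  vectors differ by `chemotype_shift` (default 2, in clr-scale log units)
  on `n_marker_substances` (default 10 of 40) marker substances; colonies
  add iid N(0, `within_noise_sd`=0.5) log-scale noise, then rows are
  closed. This matches the clr analysis model exactly and is invertible.
  Values below 1e-4 of the row total are zeroed to exercise zero handling.
  The default 60 + 60 colonies give a clean two-cluster geometry in which
  network recovery should be (and is) essentially perfect.
- **COI alignments**: one random ancestral sequence of 449 bp; the two
  species backbones differ at exactly `fixed_snps_between_species`
  (default 16) randomly placed sites. Within-species variation is
  simulated with msprime as a neutral haploid island-model coalescent over
  `n_populations` (default 4) demes with an ancestral merge at 20
  coalescent units guaranteeing coalescence even with no migration; the
  `migration` knob in [0, 1] maps to the symmetric island rate
  4m/(1 − m) (m = 1 collapses all demes into one pool). Coalescent
  mutations are laid over the species backbone on the non-fixed sites, so
  the between-species difference count is exact by construction. `theta`
  is the expected pairwise diversity of a panmictic clade. A star-genealogy
  shortcut was considered and rejected: it makes every variant a
  singleton, driving Tajima's D to ≈ −1.8 at n = 30, whereas the neutral
  coalescent keeps the site-frequency spectrum honest (mean D ≈ −0.1 at
  θ = 5, n = 30 across seeds, as the calibration tests assert). No
  recombination or selection is simulated.
- **Morphometrics**: log-measurements = per-variable baseline +
  individual isometric size (sd 0.1 log units) + a species shape offset
  (0.2 log units on 3 of 20 variables) + an allometric term (slope 0.1 ×
  size on the last variable) + biological noise (sd 0.05), with two
  technical repeats at sd 0.02 — giving ICCs around 0.97, safely above
  the 0.85 screen, and visible-but-overlapping shape separation. The
  species do not differ in size by default.
- **Environment**: colonies sit on a longitude axis; one standardized
  latent gradient drives all 19 climate variables (temperature-like
  columns load negatively, precipitation-like positively — wetter is
  cooler) with N(0, 0.3) noise, and drives occurrence of one species pair
  through a logistic model with coefficient `climate_slope` (default 2).
  Canopy, plant presence and partner identity are generated with no
  effect, as negative controls. The latent gradient is emitted as ground
  truth so slope recovery can be measured on the correct scale.

Sites (codes and coordinates along a real east–west gradient) are fixed
package data; colonies are assigned round-robin so every population
contains both species. All generators are pure functions of
(config, seed): one global seed expands into per-generator child seeds via
CRC-32-salted SeedSequences, and every emitted entity carries its ground
truth through file round-trips.

**What passing tests show — and don't.** The generator realizes the
analyses' own assumptions (log-normal compositions, neutral genealogies,
log-linear allometry, logistic occurrence). Passing calibration therefore
demonstrates correctness of the implementations and of their coupling, not
robustness to real-data pathologies: co-eluting peaks, misannotated
substances, non-neutral demography, measurement batch effects or spatially
autocorrelated climate residuals are all out of scope.

## 8. Problem sizes and defaults

Simulation-based checks use deliberately moderate sizes chosen to keep the
whole suite quick while leaving comfortable statistical margins: 500 null
replicates with 199 permutations for the type-I calibrations (standard
error ≈ 0.01 on a 0.05 rate), 20 seeds for network recovery, 100 seeds
for slope recovery and panmixia ΦST, 50 replicates for the ICC
closed-form check. The acceptance script mirrors these sizes.

## 9. Known limitations

- The haplotype network is an MSN, not TCS statistical parsimony; no
  connection limit probability is computed.
- ΦST uses pairwise-difference AMOVA only; a haplotype-frequency (GST-like)
  estimator is not implemented.
- Tajima's D significance is the beta approximation, not coalescent
  simulation.
- PERMANOVA is one-way; multi-factor partitioning is out of scope.
- The stepwise GLM explores backward single-term deletions only; it will
  not recover a term dropped early that becomes useful later.
- The chemical-network category budget is scale-dependent by design
  (percent variance); merging datasets with very different substance
  counts changes the budget.
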