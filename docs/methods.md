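# Methods

This note documents the statistical procedures, the synthetic data model,
the defaults, and the design choices behind `tfannot`.

## Target calling (TIP scheme)

For one TF, the input is a genes × bins matrix of non-negative binding
intensities in a window centred on each gene's transcription start site
(TSS). Defaults: 6,000 bp window, 100 bp bins (a 20,000 bp window is the
supported alternative for probing distal regulation; calls from the two
windows agree substantially on simulated data — the package asserts a
Jaccard overlap above 0.5 and typically observes ≈ 0.98).

* Characteristic profile: `w_i = mean_j(s_ji) / Σ_i mean_j(s_ji)` over all
  genes, putative targets included. An optional iterative refinement
  (re-estimating the profile from called targets) exists but is off by
  default; the one-pass estimator is the reference behaviour.
* Score: `g_j = Σ_i w_i s_ji` — linear in the signal, so doubling coverage
  doubles scores and the calls are invariant to gene order.
* Null: scores are standardized with the sample (n−1) standard deviation,
  `z_j = (g_j − ḡ)/s_g`, and converted to one-sided upper-tail normal
  p-values: only an *excess* of TSS-proximal binding is evidence of
  targeting. BH FDR at 0.01 (configurable) makes the call.
* Degenerate inputs are errors, not silent results: all-zero matrices
  (profile undefined), zero score variance, fewer than 3 genes.

The TSS anchoring convention is that bin 0 covers
`[TSS − window/2, TSS − window/2 + bin)`; strand orientation is assumed
handled upstream (signals pre-oriented 5'→3').

## Gene universes

Every 2×2 association test is conditioned on a gene universe that clips
both the TG set and the term member set. An overly large universe inflates
n₀₀ and with it the apparent enrichment; an overly small one inflates
apparent depletion (the odds ratio is strictly increasing in n₀₀ when the
other three cells are positive — a property test asserts this). Policy:
curated sources (OMIM-like, PharmGKB-like, Reactome-like, GO-like) are
tested against the *literature rich* universe — coding genes carrying at
least one curated annotation, with annotated non-coding genes purged;
machine sources (GWAS-like) are tested against all coding genes.

The published counts behind this construction contain a small internal
inconsistency (10,931 literature-rich genes minus 333 purged non-coding
records is 10,598, not the printed 10,561). Nothing in this package
depends on those absolute counts; the rule set, not the numbers, is what
is implemented.

## Association statistics

* Fisher's exact test, one-tailed (enrichment, OR > 1) and two-tailed.
* G-test `G = 2 Σ O ln(O/E)`, one df, as the fast likelihood-ratio
  approximation; zero margins are an error (expected counts undefined).
* Phi coefficient per the standard 2×2 formula; it equals the Pearson
  correlation of the expanded indicator vectors, which the tests verify to
  1e-12 on 1,000 random tables. Its sign gives the association direction.
* Odds ratio reported raw; log₂(OR) applies a Haldane–Anscombe 0.5
  pseudo-count to all four cells only when some cell is zero.
* BH q-values are computed within each annotation source separately
  (different sources have very different term counts and gene coverage);
  the q-driving p-value is configurable (two-tailed by default, since
  depletion is a reportable direction; the one-tailed p is always emitted
  alongside).
* Terms with fewer than 3 in-universe members are skipped (configurable):
  smaller terms support only vacuous tests.

## Randomized-compendium null model

Each real TF is paired with a fake TF holding uniformly resampled TGs.
Sampling is done *within each enrichment universe with the in-universe TG
count matched*: only in-universe genes enter the tests, so matching the
raw TG count while sampling from the universe would systematically hand
fake TFs more usable targets and bias the comparison (this is visible as a
broken triangle symmetry on structure-free data). With the in-universe
matching, real and fake tests are exchangeable under the null.

Per (TF, term) pair the real and fake p-values (G-test by default, per the
original analysis; Fisher selectable) are compared: `n_upper` counts pairs
where the real compendium wins (p_real < p_fake), `n_lower` the opposite.
Under the assumptions that true associations always land in the upper
triangle and false ones split evenly, `n_upper − n_lower` estimates the
number of true associations. Ties — common with discrete test statistics —
are counted separately and excluded from both triangles, preserving the
estimator's antisymmetry under swapping real and fake. Negative estimates
are reported as-is with a warning. The empirical FDR at a p-value cutoff
is `#{p_fake ≤ c} / #{p_real ≤ c}` (0 when the denominator is 0).

## Similarity networks and discordance

TG sharing between two TFs is the 2×2 over the universe; significance uses
the one-tailed Fisher p with BH across all pairs (default FDR 0.01).
"Low" vs "high" TG sharing is dichotomized at OR < 1 vs OR ≥ 1, with ties
going to "high". Target-function sharing compares the TFs' significant
positive term sets over the space of all tested terms (Fisher, BH at
0.05). The discordance analysis stratifies pairs by TG-sharing level and
asks, within each stratum, whether pairs with significant target-function
sharing are enriched for significant known-function sharing — the
known-function set of a TF being the terms annotating the TF gene itself.

The function–function table pairs terms that share at least one
significant regulator, flags identical regulator sets, and reports the
member-gene-overlap OR; pairs with identical regulators and OR < 1 are the
"linked without shared genes" set — functions connected through shared
regulation rather than shared members.

## Diversity (effective numbers)

Uniqueness `u_t = 1/Σ_{t'} φ²_{tt'}` over a symmetric phi matrix with unit
diagonal; φ entries undefined from zero margins are treated as 0 so they
contribute no redundancy and `u_t ≤ 1` is preserved. Diversity `π` is the
sum of uniqueness over an entity's members: three mutually uncorrelated
regulators give π = 3; k perfect copies give π = 1. Note π has no lower
bound of 1 for non-empty member sets — a single regulator that is strongly
correlated with others has u < 1 and yields π < 1; the invariant the
package guarantees is 0 < π ≤ n (π = 0 iff n = 0).

Function uniqueness is computed within each annotation source (per-source
phi matrices over member-gene sharing), and "total diversity" is the sum
of per-source π, matching the per-source presentation of the analysis this
package implements. Regulator uniqueness uses TG-sharing phi between TFs
over the pooled universe.

The pleiotropy analysis is an OLS of function diversity on regulator
diversity with the TG count as covariate (a proxy for data volume and
research attention), reporting the Wald t and two-sided p for the
predictor plus a covariate-free Spearman companion. PageRank over the
TF→TF subnetwork (damping 0.85 by default, uniform teleport, tight
1e-13 convergence tolerance) serves as the hierarchical-position control.

## Synthetic data model

The generator emulates the statistical structure the analysis assumes —
TFs preferentially target functionally coherent gene sets — without
modelling reads, chromatin state, or cell-type specificity.

Defaults (the package's reference scenario): 3,000 genes, 85% coding,
30 TFs (the first 30 coding genes, so TF→TF edges, self-loops and
known-function annotation of TF genes arise naturally), six annotation
sources emulating OMIM/GWAS/PharmGKB/Reactome/GO-BP/GO-MF with 12–20 terms
each of 10–40 members (curated sources draw members from coding genes
only; the machine source from all genes, creating the annotated non-coding
genes the universe purge removes), 30 planted TF–term links, in-term
targeting rate 0.6 against a 2% background, and binding peaks of height
5.0 (Gaussian, sd 300 bp) over noise of sd 0.5 — a 10:1 peak-to-noise
ratio. These sizes keep every stage's planted signal comfortably
detectable while a single run of the full pipeline stays in seconds.

TG membership is an independent Bernoulli per (TF, gene) — no TG–TG
correlation beyond term co-membership. Setting the in-term rate equal to
the background yields structure-free data used to validate the null model
(triangle estimate ≈ 0, empirical FDR ≈ 1) and p-value validity. Because
exact-test p-values on sparse 2×2 tables are discrete and conservative,
the null check asserts validity (P(p ≤ α) ≤ α at working α) rather than
exact uniformity, which no correct implementation could pass.

All randomness derives from a single seed expanded into fixed
per-component substreams (and a CRC-keyed substream per TF for binding
noise), so outputs are bit-reproducible across processes and adding a new
generator does not perturb existing ones.

What passing tests on this generator do *not* show: robustness to
correlated binding artifacts, promoter-composition biases, cell-type
heterogeneity, annotation incompleteness, or literature bias in curated
sources — all properties of real data the simulation deliberately omits.

## Known limitations

* The original analysis' modified TIP variant is described only in its
  supplement; the package implements the original TIP structure with the
  window size and profile estimator exposed as configuration points.
* Flat gene sets only: no GO-DAG propagation or disease-ontology
  hierarchy.
* The compendium is cell-type- and development-stage-agnostic; enhancer
  (distal) regulation beyond the TSS window is out of scope.
* Real-data headline counts (hundreds of annotated TFs, ~10⁴ significant
  associations) require the full curated compendium and live annotation
  databases; the package reproduces the *procedures* and validates them on
  synthetic ground truth plus the published count identities.
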