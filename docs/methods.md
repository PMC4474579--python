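# Methods

## Model and procedure

`netwfdr` controls the false discovery rate for `m` simultaneous gene-level
tests by weighting p-values with functional-network connectivity and
running the Benjamini–Hochberg (BH) step-up on the weighted values.

Given nonnegative weights `W_1..W_m` with `sum_i W_i = m`, the weighted
procedure forms `Q_i = min(P_i / W_i, 1)` and applies BH to the `Q_i`:
sort ascending, find the largest rank `k` with `Q_(k) <= k * level / m`,
reject the `k` smallest. The sum-to-m constraint is what preserves the FDR
guarantee at the nominal level regardless of how informative the weights
are — an adversarially wrong weighting loses power but not error control.
The adjusted value reported per gene is the step-up q-value
`q_i = min_{j >= rank(i)} m * Q_(j) / j`, capped at 1, so that
`rejected_i <=> q_i <= level` holds on any level grid.

Weights come from a functional relationship network: an undirected gene
graph whose edge confidences in `(0, 1]` are posterior probabilities that
the two genes share a biological process. The pipeline is

1. **Subnetwork extraction.** Starting from a user-supplied seed gene list,
   keep all genes reachable within `expansion` hops (default 1) over edges
   with confidence strictly above `min_confidence` (default 0). Seeds
   absent from the network are warned about and skipped; extraction fails
   only if no seed is present.
2. **Total relationship confidence (TRC).** For each gene in the testing
   universe, the sum of the confidences of its incident edges in the
   extracted subnetwork; genes outside the subnetwork get 0.
3. **`log(1 + TRC)` transform** (scheme `log1p`, default; `raw` skips it).
   Seed genes act as hubs and their TRCs can exceed the median by two
   orders of magnitude; the log transform stabilises that variance while
   preserving the gene ranking.
4. **Mean normalisation.** Divide by the mean of the transformed TRCs over
   the *full testing universe* (not just the subnetwork), giving mean-1
   weights that sum to `m` exactly. Normalising over the subnetwork only
   would break the sum constraint over all tests, and with it the FDR
   guarantee, so that reading is rejected.

### Conventions and degenerate inputs

- `Q_i` is capped at 1, and `W_i = 0` forces `Q_i = 1` (including the
  `P_i = 0` corner): a gene with no prior network support cannot be
  rejected, and adjusted values stay valid probabilities.
- If every TRC is zero (no universe gene touches the subnetwork) the
  weights fall back to all-ones with a warning: no network signal means the
  procedure must reduce to plain BH rather than reject nothing.
- Duplicate network edges keep the maximum confidence (conservative toward
  the stronger evidence, deterministic); self-loops are dropped with a
  warning; confidences outside `(0, 1]` are rejected rather than clamped,
  since they are meant to be posterior probabilities.
- Gene identifiers match exactly; optional case-folding is flag-controlled
  and off by default so that data errors stay visible.
- Tied weighted p-values receive identical q-values and identical rejection
  status (running-minimum construction); output tables are sorted by
  `(weighted_p, gene_id)` for deterministic ordering.
- The weight-sum invariant is enforced at relative tolerance `1e-9` — the
  arithmetic is closed-form, so no looser tolerance is needed.
- An optional `min_weight` epsilon floor (default 0) can lift zero-weight
  genes to a small positive weight, followed by a rescale back to sum `m`;
  the default preserves the literal TRC-proportional scheme.

### Sensitivity variant

Because the seed genes define the subnetwork, they tend to receive extreme
weights, which risks circularity. `sensitivity_weights` pins every seed
gene's weight to exactly 1 *before* rescaling, then multiplies the non-seed
weights by the common factor `(m - #seeds) / (their current sum)` so the
total is again `m`. Non-seed zero weights stay zero; the transform is
idempotent. If all genes are seeds, or the non-seed mass is zero, the
result is the uniform all-ones vector (with a warning in the latter case).

### Nominal level

The default rejection cutoff is `level = 0.2`, the conventional choice for
exploratory transcriptome screens where follow-up validation is cheap
relative to a missed finding; it is a plain argument everywhere.

## Over-representation module

Enrichment of a gene list of size `n` against a gene set of size `K` in a
universe of `N` annotated genes uses the one-sided hypergeometric upper
tail `P(X >= k)` (Fisher exact), computed via the survival function with an
exact 1 at `k = 0`. Every set with at least one universe gene is tested and
enters the multiplicity adjustment (BH by default, Bonferroni optionally);
sets with zero query overlap are hidden from the default output but still
count toward the adjustment, since they could have been significant.
Reported frequencies are exact ratios `k/n` and `K/N`. The universe
defaults to the union of the GMT members and is overridable, because
enrichment p-values are only as meaningful as the background they are
computed against.

## Simulation harness

The generator emulates the two structural features the weighting scheme
relies on; the harness then measures FDR and power by Monte Carlo.

**Network.** `n_hubs` genes (default 14, a realistic size for a curated
seed panel) are designated hubs; each is wired to `hub_degree` (default 40)
distinct non-hub genes with confidences drawn from `Beta(1, 4)` — a
right-skewed distribution on `(0, 1)` matching the empirical shape of
functional-network posteriors, where most edges are weak. A further
`background_edges` (default `m`) random edges add diffuse connectivity so
that weight mass is not confined to the hub spokes.

**Labels.** Alternative status is Bernoulli with an odds multiplier
`hub_enrichment` (default 4) inside the hub one-hop neighbourhood and a
compensating lower rate outside, chosen so the marginal alternative
fraction is exactly `pi1` (default 0.1). If the neighbourhood is so large
or the base rate so high that the outside rate would be negative, the
configuration raises as infeasible.

**P-values.** Null genes draw `p ~ Uniform(0, 1)`; alternative genes draw
`p = 1 - Phi(Z + effect)` with `Z ~ N(0, 1)` — the one-sided normal shift
model, exactly uniform at `effect = 0` and stochastically small otherwise.
Default `effect = 2.5` puts individual alternatives near the detection
boundary at `m = 2000`, where weighting has something to contribute.

**Schemes.** Each replicate is adjusted four ways at the same nominal
level: `uniform` (all weights 1 — plain BH), `network` (the log1p-TRC
pipeline with the hubs as seeds), `oracle` (weights proportional to
`1 + alternative indicator`, normalised to sum `m`), and `anti` (the oracle
reversed — adversarially mis-informative but still summing to `m`).

**Estimands.** Per replicate the false discovery proportion
`FP / max(R, 1)` and power `TP / #alternatives`; the harness reports means
over replicates (the empirical FDR is the mean FDP, matching the FDR
definition) with Monte-Carlo standard errors. Under a global null
(`pi1 = 0`) power is undefined and reported as NaN, and the mean FDP equals
the familywise error rate.

**Randomness.** Every replicate draws from `numpy`'s
`default_rng([seed, replicate_index])`, so results are bit-identical for a
given configuration regardless of execution order, and replicate streams
are independent by construction.

**Problem sizes.** The default study (`m = 2000`, 500 replicates) estimates
the empirical FDR to a standard error of roughly 0.005 and runs in well
under a minute on one CPU; unit and property tests use smaller
configurations (`m = 400`, 40 replicates) sized for quick iteration.

## What the synthetic data does and does not show

The generator reproduces the *structure* the method assumes — hub-seeded
connectivity, signal-enriched neighbourhoods, uniform null p-values — not
the marginal distributions of any real RNA-seq experiment: no count noise,
no correlation between tests, no misspecified nulls from normalisation
artefacts, and independent p-values across genes. Passing the simulation
suite therefore demonstrates the procedure's statistical properties
(error control, power ordering, exact reduction to BH) under its stated
assumptions; it does not certify performance on data whose p-values are
correlated or miscalibrated. The FDR guarantee of weighted BH is proven
for independent p-values and holds empirically under the kinds of positive
dependence common in expression data, but users with strongly dependent
tests should interpret the nominal level accordingly.

## Known limitations

- The TRC-proportional weight is heuristic; no claim of optimality is made,
  and alternative transforms plug in through the `scheme` argument.
- Genes absent from the network can never be rejected under the default
  scheme; `min_weight` exists precisely for users who find that too harsh.
- The package consumes exported edge lists; building functional networks
  from data compendia, and computing the gene-level p-values themselves,
  are out of scope.
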