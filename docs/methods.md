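# Methods

This note documents the statistical machinery, the defaults and the
design decisions behind `trait-seascape`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Trait coding and codebooks

Traits are fuzzy-coded: a taxon votes 1 for each modality it has clear
affinity for and 0 elsewhere; profile form rescales each non-empty
taxon–trait block to sum to 1, so a block reads as a frequency profile.
A block with no votes is *missing* — the taxon is undocumented for that
trait — and taxa with missing blocks are excluded from any analysis that
needs the block (`FuzzyTraitTable.complete_taxa` logs the exclusions).
Trait information resolved at genus rather than species level is carried
as a provenance flag only; no taxonomic resolution is attempted.

The bundled effect-trait codebook assigns each modality a small integer
score grading its expected contribution to benthic processes (body mass
1–6, substratum depth occupancy 1–5, mobility 0–4, sediment mixing type
0/1, ventilation 1–3, bioconstruction type 1–3, bioconstruction depth
0–4, feeding-type modalities all 1). Zero scores are meaningful: an
immobile taxon, or one that does not rework sediment or build
structures, contributes nothing to the multiplicative indices below.
Scores can be overridden from YAML (`TraitCodebook.apply_overrides`).

## Species-level indicators

Four indices estimate a taxon's potential contribution to processes
mediating benthic–pelagic coupling, each a product of trait scores:

    mi  = AF · BM · MB · SD        biomixing
    ir  = VP · BM · BT · maxBD     bioirrigation
    de  = BM · Su                  biodeposition
    Dep = BM · De                  deposit feeding

For fuzzy taxa the trait score is the affinity-weighted mean of the
modality scores under the profile (a taxon split 50/50 between two
modalities gets the average of their scores); a `max_affinity`
alternative picks the dominant modality's score instead. Su and De are
the profile affinities of the suspension- and deposit-feeding modalities
of the feeding-type trait. Raw products are rescaled across taxa by the
per-indicator maximum (an all-zero indicator stays zero) and binned
null (0), low (0, 0.1], intermediate (0.1, 0.2], high (> 0.2). Upper
bin bounds are closed; the boundary membership is a convention, chosen
once and tested. Rescaling precedes community aggregation.

## Life-history strategies

Response traits are ordinated by fuzzy correspondence analysis (below);
Ward's criterion is applied to the taxon scores on the first two axes
(scipy linkage, deterministic for a fixed input order, ties broken by
lowest pair index), cut at `k` clusters. `k` defaults to 4 — the full
POSE scheme (Precocial, Opportunist, Survivor, Episodic), defined by the
pace-of-life axis crossed with juvenile mortality — but pools that
express fewer syndromes simply leave archetypes unused. The cluster
count is a free parameter because no principled cut rule exists for
every pool; callers can inspect the linkage matrix.

Labelling matches cluster-mean profiles to canonical archetype templates
over five diagnostic traits — lifespan, age at maturity, annual
fecundity, offspring protection, offspring development — by cosine
similarity, assigning greedily from the strongest match and never using
an archetype twice; a tie within 1e-9 leaves the cluster unlabeled with
a warning. The templates encode the standard syndromes (e.g. precocial:
short life, early maturity, few well-protected internally developing
offspring; episodic: long-lived broadcast spawners with very high
fecundity and unprotected planktotrophic larvae).

## Community aggregation

Let `n_is` be the (by default log10(x+1)-transformed) density of taxon
*i* at site *s* and `p_is = n_is / Σ_i n_is` its relative share.

* response-trait CWM: `CWM_sm = Σ_i p_is q_im` — unitless, per-trait
  modalities sum to 1 per non-empty site (simplex checked to 1e-12);
* effect-trait community value: `Σ_i n_is q_im` — deliberately
  unnormalized (homogeneous of degree 1 in density), as denser
  communities exert larger absolute effects;
* community potential per indicator: `Σ_i n_is · score_i` with the
  [0, 1]-rescaled species scores, then divided by the maximum over the
  sites of the run (fixed bounds are not used; potentials are relative
  to the run);
* group proportions: relative densities summed by life-history label.

Empty sites yield NaN profiles and are logged. Raw-density weighting is
available via `use_raw=True`.

## Ordination family

All analyses are one generalized decomposition: given a centered table
Z, row weights w and a column metric m, the SVD of
`diag(√w) Z diag(√m)` yields eigenvalues λ (summing to the total
inertia `Σ_i w_i Σ_j m_j Z_ij²`), principal-coordinate row and column
scores, and normed column coefficients for projection. Axis signs are
canonicalized by making the largest-|coefficient| column loading
positive per axis; eigenvalues below 1e-12 are treated as null rank.

* **CoA** of the abundance table: `Z = P/(r cᵀ) − 1` with P the relative
  cell frequencies and r, c its margins; total inertia = χ²/N. Zero
  rows/columns are dropped with a warning.
* **MCA** of the environment table: quantitative descriptors are first
  discretized into 3 quantile classes (configurable; the class count is
  declared, not inferred from any particular data set), factors expanded
  into an indicator super-table, each row scaled to sum 1, then the CA
  of that profile table. With uniform weights the classical identity
  (levels/factors − 1) holds.
* **FCA** of the fuzzy profile super-table (profiles divided by the
  number of traits) — the same profile-CA core, which is exactly the CA
  χ²-identity on the super-table.
* **PCA** (weighted, column-standardized) for quantitative trait tables.

Each analysis accepts externally imposed row weights; this is how the
R- and Q-analyses inherit the site and species weights of the CoA of L
before RLQ, and a zero-weight row provably has no influence on the axes.

## RLQ and fourth-corner inference

RLQ decomposes the weighted cross-matrix
`tab = Z_Rᵀ D_site Z_L D_species Z_Q` under the column metrics of the
R- and Q-analyses; its total inertia (the metric-weighted sum of squared
entries of `tab`, equal to the sum of the RLQ eigenvalues) quantifies
the global trait–environment association carried by the species
distribution. Site and species scores are the projections of Z_R and
Z_Q on the normed axes.

Significance uses the sequential permutation scheme with the add-one
estimator `p = (r + 1)/(n_perm + 1)`: **model 2** permutes the site rows
of L (breaking the R–L link, i.e. re-pairing environments with
communities), **model 4** permutes the species columns (breaking L–Q).
Weights, centerings and discretized-class pairings are recomputed per
permutation exactly as the observed pipeline computes them. The default
`n_perm` is 49 999 and every permutation stream is seeded. An
association is declared only when both models reject — equivalently on
the combined `p = max(p₂, p₄)` — and the Benjamini–Hochberg adjustment
is applied across the family of all trait-modality × descriptor pairs
of a run, after the max combination (applying BH per model before
combining is available via `fdr_order`).

Per-pair fourth-corner statistics are weighted pseudo-correlations
(doubly standardized cross-products through the cell distribution of L,
in [−1, 1]) for quantitative descriptors, tested two-sided, and
correlation ratios η² for factors, tested upper-tail. Preliminary
screening retains descriptors and traits whose best unadjusted combined
p over the pair family is ≤ α_screen (α_screen = 1 is the identity;
empty retention raises). Axis-correlation tests relate each RLQ axis to
individual variables (weighted correlation or correlation ratio, with
value permutation).

**Level of the combined test.** Each component permutation test is
exactly calibrated under its own null. The max-p combination attains
the nominal level only on the boundary null where exactly one of the
two links is absent; when *both* links are absent (the generator at
`link_strength = 0`) it rejects only when both component tests do, so
its rejection rate falls below the nominal α — the calibration runs in
the test suite and the acceptance script measure both the component
rates (≈ 5%) and the combined rate (below 5%) rather than asserting
exactness for the combination. This conservativeness is a property of
the sequential procedure itself, not of this implementation.

## Trait distribution models

One network per response variable: input → 12 → 12 → 1 dense layers,
leaky-ReLU hidden activations (negative slope 0.01), linear output —
`12·d_in + 181` trainable parameters (601 at 35 input features). The
exact feature list is configurable; the default design uses the
per-site abiotic summaries plus a one-hot substratum. Inputs are
z-scored with training-split statistics only (constant features dropped
with a warning); the target is likewise z-scored per restart so the
fixed learning rate behaves identically across response scales, and
predictions are mapped back.

Fitting repeats `n_restarts` (default 50) random 0.5/0.3/0.2
train/validation/test partitions and initializations (He-scaled normal
weights, zero biases); each restart trains with full-batch Adam
(lr 0.02, β = 0.9/0.999, up to 3000 epochs) and early stopping on
validation MSE (patience 300 epochs, checked every 10), keeping the
best-validation weights. The restart with minimal validation MSE is
selected; the mean ± sd of the per-restart test MSEs is always kept in
the model card. All randomness derives from one seed through spawned
`SeedSequence`s, so a fitted model is bit-reproducible. Proportion-type
responses can be clipped to [0, 1] post hoc (no link function is used).
Grid prediction applies the selected network to every unmasked cell;
missing features raise by name and masked cells carry NaN.

## Synthetic seascapes

The generator emulates the statistical structure the analysis assumes
on a river-fed shelf: depth increasing offshore (default 5–200 m);
bottom temperature and oxygen derived from 12-month seasonal
climatologies (means and CVs computed with the package's own
climatology summaries), with oxygen declining into a hypoxic deep
stratum; salinity rising away from a river mouth (14→18); substratum
drawn per depth band (< 30 m, 30–70 m, > 70 m) with coarse sediments
frequent inshore and mud dominant at depth. Sites are grid cells
sampled uniformly without replacement (default 60 sites on a 40 × 30
grid).

The species pool (default 40 taxa) mixes Precocial/Opportunist/Episodic
archetypes (shares 0.35/0.40/0.25 — the three syndromes realized in
shelf pools of this kind) with 0/1 trait votes drawn from
archetype-specific templates over all response and effect traits
(episodic: larger sessile suspension feeders; opportunist:
deep-burrowing, ventilating conveyors; precocial: mobile surface
deposit feeders); with probability `flip_noise` (default 0.05) a trait
block is replaced by a random modality. Abundances are Poisson with a
Gaussian niche on bottom oxygen: expected log-density
`b_l + link_strength · A · exp(−(DOX − μ_l)²/2σ²)` with archetype niche
centers 60/190/280 µmol l⁻¹, width 60, amplitude A = 3 natural-log
units, species baselines around 5 ind m⁻², and lognormal site × species
noise (sd 0.4). `link_strength = 0` removes all environmental
dependence, giving an exact null; `base_density = 0` gives a valid
empty table. Everything is deterministic under a fixed seed.

What the generator does *not* emulate: spatial autocorrelation beyond
the smooth gradients, temporal dynamics, sampling-gear selectivity,
taxonomic mis-identification, and abundance overdispersion beyond the
lognormal noise (counts are Poisson, not negative-binomial). Recovery
tests passing on these seascapes therefore demonstrate correctness of
the estimators, not field performance on real survey data.

## Numerical conventions and degenerate inputs

* climatology sd uses the population denominator (n; `ddof`
  configurable); CV = sd/mean, NaN-flagged at zero mean.
* profile rows sum to 1 within 1e-12; inertia identities are tested at
  1e-10; the eigenvalue rank cutoff is 1e-12.
* permutation counts use a 1e-12 slack on ≥ comparisons so ties count
  as exceedances (conservative).
* all-identical profiles yield a flagged zero-inertia FCA; constant
  targets fit exactly via the target normalization guard; empty sites,
  all-zero indicators and fully masked grids all return well-defined
  degenerate outputs rather than raising.

## Problem sizes used in the bundled checks

The test suite and acceptance script run at desk scale, chosen so the
full set of checks completes in about a minute: 500 null seascapes of
20 sites × 25 taxa at 199 permutations for calibration, 999
permutations for power, 40-taxon pools for life-history recovery,
150-site seascapes with 10 restarts for TDM recovery, and 50 random
small tables for the inertia oracles. Defaults inside the package
(49 999 permutations, 50 restarts) remain at the full analysis scale.

## Known limitations

* MCA discretization uses rank-based quantile classes; heavily tied
  descriptors can yield unbalanced classes.
* The archetype labelling is a heuristic over five diagnostic traits;
  pools whose clusters mix syndromes may be left unlabeled.
* The TDM optimizer is full-batch Adam on small site sets; very large
  site tables would warrant mini-batching.
* Community potentials are rescaled within a run, so values are not
  comparable across runs with different site sets.
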