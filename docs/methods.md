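# Methods

## The statistic

For three standardized profiles over n samples, liquid association is the
mean elementwise triple product, LA(X, Y | Z) = (1/n) Σᵢ xᵢyᵢzᵢ.  When the
profiles have standard-normal marginals and E[X Y | Z = z] = c(z) for some
correlation curve c, the population value is E[Z·c(Z)]: the statistic is the
covariance between the mediator's level and the pair's conditional
correlation, so it is zero when c is constant and positive when c increases
with z.  The statistic is symmetric in its three arguments; the asymmetry in
the name ("Z mediates (X, Y)") is an interpretive choice, not a property of
the number.

**Denominator with missing data.** The plain formula divides by the total
sample count, which is undefined when entries are missing.  The default here
divides by the number of *complete triples* (samples where x, y and z are all
observed), keeping the statistic a mean; a `total_n` mode divides by the full
profile length instead.  With no missing data the two coincide.  Triples with
fewer than 3 complete samples are an error (or are dropped from rankings).

## Per-batch normal scores

Merged datasets concatenate samples from unrelated experiments.  Rather than
model batch effects, each gene profile is replaced, *within each batch
separately*, by the standard-normal quantiles of its ranks: the value with
rank r among m observed values becomes Φ⁻¹(r/(m+1)) (van der Waerden scores,
the convention of the rank-transform literature; Blom's (r−3/8)/(m+1/4) is
available as an option).  Ties share the average rank by default
(`average_rank`), which is deterministic and independent of input order; a
`stable_order` policy breaks ties by position instead, guaranteeing the
output is an exact permutation of the quantile grid.  Missing values stay
missing; a gene with fewer than two observed values in a batch is retained
but fully masked for that batch and flagged.  The concatenated profile is
**not** re-standardized after merging — the statistic is computed directly on
the per-batch scores — though each batch's tie-free profile sums to zero by
symmetry of the grid.

Consequences worth knowing: the transform is invariant under any strictly
increasing per-batch relabeling of the data, idempotent on tie-free input,
and antisymmetric under rank reversal.

## Search modes and ranking

`scout_z` scores every candidate Z (all genes minus the pair itself, minus
genes with too few complete triples) as one masked matrix-vector product;
`search_pairs` scores every unordered pair (Y, Z) for a fixed X as the
cross-product G·diag(x)·Gᵀ of the masked gene matrix, reporting each pair
once with its members in lexicographic order.  Both match a brute-force loop
to 1e−10 by construction (tested).  Rankings are read off each signed end:
TOP (descending scores, positive scouting genes) and BOT (ascending), with
1-based places.  Exact score ties are ordered lexicographically by gene id —
an arbitrary but reproducible rule.  The default list length is 20.

## Significance

The origin of printed p-values in the motivating analyses is not specified
anywhere, so two documented routes are provided and neither is promised to
reproduce any published p:

- **Permutation** (default; B = 10,000, one-sided in the observed direction):
  Z is shuffled across sample positions, *within each batch* by default so
  that the null respects the per-series transform, and
  p = (1 + #extreme)/(B + 1).  Missing entries travel with the shuffled
  values and each replicate is scored on its own complete triples.
- **Asymptotic**: on normal scores the null statistic is a mean of n products
  with unit variance per term, so √n·LA is referred to a standard-normal
  tail.  At n = 88 and B = 20,000 the two routes agree within Monte-Carlo
  error on Gaussian nulls (tested).

One-sided signed p-values are the default in reports because the TOP/BOT
lists are sign-specific; two-sided is available (and is what the uniformity
calibration test uses, since the signed-one-sided p of a symmetric statistic
is uniform on (0, 0.5], not (0, 1]).

The **null-pool experiment** draws lead pairs uniformly without replacement
from a user-supplied pool (distinct unordered pairs, via linear pair-index
sampling), scouts each pair over *all* candidate genes, and counts how often
each target gene takes place 1 on the positive end ("leading mediator";
a flag extends this to either end).  count/n_pairs estimates the chance
detection rate.  The pool is user-defined by inclusion or exclusion lists —
any published pool of "pathway-irrelevant" genes is not recoverable exactly,
so no default pool is shipped beyond the named-gene alias table.

## LAP views

`lap_split` orders samples by the mediator (ties broken by sample position,
deterministic), takes the top and bottom `split_fraction` of observed-z
samples (default 0.5, i.e. a median split; an odd middle sample is excluded)
and computes the Pearson correlation of (x, y) within each subgroup over
complete pairs.  Subgroups need at least 3 complete samples; a constant x or
y within a subgroup yields a flagged NaN correlation rather than an error.
Correlations are computed in whichever data space the caller passes —
transformed space is the default in reports, since that is where the
statistic lives, with raw space available for display.  The split convention
is configurable because published high/low correlation pairs for one and the
same triple differ between table and figure in the motivating study,
implying different unstated conventions; neither specific value set is an
acceptance surface of this package.

## Synthetic data and its oracle

The generator emulates a merged multi-series dataset: batches of independent
samples (default sizes 20/60/8, mirroring a three-series merge totalling 88
conditions), background genes i.i.d. N(0, 1), and planted triplets where
Z ~ N(0, 1) and (X, Y) | Z is bivariate normal with unit variances and
correlation c(Z).  Mediation families: `tanh` (c = ρ·tanh(κz), default
ρ = 0.9, κ = 1 — a strong but sub-unit correlation ceiling with an
effectively linear core), `linear_clipped`, and `constant` (a null with
correlated pair but no mediation).  Missingness is completely at random.
E[Z·c(Z)] is evaluated by 128-node Gauss–Hermite quadrature (relative error
< 1e−8 against a dense trapezoid grid; for c = tanh at ρ = κ = 1 the value
is ≈ 0.6057).

What a green synthetic test does and does not establish: it verifies the
statistic, the transform, the searches and the calibration machinery on a
model whose truth is known analytically; it says nothing about dye bias,
spatial artifacts, informative missingness, probe-level replication or any
other physics of real spotted arrays, and nothing about whether a particular
biological dataset satisfies the generative assumptions.

## Numerical and design choices

- Missing marker: NaN throughout; blanks and unparseable cells in input
  tables become NaN.  Values are written with `%.17g` and parsed in
  round-trip precision mode, so writer → reader is bit-exact for finite
  entries.
- Probe rows: tables are analysed at whatever row granularity they provide;
  an explicit, off-by-default `collapse_probes` step averages replicate
  probes (NaN-aware) *before* transformation.
- Merging: default gene policy is intersection (the statistic needs all
  three profiles on common samples); union-with-missing is available.
  Sample ids are prefixed with their series id only when collisions require
  it.
- Seeding: every stochastic operation takes an explicit integer seed;
  replicate seeds are derived through `numpy.random.SeedSequence` and kept
  below 2³¹.
- CLI: outputs are written atomically (temp file + rename) with a version +
  config-hash comment header and a JSON provenance sidecar; logs go to
  stderr only.

## Known limitations

- No multiple-testing correction across genome-wide rankings (raw p-values
  and places are reported, as is conventional for scouting lists).
- No array normalization, background correction or ComBat-style batch
  regression: the per-batch normal score *is* the batch handling.
- The asymptotic p-value ignores the slight negative dependence the
  rank transform induces within a batch; at the default within-batch
  permutation this does not matter, and the two routes agree empirically at
  n ≈ 88.
- `search_pairs` materializes a genes × genes score matrix; at ~5,000 genes
  this is ~200 MB × 2 and runs in minutes on one CPU, but it will not scale
  to very large gene sets without blocking.
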