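# Methods

## Setting and data model

`sweepmodes` asks which mode of convergent adaptation best explains allele
frequencies at a candidate locus shared by several populations.  The data
are two matrices of sample allele frequencies (populations × sites): one
from unlinked, putatively neutral sites, one from the selected region with
per-site genomic positions; plus per-population haploid sample sizes, a
single effective population size `Ne`, and a per-base recombination rate
`rec`.  At least three selected and three non-selected populations are
expected, and all populations are assumed to share one `Ne`.  Estimating
the frequencies themselves (from VCF/BAM) is out of scope, as is any allele
polarization: frequencies and positions are consumed verbatim.

At each site, deviations from the across-population mean frequency
`ε = mean(x)` are standardized by the binomial scale
`sqrt(ε (1 − ε))`; `ε` serves as the ancestral-frequency proxy.  The
unweighted mean over *all* populations is used — selected and non-selected
alike — since nothing distinguishes them at neutral sites.  Sites with
`ε ∈ {0, 1}` (monomorphic across all populations) have no defined
standardization and are dropped everywhere, with a logged count.

## Neutral coancestry

The k×k coancestry matrix `F` is the mean over usable neutral sites of
`z zᵀ`.  Two conventions matter:

* **Sampling noise lives on the model side.**  The likelihood adds
  `diag(1/n)` to every model covariance, so `F` itself must describe drift
  alone.  Sample frequencies carry binomial noise of expected magnitude
  `x(1−x)/n` per site; its unbiased per-site estimate `x̂(1−x̂)/(n−1)` is
  averaged, placed on the diagonal, spread through the mean-centering
  projector `P = I − J/k` (centering mixes per-population noise into
  off-diagonals), and subtracted.  Without this, the noise would be counted
  twice — once inside the estimate, once as `diag(1/n)` — which measurably
  biases the inferred selection coefficient downward.  Sample sizes of 1
  conventionally mean "frequencies known without sampling error" and
  disable both the correction and (effectively) nothing else; the
  correction requires n ≥ 2 everywhere.
* **Only the centered component of `F` is identifiable.**  Deviations are
  measured from the across-population mean, so the likelihood only ever
  sees `C F Cᵀ`, where `C` is the first k−1 rows of `P`.  Working in the
  (k−1)-dimensional centered coordinates restores the rank lost to
  centering and enables the fast Cholesky path.

## Mode kernels

With sweep duration approximated as `t_s = ln(4 Ne s)/s` generations
(requiring `4 Ne s > 1`), a lineage at recombination distance `r` stays
associated with the sweeping background with probability
`y = exp(−r t_s)`.  Writing `F'` for the model coancestry at distance `r`
(entries not listed are unchanged; non-selected populations are never
touched):

* **independent**: `F'_ii = y² + (1−y²) F_ii` for selected `i` — both
  lineages retained implies coalescence during the local sweep.
* **migration** (source `src`, rate `m`): all selected diagonals take the
  sweep form above.  A retained recipient lineage traces into the source
  with probability `q = y exp(−r/m)` — the migrant haplotype waits on the
  order of `1/m` generations to establish, exposed to recombination
  throughout.  Then `F'_{i,src} = q (y + (1−y) F_{i,src}) + (1−q) F_{i,src}`
  and, for two recipients, `F'_{ij} = q² + (1−q²) F_{ij}`.
* **standing** (frequency `g`, time `t`): on the standing haplotype, pair
  coalescence at rate `κ = 1/(2 Ne g)` competes with recombination at total
  rate `2r`.  Within a population the standing phase and its ancestral
  continuation together give the unbounded-time probability
  `p = κ/(κ+2r)`; between populations each lineage must first survive its
  own standing phase of `t` generations without recombining, giving
  `exp(−2rt) · p`.  Both enter as mixtures toward 1:
  `F'_ii = y²(p + (1−p)F_ii) + (1−y²)F_ii`, and analogously off-diagonal
  with `exp(−2rt) p`.  Longer standing times therefore *reduce*
  between-population sharing while leaving the within-population signal
  unchanged, which is what lets the data inform `t`.
* **standing_source**: identical, except the source population's diagonal
  uses the sweep (new-mutation) form.
* **multi**: each group in a user-supplied partition of the selected
  populations gets its own kernel on the shared `F`; convergence events in
  different groups are independent, so no cross-group coancestry is added.
  A single group reproduces the single-mode kernel bitwise.  Because the
  output schema has one `sources` column, one group per fit may use a
  source-requiring mode (migration or standing-with-source), and the source
  grid is restricted to that group's members.

A design note on the standing kernel: an earlier formulation applied the
time-limited coalescence probability `(κ/(κ+2r))(1 − e^{−(κ+2r)t})` on the
diagonal and the unbounded-time probability off-diagonal.  That inverts the
physics — it makes two lineages in *different* populations more likely to
coalesce than two in the same one for every finite `t` — and guarantees a
non-positive-semidefinite selected block, which a generator cannot
reproduce.  Summing the diagonal's two stages collapses exactly to
`κ/(κ+2r)`, and the `exp(−2rt)` decay belongs between populations; the
kernels above follow that accounting.

Full positive-definiteness of `F'` is still not guaranteed in general
(inflating a submatrix toward a shared haplotype can push small negative
eigenvalues elsewhere), which is exactly why a generalized-inverse path
exists alongside Cholesky.

## Composite likelihood

For a proposed selected site, each usable selected-region site at
`r = rec · |position − proposed|` contributes the zero-mean Gaussian
log-density of `w = C z` under `Σ(r) = C (F'(r) + diag(1/n)) Cᵀ`; the
composite log-likelihood is the sum over sites.  Sites are grouped into
`num_bins` uniform, right-closed distance bins over `[0, max r]` and the
kernel is evaluated once per occupied bin at the bin midpoint; per-bin Gram
matrices make the cost per grid point independent of site count.  Whenever
`num_bins` is at least the number of distinct distances, the distinct
distances themselves are used as bin representatives, making binning exact
(uniform midpoints alone would not be).

Two linear-algebra paths are available (`cholesky: true|false`).  The
default factorizes the whole bin stack at once; on failure it retries once
with diagonal jitter `1e-10 · trace/p`, then falls back to a batched
eigendecomposition pseudo-inverse (eigenvalues below `p · eps · max|λ|` are
treated as zero) for that stack — logged, never fatal.  The two paths agree
to relative 1e-6 whenever Cholesky succeeds.

Grids per mode multiply proposed sites by: `sels` (independent);
`sels × migs × sources` (migration); `sels × times × gs` (standing, no
source); `sels × times × gs × sources` (standing_source); the union of the
groups' axes (multi).  The neutral model has no parameters; its constant
`cle` is reported once per proposed site so the 10-column schema and
row-binding workflow hold.  Row order is the deterministic nested loop
sites → sels → migs → times → gs → sources, and MCLE ties break to the
first row in that order.  Population indices are 1-based in configs and
outputs (matching how users count rows) and 0-based internally.

## Synthetic data

The generator exists to test the estimator and likelihood against a known
truth, so it samples from the model's own covariance structure rather than
running forward simulations.  Per site, an ancestral frequency
`ε ~ Uniform(0.05, 0.95)` is drawn, and population frequencies come from a
Gaussian copula with Balding–Nichols Beta marginals:
`x_i ~ Beta(ε(1−F_ii)/F_ii, (1−ε)(1−F_ii)/F_ii)` has mean `ε` and variance
`ε(1−ε) F_ii` *exactly* on [0, 1] and tends to the two-point {0, 1} law as
`F_ii → 1` (complete coalescence), while the copula correlation
`F_ij / sqrt(F_ii F_jj)` carries the across-population structure.  Clamping
plain Gaussian draws to [0, 1] was measured to destroy variance precisely
where sweep kernels push coancestry toward 1, biasing recovered selection
coefficients low; the copula construction removes that distortion (its one
approximation: product-moment cross-correlations are attenuated by a few
percent relative to the copula parameter for intermediate coancestries).
An optional binomial layer adds finite-sample noise; when it is off, the
returned sample sizes are 1 ("no sampling error").

The default truth is the centered component of a two-clade drift matrix
(shared clade branches 0.03, terminal branches 0.05 — F_ST-scale drift
typical of the systems these models are applied to); only the centered
component is identifiable, so it is the right target for recovery tests.
The example fixture mirrors the worked example's shape: six populations,
selected indices 1, 3, 5, true site at position 0, `s = 0.05`,
`Ne = 10⁴`, `rec = 0.005` per unit position, sample sizes 10, and the
printed grids (23 selection coefficients, 9 standing times, 5 standing
frequencies, 5 migration rates, 3 proposed sources, 10 proposed sites,
1000 bins).  Region size defaults to 200 polymorphic selected-region sites
and 10,000 neutral sites — the region length is stated in the worked
example but its polymorphic-site count is not, so these were fixed once as
realistic values and used for all tests and the acceptance script.

What passing recovery tests on these data do *not* show: robustness to real
sweep genealogies (linkage between sites, non-Gaussian drift at large
F_ST), demographic misspecification, population-specific `Ne`, or
mutation-rate heterogeneity.  The generator is an oracle for the
likelihood's own assumptions, no more.

## Tunable parameters

| parameter | meaning | units | default / constraint |
|---|---|---|---|
| `Ne` | effective population size (all populations) | individuals | required, > 0 |
| `rec` | recombination rate per unit position | Morgans/unit/gen | required, > 0 |
| `sels` | proposed selection coefficients | per generation | > 0 and `4·Ne·s > 1` |
| `migs` | proposed migration rates | migrant fraction/gen | > 0 (never 0) |
| `times` | proposed standing times | generations | ≥ 0 |
| `gs` | proposed standing frequencies | — | in (0, 1) |
| `sources` | proposed source populations | 1-based index | must be selected |
| `n_sites` / `sel_sites` | proposed selected sites | — / position | exactly one given |
| `num_bins` | distance bins per proposed site | — | ≥ 1 (1000 in the example) |
| `cholesky` | fast factorization path | — | true |

## Known limitations

* Composite likelihoods ignore linkage between sites: support values are
  overconfident, and richer modes can edge out the true one without the
  difference being meaningful.  Parametric bootstrapping for formal mode
  comparison is deliberately not included.
* Grid evaluation only — no optimizer; resolution is set by the grid, and
  `s` is typically recovered to within one grid cell, with a slight
  downward pull when sample sizes are small (the model's `diag(1/n)` term
  overstates binomial noise at near-fixed sweep sites).
* Single `Ne` for all populations; no deletions, concurrent sweeps, or
  population-size variation.
* One source-requiring group per mixed fit (single `sources` column).
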