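# Methods

## Model and assumptions

`wcna` treats a two-condition time-course expression study as a pair of
co-expression graphs and asks which nodes change degree between them.
The underlying model assumptions are:

- **Profiles are comparable after min–max normalization.**  Each
  record's 12-point profile is mapped affinely onto [−1, 1], so only the
  *shape* of the trajectory matters; absolute intensity and dynamic
  range are discarded.  This suits single-channel microarray intensities
  where between-probe scale is not meaningful.  A constant profile maps
  to all zeros (the midpoint of the target interval), which makes flat
  records zero-variance and therefore edgeless downstream rather than
  spuriously correlated.
- **Similarity is assessed in the wavelet domain.**  One level of an
  orthonormal discrete wavelet transform splits each profile into a
  low-frequency trend (approximation coefficients C₁…C₆) and
  high-frequency fluctuation (detail coefficients D₁…D₆).  Correlating
  the concatenated vector [C, D] weighs trend and fluctuation agreement
  together while localizing them in time — two probes must track each
  other at both scales to correlate strongly.  Because the transform is
  orthonormal (Parseval: ‖x‖² = ‖C‖² + ‖D‖²) no variance is lost or
  double-counted.
- **Connectivity is a hard-threshold degree.**  An edge exists where
  τ ≤ |r| ≤ 1; the graph is unweighted and the only topological
  statistic used is the degree lᵢ.  Sign is deliberately ignored:
  strong anti-correlation is as much "co-regulation" as correlation.
- **Differential importance is a degree difference.**  mᵢ =
  lᵢ(A) − lᵢ(B).  The square ratios S₋ = Σ_{m<0}m²/Σm², S₊ =
  Σ_{m>0}m²/Σm² (S₋ + S₊ = 1 whenever any m ≠ 0) summarize which sign
  of rewiring carries the mass; the per-sign extreme tails are the
  reported key genes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ | 0.7 | hard correlation threshold, inclusive; edges need τ ≤ \|r\| ≤ 1 |
| wavelet basis | `haar` | any orthogonal PyWavelets basis (`db2`, `db3`, …); periodization boundary |
| decomposition level | 1 (fixed) | 12 points → 6 + 6 coefficients; even length required, odd lengths must be padded explicitly |
| smoothing window | 101 if n > 1000, else ≈ 5 % of n (odd) | centered moving average before knee detection; shrinks at edges |
| knee method | `chord` | see below; `curvature-max` and `manual` available |
| screening threshold | knee of distance curve | manual override selects exactly {d > t} |
| branch thresholds | knee per sign branch | manual overrides select m ≤ t₋ / m ≥ t₊ inclusively |

τ = 0.7 is the conventional "high correlation" cut for hard-threshold
co-expression networks and the value used in the coral study this
package reproduces.  The Haar default is the only basis whose
coefficients are hand-checkable pairwise sums/differences
(c_k = (x₂ₖ₋₁ + x₂ₖ)/√2, d_k = (x₂ₖ₋₁ − x₂ₖ)/√2) and has no boundary
spill at length 12; the basis is configurable because downstream counts
can be sensitive to it, and outputs record which basis produced them.

## Knee detection

Sorted curves (distances; per-sign degree differences) are smoothed with
a centered moving average and cut at a knee.  Two automatic detectors
are provided:

- **`chord`** (default): the point of the smoothed curve farthest from
  the straight line joining its endpoints.  This is scale-invariant —
  multiplying the values or changing the number of points does not move
  the knee — which matters for the degree-difference branches: short
  integer-valued curves with long plateaus, where slopes per index step
  routinely exceed 1.
- **`curvature-max`**: argmax of |Δ²s| / (1 + (Δ¹s)²)^{3/2}.  This is
  the textbook discrete curvature but is *unit-dependent*: wherever the
  local slope is ≫ 1 the denominator suppresses genuine corners, so on
  plateau-heavy curves it locks onto micro-kinks in the flattest region
  (any unit step in a plateau scores κ ≈ 0.7, beating the true elbow).
  It behaves well on long, dense curves whose slope is ≪ 1 per step —
  the regime of a 17 000-point distance curve — and is retained for
  that use and for comparability.
- **`manual`**: a threshold applied directly to the raw values, the
  reproduction path for published cut-offs.

Selection semantics: screening keeps records with rank strictly above
the knee index (with a manual threshold t this is exactly {d > t}).
Key-probe branches cut **by rank** under automatic knees — the members
on the extreme side of the knee point — because on integer curves the
knee value is itself a datum and value-inclusive selection would drag in
its entire plateau; manual branch thresholds are value-inclusive
(m ≤ t₋, m ≥ t₊), matching how published integer tails are stated.
Ties among equal differences at a rank cut are broken by input record
order (deterministic).  Degenerate curves (strictly linear, or all
values equal) log a warning and return the earliest index, selecting
nothing meaningful rather than guessing.

## Synthetic data

`wcna.synthetic` emulates the two-day circadian design: 12 timepoints at
4 h intervals, 3 replicates, conditions LD and DD, intensities on an
arbitrary baseline.  A planted module shares a standardized latent
signal z_c (a 24 h sinusoid of per-condition amplitude plus latent
noise); member i in condition c is √ρ_c·z_c + √(1−ρ_c)·εᵢ with unit
Gaussian εᵢ, so the expected within-module correlation is ρ_c exactly
and tightness can differ by condition — the ground-truth table records
membership and the implied sign of each probe's degree difference.
Background probes are independent Gaussian noise; replicates add
independent noise on top of the probe signal.

What the generator does *not* emulate: probe-level hybridization
effects, intensity-dependent variance, correlated background structure,
non-sinusoidal rhythms, or missing values.  Passing recovery tests on
this generator therefore demonstrates that the chain detects planted
differential tightness under idealized noise — not that it is robust to
microarray artefacts, which should be handled upstream.

Simulation sizes used by the test suite and `scripts/acceptance.py`
(300 probes, one 30-probe module with ρ = 0.9 in DD vs 0.2 in LD,
background and latent noise sd 1.0, replicate noise sd 0.3) mirror the
post-screening problem size of the coral study; at these settings the
planted module's members are the strongest negative-difference probes
and the automatic knee recovers them in full across seeds.

## Numerical choices

- Pearson correlation uses population moments (the ddof cancels in the
  ratio); vectors whose standard deviation is below 10⁻¹² relative to
  their magnitude are flagged degenerate and given r = 0 off-diagonal
  with a logged warning (constant profiles survive float summation with
  sd ≈ 10⁻¹⁷, hence the relative test).  A matrix of only degenerate
  vectors is an error.
- The adjacency comparison at τ is inclusive; the diagonal is forced to
  zero (self-correlation ignored).
- Wavelet transforms use PyWavelets with the `periodization` mode, which
  keeps exactly n/2 + n/2 coefficients and preserves orthonormality;
  perfect reconstruction and energy conservation are enforced at 10⁻⁹
  in the test suite.
- Replicate and probe-to-gene averaging are unweighted arithmetic means;
  the processing order is replicates → gene collapsing → normalization.
- Missing values are rejected at load time; the GEO series-matrix reader
  requires an explicit sample→(condition, timepoint, replicate) mapping
  table because GEO metadata encodes the design as free text, and drops
  unmapped samples with a warning rather than guessing.

## Known limitations

- Twelve timepoints give noisy correlation estimates; at τ = 0.7 and n
  = 12 spurious edges are common, so individual degrees are noisy and
  only large degree *differences* are meaningful.  The null-data test
  documents this: pure noise still yields nonzero branches, and the
  knee cut keeps them small but not empty.
- Automatic knees are heuristics.  On curves with no real elbow they
  return an arbitrary (warned) cut; published thresholds should be
  applied via the manual method when reproducing a specific analysis.
- The choice of wavelet basis is not identifiable from downstream
  counts alone; sensitivity should be checked by sweeping `haar`,
  `db2`, `db3` when exact reproduction matters.
- Gene collapsing averages probes before normalization, which weights
  probes equally regardless of their dynamic range.
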