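# wcna — wavelet correlation network analysis

`wcna` finds genes whose *network connectivity* — not merely their
expression level — changes between two experimental conditions in a
time-course expression study.  It was built for circadian microarray
designs such as the coral *Acropora millepora* experiment contrasting an
ambient light/dark cycle (LD) with constant darkness (DD): 12 timepoints
sampled every 4 h over two days, three biological replicates, two
conditions.  It is aimed at systems biologists who want a transparent,
fully scripted alternative to ad-hoc spreadsheet + MATLAB workflows for
differential co-expression analysis.

## Method

For each condition, every record's profile **x** = (x₁ … x₁₂) is

1. **normalized** to [−1, 1] by the min–max map
   x′ⱼ = 2(xⱼ − x_min)/(x_max − x_min) − 1 (constant records → 0),
   after replicate averaging and optional probe→gene collapsing;
2. **screened**: records are ranked by the between-condition Euclidean
   distance d = ‖x′⁽ᴬ⁾ − x′⁽ᴮ⁾‖₂ and the high-distance tail is kept,
   cut at a knee point of the sorted curve or at a user threshold;
3. **wavelet-transformed**: one level of dyadic discrete wavelet
   decomposition (Mallat filter bank, Haar by default, periodic
   boundary) maps the 12-point profile to six approximation
   coefficients **C** and six detail coefficients **D**; the *frequency
   vector* is the concatenation [**C**, **D**];
4. **networked**: Pearson correlations r_ij between frequency vectors
   give a correlation matrix R per condition, and a hard threshold
   places an edge where τ ≤ |r_ij| ≤ 1 (default τ = 0.7).  A record's
   connectivity lᵢ is its degree.

The between-condition degree difference mᵢ = lᵢ(A) − lᵢ(B) is summarized
by the square ratios S₋ = Σ_{m<0} m² / Σ m² and S₊ = Σ_{m>0} m² / Σ m²,
and the records in the extreme tails of the sorted differences — beyond
a knee point or explicit thresholds — are reported as *key genes*:
candidates for condition-dependent rewiring of the co-expression
network.  See `docs/methods.md` for assumptions, parameter defaults and
numerical details.

## Worked example

Simulate the study design with one planted 30-probe module whose
co-expression is tight in DD (target within-module r = 0.9) and loose in
LD (r = 0.2), then run the network chain on all probes:

```python
from wcna.synthetic import SimulationConfig, ModuleSpec, simulate_dataset
from wcna.pipeline import PipelineConfig, run_chain

cfg = SimulationConfig(
    n_probes=300,
    modules=[ModuleSpec(size=30, correlation={"LD": 0.2, "DD": 0.9},
                        amplitude={"LD": 1.0, "DD": 1.0})],
    seed=1,
)
dataset, truth = simulate_dataset(cfg)
result = run_chain(dataset, PipelineConfig(screening_skip=True))
for key in ("n_records", "n_negative", "n_positive", "n_zero",
            "square_ratio_negative", "square_ratio_positive",
            "n_key_negative", "n_key_positive", "n_key_total"):
    print(f"{key}: {result.report[key]}")
planted = set(truth.loc[truth["module"] == 0, "probe_id"])
hit = planted & set(result.table.selected_negative)
print(f"planted module recovery: {len(hit)}/{len(planted)}")
```

prints

```
n_records: 300
n_negative: 119
n_positive: 143
n_zero: 38
square_ratio_negative: 0.9576
square_ratio_positive: 0.0424
n_key_negative: 37
n_key_positive: 50
n_key_total: 87
planted module recovery: 30/30
```

Reading: 119 probes are more connected in DD than in LD (negative m),
and although slightly *more* probes have positive differences, the
negative differences carry 95.8 % of the squared-difference mass —
the planted dark-tight module dominates the rewiring signal.  All 30
planted probes land in the selected negative-difference set (the
positive selection is the knee cut of a pure-noise branch and is
correspondingly unremarkable).

The same pipeline runs from the shell:

```sh
wcna simulate --seed 1 --out sim/
wcna preprocess sim/expression.tsv --out sim/working.tsv
wcna network sim/working.tsv --tau 0.7 --out sim/net/
```

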