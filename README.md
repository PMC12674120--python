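# dwmerge

Bayesian scaling and merging of **related** crystallographic datasets under
double-Wilson structured priors.

Comparative crystallography measures small structural changes — a ligand
binding, a photo-excited intermediate, an anomalous scatterer — as differences
ΔF between structure factor amplitudes of closely related datasets. Those
differences are usually far smaller than the systematic errors of each
individual dataset, so how the unmerged intensities are scaled and merged
decides whether the signal survives. `dwmerge` treats the problem as joint
Bayesian inference: all related datasets are scaled and merged **together**,
with a prior that knows they are similar.

## The model

Complex structure factors are sums of many atomic contributions, so their real
and imaginary components are Gaussian with variance set by the symmetry
multiplicity ε<sub>h</sub>: amplitudes of acentric reflections follow the
Wilson (Rayleigh-type) law, centric ones a half-normal. For two related
structures the corresponding components are correlated with coefficient *r*
(the double-Wilson model), which makes the child amplitude conditional on its
parent

- **acentric:** F<sub>h</sub> | F<sub>Pa(h)</sub> ~ Rice(r·F<sub>Pa(h)</sub>, √(ε(1−r²)/2)),
- **centric:** F<sub>h</sub> | F<sub>Pa(h)</sub> ~ FoldedNormal(r·F<sub>Pa(h)</sub>, √(ε(1−r²))),

and reduces exactly to the univariate Wilson law at r = 0. Datasets are
organized in a single-parent DAG with one r per edge, so a whole fragment
screen or a Bijvoet-pair split can share one joint prior.

Observed intensities are modelled as I<sub>h,i</sub> ~ N(Σ<sub>h,i</sub>·F<sub>h</sub>², σ<sub>I</sub>),
where the per-observation scale Σ is predicted from experimental metadata
(image, detector position, wavelength, resolution, dataset one-hot) by a small
MLP. Inference maximizes the Monte-Carlo evidence lower bound

```
ELBO = (1/S) Σ_s [ Σ_i log p(I_i | F²_s Σ_s, σ_I)  −  Σ_h ( log q(F_h,s) − log p(F_h,s) ) ]
```

with truncated-normal surrogate posteriors q(F<sub>h</sub>) on [0, ∞),
reparameterized sampling throughout, and the structured prior p evaluated at
the same-sample parent amplitude. The correlation r can be fixed, scanned over
the geometric grid r<sub>k</sub> = 1 − 0.5<sup>k</sup>, or optimized directly
with the ELBO. Merged outputs come with the standard cross-validation metrics
(CC<sub>1/2</sub>, CC<sub>pred</sub>, CC<sub>anom</sub>) and weighted
difference structure factors
w = (1 + σ²(ΔF)/⟨σ²(ΔF)⟩ + α|ΔF|²/⟨|ΔF|²⟩)⁻¹.

A synthetic-data module generates unmerged observations with exactly this
statistical structure (correlated complex structure factors along a DAG,
centric/ε classes, Bijvoet pairs with a tunable anomalous component, smooth
image/resolution/detector scales, Gaussian noise with reported errors) plus
ground truth, so every claim is testable end to end.

## Worked example

Two related datasets (true r = 0.99, 5% of reflections perturbed, ~3
observations per reflection, ~50% intensity noise), merged first independently
to estimate r, then jointly under the bivariate prior:

```python
from dwmerge import dw
from dwmerge.refl_io import DatasetGraph
from dwmerge.simulate import benchmark_comparative, simulate_dataset
from dwmerge.vi import TrainingConfig, train
from dwmerge.postmerge import merge_posterior, difference_set

table, graph, truth, _ = simulate_dataset(benchmark_comparative(seed=7))
# -> 4982 observations, datasets: ['parent', 'child']

indep = train(table, DatasetGraph(list(graph.nodes), []),
              TrainingConfig(steps=1200, seed=7, scale_mode="fixed"))
m0 = merge_posterior(indep.posterior)
pairs = dw.make_pairs(m0[m0.dataset_id == "parent"], m0[m0.dataset_id == "child"])
r_hat, loglik = dw.fit_r_mle(pairs)
# -> fitted double-Wilson r: 0.937 (Pearson initializer 0.923)

result = train(table, graph.with_r(r_hat),
               TrainingConfig(steps=1200, seed=7, scale_mode="fixed"))
merged = merge_posterior(result.posterior)   # final ELBO: -4729.3
diffs = difference_set(merged[merged.dataset_id == "child"],
                       merged[merged.dataset_id == "parent"])
# -> 800 difference structure factors, mean |dF| 0.100, mean weight 0.541
```

The fitted r (0.937) sits below the generating value because measurement noise
in the independently merged amplitudes attenuates the estimate; the r-scan
(`dwmerge.postmerge.r_scan`) or direct optimization (`r_mode="optimized"`)
recovers values much closer to the truth — and on this benchmark the bivariate
prior raises the correlation between estimated and true ΔF from ≈0.40
(univariate) to ≈0.47.

The same pipeline is available from the shell via YAML run configs:

```bash
dwmerge simulate run.yaml   # write synthetic observations + ground truth
dwmerge merge run.yaml      # scale & merge, write merged.csv / trace / checkpoint
dwmerge fit-r run.yaml      # estimate r between merged parent/child
dwmerge scan-r run.yaml     # metrics across the grid r_k = 1 - 0.5^k
dwmerge diff run.yaml       # weighted difference structure factors
dwmerge cc run.yaml         # CC1/2 over random half-dataset repeats
```

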