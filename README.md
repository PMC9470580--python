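# glcmbayes

Bayesian dynamic profiling of gray-level co-occurrence (GLCM) texture
features for two-class image studies.

Classifiers applied to hand-crafted texture features report an accuracy
and stop. This package is for the step after (or instead of)
classification: given a two-class collection of grayscale images —
the motivating case is distinguishing brain-tumour MRI slice types —
it asks *how the texture features relate to one another*, which feature
best separates the classes, and how evidence on any feature propagates
to the rest. It is aimed at researchers doing radiomics-style texture
analysis who want an interpretable dependence model rather than a black
box.

## What it computes

1. **Texture features.** Per image, 13 Haralick-family statistics
   (energy `Σp²`, entropy `−Σp ln p`, contrast `Σ(i−j)²p`, two
   correlation variants, cluster shade/prominence, dissimilarity,
   homogeneities, autocorrelation, max probability, sum variance) from
   gray-level co-occurrence matrices `p(i,j)` over the standard
   `d ∈ {1..4} × θ ∈ {0°,45°,90°,135°}` offset grid, averaged over
   offsets.
2. **Feature ranking.** Symmetrised Kullback–Leibler divergence between
   class-conditional histograms, in bits; the top feature becomes the
   analysis target.
3. **Tree Bayesian network.** Features are discretized (default: four
   equal-frequency states) and a Chow–Liu maximum-weight spanning tree
   is learned over pairwise mutual information, with smoothed CPTs and
   exact inference:  `P(X₁..Xₙ) = Π P(Xᵢ | Pa(Xᵢ))`.
4. **Reports.** Arc strengths (KL force — which on a tree equals the
   arc's mutual information — relative weight, contribution %, Pearson
   r, G-test p-values), node forces (incoming/outgoing/total), the
   target-association table, tornado sensitivity, greedy dynamic
   profiling with Bayes factors `BF = P(s|H)/P(s)`, an
   evidence-path optimization tree, segment profiles with Welch-t and
   Bayesian (Student-t two-group) tests, and a target-evaluation report
   (reliability/precision/ROC/Gini per state; R, R², RMSE, NRMSE
   globally).

See `docs/methods.md` for the full model description and conventions.

## Worked example

Everything runs on synthetic data out of the box — two texture classes
(rough: unsmoothed noise; smooth: Gaussian-blurred noise) whose GLCM
features provably differ:

```python
from glcmbayes import (TreeBayesNet, OffsetSpec, apply_scheme,
                       default_texture_specs, extract_features,
                       fit_equal_frequency, generate_textures,
                       relative_entropy_importance, select_target)

images, labels = generate_textures(default_texture_specs(count=60, size=64), seed=0)
offsets = [OffsetSpec(d, a) for d in (1, 2) for a in (0, 45, 90, 135)]
features = extract_features(images, labels, offsets=offsets, n_levels=8)

ranking = relative_entropy_importance(features)
target = select_target(ranking)          # -> 'contrast' on this draw
discrete = apply_scheme(features, fit_equal_frequency(features, n_states=4))
results = TreeBayesNet(discrete, features=features, target=target).fit()
print(results.summary())
```

```
Tree Bayesian network (Chow-Liu / maximum-weight spanning tree)
  nodes: 13   arcs: 12   rows: 120
  MDL: 1797.76 bits (data 1290.10 + structure 507.66)

Arc strengths (KL force, bits):
       parent         child  kl_force  relative_weight  contribution_pct  mutual_information  pearson_r  p_value
 correlation1  correlation2    1.4296           1.0000           12.2825              1.4296     1.0000   0.0000
dissimilarity  homogeneity2    1.2485           0.8733           10.7263              1.2485    -0.9999   0.0000
 homogeneity2  homogeneity1    1.2485           0.8733           10.7263              1.2485     1.0000   0.0000
     contrast dissimilarity    1.1655           0.8152           10.0131              1.1655     0.9998   0.0000
  ...
```

The strongest arc joins the two correlation variants with Pearson
r = 1.0000 — they are algebraically the same quantity, and the report
surfaces that duplication; the KL-force and MI columns coincide because
deleting a tree arc loses exactly the endpoints' mutual information.
Profiling the lowest-contrast state and evaluating the network:

```python
for i, s in enumerate(results.dynamic_profile(target_state=0)[:3]):
    print(f"step {i}: {s.node} {s.state_label} "
          f"P(s|H)={100*s.posterior_prob:.2f}% BF={s.bayes_factor:.2f}")
perf = results.evaluate_target()
print(f"R={perf.r:.4f} R2={perf.r2:.4f} RMSE={perf.rmse:.4f}")
```

```
step 0: None None P(s|H)=25.00% BF=1.00
step 1: dissimilarity <=0.581339 P(s|H)=88.24% BF=3.53
step 2: entropy <=2.79255 P(s|H)=99.09% BF=3.96
R=0.9998 R2=0.9995 RMSE=0.0284
```

Each greedy step adds the single piece of hard evidence that most
raises the target state's posterior: knowing dissimilarity is in its
lowest state lifts P(contrast ≤ c₁) from the 25 % prior to 88 %
(BF 3.53), and the remaining nodes predict the target's continuous
value almost perfectly (R² ≈ 1) — the designed behaviour when one
smoothness factor drives every feature.

The same pipeline is available from the shell:

```bash
glcmbayes simulate textures --seed 0 --n 60 --out scratch/imgs
glcmbayes extract --images scratch/imgs --labels scratch/imgs/labels.csv --out features.csv
glcmbayes rank --features features.csv --out ranking.csv
glcmbayes run --seed 0 --out report/          # full pipeline + manifest
```

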