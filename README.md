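# wingmorph

Geometric-morphometric identification of female mosquitoes from wing
landmarks, with a molecular (COI) cross-check.

Accurate mosquito species identification underpins vector surveillance,
but classical keys need intact scales and legs that field specimens
often lack.  Wing shape is a robust alternative: 18 landmarks at
wing-vein junctions, superimposed by generalized Procrustes analysis
(GPA), carry enough signal to assign genus and species by linear
discriminant analysis (LDA).  `wingmorph` is a tested, reusable
implementation of that whole analysis chain for entomologists and
morphometricians:

* **GPA** — translation/scale/rotation removal (no reflections),
  centroid size CS = √Σᵢ‖xᵢ − x̄‖², consensus shapes, tangent-space
  shape variables;
* **size & allometry** — per-species centroid-size ANOVA with
  Bonferroni pairwise tests; permutation test of the multivariate
  regression of shape on log CS (R² = SS_model/SS_total, p from 500
  label permutations);
* **classification** — LDA under the Mahalanobis rule
  argmax_g [ln π_g − ½ d²(x, μ_g)], exact leave-one-out
  cross-validation (LOOCV) confusion matrices at genus and species
  rank, canonical variate analysis;
* **trees** — Saitou–Nei neighbor joining on the Mahalanobis distance
  matrix between species means, bootstrap supports from within-species
  specimen resampling; Newick I/O;
* **diagnostics** — Procrustes variance (disparity), observer-error
  analysis from replicated digitizations, and a landmark sampling
  evaluation curve (LaSEC);
* **COI arm** — HKY+Γ likelihood by Felsenstein pruning, AIC model
  selection over {JC69, K80, HKY85} × {±Γ}, NJ-seeded NNI maximum
  likelihood search, column bootstrap;
* **synthetic data** — a generator reproducing the sampling design of a
  19-species, 5-genus, 502-specimen field study, with known ground
  truth for every dataset.

Core pieces are scikit-learn style estimators
(`GeneralizedProcrustes`, `LandmarkLDA`) that compose with sklearn
model selection; module-level functions wrap them.

## Worked example

```python
import numpy as np
import wingmorph as wm

# a synthetic study: 19 species, 502 specimens, 18 landmarks, with the
# three confusable Aedes species pairs of the emulated study design
design = wm.SimulationDesign(
    merge_pairs=(("Ae_ann", "Ae_can"), ("Ae_cin", "Ae_ross"),
                 ("Ae_com", "Ae_pun")),
    seed=11)
dataset, truth = wm.simulate_landmark_dataset(design)

aligned = wm.generalized_procrustes(dataset)     # GPA
shapes = wm.tangent_projection(aligned)          # n x 36 shape variables

anova = wm.anova_centroid_size(aligned.centroid_sizes, dataset.species)
allom = wm.allometry_test(shapes, aligned.centroid_sizes, seed=0)
cm_sp = wm.loocv_confusion(shapes, dataset.species)
cm_ge = wm.loocv_confusion(shapes, dataset.genus, rank="genus")

print(f"centroid-size ANOVA  F = {anova.f_statistic:.1f}")
print(f"allometry            R2 = {100 * allom.r_squared:.1f}%, "
      f"p = {allom.p_value:.3f}")
print(f"species LOOCV        {100 * cm_sp.accuracy:.1f}%")
print(f"genus LOOCV          {100 * cm_ge.accuracy:.1f}%")
```

Output (seed 11):

```
centroid-size ANOVA  F = 205.8
allometry            R2 = 8.5%, p = 0.002
species LOOCV        86.9%
genus LOOCV          100.0%
```

The ANOVA confirms strong species-level size differences; the small but
significant allometric effect means size explains a few percent of the
pooled shape variation (at 500 permutations, p = 1/501 ≈ 0.002 is the
smallest attainable value).  Species-level LOOCV accuracy sits in the
high 80s–low 90s because the three merged species pairs are genuinely
confusable — their members reclassify at ~50–80% while all other
species stay at 94–100% — yet genus assignment is essentially perfect.
Running the row percentages (`cm_sp.row_percentages()`) reproduces that
confusion structure.

The same analysis is scriptable from the shell:

```sh
wingmorph simulate --out wings.csv --seed 11
wingmorph validate wings.csv --min-sites 3
wingmorph classify wings.csv --rank species --out confusion.csv
wingmorph run --landmarks wings.csv --out report/
```

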