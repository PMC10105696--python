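# molargm

Geometric morphometrics of reindeer (*Rangifer tarandus*) lower molars for
morphometric zooarchaeology: identifying the two Fennoscandian subspecies —
mountain reindeer (*R. t. tarandus*, wild and domestic) and forest reindeer
(*R. t. fennicus*) — from the 2D outline of the enamel–dentine junction on the
occlusal surface of isolated first and second lower molars (m1, m2), and
assigning archaeological teeth to subspecies against a modern reference
sample.

The package is written for zooarchaeologists and morphometricians who work
with tpsDig-style landmark files and need the complete analysis chain as
scriptable, tested building blocks.

## What it does

Each tooth is digitised as **9 fixed landmarks** at curvature extrema of the
enamel–dentine junction plus **66 sliding semilandmarks** spread equidistantly
along the outline (75 points, read from TPS files). The analysis chain is:

1. **Wear filtering.** Occlusal outlines change strongly with tooth wear
   (ordinal classes 0–4). Unworn (0) and heavily worn (4) teeth cannot be
   landmarked reliably and are excluded; analyses keep classes 1–3 for m1 and
   1–2 for m2, and are stratified by wear class.
2. **Superimposition.** Generalized Procrustes Analysis: every configuration
   is translated to a common centroid, scaled to unit centroid size
   CS = √Σᵢ‖xᵢ − x̄‖², and rotated to minimise the summed squared distances to
   an iteratively re-estimated consensus (reflections disallowed — teeth are
   chiral). Semilandmarks slide along their outline tangents to minimise the
   bending energy of the thin-plate spline relating each specimen to the
   consensus; all sliding amplitudes are solved jointly in one linear system.
3. **Shape statistics.** PCA of tangent-space coordinates; permutation
   Procrustes ANOVA decomposing shape variance over factors (wear, subspecies,
   status, sex, population) as sequential sums of squares with
   Freedman–Lane permutation p-values; size compared on log CS by ANOVA and
   pairwise exact Wilcoxon rank-sum tests under Benjamini–Hochberg FDR
   control; allometry tested by multivariate regression of shape on log CS.
4. **Classification.** Principal components retaining 95% of shape variance
   feed a canonical variate analysis (CVA); accuracy is estimated by
   leave-one-out cross-validated linear discriminant classification, and
   phenetic structure is summarised by a neighbour-joining tree of the
   Mahalanobis distances D²ᵢⱼ = (μᵢ−μⱼ)ᵀ W⁻¹ (μᵢ−μⱼ) between group means.
5. **Archaeological assignment.** Unknown teeth are Procrustes-aligned onto
   the modern consensus, projected into the modern shape space (they never
   influence consensus or eigenvectors) and assigned by a linear predictive
   discriminant with equal priors; results are tabulated per site.

Because comparable specimen data are not openly deposited, the package ships
a first-class synthetic generator (`molargm.simulate`) that plants the same
statistical structure — dominant wear deformation with size increasing along
wear classes, a subspecies mean-shape offset with realistic overlap, larger
forest reindeer, negligible sex effects, digitising noise — on a molar-like
outline, with the ground truth returned alongside every dataset.

## Worked example

Simulate two subspecies with a planted Mahalanobis separation Δ = 2 between
group means (n = 100 per group), superimpose, and cross-validate:

```python
import molargm as mg

design = mg.two_group_design(delta=2.0, n_per_group=100, seed=0)
dataset, truth = mg.simulate_dataset(design)

aligned = mg.gpa(dataset)                       # Procrustes superimposition
space = mg.pca_shapes(aligned)                  # tangent-space PCA
scores, k = mg.retain_components(space, 0.95)   # components w/ 95% variance
results = mg.CVA(scores, dataset.metadata["subspecies"]).fit()
print(results.summary())
```

```
Canonical Variate Analysis
  groups: fennicus (n=100), tarandus (n=100)
  retained components: 11; canonical axes: 1

Group means in canonical space:
            CV1
fennicus  1.076
tarandus -1.076

Mahalanobis distances between group means:
          fennicus  tarandus
fennicus     0.000     2.153
tarandus     2.153     0.000

Cross-validated confusion (rows = truth):
          fennicus  tarandus
fennicus        84        16
tarandus        12        88
Per-group accuracy: fennicus: 84.0%, tarandus: 88.0%
Overall accuracy: 86.0%
```

The estimated Mahalanobis distance (2.15) recovers the planted separation
(2.0), and the 86% leave-one-out accuracy sits near the analytic two-class
Gaussian expectation 100·Φ(Δ/2) ≈ 84.1% for this separation.

The same chain is available from the shell:

```sh
molargm simulate --out-dir data --seed 1 --n-per-cell 10
molargm cva --tps data/specimens.tps --metadata data/metadata.csv \
        --grouping subspecies --out confusion.csv
molargm run --config run.yaml       # full pipeline, all artifacts as CSV
```

## Layout

- `molargm.io` — TPS files (tpsDig dialect), metadata CSV, dataset assembly,
  wear filters
- `molargm.superimposition` — centroid size, OPA/GPA, equidistant resampling
- `molargm.bending` — thin-plate-spline bending energy, sliding semilandmarks
- `molargm.shape_stats` — PCA, Procrustes ANOVA, size tests, allometry
- `molargm.classification` — component retention, `CVA(...).fit()`,
  leave-one-out CV, projection and assignment of unknowns
- `molargm.phenetics` — neighbour joining, newick output
- `molargm.simulate` — template outline and synthetic datasets
- `molargm.pipeline` / `molargm.cli` — end-to-end runs behind a YAML config

See `docs/methods.md` for the statistical model, defaults and limitations.
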