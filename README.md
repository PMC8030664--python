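# svrlsm

Multivariate support-vector-regression lesion-symptom mapping (SVR-LSM)
for dissociating phonological and semantic verbal working memory after
left-hemisphere stroke — with the psychometric scoring, covariate
residualization and synthetic-cohort machinery needed to run and validate
the full pipeline without patient data.

**Who it is for.** Researchers relating behavioral deficits to lesion
anatomy across a stroke cohort: you have per-subject binary lesion masks
in a common template space, trial-level behavioral tables, and want
voxel/patch-level statistical maps of where damage predicts a deficit
after nuisance effects are removed.

## The method

1. **Scoring.** Working-memory span tasks are scored by linear
   interpolation of the list length at which accuracy crosses 75%
   (`span = L + (a_L − 75)/(a_L − a_{L+1})`, with virtual anchors of 100%
   one item below the task floor and 50% one above the ceiling). Single
   word input processing is scored as signal-detection
   `d′ = z(H) − z(F)` per foil condition (half-trial correction for
   extreme rates), and summarized by the first principal component of the
   two d′ scores — for correlation r the component explains (1+r)/2 of
   the variance with both loadings √((1+r)/2).
2. **Dependent variables.** Each span score is OLS-residualized on lesion
   size, the input-processing composite and the *other* span score, then
   min-max scaled to [0, 1].
3. **Design.** Masks are stacked into a subjects × voxels binary matrix;
   voxels lesioned in fewer than 5 subjects are dropped; voxels with
   identical lesion patterns are merged into *patches* whose
   multiplicities weight the RBF kernel
   `k(u,v) = exp(−γ Σ_j m_j (u_j − v_j)²)` — exactly equivalent to the
   full voxel computation, at a fraction of the cost.
4. **Mapping.** An ε-SVR predicts the scaled score from the lesion
   pattern. Hyperparameters (cost 0.01–10⁹, γ 10⁻⁹–10³, decade grid) are
   chosen by the permutation rank of the 5-fold cross-validated MSE; the
   per-patch statistic is the dual back-projection `β_j = Σ_i α_i X_ij`,
   and each patch's one-sided p-value is its β's rank in the β's of
   refits on shuffled scores. Patches are significant at p < 0.05 with
   β < 0 (damage should lower performance); p-values are not corrected
   across patches.

## Worked example

```python
import svrlsm as s
from svrlsm.model import HyperParams

# a 94-subject synthetic cohort: blob lesions, trial-level behavior
cohort = s.simulate_cohort(seed=1)
scores, _ = s.score_cohort(cohort.span_curves, cohort.detections,
                           lesion_volumes=cohort.lesion_voxel_counts)

model = s.SvrLsm.from_cohort(cohort.masks, scores["phon_span_scaled"].to_numpy())
grid = [HyperParams(c, g) for c in (0.1, 1, 10, 100)
        for g in (1e-4, 1e-3, 1e-2, 1e-1)]
res = model.fit(grid=grid, n_perm=199, seed=1)
print(res.summary())
```

prints

```
SVR lesion-symptom mapping results
==================================
subjects:              94
patches:               1112
voxels (covered):      1414
cost (C):              10
gamma:                 0.0001
epsilon:               0.1
model p (permutation): 0.005
permutations:          199
alpha:                 0.05  (one-sided, negative betas)
significant patches:   73 (6.6%)
seed:                  1
```

Reading it: 1414 voxels survive the 5-subject coverage filter and
compress into 1112 unique damage patterns (patches); the selected model
(C = 10, γ = 10⁻⁴) predicts the residualized phonological span better
than all 199 score-shuffled refits (p = 1/200); 73 patches show
significantly negative betas — damage there predicts a lower score.
`res.beta_volume()` / `res.p_volume()` / `res.significance_volume()`
expand the statistics onto the template grid, and comparing the
significant map with the cohort's ground-truth region gives a Dice
overlap of 0.30 here (`s.evaluate_recovery(...)`).

The same pipeline runs from the shell:

```bash
svrlsm simulate --out cohort --seed 1
svrlsm run-lsm --config config.yaml   # paths + grid + permutations + seed
```

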