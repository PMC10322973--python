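# voxelsem

Voxel-wise structural equation modeling of white-matter aging.

How are age-related declines in white matter and in cognition causally
related?  Given per-subject diffusion MRI scalar maps (FA, MD) and reaction
times from speeded working-memory tasks, `voxelsem` fits four competing
causal models **at every white-matter voxel** and selects the
best-supported one by AIC:

* **brain mediation** — age → WMI → cognition,
* **cognitive mediation** — age → cognition → WMI,
* **independent factor** — age affects both, no WMI–cognition link,
* **common factor** — a single factor G mediates both declines,

where WMI (white-matter integrity) is a latent variable indicated by the
voxel's sign-flipped FA and its MD, and cognition (BEH) is a latent variable
indicated by task mean RTs.  Each model is a covariance-structure SEM in RAM
form: implied covariance `Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ`, estimated by
minimising the ML discrepancy

    F_ML(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,

with `χ² = (N−1)·F_ML(θ̂)` and `AIC = χ² − 2·df`.  A voxel is assigned to
the lowest-AIC model that converged cleanly, has fit p > 0.05, and shows
latent correlations inside [−1, 1] (the Heywood screen); voxels failing all
filters stay unclassified.  Cluster-extent thresholds (mm³), overlap
percentages of the FA > 0.2 skeleton, path-significance (χ²-difference)
maps and atlas-label conjunctions complete the pipeline.

The package is aimed at neuroimaging statisticians who want a tested,
scriptable re-implementation of this voxel-wise SEM workflow, and ships a
synthetic-data generator with known causal ground truth (cohort, trial-level
behavior, FA/MD volumes) so every stage is verifiable end to end without
any subject data.  See `docs/methods.md` for the full model and numerical
details.

## Worked example

```python
import numpy as np
from voxelsem import synthetic_data as sd, voxel_pipeline as vp
from voxelsem.aging_models import ModelKind

cohort = sd.generate_cohort(seed=7)                      # 88 subjects, 3 age bands
behavior = sd.generate_behavior(cohort, seed=8)          # trial-level RTs
cohort = sd.attach_indicators(cohort, behavior.trials)
truth = sd.default_ground_truth(shape=(8, 8, 6))         # NULL / independent / cogmed slabs
volumes = sd.generate_volumes(cohort, behavior, truth, seed=9)

selection = vp.run_selection(volumes, cohort)            # fit 4 models per voxel
print(vp.overlap_table(selection.selected, selection.skeleton).to_string(index=False))
score = sd.recovery_score(selection.selected, truth)
print(f"cognitive-mediation recovery: {score.accuracy[ModelKind.COGNITIVE_MEDIATION]:.1%}")
_, median_r, _, _ = vp.fa_md_correlation_map(volumes.fa, volumes.md, selection.skeleton)
print(f"median voxel-wise cor(-FA, MD): {median_r:.3f}")
```

prints

```
 code        model  overlap_pct
    0 unclassified     4.166667
    1     brainmed     0.260417
    2       cogmed    47.135417
    3  independent    43.489583
    4       common     4.947917
cognitive-mediation recovery: 90.6%
median voxel-wise cor(-FA, MD): 0.561
```

Reading it: the overlap column says what percentage of the FA > 0.2 skeleton
each model claims after filtering and AIC selection (the rows partition the
skeleton).  In this 384-voxel simulation one third of the volume is pure
noise, one third truly independent-factor, one third truly
cognitive-mediation: cognitive mediation is recovered in 90.6% of its own
voxels, brain mediation wins essentially nowhere, and noise voxels split
between the two surviving models (both fit a null voxel; AIC then picks
either).  The median −FA/MD correlation of ≈ 0.55 is the generator's target
indicator reliability, the regime in which both measures plausibly indicate
one latent integrity construct.

The same workflow is available from the shell:

```bash
voxelsem simulate --out data/ --seed 7
voxelsem fit --fa data/fa.nii.gz --md data/md.nii.gz --cohort data/cohort.csv --out run/
voxelsem pathmap --fa data/fa.nii.gz --md data/md.nii.gz --cohort data/cohort.csv \
         --kind age-wm --out run/
voxelsem report --selection run/selection.nii.gz --fa data/fa.nii.gz \
         --md data/md.nii.gz --labels data/truth_labels.nii.gz --out run/
```

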