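# scpm — seed connectome-based predictive modeling

`scpm` predicts a subjective state — the feeling of stress induced by a
sustained aversive-image stressor — from how one brain region's *background*
functional connectivity changes during that stressor. It is aimed at
cognitive-neuroscience groups running within-subject task-fMRI designs who
want hypothesis-driven (seed-based) connectome-based predictive modeling
(CPM) with honest cross-validation and nonparametric inference, plus a fully
synthetic data generator so the whole chain is testable without any scanner
data.

## The method

For each participant and condition (Stressor, Neutral: 2 baseline + 6 image
runs of 66 s, TR 1 s), the pipeline

1. regresses out motion, tissue/global signals (+ derivatives), motion-spike
   indicators, and the trial-evoked response (boxcar ⊗ double-gamma HRF,
   + derivative), per run;
2. bandpass filters residuals to 0.01–0.1 Hz (the 0.17 Hz stimulus rate is
   outside the passband), concatenates runs into 132-s epochs
   (baseline/early/mid/late), and computes seed-to-voxel Fisher-z maps
   z = atanh(r) with epoch-minus-baseline differentials;
3. defines stressor-modulated clusters at the group level (voxelwise
   p < .001, bi-sided face-adjacency clustering, permutation-derived cluster
   extent for FWER α = .05);
4. fits the seed-CPM: per leave-one-out fold, clusters whose cluster-mean
   connectivity Spearman-correlates with the outcome (two-sided p < .05)
   form a positive and a negative network; OLS on each network's mean
   strength predicts the held-out participant. Predictive power is
   r_s(predicted, observed); significance comes from re-running everything
   on shuffled outcomes, p = (1 + #{null ≥ observed}) / (1 + n_perm);
5. tests cross-model feature consistency with linked shuffles (one
   participant relabeling per iteration shared by all outcomes) and finds
   anatomically overlapping every-fold clusters across seeds.

The model family per outcome is 3 seeds × 2 windows × 2 references = 12
models (Bonferroni per-model α = 0.05/12 = 0.0042).

See `docs/methods.md` for assumptions, numerical conventions, and what the
synthetic generator does and does not emulate.

## Worked example

The demo pipeline simulates a 16-participant study in which each
participant's seed–cluster coupling rises under the stressor by a
participant-specific amount, and ratings drift in proportion to that
coupling; it then runs the full chain and fits the predictive model:

```python
from scpm import run_pipeline

bundle = run_pipeline({"out_dir": "demo_out", "seed": 5,
                       "n_perm": 100, "extent_n_perm": 100})
res = bundle["result"]
print(len(bundle["clusters"]), bundle["cluster_extent_min"])
print(round(res.r_s["positive"], 2), res.p_value["positive"])
```

prints

```
1 2
0.63 0.009900990099009901
```

meaning: one supra-threshold stressor-modulated group cluster (minimum
extent 2 voxels) was found at the planted location; the positive network
built on it predicts held-out participants' stressor-induced stress ratings
with r_s = 0.63, and none of the 100 shuffled-outcome re-runs matched that
performance (p = 1/101 ≈ 0.0099).

The same stages are scriptable from the shell:

```bash
scpm simulate --out sim --seed 1
scpm connectivity --bold sim/bold_Stressor.nii.gz \
    --confounds sim/confounds_Stressor.tsv --events sim/events_Stressor.tsv \
    --seed-mask sim/seed_mask.nii.gz --dataset sim/dataset.json \
    --condition Stressor --out maps
scpm fit --features features.tsv --outcome-file outcomes.tsv \
    --scheme loo --n-perm 1000 --seed 7 --out result.json
```

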