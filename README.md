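# slgraph

Synchronization-likelihood functional connectivity and graph-theoretic
group analysis for resting-state EEG.

`slgraph` is built for a common clinical-EEG study design: two groups
(e.g. bipolar-disorder patients vs. healthy controls) with eyes-closed
resting recordings on a 29-channel 10–20 montage, compared through

1. **Synchronization likelihood (SL)** — a generalized-synchronization
   measure between every pair of channels. Each channel is time-delay
   embedded, `X_i = (x_i, x_{i+l}, …, x_{i+(m−1)l})`; for every reference
   vector a critical distance is fixed implicitly so that a fraction
   `p_ref` of candidate vectors within the window `w1 < |i−j| < w2`
   count as recurrences, and the SL of a pair is the fraction of one
   channel's recurrences shared by the other. SL ≈ `p_ref` for
   independent signals and is exactly 1 for identical or affinely
   rescaled signals. Band-specific embedding parameters follow a
   frequency-prior scheme: `l = round(fs/3·HF)`, `m = round(3·HF/LF)+1`,
   `w1 = 2l(m−1)`, `w2 = w1 + round(n_ref/p_ref)`.
2. **Weighted graph metrics** on density-thresholded SL matrices —
   clustering coefficient *C*, characteristic path length *L* (edge
   length 1/weight), global/local efficiency *E_g*, *E_l*, node strength
   *s*, betweenness *b*, and small-world indices *γ = C/C_rand*,
   *λ = L/L_rand*, *σ = γ/λ* against degree-preserving rewired
   surrogates, across connection densities from 5 % to 100 %.
3. **Permutation statistics** — covariate-adjusted (Freedman–Lane)
   label-permutation tests on mean SL and every graph metric, the
   network-based statistic (NBS) for edge-wise inference with
   family-wise-error control via the maximal suprathreshold component
   size, partial correlations between network metrics and clinical
   scores (MADRS/YMRS), and standard demographic-table tests.

Because clinical recordings are rarely shareable, the package ships a
first-class synthetic cohort generator (`slgraph.datasets`): channels
are convex mixtures of band-limited shared and private sources with a
plantable alpha-band coupling deficit over fronto-central/centro-parietal
channels (F4, FC3, FC4, Cz, CPz), EOG contamination, high-amplitude
artifact epochs, and clinical scores with a controllable correlation to
the planted severity. Every downstream stage is tested against this
known ground truth.

## Worked example

```python
import numpy as np
import slgraph as sg
from slgraph.preprocess import PreprocessConfig

# 6 patients + 6 controls, 20-s recordings at 250 Hz, planted alpha deficit
spec = sg.CohortSpec(n_patients=6, n_controls=6, fs=250.0, duration=20.0,
                     artifact_rate=0.5, seed=7)
recordings, metas = sg.generate_cohort(spec)

params = sg.embed_parameters(8, 12, 250.0, p_ref=0.05, n_ref=5)  # alpha band
pp = PreprocessConfig(n_keep=4)
mats, groups = [], []
for rec, meta in zip(recordings, metas):
    alpha = sg.preprocess_recording(rec, pp, bands=["alpha"])["alpha"]
    mats.append(sg.sl_matrix(alpha, params))
    groups.append(meta.group)

means = np.array([sg.mean_sl(m) for m in mats])
res = sg.permutation_test(means, groups, n_perm=999, seed=1)
nbs = sg.nbs(np.stack([m.values for m in mats]), groups,
             t_threshold=2.61, n_perm=999, seed=1)
```

Printing the results of this exact script gives:

```
mean alpha SL  patients: 0.1057
mean alpha SL  controls: 0.1420
permutation test: t = 0.92, p = 0.425
NBS: largest component has 27 links, corrected p = 0.016
sample links: ['Fp1-FC4', 'Fp2-FC3', 'Fp2-Cz', 'AFz-FC4', 'AFz-FC3']
```

The patients' whole-scalp mean alpha SL is lower, but with six subjects
per group and sizeable between-subject variability the global
permutation test is inconclusive (p = 0.425). The network-based
statistic, which pools evidence over connected sets of edges, still
localizes the planted fronto-central deficit decisively (corrected
p = 0.016): every listed link touches the channels carrying the planted
coupling reduction. At study-scale sample sizes the mean-SL test
becomes informative as well.

The same analysis runs end to end from the shell:

```bash
slgraph simulate --out cohort/ --n-patients 6 --n-controls 6 \
    --duration 20 --fs 250 --seed 7
slgraph run-all --input cohort/ --out results/ --band alpha --seed 1
```

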