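# dynrad — noise stability of dynamic radiomic feature curves

Radiomic studies of cine cardiac MRI usually extract features from a single
end-systolic or end-diastolic frame. Extracting features from *every* frame
of the cardiac cycle instead yields a **feature curve** — the trajectory of
one feature over the cycle — which can carry information about cardiac
dynamics. Before feature curves can feed classification models, one has to
know whether their shape survives image noise.

`dynrad` quantifies that: it adds controlled zero-mean Gaussian noise to
cine sequences at several levels with seeded replicates, extracts a battery
of 2D radiomic features (first-order statistics, grey level co-occurrence
matrix, grey level size zone matrix, each on the raw image, the four
undecimated Haar wavelet sub-bands and the rotation-invariant uniform local
binary pattern map), assembles the per-frame values into curves, and scores
each feature's stability per subject as the **mean pairwise MAE (mpMAE)**:

- For subject *s* and feature *f*, every noise instance *i* (the noise-free
  original plus each level x replicate) yields a curve
  f<sub>i</sub>(t), t = 1..T.
- All curves are normalized by the *reference* (noise-free) curve's mean
  μ<sub>ref</sub> and standard deviation σ<sub>ref</sub>, so the reference maps
  to mean 0 / std 1. Features whose reference curve is constant
  (σ<sub>ref</sub> = 0) cannot be normalized and are excluded.
- mpMAE = mean over all unordered instance pairs (i, j) of
  (1/T) Σ<sub>t</sub> |f̃<sub>i</sub>(t) − f̃<sub>j</sub>(t)|; 0 is perfect
  stability. A **within-level mpMAE** restricts pairs to instances of the
  same noise level, separating sensitivity to the *amount* of noise from
  sensitivity to the particular noise realization.

Per-subject fractional rankings on mpMAE are compared across subjects with
Spearman correlation and aggregated into a consensus ranking by median
rank. Finally, a per-feature decision tree (trained on 12-frame subsampled
curves of all noise instances, tested on noise-free curves only) probes
whether more stable features are also more useful for a five-class
diagnostic task.

Because real cine data cannot be redistributed, the package ships a seeded
**contracting-phantom generator**: an annular "myocardium" around a bright
blood pool that contracts and thickens over a closed cycle with a smooth,
subject-specific texture field. A cohort generator draws per-subject
geometry (including five caricatured diagnostic classes) and frame counts
from 12 to 50, so the whole analysis runs end-to-end with no downloads.

## Worked example

```python
from dynrad import (PhantomParams, generate_phantom, rescale_to_unit,
                    make_noise_instances, ExtractionConfig, extract_instances,
                    build_curves, normalize_all, compute_stability)

seq = rescale_to_unit(generate_phantom(PhantomParams(n_frames=24)))
instances = make_noise_instances(seq, [0.01, 0.02, 0.03, 0.04],
                                 replicates=5, base_seed=2)     # 21 instances
table = extract_instances(instances, ExtractionConfig(
    filters=("original",), families=("firstorder",)))
normalized, report = normalize_all(build_curves(table))
stab = compute_stability(normalized, report).set_index("feature_id")
for fid in ("original_firstorder_Mean", "original_firstorder_Variance"):
    row = stab.loc[fid]
    print(f"{fid}: mpMAE={row.mpMAE:.3f} within-level={row.within_level_mpMAE:.3f}")
```

prints

```
original_firstorder_Mean: mpMAE=0.806 within-level=0.776
original_firstorder_Variance: mpMAE=31.170 within-level=1.929
```

The ROI mean is unbiased under zero-mean noise, so its two scores agree
(its curves scatter symmetrically around the reference). The ROI variance
is inflated by the squared noise level, so curves from the same level agree
(small within-level score) while different levels are shifted apart (large
overall score) — the signature of a feature sensitive to the amount of
noise but not to the specific realization.

The same analysis is available from the shell:

```bash
dynrad run --config config.json          # simulate → extract → curves →
                                         # stability → consensus [→ classify]
dynrad report --config config.json      # per-feature curve panels (PNG)
```

All stages cache their outputs and re-run only when the relevant part of
the configuration changes; every table carries the config hash.

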