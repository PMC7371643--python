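"""Compare ring/fiber prevalence between stimulation-like conditions.

Four presets shift the generated ring:fiber mixture the way increasing
neuronal activity remodels the dendritic F-actin lattice.  Per image the
(ring, fiber) area-fraction pair is measured inside the dendritic mask;
per-condition uncertainty comes from bootstrap resampling and pairwise
differences from the bivariate randomization test.
"""

import matplotlib

matplotlib.use("Agg")

from dataclasses import replace

import actinseg as a
from actinseg import pipeline as pl
from actinseg.stats import bootstrap_means

order = ["high_Mg_low_Ca", "0Mg_Gly_Bic", "high_K", "Glu_Gly"]
presets = a.condition_presets(a.SceneSpec(image_shape=(192, 192), n_processes=2))

images, conditions, truths = {}, {}, {}
for ci, name in enumerate(order):
    for j in range(6):
        img_id = f"{name}_{j}"
        img, truth = a.generate_scene(replace(presets[name], seed=1000 * ci + j))
        images[img_id] = img
        conditions[img_id] = name
        truths[img_id] = truth

report = pl.run_condition_experiment(
    images, conditions, pl.truth_segmenter(truths),
    pairs=[(order[0], order[-1]), (order[0], order[1])],
    n_rep=5000, seed=0)

table = report["table"]
for name in order:
    sub = table[table.condition == name]
    boot = bootstrap_means(
        sub[["ring_area_fraction", "fiber_area_fraction"]].to_numpy(),
        n_rep=2000, seed=1, condition=name)
    sd = boot.mean_vectors.std(axis=0)
    print(f"{name}: ring {sub.ring_area_fraction.mean():.3f}+-{sd[0]:.3f}, "
          f"fiber {sub.fiber_area_fraction.mean():.3f}+-{sd[1]:.3f} (n={len(sub)})")

print()
for _, row in report["stats"]["tests"].iterrows():
    print(f"{row.condition_a} vs {row.condition_b}: "
          f"D_raw = ({row.d_raw[0]:+.3f}, {row.d_raw[1]:+.3f}), "
          f"p = {row.p_value:.2e} (empirical tail {row.p_empirical:.4f})")
# The parametric p comes from a bivariate-normal fit to the permutation
# cloud (chi-squared tail of the Mahalanobis distance); the empirical tail
# fraction is reported alongside and can never drop below 1/(n_rep+1).
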