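"""Train the 3-D CNN on a small phantom cohort (a few minutes on one CPU).

Runs the full imaging arm: simulate 80 single-lesion phantoms, segment them,
extract 16-voxel cubes, train with 5-fold cross-validation and 15-rotation
augmentation, and report the pooled out-of-fold Spearman correlation between
predicted and RNA-derived CytAct.  Small cohorts need a few more epochs than
the full-size run (300 phantoms, 10-fold; see scripts/acceptance.py).
"""

from immunopet import ModelConfig
from immunopet.experiments import cytact_recovery_experiment

cv = cytact_recovery_experiment(
    n=80, seed=1, folds=5, cfg=ModelConfig(rng_seed=1, epochs=8), verbose=True
)

print(f"pooled out-of-fold Spearman rho : {cv.pooled_spearman:.3f}")
print(f"p-value                         : {cv.pooled_spearman_p:.2e}")
print(f"per-fold validation MSE         : "
      + ", ".join(f"{v:.2f}" for v in cv.fold_val_loss))
# rho well above 0 (about 0.7 here) means the network reads the rim/core
# uptake texture that encodes the latent immune score; with only 64 training
# samples per fold expect a lower rho than the 300-phantom run's ~0.87.
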