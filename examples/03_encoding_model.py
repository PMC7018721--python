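"""Fit a per-neuron encoding model and inspect what it recovered.

A planted cell responds to 8-16 Gabor features through a sigmoid.  The
model selects features by correlation (13-point threshold grid), fits an
evidence-maximized ridge regression plus sigmoid rescaling, and picks the
threshold by ten-fold cross-validation.  Printed: CV prediction
performance, the selected-feature count, and the correlation between the
planted and the recovered weights.
"""

import numpy as np

from neurorecon import (
    SimulationConfig,
    build_gabor_bank,
    encode_images,
    fit_encoding_cv,
    fit_reverse_scale,
    forward_filter,
    generate_images,
    generate_population,
    make_cv_split,
    simulate_responses,
)

cfg = SimulationConfig.recovery_benchmark(seed=7, n_cells=2)
bank = build_gabor_bank()
images = generate_images(cfg)
bank = fit_reverse_scale(bank, images)
pop = generate_population(cfg, bank, images)
tensor, _ = simulate_responses(pop, images, cfg, bank)
features = encode_images(bank, images)
splits = make_cv_split(cfg.n_images, 10, seed=7)

for k in range(2):
    model = fit_encoding_cv(tensor.zscored[k], features, splits, cell_id=k)
    w_full = np.zeros(bank.f)
    w_full[model.selected_features] = model.weights
    w_corr = np.corrcoef(pop.weights[k], w_full[pop.feature_sets[k]])[0, 1]
    ff = forward_filter(model, bank)
    print(
        f"cell {k}: cv r = {model.cv_performance:.2f}, "
        f"threshold = {model.threshold:.3f}, "
        f"{model.n_features} features selected ({pop.feature_sets[k].size} planted), "
        f"true-weight correlation = {w_corr:.2f}, "
        f"forward-filter energy = {np.linalg.norm(ff):.2f}"
    )
# cv r ~0.9 and weight correlation ~0.8-0.9: the fitting chain recovers
# the planted feature code when responses carry enough graded signal.
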