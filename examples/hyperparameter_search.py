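"""Select penalties by module correlation over a small grid.

Scores every (lambda1, lambda2, beta1, beta2) combination by the mean
|Pearson correlation| of the latent score pairs over extracted modules,
the same criterion used to pick the operating point on real data, and
refits at the winning combination.
"""

import warnings

from hrspls import SolverConfig, generate_paired_omics, grid_search, standardize_columns

X, Y, _ = generate_paired_omics(
    n_samples=60, p_features_x=80, q_features_y=70,
    support_size_x=10, support_size_y=10, snr=2.0, seed=11,
)
Xz, _ = standardize_columns(X)
Yz, _ = standardize_columns(Y)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    best, table = grid_search(
        Xz, Yz, SolverConfig(seed=11),
        lambda1_grid=[0.1, 0.5], lambda2_grid=[0.1, 0.5],
        beta1_grid=[0.1, 0.5], beta2_grid=[0.1, 0.5],
        search_modules=2,
    )
print(table.sort_values("mean_abs_pcc", ascending=False)
      .head(5).to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"selected: lambda1={best.lambda1} lambda2={best.lambda2} "
      f"beta1={best.beta1} beta2={best.beta2}")
# each row is one penalty combination; mean_abs_pcc is its module-quality
# score, and the argmax row becomes the configuration used for the final fit.
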