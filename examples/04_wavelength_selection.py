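"""Reduce the wavelength set with the beta-coefficient and VIP rules.

Fits a PLSR on all bands, retains only the informative wavelengths under
each rule, refits on the reduced matrix, and compares the evaluations.
"""

import gingerspec as gs

dataset = gs.extract_dataset(gs.generate_dataset(
    gs.SyntheticConfig(n_samples=40, cube_rows=16, cube_cols=16, seed=5)))
train, test = gs.split_dataset(dataset, gs.SplitSpec())

j_star, _ = gs.select_lvs_loocv(train.X, train.y, max_lvs=10)
parent = gs.fit_plsr(train.X, train.y, j_star)
parent_rep = gs.evaluate(parent, train.X, train.y, test.X, test.y)
print(f"full-spectrum PLSR (J={j_star}, {dataset.n_bands} bands): "
      f"R2_test={parent_rep.r2_test:.3f} RPD_test={parent_rep.rpd_test:.2f}")

for rule in (gs.beta_select, gs.vip_select):
    sel = rule(parent, wavelengths=dataset.wavelengths)
    model, rep = gs.refit_on_selection(train.X, train.y, test.X, test.y,
                                       sel, max_lvs=10)
    lo, hi = sel.retained_wavelengths.min(), sel.retained_wavelengths.max()
    print(f"{sel.method:16s}: threshold {sel.threshold:.4g} keeps "
          f"{sel.n_retained}/{dataset.n_bands} bands ({lo:.0f}-{hi:.0f} nm) "
          f"-> R2_test={rep.r2_test:.3f} RPD_test={rep.rpd_test:.2f}")
# Both rules concentrate on the constituents' absorption features; a small
# accuracy loss against the full spectrum is the usual price of a sparser,
# cheaper acquisition.
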