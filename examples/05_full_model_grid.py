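"""Run the full 32-model study grid on a reduced synthetic campaign.

8 pre-treatments x {PLSR, LASSO} = 16 models, plus 8 x {beta, VIP}
selection refits = 32 evaluation rows, all sharing one 80/20 split.
A reduced campaign keeps this example fast; drop the size overrides to
reproduce the full 89-sample study conditions.
"""

import gingerspec as gs

dataset = gs.extract_dataset(gs.generate_dataset(
    gs.SyntheticConfig(n_samples=40, cube_rows=16, cube_cols=16, seed=0)))
result = gs.run_grid(dataset, gs.GridConfig(max_lvs=10, n_alphas=25),
                     outdir="scratch/example_grid")

print(f"{len(result.rows)} evaluation rows, {len(result.failures)} failures")
df = result.to_frame()
cols = ["treatment", "model_type", "selection_method", "hyperparameter",
        "r2_test", "rmse_test", "rpd_test", "lod", "n_bands", "quality"]
print(df[cols].round(3).to_string(index=False))

print("\nbest model per family (by test RPD):")
for family, row in gs.best_models(result).items():
    print(f"  {family:10s}: {row.treatment:5s} "
          f"R2={row.r2_test:.3f} RPD={row.rpd_test:.2f} LOD={row.lod:.3f}")
# grid_results.csv, best_models.json, manifest.json and the winners'
# measured-vs-predicted scatter CSVs land in scratch/example_grid/.
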