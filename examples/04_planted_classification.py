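"""Train the bound ensembles and map planted forest on a small landscape.

Runs the pipeline through prediction on a 50x50 world: three 20-member
balanced forest ensembles (one per label grade) vote percent-planted per
cell, the three bounds average into the final value, cells at >= 50% are
mapped planted, and national-map countries bypass the model.
"""

from plantedmap import PipelineConfig, WorldConfig
from plantedmap.pipeline import PipelineRun

cfg = PipelineConfig(
    world=WorldConfig(grid_shape=(50, 50), n_insitu_points=300, n_plots=1000, seed=3),
    seed=3,
    n_members=5,          # trimmed from 20 for a quick demonstration
    run_genus_cv=False,
)
run = PipelineRun(cfg)
run.simulate()
run.fuse()
run.impute()
run.train()
records = run.predict()
run.validate()

model_cells = records["source"] == "model"
print(f"forest cells: {len(records)}, model-predicted: {int(model_cells.sum())}, "
      f"national-map override: {int((~model_cells).sum())}")
print(f"predicted planted share: {(records['type'] == 'planted').mean():.1%}")
print("\nper-bound mean percent planted over model cells:")
for col in ("p_lower", "p_mid", "p_upper", "p_mean"):
    print(f"  {col:<8} {records.loc[model_cells, col].mean():.3f}")

vs = run.validation["vs_truth"]
print(f"\nagainst the hidden truth: accuracy {vs['accuracy']:.3f}, "
      f"F1 {vs['f1']:.3f}, planted-fraction error {vs['fraction_error']:.3f}")
# The lower bound is the most conservative labelling, so its percent runs
# below the upper bound's on average; the final map thresholds the mean of
# the three at 50%.
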