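"""Fuse the six evidence sources into three quality-graded label sets.

Shows the lower/mid/upper integration rules at work: the same landscape
yields nested planted sets (conservative -> liberal) with the low-
confidence "grey" cells excluded from the lower and mid training sets.
"""

import pandas as pd

from plantedmap import WorldConfig, generate_world, world_to_tables
from plantedmap import aggregate_insitu, apply_forest_mask, qodi_label

world = generate_world(WorldConfig(grid_shape=(60, 60), seed=42))
cells, points, _ = world_to_tables(world)
cells = cells.set_index("cell_id", drop=False)

evidence = cells.filter(like="src_").rename(columns=lambda c: c[4:])
evidence["insitu_cn"] = aggregate_insitu(points, world.grid).to_numpy()
forest = apply_forest_mask(cells)

print(f"{len(forest)} of {len(cells)} cells pass the 5 m forest mask\n")
print(f"{'level':<8}{'planted':>9}{'natural':>9}{'excluded':>10}")
planted_sets = {}
for level in ("lower", "mid", "upper"):
    labels = qodi_label(evidence.loc[forest.index], level)
    counts = labels.value_counts()
    print(f"{level:<8}{counts.get('planted', 0):>9}{counts.get('natural', 0):>9}"
          f"{counts.get('excluded', 0):>10}")
    planted_sets[level] = set(labels.index[labels == "planted"])

assert planted_sets["lower"] <= planted_sets["mid"] <= planted_sets["upper"]
print("\nplanted sets nest: lower <= mid <= upper, and the upper (most"
      "\nliberal) level never excludes a cell — its grey area is empty.")
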