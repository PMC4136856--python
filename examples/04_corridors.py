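"""Map movement corridors with least-cost and circuit models.

The suitability map is inverted into a cost surface (cost 1-100), 5
detection points on each side of the valley give 25 candidate least-cost
pathways, and the circuit model's omnidirectional current map summarises
where movement would concentrate if animals diffused over all routes.
"""

import numpy as np

from corridorscape.benchmarks import valley_scenario_case
from corridorscape.circuit import (
    measure_corridor_width, omnidirectional_current, row_transect,
)

case = valley_scenario_case(seed=11)
paths = case["paths"]

opt = paths.optimal
print(f"{len(paths.paths)} pathways "
      f"({sum(p.flag == 'alternative' for p in paths.paths)} alternatives)")
print(f"optimal corridor: {opt.length_m / 1000:.1f} km long, "
      f"cost index {opt.cost_index:.0f} per 100 m")
indices = [p.cost_index for p in paths.paths]
print(f"cost index across pathways: {np.mean(indices):.0f} "
      f"(range {min(indices):.0f} - {max(indices):.0f})")

current = omnidirectional_current(case["cost"], buffer_width=4,
                                  n_perimeter_nodes=12, pair_subsample=30,
                                  seed=0)
mid_row = opt.cells[len(opt.cells) // 2][0]
width = measure_corridor_width(current, row_transect(current, mid_row))
print(f"corridor width on a transect through the optimal path: "
      f"{width / 1000:.1f} km (cells above the 75% current quantile)")
# the current map marks the same valley crossing as the least-cost paths,
# but as a band whose width summarises corridor redundancy
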